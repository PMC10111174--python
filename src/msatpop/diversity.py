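"""Per-population diversity statistics and related test batteries.

Covers observed/expected heterozygosity with the unbiased small-sample
correction, private alleles, Wright's fixation indices via Nei's basic
statistics, chi-square HWE tests with Yates continuity correction,
permutation tests of genotypic linkage disequilibrium, moment estimators
of null-allele frequency, four individual heterozygosity indices,
Kruskal-Wallis/Dunn group comparisons, and the second-order rate-of-change
statistic for cluster-number support.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "DiversityTable",
    "FstatResult",
    "NullAlleleEstimates",
    "HetIndices",
    "ClusterSupport",
    "population_diversity",
    "global_fstats",
    "hwe_tests",
    "ld_tests",
    "null_allele_estimates",
    "individual_heterozygosity",
    "compare_groups",
    "evanno_delta_k",
    "allele_frequencies",
]


# ---------------------------------------------------------------------------
# Allele frequency helpers
# ---------------------------------------------------------------------------

def allele_frequencies(gm: GenotypeMatrix) -> list[dict[str, dict[int, float]]]:
    """Per-locus, per-population allele frequencies from typed genotypes.

    Returns a list (one entry per locus) of ``{population: {allele: freq}}``;
    populations untyped at a locus are omitted from that locus's dict.
    """
    out: list[dict[str, dict[int, float]]] = []
    pop_idx = gm.population_index()
    for l in range(gm.n_loci):
        locus: dict[str, dict[int, float]] = {}
        for pop, idx in pop_idx.items():
            alleles = gm.calls[idx, l, :].ravel()
            alleles = alleles[alleles != MISSING]
            if alleles.size == 0:
                continue
            counts = Counter(alleles.tolist())
            total = alleles.size
            locus[pop] = {a: c / total for a, c in counts.items()}
        out.append(locus)
    return out


def _locus_pop_stats(gm: GenotypeMatrix):
    """Per (locus, pop): typed count, observed het, allele count dict."""
    pop_idx = gm.population_index()
    res: list[dict[str, tuple[int, int, Counter]]] = []
    for l in range(gm.n_loci):
        locus: dict[str, tuple[int, int, Counter]] = {}
        for pop, idx in pop_idx.items():
            geno = gm.calls[idx, l, :]
            typed = geno[geno[:, 0] != MISSING]
            if len(typed) == 0:
                continue
            het = int((typed[:, 0] != typed[:, 1]).sum())
            counts = Counter(typed.ravel().tolist())
            locus[pop] = (len(typed), het, counts)
        res.append(locus)
    return res


def _unbiased_gene_diversity(counts: Counter, n_genes: int) -> float:
    """Nei's unbiased gene diversity n(1 - sum p^2)/(n - 1) over n gene copies."""
    if n_genes < 2:
        return float("nan")
    p2 = sum((c / n_genes) ** 2 for c in counts.values())
    return n_genes * (1.0 - p2) / (n_genes - 1)


# ---------------------------------------------------------------------------
# Per-population diversity table
# ---------------------------------------------------------------------------

@dataclass
class DiversityTable:
    """Per-population summary with a trailing unweighted means row."""

    table: pd.DataFrame  # index: population labels + "Mean"

    def population_row(self, pop: str) -> pd.Series:
        return self.table.loc[pop]

    @property
    def means(self) -> pd.Series:
        return self.table.loc["Mean"]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="Code")


def population_diversity(gm: GenotypeMatrix, unbiased: bool = True) -> DiversityTable:
    """Compute n, N_A, P_A, H_O, H_E and F_IS per population.

    H_O and H_E are unweighted means over loci typed in the population;
    F_IS = 1 - mean(H_O)/mean(H_E) (ratio of means).  Private alleles are
    counted per (locus, allele) combination present in exactly one
    population.
    """
    stats_ = _locus_pop_stats(gm)
    pops = gm.populations()
    if not pops:
        raise ValueError("empty genotype matrix")

    # which populations carry each (locus, allele)
    carriers: dict[tuple[int, int], set[str]] = {}
    for l, locus in enumerate(stats_):
        for pop, (_, _, counts) in locus.items():
            for a in counts:
                carriers.setdefault((l, a), set()).add(pop)

    pop_sizes = {p: len(ix) for p, ix in gm.population_index().items()}
    rows = []
    for pop in pops:
        ho_vals, he_vals = [], []
        n_alleles = 0
        n_private = 0
        typed_any = False
        for l, locus in enumerate(stats_):
            if pop not in locus:
                continue
            typed_any = True
            n_typed, het, counts = locus[pop]
            ho_vals.append(het / n_typed)
            n_genes = 2 * n_typed
            if unbiased:
                he_vals.append(_unbiased_gene_diversity(counts, n_genes))
            else:
                he_vals.append(1.0 - sum((c / n_genes) ** 2 for c in counts.values()))
            n_alleles += len(counts)
            n_private += sum(1 for a in counts if carriers[(l, a)] == {pop})
        if not typed_any:
            raise ValueError(f"population {pop!r} has no typed genotypes at any locus")
        ho = float(np.mean(ho_vals))
        he = float(np.nanmean(he_vals))
        fis = 1.0 - ho / he if he > 0 else float("nan")
        rows.append(
            dict(n=pop_sizes[pop], N_A=n_alleles, P_A=n_private, H_O=ho, H_E=he, F_IS=fis)
        )
    table = pd.DataFrame(rows, index=pops)
    table.loc["Mean"] = table.mean(axis=0, skipna=True)
    return DiversityTable(table)


# ---------------------------------------------------------------------------
# Global F statistics (Nei basic statistics, Nei & Chesser corrections)
# ---------------------------------------------------------------------------

@dataclass
class FstatResult:
    F_IS: float
    F_ST: float
    F_IT: float
    H_O: float
    H_S: float
    H_T: float
    flags: list[str] = field(default_factory=list)

    def decomposition_residual(self) -> float:
        """(1-F_IT) - (1-F_IS)(1-F_ST); zero for ratio-of-means estimates."""
        return (1 - self.F_IT) - (1 - self.F_IS) * (1 - self.F_ST)


def global_fstats(gm: GenotypeMatrix, corrected: bool = True) -> FstatResult:
    """Nei's basic statistics averaged over loci as ratios of means.

    With ``corrected=True`` (default) H_S and H_T carry the Nei & Chesser
    small-sample corrections based on the harmonic mean sample size; with
    ``corrected=False`` the raw gene diversities are used.
    """
    if len(gm.populations()) < 2:
        raise ValueError("global F statistics require at least two populations")
    stats_ = _locus_pop_stats(gm)
    ho_l, hs_l, ht_l = [], [], []
    for locus in stats_:
        if len(locus) < 2:
            continue
        s = len(locus)
        n_typed = np.array([v[0] for v in locus.values()], dtype=float)
        n_harm = s / np.sum(1.0 / n_typed)
        ho = float(np.mean([v[1] / v[0] for v in locus.values()]))
        sum_p2 = []
        all_alleles = sorted({a for _, _, c in locus.values() for a in c})
        freq_rows = []
        for n_t, _, counts in locus.values():
            n_genes = 2 * n_t
            freqs = np.array([counts.get(a, 0) / n_genes for a in all_alleles])
            freq_rows.append(freqs)
            sum_p2.append(float(np.sum(freqs**2)))
        msp2 = float(np.mean(sum_p2))
        xbar = np.mean(freq_rows, axis=0)
        if corrected:
            hs = (n_harm / (n_harm - 1)) * (1.0 - msp2 - ho / (2 * n_harm))
            ht = 1.0 - float(np.sum(xbar**2)) + hs / (n_harm * s) - ho / (2 * n_harm * s)
        else:
            hs = 1.0 - msp2
            ht = 1.0 - float(np.sum(xbar**2))
        ho_l.append(ho)
        hs_l.append(hs)
        ht_l.append(ht)
    if not ho_l:
        raise ValueError("no locus typed in two or more populations")
    Ho, Hs, Ht = (float(np.mean(v)) for v in (ho_l, hs_l, ht_l))
    flags = []
    if Ht <= 0:
        flags.append("monomorphic dataset: F_ST undefined")
        return FstatResult(float("nan"), float("nan"), float("nan"), Ho, Hs, Ht, flags)
    fis = 1.0 - Ho / Hs if Hs > 0 else float("nan")
    if Hs <= 0:
        flags.append("H_S is zero: F_IS undefined")
    return FstatResult(fis, (Ht - Hs) / Ht, 1.0 - Ho / Ht, Ho, Hs, Ht, flags)


# ---------------------------------------------------------------------------
# Hardy-Weinberg chi-square tests (Yates correction, Bonferroni threshold)
# ---------------------------------------------------------------------------

def hwe_tests(gm: GenotypeMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Chi-square HWE test per population x locus.

    Genotype classes are all unordered pairs of the alleles observed in the
    cell; expected counts follow Hardy-Weinberg proportions; the statistic
    applies the Yates continuity correction.  ``significant`` uses the
    Bonferroni-adjusted threshold alpha / (n_populations * n_loci).
    """
    pop_idx = gm.population_index()
    n_tests = len(pop_idx) * gm.n_loci
    threshold = alpha / n_tests
    rows = []
    for pop, idx in pop_idx.items():
        for l, locus in enumerate(gm.loci):
            geno = gm.calls[idx, l, :]
            typed = geno[geno[:, 0] != MISSING]
            rec = dict(population=pop, locus=locus.name, n=len(typed))
            if len(typed) == 0:
                rec.update(chi2=np.nan, df=np.nan, p=np.nan, significant=False)
                rows.append(rec)
                continue
            alleles = sorted(set(typed.ravel().tolist()))
            k = len(alleles)
            if k < 2:
                rec.update(chi2=np.nan, df=np.nan, p=np.nan, significant=False)
                rows.append(rec)
                continue
            n = len(typed)
            freqs = {
                a: np.count_nonzero(typed.ravel() == a) / (2 * n) for a in alleles
            }
            observed = Counter(
                (min(a, b), max(a, b)) for a, b in typed.tolist()
            )
            chi2 = 0.0
            n_classes = 0
            for i, a in enumerate(alleles):
                for b in alleles[i:]:
                    n_classes += 1
                    e = n * (freqs[a] ** 2 if a == b else 2 * freqs[a] * freqs[b])
                    o = observed.get((a, b), 0)
                    dev = max(abs(o - e) - 0.5, 0.0)
                    chi2 += dev * dev / e
            df = n_classes - k
            p = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")
            rec.update(chi2=chi2, df=df, p=p, significant=bool(p < threshold))
            rows.append(rec)
    out = pd.DataFrame(rows)
    out.attrs["alpha"] = alpha
    out.attrs["n_tests"] = n_tests
    out.attrs["threshold"] = threshold
    return out


# ---------------------------------------------------------------------------
# Genotypic linkage disequilibrium permutation tests
# ---------------------------------------------------------------------------

def _contingency_chi2(codes_a: np.ndarray, codes_b: np.ndarray) -> float:
    """Pearson chi-square of the two-way table of integer-coded genotypes."""
    ka = codes_a.max() + 1
    kb = codes_b.max() + 1
    table = np.bincount(codes_a * kb + codes_b, minlength=ka * kb).reshape(ka, kb)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 0.0
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    return float(((table - expected) ** 2 / expected).sum())


def ld_tests(
    gm: GenotypeMatrix, n_perm: int = 10_000, seed: int | None = None
) -> pd.DataFrame:
    """Permutation test of genotypic association for every locus pair.

    Within each population, the two-locus genotype contingency chi-square
    is compared against its distribution under random within-population
    permutations of one locus's genotypes.  p = (#{perm >= obs} + 1) /
    (n_perm + 1), hence always in (0, 1].
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    pop_idx = gm.population_index()
    rows = []
    for pop, idx in pop_idx.items():
        for la in range(gm.n_loci):
            for lb in range(la + 1, gm.n_loci):
                ga = gm.calls[idx, la, :]
                gb = gm.calls[idx, lb, :]
                both = (ga[:, 0] != MISSING) & (gb[:, 0] != MISSING)
                rec = dict(
                    population=pop,
                    locus_a=gm.loci[la].name,
                    locus_b=gm.loci[lb].name,
                    n=int(both.sum()),
                )
                if both.sum() < 2:
                    rec.update(chi2=np.nan, p=np.nan)
                    rows.append(rec)
                    continue
                sa = np.sort(ga[both], axis=1)
                sb = np.sort(gb[both], axis=1)
                _, codes_a = np.unique(sa, axis=0, return_inverse=True)
                _, codes_b = np.unique(sb, axis=0, return_inverse=True)
                codes_a = codes_a.ravel()
                codes_b = codes_b.ravel()
                obs = _contingency_chi2(codes_a, codes_b)
                hits = 0
                for _ in range(n_perm):
                    perm = rng.permutation(codes_b)
                    if _contingency_chi2(codes_a, perm) >= obs - 1e-12:
                        hits += 1
                rec.update(chi2=obs, p=(hits + 1) / (n_perm + 1))
                rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Null allele moment estimators
# ---------------------------------------------------------------------------

@dataclass
class NullAlleleEstimates:
    table: pd.DataFrame  # index: locus; columns r_chakraborty, r_brookfield, clamped

    def per_locus(self, name: str) -> pd.Series:
        return self.table.loc[name]


def null_allele_estimates(gm: GenotypeMatrix) -> NullAlleleEstimates:
    """Moment estimators of null-allele frequency per locus.

    r_chakraborty = (H_E - H_O)/(H_E + H_O); r_brookfield = (H_E - H_O)/(1 + H_E),
    with H_O and H_E the unweighted means over populations typed at the
    locus.  Negative estimates are clamped to zero and flagged.
    """
    stats_ = _locus_pop_stats(gm)
    rows = []
    for l, locus_stats in enumerate(stats_):
        name = gm.loci[l].name
        if not locus_stats:
            rows.append(dict(locus=name, r_chakraborty=np.nan, r_brookfield=np.nan, clamped=False))
            continue
        ho = float(np.mean([het / n for n, het, _ in locus_stats.values()]))
        he = float(
            np.mean(
                [
                    _unbiased_gene_diversity(c, 2 * n)
                    for n, _, c in locus_stats.values()
                    if 2 * n >= 2
                ]
            )
        )
        if not he > 0:
            rows.append(dict(locus=name, r_chakraborty=np.nan, r_brookfield=np.nan, clamped=False))
            continue
        rc = (he - ho) / (he + ho) if (he + ho) > 0 else np.nan
        rb = (he - ho) / (1.0 + he)
        clamped = bool(rc < 0 or rb < 0)
        rows.append(
            dict(
                locus=name,
                r_chakraborty=max(rc, 0.0),
                r_brookfield=max(rb, 0.0),
                clamped=clamped,
            )
        )
    return NullAlleleEstimates(pd.DataFrame(rows).set_index("locus"))


# ---------------------------------------------------------------------------
# Individual heterozygosity indices
# ---------------------------------------------------------------------------

@dataclass
class HetIndices:
    table: pd.DataFrame  # index: individual id; columns PHt, Hs_exp, IR, HL


def individual_heterozygosity(gm: GenotypeMatrix) -> HetIndices:
    """PHt, Hs_exp, IR and HL per individual.

    Allele frequencies and per-locus expected heterozygosities are computed
    over the whole dataset.  IR = (2H - sum f_i)/(2N - sum f_i) with H the
    number of homozygous typed loci, N the number of typed loci and f_i the
    frequencies of the alleles carried at homozygous loci; HL weighs loci by
    their expected heterozygosity: HL = sum(E_h)/(sum(E_h) + sum(E_j)).
    """
    n_loci = gm.n_loci
    freqs: list[dict[int, float]] = []
    he: list[float] = []
    for l in range(n_loci):
        alleles = gm.calls[:, l, :].ravel()
        alleles = alleles[alleles != MISSING]
        counts = Counter(alleles.tolist())
        total = alleles.size
        f = {a: c / total for a, c in counts.items()} if total else {}
        freqs.append(f)
        he.append(1.0 - sum(v * v for v in f.values()) if f else float("nan"))

    rows = []
    for i, ind in enumerate(gm.individual_ids):
        typed = [l for l in range(n_loci) if gm.calls[i, l, 0] != MISSING]
        if not typed:
            rows.append(dict(id=ind, PHt=np.nan, Hs_exp=np.nan, IR=np.nan, HL=np.nan))
            continue
        hom = [l for l in typed if gm.calls[i, l, 0] == gm.calls[i, l, 1]]
        het_loci = [l for l in typed if l not in hom]
        n_typed = len(typed)
        pht = len(het_loci) / n_typed
        mean_he = float(np.mean([he[l] for l in typed]))
        hs_exp = pht / mean_he if mean_he > 0 else np.nan
        sum_f = sum(2 * freqs[l][gm.calls[i, l, 0]] for l in hom)
        denom = 2 * n_typed - sum_f
        ir = (2 * len(hom) - sum_f) / denom if denom != 0 else np.nan
        e_h = sum(he[l] for l in hom)
        e_j = sum(he[l] for l in het_loci)
        hl = e_h / (e_h + e_j) if (e_h + e_j) > 0 else np.nan
        rows.append(dict(id=ind, PHt=pht, Hs_exp=hs_exp, IR=ir, HL=hl))
    return HetIndices(pd.DataFrame(rows).set_index("id"))


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn post hoc comparisons
# ---------------------------------------------------------------------------

def compare_groups(
    values: Sequence[float],
    groups: Sequence[str],
    adjust: str = "bonferroni",
) -> dict:
    """Kruskal-Wallis rank test with Dunn pairwise z-tests.

    Returns ``{"kw_chi2", "df", "p", "dunn": DataFrame}`` where the Dunn
    table carries z statistics and multiplicity-adjusted p-values
    (Bonferroni by default, ``adjust="none"`` to disable).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups.tolist()))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least two values")
    if np.all(values == values[0]):
        kw_chi2, p = 0.0, 1.0
    else:
        kw_chi2, p = stats.kruskal(*samples)
    df = len(labels) - 1

    # Dunn z statistics on mean ranks with tie correction
    n = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    mean_ranks = {g: float(ranks[groups == g].mean()) for g in labels}
    sizes = {g: int((groups == g).sum()) for g in labels}
    n_pairs = len(labels) * (len(labels) - 1) // 2
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            var = (n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))) * (
                1.0 / sizes[a] + 1.0 / sizes[b]
            )
            z = (mean_ranks[a] - mean_ranks[b]) / np.sqrt(var) if var > 0 else 0.0
            p_raw = 2.0 * stats.norm.sf(abs(z))
            p_adj = min(p_raw * n_pairs, 1.0) if adjust == "bonferroni" else p_raw
            rows.append(dict(group_a=a, group_b=b, z=z, p_raw=p_raw, p_adj=p_adj))
    return dict(kw_chi2=float(kw_chi2), df=df, p=float(p), dunn=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Cluster-number support from run log-likelihoods
# ---------------------------------------------------------------------------

@dataclass
class ClusterSupport:
    table: pd.DataFrame  # index K; columns mean_loglik, sd_loglik, delta_k

    @property
    def best_k(self) -> int:
        return int(self.table["delta_k"].idxmax())


def evanno_delta_k(loglik: Mapping[int, Sequence[float]]) -> ClusterSupport:
    """Second-order rate of change of clustering log-likelihoods.

    ``delta_k(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K))``;
    undefined (NaN) at the boundary K values and where the run standard
    deviation is zero (flagged via the ``zero_sd`` column).
    """
    ks = sorted(loglik)
    if len(ks) < 3:
        raise ValueError("need at least three consecutive K values")
    if any(len(loglik[k]) < 2 for k in ks):
        raise ValueError("need at least two runs per K")
    if ks != list(range(ks[0], ks[0] + len(ks))):
        raise ValueError("K values must be consecutive")
    mean = {k: float(np.mean(loglik[k])) for k in ks}
    sd = {k: float(np.std(loglik[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        delta = np.nan
        zero_sd = False
        if ks[0] < k < ks[-1]:
            num = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1])
            if sd[k] == 0:
                zero_sd = True
            else:
                delta = num / sd[k]
        rows.append(
            dict(K=k, mean_loglik=mean[k], sd_loglik=sd[k], delta_k=delta, zero_sd=zero_sd)
        )
    return ClusterSupport(pd.DataFrame(rows).set_index("K"))
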