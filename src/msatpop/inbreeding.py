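"""Joint Bayesian estimation of inbreeding, null alleles and genotyping
failure by Gibbs sampling, with DIC model comparison.

The observation model for each individual x locus cell mixes three
processes: with probability ``b`` genotyping fails outright (missing); an
autozygous genotype (probability F) copies a single draw from the locus
allele pool; an allozygous genotype draws twice.  The pool contains the
visible alleles plus a per-locus null allele: a null/visible pair is
observed as a homozygote and a null/null pair as missing.  All conditional
updates are conjugate after augmenting each cell with its latent class, so
the chain is a pure Gibbs sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .genotype_io import MISSING, GenotypeMatrix

__all__ = ["InbreedingPosterior", "gibbs_inbreeding_null"]

_FAILURE_CAP = 0.2  # Uniform(0, 0.2) prior on the genotyping failure rate


@dataclass
class InbreedingPosterior:
    f_mean: float
    f_hpd: tuple[float, float]
    f_samples: np.ndarray
    null_mean: dict[str, float]
    null_hpd: dict[str, tuple[float, float]]
    failure_mean: float
    dic: float
    model: str
    rhat: float
    warnings: list[str] = field(default_factory=list)


def _hpd(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the samples."""
    x = np.sort(samples)
    n = len(x)
    k = max(int(np.floor(mass * n)), 1)
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])


def _split_rhat(chain: np.ndarray) -> float:
    """Split-chain potential scale reduction factor."""
    n = len(chain) // 2
    if n < 2:
        return float("nan")
    halves = np.stack([chain[:n], chain[n : 2 * n]])
    means = halves.mean(axis=1)
    variances = halves.var(axis=1, ddof=1)
    w = variances.mean()
    b = n * means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


@dataclass
class _LocusData:
    """Per-locus sufficient description of the observed genotypes."""

    alleles: np.ndarray  # sorted visible allele states
    het_copy_counts: np.ndarray  # fixed visible-copy counts from het cells
    n_het: int
    hom_allele_idx: np.ndarray  # per observed-homozygote cell, allele index
    n_missing: int

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)


def _prepare(gm: GenotypeMatrix) -> list[_LocusData]:
    out = []
    for l in range(gm.n_loci):
        geno = gm.calls[:, l, :]
        typed = geno[geno[:, 0] != MISSING]
        n_missing = gm.n_individuals - len(typed)
        alleles = np.unique(typed.ravel()) if len(typed) else np.array([], dtype=int)
        amap = {a: i for i, a in enumerate(alleles)}
        het = typed[typed[:, 0] != typed[:, 1]]
        hom = typed[typed[:, 0] == typed[:, 1]]
        het_counts = np.zeros(len(alleles))
        for a, b in het:
            het_counts[amap[a]] += 1
            het_counts[amap[b]] += 1
        hom_idx = np.array([amap[a] for a in hom[:, 0]], dtype=int)
        out.append(_LocusData(alleles, het_counts, len(het), hom_idx, n_missing))
    return out


def _truncated_beta(rng: np.random.Generator, a: float, b: float, cap: float) -> float:
    hi = sps.beta.cdf(cap, a, b)
    u = rng.uniform(0.0, hi)
    return float(sps.beta.ppf(u, a, b))


def gibbs_inbreeding_null(
    gm: GenotypeMatrix,
    n_iter: int = 50_000,
    burnin: int = 10_000,
    thin: int = 10,
    seed: int | None = None,
    model: str = "nfb_full",
) -> InbreedingPosterior:
    """Posterior of the dataset-level inbreeding coefficient and per-locus
    null-allele frequencies under the joint model.

    ``model="nfb_full"`` estimates inbreeding, nulls and failures;
    ``model="nb_nulls_only"`` fixes F = 0 (nulls and failures only), which
    makes the two models comparable by DIC.
    """
    if model not in ("nfb_full", "nb_nulls_only"):
        raise ValueError(f"unknown model {model!r}")
    if n_iter <= burnin:
        raise ValueError("n_iter must exceed burnin")
    if gm.n_loci < 2:
        raise ValueError("need at least two loci")
    rng = np.random.default_rng(seed)
    loci = _prepare(gm)
    n_cells = gm.n_individuals * gm.n_loci
    estimate_f = model == "nfb_full"

    # state
    f = 0.2 if estimate_f else 0.0
    fail = 0.05
    pi = []  # per locus: visible allele freqs + trailing null freq
    for ld in loci:
        k = ld.n_alleles + 1
        pi.append(np.full(k, 1.0 / k))

    keep = (n_iter - burnin + thin - 1) // thin
    f_chain = np.empty(keep)
    b_chain = np.empty(keep)
    null_chain = np.empty((keep, gm.n_loci))
    dev_chain = np.empty(keep)
    kept = 0

    for it in range(n_iter):
        n_auto = 0
        n_nonfail = 0
        n_fail = 0
        new_pi = []
        loglik = 0.0
        for l, ld in enumerate(loci):
            p = pi[l]
            p_null = p[-1]
            counts = np.zeros(len(p))
            counts[:-1] += ld.het_copy_counts
            n_nonfail += ld.n_het

            # observed homozygote cells: latent class auto / allo-pure / allo-null
            if len(ld.hom_allele_idx):
                pa = p[ld.hom_allele_idx]
                w_auto = f * pa
                w_pure = (1.0 - f) * pa * pa
                w_null = (1.0 - f) * 2.0 * pa * p_null
                tot = w_auto + w_pure + w_null
                u = rng.random(len(pa)) * tot
                is_auto = u < w_auto
                is_pure = (~is_auto) & (u < w_auto + w_pure)
                is_anull = ~(is_auto | is_pure)
                n_auto += int(is_auto.sum())
                n_nonfail += len(pa)
                np.add.at(counts, ld.hom_allele_idx[is_auto], 1.0)
                np.add.at(counts, ld.hom_allele_idx[is_pure], 2.0)
                np.add.at(counts, ld.hom_allele_idx[is_anull], 1.0)
                counts[-1] += float(is_anull.sum())

            # missing cells: failure / auto-null / allo null-null
            if ld.n_missing:
                w = np.array(
                    [
                        fail,
                        (1.0 - fail) * f * p_null,
                        (1.0 - fail) * (1.0 - f) * p_null * p_null,
                    ]
                )
                draw = rng.multinomial(ld.n_missing, w / w.sum())
                n_fail += int(draw[0])
                n_auto += int(draw[1])
                n_nonfail += int(draw[1] + draw[2])
                counts[-1] += draw[1] + 2 * draw[2]

            new_pi.append(rng.dirichlet(counts + 1.0))

            # observed-data log likelihood at current parameter values
            if ld.n_het:
                het_ll = np.log((1.0 - fail) * (1.0 - f) * 2.0)
                # sum over het cells of log(pa * pb) = sum of copy counts * log p
                loglik += ld.n_het * het_ll + float(
                    np.dot(ld.het_copy_counts, np.log(np.clip(p[:-1], 1e-300, None)))
                )
            if len(ld.hom_allele_idx):
                pa = p[ld.hom_allele_idx]
                cell = (1.0 - fail) * (
                    f * pa + (1.0 - f) * (pa * pa + 2.0 * pa * p_null)
                )
                loglik += float(np.log(np.clip(cell, 1e-300, None)).sum())
            if ld.n_missing:
                cell = fail + (1.0 - fail) * (
                    f * p_null + (1.0 - f) * p_null * p_null
                )
                loglik += ld.n_missing * float(np.log(max(cell, 1e-300)))

        pi = new_pi
        if estimate_f:
            f = float(rng.beta(1 + n_auto, 1 + max(n_nonfail - n_auto, 0)))
        fail = _truncated_beta(rng, 1 + n_fail, 1 + n_cells - n_fail, _FAILURE_CAP)

        if it >= burnin and (it - burnin) % thin == 0:
            f_chain[kept] = f
            b_chain[kept] = fail
            null_chain[kept] = [p[-1] for p in pi]
            dev_chain[kept] = -2.0 * loglik
            kept += 1

    f_chain = f_chain[:kept]
    b_chain = b_chain[:kept]
    null_chain = null_chain[:kept]
    dev_chain = dev_chain[:kept]

    # DIC = mean(D) + pD with pD = mean(D) - D(posterior means)
    d_bar = float(dev_chain.mean())
    d_hat = _deviance_at(
        loci,
        f=float(f_chain.mean()) if estimate_f else 0.0,
        fail=float(b_chain.mean()),
        nulls=null_chain.mean(axis=0),
        pis=pi,
    )
    dic = 2.0 * d_bar - d_hat

    rhat = _split_rhat(f_chain if estimate_f else b_chain)
    warns = []
    if rhat > 1.1:
        warns.append(f"possible non-convergence: split-chain R-hat = {rhat:.3f}")
    locus_names = gm.locus_names
    return InbreedingPosterior(
        f_mean=float(f_chain.mean()) if estimate_f else 0.0,
        f_hpd=_hpd(f_chain) if estimate_f else (0.0, 0.0),
        f_samples=f_chain,
        null_mean={n: float(null_chain[:, l].mean()) for l, n in enumerate(locus_names)},
        null_hpd={n: _hpd(null_chain[:, l]) for l, n in enumerate(locus_names)},
        failure_mean=float(b_chain.mean()),
        dic=dic,
        model=model,
        rhat=rhat,
        warnings=warns,
    )


def _deviance_at(loci, f: float, fail: float, nulls: np.ndarray, pis) -> float:
    """Deviance at point parameter values (posterior-mean null frequencies,
    posterior-mean visible frequencies renormalized around them)."""
    loglik = 0.0
    for l, ld in enumerate(loci):
        p = np.asarray(pis[l], dtype=float).copy()
        p_null = float(nulls[l])
        if p[:-1].sum() > 0:
            p[:-1] *= (1.0 - p_null) / p[:-1].sum()
        p[-1] = p_null
        if ld.n_het:
            loglik += ld.n_het * np.log((1.0 - fail) * (1.0 - f) * 2.0) + float(
                np.dot(ld.het_copy_counts, np.log(np.clip(p[:-1], 1e-300, None)))
            )
        if len(ld.hom_allele_idx):
            pa = p[ld.hom_allele_idx]
            cell = (1.0 - fail) * (f * pa + (1.0 - f) * (pa * pa + 2.0 * pa * p_null))
            loglik += float(np.log(np.clip(cell, 1e-300, None)).sum())
        if ld.n_missing:
            cell = fail + (1.0 - fail) * (f * p_null + (1.0 - f) * p_null * p_null)
            loglik += ld.n_missing * float(np.log(max(cell, 1e-300)))
    return -2.0 * loglik
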