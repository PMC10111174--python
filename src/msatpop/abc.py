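"""Reference-table ABC: summary statistics, rejection, logistic model
choice, local-linear parameter estimation and confusion analysis.

The summary-statistic vector holds, per group: mean number of alleles per
locus, mean gene diversity, mean allele-size variance and mean
Garza-Williamson M; and per group pair: F_ST, the squared difference in
mean allele size, and the allele-sharing distance D_AS.  Statistics are
MAD-normalized over the reference table before Euclidean rejection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .coalescent import (
    MutationModel,
    ParameterDraw,
    ScenarioSpec,
    sample_priors,
    simulate_alleles,
)
from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "StatVector",
    "ReferenceTable",
    "ModelChoiceResult",
    "ParamPosterior",
    "ConfusionResult",
    "summary_stats",
    "stats_from_alleles",
    "build_reference_table",
    "model_choice",
    "estimate_params",
    "confusion",
    "subsample_clusters",
]


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

@dataclass
class StatVector:
    names: list[str]
    values: np.ndarray
    groups: list[str]

    def __len__(self) -> int:
        return len(self.values)


def _group_counts(alleles: np.ndarray, state_max: int) -> np.ndarray:
    """Allele count matrix (n_loci, state_max + 1) for one group's gene
    copies; column 0 collects the MISSING sentinel and is ignored later."""
    n, L, _ = alleles.shape
    locus_idx = np.tile(np.repeat(np.arange(L), 2), n)
    counts = np.bincount(
        locus_idx * (state_max + 1) + alleles.reshape(-1),
        minlength=L * (state_max + 1),
    ).reshape(L, state_max + 1)
    counts[:, MISSING] = 0
    return counts


def stats_from_alleles(
    blocks: list[np.ndarray], group_labels: list[str], state_max: int = 40
) -> StatVector:
    """Summary statistics from per-group allele arrays (n_i, L, 2).

    Missing genotypes (MISSING sentinel) are excluded from counts; loci for
    which any group has no typed gene copies are dropped consistently from
    every statistic.
    """
    G = len(blocks)
    L = blocks[0].shape[1]
    states = np.arange(state_max + 1, dtype=float)
    counts = np.stack([_group_counts(b, state_max) for b in blocks])  # (G, L, S+1)
    totals = counts.sum(axis=2, dtype=float)  # (G, L) typed gene copies
    keep = (totals > 0).all(axis=0)
    if not keep.any():
        raise ValueError("no locus typed in every group")
    counts = counts[:, keep, :]
    totals = totals[:, keep]

    freqs = counts / totals[:, :, None]
    n_alleles = (counts > 0).sum(axis=2)  # (G, L)
    gene_div = 1.0 - (freqs**2).sum(axis=2)
    mean_size = (freqs * states).sum(axis=2)
    var_size = (freqs * states**2).sum(axis=2) - mean_size**2
    # allele size range per group per locus
    present = counts > 0
    first = np.argmax(present, axis=2)
    last = state_max - np.argmax(present[:, :, ::-1], axis=2)
    gw_m = n_alleles / (last - first + 1.0)

    names: list[str] = []
    values: list[float] = []
    for g, lab in enumerate(group_labels):
        names += [f"A_{lab}", f"He_{lab}", f"V_{lab}", f"M_{lab}"]
        values += [
            float(n_alleles[g].mean()),
            float(gene_div[g].mean()),
            float(var_size[g].mean()),
            float(gw_m[g].mean()),
        ]
    for i in range(G):
        for j in range(i + 1, G):
            la, lb = group_labels[i], group_labels[j]
            hs = 0.5 * (gene_div[i] + gene_div[j])
            mean_freq = 0.5 * (freqs[i] + freqs[j])
            ht = 1.0 - (mean_freq**2).sum(axis=1)
            ht_bar = float(ht.mean())
            fst = (ht_bar - float(hs.mean())) / ht_bar if ht_bar > 0 else 0.0
            dmu2 = float(((mean_size[i] - mean_size[j]) ** 2).mean())
            das = _das_between(blocks[i][:, keep, :], blocks[j][:, keep, :])
            names += [f"Fst_{la}_{lb}", f"dmu2_{la}_{lb}", f"Das_{la}_{lb}"]
            values += [fst, dmu2, das]
    return StatVector(names, np.asarray(values, dtype=float), list(group_labels))


def _das_between(a: np.ndarray, b: np.ndarray) -> float:
    """Mean allele-sharing distance over all cross pairs and typed loci."""
    a = np.sort(a, axis=2)
    b = np.sort(b, axis=2)
    a1 = a[:, None, :, 0]
    a2 = a[:, None, :, 1]
    b1 = b[None, :, :, 0]
    b2 = b[None, :, :, 1]
    typed = (a1 != MISSING) & (b1 != MISSING)
    eq_full = (a1 == b1) & (a2 == b2)
    any_match = (a1 == b1) | (a1 == b2) | (a2 == b1) | (a2 == b2)
    shared = np.where(eq_full, 2.0, np.where(any_match, 1.0, 0.0))
    with np.errstate(invalid="ignore"):
        per_pair = np.where(typed, 1.0 - shared / 2.0, np.nan)
        vals = np.nanmean(per_pair, axis=2)
    return float(np.nanmean(vals))


def summary_stats(gm: GenotypeMatrix, groups: dict[str, str] | None = None) -> StatVector:
    """Summary statistics of a genotype matrix.

    ``groups`` optionally maps population labels to group (cluster) labels;
    populations absent from the mapping are dropped.
    """
    if groups:
        gm = gm.subset_populations([p for p in gm.populations() if p in groups])
        gm = gm.relabel_populations(groups)
    pop_idx = gm.population_index()
    labels = gm.populations()
    if any(len(ix) < 2 for ix in pop_idx.values()):
        raise ValueError("every group needs at least two individuals")
    state_max = max(loc.state_max for loc in gm.loci)
    blocks = [gm.calls[pop_idx[p]] for p in labels]
    return stats_from_alleles(blocks, labels, state_max=state_max)


# ---------------------------------------------------------------------------
# Reference table
# ---------------------------------------------------------------------------

@dataclass
class ReferenceTable:
    scenario_ids: np.ndarray  # (n,) str
    params: pd.DataFrame  # (n, p) flat parameter draws (NaN where unused)
    stats: np.ndarray  # (n, S)
    stat_names: list[str]
    mad: np.ndarray  # (S,)
    scenarios: dict[str, ScenarioSpec]
    sample_spec: dict[str, int]
    n_loci: int
    param_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.scenario_ids)

    def kept_stats(self) -> np.ndarray:
        return self.mad > 0

    def write_csv(self, path) -> None:
        df = pd.DataFrame(self.stats, columns=self.stat_names)
        df.insert(0, "scenario", self.scenario_ids)
        out = pd.concat([df, self.params.reset_index(drop=True)], axis=1)
        out.to_csv(path, index=False)


def _row_seeds(seed: int, scenario_index: int, row: int) -> tuple[int, int]:
    ss = np.random.SeedSequence(entropy=(seed, scenario_index, row))
    a, b = ss.generate_state(2)
    return int(a), int(b)


def _draw_bounds(spec: ScenarioSpec) -> dict[str, tuple[float, float]]:
    pr = spec.priors
    bounds: dict[str, tuple[float, float]] = {}
    for pop in spec.all_populations:
        bounds[f"Ne_{pop}"] = (float(pr.ne_range[0]), float(pr.ne_range[1]))
    for pop in spec.founded_populations():
        bounds[f"N_{pop}"] = (float(pr.founder_range[0]), float(pr.founder_range[1]))
    for name, (lo, hi) in pr.time_ranges.items():
        bounds[name] = (float(lo), float(hi))
    for a in spec.admixtures:
        bounds[f"ra_{a.target}"] = pr.ra_range
    bounds["mean_mu"] = pr.mean_mu_range
    return bounds


def build_reference_table(
    scenarios: dict[str, ScenarioSpec],
    n_per_scenario: int,
    sample_spec: dict[str, int],
    n_loci: int = 15,
    seed: int = 0,
    state_range: tuple[int, int] = (1, 40),
    geometric_p: float = 0.22,
    max_retries: int = 5,
    progress: bool = False,
) -> ReferenceTable:
    """Simulate ``n_per_scenario`` datasets per scenario.

    Every row derives its randomness from a deterministic sub-seed of
    ``seed``, so the table is bit-identical for any worker count or build
    order.  Failed simulations are retried with a fresh sub-seed.
    """
    if n_per_scenario < 100:
        raise ValueError("n_per_scenario must be >= 100")
    smin, smax = state_range
    ids: list[str] = []
    param_rows: list[dict[str, float]] = []
    stat_rows: list[np.ndarray] = []
    stat_names: list[str] | None = None
    bounds: dict[str, tuple[float, float]] = {}
    iterator = enumerate(sorted(scenarios))
    for s_idx, name in iterator:
        spec = scenarios[name]
        bounds.update(_draw_bounds(spec))
        groups = [p for p in spec.populations if sample_spec.get(p, 0) > 0]
        for row in range(n_per_scenario):
            for attempt in range(max_retries):
                sa, sb = _row_seeds(seed, s_idx, row * max_retries + attempt)
                try:
                    draw = sample_priors(spec, n_loci, seed=sa)
                    mut = MutationModel(
                        rates=draw.locus_mu,
                        geometric_p=geometric_p,
                        state_min=smin,
                        state_max=smax,
                    )
                    alleles = simulate_alleles(spec, draw, sample_spec, mut, seed=sb)
                    blocks = _split_blocks(alleles, spec, sample_spec)
                    sv = stats_from_alleles(blocks, groups, state_max=smax)
                    break
                except Exception:  # pragma: no cover - retry path
                    if attempt == max_retries - 1:
                        raise
            ids.append(name)
            param_rows.append(draw.as_flat_dict())
            stat_rows.append(sv.values)
            if stat_names is None:
                stat_names = sv.names
    stats = np.vstack(stat_rows)
    med = np.median(stats, axis=0)
    mad = np.median(np.abs(stats - med), axis=0)
    if (mad == 0).any():
        dropped = [stat_names[i] for i in np.flatnonzero(mad == 0)]
        warnings.warn(f"zero-MAD statistics dropped from distances: {dropped}")
    return ReferenceTable(
        scenario_ids=np.asarray(ids),
        params=pd.DataFrame(param_rows),
        stats=stats,
        stat_names=stat_names or [],
        mad=mad,
        scenarios=dict(scenarios),
        sample_spec=dict(sample_spec),
        n_loci=n_loci,
        param_bounds=bounds,
    )


def _split_blocks(
    alleles: np.ndarray, spec: ScenarioSpec, sample_spec: dict[str, int]
) -> list[np.ndarray]:
    blocks = []
    offset = 0
    for p in spec.populations:
        n = int(sample_spec.get(p, 0))
        if n:
            blocks.append(alleles[offset : offset + n])
        offset += n
    return blocks


# ---------------------------------------------------------------------------
# Rejection + logistic model choice
# ---------------------------------------------------------------------------

@dataclass
class ModelChoiceResult:
    direct: dict[str, float]
    logistic: dict[str, float]
    tolerance: float
    n_retained: int
    warnings: list[str] = field(default_factory=list)

    def best(self, method: str = "logistic") -> str:
        probs = getattr(self, method)
        return max(probs, key=probs.get)


def _retain(table: ReferenceTable, s_obs: np.ndarray, tolerance: float):
    keep = table.kept_stats()
    z = table.stats[:, keep] / table.mad[keep]
    z_obs = s_obs[keep] / table.mad[keep]
    d = np.sqrt(((z - z_obs) ** 2).sum(axis=1))
    n_keep = max(int(round(tolerance * len(table))), 1)
    idx = np.argpartition(d, n_keep - 1)[:n_keep]
    idx = idx[np.argsort(d[idx])]
    return idx, d[idx], z[idx] - z_obs


def model_choice(
    table: ReferenceTable, s_obs: StatVector | np.ndarray, tolerance: float = 0.01
) -> ModelChoiceResult:
    """Scenario posterior probabilities by rejection and local logistic
    regression on the ``tolerance`` fraction of nearest simulations."""
    obs = s_obs.values if isinstance(s_obs, StatVector) else np.asarray(s_obs, float)
    if tolerance * len(table) < 50:
        raise ValueError("tolerance * table size must retain at least 50 rows")
    idx, dist, x = _retain(table, obs, tolerance)
    labels = table.scenario_ids[idx]
    names = sorted(table.scenarios)
    counts = {n: float(np.mean(labels == n)) for n in names}
    warns = [f"scenario {n} absent from retained set" for n in names if counts[n] == 0.0]

    dmax = dist.max() if dist.max() > 0 else 1.0
    w = 1.0 - (dist / dmax) ** 2
    w = np.clip(w, 1e-8, None)
    present = sorted(set(labels))
    if len(present) == 1:
        logistic = {n: 1.0 if n == present[0] else 0.0 for n in names}
    else:
        clf = LogisticRegression(C=1e6, max_iter=2000)
        clf.fit(x, labels, sample_weight=w)
        probs = clf.predict_proba(np.zeros((1, x.shape[1])))[0]
        logistic = {n: 0.0 for n in names}
        for cls, p in zip(clf.classes_, probs):
            logistic[cls] = float(p)
    return ModelChoiceResult(
        direct=counts,
        logistic=logistic,
        tolerance=tolerance,
        n_retained=len(idx),
        warnings=warns,
    )


# ---------------------------------------------------------------------------
# Local-linear parameter estimation
# ---------------------------------------------------------------------------

@dataclass
class ParamPosterior:
    scenario: str
    table: pd.DataFrame  # index: parameter; columns median, q2.5, q97.5
    n_retained: int
    flags: list[str] = field(default_factory=list)

    def median(self, param: str) -> float:
        return float(self.table.loc[param, "median"])

    def interval(self, param: str) -> tuple[float, float]:
        return (
            float(self.table.loc[param, "q2.5"]),
            float(self.table.loc[param, "q97.5"]),
        )


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: np.ndarray) -> np.ndarray:
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= w.sum()
    return np.interp(q, cw, v)


def estimate_params(
    table: ReferenceTable,
    scenario_id: str,
    s_obs: StatVector | np.ndarray,
    tolerance: float = 0.01,
) -> ParamPosterior:
    """Weighted local-linear posterior for the focal scenario's parameters.

    Each parameter is logit-transformed to its prior range, adjusted by a
    weighted linear regression on the normalized statistic residuals
    (theta* = theta - b (s - s_obs)), back-transformed, and summarized by
    the weighted median and 2.5/97.5% quantiles.
    """
    obs = s_obs.values if isinstance(s_obs, StatVector) else np.asarray(s_obs, float)
    mask = table.scenario_ids == scenario_id
    if not mask.any():
        raise ValueError(f"scenario {scenario_id!r} not in table")
    sub_stats = table.stats[mask]
    sub_params = table.params.loc[mask].reset_index(drop=True)

    keep = table.kept_stats()
    z = sub_stats[:, keep] / table.mad[keep]
    z_obs = obs[keep] / table.mad[keep]
    d = np.sqrt(((z - z_obs) ** 2).sum(axis=1))
    n_keep = max(int(round(tolerance * mask.sum())), 50)
    if n_keep > mask.sum():
        raise ValueError("fewer focal rows than required retained count")
    idx = np.argsort(d)[:n_keep]
    dist = d[idx]
    x = z[idx] - z_obs
    dmax = dist.max() if dist.max() > 0 else 1.0
    w = np.clip(1.0 - (dist / dmax) ** 2, 1e-8, None)

    flags: list[str] = []
    rows = []
    q = np.array([0.5, 0.025, 0.975])
    eps = 1e-9
    for param in sub_params.columns:
        vals = sub_params[param].to_numpy(dtype=float)[idx]
        if np.isnan(vals).all():
            continue
        lo, hi = table.param_bounds.get(param, (np.nanmin(vals), np.nanmax(vals)))
        if np.nanstd(vals) == 0 or hi <= lo:
            m = float(vals[0])
            rows.append(dict(parameter=param, median=m, **{"q2.5": m, "q97.5": m}))
            continue
        u = np.clip((vals - lo) / (hi - lo), eps, 1 - eps)
        theta = np.log(u / (1 - u))
        design = np.hstack([np.ones((len(x), 1)), x])
        sw = np.sqrt(w)
        coef, _, rank, _ = np.linalg.lstsq(design * sw[:, None], theta * sw, rcond=None)
        if rank < design.shape[1]:
            flags.append(f"{param}: singular local regression, rejection quantiles used")
            adjusted = theta
        else:
            adjusted = theta - x @ coef[1:]
        back = lo + (hi - lo) / (1.0 + np.exp(-adjusted))
        med, lo_q, hi_q = _weighted_quantile(back, w, q)
        rows.append(dict(parameter=param, median=med, **{"q2.5": lo_q, "q97.5": hi_q}))
    out = pd.DataFrame(rows).set_index("parameter")
    return ParamPosterior(scenario=scenario_id, table=out, n_retained=n_keep, flags=flags)


# ---------------------------------------------------------------------------
# Confusion (type I / type II) analysis
# ---------------------------------------------------------------------------

@dataclass
class ConfusionResult:
    focal: str
    type_I: float
    type_II: float
    n_pods: int


def confusion(
    table: ReferenceTable,
    focal_scenario: str,
    n_pods: int = 500,
    tolerance: float = 0.01,
    seed: int = 0,
    geometric_p: float = 0.22,
    state_range: tuple[int, int] = (1, 40),
) -> ConfusionResult:
    """Classification error rates for the focal scenario.

    Type I: fraction of pseudo-observed datasets simulated under the focal
    scenario for which it is not the argmax of the logistic posterior.
    Type II: fraction of datasets simulated under the competing scenarios
    (evenly split) for which the focal scenario is nevertheless selected.
    """
    if n_pods < 50:
        raise ValueError("n_pods must be >= 50")
    if focal_scenario not in table.scenarios:
        raise ValueError(f"unknown scenario {focal_scenario!r}")
    smin, smax = state_range

    def classify_pods(scenario_name: str, count: int, salt: int) -> list[str]:
        spec = table.scenarios[scenario_name]
        groups = [p for p in spec.populations if table.sample_spec.get(p, 0) > 0]
        picks = []
        for i in range(count):
            sa, sb = _row_seeds(seed, salt, i)
            draw = sample_priors(spec, table.n_loci, seed=sa)
            mut = MutationModel(
                rates=draw.locus_mu, geometric_p=geometric_p,
                state_min=smin, state_max=smax,
            )
            alleles = simulate_alleles(spec, draw, table.sample_spec, mut, seed=sb)
            sv = stats_from_alleles(
                _split_blocks(alleles, spec, table.sample_spec), groups, state_max=smax
            )
            picks.append(model_choice(table, sv, tolerance).best("logistic"))
        return picks

    picks_focal = classify_pods(focal_scenario, n_pods, salt=10_000)
    type_i = float(np.mean([p != focal_scenario for p in picks_focal]))

    others = [n for n in sorted(table.scenarios) if n != focal_scenario]
    per = max(n_pods // len(others), 1)
    picks_other: list[str] = []
    for k, name in enumerate(others):
        picks_other.extend(classify_pods(name, per, salt=20_000 + k))
    type_ii = float(np.mean([p == focal_scenario for p in picks_other]))
    return ConfusionResult(
        focal=focal_scenario, type_I=type_i, type_II=type_ii, n_pods=n_pods
    )


# ---------------------------------------------------------------------------
# Cluster subsampling
# ---------------------------------------------------------------------------

def subsample_clusters(
    gm: GenotypeMatrix,
    groups: dict[str, str],
    k: int = 25,
    seed: int = 0,
) -> GenotypeMatrix:
    """Relabel populations to clusters and keep ``k`` random individuals per
    cluster (all of them, with a warning, when a cluster is smaller)."""
    gm = gm.subset_populations([p for p in gm.populations() if p in groups])
    gm = gm.relabel_populations(groups)
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for cluster, idx in gm.population_index().items():
        if len(idx) <= k:
            if len(idx) < k:
                warnings.warn(
                    f"cluster {cluster} has only {len(idx)} individuals (< {k}); keeping all"
                )
            keep.extend(idx.tolist())
        else:
            keep.extend(sorted(rng.choice(idx, size=k, replace=False).tolist()))
    return gm.take_individuals(sorted(keep))
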