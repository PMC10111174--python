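"""Generators for study-emulating synthetic genotype datasets.

Populations sit on a one-dimensional coastal transect; allele frequency
profiles drift along the chain (a stepping-stone structure whose strength
is set by the migration rate), genotypes are drawn with a configurable
inbreeding coefficient, and null alleles and missing data are injected
afterwards.  Every generated dataset passes :func:`msatpop.genotype_io.validate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import DEFAULT_SAMPLE_SIZES
from .genotype_io import MISSING, GenotypeMatrix, LocusDef, Site, SiteTable

__all__ = [
    "SynthConfig",
    "generate_study_like",
    "generate_inbred_panmictic",
    "ibd_landscape",
    "inject_nulls",
    "inject_missing",
]


@dataclass
class SynthConfig:
    """Configuration for :func:`generate_study_like`."""

    n_populations: int = 16
    sample_sizes: list[int] | None = None  # default: published per-site n
    n_loci: int = 15
    state_range: tuple[int, int] = (1, 40)
    inbreeding_f: float = 0.45
    null_rate_max: float = 0.10
    missing_fraction: float = 0.032
    migration: float = 0.05
    transect_km: float = 800.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_sizes is None:
            defaults = list(DEFAULT_SAMPLE_SIZES.values())
            if self.n_populations == len(defaults):
                self.sample_sizes = defaults
            else:
                self.sample_sizes = [20] * self.n_populations
        if len(self.sample_sizes) != self.n_populations:
            raise ValueError("one sample size per population required")
        for rate in (self.inbreeding_f, self.null_rate_max, self.missing_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if any(n < 1 for n in self.sample_sizes):
            raise ValueError("sample sizes must be >= 1")


def _chain_frequencies(
    n_pops: int,
    n_loci: int,
    n_states: int,
    migration: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stepping-stone allele frequency profiles (n_pops, n_loci, n_states).

    Each step along the chain redraws frequencies from a Dirichlet centred
    on the neighbour's profile; the concentration grows with the migration
    rate, so low migration means strong drift per step.
    """
    concentration = 2.0 + 2000.0 * migration**2 / max(1.0 - migration, 1e-6)
    freqs = np.zeros((n_pops, n_loci, n_states))
    for l in range(n_loci):
        k = int(rng.integers(4, 11))  # segregating states per locus
        support = rng.choice(n_states, size=k, replace=False)
        base = np.zeros(n_states)
        base[support] = rng.dirichlet(np.full(k, 0.6))
        freqs[0, l] = base
        for p in range(1, n_pops):
            prev = freqs[p - 1, l]
            alpha = prev * concentration + 1e-3
            freqs[p, l] = rng.dirichlet(alpha)
    return freqs


def _draw_genotypes(
    freqs: np.ndarray,
    sample_sizes: list[int],
    inbreeding_f: float,
    state_min: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw diploid genotypes; with probability F both alleles copy one draw."""
    n_pops, n_loci, n_states = freqs.shape
    total = sum(sample_sizes)
    calls = np.empty((total, n_loci, 2), dtype=np.int64)
    row = 0
    for p, n in enumerate(sample_sizes):
        for l in range(n_loci):
            f_vec = freqs[p, l]
            a1 = rng.choice(n_states, size=n, p=f_vec)
            a2 = rng.choice(n_states, size=n, p=f_vec)
            ibd = rng.random(n) < inbreeding_f
            a2[ibd] = a1[ibd]
            calls[row : row + n, l, 0] = a1 + state_min
            calls[row : row + n, l, 1] = a2 + state_min
        row += n
    return calls


def _assemble(
    calls: np.ndarray,
    sample_sizes: list[int],
    pop_names: list[str],
    n_loci: int,
    state_range: tuple[int, int],
) -> GenotypeMatrix:
    ids, pops = [], []
    for name, n in zip(pop_names, sample_sizes):
        ids.extend(f"{name}_{i + 1}" for i in range(n))
        pops.extend([name] * n)
    loci = [
        LocusDef(f"L{l + 1}", state_min=state_range[0], state_max=state_range[1])
        for l in range(n_loci)
    ]
    return GenotypeMatrix(ids, pops, loci, calls)


def _transect_sites(pop_names: list[str], transect_km: float) -> SiteTable:
    # straight south-to-north transect; ~111.19 km per degree of latitude
    deg = transect_km / 111.19
    lats = np.linspace(56.0, 56.0 + deg, len(pop_names))
    return SiteTable(
        [Site(code=name, latitude=float(lat), longitude=16.0) for name, lat in zip(pop_names, lats)]
    )


def generate_study_like(cfg: SynthConfig) -> tuple[GenotypeMatrix, SiteTable]:
    """Generate a dataset emulating the study layout.

    Defaults: 16 populations with the published sample sizes, 15 loci on a
    40-state range, inbreeding F = 0.45, per-locus null-allele rates drawn
    uniformly up to 10%, and 3.2% missing data, on an ~800 km transect.
    """
    rng = np.random.default_rng(cfg.seed)
    n_states = cfg.state_range[1] - cfg.state_range[0] + 1
    if cfg.n_populations == len(DEFAULT_SAMPLE_SIZES) and cfg.sample_sizes == list(
        DEFAULT_SAMPLE_SIZES.values()
    ):
        pop_names = list(DEFAULT_SAMPLE_SIZES)
    else:
        pop_names = [f"P{i + 1:02d}" for i in range(cfg.n_populations)]
    freqs = _chain_frequencies(
        cfg.n_populations, cfg.n_loci, n_states, cfg.migration, rng
    )
    calls = _draw_genotypes(
        freqs, cfg.sample_sizes, cfg.inbreeding_f, cfg.state_range[0], rng
    )
    gm = _assemble(calls, cfg.sample_sizes, pop_names, cfg.n_loci, cfg.state_range)
    if cfg.null_rate_max > 0:
        rates = rng.uniform(0.0, cfg.null_rate_max, size=cfg.n_loci)
        gm = inject_nulls(gm, rates, seed=int(rng.integers(2**31)))
    if cfg.missing_fraction > 0:
        gm = inject_missing(gm, cfg.missing_fraction, seed=int(rng.integers(2**31)))
    return gm, _transect_sites(pop_names, cfg.transect_km)


def ibd_landscape(
    n_pops: int,
    m: float,
    seed: int = 0,
    n_loci: int = 15,
    n_per_pop: int = 20,
    state_range: tuple[int, int] = (1, 40),
) -> tuple[GenotypeMatrix, SiteTable]:
    """Clean stepping-stone chain (no inbreeding, nulls or missing data).

    Lower migration ``m`` yields stronger isolation by distance between the
    chord-distance and great-circle matrices.
    """
    if n_pops < 4:
        raise ValueError("need at least four populations")
    rng = np.random.default_rng(seed)
    n_states = state_range[1] - state_range[0] + 1
    pop_names = [f"P{i + 1:02d}" for i in range(n_pops)]
    freqs = _chain_frequencies(n_pops, n_loci, n_states, m, rng)
    calls = _draw_genotypes(freqs, [n_per_pop] * n_pops, 0.0, state_range[0], rng)
    gm = _assemble(calls, [n_per_pop] * n_pops, pop_names, n_loci, state_range)
    return gm, _transect_sites(pop_names, 800.0)


def generate_inbred_panmictic(
    n: int,
    n_loci: int,
    inbreeding_f: float,
    null_rate: float = 0.0,
    seed: int | None = None,
    state_range: tuple[int, int] = (1, 40),
) -> GenotypeMatrix:
    """Single panmictic population with heritable null alleles.

    Unlike :func:`inject_nulls` (which nulls each physical allele copy
    independently, after genotype formation), the null here is an allele of
    the gene pool with frequency ``null_rate``: an autozygous copy of a null
    is null on both chromosomes.  This matches the generative model assumed
    by the joint Bayesian estimator and is the right ground truth for its
    calibration experiments.
    """
    rng = np.random.default_rng(seed)
    smin, smax = state_range
    n_states = smax - smin + 1
    calls = np.empty((n, n_loci, 2), dtype=np.int64)
    for l in range(n_loci):
        k = int(rng.integers(4, 11))
        support = rng.choice(n_states, size=k, replace=False) + smin
        visible = rng.dirichlet(np.full(k, 0.6)) * (1.0 - null_rate)
        states = np.concatenate([support, [MISSING]])  # MISSING doubles as null
        probs = np.concatenate([visible, [null_rate]])
        a1 = rng.choice(states, size=n, p=probs)
        a2 = rng.choice(states, size=n, p=probs)
        ibd = rng.random(n) < inbreeding_f
        a2[ibd] = a1[ibd]
        # observation step: null/null -> missing, null/visible -> homozygote
        only_first = (a1 == MISSING) & (a2 != MISSING)
        only_second = (a2 == MISSING) & (a1 != MISSING)
        a1[only_first] = a2[only_first]
        a2[only_second] = a1[only_second]
        calls[:, l, 0] = a1
        calls[:, l, 1] = a2
    loci = [LocusDef(f"L{l + 1}", state_min=smin, state_max=smax) for l in range(n_loci)]
    ids = [f"ind{i + 1}" for i in range(n)]
    return GenotypeMatrix(ids, ["p1"] * n, loci, calls)


def inject_nulls(
    gm: GenotypeMatrix, rates: np.ndarray | list[float], seed: int | None = None
) -> GenotypeMatrix:
    """Replace allele copies by nulls, independently with the locus rate.

    A null/visible genotype shows as an apparent homozygote for the visible
    allele; null/null becomes MISSING.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (gm.n_loci,):
        raise ValueError("one null rate per locus required")
    if ((rates < 0) | (rates > 1)).any():
        raise ValueError("null rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    calls = gm.calls.copy()
    typed = calls[:, :, 0] != MISSING
    nulled = rng.random(calls.shape) < rates[None, :, None]
    nulled &= typed[:, :, None]
    both = nulled.all(axis=2)
    one_first = nulled[:, :, 0] & ~nulled[:, :, 1]
    one_second = nulled[:, :, 1] & ~nulled[:, :, 0]
    calls[one_first, 0] = calls[one_first, 1]
    calls[one_second, 1] = calls[one_second, 0]
    calls[both] = MISSING
    return GenotypeMatrix(
        list(gm.individual_ids), list(gm.population_ids), list(gm.loci), calls
    )


def inject_missing(
    gm: GenotypeMatrix, fraction: float, seed: int | None = None
) -> GenotypeMatrix:
    """Set ``round(fraction * cells)`` uniformly chosen genotype cells to MISSING."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    calls = gm.calls.copy()
    total = gm.n_individuals * gm.n_loci
    n_target = int(round(fraction * total))
    if n_target:
        chosen = rng.choice(total, size=n_target, replace=False)
        i, l = np.unravel_index(chosen, (gm.n_individuals, gm.n_loci))
        calls[i, l, :] = MISSING
    return GenotypeMatrix(
        list(gm.individual_ids), list(gm.population_ids), list(gm.loci), calls
    )
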