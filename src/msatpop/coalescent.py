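"""Declarative demographic scenarios and a backward-in-time coalescent
simulator for microsatellites under a generalized stepwise mutation model.

Time is discrete in generations (geometric coalescence waiting times), so
the simulator stays accurate for effective sizes as small as the prior
minimum of 10.  Events are processed backward in time: divergences move all
lineages of a child population into its parent, admixture pulses reassign
each lineage of the admixed population to one of two sources, and founder
bottlenecks apply a reduced size for ``db`` generations just before (in
backward time) the founding event.

Mutations follow the generalized stepwise model: Poisson numbers of
mutations per branch, each a +/- k step with geometrically distributed
magnitude (parameter P; P = 0 gives the strict single-step model), with
allele states confined to a bounded range of contiguous states.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace

import numpy as np

from .genotype_io import GenotypeMatrix, LocusDef

__all__ = [
    "Divergence",
    "Admixture",
    "PriorSpec",
    "ScenarioSpec",
    "ParameterDraw",
    "MutationModel",
    "ScenarioError",
    "sample_priors",
    "simulate_alleles",
    "simulate_dataset",
    "scenario_library",
    "validate_scenario",
]


class ScenarioError(ValueError):
    """Raised for structurally invalid demographic scenarios."""


@dataclass(frozen=True)
class Divergence:
    """Backward in time, ``child`` merges into ``parent`` at ``time``.

    ``time`` is either a prior parameter name (e.g. ``"t2"``) or a number.
    """

    child: str
    parent: str
    time: str | float


@dataclass(frozen=True)
class Admixture:
    """Backward in time, each lineage of ``target`` moves to ``source_a``
    with probability ``rate`` (parameter name or number), else ``source_b``."""

    target: str
    source_a: str
    source_b: str
    time: str | float
    rate: str | float = "ra"


@dataclass
class PriorSpec:
    """Uniform priors with order constraints, plus mutation-model priors."""

    ne_range: tuple[int, int] = (10, 1500)
    founder_range: tuple[int, int] = (1, 100)
    time_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "t1": (10, 500),
            "t2": (100, 500),
            "t3": (100, 1000),
            "t4": (500, 3000),
            "t5": (500, 3000),
        }
    )
    # (a, b) means draw[a] < draw[b]
    order_constraints: tuple[tuple[str, str], ...] = (
        ("t1", "t2"),
        ("t1", "t3"),
        ("t1", "t4"),
        ("t1", "t5"),
        ("t2", "t3"),
        ("t2", "t4"),
        ("t2", "t5"),
        ("t3", "t4"),
        ("t3", "t5"),
        ("t4", "t5"),
    )
    ra_range: tuple[float, float] = (0.001, 0.999)
    mean_mu_range: tuple[float, float] = (1e-4, 1e-3)
    locus_mu_range: tuple[float, float] = (1e-5, 1e-2)
    gamma_shape: float = 2.0
    geometric_p: float = 0.22
    db: int = 5


@dataclass
class ScenarioSpec:
    """A declarative backward-in-time demographic model."""

    name: str
    populations: list[str]
    ancestor: str
    divergences: list[Divergence] = field(default_factory=list)
    admixtures: list[Admixture] = field(default_factory=list)
    bottleneck_pops: list[str] | None = None  # default: every founded population
    priors: PriorSpec = field(default_factory=PriorSpec)

    @property
    def all_populations(self) -> list[str]:
        if self.ancestor in self.populations:
            return list(self.populations)
        return list(self.populations) + [self.ancestor]

    def founded_populations(self) -> list[str]:
        out = [d.child for d in self.divergences]
        out.extend(a.target for a in self.admixtures)
        return out

    def time_parameters(self) -> list[str]:
        names = []
        for ev in [*self.divergences, *self.admixtures]:
            if isinstance(ev.time, str):
                names.append(ev.time)
        return sorted(set(names))


@dataclass
class ParameterDraw:
    """One concrete draw from a scenario's priors."""

    ne: dict[str, int]
    founder_n: dict[str, int]
    times: dict[str, int]
    rates: dict[str, float]  # admixture target -> rate
    mean_mu: float
    locus_mu: np.ndarray
    db: int = 5
    generation_time_years: float = 6.0

    def as_flat_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for pop, v in self.ne.items():
            out[f"Ne_{pop}"] = v
        for pop, v in self.founder_n.items():
            out[f"N_{pop}"] = v
        out.update(self.times)
        for pop, v in self.rates.items():
            out[f"ra_{pop}"] = v
        out["mean_mu"] = self.mean_mu
        return out


@dataclass
class MutationModel:
    """Generalized stepwise mutation with bounded allele states."""

    rates: np.ndarray  # per-locus mutation rate
    geometric_p: float = 0.22
    state_min: int = 1
    state_max: int = 40
    boundary: str = "resample"  # or "reflect"

    def __post_init__(self) -> None:
        self.rates = np.atleast_1d(np.asarray(self.rates, dtype=float))
        if not 0.0 <= self.geometric_p < 1.0:
            raise ValueError("geometric parameter P must be in [0, 1)")
        if self.boundary not in ("resample", "reflect"):
            raise ValueError("boundary must be 'resample' or 'reflect'")

    @property
    def founder_state(self) -> int:
        return (self.state_min + self.state_max) // 2


# ---------------------------------------------------------------------------
# Prior sampling
# ---------------------------------------------------------------------------

def sample_priors(
    spec: ScenarioSpec, n_loci: int, seed: int | None = None, max_tries: int = 100_000
) -> ParameterDraw:
    """Draw one parameter set satisfying all ranges and order constraints.

    Order constraints are enforced by rejection sampling over the uniform
    time priors; per-locus mutation rates follow a Gamma distribution
    around the drawn mean, truncated to the per-locus range by resampling.
    """
    rng = np.random.default_rng(seed)
    pr = spec.priors
    used = set(spec.time_parameters())
    constraints = [(a, b) for a, b in pr.order_constraints if a in used and b in used]
    for name in used:
        if name not in pr.time_ranges:
            raise ScenarioError(f"no prior range for time parameter {name!r}")

    times: dict[str, int] = {}
    for _ in range(max_tries):
        cand = {
            name: int(rng.integers(pr.time_ranges[name][0], pr.time_ranges[name][1] + 1))
            for name in used
        }
        if all(cand[a] < cand[b] for a, b in constraints):
            times = cand
            break
    else:
        raise ScenarioError("could not satisfy time order constraints (infeasible priors?)")

    ne = {
        pop: int(rng.integers(pr.ne_range[0], pr.ne_range[1] + 1))
        for pop in spec.all_populations
    }
    founder_n = {
        pop: int(rng.integers(pr.founder_range[0], pr.founder_range[1] + 1))
        for pop in spec.founded_populations()
    }
    rates = {
        a.target: float(rng.uniform(*pr.ra_range))
        for a in spec.admixtures
        if isinstance(a.rate, str)
    }
    mean_mu = float(rng.uniform(*pr.mean_mu_range))
    scale = mean_mu / pr.gamma_shape
    lo, hi = pr.locus_mu_range
    locus_mu = np.empty(n_loci)
    for i in range(n_loci):
        while True:
            v = rng.gamma(pr.gamma_shape, scale)
            if lo <= v <= hi:
                locus_mu[i] = v
                break
    return ParameterDraw(
        ne=ne,
        founder_n=founder_n,
        times=times,
        rates=rates,
        mean_mu=mean_mu,
        locus_mu=locus_mu,
        db=pr.db,
    )


# ---------------------------------------------------------------------------
# Scenario compilation
# ---------------------------------------------------------------------------

def _resolve(value: str | float, times: dict[str, int]) -> float:
    if isinstance(value, str):
        if value not in times:
            raise ScenarioError(f"unresolved time parameter {value!r}")
        return float(times[value])
    return float(value)


def _compile(spec: ScenarioSpec, draw: ParameterDraw):
    """Resolve symbolic parameters into a flat event/size program."""
    pops = spec.all_populations
    pop_id = {p: i for i, p in enumerate(pops)}
    events: list[tuple[float, str, tuple]] = []
    founding_time: dict[str, float] = {}
    for d in spec.divergences:
        t = _resolve(d.time, draw.times)
        events.append((t, "merge", (pop_id[d.child], pop_id[d.parent])))
        founding_time[d.child] = t
    for a in spec.admixtures:
        t = _resolve(a.time, draw.times)
        rate = a.rate if not isinstance(a.rate, str) else draw.rates[a.target]
        events.append(
            (t, "admix", (pop_id[a.target], pop_id[a.source_a], pop_id[a.source_b], float(rate)))
        )
        founding_time[a.target] = t
    events.sort(key=lambda e: e[0])

    bneck_pops = (
        spec.founded_populations() if spec.bottleneck_pops is None else spec.bottleneck_pops
    )
    # per pop: (bottleneck_start, bottleneck_end, bottleneck_size, normal_size)
    sizes = []
    breakpoints = set()
    for p in pops:
        ne = draw.ne[p]
        if p in bneck_pops and p in founding_time:
            tf = founding_time[p]
            start = max(tf - draw.db, 0.0)
            n_b = draw.founder_n.get(p, ne)
            sizes.append((start, tf, n_b, ne))
            breakpoints.add(start)
        else:
            sizes.append((math.inf, math.inf, ne, ne))
    breakpoints.update(t for t, _, _ in events)
    return pop_id, events, sizes, sorted(breakpoints)


def validate_scenario(spec: ScenarioSpec, n_checks: int = 5, seed: int = 0) -> list[str]:
    """Structural validation; returns a list of problems (empty when OK)."""
    problems: list[str] = []
    pops = spec.all_populations
    if len(set(pops)) != len(pops):
        problems.append("duplicate population labels")
    known = set(pops)
    for d in spec.divergences:
        for p in (d.child, d.parent):
            if p not in known:
                problems.append(f"divergence references unknown population {p!r}")
    for a in spec.admixtures:
        for p in (a.target, a.source_a, a.source_b):
            if p not in known:
                problems.append(f"admixture references unknown population {p!r}")
    founded = spec.founded_populations()
    if len(set(founded)) != len(founded):
        problems.append("a population is founded by more than one event")
    if spec.ancestor in founded:
        problems.append("ancestor population cannot be founded by an event")
    if problems:
        return problems

    # connectivity: every sampled population must be able to reach the ancestor
    merged_into: dict[str, list[str]] = {}
    for d in spec.divergences:
        merged_into.setdefault(d.child, []).append(d.parent)
    for a in spec.admixtures:
        merged_into.setdefault(a.target, []).extend([a.source_a, a.source_b])

    def can_reach_ancestor(p: str, seen: frozenset = frozenset()) -> bool:
        if p == spec.ancestor:
            return True
        if p in seen:
            return False
        return any(
            can_reach_ancestor(q, seen | {p}) for q in merged_into.get(p, [])
        )

    for p in spec.populations:
        if not can_reach_ancestor(p):
            problems.append(f"population {p!r} never coalesces into the ancestor")
    if problems:
        return problems

    # dynamic feasibility: simulate one tiny locus under a handful of draws
    mut = MutationModel(rates=np.array([1e-4]))
    sample = {p: 1 for p in spec.populations}
    for i in range(n_checks):
        try:
            draw = sample_priors(spec, n_loci=1, seed=seed + i)
            simulate_alleles(spec, draw, sample, mut, seed=seed + i)
        except ScenarioError as exc:
            problems.append(f"draw {i}: {exc}")
            break
    return problems


# ---------------------------------------------------------------------------
# Core per-locus simulator (performance sensitive: pure python + random)
# ---------------------------------------------------------------------------

def _geometric(rng: random.Random, p: float) -> int:
    """Number of trials to first success, success probability p."""
    if p >= 1.0:
        return 1
    u = rng.random()
    return int(math.log(u) / math.log1p(-p)) + 1


def _poisson(rng: random.Random, lam: float) -> int:
    if lam <= 0.0:
        return 0
    if lam > 30.0:  # normal approximation for the rare long-branch case
        return max(0, int(rng.gauss(lam, math.sqrt(lam)) + 0.5))
    limit = math.exp(-lam)
    k = 0
    prod = rng.random()
    while prod > limit:
        prod *= rng.random()
        k += 1
    return k


def _step(rng: random.Random, state: int, p_geom: float, smin: int, smax: int, reflect: bool) -> int:
    while True:
        k = 1 if p_geom <= 0.0 else int(math.log(rng.random()) / math.log(p_geom)) + 1
        s = state + k if rng.random() < 0.5 else state - k
        if smin <= s <= smax:
            return s
        if reflect:
            # reflect off the boundary once; re-draw only if still outside
            s = 2 * smin - s if s < smin else 2 * smax - s
            if smin <= s <= smax:
                return s


def _simulate_locus(
    n_samples: list[int],
    events: list[tuple[float, str, tuple]],
    sizes: list[tuple[float, float, float, float]],
    breakpoints: list[float],
    mu: float,
    p_geom: float,
    smin: int,
    smax: int,
    reflect: bool,
    rng: random.Random,
) -> list[int]:
    """Simulate one locus; returns allele states of the sampled gene copies
    in population-block order (2 * n_diploids states per population)."""
    n_pops = len(sizes)
    lineages: list[list[int]] = [[] for _ in range(n_pops)]
    parent: list[int] = []
    node_time: list[float] = []
    nid = 0
    for p, n in enumerate(n_samples):
        for _ in range(2 * n):
            lineages[p].append(nid)
            parent.append(-1)
            node_time.append(0.0)
            nid += 1
    n_leaves = nid

    def current_size(p: int, g: float) -> float:
        b0, b1, nb, ne = sizes[p]
        return nb if b0 <= g < b1 else ne

    g = 0.0
    ev_i = 0
    bp = [b for b in breakpoints if b > 0.0]
    bp_i = 0
    total = sum(len(l) for l in lineages)
    # cached candidate coalescence times; valid while a population's lineage
    # count and size regime are unchanged (geometric waits are memoryless).
    # When the per-generation pair rate is high (many lineages in a small
    # population) the one-merger-per-step approximation breaks down, so the
    # population switches to explicit Wright-Fisher generations in which all
    # lineages draw parents and multiple mergers can happen at once.
    cand = [math.inf] * n_pops
    wf_mode = [False] * n_pops
    stale = [True] * n_pops
    dense = 0.3  # pair-rate threshold for the explicit per-generation regime
    while total > 1:
        next_bp = bp[bp_i] if bp_i < len(bp) else math.inf
        best_t = math.inf
        best_p = -1
        for p in range(n_pops):
            if stale[p]:
                k = len(lineages[p])
                if k < 2:
                    cand[p] = math.inf
                else:
                    ne = current_size(p, g)
                    q = k * (k - 1) / (4.0 * ne)
                    if q > dense:
                        cand[p] = g + 1.0
                        wf_mode[p] = True
                    else:
                        cand[p] = g + _geometric(rng, q)
                        wf_mode[p] = False
                stale[p] = False
            if cand[p] < best_t:
                best_t = cand[p]
                best_p = p
        if best_p >= 0 and best_t <= next_bp:
            lin = lineages[best_p]
            if wf_mode[best_p]:
                # one explicit generation: lineages draw parent gene copies
                n_copies = max(int(2 * current_size(best_p, g)), 1)
                buckets: dict[int, list[int]] = {}
                for node in lin:
                    buckets.setdefault(rng.randrange(n_copies), []).append(node)
                new_lin = []
                for members in buckets.values():
                    while len(members) > 1:
                        a = members.pop()
                        b = members.pop()
                        parent.append(-1)
                        node_time.append(best_t)
                        parent[a] = nid
                        parent[b] = nid
                        members.append(nid)
                        nid += 1
                        total -= 1
                    new_lin.append(members[0])
                lineages[best_p] = new_lin
            else:
                # coalesce one random pair at the geometric waiting time
                k = len(lin)
                i = rng.randrange(k)
                j = rng.randrange(k - 1)
                if j >= i:
                    j += 1
                a, b = lin[i], lin[j]
                parent.append(-1)
                node_time.append(best_t)
                parent[a] = nid
                parent[b] = nid
                if i < j:
                    i, j = j, i
                lin.pop(i)
                lin.pop(j)
                lin.append(nid)
                nid += 1
                total -= 1
            g = best_t
            stale[best_p] = True
            continue
        if next_bp is math.inf:
            raise ScenarioError(
                "lineages cannot coalesce: populations remain disconnected"
            )
        g = next_bp
        bp_i += 1
        # size regimes or population contents may change: recompute all
        for p in range(n_pops):
            stale[p] = True
        while ev_i < len(events) and events[ev_i][0] <= g:
            t, kind, payload = events[ev_i]
            ev_i += 1
            if kind == "merge":
                child, par = payload
                lineages[par].extend(lineages[child])
                lineages[child] = []
            else:
                target, src_a, src_b, rate = payload
                for node in lineages[target]:
                    (lineages[src_a] if rng.random() < rate else lineages[src_b]).append(node)
                lineages[target] = []

    # drop mutations root-to-leaves; parents always have larger node ids
    founder = (smin + smax) // 2
    state = [0] * nid
    state[nid - 1] = founder
    for idx in range(nid - 2, -1, -1):
        par = parent[idx]
        s = state[par]
        n_mut = _poisson(rng, mu * (node_time[par] - node_time[idx]))
        for _ in range(n_mut):
            s = _step(rng, s, p_geom, smin, smax, reflect)
        state[idx] = s
    return state[:n_leaves]


# ---------------------------------------------------------------------------
# Public simulation API
# ---------------------------------------------------------------------------

def simulate_alleles(
    spec: ScenarioSpec,
    draw: ParameterDraw,
    sample_spec: dict[str, int],
    mut: MutationModel,
    seed: int | None = None,
) -> np.ndarray:
    """Simulate allele states; returns an int array (total_diploids, n_loci, 2).

    Individuals are blocked by population in ``spec.populations`` order
    (populations absent from ``sample_spec`` get zero samples); diploid
    genotypes pair the exchangeable sampled gene copies.
    """
    n_loci = len(mut.rates)
    rng = random.Random(seed)
    for pop in sample_spec:
        if pop not in spec.populations:
            raise ScenarioError(f"sampled population {pop!r} not in scenario")
    n_samples = [int(sample_spec.get(p, 0)) for p in spec.populations] + [0]
    if sum(n_samples) < 1:
        raise ScenarioError("no individuals sampled")
    _, events, sizes, breakpoints = _compile(spec, draw)
    total_dip = sum(n_samples)
    out = np.empty((total_dip, n_loci, 2), dtype=np.int64)
    reflect = mut.boundary == "reflect"
    for l in range(n_loci):
        states = _simulate_locus(
            n_samples,
            events,
            sizes,
            breakpoints,
            float(mut.rates[l]),
            mut.geometric_p,
            mut.state_min,
            mut.state_max,
            reflect,
            rng,
        )
        out[:, l, 0] = states[0::2]
        out[:, l, 1] = states[1::2]
    return out


def simulate_dataset(
    spec: ScenarioSpec,
    draw: ParameterDraw,
    sample_spec: dict[str, int],
    mut: MutationModel,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Simulate a full :class:`GenotypeMatrix` under the scenario."""
    alleles = simulate_alleles(spec, draw, sample_spec, mut, seed=seed)
    ids, pops = [], []
    for p in spec.populations:
        for i in range(int(sample_spec.get(p, 0))):
            ids.append(f"{p}_{i + 1}")
            pops.append(p)
    loci = [
        LocusDef(f"L{l + 1}", state_min=mut.state_min, state_max=mut.state_max)
        for l in range(len(mut.rates))
    ]
    return GenotypeMatrix(ids, pops, loci, alleles)


# ---------------------------------------------------------------------------
# Scenario library
# ---------------------------------------------------------------------------

CLUSTERS = ["I", "II", "III", "IV", "V"]


def _serial(name: str, order: list[tuple[str, str, str]], ancestor: str = "ANC") -> ScenarioSpec:
    return ScenarioSpec(
        name=name,
        populations=CLUSTERS,
        ancestor=ancestor,
        divergences=[Divergence(c, p, t) for c, p, t in order],
    )


def scenario_library() -> dict[str, ScenarioSpec]:
    """Ten competing colonization scenarios over clusters I-V.

    ``scenario1`` is the serial south-to-north stepping stone;
    ``scenario9`` derives clusters I and III independently from the
    unsampled ancestor with cluster II created by admixture of I and III.
    Scenarios 2-6 (origin in the most diverse cluster) and 7-8, 10
    (alternative admixture timings) are configurable templates from the
    same three hypothesis families.
    """
    lib: dict[str, ScenarioSpec] = {}
    # serial stepping stone: cluster I is the root; exactly four divergences
    lib["scenario1"] = _serial(
        "scenario1",
        [("II", "I", "t4"), ("III", "II", "t3"), ("IV", "III", "t2"), ("V", "IV", "t1")],
        ancestor="I",
    )
    lib["scenario2"] = _serial(
        "scenario2",
        [("I", "II", "t4"), ("III", "II", "t3"), ("IV", "III", "t2"), ("V", "IV", "t1"),
         ("II", "ANC", "t5")],
    )
    lib["scenario3"] = _serial(
        "scenario3",
        [("III", "II", "t4"), ("I", "II", "t3"), ("IV", "III", "t2"), ("V", "IV", "t1"),
         ("II", "ANC", "t5")],
    )
    lib["scenario4"] = _serial(
        "scenario4",
        [("II", "III", "t4"), ("I", "II", "t3"), ("IV", "III", "t2"), ("V", "IV", "t1"),
         ("III", "ANC", "t5")],
    )
    lib["scenario5"] = _serial(
        "scenario5",
        [("III", "II", "t3"), ("I", "II", "t2"), ("IV", "III", "t2"), ("V", "IV", "t1"),
         ("II", "ANC", "t4")],
    )
    lib["scenario6"] = _serial(
        "scenario6",
        [("II", "III", "t3"), ("I", "II", "t2"), ("IV", "III", "t2"), ("V", "IV", "t1"),
         ("III", "ANC", "t4")],
    )
    lib["scenario7"] = ScenarioSpec(
        name="scenario7",
        populations=CLUSTERS,
        ancestor="ANC",
        divergences=[
            Divergence("I", "ANC", "t5"),
            Divergence("III", "ANC", "t4"),
            Divergence("IV", "III", "t2"),
            Divergence("V", "IV", "t1"),
        ],
        admixtures=[Admixture("II", "I", "III", "t3")],
    )
    lib["scenario8"] = ScenarioSpec(
        name="scenario8",
        populations=CLUSTERS,
        ancestor="ANC",
        divergences=[
            Divergence("I", "ANC", "t4"),
            Divergence("III", "ANC", "t3"),
            Divergence("IV", "III", "t2"),
            Divergence("V", "IV", "t1"),
        ],
        admixtures=[Admixture("II", "I", "III", "t1")],
    )
    lib["scenario9"] = ScenarioSpec(
        name="scenario9",
        populations=CLUSTERS,
        ancestor="ANC",
        divergences=[
            Divergence("I", "ANC", "t4"),
            Divergence("III", "ANC", "t3"),
            Divergence("IV", "III", "t2"),
            Divergence("V", "IV", "t1"),
        ],
        admixtures=[Admixture("II", "I", "III", "t2")],
    )
    lib["scenario10"] = ScenarioSpec(
        name="scenario10",
        populations=CLUSTERS,
        ancestor="ANC",
        divergences=[
            Divergence("I", "ANC", "t5"),
            Divergence("III", "ANC", "t4"),
            Divergence("IV", "III", "t3"),
            Divergence("V", "IV", "t2"),
        ],
        admixtures=[Admixture("II", "I", "III", "t1")],
    )
    return lib
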