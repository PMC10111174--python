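"""Genetic and geographic distance matrices, NJ trees and Mantel tests."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .diversity import allele_frequencies
from .genotype_io import MISSING, GenotypeMatrix, SiteTable

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "DistanceMatrix",
    "MantelResult",
    "chord_distance_matrix",
    "shared_allele_distance",
    "great_circle_matrix",
    "mantel",
    "nj_tree",
    "bootstrap_nj",
]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative matrix with labels and a metric tag."""

    labels: list[str]
    values: np.ndarray
    metric_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < -1e-12:
            raise ValueError("negative distances")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def lower_triangle(self) -> np.ndarray:
        idx = np.tril_indices(len(self.labels), k=-1)
        return self.values[idx]

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.metric_tag)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)


# ---------------------------------------------------------------------------
# Genetic distances
# ---------------------------------------------------------------------------

def chord_distance_matrix(gm: GenotypeMatrix) -> DistanceMatrix:
    """Cavalli-Sforza & Edwards chord distance between populations.

    D_C(x, y) = (2 / (pi * L)) * sum over loci of
    sqrt(2 * (1 - sum_a sqrt(x_a * y_a))), skipping loci untyped in either
    population (L reduced accordingly).  Cells with no shared typed locus
    are NaN.
    """
    pops = gm.populations()
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    freqs = allele_frequencies(gm)
    n = len(pops)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            total = 0.0
            n_shared = 0
            for locus in freqs:
                fx = locus.get(pops[i])
                fy = locus.get(pops[j])
                if fx is None or fy is None:
                    continue
                n_shared += 1
                s = sum(math.sqrt(fx[a] * fy[a]) for a in fx.keys() & fy.keys())
                total += math.sqrt(max(2.0 * (1.0 - s), 0.0))
            d = (2.0 / (math.pi * n_shared)) * total if n_shared else float("nan")
            out[i, j] = out[j, i] = d
    return DistanceMatrix(pops, out, "D_C")


def shared_allele_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """Allele-sharing distance between populations.

    For each cross-population individual pair, the per-locus score is the
    number of shared alleles (0-2) divided by 2; D_AS = 1 - mean over loci
    and pairs, using loci typed in both individuals.
    """
    pops = gm.populations()
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    pop_idx = gm.population_index()
    n = len(pops)
    out = np.zeros((n, n))
    calls = gm.calls
    for i in range(n):
        for j in range(i + 1, n):
            scores = []
            for a in pop_idx[pops[i]]:
                for b in pop_idx[pops[j]]:
                    pair_scores = []
                    for l in range(gm.n_loci):
                        g1 = calls[a, l]
                        g2 = calls[b, l]
                        if g1[0] == MISSING or g2[0] == MISSING:
                            continue
                        shared = _shared_alleles(g1, g2)
                        pair_scores.append(shared / 2.0)
                    if pair_scores:
                        scores.append(1.0 - float(np.mean(pair_scores)))
            out[i, j] = out[j, i] = float(np.mean(scores)) if scores else float("nan")
    return DistanceMatrix(pops, out, "D_AS")


def _shared_alleles(g1, g2) -> int:
    """Number of alleles shared between two diploid genotypes (0, 1 or 2)."""
    a, b = sorted(g1.tolist())
    c, d = sorted(g2.tolist())
    if a == c and b == d:
        return 2
    if a in (c, d) or b in (c, d):
        return 1
    return 0


# ---------------------------------------------------------------------------
# Geographic distance
# ---------------------------------------------------------------------------

def great_circle_matrix(sites: SiteTable) -> DistanceMatrix:
    """Haversine distances (km) on a sphere of radius 6371.0 km."""
    coords = np.radians(sites.coordinates())
    lat = coords[:, 0][:, None]
    lon = coords[:, 1][:, None]
    dlat = lat - lat.T
    dlon = lon - lon.T
    h = np.sin(dlat / 2) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(sites.codes, d, "great_circle_km")


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int


def mantel(
    dA: DistanceMatrix,
    dB: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """One-tailed (positive) Mantel test between two distance matrices.

    r is the Pearson correlation of the lower-triangle entries; the null
    distribution permutes the labels of ``dB`` (joint row/column
    permutation); p = (#{r_perm >= r_obs} + 1) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if dA.labels != dB.labels:
        dB = dB.reorder(dA.labels)
    n = len(dA.labels)
    idx = np.tril_indices(n, k=-1)
    x = dA.values[idx]
    y = dB.values[idx]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    xc = (x - x.mean()) / x.std()
    r_obs = float(np.mean(xc * (y - y.mean()) / y.std()))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = dB.values[np.ix_(perm, perm)][idx]
        r_perm = float(np.mean(xc * (yp - yp.mean()) / yp.std()))
        if r_perm >= r_obs - 1e-12:
            hits += 1
    return MantelResult(r=r_obs, p=(hits + 1) / (n_perm + 1), n_perm=n_perm)


# ---------------------------------------------------------------------------
# Neighbor joining with locus bootstrap
# ---------------------------------------------------------------------------

def _nj_merge_order(d: np.ndarray, labels: list[str]) -> "TreeNodeLite":
    """Saitou-Nei neighbor joining; returns the (arbitrarily rooted) tree."""
    nodes = [TreeNodeLite(name=l) for l in labels]
    dist = d.astype(float).copy()
    while len(nodes) > 2:
        m = len(nodes)
        r = dist.sum(axis=1)
        q = (m - 2) * dist - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        dij = dist[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        parent = TreeNodeLite(children=[nodes[i], nodes[j]])
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        new_row = 0.5 * (dist[i, :] + dist[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        new_dist = np.empty((m - 1, m - 1))
        new_dist[:-1, :-1] = dist[np.ix_(keep, keep)]
        new_dist[-1, :-1] = new_row[keep]
        new_dist[:-1, -1] = new_row[keep]
        new_dist[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [parent]
        dist = new_dist
    if len(nodes) == 2:
        a, b = nodes
        b.length = max(dist[0, 1], 0.0)
        a.children.append(b)
        return a
    return nodes[0]


@dataclass
class TreeNodeLite:
    name: str | None = None
    length: float | None = None
    children: list = None
    support: float | None = None

    def __post_init__(self):
        if self.children is None:
            self.children = []

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions as canonical frozensets of leaf names."""
        all_leaves = frozenset(self.leaves())
        out = set()

        def walk(node):
            for child in node.children:
                side = frozenset(child.leaves())
                if 1 < len(side) < len(all_leaves) - 1:
                    other = all_leaves - side
                    out.add(min(side, other, key=lambda s: sorted(s)))
                walk(child)

        walk(self)
        return out

    def newick(self) -> str:
        def fmt(node):
            if node.is_leaf():
                label = node.name or ""
            else:
                inner = ",".join(fmt(c) for c in node.children)
                sup = "" if node.support is None else f"{node.support:g}"
                label = f"({inner}){sup}"
            if node.length is not None:
                label += f":{node.length:.6g}"
            return label

        return fmt(self) + ";"


def nj_tree(d: DistanceMatrix) -> TreeNodeLite:
    """Neighbor-joining tree over the matrix labels (branch lengths >= 0)."""
    if len(d.labels) < 3:
        raise ValueError("need at least three labels")
    if np.isnan(d.values).any():
        raise ValueError("distance matrix has NA cells; prune labels first")
    return _nj_merge_order(d.values, list(d.labels))


def bootstrap_nj(
    gm: GenotypeMatrix,
    n_boot: int = 1000,
    seed: int | None = None,
    distance: str = "D_AS",
) -> TreeNodeLite:
    """NJ tree on the full data with bootstrap-over-loci support values.

    Support for each internal edge is the percentage of replicate trees
    (loci resampled with replacement) containing the same bipartition.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    dist_fn = {"D_AS": shared_allele_distance, "D_C": chord_distance_matrix}[distance]
    tree = nj_tree(dist_fn(gm))
    counts: dict[frozenset, int] = {bp: 0 for bp in tree.bipartitions()}
    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        loci = rng.integers(0, gm.n_loci, size=gm.n_loci)
        rep = nj_tree(dist_fn(gm.take_loci(loci)))
        for bp in rep.bipartitions():
            if bp in counts:
                counts[bp] += 1

    all_leaves = frozenset(tree.leaves())

    def annotate(node):
        for child in node.children:
            side = frozenset(child.leaves())
            if 1 < len(side) < len(all_leaves) - 1:
                key = min(side, all_leaves - side, key=lambda s: sorted(s))
                child.support = 100.0 * counts[key] / n_boot
            annotate(child)

    annotate(tree)
    return tree
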