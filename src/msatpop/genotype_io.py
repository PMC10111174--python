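"""Reading, writing and validating diploid microsatellite genotype data.

Genotypes are stored as unordered pairs of integer allele states (repeat
length codes) per individual and locus.  A genotype is either fully typed
or fully missing; half-typed genotypes are rejected at parse time.

Supported formats: GenePop text files (2- or 3-digit allele codes), a flat
CSV genotype dialect (one row per individual, two columns per locus), and
a CSV site table with degree-minute or decimal coordinates.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Sentinel allele state for a missing genotype (both allele slots).
MISSING = 0

__all__ = [
    "MISSING",
    "LocusDef",
    "GenotypeMatrix",
    "SiteTable",
    "Site",
    "ValidationReport",
    "GenePopParseError",
    "read_genepop",
    "write_genepop",
    "read_genotype_csv",
    "write_genotype_csv",
    "read_sites",
    "parse_coordinate",
    "validate",
]


class GenePopParseError(ValueError):
    """Raised when a genotype file does not conform to its declared layout."""


@dataclass(frozen=True)
class LocusDef:
    """Definition of one microsatellite locus.

    Parameters
    ----------
    name
        Locus label, unique within a dataset.
    motif_length
        Repeat motif length in base pairs (>= 1).
    state_min, state_max
        Inclusive range of permitted allele states.  The default width is
        40 contiguous states.
    """

    name: str
    motif_length: int = 1
    state_min: int = 1
    state_max: int = 40

    def __post_init__(self) -> None:
        if self.motif_length < 1:
            raise ValueError(f"locus {self.name}: motif_length must be >= 1")
        if self.state_max - self.state_min + 1 < 2:
            raise ValueError(f"locus {self.name}: state range width must be >= 2")

    @property
    def n_states(self) -> int:
        return self.state_max - self.state_min + 1


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls for individuals x loci with population labels.

    ``calls`` has shape ``(n_individuals, n_loci, 2)``; a missing genotype
    is encoded as ``(MISSING, MISSING)``.
    """

    individual_ids: list[str]
    population_ids: list[str]
    loci: list[LocusDef]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n = len(self.individual_ids)
        if len(self.population_ids) != n:
            raise ValueError("one population label required per individual")
        if self.calls.shape != (n, len(self.loci), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"({n}, {len(self.loci)}, 2)"
            )
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            i, l = np.argwhere(half)[0]
            raise ValueError(
                f"half-missing genotype for individual "
                f"{self.individual_ids[i]!r} at locus {self.loci[l].name!r}"
            )

    # -- basic introspection -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_names(self) -> list[str]:
        return [loc.name for loc in self.loci]

    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.population_ids:
            seen.setdefault(p)
        return list(seen)

    def population_index(self) -> dict[str, np.ndarray]:
        """Map population label -> integer indices of its individuals."""
        pops = np.asarray(self.population_ids)
        return {p: np.flatnonzero(pops == p) for p in self.populations()}

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci) mask of missing genotypes."""
        return self.calls[:, :, 0] == MISSING

    # -- subsetting ----------------------------------------------------------

    def take_individuals(self, idx: np.ndarray | list[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        return GenotypeMatrix(
            [self.individual_ids[i] for i in idx],
            [self.population_ids[i] for i in idx],
            list(self.loci),
            self.calls[idx].copy(),
        )

    def take_loci(self, idx: np.ndarray | list[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        return GenotypeMatrix(
            list(self.individual_ids),
            list(self.population_ids),
            [self.loci[i] for i in idx],
            self.calls[:, idx].copy(),
        )

    def subset_populations(self, keep: list[str]) -> "GenotypeMatrix":
        keep_set = set(keep)
        idx = [i for i, p in enumerate(self.population_ids) if p in keep_set]
        return self.take_individuals(idx)

    def relabel_populations(self, mapping: dict[str, str]) -> "GenotypeMatrix":
        """Return a copy with population labels mapped (e.g. site -> cluster)."""
        return GenotypeMatrix(
            list(self.individual_ids),
            [mapping.get(p, p) for p in self.population_ids],
            list(self.loci),
            self.calls.copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        sorted_calls = np.sort(self.calls, axis=2)
        other_sorted = np.sort(other.calls, axis=2)
        return (
            self.individual_ids == other.individual_ids
            and self.population_ids == other.population_ids
            and self.locus_names == other.locus_names
            and np.array_equal(sorted_calls, other_sorted)
        )


@dataclass(frozen=True)
class Site:
    code: str
    latitude: float
    longitude: float
    sample_year: int | None = None
    cluster_id: str | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"site {self.code}: latitude {self.latitude} out of range")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"site {self.code}: longitude {self.longitude} out of range")


@dataclass
class SiteTable:
    sites: list[Site]

    def __post_init__(self) -> None:
        codes = [s.code for s in self.sites]
        if len(set(codes)) != len(codes):
            raise ValueError("site codes must be unique")

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    @property
    def codes(self) -> list[str]:
        return [s.code for s in self.sites]

    def coordinates(self) -> np.ndarray:
        """(n, 2) array of (latitude, longitude) in decimal degrees."""
        return np.array([[s.latitude, s.longitude] for s in self.sites])

    def get(self, code: str) -> Site:
        for s in self.sites:
            if s.code == code:
                return s
        raise KeyError(code)


# ---------------------------------------------------------------------------
# GenePop format
# ---------------------------------------------------------------------------

def _detect_digits(token: str) -> int:
    if len(token) in (4, 6):
        return len(token) // 2
    raise GenePopParseError(f"genotype token {token!r} is not 4 or 6 digits wide")


def read_genepop(path: str | Path, dialect: str | None = None) -> GenotypeMatrix:
    """Read a GenePop text file.

    Parameters
    ----------
    path
        Path to the file (title line, locus names, ``Pop`` blocks).
    dialect
        ``"2-digit"`` or ``"3-digit"``; autodetected from the first
        genotype token when omitted.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise GenePopParseError("file too short to be a GenePop file")

    # locus names: either one per line or comma separated on one line
    i = 1
    locus_names: list[str] = []
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = lines[i].strip()
        if chunk:
            locus_names.extend(t.strip() for t in chunk.split(",") if t.strip())
        i += 1
    if i == len(lines):
        raise GenePopParseError("no 'Pop' line found")
    if not locus_names:
        raise GenePopParseError("no locus names declared before first 'Pop'")

    digits = {"2-digit": 2, "3-digit": 3}.get(dialect) if dialect else None

    individual_ids: list[str] = []
    population_ids: list[str] = []
    rows: list[list[int]] = []
    pop_counter = 0
    pop_label = ""
    for lineno in range(i, len(lines)):
        raw = lines[lineno]
        line = raw.strip()
        if not line:
            continue
        if line.lower() == "pop":
            pop_counter += 1
            pop_label = f"pop{pop_counter}"
            continue
        if pop_counter == 0:
            raise GenePopParseError(f"line {lineno + 1}: genotype data before 'Pop'")
        if "," not in line:
            raise GenePopParseError(f"line {lineno + 1}: missing ',' separator")
        ind_id, geno_part = line.split(",", 1)
        tokens = geno_part.split()
        if len(tokens) != len(locus_names):
            raise GenePopParseError(
                f"line {lineno + 1}: expected {len(locus_names)} genotypes, "
                f"found {len(tokens)}"
            )
        row: list[int] = []
        for tok in tokens:
            if not tok.isdigit():
                raise GenePopParseError(f"line {lineno + 1}: bad genotype token {tok!r}")
            if digits is None:
                digits = _detect_digits(tok)
            if len(tok) != 2 * digits:
                raise GenePopParseError(
                    f"line {lineno + 1}: token {tok!r} does not match "
                    f"{digits}-digit dialect"
                )
            a1, a2 = int(tok[:digits]), int(tok[digits:])
            if (a1 == 0) != (a2 == 0):
                raise GenePopParseError(
                    f"line {lineno + 1}: half-missing genotype {tok!r}"
                )
            row.extend((a1, a2))
        individual_ids.append(ind_id.strip())
        population_ids.append(pop_label)
        rows.append(row)

    if not rows:
        raise GenePopParseError("no individuals found")
    calls = np.asarray(rows, dtype=np.int64).reshape(len(rows), len(locus_names), 2)
    state_max = max(40, int(calls.max()))
    loci = [LocusDef(name, state_min=1, state_max=state_max) for name in locus_names]
    return GenotypeMatrix(individual_ids, population_ids, loci, calls)


def write_genepop(
    gm: GenotypeMatrix, path: str | Path, dialect: str = "3-digit", title: str = "msatpop export"
) -> None:
    """Write a GenePop file re-readable by :func:`read_genepop` without loss."""
    if gm.n_individuals == 0:
        raise ValueError("cannot write a GenePop file with no individuals")
    digits = {"2-digit": 2, "3-digit": 3}[dialect]
    limit = 10**digits - 1
    if gm.calls.max() > limit:
        raise ValueError(
            f"allele state {gm.calls.max()} does not fit in {digits}-digit codes"
        )
    out = [title]
    out.extend(gm.locus_names)
    pop_idx = gm.population_index()
    for pop, idx in pop_idx.items():
        out.append("Pop")
        for i in idx:
            toks = [
                f"{gm.calls[i, l, 0]:0{digits}d}{gm.calls[i, l, 1]:0{digits}d}"
                for l in range(gm.n_loci)
            ]
            out.append(f"{gm.individual_ids[i]} , " + " ".join(toks))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# CSV genotype dialect: id, pop, locus1_a1, locus1_a2, locus2_a1, ...
# ---------------------------------------------------------------------------

def read_genotype_csv(
    path: str | Path,
    id_column: int = 0,
    pop_column: int = 1,
    missing_tokens: tuple[str, ...] = ("", "0", "NA", "-9"),
) -> GenotypeMatrix:
    """Read the flat CSV dialect (header row; two allele columns per locus).

    Column positions are configurable because deposited datasets vary in
    their leading metadata columns.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        data_cols = [
            c for c in range(len(header)) if c not in (id_column, pop_column)
        ]
        if len(data_cols) % 2:
            raise ValueError("odd number of allele columns")
        locus_names = [header[c].rsplit("_", 1)[0] for c in data_cols[::2]]
        ids, pops, rows = [], [], []
        for lineno, rec in enumerate(reader, start=2):
            if not rec:
                continue
            ids.append(rec[id_column])
            pops.append(rec[pop_column])
            row = []
            for c1, c2 in zip(data_cols[::2], data_cols[1::2]):
                t1, t2 = rec[c1].strip(), rec[c2].strip()
                m1, m2 = t1 in missing_tokens, t2 in missing_tokens
                if m1 != m2:
                    raise ValueError(f"line {lineno}: half-missing genotype")
                row.extend((MISSING, MISSING) if m1 else (int(t1), int(t2)))
            rows.append(row)
    calls = np.asarray(rows, dtype=np.int64).reshape(len(rows), len(locus_names), 2)
    state_max = max(40, int(calls.max()))
    loci = [LocusDef(n, state_min=1, state_max=state_max) for n in locus_names]
    return GenotypeMatrix(ids, pops, loci, calls)


def write_genotype_csv(gm: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        header = ["id", "pop"]
        for name in gm.locus_names:
            header.extend((f"{name}_1", f"{name}_2"))
        writer.writerow(header)
        for i in range(gm.n_individuals):
            row = [gm.individual_ids[i], gm.population_ids[i]]
            row.extend(str(a) for a in gm.calls[i].ravel())
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Site table
# ---------------------------------------------------------------------------

_DM_RE = re.compile(
    r"""^\s*(\d+(?:\.\d+)?)\s*[°d]\s*(?:(\d+(?:\.\d+)?)\s*[′'m])?\s*([NSEW])?\s*$""",
    re.VERBOSE,
)


def parse_coordinate(text: str) -> float:
    """Parse a coordinate given as decimal degrees or degree-minute notation.

    ``"60°31′"`` -> 60 + 31/60; a trailing S or W hemisphere letter negates.
    """
    text = str(text).strip()
    try:
        return float(text)
    except ValueError:
        pass
    m = _DM_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse coordinate {text!r}")
    deg = float(m.group(1))
    minutes = float(m.group(2)) if m.group(2) else 0.0
    value = deg + minutes / 60.0
    if m.group(3) in ("S", "W"):
        value = -value
    return value


def read_sites(path: str | Path) -> SiteTable:
    """Read a CSV site table with columns code, latitude, longitude
    (+ optional sample_year, cluster)."""
    sites: list[Site] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        cols = {c.lower().strip(): c for c in reader.fieldnames or []}
        for key in ("code", "latitude", "longitude"):
            if key not in cols:
                raise ValueError(f"site table missing required column {key!r}")
        for lineno, rec in enumerate(reader, start=2):
            try:
                lat = parse_coordinate(rec[cols["latitude"]])
                lon = parse_coordinate(rec[cols["longitude"]])
            except ValueError as exc:
                raise ValueError(f"row {lineno}: {exc}") from exc
            year = rec.get(cols.get("sample_year", ""), "")
            cluster = rec.get(cols.get("cluster", ""), "") or None
            sites.append(
                Site(
                    code=rec[cols["code"]].strip(),
                    latitude=lat,
                    longitude=lon,
                    sample_year=int(year) if year else None,
                    cluster_id=cluster,
                )
            )
    return SiteTable(sites)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    n_individuals: int
    n_loci: int
    population_sizes: dict[str, int]
    missing_per_locus: dict[str, int]
    missing_fraction: float
    problems: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.problems

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def validate(gm: GenotypeMatrix) -> ValidationReport:
    """Report per-population sizes, per-locus missingness and range problems."""
    miss = gm.missing_mask()
    problems: list[str] = []
    for l, locus in enumerate(gm.loci):
        typed = gm.calls[:, l][~miss[:, l]]
        if typed.size and (
            typed.min() < locus.state_min or typed.max() > locus.state_max
        ):
            problems.append(
                f"locus {locus.name}: allele states outside declared range "
                f"[{locus.state_min}, {locus.state_max}]"
            )
    sizes = {p: int(len(ix)) for p, ix in gm.population_index().items()}
    total = gm.n_individuals * gm.n_loci
    return ValidationReport(
        n_individuals=gm.n_individuals,
        n_loci=gm.n_loci,
        population_sizes=sizes,
        missing_per_locus={
            loc.name: int(miss[:, l].sum()) for l, loc in enumerate(gm.loci)
        },
        missing_fraction=float(miss.sum() / total) if total else 0.0,
        problems=problems,
    )
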