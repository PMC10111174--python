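"""Bundled reference data: the 16 Baltic-coast sampling sites with their
published per-population diversity summaries, and the default site-to-
cluster assignment used for scenario inference."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .genotype_io import Site, SiteTable, parse_coordinate

__all__ = [
    "load_site_summaries",
    "load_sites",
    "DEFAULT_CLUSTER_MAP",
    "DEFAULT_SAMPLE_SIZES",
]

#: Site code -> genetic cluster (I-V, south to north); the three small,
#: poorly genotyped sites (Vad, Sol, Ror) are unassigned and excluded from
#: scenario inference.  Overridable wherever a cluster map is accepted.
DEFAULT_CLUSTER_MAP: dict[str, str] = {
    "Hal": "I",
    "Lis": "I",
    "Res": "II",
    "Em": "II",
    "Ver": "II",
    "Tul42": "III",
    "Tul3": "III",
    "Tul11": "III",
    "Get": "III",
    "Bla": "IV",
    "Ham": "IV",
    "Vuo": "V",
    "Nad": "V",
}


def load_site_summaries() -> pd.DataFrame:
    """Published per-site summary table (n, N_A, P_A, H_O, H_E, F_IS)."""
    with resources.files("msatpop.data").joinpath("baltic_sites.csv").open() as fh:
        return pd.read_csv(fh)


def load_sites() -> SiteTable:
    """The 16 sampling sites with decimal-degree coordinates."""
    df = load_site_summaries()
    sites = [
        Site(
            code=rec.code,
            latitude=parse_coordinate(rec.latitude),
            longitude=parse_coordinate(rec.longitude),
            sample_year=int(rec.sample_year),
            cluster_id=rec.cluster if isinstance(rec.cluster, str) else None,
        )
        for rec in df.itertuples()
    ]
    return SiteTable(sites)


#: Per-site number of genotyped individuals, in table order.
DEFAULT_SAMPLE_SIZES: dict[str, int] = dict(
    zip(load_site_summaries()["code"], load_site_summaries()["n"])
)
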