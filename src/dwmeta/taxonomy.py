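"""SSU rRNA based taxonomic profiling of assembled metagenomes.

Scaffolds carrying small-subunit rRNA genes act as taxonomic anchors. Hits are
filtered (alignment length >= 100 bp, e-value < 1e-5, host scaffold not
classified as contaminant), deduplicated to the longest gene per scaffold, and
converted to per-sample relative abundances via RPKM of the host scaffold:

    RPKM_i = reads_i / (L_i[kb] * total_mapped[millions])
    relabund_i = RPKM_i / sum_j RPKM_j          (over SSU-bearing scaffolds)

Read counts are reconstructed from mean depth as ``cov_i * L_i / read_length``.
Profiles can then be aggregated to any taxonomic rank, optionally splitting
the phylum Proteobacteria at class level as is conventional in drinking-water
surveys.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .decontam import ScaffoldTable

__all__ = [
    "TaxonProfile",
    "RANKS",
    "make_hit_table",
    "filter_ssu_hits",
    "dedupe_per_scaffold",
    "ssu_relative_abundance",
    "aggregate_by_rank",
]

HIT_COLUMNS = ["hit_id", "scaffold_id", "domain", "lineage", "align_len", "evalue", "gene_len"]

#: lineage fields, outermost first; position in this tuple = index in the
#: semicolon-separated lineage path
RANKS = ("domain", "phylum", "class", "order", "family", "genus")


@dataclass
class TaxonProfile:
    """Relative abundances of taxa in one sample at one rank.

    ``abundances`` is a Series mapping taxon name (or full lineage path when
    ``rank == "lineage"``) to a fraction; nonempty profiles sum to 1.
    """

    sample_id: str
    rank: str
    abundances: pd.Series

    def __post_init__(self) -> None:
        if (self.abundances < 0).any():
            raise ValueError("abundances must be nonnegative")
        if len(self.abundances) and abs(self.abundances.sum() - 1.0) > 1e-9:
            raise ValueError("nonempty profile must sum to 1")


def make_hit_table(rows: Iterable[dict]) -> pd.DataFrame:
    """Build an SSU hit table (one row per hit) with the canonical columns."""
    df = pd.DataFrame(list(rows), columns=HIT_COLUMNS)
    return df


def filter_ssu_hits(
    hits: pd.DataFrame,
    min_align: int = 100,
    max_evalue: float = 1e-5,
    true_scaffolds: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Keep hits with alignment length >= ``min_align`` and e-value strictly
    below ``max_evalue``; hits on scaffolds outside ``true_scaffolds`` (i.e.
    classified contaminant) are removed when that roster is given."""
    if min_align <= 0 or max_evalue <= 0:
        raise ValueError("thresholds must be positive")
    keep = (hits["align_len"] >= min_align) & (hits["evalue"] < max_evalue)
    if true_scaffolds is not None:
        keep &= hits["scaffold_id"].isin(set(true_scaffolds))
    return hits.loc[keep].copy()


def dedupe_per_scaffold(hits: pd.DataFrame) -> pd.DataFrame:
    """Retain the single longest SSU gene per scaffold; on equal gene length
    the lexicographically first hit id wins (deterministic)."""
    if hits.empty:
        return hits.copy()
    best = (
        hits.sort_values(["gene_len", "hit_id"], ascending=[False, True], kind="mergesort")
        .groupby("scaffold_id", sort=False)
        .head(1)
    )
    return hits.loc[hits.index.isin(best.index)].copy()


def ssu_relative_abundance(
    hits: pd.DataFrame,
    scaffolds: ScaffoldTable,
    sample_id: str,
    read_length: float = 250.0,
    total_reads: float | None = None,
) -> TaxonProfile:
    """Lineage-level relative abundance profile for one sample.

    ``hits`` must already be filtered and deduplicated. ``total_reads``
    defaults to the total mapped reads reconstructed from coverage over the
    sample's co-assembly; it cancels in the final normalization but is kept so
    intermediate RPKM values have their conventional scale.
    """
    if sample_id not in scaffolds.cov.columns:
        raise KeyError(f"unknown sample {sample_id!r}")
    hit_scaffs = [s for s in hits["scaffold_id"] if s in scaffolds.meta.index]
    if not hit_scaffs:
        return TaxonProfile(sample_id, "lineage", pd.Series(dtype=float))
    lengths = scaffolds.meta.loc[hit_scaffs, "length"].to_numpy(dtype=float)
    cov = scaffolds.cov.loc[hit_scaffs, sample_id].to_numpy(dtype=float)
    reads = cov * lengths / read_length
    if total_reads is None:
        system = scaffolds.meta.loc[hit_scaffs[0], "system"]
        sys_ids = scaffolds.meta.index[scaffolds.meta["system"] == system]
        total_reads = float(
            (scaffolds.cov.loc[sys_ids, sample_id] * scaffolds.meta.loc[sys_ids, "length"]).sum()
            / read_length
        )
    if total_reads <= 0:
        total_reads = 1.0  # RPKM scale is arbitrary here; normalization below cancels it
    rpkm = reads / ((lengths / 1e3) * (total_reads / 1e6))
    total_rpkm = rpkm.sum()
    if total_rpkm == 0:
        raise ValueError(f"no SSU-bearing scaffold has coverage in sample {sample_id!r}")
    frac = rpkm / total_rpkm
    lineages = hits.set_index("scaffold_id").loc[hit_scaffs, "lineage"]
    ab = pd.Series(frac, index=pd.Index(lineages, name="lineage")).groupby(level=0).sum()
    return TaxonProfile(sample_id, "lineage", ab)


def _taxon_at_rank(lineage: str, rank: str, split_proteobacteria: bool) -> str:
    parts = lineage.split(";")
    idx = RANKS.index(rank)
    if idx >= len(parts) or not parts[idx]:
        return "unclassified"
    name = parts[idx]
    if (
        split_proteobacteria
        and rank == "phylum"
        and name == "Proteobacteria"
        and idx + 1 < len(parts)
        and parts[idx + 1]
    ):
        return parts[idx + 1]
    return name


def aggregate_by_rank(
    profile: TaxonProfile, rank: str, split_proteobacteria: bool = False
) -> TaxonProfile:
    """Sum lineage-level abundances within each taxon at ``rank``.

    With ``split_proteobacteria`` the phylum Proteobacteria is reported at
    class resolution while all other phyla stay at phylum level. Aggregation
    preserves the total exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    if profile.rank != "lineage":
        raise ValueError("can only aggregate a lineage-level profile")
    if profile.abundances.empty:
        return TaxonProfile(profile.sample_id, rank, pd.Series(dtype=float))
    names = [
        _taxon_at_rank(lin, rank, split_proteobacteria) for lin in profile.abundances.index
    ]
    ab = profile.abundances.groupby(pd.Index(names, name=rank)).sum()
    return TaxonProfile(profile.sample_id, rank, ab)
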