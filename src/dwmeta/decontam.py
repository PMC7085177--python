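"""Negative-control based scaffold decontamination and assembly statistics.

Assembled scaffolds from low-biomass samples (drinking water) routinely contain
sequences introduced by reagents, filters, or library preparation. When negative
controls (reagent and filter blanks) are sequenced alongside the samples, each
scaffold can be classified as *true* or *contaminant* by comparing its relative
abundance (RA) and its normalized coverage deviation (NCD = depth SD / mean
depth, a coverage-evenness statistic) between the sample read set (S) and the
contaminant read set (C, negative-control reads not attributable to a spiked
mock community):

* true scaffold:        RA_C = 0,  or  RA_S > RA_C and NCD_S < NCD_C
* contaminant scaffold: RA_S = 0,  or  RA_C > RA_S and NCD_C < NCD_S

RA_S normalizes sample coverage by the summed sample coverage of the
co-assembly; RA_C normalizes contaminant coverage by the summed coverage of the
*full* negative-control read set (NC). Scaffolds matching neither branch are
labeled ambiguous and excluded from downstream "true" sets, as is the
degenerate case of a scaffold covered by neither read set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScaffoldTable",
    "ClassificationResult",
    "AssemblyStats",
    "UndefinedAbundanceError",
    "length_filter",
    "relative_abundance",
    "ncd",
    "classify_scaffold",
    "classify_all",
    "assembly_stats",
]

LABEL_TRUE = "true"
LABEL_CONTAMINANT = "contaminant"
LABEL_AMBIGUOUS = "ambiguous"

#: which printed condition fired
BRANCH_RA_C_ZERO = "ra_c_zero"
BRANCH_SAMPLE_DOMINANT = "sample_dominant"  # RA_S > RA_C and NCD_S < NCD_C
BRANCH_RA_S_ZERO = "ra_s_zero"
BRANCH_CONTROL_DOMINANT = "control_dominant"  # RA_C > RA_S and NCD_C < NCD_S
BRANCH_NONE = "none"


class UndefinedAbundanceError(ValueError):
    """Raised when a relative abundance has a zero denominator but nonzero numerator."""


@dataclass
class ScaffoldTable:
    """Per-scaffold metadata and coverage statistics under three read sets.

    Parameters
    ----------
    meta : DataFrame indexed by scaffold id with columns ``system`` (the
        co-assembly the scaffold belongs to), ``length`` (bp) and ``gc``
        (fraction in [0, 1]).
    cov, cov_sd : scaffold x sample mean depth and per-base depth SD from the
        true sample read sets.
    contam_cov, contam_cov_sd : scaffold x negative-control mean depth and SD
        attributable to contaminant reads.
    nc_cov : scaffold x negative-control mean depth from *all* negative-control
        reads (contaminant + mock background); this is the RA_C denominator.
    sample_systems : optional mapping sample id -> system id. When present,
        classification and profiling restrict each co-assembly to its own
        samples.
    """

    meta: pd.DataFrame
    cov: pd.DataFrame
    cov_sd: pd.DataFrame
    contam_cov: pd.DataFrame
    contam_cov_sd: pd.DataFrame
    nc_cov: pd.DataFrame
    sample_systems: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.meta.index.equals(self.cov.index):
            # keep all coverage frames aligned to the metadata roster
            self.cov = self.cov.reindex(self.meta.index).fillna(0.0)
        for name in ("cov_sd", "contam_cov", "contam_cov_sd", "nc_cov"):
            frame = getattr(self, name)
            if not self.meta.index.equals(frame.index):
                setattr(self, name, frame.reindex(self.meta.index).fillna(0.0))
        if len(self.meta) and (self.meta["length"] < 1).any():
            raise ValueError("scaffold lengths must be >= 1 bp")
        for name in ("cov", "cov_sd", "contam_cov", "contam_cov_sd", "nc_cov"):
            if (getattr(self, name).to_numpy() < 0).any():
                raise ValueError(f"negative values in {name}")

    # -- convenience accessors -------------------------------------------------
    @property
    def scaffold_ids(self) -> pd.Index:
        return self.meta.index

    @property
    def samples(self) -> list[str]:
        return list(self.cov.columns)

    @property
    def controls(self) -> list[str]:
        return list(self.nc_cov.columns)

    def __len__(self) -> int:
        return len(self.meta)

    def subset(self, scaffold_ids: Iterable[str]) -> "ScaffoldTable":
        """Return a new table restricted to ``scaffold_ids`` (order preserved)."""
        ids = [s for s in self.scaffold_ids if s in set(scaffold_ids)]
        return ScaffoldTable(
            meta=self.meta.loc[ids].copy(),
            cov=self.cov.loc[ids].copy(),
            cov_sd=self.cov_sd.loc[ids].copy(),
            contam_cov=self.contam_cov.loc[ids].copy(),
            contam_cov_sd=self.contam_cov_sd.loc[ids].copy(),
            nc_cov=self.nc_cov.loc[ids].copy(),
            sample_systems=dict(self.sample_systems) if self.sample_systems else None,
        )

    def samples_of_system(self, system: str) -> list[str]:
        if self.sample_systems is None:
            return self.samples
        return [s for s in self.samples if self.sample_systems.get(s) == system]

    def mapped_reads(self, read_length: float = 250.0) -> pd.DataFrame:
        """Reconstruct per-sample properly-paired read counts from coverage."""
        return self.cov.mul(self.meta["length"] / read_length, axis=0)


@dataclass(frozen=True)
class ClassificationResult:
    scaffold_id: str | None
    label: str
    branch: str
    ra_s: float
    ra_c: float
    ncd_s: float
    ncd_c: float


@dataclass(frozen=True)
class AssemblyStats:
    n_scaffolds: int
    total_size: int
    n50: int
    gc_mean: float  # percent, length-weighted
    pct_mapped: float  # percent; NaN when sample totals unknown


def length_filter(table: ScaffoldTable, min_len: int = 500) -> ScaffoldTable:
    """Discard scaffolds shorter than ``min_len`` (a scaffold of exactly
    ``min_len`` bp survives); input order preserved."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    keep = table.meta.index[table.meta["length"] >= min_len]
    return table.subset(keep)


def relative_abundance(
    cov: Sequence[float] | np.ndarray, denom_cov: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Relative abundance of each scaffold within one read set.

    ``RA_i = cov_i / sum_j(denom_cov_j)``. For the sample read set the
    denominator is the same coverage vector (self-normalization); for the
    contaminant read set the denominator is the summed negative-control
    coverage.
    """
    cov = np.asarray(cov, dtype=float)
    denom_cov = np.asarray(denom_cov, dtype=float)
    if (cov < 0).any() or (denom_cov < 0).any():
        raise ValueError("coverage values must be nonnegative")
    total = denom_cov.sum()
    if total == 0:
        if cov.sum() == 0:
            return np.zeros_like(cov)
        raise UndefinedAbundanceError(
            "all-zero denominator read set with nonzero scaffold coverage"
        )
    return cov / total


def ncd(depth_mean: float, depth_sd: float) -> float:
    """Normalized coverage deviation: depth SD over mean depth.

    A zero-coverage scaffold returns +inf so it can never win a "lower NCD"
    comparison (it carries no evidence of even coverage).
    """
    if depth_mean < 0 or depth_sd < 0:
        raise ValueError("depth statistics must be nonnegative")
    if depth_mean == 0:
        return math.inf
    return depth_sd / depth_mean


def classify_scaffold(
    ra_s: float,
    ra_c: float,
    ncd_s: float,
    ncd_c: float,
    scaffold_id: str | None = None,
) -> ClassificationResult:
    """Apply the piecewise true/contaminant rule to one scaffold.

    Branch precedence: a scaffold covered by neither read set (RA_S = RA_C = 0)
    is uninformative and labeled ambiguous; otherwise RA_C = 0 -> true,
    RA_S = 0 -> contaminant, then the comparative RA/NCD branches; anything
    matching no branch is ambiguous and excluded from downstream true sets.
    """
    if ra_s < 0 or ra_c < 0 or ncd_s < 0 or ncd_c < 0:
        raise ValueError("inputs must be nonnegative")
    if ra_s == 0 and ra_c == 0:
        label, branch = LABEL_AMBIGUOUS, BRANCH_NONE
    elif ra_c == 0:
        label, branch = LABEL_TRUE, BRANCH_RA_C_ZERO
    elif ra_s == 0:
        label, branch = LABEL_CONTAMINANT, BRANCH_RA_S_ZERO
    elif ra_s > ra_c and ncd_s < ncd_c:
        label, branch = LABEL_TRUE, BRANCH_SAMPLE_DOMINANT
    elif ra_c > ra_s and ncd_c < ncd_s:
        label, branch = LABEL_CONTAMINANT, BRANCH_CONTROL_DOMINANT
    else:
        label, branch = LABEL_AMBIGUOUS, BRANCH_NONE
    return ClassificationResult(scaffold_id, label, branch, ra_s, ra_c, ncd_s, ncd_c)


def _pooled_stats(mean_frame: pd.DataFrame, sd_frame: pd.DataFrame, cols: list[str]):
    """Pool per-column depth means/SDs into a single read-set mean and SD.

    Depths of pooled read sets add; per-base variances of independent
    contributions add, so pooled SD = sqrt(sum of variances).
    """
    mean = mean_frame[cols].sum(axis=1).to_numpy()
    sd = np.sqrt((sd_frame[cols] ** 2).sum(axis=1).to_numpy())
    return mean, sd


def classify_all(table: ScaffoldTable) -> pd.DataFrame:
    """Classify every scaffold, computing RA/NCD within each system's
    co-assembly independently.

    Returns a DataFrame with columns ``scaffold_id, system, label, branch,
    ra_s, ra_c, ncd_s, ncd_c`` in the input scaffold order.
    """
    rows: list[dict] = []
    controls = table.controls
    for system, meta_sys in table.meta.groupby("system", sort=False):
        ids = meta_sys.index
        sys_samples = table.samples_of_system(system)
        s_mean, s_sd = _pooled_stats(
            table.cov.loc[ids], table.cov_sd.loc[ids], sys_samples
        )
        c_mean, c_sd = _pooled_stats(
            table.contam_cov.loc[ids], table.contam_cov_sd.loc[ids], controls
        )
        nc_mean = table.nc_cov.loc[ids].sum(axis=1).to_numpy()
        ra_s = relative_abundance(s_mean, s_mean)
        ra_c = relative_abundance(c_mean, nc_mean)
        for i, sid in enumerate(ids):
            ncd_s = ncd(s_mean[i], s_sd[i])
            ncd_c = ncd(c_mean[i], c_sd[i])
            res = classify_scaffold(ra_s[i], ra_c[i], ncd_s, ncd_c, scaffold_id=sid)
            rows.append(
                {
                    "scaffold_id": sid,
                    "system": system,
                    "label": res.label,
                    "branch": res.branch,
                    "ra_s": res.ra_s,
                    "ra_c": res.ra_c,
                    "ncd_s": res.ncd_s,
                    "ncd_c": res.ncd_c,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.set_index("scaffold_id").loc[table.scaffold_ids].reset_index()
    return out


def true_scaffolds(table: ScaffoldTable, classification: pd.DataFrame) -> ScaffoldTable:
    """Subset the table to scaffolds labeled true (contaminant and ambiguous
    scaffolds are excluded from all further analyses)."""
    keep = classification.loc[classification["label"] == LABEL_TRUE, "scaffold_id"]
    return table.subset(keep)


def n50(lengths: Sequence[int] | np.ndarray) -> int:
    """Smallest length L such that scaffolds of length >= L cover at least half
    of the total assembly bases."""
    lengths = np.asarray(lengths, dtype=np.int64)
    if lengths.size == 0:
        raise ValueError("N50 is undefined for an empty assembly")
    lengths = np.sort(lengths)[::-1]
    csum = np.cumsum(lengths)
    half = csum[-1] / 2.0
    idx = int(np.searchsorted(csum, half, side="left"))
    return int(lengths[idx])


def assembly_stats(
    table: ScaffoldTable,
    sample_totals: Mapping[str, float] | None = None,
    read_length: float = 250.0,
) -> AssemblyStats:
    """Summary statistics for one (sub)assembly: scaffold count, total size,
    N50, length-weighted mean GC (%), and the percentage of sample reads
    mapping back to the scaffolds (when per-sample sequencing totals are
    supplied)."""
    if len(table) == 0:
        raise ValueError("assembly statistics require a nonempty scaffold table")
    lengths = table.meta["length"].to_numpy()
    gc_mean = 100.0 * float(np.average(table.meta["gc"], weights=lengths))
    pct_mapped = float("nan")
    if sample_totals is not None:
        mapped = table.mapped_reads(read_length)
        cols = [s for s in mapped.columns if s in sample_totals]
        total = sum(sample_totals[s] for s in cols)
        if total > 0:
            pct_mapped = 100.0 * float(mapped[cols].to_numpy().sum()) / total
            pct_mapped = min(pct_mapped, 100.0)
    return AssemblyStats(
        n_scaffolds=len(table),
        total_size=int(lengths.sum()),
        n50=n50(lengths),
        gc_mean=gc_mean,
        pct_mapped=pct_mapped,
    )
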