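"""Metagenome-assembled genome (MAG) detection, categorization and abundance.

A MAG passes quality control with completeness strictly above 50% and
redundancy strictly below 10%. It is *detected* in a sample when at least 25%
of its bases are covered by at least one read from that sample (breadth of
coverage). Detection frequencies per disinfection group drive a four-way
categorization:

* D-only:  detected in >= 20% of disinfected samples and in no non-disinfected sample
* ND-only: detected in >= 20% of non-disinfected samples and in no disinfected sample
* both:    detected in >= 20% of the samples of each group
* other:   everything else

Per-sample MAG abundance is RPKM = reads / (total_reads[millions] x
MAG_length[kb]), reported only where the MAG is detected. Genome size is
estimated by scaling MAG length with the inverse of its completeness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MAGRecord",
    "quality_filter",
    "detect",
    "detection_frequencies",
    "categorize",
    "mag_rpkm",
    "mag_rpkm_table",
    "estimate_genome_size",
]

CATEGORY_D_ONLY = "D-only"
CATEGORY_ND_ONLY = "ND-only"
CATEGORY_BOTH = "both"
CATEGORY_OTHER = "other"


@dataclass(frozen=True)
class MAGRecord:
    mag_id: str
    length: int  # bp, sum of member scaffolds
    completeness: float  # percent (0, 100]
    redundancy: float  # percent >= 0
    member_scaffolds: frozenset = field(default_factory=frozenset)
    taxonomy: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("MAG length must be >= 1 bp")
        if not (0 < self.completeness <= 100):
            raise ValueError("completeness must be in (0, 100]")
        if self.redundancy < 0:
            raise ValueError("redundancy must be >= 0")


def quality_filter(
    mags: Iterable[MAGRecord],
    min_completeness: float = 50.0,
    max_redundancy: float = 10.0,
) -> list[MAGRecord]:
    """Keep MAGs with completeness strictly above and redundancy strictly
    below the thresholds (a MAG at exactly 50% completeness or exactly 10%
    redundancy is discarded)."""
    return [
        m
        for m in mags
        if m.completeness > min_completeness and m.redundancy < max_redundancy
    ]


def detect(breadth: pd.DataFrame, threshold: float = 0.25) -> pd.DataFrame:
    """Boolean MAG x sample detection matrix: detected iff breadth of coverage
    >= ``threshold`` (inclusive)."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    arr = breadth.to_numpy(dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("breadth values must lie in [0, 1]")
    return breadth >= threshold


def detection_frequencies(
    detection: pd.DataFrame, groups: Mapping[str, str]
) -> pd.DataFrame:
    """Per-MAG detection frequency and detection count in each group, pooling
    all samples of the group across systems."""
    out = {}
    for g in sorted(set(groups[s] for s in detection.columns)):
        cols = [s for s in detection.columns if groups[s] == g]
        out[f"freq_{g}"] = detection[cols].mean(axis=1)
        out[f"n_detected_{g}"] = detection[cols].sum(axis=1)
    return pd.DataFrame(out)


def categorize(
    detection: pd.DataFrame,
    groups: Mapping[str, str],
    freq_threshold: float = 0.20,
) -> pd.DataFrame:
    """Assign each MAG to D-only / ND-only / both / other.

    ``groups`` maps sample id to "D" or "ND". Frequencies pool all samples of
    a group; the >= 20% frequency threshold is inclusive.
    """
    labels = set(groups[s] for s in detection.columns)
    if labels != {"D", "ND"}:
        raise ValueError("groups must map samples onto exactly {'D', 'ND'}")
    freqs = detection_frequencies(detection, groups)
    cats = []
    for mag_id, row in freqs.iterrows():
        fd, fnd = row["freq_D"], row["freq_ND"]
        nd_det, d_det = row["n_detected_ND"], row["n_detected_D"]
        if fd >= freq_threshold and nd_det == 0:
            cat = CATEGORY_D_ONLY
        elif fnd >= freq_threshold and d_det == 0:
            cat = CATEGORY_ND_ONLY
        elif fd >= freq_threshold and fnd >= freq_threshold:
            cat = CATEGORY_BOTH
        else:
            cat = CATEGORY_OTHER
        cats.append(cat)
    freqs["category"] = cats
    return freqs


def mag_rpkm(
    read_count: float, total_reads: float, mag_len: int, detection: bool
) -> float:
    """RPKM of one MAG in one sample, masked (NaN) where the MAG is not
    detected at the breadth threshold."""
    if total_reads <= 0:
        raise ValueError("total read count must be positive")
    if mag_len <= 0:
        raise ValueError("MAG length must be positive")
    if not detection:
        return float("nan")
    return read_count / ((total_reads / 1e6) * (mag_len / 1e3))


def mag_rpkm_table(
    read_counts: pd.DataFrame,
    total_reads: Mapping[str, float],
    mag_lengths: Mapping[str, int],
    detection: pd.DataFrame,
) -> pd.DataFrame:
    """Vectorized MAG x sample RPKM with non-detected cells masked to NaN."""
    totals = pd.Series({s: float(total_reads[s]) for s in read_counts.columns})
    lengths = pd.Series({m: float(mag_lengths[m]) for m in read_counts.index})
    rpkm = read_counts.div(totals / 1e6, axis=1).div(lengths / 1e3, axis=0)
    return rpkm.where(detection.loc[rpkm.index, rpkm.columns])


def estimate_genome_size(mag_len: int, completeness: float) -> float:
    """Completeness-corrected genome size: ``mag_len * 100 / completeness``."""
    if completeness <= 0 or completeness > 100:
        raise ValueError("completeness must be in (0, 100]")
    if mag_len <= 0:
        raise ValueError("MAG length must be positive")
    return mag_len * 100.0 / completeness
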