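"""KEGG orthology (KO) and module level functional profiling.

KO abundances are estimated from host-scaffold coverage: the read count of a
KO in a sample is ``cov * scaffold_len / read_len`` summed over the scaffolds
carrying it. Two retention filters apply before any module arithmetic:

1. a (sample, KO) pair counts as *detected* only if the KO lies on at least
   one scaffold with strictly greater than 1x coverage in that sample, and
2. a KO is kept in a drinking water system only if it is detected in at least
   two samples of that system.

KEGG modules are ordered blocks of reaction steps; each block is satisfied by
any one of its alternative entries, and an entry that is a complex (subunits
joined by ``+``) requires all of its subunits. Module completeness is the
fraction of satisfied blocks; module abundance is the median read count of the
module's detected KOs in a sample. For comparative statistics only modules
with at most one missing block and at least 50% completeness are retained.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .decontam import ScaffoldTable

__all__ = [
    "ModuleCatalog",
    "KOAbundanceTable",
    "parse_module_definition",
    "format_module_definition",
    "ko_read_count",
    "filter_kos",
    "ko_abundance",
    "module_completeness",
    "module_abundance",
    "module_profiles",
    "filter_modules",
]

ANNOTATION_COLUMNS = ["orf_id", "scaffold_id", "ko_id"]

#: a block is a list of alternatives; each alternative is a tuple of KOs that
#: must all be present (a singleton tuple for a plain KO)
Block = list[tuple[str, ...]]


def _split_top(text: str, sep: str) -> list[str]:
    """Split on ``sep`` ignoring separators nested inside parentheses."""
    parts, depth, buf = [], 0, []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"unbalanced parentheses in {text!r}")
        if ch == sep and depth == 0:
            parts.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
    if depth != 0:
        raise ValueError(f"unbalanced parentheses in {text!r}")
    parts.append("".join(buf))
    return parts


def _strip_outer(text: str) -> str:
    text = text.strip()
    while text.startswith("(") and text.endswith(")"):
        # only strip when the parentheses actually wrap the whole expression
        depth = 0
        wraps = True
        for i, ch in enumerate(text):
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth == 0 and i < len(text) - 1:
                    wraps = False
                    break
        if not wraps:
            break
        text = text[1:-1].strip()
    return text


def parse_module_definition(definition: str) -> list[Block]:
    """Parse a KEGG-style module DEFINITION line into blocks.

    Whitespace separates sequential blocks, commas separate alternatives
    within a block, ``+`` joins complex subunits, and parentheses (one level)
    group alternatives inside a complex: ``(K1,K2)+K3`` expands to the
    alternatives ``K1+K3`` and ``K2+K3``.
    """
    blocks: list[Block] = []
    for raw_block in definition.split():
        block_text = _strip_outer(raw_block)
        if not block_text:
            continue
        alternatives: Block = []
        for alt in _split_top(block_text, ","):
            alt = _strip_outer(alt)
            if not alt:
                raise ValueError(f"empty alternative in block {raw_block!r}")
            # each '+' part is either a KO or a parenthesized option group
            option_sets: list[list[str]] = []
            for part in _split_top(alt, "+"):
                part = part.strip()
                inner = _strip_outer(part)
                options = [p.strip() for p in inner.split(",")] if "," in inner else [inner]
                if any(not o for o in options):
                    raise ValueError(f"malformed complex {alt!r}")
                option_sets.append(options)
            for combo in itertools.product(*option_sets):
                alternatives.append(tuple(combo))
        if not alternatives:
            raise ValueError(f"empty block in definition {definition!r}")
        blocks.append(alternatives)
    if not blocks:
        raise ValueError("module definition has no blocks")
    return blocks


def format_module_definition(blocks: Sequence[Block]) -> str:
    """Inverse of :func:`parse_module_definition` (complex option groups are
    emitted expanded)."""
    out = []
    for block in blocks:
        alts = ",".join("+".join(alt) for alt in block)
        out.append(f"({alts})" if len(block) > 1 else alts)
    return " ".join(out)


@dataclass
class ModuleCatalog:
    """KEGG modules as ordered blocks of alternative KOs/complexes."""

    definitions: dict[str, str]
    blocks: dict[str, list[Block]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.blocks:
            self.blocks = {
                mid: parse_module_definition(d) for mid, d in self.definitions.items()
            }

    def __len__(self) -> int:
        return len(self.definitions)

    def __iter__(self):
        return iter(self.definitions)

    def kos(self, module_id: str) -> set[str]:
        return {ko for block in self.blocks[module_id] for alt in block for ko in alt}

    @classmethod
    def from_definitions(cls, definitions: Mapping[str, str]) -> "ModuleCatalog":
        return cls(dict(definitions))

    @classmethod
    def read(cls, path) -> "ModuleCatalog":
        """Read a flat ``module_id<TAB>definition`` file."""
        defs: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                mid, definition = line.split("\t", 1)
                defs[mid] = definition
        return cls(defs)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for mid, definition in self.definitions.items():
                fh.write(f"{mid}\t{definition}\n")


def ko_read_count(cov: float, scaffold_len: float, read_len: float) -> float:
    """Estimated reads supporting a KO on one host scaffold:
    ``cov * scaffold_len / read_len``; counts from multiple host scaffolds add."""
    if read_len <= 0:
        raise ValueError("read length must be positive")
    if scaffold_len <= 0:
        raise ValueError("scaffold length must be positive")
    return cov * scaffold_len / read_len


def filter_kos(
    annotations: pd.DataFrame,
    scaffolds: ScaffoldTable,
    min_cov: float = 1.0,
    min_samples: int = 2,
) -> set[tuple[str, str]]:
    """Retained (sample, KO) pairs under the coverage and recurrence filters.

    A pair survives iff the KO lies on >= 1 scaffold with coverage strictly
    greater than ``min_cov`` in that sample, and the KO is detected (by that
    same criterion) in >= ``min_samples`` samples of the same system.
    """
    retained: set[tuple[str, str]] = set()
    if annotations.empty:
        return retained
    ann = annotations.merge(
        scaffolds.meta[["system"]], left_on="scaffold_id", right_index=True, how="inner"
    )
    for system, ann_sys in ann.groupby("system", sort=False):
        sys_samples = scaffolds.samples_of_system(system)
        if not sys_samples:
            continue
        # scaffold x sample detection at > min_cov
        host_ids = ann_sys["scaffold_id"].unique()
        covered = scaffolds.cov.loc[host_ids, sys_samples] > min_cov
        detected: dict[str, set[str]] = {}
        for ko, grp in ann_sys.groupby("ko_id", sort=False):
            hit = covered.loc[grp["scaffold_id"].unique()].any(axis=0)
            detected[ko] = set(hit.index[hit])
        for ko, samples in detected.items():
            if len(samples) >= min_samples:
                retained.update((s, ko) for s in samples)
    return retained


@dataclass
class KOAbundanceTable:
    """Sample x KO estimated read counts and RPKM-normalized abundances."""

    counts: pd.DataFrame
    rpkm: pd.DataFrame

    def kos_present(self, sample_id: str) -> set[str]:
        row = self.counts.loc[sample_id]
        return set(row.index[row > 0])


def ko_abundance(
    annotations: pd.DataFrame,
    scaffolds: ScaffoldTable,
    retained: set[tuple[str, str]] | None = None,
    read_length: float = 250.0,
    total_reads: Mapping[str, float] | None = None,
) -> KOAbundanceTable:
    """Estimate per-sample KO read counts and RPKM.

    When ``retained`` is given (the output of :func:`filter_kos`) all other
    (sample, KO) cells are zeroed. RPKM divides the count by total sample
    reads (millions) and the summed length (kb) of the KO's host scaffolds in
    the sample's system.
    """
    samples = scaffolds.samples
    if annotations.empty:
        empty = pd.DataFrame(0.0, index=pd.Index(samples, name="sample_id"), columns=[])
        return KOAbundanceTable(empty, empty.copy())
    ann = annotations.merge(
        scaffolds.meta[["system", "length"]],
        left_on="scaffold_id",
        right_index=True,
        how="inner",
    ).drop_duplicates(["scaffold_id", "ko_id"])
    kos = sorted(ann["ko_id"].unique())
    counts = pd.DataFrame(0.0, index=pd.Index(samples, name="sample_id"), columns=kos)
    hostlen = pd.DataFrame(0.0, index=counts.index, columns=kos)
    for system, ann_sys in ann.groupby("system", sort=False):
        sys_samples = scaffolds.samples_of_system(system)
        if not sys_samples:
            continue
        per_scaffold = scaffolds.cov.loc[ann_sys["scaffold_id"], sys_samples].mul(
            scaffolds.meta.loc[ann_sys["scaffold_id"], "length"].to_numpy() / read_length,
            axis=0,
        )
        per_scaffold.index = pd.Index(ann_sys["ko_id"])
        ko_counts = per_scaffold.groupby(level=0).sum()
        counts.loc[sys_samples, ko_counts.index] += ko_counts.T.loc[sys_samples]
        lens = ann_sys.groupby("ko_id")["length"].sum()
        for s in sys_samples:
            hostlen.loc[s, lens.index] += lens
    if retained is not None:
        mask = pd.DataFrame(False, index=counts.index, columns=counts.columns)
        for s, ko in retained:
            if s in mask.index and ko in mask.columns:
                mask.loc[s, ko] = True
        counts = counts.where(mask, 0.0)
    if total_reads is None:
        total_reads = scaffolds.mapped_reads(read_length).sum(axis=0).to_dict()
    totals = pd.Series({s: float(total_reads.get(s, 0.0)) for s in samples})
    with np.errstate(divide="ignore", invalid="ignore"):
        rpkm = counts.div(totals / 1e6, axis=0).div(hostlen / 1e3)
    rpkm = rpkm.fillna(0.0).replace([np.inf, -np.inf], 0.0)
    return KOAbundanceTable(counts, rpkm)


def module_completeness(
    blocks: Sequence[Block], present_kos: Iterable[str]
) -> tuple[float, int]:
    """Fraction of complete blocks and the number of missing blocks.

    A block is complete iff at least one alternative is fully present; a
    complex alternative requires all of its subunits.
    """
    present = set(present_kos)
    if not blocks:
        raise ValueError("module has no blocks")
    complete = 0
    for block in blocks:
        if not block:
            raise ValueError("malformed module: empty block")
        if any(all(ko in present for ko in alt) for alt in block):
            complete += 1
    missing = len(blocks) - complete
    return complete / len(blocks), missing


def module_abundance(
    blocks: Sequence[Block], ko_abundances: Mapping[str, float]
) -> tuple[float, bool]:
    """Median abundance of the module's detected KOs in one sample.

    ``ko_abundances`` maps the sample's *retained* KOs to their read counts.
    Modules with no detected member KO get abundance 0 and detected=False.
    Even-count medians use the mean of the two central values.
    """
    member_kos = {ko for block in blocks for alt in block for ko in alt}
    values = [ko_abundances[ko] for ko in sorted(member_kos) if ko in ko_abundances]
    if not values:
        return 0.0, False
    return float(np.median(values)), True


def module_profiles(
    catalog: ModuleCatalog,
    ko_table: KOAbundanceTable,
) -> pd.DataFrame:
    """Per (sample, module) abundance, detection flag, completeness and block
    counts, computed from the retained KO counts."""
    rows = []
    for sample_id in ko_table.counts.index:
        row = ko_table.counts.loc[sample_id]
        present = {ko: v for ko, v in row.items() if v > 0}
        for mid in catalog:
            blocks = catalog.blocks[mid]
            completeness, missing = module_completeness(blocks, present.keys())
            abundance, detected = module_abundance(blocks, present)
            rows.append(
                {
                    "sample_id": sample_id,
                    "module_id": mid,
                    "abundance": abundance,
                    "detected": detected,
                    "completeness": completeness,
                    "missing_blocks": missing,
                    "total_blocks": len(blocks),
                }
            )
    return pd.DataFrame(rows)


def filter_modules(
    profiles: pd.DataFrame,
    max_missing: int = 1,
    min_completeness: float = 0.5,
) -> pd.DataFrame:
    """Retain rows with at most ``max_missing`` missing blocks and completeness
    of at least ``min_completeness`` (both bounds inclusive)."""
    keep = (profiles["missing_blocks"] <= max_missing) & (
        profiles["completeness"] >= min_completeness
    )
    return profiles.loc[keep].copy()
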