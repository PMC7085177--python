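"""Community dissimilarity: MinHash sketches, Bray-Curtis, BioEnv, and
permutation tests on distance matrices.

Sketch distances follow the standard MinHash construction: the sketch keeps
the ``size`` smallest 64-bit hash values over canonical (strand-minimum)
k-mers; the Jaccard index ``j`` between two sequence sets is estimated from
the merged sketch, and converted to a distance with

    D = -(1/k) * ln(2j / (1 + j)),   capped at 1, with j = 0 -> D = 1.

Bray-Curtis dissimilarity on KO abundance vectors, an exhaustive BioEnv search
over environmental-variable subsets (Spearman correlation between community
distances and Euclidean distances of z-scored variable subsets), a
label-permutation group test on pairwise distance distributions, and Pearson
correlation of distance matrices complete the comparison toolkit.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, rankdata
from skbio import DistanceMatrix

__all__ = [
    "Sketch",
    "BioEnvResult",
    "PermTestResult",
    "minhash_sketch",
    "sketch_distance",
    "sketch_distance_matrix",
    "bray_curtis",
    "bray_curtis_matrix",
    "bioenv",
    "group_distance_test",
    "matrix_correlation",
]

_U64 = np.uint64
_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase


def _mix64(x: np.ndarray, seed: int) -> np.ndarray:
    """64-bit finalizer-style hash (invertible, so distinct k-mers collide
    never) with the seed folded in."""
    x = x.astype(_U64, copy=True)
    x ^= _U64((seed * 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF)
    x ^= x >> _U64(33)
    x *= _U64(0xFF51AFD7ED558CCD)
    x ^= x >> _U64(33)
    x *= _U64(0xC4CEB9FE1A85EC53)
    x ^= x >> _U64(33)
    return x


def _canonical_codes(seq: str, k: int) -> np.ndarray:
    """2-bit packed codes of the canonical k-mers of ``seq``; windows touching
    non-ACGT symbols are skipped."""
    b = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    m = len(b) - k + 1
    if m <= 0:
        return np.empty(0, dtype=_U64)
    invalid = (b > 3).astype(np.int32)
    bad = np.cumsum(np.concatenate([[0], invalid]))
    window_bad = (bad[k:] - bad[:-k]) > 0
    b64 = b.astype(_U64)
    fwd = np.zeros(m, dtype=_U64)
    for j in range(k):
        fwd = (fwd << _U64(2)) | b64[j : j + m]
    rev = np.zeros(m, dtype=_U64)
    for j in range(k - 1, -1, -1):
        rev = (rev << _U64(2)) | (_U64(3) - b64[j : j + m])
    canon = np.minimum(fwd, rev)
    return canon[~window_bad]


@dataclass(frozen=True)
class Sketch:
    """MinHash sketch: the ``size`` smallest distinct hash values of canonical
    k-mers, stored sorted ascending."""

    k: int
    size: int
    seed: int
    hashes: np.ndarray

    def __post_init__(self) -> None:
        if len(self.hashes) > self.size:
            raise ValueError("sketch holds more hashes than its size")
        if len(self.hashes) > 1 and not (self.hashes[:-1] < self.hashes[1:]).all():
            raise ValueError("sketch hashes must be strictly increasing")


def minhash_sketch(
    sequences: Iterable[str],
    k: int = 21,
    size: int = 1000,
    seed: int = 42,
    min_copies: int = 1,
) -> Sketch:
    """Sketch a sequence set.

    ``min_copies`` drops k-mers seen fewer than that many times across the
    whole set (useful in read mode, where singleton k-mers are dominated by
    sequencing errors; the field default there is 2).
    """
    if k < 1 or size < 1:
        raise ValueError("k and size must be >= 1")
    if 2 * k > 64:
        raise ValueError("k must be <= 32 for 2-bit packing")
    chunks = [_canonical_codes(str(s), k) for s in sequences]
    if chunks:
        codes = np.concatenate(chunks)
    else:
        codes = np.empty(0, dtype=_U64)
    if codes.size == 0:
        return Sketch(k, size, seed, np.empty(0, dtype=_U64))
    if min_copies > 1:
        uniq, counts = np.unique(codes, return_counts=True)
        uniq = uniq[counts >= min_copies]
    else:
        uniq = np.unique(codes)
    hashes = np.sort(_mix64(uniq, seed))
    return Sketch(k, size, seed, hashes[:size])


def sketch_distance(a: Sketch, b: Sketch) -> float:
    """Mash-style distance from the merged-sketch Jaccard estimate."""
    if (a.k, a.size, a.seed) != (b.k, b.size, b.seed):
        raise ValueError("sketches have mismatched parameters (k, size, seed)")
    if len(a.hashes) == 0 and len(b.hashes) == 0:
        return 0.0
    if len(a.hashes) == 0 or len(b.hashes) == 0:
        return 1.0
    union = np.union1d(a.hashes, b.hashes)
    merged = union[: a.size]
    shared = int(
        (np.isin(merged, a.hashes, assume_unique=True)
         & np.isin(merged, b.hashes, assume_unique=True)).sum()
    )
    j = shared / len(merged)
    if j == 0.0:
        return 1.0
    d = -(1.0 / a.k) * math.log(2.0 * j / (1.0 + j))
    return min(d, 1.0)


def sketch_distance_matrix(sketches: Mapping[str, Sketch]) -> DistanceMatrix:
    ids = list(sketches)
    n = len(ids)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        mat[i, j] = mat[j, i] = sketch_distance(sketches[ids[i]], sketches[ids[j]])
    return DistanceMatrix(mat, ids)


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity ``sum|x-y| / sum(x+y)``; two all-zero vectors
    are defined as identical (0)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be nonnegative")
    denom = (x + y).sum()
    if denom == 0:
        return 0.0
    return float(np.abs(x - y).sum() / denom)


def bray_curtis_matrix(abundances: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis over the rows (samples) of an abundance table."""
    ids = list(abundances.index)
    arr = abundances.to_numpy(dtype=float)
    n = len(ids)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        mat[i, j] = mat[j, i] = bray_curtis(arr[i], arr[j])
    return DistanceMatrix(mat, ids)


@dataclass
class BioEnvResult:
    """All evaluated variable subsets ranked by Spearman rho."""

    results: pd.DataFrame  # columns: subset (tuple), size, rho; sorted by rho desc
    best_subset: tuple[str, ...]
    best_rho: float

    @property
    def n_subsets(self) -> int:
        return len(self.results)


def bioenv(
    community: DistanceMatrix,
    env: pd.DataFrame,
    variables: Sequence[str] | None = None,
) -> BioEnvResult:
    """Exhaustive BioEnv search.

    For every nonempty subset of candidate variables, z-score the variables
    (sample SD), compute Euclidean distances between samples on the subset,
    and rank-correlate (Spearman, average ranks for ties) that condensed
    vector against the community distances. Evaluates exactly ``2^n - 1``
    subsets. Constant variables are excluded with a warning.
    """
    samples = list(community.ids)
    if variables is None:
        variables = list(env.columns)
    if not variables:
        raise ValueError("no candidate variables")
    table = env.loc[samples, list(variables)].astype(float)
    if table.isna().any().any():
        raise ValueError("environmental table has missing values for these samples")
    sd = table.std(ddof=1)
    constant = [v for v in variables if sd[v] == 0 or np.isnan(sd[v])]
    if constant:
        warnings.warn(
            f"excluding constant environmental variables: {constant}", stacklevel=2
        )
        variables = [v for v in variables if v not in constant]
        if not variables:
            raise ValueError("all candidate variables are constant")
    z = (table[variables] - table[variables].mean()) / table[variables].std(ddof=1)
    z = z.to_numpy()
    comm_rank = rankdata(community.condensed_form())
    rows = []
    for r in range(1, len(variables) + 1):
        for subset_idx in itertools.combinations(range(len(variables)), r):
            ed = pdist(z[:, subset_idx], metric="euclidean")
            rho = float(np.corrcoef(rankdata(ed), comm_rank)[0, 1])
            rows.append(
                {
                    "subset": tuple(variables[i] for i in subset_idx),
                    "size": r,
                    "rho": rho,
                }
            )
    results = pd.DataFrame(rows).sort_values(
        ["rho", "size"], ascending=[False, True], kind="mergesort"
    )
    results = results.reset_index(drop=True)
    best = results.iloc[0]
    return BioEnvResult(results, tuple(best["subset"]), float(best["rho"]))


@dataclass(frozen=True)
class PermTestResult:
    observed: float
    n_perm: int
    p_value: float
    seed: int
    method: str


def _pairclass_f(d: np.ndarray, is_a: np.ndarray, iu: tuple[np.ndarray, np.ndarray]):
    """One-way ANOVA F of pairwise distances across the three pair classes
    (within group A, within group B, between), vectorized over permutations.

    ``is_a``: (P, n) boolean matrix of group-A membership per permutation.
    """
    ai = is_a[:, iu[0]]
    aj = is_a[:, iu[1]]
    classes = np.stack([ai & aj, ~ai & ~aj, ai ^ aj])  # (3, P, npairs)
    npairs = d.size
    grand = d.mean()
    sst = ((d - grand) ** 2).sum()
    counts = classes.sum(axis=2)  # (3, P)
    sums = classes @ d  # (3, P)
    with np.errstate(divide="ignore", invalid="ignore"):
        means = sums / counts
    ssb = (counts * (means - grand) ** 2).sum(axis=0)
    ssw = sst - ssb
    dfb, dfw = 2, npairs - 3
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / dfb) / (ssw / dfw)
    return np.nan_to_num(f, nan=0.0, posinf=np.inf)


def group_distance_test(
    dist: DistanceMatrix,
    groups: Mapping[str, str],
    n_perm: int = 999,
    seed: int = 0,
    method: str = "pairclass",
) -> PermTestResult:
    """Permutation test for a group effect on pairwise distances.

    ``method="pairclass"`` (default): the observed statistic is an F-like
    ratio of among- to within-class variance of the pairwise distances, the
    classes being within-group-1, within-group-2 and between-group pairs. The
    null is built by reshuffling group labels ``n_perm`` times;
    ``p = (exceedances + 1) / (n_perm + 1)``.

    ``method="permanova"`` delegates to scikit-bio's PERMANOVA on the
    distance matrix itself (pseudo-F on sums of squares).
    """
    samples = list(dist.ids)
    labels = np.array([groups[s] for s in samples])
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError("exactly two groups are required")
    sizes = [(labels == u).sum() for u in uniq]
    if min(sizes) < 2:
        raise ValueError("degenerate grouping: each group needs >= 2 samples")
    if method == "permanova":
        from skbio.stats.distance import permanova

        np.random.seed(seed % (2**32))
        res = permanova(dist, grouping=list(labels), permutations=n_perm)
        return PermTestResult(
            float(res["test statistic"]), n_perm, float(res["p-value"]), seed, method
        )
    if method != "pairclass":
        raise ValueError(f"unknown method {method!r}")
    n = len(samples)
    iu = np.triu_indices(n, 1)
    d = dist.condensed_form()
    is_a_obs = (labels == uniq[0])[None, :]
    f_obs = float(_pairclass_f(d, is_a_obs, iu)[0])
    rng = np.random.default_rng(seed)
    # permute a *sorted* label vector so the null sequence depends only on the
    # group sizes and the seed, not on the input sample order
    base = np.sort(labels == uniq[0])
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    perms = base[order]
    f_null = _pairclass_f(d, perms, iu)
    exceed = int((f_null >= f_obs).sum())
    p = (exceed + 1) / (n_perm + 1)
    return PermTestResult(f_obs, n_perm, p, seed, "pairclass")


def aggregate_distance_matrix(
    dm: DistanceMatrix, mapping: Mapping[str, str]
) -> DistanceMatrix:
    """Average a sample-level distance matrix into group (e.g. system) level:
    the (A, B) entry is the mean distance over all cross pairs with one sample
    in A and one in B."""
    groups = sorted(set(mapping[s] for s in dm.ids))
    idx = {g: [i for i, s in enumerate(dm.ids) if mapping[s] == g] for g in groups}
    data = dm.data
    n = len(groups)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        block = data[np.ix_(idx[groups[i]], idx[groups[j]])]
        mat[i, j] = mat[j, i] = float(block.mean())
    return DistanceMatrix(mat, groups)


def matrix_correlation(
    a: DistanceMatrix,
    b: DistanceMatrix,
    mapping: Mapping[str, str] | None = None,
) -> float:
    """Pearson correlation between the condensed upper triangles of two
    distance matrices. When ``mapping`` is given, ``a`` is first averaged to
    the coarser label set (e.g. read-level sample distances averaged within
    system pairs before comparison with scaffold-level system distances)."""
    if mapping is not None:
        a = aggregate_distance_matrix(a, mapping)
    if set(a.ids) != set(b.ids):
        raise ValueError("distance matrices must share labels")
    b = b.filter(a.ids)
    x = a.condensed_form()
    y = b.condensed_form()
    if x.size < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    return float(pearsonr(x, y)[0])
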