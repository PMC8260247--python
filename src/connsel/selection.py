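"""Voxel-set selection under the leave-one-split-out scheme.

The six runs are partitioned into three splits of two runs; each fold
uses one split for voxel selection (connectivity or activation scores)
and the remaining two splits for decoding, keeping selection and
decoding data disjoint to avoid circular analysis.  Selection modes:
``most_connected`` / ``least_connected`` (top/bottom k by mean Fisher-z
connectivity), ``most_activated`` (top k by the comparison-specific
contrast t), and activation-matched ``matched_strong`` /
``matched_weak`` pairs drawn by permutation from a connectivity median
split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

MOST_CONNECTED = "most_connected"
LEAST_CONNECTED = "least_connected"
MOST_ACTIVATED = "most_activated"
MATCHED_STRONG = "matched_strong"
MATCHED_WEAK = "matched_weak"

MATCH_THRESHOLDS = ("liberal", "intermediate", "strict")

DEFAULT_K = 100


@dataclass(frozen=True)
class Fold:
    fold_id: int
    selection_split: tuple[int, ...]
    decoding_splits: tuple[tuple[int, ...], ...]

    @property
    def decoding_runs(self) -> tuple[int, ...]:
        return tuple(r for s in self.decoding_splits for r in s)


@dataclass
class SplitScheme:
    """Three disjoint run pairs and the folds they generate."""

    splits: list[tuple[int, ...]]
    folds: list[Fold] = field(default_factory=list)

    def __post_init__(self):
        if not self.folds:
            self.folds = [
                Fold(
                    fold_id=i,
                    selection_split=s,
                    decoding_splits=tuple(
                        t for j, t in enumerate(self.splits) if j != i
                    ),
                )
                for i, s in enumerate(self.splits)
            ]


def make_split_scheme(n_runs: int = 6, seed: int = 0,
                      splits: list[tuple[int, ...]] | None = None) -> SplitScheme:
    """Randomly partition runs into three two-run splits; build folds.

    Each split serves as the selection split in exactly one fold, with
    the remaining two splits providing the decoding data.  ``n_runs``
    must be 6 unless an explicit partition override is supplied.
    """
    if splits is not None:
        flat = sorted(r for s in splits for r in s)
        if flat != list(range(len(flat))):
            raise ValueError("explicit splits must partition the runs")
        return SplitScheme(splits=[tuple(s) for s in splits])
    if n_runs != 6:
        raise ValueError("n_runs must be 6 (or pass an explicit partition)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_runs)
    parts = [tuple(sorted(int(r) for r in perm[i : i + 2])) for i in range(0, n_runs, 2)]
    return SplitScheme(splits=parts)


@dataclass
class VoxelSet:
    """An ordered set of selected voxel indices with provenance."""

    indices: np.ndarray
    k: int
    mode: str
    fold_id: int | None = None
    contrast_used: str | None = None
    region: str | None = None

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size != self.k:
            raise ValueError("voxel set size must equal k")

    def to_dict(self) -> dict:
        return {
            "indices": self.indices.tolist(),
            "k": self.k,
            "mode": self.mode,
            "fold_id": self.fold_id,
            "contrast_used": self.contrast_used,
            "region": self.region,
        }


def _ranked(scores: np.ndarray, eligibility: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    elig = np.isfinite(scores)
    if eligibility is not None:
        elig &= np.asarray(eligibility, dtype=bool)
    pool = np.flatnonzero(elig)
    return pool, scores[pool]


def select_top_k(
    scores: np.ndarray,
    k: int = DEFAULT_K,
    direction: str = "most",
    eligibility: np.ndarray | None = None,
    **set_kwargs,
) -> VoxelSet:
    """k voxels with the largest ("most") or smallest ("least") scores.

    Ties are broken by ascending voxel index.  Requires at least 2k
    eligible voxels so most/least sets are disjoint by construction.
    """
    if direction not in ("most", "least"):
        raise ValueError("direction must be 'most' or 'least'")
    pool, vals = _ranked(scores, eligibility)
    if pool.size < 2 * k:
        raise ValueError(f"need >= {2 * k} eligible voxels, have {pool.size}")
    key = -vals if direction == "most" else vals
    order = np.lexsort((pool, key))
    mode = MOST_CONNECTED if direction == "most" else LEAST_CONNECTED
    return VoxelSet(indices=pool[order[:k]], k=k,
                    mode=set_kwargs.pop("mode", mode), **set_kwargs)


def select_most_activated(
    tmap: np.ndarray,
    k: int = DEFAULT_K,
    contrast: str | None = None,
    eligibility: np.ndarray | None = None,
    **set_kwargs,
) -> VoxelSet:
    """Top-k voxels by the comparison-specific contrast t value."""
    return select_top_k(
        tmap, k=k, direction="most", eligibility=eligibility,
        mode=MOST_ACTIVATED, contrast_used=contrast, **set_kwargs,
    )


def pooled_t(a_mean, a_var, b_mean, b_var, n_a, n_b):
    """Student's pooled-variance two-sample t (vectorized).

    The degenerate case of zero pooled variance (all values equal) is
    defined as t = 0.
    """
    sp2 = ((n_a - 1) * a_var + (n_b - 1) * b_var) / (n_a + n_b - 2)
    denom = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (a_mean - b_mean) / np.where(denom > 0, denom, 1.0), 0.0)
    return t


def _retain(t: np.ndarray, df: int, threshold_mode: str) -> np.ndarray:
    if threshold_mode == "liberal":
        p = 2 * stats.t.sf(np.abs(t), df)
        return p > 0.10
    if threshold_mode == "intermediate":
        return (t >= -0.5) & (t <= 0.5)
    if threshold_mode == "strict":
        return (t >= -0.5) & (t <= 0.0)
    raise ValueError(f"threshold_mode must be one of {MATCH_THRESHOLDS}")


def matched_activation_pairs(
    mean_z: np.ndarray,
    t_values: np.ndarray,
    k: int = DEFAULT_K,
    threshold_mode: str = "liberal",
    n_draws: int = 10000,
    seed: int = 0,
    eligibility: np.ndarray | None = None,
    fold_id: int | None = None,
    contrast: str | None = None,
) -> list[tuple[VoxelSet, VoxelSet]]:
    """Activation-matched strongly/weakly connected voxel-set pairs.

    Voxels are median split by their mean connectivity z; each draw
    samples one random k-subset from the upper ("strong") and lower
    ("weak") half and compares the subsets' activation t values with a
    pooled two-sample t test.  A pair is retained under

    * ``liberal`` — two-tailed p > 0.10,
    * ``intermediate`` — t within [-0.5, +0.5],
    * ``strict`` — t within [-0.5, 0] (strong set's activation no
      higher than the weak set's).

    An empty return signals that the matching constraint could not be
    met; downstream analyses drop that subject/region, as happens with
    real data when connectivity and activation are too entangled.
    """
    mean_z = np.asarray(mean_z, dtype=float)
    t_values = np.asarray(t_values, dtype=float)
    elig = np.isfinite(mean_z) & np.isfinite(t_values)
    if eligibility is not None:
        elig &= np.asarray(eligibility, dtype=bool)
    pool = np.flatnonzero(elig)
    if pool.size < 2 * k:
        raise ValueError(f"need >= {2 * k} eligible voxels, have {pool.size}")
    med = np.median(mean_z[pool])
    hi = pool[mean_z[pool] > med]
    lo = pool[mean_z[pool] <= med]
    # guard against gross imbalance when many scores tie at the median
    if hi.size < k or lo.size < k:
        order = pool[np.lexsort((pool, mean_z[pool]))]
        lo, hi = order[: pool.size // 2], order[pool.size // 2 :]
    if hi.size < k or lo.size < k:
        return []

    rng = np.random.default_rng(seed)
    # uniform k-subsets via ranking independent uniforms (vectorized)
    strong_draws = hi[np.argpartition(rng.random((n_draws, hi.size)), k - 1, axis=1)[:, :k]]
    weak_draws = lo[np.argpartition(rng.random((n_draws, lo.size)), k - 1, axis=1)[:, :k]]

    ts = t_values[strong_draws]
    tw = t_values[weak_draws]
    t = pooled_t(ts.mean(1), ts.var(1, ddof=1), tw.mean(1), tw.var(1, ddof=1), k, k)
    keep = _retain(t, 2 * k - 2, threshold_mode)

    pairs = []
    for d in np.flatnonzero(keep):
        pairs.append(
            (
                VoxelSet(np.sort(strong_draws[d]), k, MATCHED_STRONG,
                         fold_id=fold_id, contrast_used=contrast),
                VoxelSet(np.sort(weak_draws[d]), k, MATCHED_WEAK,
                         fold_id=fold_id, contrast_used=contrast),
            )
        )
    return pairs
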