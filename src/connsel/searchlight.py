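"""Good-seed searchlight: map where in the brain connectivity-based
voxel selection yields a decoding advantage.

A searchlight of the k nearest gray-matter voxels (k = 100 by default,
approximating "~100 contiguous voxels") is centered on every
gray-matter voxel outside the current target region.  The neighborhood
mean residual time course serves as a single seed series: each target
voxel's Fisher-z correlation to it ranks the voxels, the top-100 /
bottom-100 sets are decoded with a single odd/even-run fold, and the
two accuracies are assigned to the searchlight's center voxel.  The
most-minus-least difference map per subject feeds the sign-flip
permutation group analysis.

The module is fully deterministic: it draws no random numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from . import selection as sel
from .connectivity import fisher_z
from .decoding import SubjectAnalysis, batch_accuracy, split_patterns
from .layout import RegionLayout
from .simulate import SubjectDataset

SEARCHLIGHT_K = 100


def neighborhoods(layout: RegionLayout, k: int = SEARCHLIGHT_K) -> np.ndarray:
    """k-nearest gray-voxel neighborhoods around every gray voxel.

    Returns an (n_gray, k) array whose rows hold flat grid indices of
    the k gray voxels nearest (Euclidean) to each gray center, center
    included; distance ties are broken by ascending voxel index.
    """
    gray = layout.gray_indices()
    if gray.size < k:
        raise ValueError("gray mask smaller than the searchlight size")
    coords = np.column_stack(np.unravel_index(gray, layout.grid_dims)).astype(float)
    n = gray.size
    out = np.empty((n, k), dtype=int)
    chunk = max(1, int(2e7 // max(n, 1)))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d2 = ((coords[start:stop, None, :] - coords[None, :, :]) ** 2).sum(-1)
        # squared distances on an integer lattice are exact, so sorting on
        # (distance, index) gives a fully deterministic tie-break
        for row in range(stop - start):
            order = np.lexsort((gray, d2[row]))
            out[start + row] = gray[order[:k]]
    return out


@dataclass
class SearchlightMap:
    """Per-center decoding accuracies for one subject/target/comparison."""

    centers: np.ndarray  # flat grid indices
    values: dict[str, np.ndarray]  # mode -> per-center accuracy (NaN = missing)
    target_region: str
    comparison: tuple[str, str]
    grid_dims: tuple[int, int, int]

    def volume(self, mode: str) -> np.ndarray:
        vol = np.full(self.grid_dims, np.nan)
        vol.ravel()[self.centers] = self.values[mode]
        return vol

    def difference(self) -> np.ndarray:
        return self.values[sel.MOST_CONNECTED] - self.values[sel.LEAST_CONNECTED]


def odd_even_splits(n_runs: int) -> tuple[tuple[int, ...], tuple[int, ...]]:
    return tuple(range(0, n_runs, 2)), tuple(range(1, n_runs, 2))


def searchlight_radius(k: int = SEARCHLIGHT_K) -> float:
    """Approximate radius (voxels) of a k-voxel spherical neighborhood."""
    return (3.0 * k / (4.0 * np.pi)) ** (1.0 / 3.0)


def goodseed_support(layout: RegionLayout, coupled: np.ndarray,
                     k: int = SEARCHLIGHT_K) -> np.ndarray:
    """Boolean grid of centers whose searchlight can reach coupled voxels.

    A center constitutes a planted "good seed" precisely when its
    k-voxel neighborhood overlaps the voxels carrying the shared latent
    signal; this is the coupled set dilated by the searchlight radius.
    Used by tests as the ground truth for localization checks.
    """
    from scipy import ndimage

    vol = np.zeros(layout.grid_dims, dtype=bool)
    vol.ravel()[np.asarray(coupled, dtype=int)] = True
    return ndimage.binary_dilation(
        vol, iterations=int(np.ceil(searchlight_radius(k))))


def goodseed_maps(
    subject: SubjectDataset,
    target_region: str,
    comparison: tuple[str, str],
    k: int = SEARCHLIGHT_K,
    n_select: int = sel.DEFAULT_K,
    analysis: SubjectAnalysis | None = None,
    neighborhood_idx: np.ndarray | None = None,
) -> SearchlightMap:
    """Most-/least-connected decoding maps over all eligible centers.

    Centers are gray voxels outside ``target_region``.  Selection uses
    the connectivity of target voxels to the neighborhood-mean series
    over all six runs' residuals; decoding uses a single odd/even-run
    fold (circularity is benign here because no activation comparison
    is involved).  Centers whose seed series has zero variance are NaN.
    """
    layout = subject.layout
    sa = analysis or SubjectAnalysis(subject)
    gray = layout.gray_indices()
    nb = neighborhood_idx if neighborhood_idx is not None else neighborhoods(layout, k)
    target_vox = layout.regions[target_region]
    keep = ~np.isin(gray, target_vox)
    centers = gray[keep]
    nb = nb[keep]

    resid = sa.resid_concat(tuple(range(subject.n_runs)))
    T = resid.shape[0]
    # neighborhood-mean seed series via a sparse averaging operator;
    # target-region voxels are excluded from the seed role, so neighborhoods
    # overlapping the target average only their non-target members
    n_c = centers.size
    member_ok = ~np.isin(nb, target_vox)
    counts = member_ok.sum(axis=1).astype(float)
    weights = np.where(member_ok, 1.0 / np.maximum(counts, 1.0)[:, None], 0.0)
    indptr = np.arange(0, (n_c + 1) * nb.shape[1], nb.shape[1])
    S = sparse.csc_matrix(
        (weights.ravel(), nb.ravel(), indptr), shape=(resid.shape[1], n_c),
    )
    seed_series = np.asarray(resid @ S)  # (T, n_c)
    seed_series[:, counts == 0] = 0.0  # fully-in-target neighborhoods: no seed

    tgt = resid[:, target_vox]
    tc = tgt - tgt.mean(axis=0)
    sc = seed_series - seed_series.mean(axis=0)
    tsd = tc.std(axis=0)
    ssd = sc.std(axis=0)
    eligible_t = tsd > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (tc.T @ sc) / T / np.outer(np.where(eligible_t, tsd, np.nan),
                                       np.where(ssd > 0, ssd, np.nan))
    z = fisher_z(r)  # (n_target, n_c)

    odd, even = odd_even_splits(subject.n_runs)
    pa = split_patterns(sa.statmaps, target_vox, odd, comparison)
    pb = split_patterns(sa.statmaps, target_vox, even, comparison)

    values = {
        sel.MOST_CONNECTED: np.full(n_c, np.nan),
        sel.LEAST_CONNECTED: np.full(n_c, np.nan),
    }
    good = ssd > 0
    good_idx = np.flatnonzero(good)
    if good_idx.size:
        zg = z[:, good_idx]
        most_sets = np.empty((good_idx.size, n_select), dtype=int)
        least_sets = np.empty((good_idx.size, n_select), dtype=int)
        local = np.arange(target_vox.size)
        for j in range(good_idx.size):
            col = zg[:, j]
            elig = np.isfinite(col)
            pool = local[elig]
            vals = col[elig]
            order = np.lexsort((pool, -vals))
            most_sets[j] = pool[order[:n_select]]
            order = np.lexsort((pool, vals))
            least_sets[j] = pool[order[:n_select]]
        values[sel.MOST_CONNECTED][good_idx] = batch_accuracy(pa, pb, most_sets)
        values[sel.LEAST_CONNECTED][good_idx] = batch_accuracy(pa, pb, least_sets)

    return SearchlightMap(
        centers=centers, values=values, target_region=target_region,
        comparison=tuple(comparison), grid_dims=layout.grid_dims,
    )
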