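"""Split-half correlation decoding over selected voxel sets.

The discriminability statistic for a pair of conditions is computed by
correlating each condition's multivoxel pattern (run-averaged betas,
restricted to a voxel set) across two independent data halves, forming
a 2 (split) x 2 (condition) correlation matrix, and subtracting the
mean between-condition (off-diagonal) from the mean within-condition
(on-diagonal) correlation.  Positive values mean patterns are more
similar to themselves than to the other condition across halves.

:func:`decode_all` runs the full per-subject analysis: per-run GLM,
task-regressed band-passed residuals, per-fold seed definition and
voxel selection, and fold-wise decoding for every region, comparison
and selection mode, returning a tidy long-format table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import selection as sel
from .connectivity import (
    ConnectivityProfile,
    bandpass,
    connectivity_profile,
    nuisance_matrix,
    task_regress,
)
from .glm import (
    RunStatMaps,
    build_design_matrix,
    fit_glm_run,
    pairwise_contrast,
    preference_contrast,
)
from .simulate import SubjectDataset

N_SEED_VOXELS = 100


def comparison_label(cat_a: str, cat_b: str) -> str:
    return f"{cat_a[0].upper()}v{cat_b[0].upper()}"


def comparisons_for(category: str, all_categories=("tools", "faces", "places")):
    """The two binary comparisons run for a category's target regions."""
    return [(category, other) for other in all_categories if other != category]


@dataclass
class PatternPair:
    """Condition x voxel pattern matrices for the two decoding halves."""

    split_a: np.ndarray
    split_b: np.ndarray
    conditions: tuple[str, str]

    def __post_init__(self):
        if self.split_a.shape != self.split_b.shape:
            raise ValueError("pattern halves must share shape")


def splithalf_accuracy(pair: PatternPair) -> float:
    """Within- minus between-condition split-half pattern correlation.

    Returns NaN when any pattern has zero variance (correlation
    undefined); bounded in [-2, 2] otherwise.
    """
    a, b = pair.split_a, pair.split_b
    if a.shape[1] < 3:
        raise ValueError("need at least 3 voxels for pattern correlation")
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    asd = ac.std(axis=1)
    bsd = bc.std(axis=1)
    if (asd == 0).any() or (bsd == 0).any():
        return float("nan")
    corr = (ac @ bc.T) / a.shape[1] / np.outer(asd, bsd)
    within = np.mean(np.diag(corr))
    between = np.mean(corr[~np.eye(2, dtype=bool)])
    return float(within - between)


def extract_patterns(
    statmaps: list[RunStatMaps],
    voxel_set: sel.VoxelSet,
    decoding_splits: tuple[tuple[int, ...], tuple[int, ...]],
    comparison: tuple[str, str],
) -> PatternPair:
    """Run-averaged beta patterns for both halves, restricted to a voxel set."""
    idx = voxel_set.indices
    n_vox = statmaps[0].betas.shape[1]
    if idx.min() < 0 or idx.max() >= n_vox:
        raise ValueError("voxel set references voxels outside the data")
    halves = []
    for split in decoding_splits:
        rows = []
        for cond in comparison:
            c = statmaps[0].condition_names.index(cond)
            rows.append(np.mean([statmaps[r].betas[c, idx] for r in split], axis=0))
        halves.append(np.array(rows))
    return PatternPair(split_a=halves[0], split_b=halves[1], conditions=tuple(comparison))


def split_patterns(
    statmaps: list[RunStatMaps],
    voxels: np.ndarray,
    split: tuple[int, ...],
    comparison: tuple[str, str],
) -> np.ndarray:
    """(condition x voxel) run-averaged beta patterns for one data half."""
    rows = []
    for cond in comparison:
        c = statmaps[0].condition_names.index(cond)
        rows.append(np.mean([statmaps[r].betas[c, voxels] for r in split], axis=0))
    return np.array(rows)


def batch_accuracy(pattern_a: np.ndarray, pattern_b: np.ndarray,
                   sets: np.ndarray) -> np.ndarray:
    """Split-half accuracy for many voxel subsets of one pattern pair.

    ``pattern_a``/``pattern_b`` are (2 x n_voxels) half patterns;
    ``sets`` is an (m x k) array of column indices.  Returns m
    accuracies (NaN where a subset pattern has zero variance).  Agrees
    with :func:`splithalf_accuracy` applied subset by subset.
    """
    A = pattern_a[:, sets]  # (2, m, k)
    B = pattern_b[:, sets]
    Ac = A - A.mean(axis=-1, keepdims=True)
    Bc = B - B.mean(axis=-1, keepdims=True)
    asd = Ac.std(axis=-1)
    bsd = Bc.std(axis=-1)
    k = sets.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.einsum("cmk,dmk->cdm", Ac, Bc) / k / (asd[:, None, :] * bsd[None, :, :])
    acc = 0.5 * (corr[0, 0] + corr[1, 1]) - 0.5 * (corr[0, 1] + corr[1, 0])
    bad = (asd == 0).any(axis=0) | (bsd == 0).any(axis=0)
    acc[bad] = np.nan
    return acc


def tsnr(run_timeseries: np.ndarray) -> np.ndarray:
    """Per-voxel temporal SNR: mean signal amplitude / SD over time.

    Zero-SD voxels are returned as +/-inf and should be excluded from
    set averages (see :func:`tsnr_table`).
    """
    ts = np.asarray(run_timeseries, dtype=float)
    if ts.shape[0] < 2:
        raise ValueError("need at least 2 time points")
    mean = ts.mean(axis=0)
    sd = ts.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), np.inf * np.sign(mean))


class SubjectAnalysis:
    """Cached per-subject products: GLM fits and connectivity residuals.

    Everything downstream (selection, decoding, searchlight, SNR) reads
    from here, so the expensive per-run computations happen once per
    subject.
    """

    def __init__(self, dataset: SubjectDataset, hp_cutoff_seconds: float = 256.0):
        self.dataset = dataset
        self.layout = dataset.layout
        self.design_matrices = []
        self.statmaps: list[RunStatMaps] = []
        self.residuals: list[np.ndarray] = []
        for r, (ts, spec) in enumerate(zip(dataset.runs, dataset.design)):
            dm = build_design_matrix(
                spec, n_volumes=ts.shape[0], motion=dataset.motion[r],
                hp_cutoff_seconds=hp_cutoff_seconds,
            )
            self.design_matrices.append(dm)
            self.statmaps.append(fit_glm_run(ts, dm))
            nuis = nuisance_matrix(dataset.motion[r], dataset.global_proxy(r))
            resid = task_regress(ts, dm, nuis)
            self.residuals.append(
                bandpass(resid, tr_seconds=dataset.tr_seconds)
            )
        self._conditions = self.statmaps[0].condition_names

    # --- split-level products -----------------------------------------

    def split_tmap(self, runs: tuple[int, ...], weights: np.ndarray) -> np.ndarray:
        """Activation map for a data split: mean of run-wise contrast t maps."""
        return np.mean([self.statmaps[r].tmap(weights) for r in runs], axis=0)

    def resid_concat(self, runs: tuple[int, ...],
                     columns: np.ndarray | None = None) -> np.ndarray:
        if columns is None:
            return np.concatenate([self.residuals[r] for r in runs], axis=0)
        return np.concatenate([self.residuals[r][:, columns] for r in runs], axis=0)

    def seed_indices(self, target: str, runs: tuple[int, ...]) -> dict[str, np.ndarray]:
        """Top activated voxels within each same-category seed region.

        Seeds are the ``N_SEED_VOXELS`` most-activated voxels (by the
        seed region's own category-preference contrast) within each
        other region sharing the target's category, estimated from the
        selection split only.
        """
        out = {}
        for region in self.layout.seed_regions_for(target):
            vox = self.layout.regions[region]
            w = preference_contrast(self.layout.categories[region], self._conditions)
            t = self.split_tmap(runs, w)[vox]
            k = min(N_SEED_VOXELS, vox.size)
            order = np.lexsort((vox, -t))
            out[region] = np.sort(vox[order[:k]])
        return out

    def connectivity(self, target: str, fold: sel.Fold) -> ConnectivityProfile:
        """Target-to-seed connectivity profile from the fold's selection split."""
        runs = fold.selection_split
        tgt = self.resid_concat(runs, self.layout.regions[target])
        seeds = {
            name: self.resid_concat(runs, idx)
            for name, idx in self.seed_indices(target, runs).items()
        }
        return connectivity_profile(tgt, seeds, fold_id=fold.fold_id)

    def activation_t(self, target: str, runs: tuple[int, ...],
                     comparison: tuple[str, str]) -> np.ndarray:
        """Comparison-specific contrast t over the target's voxels."""
        w = pairwise_contrast(comparison[0], comparison[1], self._conditions)
        return self.split_tmap(runs, w)[self.layout.regions[target]]

    # --- decoding ------------------------------------------------------

    def decode_set(self, voxel_set: sel.VoxelSet, fold: sel.Fold,
                   comparison: tuple[str, str]) -> float:
        pair = extract_patterns(self.statmaps, voxel_set, fold.decoding_splits, comparison)
        return splithalf_accuracy(pair)


def _region_local_set(layout, region: str, local_set: sel.VoxelSet) -> sel.VoxelSet:
    """Map region-local indices to grid-flat indices."""
    vox = layout.regions[region]
    return sel.VoxelSet(vox[local_set.indices], local_set.k, local_set.mode,
                        fold_id=local_set.fold_id,
                        contrast_used=local_set.contrast_used, region=region)


def decode_all(
    cohort: list[SubjectDataset],
    scheme: sel.SplitScheme,
    regions: list[str] | None = None,
    comparisons: dict[str, list[tuple[str, str]]] | None = None,
    modes: tuple[str, ...] = (sel.MOST_CONNECTED, sel.LEAST_CONNECTED, sel.MOST_ACTIVATED),
    k: int = sel.DEFAULT_K,
    analyses: dict[str, "SubjectAnalysis"] | None = None,
) -> pd.DataFrame:
    """Full fold-wise decoding table for a cohort.

    Returns a long-format table (subject, region, category, comparison,
    mode, fold, accuracy).  Fold accuracies are averaged per cell before
    group inference (see :func:`fold_average`).  Rows whose accuracy is
    undefined (zero-variance patterns) are dropped.
    """
    rows = []
    for ds in cohort:
        layout = ds.layout
        sa = (analyses or {}).get(ds.subject_id) or SubjectAnalysis(ds)
        targets = regions or layout.target_regions()
        for region in targets:
            cat = layout.categories[region]
            comps = (comparisons or {}).get(region) or comparisons_for(cat)
            for fold in scheme.folds:
                prof = sa.connectivity(region, fold)
                elig = prof.eligible
                common = dict(fold_id=fold.fold_id)
                sets = {}
                if sel.MOST_CONNECTED in modes:
                    sets[sel.MOST_CONNECTED] = sel.select_top_k(
                        prof.mean_z, k, "most", elig, **common)
                if sel.LEAST_CONNECTED in modes:
                    sets[sel.LEAST_CONNECTED] = sel.select_top_k(
                        prof.mean_z, k, "least", elig, **common)
                for comp in comps:
                    label = comparison_label(*comp)
                    per_comp = dict(sets)
                    if sel.MOST_ACTIVATED in modes:
                        t = sa.activation_t(region, fold.selection_split, comp)
                        per_comp[sel.MOST_ACTIVATED] = sel.select_most_activated(
                            t, k, contrast=f"{comp[0]}>{comp[1]}",
                            eligibility=elig, **common)
                    for mode, local_set in per_comp.items():
                        gset = _region_local_set(layout, region, local_set)
                        acc = sa.decode_set(gset, fold, comp)
                        if np.isfinite(acc):
                            rows.append(
                                (ds.subject_id, region, cat, label, mode,
                                 fold.fold_id, acc)
                            )
        del sa
    return pd.DataFrame(
        rows,
        columns=["subject", "region", "category", "comparison", "mode",
                 "fold", "accuracy"],
    )


def fold_average(table: pd.DataFrame) -> pd.DataFrame:
    """Mean accuracy across decoding folds per subject/region/comparison/mode."""
    keys = ["subject", "region", "category", "comparison", "mode"]
    return table.groupby(keys, as_index=False)["accuracy"].mean()


def matched_decoding_table(
    cohort: list[SubjectDataset],
    scheme: sel.SplitScheme,
    threshold_mode: str = "liberal",
    n_draws: int = 10000,
    seed: int = 0,
    k: int = sel.DEFAULT_K,
    regions: list[str] | None = None,
    analyses: dict[str, "SubjectAnalysis"] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Activation-matched decoding: permutation-averaged accuracies.

    For every subject/region/fold/comparison, draws ``n_draws`` random
    strong/weak voxel-set pairs from the connectivity median split,
    retains only activation-matched pairs under ``threshold_mode``, and
    averages decoding accuracy over the retained pairs.  Cells with no
    retained pair are absent from the table (the subject drops out of
    that region's group analysis).

    Returns the (fold-level) accuracy table and a retention table with
    the retained-pair fraction per cell.
    """
    draw_ss = np.random.SeedSequence(seed)
    rows = []
    ret_rows = []
    for ds in cohort:
        layout = ds.layout
        sa = (analyses or {}).get(ds.subject_id) or SubjectAnalysis(ds)
        targets = regions or layout.target_regions()
        for region in targets:
            cat = layout.categories[region]
            vox = layout.regions[region]
            for fold in scheme.folds:
                prof = sa.connectivity(region, fold)
                for comp in comparisons_for(cat):
                    label = comparison_label(*comp)
                    t_vals = sa.activation_t(region, fold.selection_split, comp)
                    child = int(draw_ss.spawn(1)[0].generate_state(1)[0] % (2**31))
                    pairs = sel.matched_activation_pairs(
                        prof.mean_z, t_vals, k=k, threshold_mode=threshold_mode,
                        n_draws=n_draws, seed=child,
                        eligibility=prof.eligible, fold_id=fold.fold_id,
                        contrast=f"{comp[0]}>{comp[1]}",
                    )
                    ret_rows.append(
                        (ds.subject_id, region, cat, label, fold.fold_id,
                         threshold_mode, len(pairs) / n_draws)
                    )
                    if not pairs:
                        continue
                    pa = split_patterns(sa.statmaps, vox, fold.decoding_splits[0], comp)
                    pb = split_patterns(sa.statmaps, vox, fold.decoding_splits[1], comp)
                    for mode, which in ((sel.MATCHED_STRONG, 0), (sel.MATCHED_WEAK, 1)):
                        sets = np.array([p[which].indices for p in pairs])
                        accs = batch_accuracy(pa, pb, sets)
                        if np.isfinite(accs).any():
                            rows.append(
                                (ds.subject_id, region, cat, label, mode,
                                 fold.fold_id, float(np.nanmean(accs)))
                            )
        del sa
    table = pd.DataFrame(
        rows, columns=["subject", "region", "category", "comparison", "mode",
                       "fold", "accuracy"])
    retention = pd.DataFrame(
        ret_rows, columns=["subject", "region", "category", "comparison",
                           "fold", "threshold", "retention_rate"])
    return table, retention


def tsnr_table(
    cohort: list[SubjectDataset],
    scheme: sel.SplitScheme,
    k: int = sel.DEFAULT_K,
    analyses: dict[str, "SubjectAnalysis"] | None = None,
) -> pd.DataFrame:
    """Mean temporal SNR of most-/least-connected voxel sets.

    tSNR is computed per voxel per run on the raw time series, averaged
    over the six runs, then averaged over the voxels of each set (and
    over the three folds' sets), per subject and region.
    """
    rows = []
    for ds in cohort:
        layout = ds.layout
        sa = (analyses or {}).get(ds.subject_id) or SubjectAnalysis(ds)
        run_tsnr = np.array([tsnr(run) for run in ds.runs])
        with np.errstate(invalid="ignore"):
            mean_tsnr = np.where(np.isfinite(run_tsnr), run_tsnr, np.nan).mean(axis=0)
        for region in layout.target_regions():
            vox = layout.regions[region]
            per_mode = {sel.MOST_CONNECTED: [], sel.LEAST_CONNECTED: []}
            for fold in scheme.folds:
                prof = sa.connectivity(region, fold)
                for mode, direction in ((sel.MOST_CONNECTED, "most"),
                                        (sel.LEAST_CONNECTED, "least")):
                    vset = sel.select_top_k(prof.mean_z, k, direction, prof.eligible)
                    vals = mean_tsnr[vox[vset.indices]]
                    per_mode[mode].append(np.nanmean(vals))
            for mode, vals in per_mode.items():
                rows.append((ds.subject_id, region, layout.categories[region],
                             mode, float(np.mean(vals))))
        del sa
    return pd.DataFrame(
        rows, columns=["subject", "region", "category", "mode", "tsnr"])
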