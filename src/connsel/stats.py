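"""Group-level inference: paired t tests, repeated-measures ANOVA,
threshold-free cluster enhancement and sign-flip permutation maps.

Decoding accuracies (fold-averaged per subject) are compared across
voxel-selection modes with within-subject designs: paired t tests with
Bonferroni correction for post hocs, and two-/three-way
repeated-measures ANOVAs (voxel selection type x region x decoding
comparison) with partial eta squared effect sizes.  Searchlight
difference maps are tested with a max-statistic sign-flip permutation
scheme on TFCE-enhanced mean/SE maps, thresholded at Z > 1.65.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.anova import AnovaRM


def paired_t(values_a, values_b) -> tuple[float, int, float]:
    """Two-tailed paired t test; returns (t, df, p).

    Pairs with a missing value in either condition are dropped
    (listwise deletion).  Zero-variance differences raise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    d = a[keep] - b[keep]
    if d.size < 2:
        raise ValueError("need at least 2 complete pairs")
    if d.std(ddof=1) == 0:
        if d.mean() == 0:
            return 0.0, int(d.size - 1), 1.0  # identical inputs
        raise ValueError("zero-variance nonzero differences: t undefined")
    res = stats.ttest_rel(a[keep], b[keep])
    return float(res.statistic), int(d.size - 1), float(res.pvalue)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Corrected per-test alpha for m comparisons."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


@dataclass
class AnovaResult:
    """Within-subject ANOVA table: F, df, p and partial eta squared per term."""

    table: pd.DataFrame  # index: term; columns: F, df_num, df_den, p, partial_eta_sq
    n_subjects: int

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]


def rm_anova(
    table: pd.DataFrame,
    dv: str,
    within_factors: list[str],
    subject_id: str = "subject",
) -> AnovaResult:
    """Repeated-measures ANOVA over fully crossed within-subject factors.

    Subjects missing any cell of the design are dropped before fitting
    (mirroring subject dropout in the matched-activation analyses).
    Uncorrected degrees of freedom are reported; partial eta squared is
    derived as F*dfn / (F*dfn + dfd).
    """
    df = table.dropna(subset=[dv]).copy()
    n_cells = int(np.prod([df[f].nunique() for f in within_factors]))
    counts = df.groupby(subject_id, observed=True).size()
    complete = counts[counts == n_cells].index
    df = df[df[subject_id].isin(complete)]
    n_sub = df[subject_id].nunique()
    if n_sub < 2:
        raise ValueError("need at least 2 subjects with complete designs")
    if np.ptp(df[dv].to_numpy(dtype=float)) == 0:
        # constant response: no effect anywhere, F defined as 0
        from itertools import combinations

        terms = [
            ":".join(c)
            for r in range(1, len(within_factors) + 1)
            for c in combinations(within_factors, r)
        ]
        tab = pd.DataFrame(
            {"F": 0.0, "df_num": np.nan, "df_den": np.nan, "p": 1.0,
             "partial_eta_sq": 0.0},
            index=pd.Index(terms))
        return AnovaResult(table=tab, n_subjects=n_sub)
    fit = AnovaRM(df, depvar=dv, subject=subject_id, within=within_factors).fit()
    tab = fit.anova_table.rename(
        columns={"F Value": "F", "Num DF": "df_num", "Den DF": "df_den",
                 "Pr > F": "p"}
    )
    fdfn = tab["F"] * tab["df_num"]
    tab["partial_eta_sq"] = fdfn / (fdfn + tab["df_den"])
    return AnovaResult(table=tab, n_subjects=n_sub)


TFCE_E = 0.5
TFCE_H = 2.0
_TFCE_STEPS = 100


def tfce(stat_map: np.ndarray, E: float = TFCE_E, H: float = TFCE_H,
         dh: float | None = None, n_steps: int = _TFCE_STEPS) -> np.ndarray:
    """Threshold-free cluster enhancement of a 3-D map (positive side).

    For each voxel, integrates extent^E * height^H over thresholds from
    dh up to the map maximum in steps of dh (default: max/``n_steps``
    with ``n_steps`` = 100), with clusters formed by 6-connectivity.
    NaNs are treated as zero.
    """
    m = np.nan_to_num(np.asarray(stat_map, dtype=float), nan=0.0)
    peak = m.max()
    if peak <= 0:
        return np.zeros_like(m)
    if dh is None:
        dh = peak / n_steps
    structure = ndimage.generate_binary_structure(3, 1)
    out = np.zeros_like(m)
    h = dh
    while h <= peak + 1e-12:
        supra = m >= h
        labels, n = ndimage.label(supra, structure=structure)
        if n == 0:
            break
        sizes = np.bincount(labels.ravel())
        contrib = (sizes[labels] ** E) * (h**H) * dh
        out[supra] += contrib[supra]
        h += dh
    return out


@dataclass
class GroupMap:
    """Permutation z map for a paired (most - least) searchlight contrast."""

    z: np.ndarray  # 3-D grid
    p: np.ndarray
    threshold: float
    n_perm: int
    mask: np.ndarray  # analyzed voxels

    def suprathreshold(self) -> np.ndarray:
        return (self.z > self.threshold) & self.mask


def signflip_group_map(
    subject_diff_maps: np.ndarray,
    grid_dims: tuple[int, int, int] | None = None,
    n_perm: int = 10000,
    seed: int = 0,
    threshold: float = 1.65,
    mask: np.ndarray | None = None,
    tfce_steps: int = _TFCE_STEPS,
) -> GroupMap:
    """Max-statistic sign-flip permutation test on TFCE-enhanced maps.

    ``subject_diff_maps`` is (n_subjects x n_voxels) of per-subject
    most-minus-least difference values (flattened grid, or arbitrary
    masked vector with ``mask``/``grid_dims`` giving the geometry).
    The observed statistic is the TFCE of the group mean/SE map; the
    null is its maximum under random per-subject sign flips.  Family-
    wise-corrected p values are converted to z scores and thresholded
    at ``threshold`` (default Z > 1.65, one-tailed most > least).
    """
    import warnings

    d = np.asarray(subject_diff_maps, dtype=float)
    if d.ndim != 2 or d.shape[0] < 2:
        raise ValueError("need a (n_subjects x n_voxels) array with >= 2 subjects")
    if n_perm < 100:
        warnings.warn("n_perm < 100: permutation tail estimates are unstable")
    n_sub, n_vox = d.shape
    if grid_dims is None:
        raise ValueError("grid_dims is required to form clusters")
    if mask is None:
        mask = np.isfinite(d).all(axis=0)
    else:
        mask = np.asarray(mask, dtype=bool).ravel() & np.isfinite(d).all(axis=0)
    dm = np.where(mask, np.nan_to_num(d, nan=0.0), 0.0)

    def stat_volume(signs: np.ndarray) -> np.ndarray:
        x = dm * signs[:, None]
        mean = x.mean(axis=0)
        se = x.std(axis=0, ddof=1) / np.sqrt(n_sub)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, mean / np.where(se > 0, se, 1.0), 0.0)
        return tfce(np.where(mask, t, 0.0).reshape(grid_dims), n_steps=tfce_steps)

    observed = stat_volume(np.ones(n_sub))
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for i in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n_sub)
        null_max[i] = stat_volume(signs).max()

    obs_flat = observed.ravel()
    # p = (1 + #{null >= obs}) / (n_perm + 1), family-wise via max statistic
    exceed = (null_max[None, :] >= obs_flat[mask][:, None]).sum(axis=1)
    p_masked = (1.0 + exceed) / (n_perm + 1.0)
    p = np.ones(n_vox)
    p[mask] = p_masked
    z = np.full(n_vox, -np.inf)
    z[mask] = stats.norm.isf(p_masked)
    return GroupMap(
        z=z.reshape(grid_dims),
        p=p.reshape(grid_dims),
        threshold=threshold,
        n_perm=n_perm,
        mask=mask.reshape(grid_dims),
    )
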