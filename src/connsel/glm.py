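"""First-level GLM: design matrices, OLS beta maps and contrast t maps.

Condition boxcars are convolved with the canonical double-gamma
hemodynamic response (no temporal/dispersion derivatives) at a fine
microtime grid and resampled at the TR.  Estimation is ordinary least
squares per run; slow drift is absorbed by a discrete-cosine basis in
the design rather than by pre-filtering (an equivalent projection).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .design import DesignSpec

# Conventional double-gamma parameters: response peaking at ~5 s with a
# late undershoot of 1/6 amplitude, 32 s kernel support.
HRF_PEAK_DELAY = 6.0
HRF_UNDERSHOOT_DELAY = 16.0
HRF_PEAK_DISP = 1.0
HRF_UNDERSHOOT_DISP = 1.0
HRF_UNDERSHOOT_RATIO = 1.0 / 6.0
HRF_LENGTH_SECONDS = 32.0

_MICRO_DT = 0.1  # microtime resolution for convolution (s)


def _gamma_pdf(t: np.ndarray, shape: float, scale: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos] / scale
    out[pos] = np.exp(
        (shape - 1) * np.log(tp) - tp - special.gammaln(shape)
    ) / scale
    return out


def canonical_hrf(tr_seconds: float, duration_seconds: float = HRF_LENGTH_SECONDS,
                  dt: float | None = None) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``dt`` (default: the TR).

    Peak-normalized to 1; value at t = 0 is exactly 0; the post-peak
    undershoot is negative.
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    step = tr_seconds if dt is None else dt
    t = np.arange(0.0, duration_seconds + step / 2, step)
    h = _gamma_pdf(t, HRF_PEAK_DELAY / HRF_PEAK_DISP, HRF_PEAK_DISP) - (
        HRF_UNDERSHOOT_RATIO
        * _gamma_pdf(t, HRF_UNDERSHOOT_DELAY / HRF_UNDERSHOOT_DISP, HRF_UNDERSHOOT_DISP)
    )
    return h / h.max()


def convolve_boxcar(design: DesignSpec, condition: str, n_volumes: int) -> np.ndarray:
    """HRF-convolved condition boxcar, sampled at TR, truncated to the run."""
    box = design.boxcar(condition, _MICRO_DT)
    h = canonical_hrf(design.tr_seconds, dt=_MICRO_DT)
    conv = np.convolve(box, h)[: box.size]
    step = int(round(design.tr_seconds / _MICRO_DT))
    reg = conv[::step][:n_volumes]
    if reg.size < n_volumes:
        raise ValueError("design shorter than requested volume count")
    return reg


def drift_basis(n_volumes: int, tr_seconds: float, hp_cutoff_seconds: float) -> np.ndarray:
    """Discrete-cosine drift columns absorbing fluctuations slower than the cutoff.

    Component k has period 2T/k.  Components slower than the high-pass
    cutoff are included, except the half-cycle k = 1 term whose period
    exceeds the run and is not separable from a linear trend within it.
    Columns are unit-normalized; the intercept is kept separate.
    """
    T = n_volumes * tr_seconds
    cols = []
    k = 2
    while 2 * T / k > hp_cutoff_seconds:
        t = (np.arange(n_volumes) + 0.5) / n_volumes
        c = np.cos(np.pi * k * t)
        cols.append(c / np.linalg.norm(c))
        k += 1
    if not cols:
        return np.empty((n_volumes, 0))
    return np.column_stack(cols)


@dataclass
class DesignMatrix:
    """Time x regressor matrix for one run, with named columns."""

    matrix: np.ndarray
    regressor_names: list[str]
    condition_names: list[str]
    tr_seconds: float

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def condition_columns(self) -> np.ndarray:
        idx = [self.regressor_names.index(c) for c in self.condition_names]
        return self.matrix[:, idx]


def build_design_matrix(
    design: DesignSpec,
    n_volumes: int | None = None,
    motion: np.ndarray | None = None,
    hp_cutoff_seconds: float = 256.0,
) -> DesignMatrix:
    """Assemble [conditions | drift | motion | intercept] for one run.

    One regressor per condition (intact and scrambled), six motion
    regressors when supplied, a single intercept, and the discrete-cosine
    drift basis for the given high-pass cutoff.
    """
    if n_volumes is None:
        n_volumes = design.n_volumes
    last_end = max(b.onset_seconds + b.duration_seconds for b in design.blocks)
    if last_end > n_volumes * design.tr_seconds:
        raise ValueError("a block extends past the end of the run")
    cols = []
    names = []
    for cond in design.conditions:
        cols.append(convolve_boxcar(design, cond, n_volumes))
        names.append(cond)
    drift = drift_basis(n_volumes, design.tr_seconds, hp_cutoff_seconds)
    for j in range(drift.shape[1]):
        cols.append(drift[:, j])
        names.append(f"drift_{j + 1}")
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != n_volumes:
            raise ValueError("motion regressors must match the volume count")
        for j in range(motion.shape[1]):
            cols.append(motion[:, j])
            names.append(f"motion_{j + 1}")
    cols.append(np.ones(n_volumes))
    names.append("intercept")
    return DesignMatrix(
        matrix=np.column_stack(cols),
        regressor_names=names,
        condition_names=list(design.conditions),
        tr_seconds=design.tr_seconds,
    )


@dataclass
class RunStatMaps:
    """OLS estimates for one run: betas, residual variance, t machinery."""

    betas: np.ndarray  # condition x voxel
    all_betas: np.ndarray  # regressor x voxel
    residual_df: int
    residual_variance: np.ndarray  # per voxel
    xtx_inv: np.ndarray  # regressor x regressor
    condition_names: list[str]
    regressor_names: list[str]

    def tmap(self, contrast_weights: np.ndarray) -> np.ndarray:
        return contrast_tmap(self, contrast_weights)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    # report columns whose removal restores full rank
    bad = []
    rank = np.linalg.matrix_rank(X)
    for j in range(X.shape[1]):
        sub = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(sub) == rank:
            bad.append(names[j])
    return bad


def fit_glm_run(run_timeseries: np.ndarray, design_matrix: DesignMatrix) -> RunStatMaps:
    """Run-wise OLS fit: betas, residual variance and degrees of freedom.

    Raises
    ------
    ValueError
        On row-count mismatch or a rank-deficient design (the error
        names the collinear columns).
    """
    Y = np.asarray(run_timeseries, dtype=float)
    X = design_matrix.matrix
    if Y.shape[0] != X.shape[0]:
        raise ValueError("time-series rows must match design rows")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X, design_matrix.regressor_names)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    betas = xtx_inv @ (X.T @ Y)
    resid = Y - X @ betas
    df = Y.shape[0] - X.shape[1]
    resvar = (resid**2).sum(axis=0) / df
    cond_idx = [design_matrix.regressor_names.index(c) for c in design_matrix.condition_names]
    return RunStatMaps(
        betas=betas[cond_idx],
        all_betas=betas,
        residual_df=df,
        residual_variance=resvar,
        xtx_inv=xtx_inv,
        condition_names=list(design_matrix.condition_names),
        regressor_names=list(design_matrix.regressor_names),
    )


def _full_weights(maps: RunStatMaps, contrast_weights: np.ndarray) -> np.ndarray:
    w = np.asarray(contrast_weights, dtype=float)
    if w.size != len(maps.condition_names):
        raise ValueError("contrast length must equal the condition count")
    full = np.zeros(len(maps.regressor_names))
    for cw, cname in zip(w, maps.condition_names):
        full[maps.regressor_names.index(cname)] = cw
    return full


def contrast_tmap(maps: RunStatMaps, contrast_weights: np.ndarray) -> np.ndarray:
    """Per-voxel t statistic for a condition contrast.

    t = c'b / sqrt(sigma^2 * c'(X'X)^-1 c).  Voxels with zero residual
    variance get NaN (flagged, excluded from selection downstream).
    """
    full = _full_weights(maps, contrast_weights)
    eff = full @ maps.all_betas
    cvc = float(full @ maps.xtx_inv @ full)
    if cvc == 0.0:
        return np.zeros_like(eff)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(maps.residual_variance * cvc)
        t = np.where(se > 0, eff / np.where(se > 0, se, 1.0), np.nan)
    return t


def preference_contrast(category: str, condition_names: list[str]) -> np.ndarray:
    """Category-preference contrast: 1 on the category, -1/3 on the other
    three intact categories, 0 on scrambled conditions.

    e.g. tools > [faces + places + animals].
    """
    from .design import INTACT_CONDITIONS

    if category not in INTACT_CONDITIONS:
        raise ValueError(f"unknown intact category {category!r}")
    w = np.zeros(len(condition_names))
    for i, c in enumerate(condition_names):
        if c == category:
            w[i] = 1.0
        elif c in INTACT_CONDITIONS:
            w[i] = -1.0 / 3.0
    return w


def pairwise_contrast(cat_a: str, cat_b: str, condition_names: list[str]) -> np.ndarray:
    """Simple A > B contrast (1 / -1) used for comparison-specific selection."""
    w = np.zeros(len(condition_names))
    w[condition_names.index(cat_a)] = 1.0
    w[condition_names.index(cat_b)] = -1.0
    return w
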