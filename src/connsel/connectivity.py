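"""Task-regressed, band-passed residuals and target-to-seed connectivity.

Functional connectivity is computed on "pseudo-resting-state" data: the
task-evoked response, motion (plus first temporal derivatives), a
global-signal proxy and the intercept are regressed out of each run, the
residuals are band-pass filtered to 0.01-0.1 Hz, runs belonging to a
data split are concatenated, and Pearson correlations between each
target-region voxel and every same-category seed voxel are Fisher-z
transformed.  A voxel's connectivity score is its mean z over all seed
voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glm import DesignMatrix

#: |r| is clipped below 1 so the Fisher transform stays finite.
R_CLIP = 1.0 - 1e-7

BAND_LOW_HZ = 0.01
BAND_HIGH_HZ = 0.1
#: transition half-width of the spectral rolloff, as a fraction of the edge
_EDGE_FRAC = 0.25


def bandpass(
    timeseries: np.ndarray,
    low_hz: float = BAND_LOW_HZ,
    high_hz: float = BAND_HIGH_HZ,
    tr_seconds: float = 2.0,
) -> np.ndarray:
    """Zero-phase band-pass along the time axis (axis 0).

    Implemented in the frequency domain with a raised-cosine rolloff at
    each band edge, which is exactly zero-phase and free of the edge
    transients an IIR filter produces on runs this short (88 samples).
    Passband gain is within 10% of unity across the band; stopband gain
    at twice the upper edge is below 0.1; DC is removed entirely.
    """
    nyquist = 0.5 / tr_seconds
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(f"high_hz must be below the Nyquist frequency {nyquist} Hz")
    x = np.asarray(timeseries, dtype=float)
    F = _bandpass_operator(x.shape[0], low_hz, high_hz, tr_seconds)
    return F @ x


def bandpass_gain(freqs: np.ndarray, low_hz: float = BAND_LOW_HZ,
                  high_hz: float = BAND_HIGH_HZ) -> np.ndarray:
    """Transfer-function gain of :func:`bandpass` at the given frequencies."""

    def _taper(f, lo, hi, rising):
        # half-cosine from 0 to 1 (rising) or 1 to 0 over [lo, hi]
        t = np.clip((f - lo) / max(hi - lo, 1e-12), 0.0, 1.0)
        s = 0.5 - 0.5 * np.cos(np.pi * t)
        return s if rising else 1.0 - s

    lw = _EDGE_FRAC * low_hz
    hw = _EDGE_FRAC * high_hz
    gain = _taper(freqs, low_hz - lw, low_hz + lw, rising=True) * _taper(
        freqs, high_hz - hw, high_hz + hw, rising=False
    )
    gain[freqs == 0] = 0.0
    return gain


_BP_CACHE: dict[tuple, np.ndarray] = {}


def _bandpass_operator(n: int, low_hz: float, high_hz: float,
                       tr_seconds: float) -> np.ndarray:
    """The n x n matrix realizing the zero-phase spectral filter (cached)."""
    key = (n, low_hz, high_hz, tr_seconds)
    F = _BP_CACHE.get(key)
    if F is None:
        gain = bandpass_gain(np.fft.rfftfreq(n, d=tr_seconds), low_hz, high_hz)
        F = np.fft.irfft(gain[:, None] * np.fft.rfft(np.eye(n), axis=0), n=n, axis=0)
        _BP_CACHE[key] = F
    return F


def nuisance_matrix(
    motion: np.ndarray, global_proxy: np.ndarray | None = None
) -> np.ndarray:
    """Standard nuisance set: 6 motion series, their first-order temporal
    derivatives (backward differences, zero-padded), and one combined
    global-signal proxy."""
    motion = np.asarray(motion, dtype=float)
    deriv = np.vstack([np.zeros((1, motion.shape[1])), np.diff(motion, axis=0)])
    cols = [motion, deriv]
    if global_proxy is not None:
        cols.append(np.asarray(global_proxy, dtype=float).reshape(-1, 1))
    return np.column_stack(cols)


def task_regress(
    run_timeseries: np.ndarray,
    design_matrix: DesignMatrix,
    nuisance: np.ndarray | None = None,
) -> np.ndarray:
    """Residualize a run against [task regressors | nuisance | intercept].

    Removes the HRF-convolved condition responses along with motion and
    global-signal nuisance, leaving the spontaneous fluctuations that
    carry functional connectivity.
    """
    Y = np.asarray(run_timeseries, dtype=float)
    task = design_matrix.condition_columns()
    blocks = [task]
    if nuisance is not None:
        nuisance = np.asarray(nuisance, dtype=float)
        if nuisance.shape[0] != Y.shape[0]:
            raise ValueError("nuisance rows must match the run length")
        blocks.append(nuisance)
    blocks.append(np.ones((Y.shape[0], 1)))
    X = np.column_stack(blocks)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient regression matrix")
    beta = np.linalg.solve(X.T @ X, X.T @ Y)
    return Y - X @ beta


@dataclass
class ConnectivityProfile:
    """Fisher-z target x seed matrix plus the per-voxel mean score."""

    z_matrix: np.ndarray  # target voxel x seed voxel
    mean_z: np.ndarray  # per target voxel
    eligible: np.ndarray  # bool per target voxel (zero-variance voxels flagged)
    seed_slices: dict[str, slice] | None = None
    fold_id: int | None = None


def fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def connectivity_profile(
    target_ts: np.ndarray,
    seed_ts_by_region: dict[str, np.ndarray] | np.ndarray,
    fold_id: int | None = None,
) -> ConnectivityProfile:
    """Fisher-z connectivity of each target voxel to every seed voxel.

    ``seed_ts_by_region`` maps seed-region names to (time x voxel)
    blocks (or is a single such block); blocks are concatenated along
    voxels, so ``mean_z`` averages over all seed voxels regardless of
    region ordering.  Zero-variance target voxels are flagged ineligible
    and their rows set to NaN; zero-variance seed voxels yield NaN
    columns that are excluded from the mean.
    """
    if isinstance(seed_ts_by_region, dict):
        seed_blocks = [np.asarray(v, dtype=float) for v in seed_ts_by_region.values()]
        names = list(seed_ts_by_region)
    else:
        seed_blocks = [np.asarray(seed_ts_by_region, dtype=float)]
        names = ["seed"]
    seeds = np.column_stack(seed_blocks)
    tgt = np.asarray(target_ts, dtype=float)
    if tgt.shape[0] != seeds.shape[0]:
        raise ValueError("target and seed time axes must align")
    T = tgt.shape[0]

    tgt_c = tgt - tgt.mean(axis=0)
    seed_c = seeds - seeds.mean(axis=0)
    tgt_sd = tgt_c.std(axis=0)
    seed_sd = seed_c.std(axis=0)
    eligible = tgt_sd > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        num = tgt_c.T @ seed_c / T
        r = num / np.outer(np.where(eligible, tgt_sd, np.nan),
                           np.where(seed_sd > 0, seed_sd, np.nan))
    z = fisher_z(r)
    finite = np.isfinite(z)
    counts = finite.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_z = np.where(finite, z, 0.0).sum(axis=1) / np.where(counts, counts, np.nan)

    slices = {}
    start = 0
    for name, blk in zip(names, seed_blocks):
        slices[name] = slice(start, start + blk.shape[1])
        start += blk.shape[1]
    return ConnectivityProfile(
        z_matrix=z, mean_z=mean_z, eligible=eligible, seed_slices=slices,
        fold_id=fold_id,
    )
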