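"""Synthetic BOLD cohorts with planted connectivity and pattern structure.

Each simulated subject is a multi-run voxel x time dataset on a 3-D grid
in which the statistical structure the analysis assumes is planted by
construction and recorded in a truth ledger (read only by tests, never
by analysis code):

* **Connectivity** — a band-limited (0.01-0.1 Hz) latent signal, one per
  category per run, is injected into all voxels of that category's seed
  regions and into a random "informative" fraction of each target
  region's voxels.  Its standard-deviation ratio to the noise is
  ``coupling_strength``.
* **Patterns** — each target/seed region carries condition-specific
  multivoxel patterns (i.i.d. Gaussian across voxels, fixed within
  subject) of amplitude ``pattern_snr``; by default they ride on the
  informative (coupled) voxels so that distal connectivity indexes local
  discriminability.  Setting ``pattern_carrier="activation"`` ties them
  to the univariate activation profile instead, for confound studies.
* **Activation** — a heterogeneous per-voxel univariate amplitude,
  scaled by ``activation_gain`` and independent of the informative set
  unless ``activation_coupled`` is set, so that activation and
  connectivity are separately controllable.

Every voxel carries the same noise composition — a band-limited slow
component of SD ``coupling_strength`` plus white noise filling the
remainder of ``noise_sd``² — so planting connectivity changes only the
cross-correlation structure (shared vs private slow components), never
a voxel's marginal variance or spectrum.  A flat baseline completes the
signal; six smooth random-walk motion series per run exercise the
nuisance interface but carry no signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .connectivity import bandpass
from .design import CONDITIONS, INTACT_CONDITIONS, DesignSpec, make_design
from .glm import convolve_boxcar
from .layout import RegionLayout, six_region_layout

#: Non-preferred intact categories still drive visual cortex, scrambled
#: stimuli less so; relative response amplitudes per condition class.
PREF_OWN = 1.0
PREF_OTHER_INTACT = 0.3
PREF_SCRAMBLED = 0.15

BASELINE = 100.0


@dataclass(frozen=True)
class EffectSpec:
    """Planted-effect parameters for one simulated cohort.

    Defaults are the study conditions used throughout: moderate coupling
    (target-seed correlations well under 1 after denoising), a pattern
    amplitude calibrated so that informative voxel sets decode reliably
    above chance at the single-subject level, unit noise, and activation
    statistically independent of connectivity.
    """

    coupling_strength: float = 0.5
    frac_informative: float = 0.5
    pattern_snr: float = 0.1
    activation_gain: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0
    #: tie the univariate activation profile to the coupled voxels
    activation_coupled: bool = False
    #: "coupled": patterns ride on informative voxels (default);
    #: "activation": pattern amplitude follows the activation profile.
    pattern_carrier: str = "coupled"

    def __post_init__(self):
        if min(self.coupling_strength, self.pattern_snr,
               self.activation_gain, self.noise_sd) < 0:
            raise ValueError("effect magnitudes must be nonnegative")
        if not 0.0 <= self.frac_informative <= 1.0:
            raise ValueError("frac_informative must lie in [0, 1]")
        if self.pattern_carrier not in ("coupled", "activation"):
            raise ValueError("pattern_carrier must be 'coupled' or 'activation'")


@dataclass
class SubjectTruth:
    """Planted structure, for test assertions only — analysis never reads it."""

    informative: dict[str, np.ndarray]  # region -> flat voxel indices
    patterns: dict[str, dict[str, np.ndarray]]  # region -> condition -> per-voxel
    activation: dict[str, np.ndarray]  # region -> per-voxel amplitude profile
    latents: dict[str, list[np.ndarray]] = field(default_factory=dict)


@dataclass
class SubjectDataset:
    """One subject: per-run (time x voxel) matrices plus masks and design."""

    runs: list[np.ndarray]
    tr_seconds: float
    layout: RegionLayout
    design: list[DesignSpec]
    motion: list[np.ndarray]
    truth: SubjectTruth | None = None
    subject_id: str = "sub-00"

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def n_voxels(self) -> int:
        return self.runs[0].shape[1]

    def global_proxy(self, run: int) -> np.ndarray:
        """Mean time course over non-gray voxels (white-matter/CSF proxy)."""
        return self.runs[run][:, self.layout.nongray_indices()].mean(axis=1)


def _band_limited_latent(n_volumes: int, tr: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD noise confined to the 0.01-0.1 Hz connectivity passband."""
    x = rng.standard_normal(n_volumes)
    y = bandpass(x[:, None], tr_seconds=tr)[:, 0]
    sd = y.std()
    return y / sd if sd > 0 else y


def _band_limited_noise(n_volumes: int, tr: float, rng: np.random.Generator,
                        n_series: int) -> np.ndarray:
    """Independent band-limited noise series, one per column."""
    return bandpass(rng.standard_normal((n_volumes, n_series)), tr_seconds=tr)


def _orthogonalize(v: np.ndarray, basis: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(basis)
    return v - q @ (q.T @ v)


def _motion_walk(n_volumes: int, rng: np.random.Generator) -> np.ndarray:
    steps = rng.standard_normal((n_volumes, 6)) * 0.02
    walk = np.cumsum(steps, axis=0)
    # light smoothing for realism
    kernel = np.ones(5) / 5
    return np.column_stack(
        [np.convolve(walk[:, j], kernel, mode="same") for j in range(6)]
    )


def simulate_subject(
    layout: RegionLayout,
    design: list[DesignSpec],
    effect: EffectSpec,
    subject_id: str = "sub-00",
) -> SubjectDataset:
    """Simulate one subject's multi-run dataset with planted structure.

    Voxel time course = activation-scaled, HRF-convolved condition
    responses (weighted per voxel by the planted pattern values)
    + a band-limited slow component (shared latent for coupled voxels,
    private series otherwise, SD = coupling_strength) + white noise
    + baseline.  Latents are orthogonalized against the run's full
    first-level design span so the planted connectivity is neither an
    artifact of shared task drive nor leaks into condition betas.
    """
    rng = np.random.default_rng(effect.seed)
    n_vox = layout.n_voxels
    categories = sorted({c for c in layout.categories.values()})

    # --- per-region planted structure ---------------------------------
    informative: dict[str, np.ndarray] = {}
    patterns: dict[str, dict[str, np.ndarray]] = {}
    activation: dict[str, np.ndarray] = {}
    amp = np.zeros((n_vox, len(CONDITIONS)))  # per-voxel response amplitude
    cond_index = {c: i for i, c in enumerate(CONDITIONS)}

    for name, vox in layout.regions.items():
        cat = layout.categories[name]
        nv = vox.size
        act = np.abs(rng.normal(1.0, 0.35, size=nv))
        if layout.roles[name] == "target":
            k = int(round(effect.frac_informative * nv))
            info = np.sort(rng.choice(vox, size=k, replace=False))
        else:
            info = vox.copy()  # all seed-region voxels carry the latent
        informative[name] = info
        info_local = np.isin(vox, info)
        if effect.activation_coupled:
            act = act + 1.0 * info_local
        activation[name] = act

        pref = {c: PREF_SCRAMBLED for c in CONDITIONS}
        for c in INTACT_CONDITIONS:
            pref[c] = PREF_OWN if c == cat else PREF_OTHER_INTACT
        region_patterns: dict[str, np.ndarray] = {}
        if effect.pattern_carrier == "activation":
            carrier = act / max(act.mean(), 1e-12)
        else:
            carrier = info_local.astype(float)
        for c in INTACT_CONDITIONS:
            p = rng.standard_normal(nv)
            w = effect.pattern_snr * p * carrier
            # patterns shape multivoxel geometry only: remove any regional
            # mean response they would add (that is activation's job)
            w -= w.mean()
            region_patterns[c] = w
            amp[vox, cond_index[c]] += (
                effect.activation_gain * act * pref[c] + region_patterns[c]
            )
        for c in CONDITIONS[len(INTACT_CONDITIONS):]:
            amp[vox, cond_index[c]] += effect.activation_gain * act * pref[c]
        patterns[name] = region_patterns

    truth = SubjectTruth(informative=informative, patterns=patterns,
                         activation=activation, latents={c: [] for c in categories})

    # --- assemble runs -------------------------------------------------
    runs = []
    motion = []
    for spec in design:
        n_t = spec.n_volumes
        regs = np.column_stack(
            [convolve_boxcar(spec, c, n_t) for c in CONDITIONS]
        )
        run_motion = _motion_walk(n_t, rng)
        # latents are orthogonalized against the full first-level design
        # span so planted connectivity cannot leak into condition betas
        # through partialling with motion or the intercept
        glm_span = np.column_stack([regs, run_motion, np.ones(n_t)])
        data = BASELINE + regs @ amp.T
        # Every voxel receives the same noise composition -- a slow
        # band-limited component of SD coupling_strength plus white noise
        # filling the remainder of noise_sd^2 -- so that planting
        # connectivity never alters a voxel's marginal variance, spectrum
        # or GLM residual behavior.  Coupled voxels SHARE their category's
        # band-limited latent; all other voxels get private ones.  Only
        # the cross-correlation structure distinguishes them, which keeps
        # connectivity dissociable from activation t values.
        c = effect.coupling_strength
        white_sd = np.sqrt(max(effect.noise_sd**2 - c**2, 0.0))
        if c > 0:
            private = _band_limited_noise(n_t, spec.tr_seconds, rng, n_vox)
            private = _orthogonalize(private, glm_span)
            psd = private.std(axis=0)
            private /= np.where(psd > 0, psd, 1.0)
            data += c * private
            for cat in categories:
                latent = _band_limited_latent(n_t, spec.tr_seconds, rng)
                latent = _orthogonalize(latent, glm_span)
                sd = latent.std()
                if sd > 0:
                    latent = latent / sd
                truth.latents[cat].append(latent)
                coupled = np.concatenate(
                    [informative[r] for r in layout.regions
                     if layout.categories[r] == cat]
                )
                # replace the private slow component by the shared latent
                data[:, coupled] += c * (latent[:, None] - private[:, coupled])
        else:
            for cat in categories:
                truth.latents[cat].append(np.zeros(n_t))
        data += white_sd * rng.standard_normal((n_t, n_vox))
        runs.append(data)
        motion.append(run_motion)

    return SubjectDataset(
        runs=runs,
        tr_seconds=design[0].tr_seconds,
        layout=layout,
        design=design,
        motion=motion,
        truth=truth,
        subject_id=subject_id,
    )


def simulate_cohort(
    n_subjects: int,
    effect: EffectSpec = EffectSpec(),
    seed: int = 0,
    layout: RegionLayout | None = None,
    n_runs: int = 6,
) -> list[SubjectDataset]:
    """Simulate independent subjects from per-subject RNG streams.

    Each subject receives its own design randomization and effect seed,
    both derived from the master ``seed``; a fixed master seed therefore
    reproduces the cohort bit for bit.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    if layout is None:
        layout = six_region_layout()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects)
    cohort = []
    for i, child in enumerate(children):
        sub_seed, design_seed = (int(s) for s in child.generate_state(2) % (2**31))
        designs = make_design(n_runs=n_runs, seed=design_seed)
        cohort.append(
            simulate_subject(
                layout, designs, replace(effect, seed=sub_seed),
                subject_id=f"sub-{i:02d}",
            )
        )
    return cohort
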