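"""Block-design timing for the simulated localizer task.

Each run alternates 6 s stimulus blocks with 6 s fixation, bracketed by
16 s fixation at the start and end.  Four intact categories (tools,
faces, places, animals) appear twice per run and each category's
phase-scrambled variant once, giving 12 blocks and a run length of
16 + 12 x 12 + 16 = 176 s = 88 volumes at TR 2 s.  Block order is
randomized independently per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TR_SECONDS = 2.0
BLOCK_SECONDS = 6.0
FIXATION_SECONDS = 6.0
LEAD_SECONDS = 16.0

INTACT_CONDITIONS = ("tools", "faces", "places", "animals")
SCRAMBLED_CONDITIONS = tuple(f"scrambled_{c}" for c in INTACT_CONDITIONS)
CONDITIONS = INTACT_CONDITIONS + SCRAMBLED_CONDITIONS

#: blocks per run per condition
_N_BLOCKS = {c: 2 for c in INTACT_CONDITIONS} | {c: 1 for c in SCRAMBLED_CONDITIONS}


@dataclass(frozen=True)
class Block:
    condition: str
    onset_seconds: float
    duration_seconds: float


@dataclass
class DesignSpec:
    """Condition onsets/durations for one run."""

    blocks: list[Block]
    tr_seconds: float = TR_SECONDS
    conditions: tuple[str, ...] = CONDITIONS
    run_index: int = 0
    _duration: float | None = field(default=None, repr=False)

    @property
    def duration_seconds(self) -> float:
        if self._duration is not None:
            return self._duration
        last = max(b.onset_seconds + b.duration_seconds for b in self.blocks)
        return last + FIXATION_SECONDS + LEAD_SECONDS

    @property
    def n_volumes(self) -> int:
        return int(round(self.duration_seconds / self.tr_seconds))

    def condition_order(self) -> list[str]:
        return [b.condition for b in sorted(self.blocks, key=lambda b: b.onset_seconds)]

    def boxcar(self, condition: str, dt: float) -> np.ndarray:
        """Indicator of ``condition`` sampled on a grid of step ``dt``."""
        n = int(round(self.duration_seconds / dt))
        t = np.arange(n) * dt
        out = np.zeros(n)
        for b in self.blocks:
            if b.condition == condition:
                out[(t >= b.onset_seconds) & (t < b.onset_seconds + b.duration_seconds)] = 1.0
        return out


def _run_design(order: list[str], run_index: int) -> DesignSpec:
    blocks = []
    t = LEAD_SECONDS
    for cond in order:
        blocks.append(Block(cond, t, BLOCK_SECONDS))
        t += BLOCK_SECONDS + FIXATION_SECONDS
    total = t + LEAD_SECONDS  # t already includes the final post-block fixation
    return DesignSpec(blocks=blocks, run_index=run_index, _duration=total)


def make_design(n_runs: int = 6, seed: int = 0) -> list[DesignSpec]:
    """Per-run block designs with block order randomized across runs.

    Parameters
    ----------
    n_runs
        Number of runs (six in the emulated study).
    seed
        Seed for the block-order RNG; the same seed reproduces the same
        orders exactly.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    base = [c for c in CONDITIONS for _ in range(_N_BLOCKS[c])]
    designs = []
    for r in range(n_runs):
        order = [base[i] for i in rng.permutation(len(base))]
        designs.append(_run_design(order, r))
    return designs
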