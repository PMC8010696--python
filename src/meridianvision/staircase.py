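"""Three-down one-up adaptive staircase for 2IFC contrast thresholds.

Contrast is multiplied by 0.9 after every three consecutive correct
responses (the streak counter resets after a step) and by the reciprocal
step after every error, converging on the contrast supporting
(1/2)^(1/3) ~= 79.3% correct. Thresholds are estimated as the geometric
mean of an even number of late reversal contrasts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .synthetic_data import Meridian, ObserverModel

DEFAULT_SF_GRID = (0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 16.0)


@dataclass(frozen=True)
class StaircaseConfig:
    """Parameters of the 3-down-1-up multiplicative staircase.

    The up step defaults to 1/0.9, log-symmetric with the down step, which
    preserves the canonical 79.3% convergence level; set
    ``step_up_factor=1.1`` for a literal +10% step.
    """

    n_trials: int = 100
    n_down: int = 3
    step_down_factor: float = 0.9
    step_up_factor: float = 1.0 / 0.9
    start_contrast: float = 0.1
    contrast_floor: float = 1e-4
    contrast_ceiling: float = 1.0
    sf_grid: tuple = DEFAULT_SF_GRID
    discard_reversals: str = "parity-3-or-4"
    min_reversals: int = 6

    def __post_init__(self) -> None:
        if not 0.0 < self.step_down_factor < 1.0 < self.step_up_factor:
            raise ValueError("need 0 < step_down_factor < 1 < step_up_factor")
        if self.n_trials < 20:
            raise ValueError("n_trials must be >= 20")
        if self.n_down < 1:
            raise ValueError("n_down must be >= 1")
        if not 0.0 < self.contrast_floor < self.contrast_ceiling <= 1.0:
            raise ValueError("need 0 < floor < ceiling <= 1")
        if not self.contrast_floor <= self.start_contrast <= self.contrast_ceiling:
            raise ValueError("start_contrast outside [floor, ceiling]")
        grid = np.asarray(self.sf_grid, float)
        if grid.size and np.any(np.diff(grid) <= 0):
            raise ValueError("sf_grid must be strictly increasing")


class ThresholdEstimate(NamedTuple):
    value: float          # contrast fraction; nan when not converged
    converged: bool
    n_reversals_used: int


@dataclass
class StaircaseRun:
    """Trial-by-trial record of one staircase on one (eye, meridian, sf) cell."""

    sf: float
    meridian: Meridian
    contrasts: np.ndarray          # contrast presented on each trial
    correct: np.ndarray            # response on each trial
    reversal_indices: np.ndarray   # trial indices of staircase direction flips
    threshold_estimate: float      # nan when not converged
    converged: bool

    def to_frame(self, block: int = 0) -> pd.DataFrame:
        return pd.DataFrame({
            "block": block,
            "sf_cpd": self.sf,
            "meridian": self.meridian,
            "trial": np.arange(len(self.contrasts)),
            "contrast": self.contrasts,
            "correct": self.correct.astype(int),
        })


def detect_reversals(contrasts: Sequence[float]) -> np.ndarray:
    """Trial indices where the staircase's direction of contrast change flips.

    A reversal is recorded at the extremum trial (the peak or valley whose
    contrast gets averaged). Trials before the first contrast step carry no
    direction and are excluded; zero changes (e.g. at the floor/ceiling clip)
    do not alter the prevailing direction.
    """
    c = np.asarray(contrasts, float)
    if c.size == 0:
        raise ValueError("empty trial log")
    steps = np.sign(np.diff(np.log(c)))
    reversals = []
    prev = 0.0
    for j, s in enumerate(steps):
        if s == 0.0:
            continue
        if prev != 0.0 and s != prev:
            reversals.append(j)  # trial j is the extremum preceding change j
        prev = s
    return np.asarray(reversals, dtype=int)


def estimate_threshold(reversal_contrasts: Sequence[float],
                       config: StaircaseConfig | None = None) -> ThresholdEstimate:
    """Geometric mean of an even count of late reversal contrasts.

    The first four reversals are discarded when that leaves an even count,
    otherwise the first three; fewer than ``min_reversals`` reversals yields
    a non-converged flag and no estimate.
    """
    config = config or StaircaseConfig()
    vals = np.asarray(reversal_contrasts, float)
    n = vals.size
    if n < config.min_reversals or n < 2:
        return ThresholdEstimate(math.nan, False, 0)
    if n >= 6:
        drop = 4 if (n - 4) % 2 == 0 else 3
    else:  # short staircases (permissive min_reversals): just keep an even count
        drop = n % 2
    kept = vals[drop:]
    est = float(10.0 ** np.mean(np.log10(kept)))
    est = min(max(est, config.contrast_floor), config.contrast_ceiling)
    return ThresholdEstimate(est, True, kept.size)


def run_staircase(observer: ObserverModel, sf: float, meridian: Meridian,
                  config: StaircaseConfig | None = None,
                  rng: np.random.Generator | None = None) -> StaircaseRun:
    """Simulate one 3-down-1-up staircase against a Weibull 2IFC observer."""
    config = config or StaircaseConfig()
    rng = np.random.default_rng() if rng is None else rng

    # closed-form P(correct) with the per-cell sensitivity precomputed
    s = float(observer.csf(meridian).sensitivity(sf))
    slope = observer.psychometric_slope
    scale = 1.0 - observer.guess_rate - observer.lapse_rate
    guess = observer.guess_rate

    contrast = config.start_contrast
    down, up = config.step_down_factor, config.step_up_factor
    floor, ceil = config.contrast_floor, config.contrast_ceiling
    contrasts = np.empty(config.n_trials)
    correct = np.empty(config.n_trials, dtype=bool)
    u = rng.random(config.n_trials)
    streak = 0
    for i in range(config.n_trials):
        contrasts[i] = contrast
        p = guess + scale * (1.0 - math.exp(-((contrast * s) ** slope)))
        ok = u[i] < p
        correct[i] = ok
        if ok:
            streak += 1
            if streak == config.n_down:
                contrast *= down
                streak = 0
        else:
            streak = 0
            contrast *= up
        contrast = min(max(contrast, floor), ceil)

    reversals = detect_reversals(contrasts)
    est = estimate_threshold(contrasts[reversals], config)
    return StaircaseRun(sf=sf, meridian=meridian, contrasts=contrasts,
                        correct=correct, reversal_indices=reversals,
                        threshold_estimate=est.value, converged=est.converged)


def measure_csf_thresholds(observer: ObserverModel,
                           config: StaircaseConfig | None = None,
                           rng: np.random.Generator | None = None,
                           randomize_blocks: bool = True) -> dict:
    """Run the full per-eye session: one staircase block per (sf, meridian).

    Returns ``{(meridian, sf): StaircaseRun}`` for the 14-block layout
    (7 spatial frequencies x 2 meridians), block order randomized.
    """
    config = config or StaircaseConfig()
    rng = np.random.default_rng() if rng is None else rng
    cells = [(m, sf) for sf in config.sf_grid for m in ("strong", "weak")]
    if randomize_blocks:
        cells = [cells[i] for i in rng.permutation(len(cells))]
    return {(m, sf): run_staircase(observer, sf, m, config, rng)
            for m, sf in cells}


def session_to_frame(runs: dict) -> pd.DataFrame:
    """Concatenate a session's trial logs into one CSV-ready frame."""
    frames = [run.to_frame(block=b) for b, run in enumerate(runs.values())]
    return pd.concat(frames, ignore_index=True)
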