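"""Logistic psychometric family and maximum-likelihood model selection.

The adaptive thresholding engine works with a fixed family of logistic
psychometric functions

    p(x) = gamma + (1 - gamma) / (1 + exp(-beta * (x - alpha)))

where ``x`` is motion coherence in percent (0-100 scale), ``alpha`` the
midpoint, ``beta`` the slope (per percentage point of coherence) and
``gamma`` the guess rate (1/8 = 12.5% for an 8-alternative forced choice).
Candidate functions share ``beta`` and ``gamma`` and differ only in
``alpha``; after each trial the candidate maximizing the likelihood of the
full response history is selected and the next stimulus is placed at that
candidate's target-accuracy level (the "sweet point" at 70% correct).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PsychometricFunction",
    "HypothesisGrid",
    "TrialRecord",
    "prob_correct",
    "level_for_target",
    "build_hypothesis_grid",
    "log_likelihood",
    "select_mle",
    "GUESS_RATE_8AFC",
    "DEFAULT_SLOPE",
    "DEFAULT_TARGET",
    "DEFAULT_GRID_SIZE",
]

#: Chance performance in an eight-alternative forced choice task.
GUESS_RATE_8AFC = 0.125
#: Slope of the candidate psychometric functions, per % coherence.
DEFAULT_SLOPE = 0.5
#: Target proportion correct tracked by the adaptive procedure.
DEFAULT_TARGET = 0.70
#: Number of candidate midpoints in the hypothesis grid.
DEFAULT_GRID_SIZE = 150


@dataclass(frozen=True)
class PsychometricFunction:
    """One member of the logistic family: midpoint, slope, guess rate."""

    alpha: float
    beta: float = DEFAULT_SLOPE
    gamma: float = GUESS_RATE_8AFC

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma < 1.0):
            raise ValueError(f"gamma must be in [0, 1), got {self.gamma}")
        if not self.beta > 0.0:
            raise ValueError(f"beta must be positive, got {self.beta}")


@dataclass(frozen=True)
class TrialRecord:
    """A single trial: presented coherence level and response correctness."""

    level: float
    correct: bool
    hemifield: str = "left"
    block_index: int = 1
    trial_index: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.level <= 100.0):
            raise ValueError(f"level must be in [0, 100], got {self.level}")
        if self.hemifield not in ("left", "right"):
            raise ValueError(f"hemifield must be 'left' or 'right', got {self.hemifield!r}")


def prob_correct(x, pf: PsychometricFunction):
    """Probability of a correct response at coherence ``x`` under ``pf``.

    Accepts scalars or arrays; the value lies strictly between ``gamma``
    and 1 for finite ``x``.
    """
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        p = pf.gamma + (1.0 - pf.gamma) / (1.0 + np.exp(-pf.beta * (x - pf.alpha)))
    return p if p.ndim else float(p)


def level_for_target(pf: PsychometricFunction, p_target: float) -> float:
    """Coherence level at which ``pf`` predicts ``p_target`` correct.

    Closed-form inverse of :func:`prob_correct`:

        x = alpha - (1/beta) * ln((1 - p) / (p - gamma))

    Raises ``ValueError`` when ``p_target`` lies outside ``(gamma, 1)``,
    where the logistic is not invertible.
    """
    if not (pf.gamma < p_target < 1.0):
        raise ValueError(
            f"target probability {p_target} outside attainable range ({pf.gamma}, 1)"
        )
    return pf.alpha - np.log((1.0 - p_target) / (p_target - pf.gamma)) / pf.beta


@dataclass(frozen=True)
class HypothesisGrid:
    """Ordered candidate psychometric functions differing only in midpoint."""

    alphas: tuple
    beta: float = DEFAULT_SLOPE
    gamma: float = GUESS_RATE_8AFC
    p_target: float = DEFAULT_TARGET

    def __post_init__(self) -> None:
        a = np.asarray(self.alphas, dtype=float)
        if a.size < 2:
            raise ValueError("grid needs at least 2 hypotheses")
        if not np.all(np.diff(a) > 0):
            raise ValueError("alphas must be strictly increasing")

    def __len__(self) -> int:
        return len(self.alphas)

    def __getitem__(self, k: int) -> PsychometricFunction:
        return PsychometricFunction(self.alphas[k], self.beta, self.gamma)

    @property
    def functions(self) -> list:
        return [self[k] for k in range(len(self))]


def build_hypothesis_grid(
    count: int = DEFAULT_GRID_SIZE,
    beta: float = DEFAULT_SLOPE,
    gamma: float = GUESS_RATE_8AFC,
    level_range: tuple = (0.0, 100.0),
    p_target: float = DEFAULT_TARGET,
) -> HypothesisGrid:
    """Build the midpoint grid so target levels span ``level_range``.

    The midpoints are evenly spaced and parameterized so that the
    target-accuracy levels of the first and last hypotheses coincide with
    the bounds of ``level_range`` — i.e. a 150-point grid with the default
    range lets the procedure present any coherence in 0-100% at 70%
    predicted accuracy.
    """
    lo, hi = float(level_range[0]), float(level_range[1])
    if count < 2:
        raise ValueError("count must be >= 2")
    if not hi > lo:
        raise ValueError(f"degenerate level range ({lo}, {hi})")
    # offset between a midpoint and its target level, constant across grid
    offset = level_for_target(PsychometricFunction(0.0, beta, gamma), p_target)
    alphas = np.linspace(lo - offset, hi - offset, count)
    return HypothesisGrid(tuple(alphas), beta, gamma, p_target)


def log_likelihood(history: Sequence[TrialRecord], pf: PsychometricFunction) -> float:
    """Bernoulli log-likelihood of a trial history under one candidate."""
    if len(history) == 0:
        raise ValueError("empty trial history")
    total = 0.0
    for rec in history:
        # clamp float saturation at 1 so the likelihood stays finite for
        # every grid member even after an incorrect easy trial
        p = min(prob_correct(rec.level, pf), 1.0 - 1e-12)
        total += np.log(p) if rec.correct else np.log1p(-p)
    return float(total)


def grid_log_likelihoods(grid: HypothesisGrid, history: Sequence[TrialRecord]) -> np.ndarray:
    """Vector of log-likelihoods of ``history`` across all grid members."""
    if len(history) == 0:
        raise ValueError("empty trial history")
    alphas = np.asarray(grid.alphas)
    levels = np.array([r.level for r in history])
    correct = np.array([r.correct for r in history], dtype=bool)
    # (n_trials, n_hypotheses)
    with np.errstate(over="ignore"):
        p = grid.gamma + (1.0 - grid.gamma) / (
            1.0 + np.exp(-grid.beta * (levels[:, None] - alphas[None, :]))
        )
    p = np.minimum(p, 1.0 - 1e-12)  # keep log1p(-p) finite at float saturation
    ll = np.where(correct[:, None], np.log(p), np.log1p(-p))
    return ll.sum(axis=0)


def select_mle(grid: HypothesisGrid, history: Sequence[TrialRecord]) -> PsychometricFunction:
    """Grid member maximizing the history likelihood (full scan).

    Ties are broken deterministically in favor of the lowest midpoint (the
    most sensitive hypothesis). Likelihood along the grid is not assumed
    unimodal, so the argmax is always found by exhaustive scan.
    """
    ll = grid_log_likelihoods(grid, history)
    # np.argmax returns the first (lowest-alpha) index among exact ties
    return grid[int(np.argmax(ll))]
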