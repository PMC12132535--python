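"""Adaptive thresholding session: interleaved left/right hemifield tracks.

One stimulation session presents 160 trials per hemifield across five
blocks. Each hemifield runs its own independent maximum-likelihood track:
after every response the best-fitting candidate psychometric function is
re-selected over the full per-hemifield history and the next stimulus is
placed at that candidate's 70%-correct level, clipped to the presentable
range. The final threshold is the target level of the hypothesis selected
after all trials (``all-blocks`` mode); the per-block variant resets the
track each block and averages the five block thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .psychometric import (
    DEFAULT_GRID_SIZE,
    DEFAULT_TARGET,
    HypothesisGrid,
    PsychometricFunction,
    TrialRecord,
    build_hypothesis_grid,
    level_for_target,
    select_mle,
)

__all__ = [
    "SessionConfig",
    "TrackState",
    "SessionResult",
    "next_level",
    "update_track",
    "run_interleaved_session",
]


@dataclass(frozen=True)
class SessionConfig:
    """Session-level parameters of the adaptive procedure."""

    trials_per_hemifield: int = 160
    blocks: int = 5
    p_target: float = DEFAULT_TARGET
    initial_level: float = 100.0
    threshold_mode: str = "all-blocks"  # or "per-block-average"
    grid_size: int = DEFAULT_GRID_SIZE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_hemifield % self.blocks != 0:
            raise ValueError(
                f"trials_per_hemifield ({self.trials_per_hemifield}) must be "
                f"divisible by blocks ({self.blocks})"
            )
        if self.threshold_mode not in ("all-blocks", "per-block-average"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if not (0.0 <= self.initial_level <= 100.0):
            raise ValueError("initial_level must be in [0, 100]")

    @property
    def trials_per_block(self) -> int:
        return self.trials_per_hemifield // self.blocks


@dataclass
class TrackState:
    """One hemifield's adaptive track.

    Keeps the cumulative per-hypothesis log-likelihood so an update is
    O(grid) rather than O(grid x history); ``select_mle`` over the stored
    history gives the identical answer (asserted in tests).
    """

    hemifield: str
    grid: HypothesisGrid
    history: list = field(default_factory=list)
    _loglik: Optional[np.ndarray] = None

    @property
    def current_mle(self) -> Optional[PsychometricFunction]:
        if self._loglik is None:
            return None
        return self.grid[int(np.argmax(self._loglik))]


def next_level(track: TrackState, config: SessionConfig) -> float:
    """Coherence to present next: the current MLE's target level, clipped."""
    mle = track.current_mle
    if mle is None:
        return float(config.initial_level)
    level = level_for_target(mle, config.p_target)
    return float(np.clip(level, 0.0, 100.0))


def update_track(track: TrackState, record: TrialRecord) -> TrackState:
    """Append a trial and re-select the maximum-likelihood hypothesis."""
    if record.hemifield != track.hemifield:
        raise ValueError(
            f"record hemifield {record.hemifield!r} does not match track "
            f"{track.hemifield!r}"
        )
    grid = track.grid
    alphas = np.asarray(grid.alphas)
    with np.errstate(over="ignore"):
        p = grid.gamma + (1.0 - grid.gamma) / (
            1.0 + np.exp(-grid.beta * (record.level - alphas))
        )
    p = np.minimum(p, 1.0 - 1e-12)  # same clamp as grid_log_likelihoods
    delta = np.log(p) if record.correct else np.log1p(-p)
    loglik = delta if track._loglik is None else track._loglik + delta
    return TrackState(track.hemifield, grid, track.history + [record], loglik)


@dataclass(frozen=True)
class SessionResult:
    """Final thresholds plus the complete trial log."""

    threshold_left: float
    threshold_right: float
    trial_log: tuple
    config_echo: SessionConfig
    final_level_left: float = float("nan")
    final_level_right: float = float("nan")


def _track_threshold(track: TrackState, config: SessionConfig) -> float:
    mle = track.current_mle
    if mle is None:
        raise RuntimeError("cannot extract a threshold from an empty track")
    return float(np.clip(level_for_target(mle, config.p_target), 0.0, 100.0))


def run_interleaved_session(observer_left, observer_right, config: SessionConfig) -> SessionResult:
    """Run a full two-track session against simulated (or real) observers.

    ``observer_left`` / ``observer_right`` must expose
    ``respond(level, rng) -> bool``. The left/right presentation order is
    randomized within each block under the session seed; each track's
    hypothesis sequence depends only on its own response stream, never on
    the interleaving.
    """
    root = np.random.SeedSequence(config.seed)
    ss_order, ss_left, ss_right = root.spawn(3)
    rng_order = np.random.default_rng(ss_order)
    rngs = {"left": np.random.default_rng(ss_left), "right": np.random.default_rng(ss_right)}
    observers = {"left": observer_left, "right": observer_right}

    grid = build_hypothesis_grid(count=config.grid_size, p_target=config.p_target)
    tracks = {"left": TrackState("left", grid), "right": TrackState("right", grid)}
    block_thresholds: dict = {"left": [], "right": []}
    trial_counts = {"left": 0, "right": 0}
    log: list = []

    per_block = config.trials_per_block
    for block in range(1, config.blocks + 1):
        order = np.array(["left"] * per_block + ["right"] * per_block)
        rng_order.shuffle(order)
        for side in order:
            track = tracks[side]
            level = next_level(track, config)
            correct = observers[side].respond(level, rngs[side])
            trial_counts[side] += 1
            rec = TrialRecord(
                level=level,
                correct=bool(correct),
                hemifield=side,
                block_index=block,
                trial_index=trial_counts[side],
            )
            tracks[side] = update_track(track, rec)
            log.append(rec)
        if config.threshold_mode == "per-block-average":
            for side in ("left", "right"):
                block_thresholds[side].append(_track_threshold(tracks[side], config))
                tracks[side] = TrackState(side, grid)  # reset between blocks

    if config.threshold_mode == "per-block-average":
        thr = {s: float(np.mean(block_thresholds[s])) for s in ("left", "right")}
        final_levels = {s: block_thresholds[s][-1] for s in ("left", "right")}
    else:
        thr = {s: _track_threshold(tracks[s], config) for s in ("left", "right")}
        final_levels = {
            s: next(r.level for r in reversed(log) if r.hemifield == s)
            for s in ("left", "right")
        }

    return SessionResult(
        threshold_left=thr["left"],
        threshold_right=thr["right"],
        trial_log=tuple(log),
        config_echo=config,
        final_level_left=final_levels["left"],
        final_level_right=final_levels["right"],
    )
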