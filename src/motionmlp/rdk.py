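"""Frame-level random-dot-kinematogram generator.

Reproduces the dot kinematics of the motion-discrimination stimulus: 150
white dots (0.12 deg) in an 8-deg circular aperture (~3 dots/deg^2),
drifting at 13.3 deg/s for 106 ms at 60 Hz. On every frame each dot is
independently assigned signal or noise identity with P(signal) equal to the
nominal coherence — the per-frame re-draw that suppresses motion streaks.
Signal dots translate one frame step along one of the eight cardinal
trajectories (45-degree spacing); noise dots relocate uniformly within the
aperture. A dot that outlives its 47 ms lifetime or exits the aperture is
replaced at a random position, keeping dot count (hence density) constant.
Initial dot ages are staggered so replacements spread across frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import cos, pi, sin

import numpy as np

__all__ = ["RDKParams", "FrameStack", "generate_rdk", "empirical_signal_fraction"]

#: The eight cardinal/diagonal motion trajectories, degrees counterclockwise from +x.
DIRECTIONS_DEG = tuple(range(0, 360, 45))


@dataclass(frozen=True)
class RDKParams:
    """Stimulus geometry and timing, all in visual degrees / ms / Hz."""

    n_dots: int = 150
    dot_diameter: float = 0.12
    aperture_diameter: float = 8.0
    eccentricity: float = 12.0
    speed: float = 13.3
    lifetime_ms: float = 47.0
    duration_ms: float = 106.0
    frame_rate: float = 60.0
    reassign_each_frame: bool = True  # False: fixed signal/noise identities

    @property
    def density(self) -> float:
        """Dots per square degree of aperture."""
        return self.n_dots / (pi * (self.aperture_diameter / 2.0) ** 2)

    @property
    def n_frames(self) -> int:
        """round(duration / frame period): 106 ms at 60 Hz -> 6 frames."""
        return int(round(self.duration_ms * self.frame_rate / 1000.0))

    @property
    def step(self) -> float:
        """Per-frame displacement of a signal dot, deg."""
        return self.speed / self.frame_rate

    @property
    def lifetime_frames(self) -> int:
        """Displacement steps a dot survives: floor(47 / 16.67) = 2."""
        return int(self.lifetime_ms * self.frame_rate / 1000.0)


@dataclass(frozen=True)
class FrameStack:
    """Per-frame dot positions (aperture-centered deg) and role labels."""

    positions: np.ndarray  # (n_frames, n_dots, 2)
    is_signal: np.ndarray  # (n_frames, n_dots) bool
    params: RDKParams
    coherence: float
    direction_deg: float

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]


def _uniform_in_disc(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2.0 * pi
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def generate_rdk(
    coherence: float,
    direction_deg: float,
    params: RDKParams = RDKParams(),
    seed: int = 0,
) -> FrameStack:
    """Generate one stimulus presentation at the given nominal coherence.

    ``direction_deg`` must be one of the eight 45-degree-spaced
    trajectories. The returned stack is deterministic in ``seed``.
    """
    if not (0.0 <= coherence <= 100.0):
        raise ValueError(f"coherence must be in [0, 100], got {coherence}")
    if direction_deg % 360 not in DIRECTIONS_DEG:
        raise ValueError(f"direction must be one of {DIRECTIONS_DEG}, got {direction_deg}")
    rng = np.random.default_rng(seed)
    radius = params.aperture_diameter / 2.0
    n = params.n_dots
    p_signal = coherence / 100.0
    vx = params.step * cos(direction_deg * pi / 180.0)
    vy = params.step * sin(direction_deg * pi / 180.0)

    pos = _uniform_in_disc(rng, n, radius)
    # asynchronous onsets: stagger initial ages across the lifetime
    age = rng.integers(0, max(params.lifetime_frames, 1), size=n)
    signal = rng.random(n) < p_signal

    positions = np.empty((params.n_frames, n, 2))
    roles = np.empty((params.n_frames, n), dtype=bool)
    positions[0] = pos
    roles[0] = signal

    for f in range(1, params.n_frames):
        if params.reassign_each_frame:
            signal = rng.random(n) < p_signal
        new_pos = pos.copy()
        # signal dots translate; noise dots relocate uniformly
        new_pos[signal, 0] += vx
        new_pos[signal, 1] += vy
        n_noise = int((~signal).sum())
        new_pos[~signal] = _uniform_in_disc(rng, n_noise, radius)
        age = age + 1
        expired = age >= params.lifetime_frames
        escaped = np.hypot(new_pos[:, 0], new_pos[:, 1]) > radius
        replace = expired | escaped
        n_rep = int(replace.sum())
        if n_rep:
            new_pos[replace] = _uniform_in_disc(rng, n_rep, radius)
            age[replace] = 0
        pos = new_pos
        positions[f] = pos
        roles[f] = signal

    return FrameStack(positions, roles, params, coherence, float(direction_deg))


def empirical_signal_fraction(stack: FrameStack) -> float:
    """Mean fraction of dots carrying the coherent motion signal per frame."""
    if stack.n_frames == 0:
        raise ValueError("empty frame stack")
    return float(stack.is_signal.mean())


def export_frames(stack: FrameStack, path) -> None:
    """Write the stack as columnar text: frame, dot, x, y, role."""
    import pandas as pd

    nf, nd, _ = stack.positions.shape
    frame_idx = np.repeat(np.arange(nf), nd)
    dot_idx = np.tile(np.arange(nd), nf)
    df = pd.DataFrame(
        {
            "frame": frame_idx,
            "dot": dot_idx,
            "x": stack.positions[:, :, 0].ravel(),
            "y": stack.positions[:, :, 1].ravel(),
            "role": np.where(stack.is_signal.ravel(), "signal", "noise"),
        }
    )
    df.to_csv(path, sep="\t", index=False)
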