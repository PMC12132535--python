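"""Synthetic stand-ins for participants and imaging data.

Three generators back the validation of the pipeline:

* :class:`SimulatedObserver` — a Bernoulli responder governed by a true
  psychometric function, optionally with a lapse rate, used to exercise the
  adaptive thresholding engine and measure parameter recovery.
* :func:`generate_cohort` — balanced within-subject cohorts of coherence
  thresholds (participant x condition x hemifield x session order) with
  subject random effects, a linear session-order learning drift, condition
  x hemifield shifts, and residual noise. Condition order is counterbalanced
  across the six permutations of the three conditions.
* :func:`generate_volume_pair` — co-registered 3-D scalar fields emulating
  a functional-contrast t-map and a stimulation e-field magnitude inside a
  shared ellipsoidal brain mask, with a dial (``overlap_strength``) moving
  the e-field peak toward the t-map's principal activation blob.

Default cohort effects encode the study conditions: 42 participants, and
residual noise scaled so the per-participant difference-of-differences
score (the paired quantity behind the d = 0.54 sampling plan) has standard
deviation 14.8% coherence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .psychometric import PsychometricFunction, prob_correct

__all__ = [
    "SimulatedObserver",
    "CohortEffects",
    "CONDITIONS",
    "HEMIFIELDS",
    "generate_cohort",
    "VolumePair",
    "generate_volume_pair",
]

CONDITIONS = ("hMT_active", "hMT_sham", "forehead_active")
HEMIFIELDS = ("ipsilateral", "contralateral")


@dataclass(frozen=True)
class SimulatedObserver:
    """Stochastic observer with logistic sensitivity and a lapse rate.

    On a lapse (probability ``lapse``) the observer guesses, so the
    response probability is ``(1-lapse) * p(x) + lapse * gamma``.
    """

    true_pf: PsychometricFunction
    lapse: float = 0.0

    def prob(self, level: float) -> float:
        p = prob_correct(level, self.true_pf)
        return (1.0 - self.lapse) * p + self.lapse * self.true_pf.gamma

    def respond(self, level: float, rng: np.random.Generator) -> bool:
        if not (0.0 <= level <= 100.0):
            raise ValueError(f"level must be in [0, 100], got {level}")
        return bool(rng.random() < self.prob(level))


@dataclass(frozen=True)
class CohortEffects:
    """Population parameters of a simulated cohort (all in % coherence).

    ``condition_hemifield_effect`` maps ``(condition, hemifield)`` to a true
    mean shift; the default empty map is the global null. ``residual_sd``
    defaults to 7.4 so the difference-of-differences score
    (active ipsi-contra minus sham ipsi-contra) has SD 2 x 7.4 = 14.8.
    """

    n_participants: int = 42
    grand_mean: float = 70.0
    subject_sd: float = 7.4
    condition_hemifield_effect: tuple = ()  # ((condition, hemifield, shift), ...)
    session_learning_slope: float = 0.0
    residual_sd: float = 7.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subject_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        for cond, hemi, _ in self.condition_hemifield_effect:
            if cond not in CONDITIONS or hemi not in HEMIFIELDS:
                raise ValueError(f"unknown condition/hemifield pair ({cond}, {hemi})")

    def effect(self, condition: str, hemifield: str) -> float:
        for cond, hemi, shift in self.condition_hemifield_effect:
            if cond == condition and hemi == hemifield:
                return float(shift)
        return 0.0


def generate_cohort(effects: CohortEffects) -> pd.DataFrame:
    """Simulate a balanced threshold table under the additive cohort model.

    threshold(p, c, h) = grand_mean + subject(p) + slope * (session - 1)
                         + effect(c, h) + noise,
    truncated to [0, 100]. Returns a long-format table with columns
    participant, condition, hemifield, session_order, threshold. Condition
    order is counterbalanced over the 6 permutations; when n is not
    divisible by 6 the remainder is assigned to the first permutations in
    itertools order.
    """
    rng = np.random.default_rng(effects.seed)
    n = effects.n_participants
    perms = list(itertools.permutations(CONDITIONS))
    subject_effect = rng.normal(0.0, effects.subject_sd, size=n)

    rows = []
    for p in range(n):
        order = perms[p % 6]
        for session, cond in enumerate(order, start=1):
            learning = effects.session_learning_slope * (session - 1)
            for hemi in HEMIFIELDS:
                thr = (
                    effects.grand_mean
                    + subject_effect[p]
                    + learning
                    + effects.effect(cond, hemi)
                    + rng.normal(0.0, effects.residual_sd)
                )
                rows.append((f"P{p + 1:03d}", cond, hemi, session, float(np.clip(thr, 0.0, 100.0))))
    return pd.DataFrame(
        rows, columns=["participant", "condition", "hemifield", "session_order", "threshold"]
    )


@dataclass(frozen=True)
class VolumePair:
    """Two co-registered 3-D scalar fields sharing one brain mask."""

    tmap: np.ndarray
    efield: np.ndarray
    mask: np.ndarray
    voxel_size: tuple = (2.5, 2.5, 2.5)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        if not (self.tmap.shape == self.efield.shape == self.mask.shape):
            raise ValueError("tmap, efield and mask must share one shape")


def generate_volume_pair(
    shape: tuple = (24, 24, 24),
    overlap_strength: float = 0.5,
    seed: int = 0,
    n_blobs: int = 3,
) -> VolumePair:
    """Synthetic t-map / e-field pair with controllable co-localization.

    The t-map is a sum of Gaussian blobs inside an ellipsoidal mask (the
    strongest is the "principal" activation); the e-field decays smoothly
    from a point at the mask surface. ``overlap_strength`` in [0, 1] slides
    the e-field source from a random far surface point (0) to the surface
    point nearest the principal blob (1).
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 8:
        raise ValueError(f"shape must be 3-D with every axis >= 8, got {shape}")
    if not (0.0 <= overlap_strength <= 1.0):
        raise ValueError("overlap_strength must be in [0, 1]")
    rng = np.random.default_rng(seed)

    grid = np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij"), axis=-1)
    center = (np.asarray(shape) - 1) / 2.0
    semi = np.asarray(shape) * 0.42
    ellip = ((grid - center) / semi) ** 2
    mask = ellip.sum(axis=-1) <= 1.0

    # t-map: Gaussian blobs at random in-mask centers, heaviest first
    sigma = min(shape) / 8.0
    amplitudes = np.sort(rng.uniform(2.0, 8.0, size=n_blobs))[::-1]
    in_mask = np.argwhere(ellip.sum(axis=-1) <= 0.5)  # keep blob centers interior
    blob_centers = in_mask[rng.choice(len(in_mask), size=n_blobs, replace=False)].astype(float)
    tmap = np.zeros(shape)
    for amp, c in zip(amplitudes, blob_centers):
        d2 = ((grid - c) ** 2).sum(axis=-1)
        tmap += amp * np.exp(-d2 / (2.0 * sigma**2))
    tmap += rng.normal(0.0, 0.05, size=shape)  # mild measurement noise

    principal = blob_centers[0]

    def surface_point(direction: np.ndarray) -> np.ndarray:
        d = direction / np.linalg.norm(direction / semi)
        return center + d

    # Source sits on the mask surface. At overlap_strength=0 its direction is
    # uniformly random (co-localization only by chance); at 1 it is the surface
    # point nearest the principal blob. Intermediate values rotate the random
    # direction toward the blob direction (spherical interpolation).
    toward = principal - center
    if np.linalg.norm(toward) < 1e-9:
        toward = rng.normal(size=3)
    near_dir = toward / np.linalg.norm(toward)
    rand_dir = rng.normal(size=3)
    rand_dir /= np.linalg.norm(rand_dir)
    mix = (1.0 - overlap_strength) * rand_dir + overlap_strength * near_dir
    if np.linalg.norm(mix) < 1e-9:  # opposite directions at s=0.5: nudge
        mix = near_dir + 1e-6 * rng.normal(size=3)
    src = surface_point(mix)

    dist = np.sqrt(((grid - src) ** 2).sum(axis=-1))
    efield = np.exp(-dist / (min(shape) / 3.0))
    efield += rng.normal(0.0, 1e-4, size=shape)  # break exact ties

    tmap = np.where(mask, tmap, 0.0)
    efield = np.where(mask, efield, 0.0)
    affine = np.diag([2.5, 2.5, 2.5, 1.0])
    affine[:3, 3] = -center * 2.5
    return VolumePair(tmap=tmap, efield=efield, mask=mask, affine=affine)
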