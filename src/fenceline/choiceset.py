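"""Matched used-available strata at the two analysis scales.

Crossing scale: each used step is matched with k available steps whose
lengths and turning angles are resampled from the animal's own empirical
step-kernel, all sharing the used step's anchor (the previous used point)
and referenced to the previous step's heading.

Proximity scale: each used relocation is matched with k points drawn
area-uniformly within a circular buffer around it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import Step, TrackPoint

logger = logging.getLogger(__name__)

K_AVAILABLE = 5  # available candidates per used relocation, both scales
BUFFER_RADIUS_M = 6746.0  # proximity-scale buffer: 90th pct of 4-day displacements


@dataclass
class EmpiricalKernel:
    """An individual's observed step lengths and turning angles, verbatim.

    Kernels are strictly per animal: availability for one individual is never
    generated from another individual's movement (avoids circularity and keeps
    tactic comparisons fair).
    """

    animal_id: str
    step_lengths: np.ndarray
    turning_angles: np.ndarray

    def __post_init__(self) -> None:
        self.step_lengths = np.asarray(self.step_lengths, dtype=float)
        self.turning_angles = np.asarray(self.turning_angles, dtype=float)

    def draw(self, k: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """k (length, turn) pairs resampled independently with replacement."""
        return (
            rng.choice(self.step_lengths, size=k, replace=True),
            rng.choice(self.turning_angles, size=k, replace=True),
        )


@dataclass
class ParametricKernel:
    """Gamma step lengths and von Mises turning angles.

    The parametric alternative to empirical resampling: used for sensitivity
    checks, and in simulation studies where the generating kernel is known —
    availability drawn from the true proposal removes the attenuation that
    realized (selection-distorted) step distributions induce.
    """

    gamma_shape: float
    gamma_scale: float
    vonmises_kappa: float
    vonmises_mu: float = 0.0

    def draw(self, k: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        return (
            rng.gamma(self.gamma_shape, self.gamma_scale, size=k),
            rng.vonmises(self.vonmises_mu, self.vonmises_kappa, size=k),
        )


def fit_parametric_kernel(kernel: EmpiricalKernel) -> ParametricKernel:
    """Gamma / von Mises MLE fit to an animal's observed steps."""
    from scipy import stats

    shape, _, scale = stats.gamma.fit(kernel.step_lengths, floc=0)
    kappa, _, _ = stats.vonmises.fit(kernel.turning_angles, fscale=1)
    return ParametricKernel(shape, scale, kappa)


def build_kernel(steps: list[Step]) -> EmpiricalKernel | None:
    """Empirical movement kernel from one animal's steps.

    Returns None (with a warning) when fewer than two steps have a defined
    turning angle; such animals cannot enter crossing-scale sampling.
    """
    if not steps:
        return None
    animal_id = steps[0].animal_id
    lengths = np.array([s.step_length for s in steps], dtype=float)
    angles = np.array(
        [s.turning_angle for s in steps if s.turning_angle is not None], dtype=float
    )
    if len(angles) < 2:
        logger.warning("animal %s: <2 defined turning angles; excluded", animal_id)
        return None
    return EmpiricalKernel(animal_id, lengths, angles)


def sample_available_steps(
    anchor_xy: tuple[float, float],
    prev_heading: float,
    kernel: EmpiricalKernel | ParametricKernel,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """k candidate endpoints from the movement kernel; shape (k, 2).

    Lengths and turning angles are drawn independently; candidate heading =
    previous heading + drawn turn.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    L, theta = kernel.draw(k, rng)
    heading = prev_heading + theta
    return np.column_stack(
        [anchor_xy[0] + L * np.cos(heading), anchor_xy[1] + L * np.sin(heading)]
    )


def sample_available_points(
    center_xy: tuple[float, float],
    radius: float,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """k points uniform over the disc of ``radius`` around the center; (k, 2)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    r = radius * np.sqrt(rng.random(k))
    phi = rng.random(k) * 2 * np.pi
    return np.column_stack(
        [center_xy[0] + r * np.cos(phi), center_xy[1] + r * np.sin(phi)]
    )


def build_crossing_strata(
    steps: list[Step],
    kernel: EmpiricalKernel | ParametricKernel,
    rng: np.random.Generator,
    k: int = K_AVAILABLE,
) -> pd.DataFrame:
    """Crossing-scale choice sets for one animal.

    One stratum per used step with a defined prior heading (the step before
    it must be contiguous): the used endpoint plus k available endpoints, all
    stepping from the same anchor. Columns: stratum_id, case, animal_id,
    scale, x, y, anchor_x, anchor_y.
    """
    rows = []
    prev: Step | None = None
    n_strata = 0
    for step in steps:
        if prev is not None and step.turning_angle is not None:
            sid = f"{step.animal_id}:c{n_strata}"
            ax, ay = step.start.x, step.start.y
            rows.append((sid, 1, step.animal_id, step.end.x, step.end.y, ax, ay))
            for ex, ey in sample_available_steps((ax, ay), prev.heading, kernel, k, rng):
                rows.append((sid, 0, step.animal_id, ex, ey, ax, ay))
            n_strata += 1
        prev = step
    df = pd.DataFrame(
        rows, columns=["stratum_id", "case", "animal_id", "x", "y", "anchor_x", "anchor_y"]
    )
    df.insert(3, "scale", "crossing")
    return df


def build_proximity_strata(
    points: list[TrackPoint],
    rng: np.random.Generator,
    radius: float = BUFFER_RADIUS_M,
    k: int = K_AVAILABLE,
) -> pd.DataFrame:
    """Proximity-scale choice sets: each relocation vs k disc-uniform points."""
    rows = []
    for i, p in enumerate(points):
        sid = f"{p.animal_id}:p{i}"
        rows.append((sid, 1, p.animal_id, p.x, p.y))
        for ex, ey in sample_available_points((p.x, p.y), radius, k, rng):
            rows.append((sid, 0, p.animal_id, ex, ey))
    df = pd.DataFrame(rows, columns=["stratum_id", "case", "animal_id", "x", "y"])
    df.insert(3, "scale", "proximity")
    return df
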