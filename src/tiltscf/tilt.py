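"""Stage-tilt transform of orientation sets and the ice-thickness factor.

Tilting the stage by alpha rotates the specimen (and every particle riding on
it) by a lab-frame rotation about the goniometer axis while the beam stays
fixed.  With orientation matrices mapping lab to particle frame, that is a
right-composition with the transposed lab rotation.  For a population sharing
one viewing direction but uniform in-plane psi, the transform spreads the
viewing directions over a cone of half-angle alpha about the original
centroid — the cone-of-illumination geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import OrientationSet, eulers_from_rotations, rotation_about_axis

__all__ = ["TiltSpec", "apply_stage_tilt", "effective_ice_factor"]


@dataclass(frozen=True)
class TiltSpec:
    """Stage tilt angle (degrees) and goniometer axis label ('x' or 'y')."""

    alpha: float
    tilt_axis: str = "y"

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha < 90.0):
            raise ValueError("alpha must be in [0, 90)")
        if self.tilt_axis.lower() not in ("x", "y"):
            raise ValueError("tilt_axis must be 'x' or 'y'")


def apply_stage_tilt(
    orients: OrientationSet, spec: TiltSpec | float
) -> OrientationSet:
    """Tilt the stage: compose every orientation with the lab rotation.

    Accepts a :class:`TiltSpec` or a bare angle in degrees (axis 'y').
    Population size, order, and weights are preserved; angles are returned in
    canonical Euler form.  Negative bare angles are accepted so that a tilt
    can be undone exactly (``apply_stage_tilt(out, -alpha)``).
    """
    if isinstance(spec, TiltSpec):
        alpha, axis = spec.alpha, spec.tilt_axis
    else:
        alpha, axis = float(spec), "y"
        if not (-90.0 < alpha < 90.0):
            raise ValueError("alpha must be in (-90, 90)")
    if alpha == 0.0:
        return OrientationSet(
            orients.angles.copy(), orients.weights.copy(),
            label=orients.label, seed=orients.seed,
        )
    T = rotation_about_axis(axis, alpha)
    R = orients.rotations() @ T.T  # lab-frame stage rotation, beam fixed
    angles = eulers_from_rotations(R)
    label = f"{orients.label}|tilt({alpha:g}deg,{axis})" if orients.label else (
        f"tilt({alpha:g}deg,{axis})")
    return OrientationSet(angles, orients.weights.copy(), label=label,
                          seed=orients.seed)


def effective_ice_factor(alpha: float) -> float:
    """Relative beam path length through the ice at stage tilt alpha: 1/cos."""
    if not (0.0 <= alpha < 90.0):
        raise ValueError("alpha must be in [0, 90)")
    return float(1.0 / np.cos(np.deg2rad(alpha)))
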