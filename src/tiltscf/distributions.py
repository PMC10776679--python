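"""Seeded generators for synthetic orientation scenarios.

Scenarios: uniform, single cone, two orthogonal cones, side-like, top-like,
plus "sprinkling" (replacing a fraction of a population with uniform draws).
All generators are pure functions of their arguments — the same seed yields
bit-identical output.

Cone populations are uniform over spherical-cap *area* (cos of the polar
angle uniform on [cos(half_angle), 1]); in-plane psi is always uniform on
[-180, 180).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    OrientationSet,
    eulers_from_rotations,
    rotation_about_axis,
    rotations_from_eulers,
)

__all__ = [
    "DistributionSpec",
    "generate",
    "sample_uniform",
    "sample_cone",
    "sample_two_orthogonal_cones",
    "add_sprinkles",
    "sample_side_like",
    "sample_top_like",
]

SCENARIOS = ("uniform", "single_cone", "two_orthogonal_cones", "side_like", "top_like")

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class DistributionSpec:
    """Declarative description of a synthetic orientation population."""

    scenario: str
    n: int = 10_000
    cone_half_angle: float = 30.0
    sprinkle_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}"
            )
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0.0 <= self.sprinkle_fraction <= 1.0):
            raise ValueError("sprinkle_fraction must be in [0, 1]")
        if self.scenario in ("single_cone", "two_orthogonal_cones"):
            if not (0.0 < self.cone_half_angle <= 90.0):
                raise ValueError("cone_half_angle must be in (0, 90]")

    def to_text(self) -> str:
        lines = [f"{k}={getattr(self, k)}" for k in (
            "scenario", "n", "cone_half_angle", "sprinkle_fraction", "seed")]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "DistributionSpec":
        kv: dict[str, str] = {}
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed spec line: {raw!r}")
            k, v = (s.strip() for s in line.split("=", 1))
            kv[k] = v
        return cls(
            scenario=kv["scenario"],
            n=int(kv.get("n", 10_000)),
            cone_half_angle=float(kv.get("cone_half_angle", 30.0)),
            sprinkle_fraction=float(kv.get("sprinkle_fraction", 0.0)),
            seed=int(kv.get("seed", 0)),
        )


def _uniform_angles(rng: np.random.Generator, n: int) -> np.ndarray:
    """(rot, tilt, psi) rows for Haar-uniform viewing directions + psi."""
    rot = rng.uniform(-180.0, 180.0, n)
    tilt = np.rad2deg(np.arccos(rng.uniform(-1.0, 1.0, n)))
    psi = rng.uniform(-180.0, 180.0, n)
    return np.stack([rot, tilt, psi], axis=1)


def sample_uniform(n: int, seed: int) -> OrientationSet:
    """n orientations drawn from the uniform (Haar) measure on rotations."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return OrientationSet(_uniform_angles(rng, n), label="uniform", seed=seed)


def _cone_angles(rng: np.random.Generator, n: int, half_angle: float) -> np.ndarray:
    """Cone about +z, area-uniform over the spherical cap."""
    cos_min = np.cos(np.deg2rad(half_angle))
    tilt = np.rad2deg(np.arccos(rng.uniform(cos_min, 1.0, n)))
    rot = rng.uniform(-180.0, 180.0, n)
    psi = rng.uniform(-180.0, 180.0, n)
    return np.stack([rot, tilt, psi], axis=1)


def sample_cone(
    n: int,
    half_angle: float,
    seed: int,
    axis: np.ndarray | None = None,
) -> OrientationSet:
    """Viewing directions area-uniform within ``half_angle`` of ``axis``.

    ``axis`` defaults to the beam axis +z; any other unit vector is realized
    by left-rotating the +z cone, which preserves the uniform psi measure.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 < half_angle <= 90.0):
        raise ValueError("half_angle must be in (0, 90]")
    rng = np.random.default_rng(seed)
    angles = _cone_angles(rng, n, half_angle)
    if axis is not None:
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        if axis[2] < 1.0 - 1e-12:
            z = np.array([0.0, 0.0, 1.0])
            pivot = np.cross(z, axis)
            if np.linalg.norm(pivot) < 1e-12:  # antipodal axis
                pivot = np.array([1.0, 0.0, 0.0])
            ang = np.rad2deg(np.arccos(np.clip(axis[2], -1.0, 1.0)))
            Q = rotation_about_axis(pivot, ang)
            angles = eulers_from_rotations(Q @ rotations_from_eulers(angles))
    return OrientationSet(angles, label=f"cone({half_angle}deg)", seed=seed)


def sample_two_orthogonal_cones(n: int, half_angle: float, seed: int) -> OrientationSet:
    """Population split 50/50 between identical cones about +z and +x."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 < half_angle <= 90.0):
        raise ValueError("half_angle must be in (0, 90]")
    n_z = n // 2
    n_x = n - n_z
    rng = np.random.default_rng(seed)
    a_z = _cone_angles(rng, n_z, half_angle) if n_z else np.empty((0, 3))
    a_x = _cone_angles(rng, n_x, half_angle)
    Q = rotation_about_axis("y", 90.0)  # takes +z to +x
    a_x = eulers_from_rotations(Q @ rotations_from_eulers(a_x))
    angles = np.concatenate([a_z, a_x], axis=0)
    return OrientationSet(angles, label=f"two_cones({half_angle}deg)", seed=seed)


def add_sprinkles(base: OrientationSet, fraction: float, seed: int) -> OrientationSet:
    """Replace a fraction of ``base`` (rounded to nearest) with uniform draws.

    Replacement indices are chosen uniformly without replacement; all other
    items are untouched, so the population size is conserved.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    n = len(base)
    k = int(round(fraction * n))
    angles = base.angles.copy()
    if k > 0:
        rng = np.random.default_rng(seed)
        idx = rng.choice(n, size=k, replace=False)
        angles[idx] = _uniform_angles(rng, k)
    label = f"{base.label}+sprinkles({fraction:.2f})" if base.label else "sprinkled"
    return OrientationSet(angles, base.weights.copy(), label=label, seed=seed)


def sample_side_like(
    n: int, seed: int | None = None, deterministic: bool = False
) -> OrientationSet:
    """Pure side views: every viewing direction on the equator (tilt = 90).

    Deterministic mode spaces rot evenly over [-180, 180) and staggers psi by
    a golden-ratio sequence (deterministic, quasi-uniform); stochastic mode
    draws rot and psi uniformly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if deterministic:
        rot = -180.0 + 360.0 * np.arange(n) / n
        psi = ((np.arange(n) * 360.0 * _GOLDEN) % 360.0) - 180.0
    else:
        rng = np.random.default_rng(seed)
        rot = rng.uniform(-180.0, 180.0, n)
        psi = rng.uniform(-180.0, 180.0, n)
    tilt = np.full(n, 90.0)
    angles = np.stack([rot, tilt, psi], axis=1)
    return OrientationSet(angles, label="side_like", seed=seed)


def sample_top_like(n: int, jitter_half_angle: float, seed: int) -> OrientationSet:
    """Tight cone about the beam axis (preferred-orientation pathology).

    ``jitter_half_angle`` of 0 puts every direction exactly on +z (psi still
    uniform); otherwise equivalent to :func:`sample_cone` about +z.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= jitter_half_angle <= 10.0):
        raise ValueError("jitter_half_angle must be in [0, 10]")
    if jitter_half_angle == 0.0:
        rng = np.random.default_rng(seed)
        angles = np.stack(
            [np.zeros(n), np.zeros(n), rng.uniform(-180.0, 180.0, n)], axis=1
        )
        return OrientationSet(angles, label="top_like(0deg)", seed=seed)
    out = sample_cone(n, jitter_half_angle, seed)
    return OrientationSet(out.angles, label=f"top_like({jitter_half_angle}deg)",
                          seed=seed)


def generate(spec: DistributionSpec) -> OrientationSet:
    """Realize a :class:`DistributionSpec` (sprinkles applied last)."""
    if spec.scenario == "uniform":
        out = sample_uniform(spec.n, spec.seed)
    elif spec.scenario == "single_cone":
        out = sample_cone(spec.n, spec.cone_half_angle, spec.seed)
    elif spec.scenario == "two_orthogonal_cones":
        out = sample_two_orthogonal_cones(spec.n, spec.cone_half_angle, spec.seed)
    elif spec.scenario == "side_like":
        out = sample_side_like(spec.n, seed=spec.seed)
    elif spec.scenario == "top_like":
        out = sample_top_like(spec.n, min(spec.cone_half_angle, 10.0), spec.seed)
    else:  # pragma: no cover - guarded by DistributionSpec
        raise ValueError(spec.scenario)
    if spec.sprinkle_fraction > 0:
        out = add_sprinkles(out, spec.sprinkle_fraction, seed=spec.seed + 1_000_003)
    return out
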