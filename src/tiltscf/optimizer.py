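"""Tilt sweeps, minimal-tilt recommendation, and scenario heat-map grids.

The planning question: given an orientation distribution (synthetic scenario
or experimental angles), what is the smallest stage tilt whose transformed
distribution is "fully sampled", i.e. reaches the side-view SCF baseline of
0.81 (= 8/pi^2)?  Scans simulate the stage-tilt transform over a grid of
angles (default 0 plus 10..60 in 10-degree steps) and average the SCF* over
replicate seeds, since values near threshold are Monte-Carlo noisy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .distributions import DistributionSpec, generate
from .geometry import OrientationSet
from .sampling import build_shell_grid, scf_of_orientations
from .tilt import TiltSpec, apply_stage_tilt, effective_ice_factor

__all__ = [
    "FULLY_SAMPLED_SCF",
    "OptimizerConfig",
    "TiltScanResult",
    "HeatmapGrid",
    "TiltRecommendation",
    "scan_tilts",
    "min_tilt_for_threshold",
    "fig_grid",
    "recommend_tilt",
]

#: side-view SCF, the threshold for a fully sampled reconstruction (8/pi^2)
FULLY_SAMPLED_SCF = 0.81

DEFAULT_TILT_GRID = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0)


@dataclass(frozen=True)
class OptimizerConfig:
    tilt_grid: tuple[float, ...] = DEFAULT_TILT_GRID
    scf_threshold: float = FULLY_SAMPLED_SCF
    replicates: int = 5
    base_seed: int = 0
    resolution: float = 1.5
    circle_samples: int = 1000
    zero_handling: str = "floor_one"
    tilt_axis: str = "y"

    def __post_init__(self) -> None:
        grid = tuple(float(t) for t in self.tilt_grid)
        if list(grid) != sorted(grid):
            raise ValueError("tilt_grid must be sorted ascending")
        if grid and not (0.0 <= grid[0] and grid[-1] < 90.0):
            raise ValueError("tilt_grid must lie within [0, 90)")
        if not (0.0 < self.scf_threshold <= 1.0):
            raise ValueError("scf_threshold must be in (0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        object.__setattr__(self, "tilt_grid", grid)


@dataclass
class TiltScanResult:
    """SCF* as a function of stage tilt, averaged over replicates."""

    tilts: np.ndarray             # (T,)
    scf_star: np.ndarray          # (T, R) per-replicate values
    spec: DistributionSpec | None
    config: OptimizerConfig

    @property
    def mean_scf_star(self) -> np.ndarray:
        return self.scf_star.mean(axis=1)

    @property
    def stderr_scf_star(self) -> np.ndarray:
        r = self.scf_star.shape[1]
        if r < 2:
            return np.zeros(len(self.tilts))
        return self.scf_star.std(axis=1, ddof=1) / np.sqrt(r)

    def as_table(self) -> str:
        lines = ["tilt_deg\tmean_scf_star\tstderr\tice_factor"]
        for t, m, e in zip(self.tilts, self.mean_scf_star, self.stderr_scf_star):
            lines.append(f"{t:g}\t{m:.4f}\t{e:.4f}\t{effective_ice_factor(t):.4f}")
        return "\n".join(lines) + "\n"


def _replicate_seed(base_seed: int, replicate: int) -> int:
    # spawn independent, reproducible streams per replicate
    return int(np.random.SeedSequence([base_seed, replicate]).generate_state(1)[0])


def _scan_set(
    orients: OrientationSet, config: OptimizerConfig, grid
) -> np.ndarray:
    out = np.empty(len(config.tilt_grid))
    for j, alpha in enumerate(config.tilt_grid):
        tilted = (orients if alpha == 0.0 else
                  apply_stage_tilt(orients, TiltSpec(alpha, config.tilt_axis)))
        res = scf_of_orientations(
            tilted, resolution=config.resolution,
            circle_samples=config.circle_samples,
            zero_handling=config.zero_handling, grid=grid,
        )
        out[j] = res.scf_star if config.zero_handling == "floor_one" else res.scf
    return out


def scan_tilts(
    spec: DistributionSpec, config: OptimizerConfig = OptimizerConfig()
) -> TiltScanResult:
    """Mean SCF* per tilt for a generated scenario, over replicate seeds."""
    grid = build_shell_grid(config.resolution)
    values = np.empty((len(config.tilt_grid), config.replicates))
    for r in range(config.replicates):
        seed = _replicate_seed(config.base_seed, r)
        orients = generate(replace(spec, seed=seed))
        values[:, r] = _scan_set(orients, config, grid)
    return TiltScanResult(
        tilts=np.asarray(config.tilt_grid, dtype=float),
        scf_star=values, spec=spec, config=config,
    )


def min_tilt_for_threshold(
    scan: TiltScanResult, threshold: float | None = None
) -> float | None:
    """Smallest grid tilt whose mean SCF* meets the threshold, else None."""
    if len(scan.tilts) == 0:
        raise ValueError("empty tilt scan")
    th = scan.config.scf_threshold if threshold is None else threshold
    means = scan.mean_scf_star
    qualifying = np.nonzero(means >= th)[0]
    if len(qualifying) == 0:
        return None
    return float(scan.tilts[qualifying[0]])


@dataclass
class HeatmapGrid:
    """Mean SCF* over (cone half-angle, sprinkle fraction, tilt) cells."""

    scenario: str
    cone_half_angles: np.ndarray
    sprinkle_fractions: np.ndarray
    tilts: np.ndarray
    values: np.ndarray  # (len(cones), len(sprinkles), len(tilts))
    config: OptimizerConfig

    def as_table(self) -> str:
        lines = ["cone_half_angle\tsprinkle_fraction\ttilt_deg\tmean_scf_star"]
        for i, c in enumerate(self.cone_half_angles):
            for j, s in enumerate(self.sprinkle_fractions):
                for k, t in enumerate(self.tilts):
                    lines.append(f"{c:g}\t{s:g}\t{t:g}\t{self.values[i, j, k]:.4f}")
        return "\n".join(lines) + "\n"

    def plot(self, path) -> None:
        """Render one panel per tilt angle (cone angle x sprinkle fraction)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        nt = len(self.tilts)
        fig, axes = plt.subplots(1, nt, figsize=(3 * nt, 3), squeeze=False)
        for k, (ax, t) in enumerate(zip(axes[0], self.tilts)):
            im = ax.imshow(
                self.values[:, :, k], origin="lower", vmin=0.0, vmax=1.0,
                cmap="RdYlBu", aspect="auto",
                extent=(
                    float(self.sprinkle_fractions[0]) * 100,
                    float(self.sprinkle_fractions[-1]) * 100,
                    float(self.cone_half_angles[0]),
                    float(self.cone_half_angles[-1]),
                ),
            )
            ax.set_title(f"tilt {t:g}\N{DEGREE SIGN}")
            ax.set_xlabel("sprinkles (%)")
            if k == 0:
                ax.set_ylabel("cone half-angle (deg)")
        fig.colorbar(im, ax=axes[0, -1], label="SCF*")
        fig.suptitle(self.scenario)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def fig_grid(
    scenario: str,
    cone_half_angles,
    sprinkle_fractions,
    config: OptimizerConfig = OptimizerConfig(),
    n: int = 10_000,
) -> HeatmapGrid:
    """Full Cartesian decision grid for a cone scenario.

    ``scenario`` is 'single_cone' or 'two_orthogonal_cones'.
    """
    if scenario not in ("single_cone", "two_orthogonal_cones"):
        raise ValueError("scenario must be 'single_cone' or 'two_orthogonal_cones'")
    cones = np.asarray(list(cone_half_angles), dtype=float)
    fracs = np.asarray(list(sprinkle_fractions), dtype=float)
    if len(cones) == 0 or len(fracs) == 0:
        raise ValueError("axes must be nonempty")
    values = np.empty((len(cones), len(fracs), len(config.tilt_grid)))
    for i, cone in enumerate(cones):
        for j, frac in enumerate(fracs):
            spec = DistributionSpec(
                scenario=scenario, n=n, cone_half_angle=float(cone),
                sprinkle_fraction=float(frac), seed=config.base_seed,
            )
            scan = scan_tilts(spec, config)
            values[i, j, :] = scan.mean_scf_star
    return HeatmapGrid(
        scenario=scenario, cone_half_angles=cones, sprinkle_fractions=fracs,
        tilts=np.asarray(config.tilt_grid, dtype=float), values=values,
        config=config,
    )


CAVEAT = (
    "Predictions from experimentally refined angles can be optimistic: "
    "false-positive orientation assignments inflate the apparent coverage, "
    "so consider applying a slightly higher tilt than recommended."
)


@dataclass
class TiltRecommendation:
    recommended_tilt: float | None
    tilts: np.ndarray
    scf_star: np.ndarray
    ice_factors: np.ndarray
    threshold: float
    caveat: str = CAVEAT

    def as_table(self) -> str:
        lines = ["tilt_deg\tscf_star\tice_factor"]
        for t, v, f in zip(self.tilts, self.scf_star, self.ice_factors):
            lines.append(f"{t:g}\t{v:.4f}\t{f:.4f}")
        rec = "none_reachable" if self.recommended_tilt is None else (
            f"{self.recommended_tilt:g}")
        lines.append(f"# recommended_tilt={rec} threshold={self.threshold:g}")
        lines.append(f"# caveat: {self.caveat}")
        return "\n".join(lines) + "\n"


def recommend_tilt(
    orients: OrientationSet,
    config: OptimizerConfig = OptimizerConfig(),
    fine: bool = False,
) -> TiltRecommendation:
    """Minimal qualifying tilt for a *given* orientation set.

    The tilt transform is applied directly to the set (no re-generation, so
    no replicates).  With ``fine=True`` the answer is refined to 1-degree
    steps between the last failing and first qualifying coarse tilts.
    """
    grid = build_shell_grid(config.resolution)
    tilts = np.asarray(config.tilt_grid, dtype=float)
    values = _scan_set(orients, config, grid)
    th = config.scf_threshold
    qual = np.nonzero(values >= th)[0]
    rec = float(tilts[qual[0]]) if len(qual) else None
    if fine and rec is not None and qual[0] > 0:
        lo = tilts[qual[0] - 1]
        fine_tilts = np.arange(lo + 1.0, rec, 1.0)
        if len(fine_tilts):
            fine_cfg = replace(config, tilt_grid=tuple(fine_tilts))
            fine_vals = _scan_set(orients, fine_cfg, grid)
            fq = np.nonzero(fine_vals >= th)[0]
            if len(fq):
                rec = float(fine_tilts[fq[0]])
            tilts = np.concatenate([tilts, fine_tilts])
            values = np.concatenate([values, fine_vals])
            order = np.argsort(tilts)
            tilts, values = tilts[order], values[order]
    return TiltRecommendation(
        recommended_tilt=rec,
        tilts=tilts,
        scf_star=values,
        ice_factors=np.array([effective_ice_factor(t) for t in tilts]),
        threshold=th,
    )
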