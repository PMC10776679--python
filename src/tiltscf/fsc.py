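"""Global and directional (conical / 3D) FSC evaluation of half-map pairs.

Fourier shell correlation is the normalized cross-correlation of two
volumes' discrete Fourier transforms over spherical frequency shells at
integer voxel radii (nearest-integer assignment).  Directional resolution is
measured by restricting the correlation sums to the antipodal union of cones
about a lattice of directions; stacking the per-direction curves over
Fourier space yields the 3D FSC volume.  Resolution is read at the first
downward crossing of a threshold (default 0.143), linearly interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np

__all__ = [
    "FSC_THRESHOLD",
    "VolumeGrid",
    "FSCCurve",
    "ConicalFSCSet",
    "ResolutionEstimate",
    "global_fsc",
    "resolution_at_threshold",
    "conical_fsc",
    "assemble_3dfsc",
    "make_synthetic_halfmaps",
    "fibonacci_hemisphere",
]

#: half-map FSC resolution cut-off criterion
FSC_THRESHOLD = 0.143


@dataclass
class VolumeGrid:
    """Cubic 3D density grid with voxel size in Angstrom."""

    data: np.ndarray
    voxel_size: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or len(set(self.data.shape)) != 1:
            raise ValueError(f"volume must be cubic, got shape {self.data.shape}")
        if self.data.shape[0] % 2 != 0:
            raise ValueError("side length must be even")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")
        if self.mask is not None and self.mask.shape != self.data.shape:
            raise ValueError("mask shape must match volume shape")

    @property
    def side(self) -> int:
        return self.data.shape[0]

    @property
    def nyquist(self) -> float:
        """Nyquist frequency in 1/Angstrom."""
        return 0.5 / self.voxel_size


@dataclass
class FSCCurve:
    frequencies: np.ndarray   # (K,) 1/Angstrom, strictly increasing
    correlations: np.ndarray  # (K,) in [-1, 1]
    shell_counts: np.ndarray  # (K,) Fourier voxels per shell
    voxel_size: float

    def as_table(self) -> str:
        lines = ["frequency_invA\tfsc\tn_voxels"]
        for f, c, n in zip(self.frequencies, self.correlations, self.shell_counts):
            lines.append(f"{f:.6f}\t{c:.6f}\t{int(n)}")
        return "\n".join(lines) + "\n"


class ResolutionEstimate(NamedTuple):
    resolution: float  # Angstrom
    crossed: bool      # False when the curve never drops below threshold


def _shell_indices(side: int) -> tuple[np.ndarray, int]:
    """Nearest-integer radial shell index for every Fourier voxel."""
    k = np.fft.fftfreq(side) * side
    kx, ky, kz = np.meshgrid(k, k, k, indexing="ij")
    r = np.sqrt(kx**2 + ky**2 + kz**2)
    shell = np.rint(r).astype(np.intp)
    return shell, side // 2


def _check_pair(v1: VolumeGrid, v2: VolumeGrid, mask: np.ndarray | None) -> None:
    if v1.data.shape != v2.data.shape:
        raise ValueError(
            f"volume shapes differ: {v1.data.shape} vs {v2.data.shape}")
    if not np.isclose(v1.voxel_size, v2.voxel_size, rtol=1e-4):
        raise ValueError(
            f"voxel sizes differ: {v1.voxel_size} vs {v2.voxel_size}")
    if mask is not None and mask.shape != v1.data.shape:
        raise ValueError("mask shape must match volume shape")


def _fsc_sums(F1, F2, shell, n_shells, select=None):
    """Per-shell (cross, power1, power2, count) sums, optionally masked."""
    cross = (F1 * np.conj(F2)).real
    p1 = np.abs(F1) ** 2
    p2 = np.abs(F2) ** 2
    sh = shell.ravel()
    if select is not None:
        keep = select.ravel()
        sh = sh[keep]
        cross, p1, p2 = (a.ravel()[keep] for a in (cross, p1, p2))
    else:
        cross, p1, p2 = (a.ravel() for a in (cross, p1, p2))
    m = n_shells + 1
    num = np.bincount(sh, weights=cross, minlength=m)[:m]
    d1 = np.bincount(sh, weights=p1, minlength=m)[:m]
    d2 = np.bincount(sh, weights=p2, minlength=m)[:m]
    cnt = np.bincount(sh, minlength=m)[:m]
    return num, d1, d2, cnt


def _curve_from_sums(num, d1, d2, cnt, side, voxel_size) -> FSCCurve:
    shells = np.arange(1, side // 2 + 1)
    denom = np.sqrt(d1[shells] * d2[shells])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, num[shells] / denom, 0.0)
    return FSCCurve(
        frequencies=shells / (side * voxel_size),
        correlations=corr,
        shell_counts=cnt[shells],
        voxel_size=voxel_size,
    )


def global_fsc(
    v1: VolumeGrid, v2: VolumeGrid, mask: np.ndarray | None = None
) -> FSCCurve:
    """FSC over integer-radius shells (shell 1 .. Nyquist)."""
    _check_pair(v1, v2, mask)
    d1 = v1.data * mask if mask is not None else v1.data
    d2 = v2.data * mask if mask is not None else v2.data
    F1 = np.fft.fftn(d1)
    F2 = np.fft.fftn(d2)
    shell, n_shells = _shell_indices(v1.side)
    shell = np.minimum(shell, n_shells)  # corner voxels folded into Nyquist
    sums = _fsc_sums(F1, F2, shell, n_shells)
    return _curve_from_sums(*sums, v1.side, v1.voxel_size)


def resolution_at_threshold(
    curve: FSCCurve, threshold: float = FSC_THRESHOLD
) -> ResolutionEstimate:
    """Resolution at the first downward threshold crossing (interpolated).

    Returns the Nyquist-limited value (2 x voxel size) flagged
    ``crossed=False`` when the curve never drops below the threshold.
    Shells with no Fourier voxels (possible for narrow cones at low
    frequency) carry no information and are skipped.
    """
    keep = curve.shell_counts > 0
    f = curve.frequencies[keep]
    c = curve.correlations[keep]
    if len(f) == 0:
        return ResolutionEstimate(resolution=2.0 * curve.voxel_size, crossed=False)
    below = np.nonzero(c < threshold)[0]
    if len(below) == 0:
        return ResolutionEstimate(resolution=2.0 * curve.voxel_size, crossed=False)
    i = below[0]
    if i == 0:
        return ResolutionEstimate(resolution=float(1.0 / f[0]), crossed=True)
    # linear interpolation between the last shell above and the first below
    f_lo, f_hi = f[i - 1], f[i]
    c_lo, c_hi = c[i - 1], c[i]
    frac = (c_lo - threshold) / (c_lo - c_hi)
    f_cross = f_lo + frac * (f_hi - f_lo)
    return ResolutionEstimate(resolution=float(1.0 / f_cross), crossed=True)


def fibonacci_hemisphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the upper hemisphere (z >= 0)."""
    i = np.arange(n)
    z = (i + 0.5) / n                      # area-uniform in z on (0, 1)
    phi = 2.0 * np.pi * ((i * (np.sqrt(5.0) - 1.0) / 2.0) % 1.0)
    s = np.sqrt(1.0 - z**2)
    return np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)


@dataclass
class ConicalFSCSet:
    directions: np.ndarray          # (D, 3) unit vectors, upper hemisphere
    curves: list[FSCCurve]
    cone_half_angle: float          # degrees
    voxel_size: float

    def resolutions(self, threshold: float = FSC_THRESHOLD) -> np.ndarray:
        return np.array(
            [resolution_at_threshold(c, threshold).resolution for c in self.curves]
        )


def conical_fsc(
    v1: VolumeGrid,
    v2: VolumeGrid,
    cone_half_angle: float = 20.0,
    n_directions: int = 192,
    mask: np.ndarray | None = None,
) -> ConicalFSCSet:
    """Per-direction FSC restricted to antipodal cone pairs about a lattice.

    A Fourier voxel contributes to direction d when the angle between its
    frequency vector and +/-d is at most ``cone_half_angle``; the zero
    frequency contributes everywhere.  With a 90-degree cone every curve
    equals the global FSC exactly.
    """
    if not (0.0 < cone_half_angle <= 90.0):
        raise ValueError("cone_half_angle must be in (0, 90]")
    if n_directions < 1:
        raise ValueError("n_directions must be >= 1")
    _check_pair(v1, v2, mask)
    d1 = v1.data * mask if mask is not None else v1.data
    d2 = v2.data * mask if mask is not None else v2.data
    F1 = np.fft.fftn(d1)
    F2 = np.fft.fftn(d2)
    side = v1.side
    shell, n_shells = _shell_indices(side)
    shell = np.minimum(shell, n_shells)
    k = np.fft.fftfreq(side) * side
    kx, ky, kz = np.meshgrid(k, k, k, indexing="ij")
    r = np.sqrt(kx**2 + ky**2 + kz**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        khat = np.stack([np.where(r > 0, a / r, 0.0) for a in (kx, ky, kz)])
    # a 90-degree cone must select everything (cos(90) is not exactly 0)
    cos_cone = -1.0 if cone_half_angle >= 90.0 else np.cos(
        np.deg2rad(cone_half_angle))
    dirs = fibonacci_hemisphere(n_directions)
    curves = []
    for d in dirs:
        proj = np.abs(khat[0] * d[0] + khat[1] * d[1] + khat[2] * d[2])
        select = (proj >= cos_cone) | (r == 0)
        sums = _fsc_sums(F1, F2, shell, n_shells, select=select)
        curves.append(_curve_from_sums(*sums, side, v1.voxel_size))
    return ConicalFSCSet(
        directions=dirs, curves=curves,
        cone_half_angle=cone_half_angle, voxel_size=v1.voxel_size,
    )


def assemble_3dfsc(cset: ConicalFSCSet, side: int) -> VolumeGrid:
    """3D FSC volume: each Fourier voxel takes its nearest direction's curve.

    Returned in fftshifted layout (origin at the center voxel, value 1), so
    central slices are directly renderable.
    """
    if len(cset.curves) == 0:
        raise ValueError("empty conical FSC set")
    shell, n_shells = _shell_indices(side)
    shell = np.minimum(shell, n_shells)
    k = np.fft.fftfreq(side) * side
    kx, ky, kz = np.meshgrid(k, k, k, indexing="ij")
    r = np.sqrt(kx**2 + ky**2 + kz**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        khat = np.stack(
            [np.where(r > 0, a / r, 0.0) for a in (kx, ky, kz)], axis=-1)
    # nearest direction by |cos| (antipodes identified)
    dots = np.abs(khat.reshape(-1, 3) @ cset.directions.T)
    nearest = np.argmax(dots, axis=1).reshape(shell.shape)
    table = np.zeros((len(cset.curves), n_shells + 1))
    for i, curve in enumerate(cset.curves):
        table[i, 0] = 1.0  # zero frequency
        table[i, 1:] = curve.correlations
    vol = table[nearest, shell]
    return VolumeGrid(np.fft.fftshift(vol), cset.voxel_size)


def make_synthetic_halfmaps(
    side: int,
    voxel_size: float,
    snr_profile: float | Callable[[np.ndarray], np.ndarray] = 1.0,
    anisotropy_axis: np.ndarray | None = None,
    anisotropy_cutoff: float = 0.5,
    anisotropy_cone: float = 30.0,
    seed: int = 0,
) -> tuple[VolumeGrid, VolumeGrid]:
    """Half-map pair with a common signal and prescribed per-shell SNR.

    The signal and both noise realizations are white fields shaped in
    Fourier space by radial factors, so the expected FSC at a shell with SNR
    s is s/(s+1).  With ``anisotropy_axis`` set, the signal is zeroed beyond
    ``anisotropy_cutoff`` (fraction of Nyquist) inside the antipodal cone of
    ``anisotropy_cone`` degrees about the axis, degrading resolution along
    that direction only.
    """
    if side < 32 or side % 2:
        raise ValueError("side must be even and >= 32")
    rng = np.random.default_rng(seed)
    shell, n_shells = _shell_indices(side)
    shell = np.minimum(shell, n_shells)
    radii = np.arange(n_shells + 1, dtype=float)
    if callable(snr_profile):
        snr = np.asarray(snr_profile(radii), dtype=float)
    else:
        snr = np.full(n_shells + 1, float(snr_profile))
    snr = np.clip(snr, 0.0, None)

    amp = np.sqrt(snr)[shell]  # signal/noise amplitude ratio per voxel
    Fsig = np.fft.fftn(rng.standard_normal((side, side, side))) * amp
    if anisotropy_axis is not None:
        axis = np.asarray(anisotropy_axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        k = np.fft.fftfreq(side) * side
        kx, ky, kz = np.meshgrid(k, k, k, indexing="ij")
        r = np.sqrt(kx**2 + ky**2 + kz**2)
        with np.errstate(invalid="ignore", divide="ignore"):
            proj = np.abs(kx * axis[0] + ky * axis[1] + kz * axis[2])
            proj = np.where(r > 0, proj / r, 0.0)
        in_cone = proj >= np.cos(np.deg2rad(anisotropy_cone))
        Fsig = np.where(in_cone & (r > anisotropy_cutoff * (side // 2)), 0.0, Fsig)
    halves = []
    for _ in range(2):
        noise = np.fft.fftn(rng.standard_normal((side, side, side)))
        halves.append(VolumeGrid(np.fft.ifftn(Fsig + noise).real, voxel_size))
    return halves[0], halves[1]
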