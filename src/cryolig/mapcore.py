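"""Grid statistics, threshold selection, and Fourier shell correlation.

Two threshold rules are supported, mirroring how cryo-EM maps are displayed
in practice: an SD-multiple rule (level = mean + k·SD, e.g. the 7×SD level
used to envelope a simulated ligand map) and an enclosed-volume rule (the
level at which the isosurface encloses a stated physical volume, e.g.
153,000 Å³ for a ~150 kDa detergent-solubilized transporter).

Thresholding is closed: a voxel counts when value >= level. The
enclosed-volume level is the m-th largest voxel value with
m = round(target / voxel_volume); ties at the level are all included, so
the realized volume can exceed the target by the tied voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .grid import DensityMap

__all__ = [
    "ThresholdResult",
    "FscCurve",
    "ResolutionResult",
    "map_stats",
    "sd_threshold",
    "enclosed_volume",
    "threshold_for_volume",
    "fsc_curve",
    "resolution_at",
]


@dataclass(frozen=True)
class ThresholdResult:
    level: float
    enclosed_volume: float
    voxel_count: int


@dataclass
class FscCurve:
    """Radial FSC between two half-maps.

    shell_center: spatial frequency in Å⁻¹, ascending; one shell per integer
    Fourier-voxel radius up to Nyquist. Empty shells are omitted and their
    radii listed in ``empty_shells``.
    """

    shell_center: np.ndarray
    fsc: np.ndarray
    n_voxels: np.ndarray
    empty_shells: list[int]

    def to_tsv(self) -> str:
        lines = ["shell_center_invA\tfsc\tn_voxels"]
        for s, f, n in zip(self.shell_center, self.fsc, self.n_voxels):
            lines.append(f"{s:.6f}\t{f:.6f}\t{int(n)}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class ResolutionResult:
    resolution: float  # Å
    nyquist_limited: bool


def map_stats(dmap: DensityMap) -> tuple[float, float]:
    """Arithmetic mean and population SD over all voxels."""
    v = dmap.values
    return float(v.mean()), float(v.std())


def sd_threshold(dmap: DensityMap, k: float) -> float:
    """Display level mean + k·SD (k = 7 envelopes a simulated ligand map)."""
    if not np.isfinite(k):
        raise DomainError("SD multiplier must be finite")
    mean, sd = map_stats(dmap)
    return mean + k * sd


def enclosed_volume(dmap: DensityMap, level: float) -> ThresholdResult:
    """Voxel count and physical volume of {value >= level}."""
    if not np.isfinite(level):
        raise DomainError("level must be finite")
    count = int(np.count_nonzero(dmap.values >= level))
    return ThresholdResult(float(level), count * dmap.voxel_volume, count)


def threshold_for_volume(dmap: DensityMap, target_volume: float) -> ThresholdResult:
    """Level at which the isosurface encloses ``target_volume`` Å³.

    The level is the m-th largest voxel value, m = round(target/voxel_volume);
    the returned volume is recomputed at that level (ties included).
    """
    if not (0 < target_volume <= dmap.total_volume):
        raise DomainError(
            f"target_volume {target_volume} outside (0, {dmap.total_volume}]"
        )
    m = int(round(target_volume / dmap.voxel_volume))
    m = max(1, min(m, dmap.values.size))
    flat = dmap.values.ravel()
    # m-th largest value via partial sort
    level = float(np.partition(flat, flat.size - m)[flat.size - m])
    return enclosed_volume(dmap, level)


def fsc_curve(half1: DensityMap, half2: DensityMap, n_shells: int | None = None) -> FscCurve:
    """Fourier shell correlation between two half-maps.

    FSC(s) = Re(Σ F1·conj(F2)) / sqrt(Σ|F1|² · Σ|F2|²) over the shell of
    Fourier voxels with rounded integer radius s; shells are one
    reciprocal-voxel wide and run up to Nyquist (radius N/2 of the smallest
    axis). No mask or sharpening is applied.
    """
    if half1.dims != half2.dims:
        raise DomainError(f"dim mismatch {half1.dims} vs {half2.dims}")
    if not np.allclose(half1.voxel_size, half2.voxel_size):
        raise DomainError("voxel_size mismatch between half maps")

    f1 = np.fft.fftn(half1.values)
    f2 = np.fft.fftn(half2.values)

    dims = half1.dims
    # integer frequency index per axis, normalized so radius is in units of
    # the largest-axis frequency step (exact integers for cubic maps)
    nmax = max(dims)
    grids = np.meshgrid(
        *[np.fft.fftfreq(n) * nmax for n in dims], indexing="ij"
    )
    radius = np.rint(np.sqrt(sum(g * g for g in grids))).astype(int)

    max_shell = n_shells if n_shells is not None else min(dims) // 2
    max_shell = min(max_shell, int(radius.max()))
    dq = 1.0 / (nmax * float(np.mean(half1.voxel_size)))  # Å⁻¹ per shell

    cross = np.real(f1 * np.conj(f2))
    p1 = np.abs(f1) ** 2
    p2 = np.abs(f2) ** 2

    nbins = max_shell + 1
    flat_r = radius.ravel()
    sel = flat_r <= max_shell
    counts = np.bincount(flat_r[sel], minlength=nbins)
    num = np.bincount(flat_r[sel], weights=cross.ravel()[sel], minlength=nbins)
    d1 = np.bincount(flat_r[sel], weights=p1.ravel()[sel], minlength=nbins)
    d2 = np.bincount(flat_r[sel], weights=p2.ravel()[sel], minlength=nbins)

    centers, vals, nvox, empty = [], [], [], []
    for s in range(1, nbins):  # shell 0 is the DC term alone; start at 1
        if counts[s] == 0:
            empty.append(s)
            continue
        denom = np.sqrt(d1[s] * d2[s])
        fsc = num[s] / denom if denom > 0 else 0.0
        centers.append(s * dq)
        vals.append(float(np.clip(fsc, -1.0, 1.0)))
        nvox.append(int(counts[s]))
    return FscCurve(np.array(centers), np.array(vals), np.array(nvox), empty)


def resolution_at(curve: FscCurve, criterion: float = 0.143) -> ResolutionResult:
    """Resolution at the first downward crossing of ``criterion``.

    Linear interpolation in frequency between the bracketing shells; if the
    curve never falls below the criterion the result is the Nyquist shell's
    resolution with ``nyquist_limited=True``.
    """
    if not (0 < criterion < 1):
        raise DomainError(f"criterion must be in (0, 1), got {criterion}")
    if len(curve.fsc) == 0:
        raise DomainError("empty FSC curve")
    f = curve.fsc
    q = curve.shell_center
    for i in range(len(f)):
        if f[i] < criterion:
            if i == 0:
                return ResolutionResult(1.0 / q[0], False)
            # interpolate frequency of the crossing between shells i-1 and i
            f0, f1 = f[i - 1], f[i]
            t = (f0 - criterion) / (f0 - f1)
            qc = q[i - 1] + t * (q[i] - q[i - 1])
            return ResolutionResult(float(1.0 / qc), False)
    return ResolutionResult(float(1.0 / q[-1]), True)
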