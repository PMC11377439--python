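"""Coherent pixel binning, interferogram synthesis and the phase-memory statistic.

Detected photons are summed coherently per pixel through the complex
accumulator ``A = sum sqrt(W) exp(i Psi)``: the coherent intensity is
``I = |A|^2`` (algebraically identical to the pairwise interference sum)
and the speckle phase is ``psi = arg(A)``.  The incoherent weight sum
``sum W`` is kept alongside: it is the radiometric estimator that converges
to the physical intensity for both ballistic and diffuse light, whereas the
coherent estimator is meaningful for speckle statistics (see
docs/methods.md for the distinction).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .beams import BeamSpec, wrap_phase

__all__ = [
    "PixelGrid",
    "FieldMap",
    "ImagePair",
    "AnnulusSpec",
    "PhaseMemoryResult",
    "accumulate_image",
    "interferogram",
    "phase_memory",
    "write_image_pair",
    "read_image_pair",
]


@dataclass(frozen=True)
class PixelGrid:
    """Square-pixel detector grid.

    Arrays are row-major ``(ny, nx)`` with x rightward along columns and y
    upward along rows; ``origin`` is the centre of pixel (0, 0) in mm.
    """

    nx: int
    ny: int
    pitch: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.nx < 1 or self.ny < 1:
            raise ValueError("pixel counts must be >= 1")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")

    @classmethod
    def centered(cls, n: int, pitch: float) -> "PixelGrid":
        """n x n grid with the beam axis on the centre of pixel (n//2, n//2).

        For even n the axis sits on a pixel centre (FFT-shift convention),
        which keeps the pixel coordinates aligned with discrete Fourier
        transforms in the sorter and interferometry paths.
        """
        half = n // 2
        return cls(nx=n, ny=n, pitch=pitch, origin=(-half * pitch, -half * pitch))

    @property
    def x_centers(self) -> np.ndarray:
        return self.origin[0] + self.pitch * np.arange(self.nx)

    @property
    def y_centers(self) -> np.ndarray:
        return self.origin[1] + self.pitch * np.arange(self.ny)

    def meshgrid(self):
        return np.meshgrid(self.x_centers, self.y_centers)

    def index_of(self, x, y):
        """Pixel indices (iy, ix) of points; may fall outside [0, n)."""
        ix = np.floor((np.asarray(x) - self.origin[0]) / self.pitch + 0.5).astype(np.int64)
        iy = np.floor((np.asarray(y) - self.origin[1]) / self.pitch + 0.5).astype(np.int64)
        return iy, ix

    def to_dict(self):
        return {"nx": self.nx, "ny": self.ny, "pitch_mm": self.pitch,
                "origin_mm": list(self.origin)}


@dataclass
class FieldMap:
    """Complex field sampled on a pixel grid."""

    data: np.ndarray
    grid: PixelGrid

    @property
    def intensity(self):
        return np.abs(self.data) ** 2

    @property
    def phase(self):
        return np.angle(self.data)

    @classmethod
    def from_beam(cls, beam: BeamSpec, grid: PixelGrid, z: float = 0.0) -> "FieldMap":
        X, Y = grid.meshgrid()
        rho = np.hypot(X, Y)
        phi = np.arctan2(Y, X)
        from .beams import lg_field

        return cls(data=lg_field(beam, (rho, phi, np.full_like(rho, float(z)))), grid=grid)


@dataclass
class ImagePair:
    """Paired intensity and wrapped-phase speckle images with grid metadata.

    ``intensity`` is the coherent pixel sum; ``weight`` the incoherent sum
    of photon weights; ``phase`` is NaN wherever no photon landed (phase is
    undefined there, not zero); ``occupancy`` counts photons per pixel.
    """

    intensity: np.ndarray
    phase: np.ndarray
    occupancy: np.ndarray
    grid: PixelGrid
    weight: np.ndarray | None = None
    field: np.ndarray | None = field(default=None, repr=False)
    n_outside: int = 0

    def to_field(self) -> FieldMap:
        """Per-pixel complex field sqrt(I) exp(i psi) (0 where unoccupied)."""
        if self.field is not None:
            return FieldMap(data=self.field.copy(), grid=self.grid)
        psi = np.where(np.isnan(self.phase), 0.0, self.phase)
        amp = np.sqrt(np.maximum(self.intensity, 0.0))
        return FieldMap(data=amp * np.exp(1j * psi) * (self.occupancy > 0), grid=self.grid)


def accumulate_image(records, grid: PixelGrid) -> ImagePair:
    """Bin detection records into coherent intensity/phase images.

    Per pixel: ``I = sum W + 2 sum_{i<j} sqrt(W_i W_j) cos(Psi_i - Psi_j)``
    and ``psi = atan2(sum sqrt(W) sin Psi, sum sqrt(W) cos Psi)``, evaluated
    through the complex accumulator ``A = sum sqrt(W) e^{i Psi}`` (identical
    algebra).  Records falling outside the grid are counted and excluded.
    """
    acc = np.zeros((grid.ny, grid.nx), dtype=complex)
    wsum = np.zeros((grid.ny, grid.nx))
    occ = np.zeros((grid.ny, grid.nx), dtype=np.int64)
    n_outside = 0
    if len(records):
        iy, ix = grid.index_of(records.x, records.y)
        inside = (ix >= 0) & (ix < grid.nx) & (iy >= 0) & (iy < grid.ny)
        n_outside = int(np.sum(~inside))
        iy, ix = iy[inside], ix[inside]
        amp = np.sqrt(records.w[inside]) * np.exp(1j * records.psi[inside])
        np.add.at(acc, (iy, ix), amp)
        np.add.at(wsum, (iy, ix), records.w[inside])
        np.add.at(occ, (iy, ix), 1)
    intensity = np.abs(acc) ** 2
    phase = np.where(occ > 0, np.angle(acc), np.nan)
    return ImagePair(intensity=intensity, phase=phase, occupancy=occ, grid=grid,
                     weight=wsum, field=acc, n_outside=n_outside)


def interferogram(
    sample,
    reference: BeamSpec | None = None,
    *,
    tilt: float = 0.0,
    reference_amplitude: float = 1.0,
    reference_waist: float | None = None,
) -> np.ndarray:
    """Intensity of the sample field interfered with an expanded Gaussian.

    ``I = |E_s + E_r|^2`` where the reference is a plane-wave-like expanded
    Gaussian, optionally tilted about y by ``tilt`` radians: on-axis
    (``tilt = 0``) produces spiral fringes for a vortex sample, off-axis
    produces forked straight fringes of period ``lambda / sin(tilt)``.
    """
    if isinstance(sample, ImagePair):
        fm = sample.to_field()
    elif isinstance(sample, FieldMap):
        fm = sample
    else:
        raise TypeError("sample must be a FieldMap or ImagePair")
    grid = fm.grid
    X, Y = grid.meshgrid()
    wavelength = reference.wavelength if reference is not None else 633e-6
    if reference_waist is None:
        reference_waist = 20.0 * max(grid.nx, grid.ny) * grid.pitch
    k = 2.0 * np.pi / wavelength
    env = reference_amplitude * np.exp(-(X**2 + Y**2) / reference_waist**2)
    e_ref = env * np.exp(-1j * k * math.sin(tilt) * X)
    return np.abs(fm.data + e_ref) ** 2


@dataclass(frozen=True)
class AnnulusSpec:
    """Annular (optionally sector-restricted) analysis region, mm and radians."""

    r_inner: float
    r_outer: float
    phi_min: float = -np.pi
    phi_max: float = np.pi
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if not 0.0 <= self.r_inner < self.r_outer:
            raise ValueError("need 0 <= r_inner < r_outer")
        if self.phi_max <= self.phi_min:
            raise ValueError("sector bounds must be ordered")

    def mask(self, grid: PixelGrid) -> np.ndarray:
        X, Y = grid.meshgrid()
        dx = X - self.center[0]
        dy = Y - self.center[1]
        r = np.hypot(dx, dy)
        phi = np.arctan2(dy, dx)
        m = (r >= self.r_inner) & (r < self.r_outer)
        if (self.phi_min, self.phi_max) != (-np.pi, np.pi):
            m &= (phi >= self.phi_min) & (phi <= self.phi_max)
        return m

    @classmethod
    def for_beam(cls, beam: BeamSpec, z: float = 0.0, lo: float = 0.7, hi: float = 1.3) -> "AnnulusSpec":
        """Annulus bracketing the bright ring of an LG mode at depth z."""
        ring = float(beam.width(z)) * math.sqrt(max(abs(beam.topological_charge), 1) / 2.0)
        return cls(r_inner=lo * ring, r_outer=hi * ring)


@dataclass
class PhaseMemoryResult:
    """Annular relative-phase statistics.

    ``resultant_length`` is the intensity-weighted mean resultant length
    R = |sum I exp(i dpsi)| / sum I of the wrapped phase difference: R near 1
    means the initial helical phase modulation is retained through the
    medium; R near 0 means it is fully scrambled.
    """

    delta_phase: np.ndarray
    resultant_length: float
    n_pixels: int
    mean_delta: float


def phase_memory(measured: ImagePair, reference_phase, annulus: AnnulusSpec) -> PhaseMemoryResult:
    """Compare a measured speckle phase with a reference phase over an annulus."""
    ref = reference_phase.phase if isinstance(reference_phase, (ImagePair, FieldMap)) else np.asarray(reference_phase)
    if ref.shape != measured.phase.shape:
        raise ValueError("measured and reference maps must share one grid")
    mask = annulus.mask(measured.grid) & (measured.occupancy > 0) & ~np.isnan(ref)
    n_px = int(mask.sum())
    if n_px < 10:
        raise ValueError(f"annulus contains only {n_px} occupied pixels (need >= 10)")
    dpsi = wrap_phase(measured.phase - ref)
    weights = measured.intensity
    z = np.sum(weights[mask] * np.exp(1j * dpsi[mask]))
    denom = float(np.sum(weights[mask]))
    out = np.full(measured.phase.shape, np.nan)
    out[mask] = dpsi[mask]
    return PhaseMemoryResult(
        delta_phase=out,
        resultant_length=float(np.abs(z) / denom) if denom > 0 else 0.0,
        n_pixels=n_px,
        mean_delta=float(np.angle(z)),
    )


def write_image_pair(prefix, pair: ImagePair, metadata=None):
    """Write intensity/phase/occupancy as 32-bit float TIFFs + JSON sidecar."""
    import tifffile

    prefix = str(prefix)
    tifffile.imwrite(prefix + "_intensity.tif", pair.intensity.astype(np.float32))
    tifffile.imwrite(prefix + "_phase.tif", pair.phase.astype(np.float32))
    tifffile.imwrite(prefix + "_occupancy.tif", pair.occupancy.astype(np.float32))
    if pair.weight is not None:
        tifffile.imwrite(prefix + "_weight.tif", pair.weight.astype(np.float32))
    meta = {"grid": pair.grid.to_dict(), "n_outside": pair.n_outside}
    meta.update(metadata or {})
    with open(prefix + "_meta.json", "w") as f:
        json.dump(meta, f, indent=2, default=str)


def read_image_pair(prefix) -> ImagePair:
    import tifffile

    prefix = str(prefix)
    with open(prefix + "_meta.json") as f:
        meta = json.load(f)
    g = meta["grid"]
    grid = PixelGrid(nx=g["nx"], ny=g["ny"], pitch=g["pitch_mm"], origin=tuple(g["origin_mm"]))
    intensity = tifffile.imread(prefix + "_intensity.tif").astype(float)
    phase = tifffile.imread(prefix + "_phase.tif").astype(float)
    occ = tifffile.imread(prefix + "_occupancy.tif").astype(np.int64)
    try:
        weight = tifffile.imread(prefix + "_weight.tif").astype(float)
    except FileNotFoundError:
        weight = None
    return ImagePair(intensity=intensity, phase=phase, occupancy=occ, grid=grid,
                     weight=weight, n_outside=meta.get("n_outside", 0))
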