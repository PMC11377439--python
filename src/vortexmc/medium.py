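"""Slab optical properties, Henyey-Greenstein scattering and boundary physics.

The slab is homogeneous with scattering coefficient ``mu_s``, absorption
coefficient ``mu_a``, scattering anisotropy ``g`` (the mean cosine of the
single-scattering polar angle) and refractive index ``n``, bounded by the
planes ``z = 0`` and ``z = d``.  Optical depth is measured in transport
mean free paths: ``d/l*`` with ``l* = 1/(mu_s (1 - g))``, the length scale
over which direction memory is lost.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels

__all__ = [
    "MediumOptics",
    "BoundaryInteraction",
    "optical_depth",
    "hg_pdf",
    "hg_cdf",
    "sample_scatter_angles",
    "sample_free_path",
    "boundary_interact",
    "TabulatedPhaseFunction",
]


@dataclass(frozen=True)
class MediumOptics:
    """Optical properties of a turbid slab (per-mm coefficients, mm thickness)."""

    mus: float
    mua: float
    g: float
    n: float
    thickness: float
    n_ambient: float = 1.0
    rayleigh_factor: float = 1.0

    def __post_init__(self):
        if self.mus < 0:
            raise ValueError(f"mus must be >= 0, got {self.mus}")
        if self.mua < 0:
            raise ValueError(f"mua must be >= 0, got {self.mua}")
        if not -1.0 < self.g < 1.0:
            raise ValueError(f"anisotropy g must lie in (-1, 1), got {self.g}")
        if self.n < 1.0 or self.n_ambient < 1.0:
            raise ValueError("refractive indices must be >= 1")
        if self.thickness <= 0:
            raise ValueError(f"thickness must be positive, got {self.thickness}")
        if self.rayleigh_factor < 0:
            raise ValueError("rayleigh_factor must be >= 0")
        if self.mus > 0 and self.mua > 0.1 * self.mus:
            warnings.warn(
                "mua > 0.1*mus: the free-path sampler assumes mua << mus",
                stacklevel=3,
            )

    @property
    def mean_free_path(self) -> float:
        """Scattering mean free path 1/mu_s (mm); inf for a clear medium."""
        return math.inf if self.mus == 0 else 1.0 / self.mus

    @property
    def transport_mean_free_path(self) -> float:
        """Transport (reduced) mean free path l* = 1/(mu_s (1-g)) (mm)."""
        return math.inf if self.mus == 0 else 1.0 / (self.mus * (1.0 - self.g))

    @property
    def optical_depth(self) -> float:
        return optical_depth(self)


def optical_depth(medium: MediumOptics) -> float:
    """Slab optical depth d/l* = d * mu_s * (1 - g).

    The transport definition of l* reproduces the conventional labelling of
    tissue phantoms (e.g. d=8 mm, mu_s=6 mm^-1, g=0.8 -> d/l* = 9.6); see
    docs/methods.md for why the naive l*=1/mu_s is not used.
    """
    return medium.thickness * medium.mus * (1.0 - medium.g)


def hg_pdf(cos_theta, g):
    """Henyey-Greenstein phase function per steradian.

    ``p(cos t) = (1/4pi) (1-g^2) / (1 + g^2 - 2 g cos t)^(3/2)``.
    """
    if not abs(g) < 1.0:
        raise ValueError("|g| must be < 1")
    c = np.asarray(cos_theta, dtype=float)
    if np.any(np.abs(c) > 1.0 + 1e-12):
        raise ValueError("|cos_theta| must be <= 1")
    out = (1.0 - g * g) / (4.0 * np.pi * (1.0 + g * g - 2.0 * g * c) ** 1.5)
    return out if np.ndim(out) else float(out)


def hg_cdf(cos_theta, g):
    """CDF of cos(theta') under Henyey-Greenstein (useful for KS tests)."""
    c = np.asarray(cos_theta, dtype=float)
    if abs(g) < 1e-12:
        out = (c + 1.0) / 2.0
    else:
        out = (1.0 - g * g) / (2.0 * g) * (
            1.0 / np.sqrt(1.0 + g * g - 2.0 * g * c) - 1.0 / (1.0 + g)
        )
    return out if np.ndim(out) else float(out)


def sample_scatter_angles(g, xi1, xi2):
    """Closed-form inverse-CDF draw of (cos theta', azimuth).

    ``cos t = (1/2g)[1 + g^2 - ((1-g^2)/(1 - g + 2 g xi1))^2]`` for ``g != 0``
    and ``2 xi1 - 1`` otherwise; the azimuth is uniform, ``2 pi xi2``.
    ``xi1, xi2`` must lie in (0, 1].
    """
    xi1 = np.asarray(xi1, dtype=float)
    xi2 = np.asarray(xi2, dtype=float)
    if np.any(xi1 <= 0) or np.any(xi1 > 1) or np.any(xi2 <= 0) or np.any(xi2 > 1):
        raise ValueError("xi must lie in (0, 1]")
    if abs(g) < 1e-12:
        cos_t = 2.0 * xi1 - 1.0
    else:
        t = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi1)
        cos_t = (1.0 + g * g - t * t) / (2.0 * g)
        cos_t = np.clip(cos_t, -1.0, 1.0)
    az = 2.0 * np.pi * xi2
    if np.ndim(cos_t) == 0:
        return float(cos_t), float(az)
    return cos_t, az


class TabulatedPhaseFunction:
    """Inverse-CDF lookup sampler for an arbitrary tabulated phase function.

    Accepts per-steradian density values on a grid of cos(theta'); azimuthal
    symmetry is assumed.  Provided for phase functions without an analytic
    inversion (the engine itself uses the closed-form Henyey-Greenstein path).
    """

    def __init__(self, cos_grid, pdf_values):
        cos_grid = np.asarray(cos_grid, dtype=float)
        pdf_values = np.asarray(pdf_values, dtype=float)
        if cos_grid.ndim != 1 or cos_grid.size < 2 or np.any(np.diff(cos_grid) <= 0):
            raise ValueError("cos_grid must be strictly increasing")
        if np.any(pdf_values < 0):
            raise ValueError("pdf must be non-negative")
        dens = pdf_values  # the sin(theta) Jacobian is absorbed by the cos grid
        cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) * 0.5 * np.diff(cos_grid))])
        if cdf[-1] <= 0:
            raise ValueError("pdf integrates to zero")
        self._cdf = cdf / cdf[-1]
        self._grid = cos_grid

    def sample(self, xi1, xi2):
        xi1 = np.asarray(xi1, dtype=float)
        cos_t = np.interp(xi1, self._cdf, self._grid)
        az = 2.0 * np.pi * np.asarray(xi2, dtype=float)
        if np.ndim(cos_t) == 0:
            return float(cos_t), float(az)
        return cos_t, az


def sample_free_path(mus, xi):
    """Exponential free path l = -ln(xi)/mu_s; xi in (0, 1]."""
    xi = np.asarray(xi, dtype=float)
    if np.any(xi <= 0) or np.any(xi > 1):
        raise ValueError("xi must lie in (0, 1]")
    if mus < 0:
        raise ValueError("mus must be >= 0")
    if mus == 0:
        out = np.full_like(xi, np.inf)
    else:
        out = -np.log(xi) / mus
    return out if np.ndim(out) else float(out)


@dataclass(frozen=True)
class BoundaryInteraction:
    """Both branches of a Snell/Fresnel interaction at a plane interface.

    The transmitted polarization vectors absorb the power-normalization
    factor ``sqrt(n2 cos t / n1 cos i)`` so that ``|P_t|^2 + |P_r|^2 = |P|^2``
    per incident vector; ``transmittance``/``reflectance`` refer to the power
    carried by the current polarization pair.  ``transmitted_direction`` is
    ``None`` beyond the critical angle (total internal reflection).
    """

    transmitted_direction: np.ndarray | None
    reflected_direction: np.ndarray
    transmittance: float
    reflectance: float
    pol_x_transmitted: np.ndarray | None
    pol_y_transmitted: np.ndarray | None
    pol_x_reflected: np.ndarray
    pol_y_reflected: np.ndarray


def boundary_interact(direction, pol_x, pol_y, n1, n2, surface_normal) -> BoundaryInteraction:
    """Snell refraction and polarization-resolved Fresnel split.

    ``surface_normal`` must point into the destination medium, i.e.
    ``direction . normal > 0``.  Each polarization vector is decomposed into
    s- and p-components relative to the plane of incidence and the Fresnel
    amplitude coefficients are applied separately; at exactly normal
    incidence the s/p frame is degenerate and the incoming frame is reused
    (the coefficients coincide there).
    """
    d = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(d) - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    if n1 < 1.0 or n2 < 1.0:
        raise ValueError("refractive indices must be >= 1")
    nrm = np.asarray(surface_normal, dtype=float)
    nrm = nrm / np.linalg.norm(nrm)
    if np.dot(d, nrm) <= 0:
        raise ValueError("surface normal must satisfy direction . normal > 0")
    px = np.asarray(pol_x, dtype=float)
    py = np.asarray(pol_y, dtype=float)
    out = _kernels.boundary_event(
        d[0], d[1], d[2], nrm[0], nrm[1], nrm[2], float(n1), float(n2),
        px[0], px[1], px[2], py[0], py[1], py[2],
    )
    (tir, T, tdx, tdy, tdz, rdx, rdy, rdz,
     tpxx, tpxy, tpxz, tpyx, tpyy, tpyz,
     rpxx, rpxy, rpxz, rpyx, rpyy, rpyz) = out
    tir = bool(tir)
    return BoundaryInteraction(
        transmitted_direction=None if tir else np.array([tdx, tdy, tdz]),
        reflected_direction=np.array([rdx, rdy, rdz]),
        transmittance=float(T),
        reflectance=float(1.0 - T),
        pol_x_transmitted=None if tir else np.array([tpxx, tpxy, tpxz]),
        pol_y_transmitted=None if tir else np.array([tpyx, tpyy, tpyz]),
        pol_x_reflected=np.array([rpxx, rpxy, rpxz]),
        pol_y_reflected=np.array([rpyx, rpyy, rpyz]),
    )
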