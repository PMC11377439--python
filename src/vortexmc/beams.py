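"""Analytic Laguerre-Gaussian (LG) modes and photon-source synthesis.

A Laguerre-Gaussian mode ``LG_p^l`` is the paraxial laser mode with radial
index ``p`` and topological charge ``l`` (the integer winding number of the
helical phase ``exp(-i*l*phi)``).  This module evaluates the normalized
complex field, its phase (including the Gouy term), the skew launch
directions given by the local Poynting vector, and builds the Monte Carlo
source ensemble whose photon density follows the mode intensity.  It also
synthesizes the forked diffraction gratings used on a spatial light
modulator to imprint a chosen topological charge.

Units are millimetres and radians throughout; fields are normalized so that
``integral |LG|^2 rho drho dphi = 1``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy.special import eval_genlaguerre
from scipy.stats import qmc

__all__ = [
    "BeamSpec",
    "CylindricalPoint",
    "SourceEnsemble",
    "lg_field",
    "lg_phase",
    "lg_phase_unwrapped",
    "launch_direction",
    "sample_source",
    "fork_hologram",
    "wrap_phase",
]


def wrap_phase(psi):
    """Wrap angles to the interval (-pi, pi].

    Implemented as ``arctan2(sin, cos)`` so the argument reduction matches
    ``np.angle(exp(i psi))`` to rounding even for phases of millions of
    radians (optical-path phases).
    """
    x = np.asarray(psi, dtype=float)
    w = np.arctan2(np.sin(x), np.cos(x))
    return w if w.ndim else float(w)


@dataclass(frozen=True)
class BeamSpec:
    """Laguerre-Gaussian mode and optics parameters.

    Parameters
    ----------
    topological_charge
        Signed azimuthal index ``l``.
    radial_index
        Non-negative radial index ``p``.
    waist
        Zero-order Gaussian waist ``w(0)`` in mm.
    wavelength
        Vacuum wavelength in mm.
    angular_frequency
        Optical angular frequency; only a common scale factor of the
        Poynting vector and never affects normalized directions.
    """

    topological_charge: int
    radial_index: int = 0
    waist: float = 0.8
    wavelength: float = 633e-6
    angular_frequency: float = 1.0

    def __post_init__(self):
        if self.waist <= 0 or not math.isfinite(self.waist):
            raise ValueError(f"waist must be positive, got {self.waist}")
        if self.wavelength <= 0 or not math.isfinite(self.wavelength):
            raise ValueError(f"wavelength must be positive, got {self.wavelength}")
        if self.radial_index < 0:
            raise ValueError(f"radial index must be >= 0, got {self.radial_index}")
        if int(self.topological_charge) != self.topological_charge:
            raise ValueError("topological charge must be an integer")

    @property
    def k(self) -> float:
        """Wavenumber 2*pi/lambda (mm^-1)."""
        return 2.0 * np.pi / self.wavelength

    @property
    def rayleigh_range(self) -> float:
        """z_R = pi w(0)^2 / lambda (mm)."""
        return np.pi * self.waist**2 / self.wavelength

    def width(self, z):
        """Beam radius w(z) = w(0) sqrt(1 + (z/z_R)^2)."""
        return self.waist * np.sqrt(1.0 + (np.asarray(z, dtype=float) / self.rayleigh_range) ** 2)

    def gouy(self, z):
        """Gouy phase G(z) = (2p + |l| + 1) arctan(z/z_R)."""
        order = 2 * self.radial_index + abs(self.topological_charge) + 1
        return order * np.arctan(np.asarray(z, dtype=float) / self.rayleigh_range)


@dataclass(frozen=True)
class CylindricalPoint:
    """Point in the beam's cylindrical frame (rho >= 0, phi in (-pi, pi], z)."""

    rho: float
    phi: float = 0.0
    z: float = 0.0

    def __post_init__(self):
        if self.rho < 0 or not math.isfinite(self.rho):
            raise ValueError(f"rho must be finite and >= 0, got {self.rho}")
        if not (math.isfinite(self.phi) and math.isfinite(self.z)):
            raise ValueError("phi and z must be finite")


def _coords(pt):
    if isinstance(pt, CylindricalPoint):
        return pt.rho, pt.phi, pt.z
    rho, phi, z = pt
    return np.asarray(rho, float), np.asarray(phi, float), np.asarray(z, float)


def lg_field(beam: BeamSpec, pt):
    """Complex LG_p^l amplitude in the paraxial approximation.

    Accepts a :class:`CylindricalPoint` or a ``(rho, phi, z)`` array triple
    and broadcasts.  Normalized so the transverse power integral is one;
    sign conventions are ``exp(-i l phi)`` and ``exp(-i k z)``.
    """
    rho, phi, z = _coords(pt)
    if not (np.all(np.isfinite(rho)) and np.all(np.isfinite(phi)) and np.all(np.isfinite(z))):
        raise ValueError("non-finite coordinates")
    if np.any(np.asarray(rho) < 0):
        raise ValueError("rho must be >= 0")
    ell = beam.topological_charge
    p = beam.radial_index
    a = abs(ell)
    w = beam.width(z)
    zr = beam.rayleigh_range
    k = beam.k
    norm = math.sqrt(2.0 * math.factorial(p) / (np.pi * math.factorial(a + p)))
    x = 2.0 * rho**2 / w**2
    radial = (norm / w) * (np.sqrt(2.0) * rho / w) ** a * eval_genlaguerre(p, a, x) * np.exp(-rho**2 / w**2)
    # share the exact phase expression with lg_phase so the two agree to
    # rounding even when |k z| is many million radians
    phase = lg_phase_unwrapped(beam, (rho, phi, z))
    out = radial * np.exp(1j * phase)
    return out if np.ndim(out) else complex(out)


def lg_phase_unwrapped(beam: BeamSpec, pt):
    """Phase evolution Psi = -k rho^2 z / (2(z^2+z_R^2)) - l phi - k z + G(z), unwrapped."""
    rho, phi, z = _coords(pt)
    if not (np.all(np.isfinite(rho)) and np.all(np.isfinite(phi)) and np.all(np.isfinite(z))):
        raise ValueError("non-finite coordinates")
    zr = beam.rayleigh_range
    psi = (
        -beam.k * np.asarray(rho) ** 2 * z / (2.0 * (np.asarray(z) ** 2 + zr**2))
        - beam.topological_charge * np.asarray(phi)
        - beam.k * np.asarray(z)
        + beam.gouy(z)
    )
    return psi if np.ndim(psi) else float(psi)


def lg_phase(beam: BeamSpec, pt):
    """Phase of the LG mode wrapped to (-pi, pi]."""
    return wrap_phase(lg_phase_unwrapped(beam, pt))


def launch_direction(beam: BeamSpec, x, y, z=0.0):
    """Unit launch direction from the local Poynting vector of the mode.

    ``s = normalize(k z x/(z^2+z_R^2) - l y/(x^2+y^2),
                    k z y/(z^2+z_R^2) + l x/(x^2+y^2), k)``.
    The optical angular frequency is a common scale factor and cancels.
    Raises for an on-axis request when ``l != 0`` (the azimuthal term is
    singular there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    r2 = x**2 + y**2
    ell = beam.topological_charge
    if ell != 0 and np.any(r2 <= 0.0):
        raise ValueError("launch direction is singular on axis for l != 0")
    zr = beam.rayleigh_range
    k = beam.k
    curv = k * z / (z**2 + zr**2)
    if ell == 0:
        azim_x = np.zeros_like(x)
        azim_y = np.zeros_like(y)
    else:
        azim_x = -ell * y / r2
        azim_y = ell * x / r2
    sx = curv * x + azim_x
    sy = curv * y + azim_y
    sz = np.broadcast_to(np.asarray(k, dtype=float), sx.shape).copy()
    s = np.stack(np.broadcast_arrays(sx, sy, sz), axis=-1)
    s /= np.linalg.norm(s, axis=-1, keepdims=True)
    return s


@dataclass
class SourceEnsemble:
    """Struct-of-arrays bundle of Monte Carlo source photons.

    Positions lie in the launch plane ``z = z_launch``; each photon carries
    the local mode phase, the Poynting launch direction and a pair of real
    polarization vectors (images of the transverse basis scaled by the
    Jones amplitudes of the initial linear polarization).
    """

    x: np.ndarray
    y: np.ndarray
    psi0: np.ndarray
    directions: np.ndarray  # (n, 3) unit vectors
    pol_x: np.ndarray  # (n, 3)
    pol_y: np.ndarray  # (n, 3)
    weight: np.ndarray  # (n,)
    z_launch: float = 0.0
    beam: BeamSpec | None = field(default=None, repr=False)

    def __len__(self):
        return self.x.shape[0]


def _radial_profile(beam, z, r_max, n_grid=4096):
    """Tabulated radial density f(rho) = |LG|^2 * rho on [0, r_max]."""
    rho = np.linspace(0.0, r_max, n_grid)
    amp2 = np.abs(lg_field(beam, (rho, np.zeros_like(rho), np.full_like(rho, z)))) ** 2
    return rho, amp2


def sample_source(
    beam: BeamSpec,
    n: int,
    z_launch: float = 0.0,
    seed=None,
    polarization=(1.0, 0.0),
    method: str = "rejection",
    r_max: float | None = None,
) -> SourceEnsemble:
    """Draw ``n`` source photons with transverse density ``|LG|^2``.

    ``method='rejection'`` uses plain rejection sampling against the mode
    intensity; ``method='stratified'`` maps scrambled-Sobol points through
    the numerically inverted radial CDF, which removes most of the Poisson
    pixel noise in downstream ballistic images.  A guard band excludes
    ``rho < 1e-12 * w0`` where the skew-angle formula is singular.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    w = float(beam.width(z_launch))
    ell, p = beam.topological_charge, beam.radial_index
    if r_max is None:
        r_max = w * (math.sqrt((abs(ell) + 2 * p) / 2.0) + 5.0)
    guard = 1e-12 * beam.waist

    if method == "rejection":
        rho = np.empty(0)
        phi = np.empty(0)
        grid, amp2 = _radial_profile(beam, z_launch, r_max)
        fmax = float(amp2.max()) * 1.05
        max_rounds = 1000
        for _ in range(max_rounds):
            need = n - rho.size
            if need <= 0:
                break
            m = max(int(need / max(0.02, amp2.mean() / fmax)), 2 * need)
            m = min(m, 4_000_000)
            cand_rho = r_max * np.sqrt(rng.random(m))
            accept_p = np.abs(
                lg_field(beam, (cand_rho, np.zeros(m), np.full(m, z_launch)))
            ) ** 2 / fmax
            if np.any(accept_p > 1.0 + 1e-9):
                raise RuntimeError("rejection envelope violated (internal bug)")
            keep = (rng.random(m) < accept_p) & (cand_rho > guard)
            cand_rho = cand_rho[keep]
            rho = np.concatenate([rho, cand_rho])
        else:
            raise RuntimeError("rejection sampling failed to converge")
        rho = rho[:n]
        phi = rng.uniform(-np.pi, np.pi, n)
    elif method == "stratified":
        grid, amp2 = _radial_profile(beam, z_launch, r_max)
        dens = amp2 * grid  # radial pdf (unnormalized)
        cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) * 0.5 * np.diff(grid))])
        cdf /= cdf[-1]
        # strictly increasing part for interpolation
        keep = np.concatenate([[True], np.diff(cdf) > 0])
        sob = qmc.Sobol(d=2, scramble=True, seed=rng)
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*balance properties.*")
            pts = sob.random(n)
        rho = np.interp(pts[:, 0], cdf[keep], grid[keep])
        rho = np.clip(rho, guard * 1.01, r_max)
        phi = wrap_phase(2.0 * np.pi * pts[:, 1] - np.pi)
    else:
        raise ValueError(f"unknown sampling method {method!r}")

    x = rho * np.cos(phi)
    y = rho * np.sin(phi)
    psi0 = lg_phase(beam, (rho, phi, np.full(n, float(z_launch))))
    dirs = launch_direction(beam, x, y, np.full(n, float(z_launch)))

    ax, ay = polarization
    nrm = math.hypot(ax, ay)
    if nrm == 0:
        raise ValueError("polarization amplitudes cannot both be zero")
    ax, ay = ax / nrm, ay / nrm
    # transverse triad: ex orthogonalized against s, ey = s x ex
    ex = np.zeros_like(dirs)
    ex[:, 0] = 1.0
    ex -= np.sum(ex * dirs, axis=1, keepdims=True) * dirs
    ex /= np.linalg.norm(ex, axis=1, keepdims=True)
    ey = np.cross(dirs, ex)
    return SourceEnsemble(
        x=x,
        y=y,
        psi0=np.asarray(psi0, dtype=float),
        directions=dirs,
        pol_x=ax * ex,
        pol_y=ay * ey,
        weight=np.ones(n),
        z_launch=float(z_launch),
        beam=beam,
    )


def fork_hologram(ell: int, grating_period: float, grid) -> np.ndarray:
    """Forked SLM phase grating ``wrap(l*atan2(y, x) + 2 pi x / Lambda)``.

    ``grid`` is a :class:`vortexmc.detector.PixelGrid`.  The returned map
    carries an ``l``-pronged fork dislocation at the origin: a horizontal
    cut through the origin shows ``|l|`` extra fringe terminations.
    """
    if grating_period <= 0:
        raise ValueError("grating period must be positive")
    X, Y = grid.meshgrid()
    return wrap_phase(ell * np.arctan2(Y, X) + 2.0 * np.pi * X / grating_period)


def mode_power(beam: BeamSpec, z: float = 0.0, r_max: float | None = None) -> float:
    """Transverse power integral of the mode (adaptive quadrature); ~1."""
    if r_max is None:
        r_max = beam.width(z) * (math.sqrt((abs(beam.topological_charge) + 2 * beam.radial_index) / 2.0) + 8.0)

    def integrand(rho):
        a = lg_field(beam, (np.asarray([rho]), np.zeros(1), np.asarray([float(z)])))
        return float(np.abs(a[0]) ** 2 * rho)

    val, _ = integrate.quad(integrand, 0.0, r_max, limit=200)
    return 2.0 * np.pi * val
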