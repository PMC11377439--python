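"""Photon-packet transport through the slab.

Each Monte Carlo photon performs a move/scatter/attenuate random walk:
exponential free paths, Beer-Lambert weight attenuation, Henyey-Greenstein
deflections, and at every scattering event the transverse projection of the
polarization pair onto the new propagation direction,

    P_i = -s_i x [s_i x P_{i-1}] = [I - s_i (x) s_i] P_{i-1},

whose un-renormalized shrinkage encodes depolarization.  Photons terminate
when the tracked weight falls below the floor, the scattering-event cap is
exceeded, or they leave the slab; exiting photons are tested against the
detector window and acceptance cone and recorded with their accumulated
phase and polarized/depolarized weights.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .beams import SourceEnsemble
from .medium import MediumOptics, boundary_interact, sample_free_path, sample_scatter_angles

__all__ = [
    "RunConfig",
    "PhotonPacket",
    "DetectionRecords",
    "TransportSummary",
    "project_polarization",
    "step",
    "run_transport",
]

_CHUNK = 1_000_000  # photons per kernel batch (fixed so runs are bit-reproducible)


@dataclass(frozen=True)
class RunConfig:
    """Transport run parameters.

    ``na`` is the detector acceptance half-angle in radians, compared
    directly against ``acos(s_N . s_d)``; ``geometry`` selects the detector
    plane: ``"transmission"`` (z = d) or ``"reflection"`` (z = 0).
    """

    n_incident: int
    n_detect: int
    detector_halfwidth: float
    na: float = np.pi / 2
    detector_tilt: float = 0.0
    source_tilt: float = 0.0
    geometry: str = "transmission"
    weight_floor: float = 1e-4
    max_events: int = 1000
    apply_exit_fresnel: bool = True
    seed: int | None = None

    def __post_init__(self):
        if self.n_detect < 1 or self.n_incident < self.n_detect:
            raise ValueError("need n_incident >= n_detect >= 1")
        if not 0.0 < self.weight_floor < 1.0:
            raise ValueError("weight floor must lie in (0, 1)")
        if not 0.0 < self.na <= np.pi / 2:
            raise ValueError("NA (acceptance half-angle) must lie in (0, pi/2]")
        if self.detector_halfwidth <= 0:
            raise ValueError("detector halfwidth must be positive")
        if self.geometry not in ("transmission", "reflection"):
            raise ValueError("geometry must be 'transmission' or 'reflection'")
        if self.max_events < 1:
            raise ValueError("max_events must be >= 1")
        if self.seed is None:
            raise ValueError("a seed is required; runs must be reproducible")

    @property
    def detector_axis(self) -> np.ndarray:
        """Unit vector s_d = [sin(-theta_d), 0, +-cos(theta_d)] along the detector."""
        zs = 1.0 if self.geometry == "transmission" else -1.0
        return np.array([
            math.sin(-self.detector_tilt), 0.0, zs * math.cos(self.detector_tilt)
        ])


def project_polarization(pol, direction):
    """Transverse projection ``P - (P.s) s`` of a polarization vector.

    Applied (without renormalization) to both polarization vectors at every
    scattering event; the lost longitudinal component is the per-event
    depolarization of this model.
    """
    s = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(s) - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    p = np.asarray(pol, dtype=float)
    return p - np.dot(p, s) * s


@dataclass
class PhotonPacket:
    """One photon's walk state (positions mm, phase rad, unit direction)."""

    position: np.ndarray
    direction: np.ndarray
    weight: float = 1.0
    pol_x: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    pol_y: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 0.0]))
    phase: float = 0.0
    path_length: float = 0.0
    n_events: int = 0
    alive: bool = True
    at_boundary: bool = False


def step(packet: PhotonPacket, medium: MediumOptics, rng, k0: float) -> PhotonPacket:
    """Advance a packet by one free path inside the slab.

    Draws the free path, moves the packet, attenuates the weight by
    Beer-Lambert, subtracts ``k0 * n * l`` from the phase and either performs
    a scattering event (deflection + polarization projection + Rayleigh
    factor) or, if the segment crosses a slab face, truncates at the face
    and flags ``at_boundary`` for hand-off to the boundary interaction.
    """
    if not packet.alive:
        raise ValueError("cannot step a dead packet")
    l = sample_free_path(medium.mus, 1.0 - rng.random())
    d = packet.direction
    z = packet.position[2]
    if d[2] > 0:
        t_face = (medium.thickness - z) / d[2]
    elif d[2] < 0:
        t_face = -z / d[2]
    else:
        t_face = math.inf
    hit = t_face <= l
    seg = t_face if hit else l
    packet.position = packet.position + d * seg
    packet.phase -= k0 * medium.n * seg
    packet.path_length += seg
    packet.weight *= math.exp(-medium.mua * seg)
    if hit:
        packet.position[2] = medium.thickness if d[2] > 0 else 0.0
        packet.at_boundary = True
        return packet
    packet.n_events += 1
    cos_t, az = sample_scatter_angles(medium.g, 1.0 - rng.random(), max(rng.random(), 1e-300))
    packet.direction = np.array(
        _kernels.rotate_direction(d[0], d[1], d[2], cos_t, az)
    )
    packet.pol_x = project_polarization(packet.pol_x, packet.direction)
    packet.pol_y = project_polarization(packet.pol_y, packet.direction)
    packet.weight *= medium.rayleigh_factor
    if packet.weight < 1e-300:
        packet.alive = False
    return packet


@dataclass
class DetectionRecords:
    """Detector-plane photons (struct of arrays).

    ``psi`` is the total accumulated phase Psi_N = psi_0 - k n sum(l_i);
    ``w = w_par + w_perp`` holds exactly per record.
    """

    x: np.ndarray
    y: np.ndarray
    directions: np.ndarray
    psi: np.ndarray
    w: np.ndarray
    w_par: np.ndarray
    w_perp: np.ndarray
    n_events: np.ndarray

    def __len__(self):
        return self.x.shape[0]

    @staticmethod
    def concatenate(parts):
        return DetectionRecords(
            x=np.concatenate([p.x for p in parts]) if parts else np.empty(0),
            y=np.concatenate([p.y for p in parts]) if parts else np.empty(0),
            directions=np.concatenate([p.directions for p in parts]) if parts else np.empty((0, 3)),
            psi=np.concatenate([p.psi for p in parts]) if parts else np.empty(0),
            w=np.concatenate([p.w for p in parts]) if parts else np.empty(0),
            w_par=np.concatenate([p.w_par for p in parts]) if parts else np.empty(0),
            w_perp=np.concatenate([p.w_perp for p in parts]) if parts else np.empty(0),
            n_events=np.concatenate([p.n_events for p in parts]) if parts else np.empty(0, dtype=np.int64),
        )

    def to_hdf5(self, path, metadata=None):
        """Dump the record table to an HDF5 file."""
        import h5py

        with h5py.File(path, "w") as f:
            g = f.create_group("detections")
            g.create_dataset("x", data=self.x)
            g.create_dataset("y", data=self.y)
            g.create_dataset("sx", data=self.directions[:, 0])
            g.create_dataset("sy", data=self.directions[:, 1])
            g.create_dataset("sz", data=self.directions[:, 2])
            g.create_dataset("phase", data=self.psi)
            g.create_dataset("w", data=self.w)
            g.create_dataset("w_par", data=self.w_par)
            g.create_dataset("w_perp", data=self.w_perp)
            g.create_dataset("n_events", data=self.n_events)
            for key, val in (metadata or {}).items():
                f.attrs[key] = val


@dataclass
class TransportSummary:
    """Weight ledger of a run; all buckets sum to ``w_launched`` exactly."""

    launched: int
    detected: int
    w_launched: float
    w_entry_reflected: float
    w_absorbed: float
    w_exit_undetected: float
    w_terminated_floor: float
    w_terminated_cap: float
    w_detected: float
    w_gamma_loss: float

    @property
    def closure_error(self) -> float:
        if self.w_launched == 0:
            return 0.0
        tot = (self.w_entry_reflected + self.w_absorbed + self.w_exit_undetected
               + self.w_terminated_floor + self.w_terminated_cap
               + self.w_detected + self.w_gamma_loss)
        return abs(tot - self.w_launched) / self.w_launched


@dataclass
class TransportResult:
    records: DetectionRecords
    summary: TransportSummary

    @property
    def no_detections(self) -> bool:
        return len(self.records) == 0


def _tilt_source(source: SourceEnsemble, theta: float) -> SourceEnsemble:
    """Rotate the whole source about the y axis by the tilt angle."""
    c, s = math.cos(theta), math.sin(theta)
    rot = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    return replace(
        source,
        directions=source.directions @ rot.T,
        pol_x=source.pol_x @ rot.T,
        pol_y=source.pol_y @ rot.T,
    )


def run_transport(source, medium: MediumOptics, config: RunConfig) -> TransportResult:
    """Transport source photons through the slab and collect detections.

    ``source`` may be a fixed :class:`SourceEnsemble` or a callable
    ``factory(n, seed) -> SourceEnsemble`` which is invoked in fixed-size
    chunks until the detector quota ``n_detect`` is reached or ``n_incident``
    photons have been launched.  Identical seed and configuration produce
    bit-identical records.
    """
    ss = np.random.SeedSequence(config.seed)
    kernel_seeds = ss.spawn(1)[0].generate_state(1 + config.n_incident // _CHUNK + 2)
    source_ss = ss.spawn(2)[1]

    if isinstance(source, SourceEnsemble):
        chunks = [source]
        factory = None
        beam = source.beam
    else:
        factory = source
        chunks = None
        beam = None

    det_at_exit = config.geometry == "transmission"
    sdet = config.detector_axis
    parts = []
    totals = np.zeros(8)
    launched = 0
    detected = 0
    budget = config.n_incident
    quota = config.n_detect
    chunk_idx = 0

    while detected < quota and launched < budget:
        if factory is not None:
            n = min(_CHUNK, budget - launched)
            src = factory(n, np.random.default_rng(source_ss.spawn(chunk_idx + 1)[0]))
        else:
            if chunk_idx >= len(chunks):
                break
            src = chunks[chunk_idx]
            if len(src) > budget - launched:
                raise ValueError("source ensemble larger than the incident budget")
        if beam is None:
            beam = src.beam
        if config.source_tilt != 0.0:
            src = _tilt_source(src, config.source_tilt)
        k0 = src.beam.k if src.beam is not None else 2.0 * np.pi / 633e-6
        room = quota - detected
        out_x = np.empty(room)
        out_y = np.empty(room)
        out_s = np.empty((room, 3))
        out_psi = np.empty(room)
        out_w = np.empty(room)
        out_wpar = np.empty(room)
        out_wperp = np.empty(room)
        out_nev = np.empty(room, dtype=np.int64)
        res = _kernels.transport_loop(
            src.x, src.y, src.psi0, src.directions, src.pol_x, src.pol_y, src.weight,
            k0, medium.mus, medium.mua, medium.g, medium.n, medium.n_ambient,
            medium.thickness, medium.rayleigh_factor,
            config.weight_floor, config.max_events,
            config.detector_halfwidth, math.cos(config.na), sdet, det_at_exit,
            config.apply_exit_fresnel,
            room, int(kernel_seeds[chunk_idx]),
            out_x, out_y, out_s, out_psi, out_w, out_wpar, out_wperp, out_nev,
        )
        count = res[0]
        launched += res[1]
        totals += np.array(res[2:])
        detected += count
        parts.append(DetectionRecords(
            x=out_x[:count].copy(), y=out_y[:count].copy(),
            directions=out_s[:count].copy(), psi=out_psi[:count].copy(),
            w=out_w[:count].copy(), w_par=out_wpar[:count].copy(),
            w_perp=out_wperp[:count].copy(), n_events=out_nev[:count].copy(),
        ))
        chunk_idx += 1

    records = DetectionRecords.concatenate(parts)
    summary = TransportSummary(
        launched=launched, detected=detected,
        w_launched=float(totals[0]), w_entry_reflected=float(totals[1]),
        w_absorbed=float(totals[2]), w_exit_undetected=float(totals[3]),
        w_terminated_floor=float(totals[4]), w_terminated_cap=float(totals[5]),
        w_detected=float(totals[6]), w_gamma_loss=float(totals[7]),
    )
    if summary.detected == 0:
        warnings.warn(
            "no detections: the incident budget was exhausted before any photon "
            "reached the detector", stacklevel=2,
        )
    return TransportResult(records=records, summary=summary)
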