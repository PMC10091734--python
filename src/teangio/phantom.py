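"""Synthetic dynamic vessel phantom and multi-coil radial k-space generator.

The generator emulates, at desk scale, a 2D radial SPGR angiography
acquisition: a handful of curved vessels carrying a gamma-dispersed ASL
bolus (with distinct early/middle/late arrival times), static tissue of two
T1 classes following the background-suppressed saturation-recovery history
of the readout, smooth complex coil sensitivities, evenly distributed
radial spokes acquired segment-by-segment with the same spokes repeated for
every label/control/encoding condition, additive complex Gaussian noise,
and a slow global B0-drift phase (linear in acquisition time).

Spoke data are synthesized by *exact* discrete Fourier evaluation of the
component images at the spoke sample locations — deliberately not the
gridding code used for reconstruction, so forward and inverse models do not
share an interpolation error ("inverse crime").
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .bgs import tissue_mz_readout
from .flip_angles import FlipAngleSchedule, acquired_signal_profile
from .protocol import HadamardScheme, ProtocolTimings, hadamard_encoding
from .signal_model import SignalModelParams, _bolus_fraction_closed

__all__ = [
    "Vessel",
    "VesselPhantom",
    "PhantomConfig",
    "RadialTrajectory",
    "RadialKspace",
    "make_phantom",
    "make_coil_maps",
    "radial_trajectory",
    "synthesize_kspace",
    "component_kspace_cache",
    "dft_points",
]

TISSUE_T1_CLASSES = (0.791, 1.445)  # white / gray matter, seconds


@dataclasses.dataclass(frozen=True)
class Vessel:
    """One vessel: a centerline polyline (row, col pixels) dilated by
    ``radius_px``, carrying a dispersed bolus."""

    path: np.ndarray
    radius_px: float
    arrival_time: float
    amplitude: float = 1.0
    sharpness: float = 10.0
    time_to_peak: float = 0.1


@dataclasses.dataclass(frozen=True)
class VesselPhantom:
    matrix: int
    vessels: tuple[Vessel, ...]
    tissue_amplitude: np.ndarray
    tissue_t1: np.ndarray
    brain_mask: np.ndarray

    def vessel_images(self) -> np.ndarray:
        """Rasterized vessel masks scaled by amplitude, [vessel, y, x]."""
        return np.array(
            [rasterize_vessel(v, self.matrix) * v.amplitude for v in self.vessels]
        )


@dataclasses.dataclass(frozen=True)
class PhantomConfig:
    matrix: int = 96
    n_vessels: int = 3
    vessel_radius_px: float = 1.8
    arrival_times: tuple[float, ...] = (0.35, 0.65, 0.95)
    vessel_amplitude: float = 1.0
    sharpness: float = 10.0
    time_to_peak: float = 0.1
    tissue_amplitude: float = 1.0


def rasterize_vessel(vessel: Vessel, matrix: int) -> np.ndarray:
    """Binary dilation of the polyline by the vessel radius (float image)."""
    path = np.asarray(vessel.path, dtype=float)
    # densify the polyline to ~0.25 px steps
    pts = [path[:1]]
    for a, b in zip(path[:-1], path[1:]):
        seg = np.linalg.norm(b - a)
        n = max(2, int(np.ceil(seg / 0.1)))
        pts.append(np.linspace(a, b, n)[1:])
    dense = np.concatenate(pts)
    tree = cKDTree(dense)
    rr, cc = np.mgrid[0:matrix, 0:matrix]
    pix = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    dist, _ = tree.query(pix, distance_upper_bound=vessel.radius_px + 1.0)
    mask = (dist <= vessel.radius_px + 1e-9).reshape(matrix, matrix)
    return mask.astype(float)


def polyline_length(path: np.ndarray) -> float:
    path = np.asarray(path, dtype=float)
    return float(np.sum(np.linalg.norm(np.diff(path, axis=0), axis=1)))


def make_phantom(config: PhantomConfig | None = None, seed: int = 0) -> VesselPhantom:
    """Deterministic (seeded) digital phantom with >= 3 vessels of distinct
    arrival times and a two-class static tissue background."""
    cfg = config or PhantomConfig()
    rng = np.random.default_rng(seed)
    m = cfg.matrix
    center = (m - 1) / 2.0
    brain_r = 0.42 * m

    rr, cc = np.mgrid[0:m, 0:m]
    rho = np.hypot(rr - center, cc - center)
    brain = rho <= brain_r

    # two-class tissue map from thresholded smooth noise
    blobs = gaussian_filter(rng.standard_normal((m, m)), sigma=m / 12.0)
    gray = blobs > np.median(blobs[brain])
    tissue_t1 = np.where(gray, TISSUE_T1_CLASSES[1], TISSUE_T1_CLASSES[0])
    tissue_t1 = np.where(brain, tissue_t1, 0.0)
    tissue_amp = np.where(brain, cfg.tissue_amplitude, 0.0).astype(float)

    vessels = []
    arrivals = cfg.arrival_times
    for i in range(cfg.n_vessels):
        # curved arc from near the center outward, one per sector
        phi0 = 2 * np.pi * i / cfg.n_vessels + rng.uniform(-0.3, 0.3)
        bend = rng.uniform(-0.9, 0.9)
        radii = np.linspace(0.06 * m, 0.36 * m, 24)
        angles = phi0 + bend * np.linspace(0.0, 1.0, 24) ** 1.5
        path = np.column_stack(
            [center + radii * np.sin(angles), center + radii * np.cos(angles)]
        )
        margin = cfg.vessel_radius_px + 1.0
        if path.min() < margin or path.max() > m - 1 - margin:
            raise ValueError("vessel path falls outside the field of view")
        vessels.append(
            Vessel(
                path=path,
                radius_px=cfg.vessel_radius_px,
                arrival_time=arrivals[i % len(arrivals)],
                amplitude=cfg.vessel_amplitude,
                sharpness=cfg.sharpness,
                time_to_peak=cfg.time_to_peak,
            )
        )
    return VesselPhantom(
        matrix=m,
        vessels=tuple(vessels),
        tissue_amplitude=tissue_amp,
        tissue_t1=tissue_t1,
        brain_mask=brain,
    )


def make_coil_maps(matrix: int, n_coils: int = 8) -> np.ndarray:
    """Smooth complex coil sensitivities: Gaussian magnitude lobes around the
    FOV with low-order polynomial phase, [coil, y, x]."""
    m = matrix
    center = (m - 1) / 2.0
    rr, cc = np.mgrid[0:m, 0:m]
    y = (rr - center) / m
    x = (cc - center) / m
    maps = np.empty((n_coils, m, m), dtype=complex)
    for c in range(n_coils):
        phi = 2 * np.pi * c / n_coils
        cy, cx = 0.55 * np.sin(phi), 0.55 * np.cos(phi)
        mag = np.exp(-((y - cy) ** 2 + (x - cx) ** 2) / (2 * 0.35**2))
        phase = 2.0 * (x * np.cos(phi) + y * np.sin(phi)) + 1.5 * x * y * np.cos(2 * phi)
        maps[c] = mag * np.exp(1j * phase)
    # normalize root-sum-of-squares to ~1 in the FOV center region
    rss = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
    maps /= rss.mean()
    return maps


@dataclasses.dataclass(frozen=True)
class RadialTrajectory:
    """Evenly distributed radial spokes in cycles/pixel, |k| <= 0.5.

    ``segment_of_spoke``/``position_of_spoke`` encode the acquisition
    ordering: segment ``s`` plays ``spokes_per_frame`` consecutive spokes in
    sequential angular order within every readout frame, the same spokes for
    every encoding/average, before the next segment advances.
    """

    angles: np.ndarray
    kx: np.ndarray  # [spoke, sample]
    ky: np.ndarray
    spokes_per_frame: int

    @property
    def n_spokes(self) -> int:
        return self.angles.size

    @property
    def n_samples(self) -> int:
        return self.kx.shape[1]

    @property
    def n_segments(self) -> int:
        return self.n_spokes // self.spokes_per_frame

    @property
    def segment_of_spoke(self) -> np.ndarray:
        return np.arange(self.n_spokes) // self.spokes_per_frame

    @property
    def position_of_spoke(self) -> np.ndarray:
        return np.arange(self.n_spokes) % self.spokes_per_frame

    def points(self) -> np.ndarray:
        """All sample coordinates flattened to [n_spokes*n_samples, 2]."""
        return np.column_stack([self.kx.ravel(), self.ky.ravel()])

    def subset(self, segments: np.ndarray) -> "RadialTrajectory":
        """Trajectory restricted to the given segment indices (angular
        undersampling keeps the retained spokes evenly usable)."""
        keep = np.isin(self.segment_of_spoke, segments)
        return RadialTrajectory(
            angles=self.angles[keep],
            kx=self.kx[keep],
            ky=self.ky[keep],
            spokes_per_frame=self.spokes_per_frame,
        )


def radial_trajectory(
    n_spokes: int,
    n_samples: int,
    ordering: str = "sequential",
    spokes_per_frame: int = 12,
) -> RadialTrajectory:
    """Angularly even full-spoke radial trajectory over [0, pi)."""
    if n_spokes < 1:
        raise ValueError("n_spokes must be >= 1")
    if ordering != "sequential":
        raise ValueError("only sequential angular ordering is supported")
    angles = np.arange(n_spokes) * np.pi / n_spokes
    radii = (np.arange(n_samples) - n_samples // 2) / n_samples  # cycles/pixel
    kx = np.outer(np.cos(angles), radii)
    ky = np.outer(np.sin(angles), radii)
    return RadialTrajectory(
        angles=angles, kx=kx, ky=ky, spokes_per_frame=spokes_per_frame
    )


def dft_points(
    image: np.ndarray, kx: np.ndarray, ky: np.ndarray, dtype=np.complex128
) -> np.ndarray:
    """Exact DFT of ``image`` at arbitrary k-space points (cycles/pixel).

    The image center is pixel ``(M//2, M//2)``, matching the FFT-shift
    convention of the reconstruction.  ``dtype=complex64`` trades ~1e-5
    relative accuracy for speed on large syntheses.
    """
    m = image.shape[-1]
    x = np.arange(m) - m // 2
    rr, cc = np.meshgrid(x, x, indexing="ij")
    coords = np.stack([cc.ravel(), rr.ravel()]).astype(float)  # (2, m^2)
    flat = np.asarray(image).reshape(-1, m * m).astype(dtype)
    pts = np.column_stack([np.asarray(kx).ravel(), np.asarray(ky).ravel()])
    real_dtype = np.float32 if dtype == np.complex64 else np.float64
    out = np.empty((flat.shape[0], pts.shape[0]), dtype=dtype)
    chunk = max(1, int(4e7 // (m * m)))
    for i in range(0, pts.shape[0], chunk):
        phase = ((-2.0 * np.pi) * (pts[i : i + chunk] @ coords)).astype(
            real_dtype, copy=False
        )
        e = np.cos(phase) + 1j * np.sin(phase)
        out[:, i : i + chunk] = flat @ e.T.astype(dtype, copy=False)
    return out.reshape(image.shape[:-2] + np.asarray(kx).shape)


def component_kspace_cache(
    phantom: VesselPhantom,
    trajectory: RadialTrajectory,
    coil_maps: np.ndarray,
    dtype=np.complex128,
) -> np.ndarray:
    """Exact DFT of every coil-weighted component image (each vessel, then
    the two tissue T1 classes) at every trajectory point,
    shaped [component, spoke, sample, coil].

    This depends only on the phantom geometry, trajectory and coil maps, so
    it can be computed once and shared between protocol/schedule syntheses
    (including angularly undersampled subsets, by slicing the spoke axis).
    """
    comps = [img for img in phantom.vessel_images()]
    for t1 in TISSUE_T1_CLASSES:
        comps.append(phantom.tissue_amplitude * (phantom.tissue_t1 == t1))
    comp_imgs = np.array(comps)  # [comp, y, x]
    n_comp = comp_imgs.shape[0]
    n_coils = coil_maps.shape[0]
    coil_comp = comp_imgs[:, None] * coil_maps[None, :]  # [comp, coil, y, x]
    k_comp = dft_points(
        coil_comp.reshape(n_comp * n_coils, phantom.matrix, phantom.matrix),
        trajectory.kx,
        trajectory.ky,
        dtype=dtype,
    ).reshape(n_comp, n_coils, trajectory.n_spokes, trajectory.n_samples)
    return np.moveaxis(k_comp, 1, -1)


@dataclasses.dataclass
class RadialKspace:
    """Multi-coil radial spoke data,
    indexed [encoding, average, frame, spoke, sample, coil]."""

    samples: np.ndarray
    trajectory: RadialTrajectory
    protocol: ProtocolTimings
    scheme: HadamardScheme
    meta: dict

    @property
    def n_encodings(self) -> int:
        return self.samples.shape[0]


def _vessel_weights(
    phantom: VesselPhantom,
    protocol: ProtocolTimings,
    schedule: FlipAngleSchedule,
    scheme: HadamardScheme,
    t1_blood: float,
) -> np.ndarray:
    """Per-encoding, per-excitation transverse amplitude of each vessel.

    Encoding ``i`` carries ``sum_j sign[i,j]/2 * S_j`` so that decoding (or
    plain control-label subtraction) recovers each block's bolus signal
    exactly; label and control acquisitions differ only in the vessel sign.
    """
    t_exc = protocol.excitation_times()
    profile = acquired_signal_profile(schedule)
    w = np.zeros((scheme.n_encodings, protocol.n_excitations, len(phantom.vessels)))
    for vi, vessel in enumerate(phantom.vessels):
        params = SignalModelParams(
            sharpness=vessel.sharpness,
            time_to_peak=vessel.time_to_peak,
            arrival_time=vessel.arrival_time,
            label_duration=protocol.block_label_duration,
            amplitude=vessel.amplitude,
            t1_blood=t1_blood,
            readout_tr=protocol.readout_tr,
            readout_start=protocol.readout_start,
        )
        for j in range(scheme.n_blocks):
            bolus = _bolus_fraction_closed(t_exc, params, protocol.block_start(j + 1))
            s_j = params.amplitude * profile * bolus
            for i in range(scheme.n_encodings):
                w[i, :, vi] += 0.5 * scheme.matrix[i, j] * s_j
    return w


def _tissue_weights(
    phantom: VesselPhantom,
    protocol: ProtocolTimings,
    schedule: FlipAngleSchedule,
    t_null_norf: float,
) -> np.ndarray:
    """Per-excitation transverse tissue signal for each T1 class."""
    out = np.empty((len(TISSUE_T1_CLASSES), protocol.n_excitations))
    for ci, t1 in enumerate(TISSUE_T1_CLASSES):
        state = tissue_mz_readout(t_null_norf, schedule, t1, protocol.readout_tr)
        out[ci] = state.signal
    return out


def synthesize_kspace(
    phantom: VesselPhantom,
    protocol: ProtocolTimings,
    schedule: FlipAngleSchedule,
    trajectory: RadialTrajectory,
    *,
    n_coils: int = 8,
    n_averages: int = 1,
    noise_sd: float = 0.0,
    b0_drift_rate: float = 0.0,
    t_null_norf: float = 0.100,
    t1_blood: float = 1.65,
    prep_deadtime: float = 1.0,
    seed: int = 0,
    dtype=np.complex128,
    coil_maps: np.ndarray | None = None,
    component_kspace: np.ndarray | None = None,
) -> RadialKspace:
    """Forward-model a full acquisition of the phantom.

    Per encoding and excitation, the instantaneous image is the sum of the
    vessel components (Hadamard-signed bolus signal) and the two tissue
    classes (saturation-recovery transverse signal), multiplied by the coil
    maps; each spoke samples the exact DFT of that image, with a global
    B0-drift phase (``b0_drift_rate`` rad/s, linear in acquisition time) and
    additive complex Gaussian noise of per-channel SD ``noise_sd``.
    """
    scheme = hadamard_encoding(protocol.n_blocks)
    if schedule.n_excitations != protocol.n_excitations:
        raise ValueError("schedule length must match the protocol")
    if trajectory.n_spokes % trajectory.spokes_per_frame:
        raise ValueError("n_spokes must be a multiple of spokes_per_frame")
    if trajectory.spokes_per_frame != protocol.excitations_per_frame:
        raise ValueError("spokes_per_frame must equal excitations_per_frame")
    rng = np.random.default_rng(seed)
    if coil_maps is None:
        coil_maps = make_coil_maps(phantom.matrix, n_coils)
    else:
        n_coils = coil_maps.shape[0]

    if component_kspace is None:
        component_kspace = component_kspace_cache(
            phantom, trajectory, coil_maps, dtype=dtype
        )
    k_comp = component_kspace  # [comp, spoke, sample, coil]
    n_comp = k_comp.shape[0]
    if n_comp != len(phantom.vessels) + len(TISSUE_T1_CLASSES):
        raise ValueError("component k-space does not match the phantom")
    if k_comp.shape[1] != trajectory.n_spokes:
        raise ValueError("component k-space does not match the trajectory")

    # per-encoding, per-excitation combination weights
    w = np.zeros((scheme.n_encodings, protocol.n_excitations, n_comp))
    w[:, :, : len(phantom.vessels)] = _vessel_weights(
        phantom, protocol, schedule, scheme, t1_blood
    )
    w[:, :, len(phantom.vessels):] = _tissue_weights(
        phantom, protocol, schedule, t_null_norf
    ).T[None]

    n_enc, n_frames = scheme.n_encodings, protocol.n_frames
    pos = trajectory.position_of_spoke
    exc_idx = (
        np.arange(n_frames)[:, None] * protocol.excitations_per_frame + pos[None, :]
    )  # [frame, spoke]
    w_frame = w[:, exc_idx]  # [enc, frame, spoke, comp]
    if dtype == np.complex64:
        w_frame = w_frame.astype(np.float32)
        k_comp = np.asarray(k_comp, dtype=np.complex64)
    k = np.einsum("efsc,csmq->efsmq", w_frame, k_comp)  # enc,frame,spoke,samp,coil
    k = np.broadcast_to(k[:, None], (n_enc, n_averages) + k.shape[1:]).astype(dtype)
    k = np.array(k)  # materialize

    if b0_drift_rate != 0.0:
        seg = trajectory.segment_of_spoke
        prep_period = protocol.readout_start + protocol.n_excitations * protocol.readout_tr + prep_deadtime
        prep_idx = (
            seg[None, None, :] * (n_enc * n_averages)
            + np.arange(n_enc)[:, None, None] * n_averages
            + np.arange(n_averages)[None, :, None]
        )  # [enc, avg, spoke]
        t_acq = (
            prep_idx[:, :, None, :] * prep_period
            + protocol.readout_start
            + exc_idx[None, None] * protocol.readout_tr
        )  # [enc, avg, frame, spoke]
        k *= np.exp(1j * b0_drift_rate * t_acq)[..., None, None].astype(dtype)

    if noise_sd > 0:
        noise = rng.standard_normal(k.shape + (2,))
        k += (noise_sd * (noise[..., 0] + 1j * noise[..., 1])).astype(dtype)

    meta = dict(
        scheme_label=schedule.scheme,
        protocol=protocol.name,
        noise_sd=noise_sd,
        b0_drift_rate=b0_drift_rate,
        t_null_norf=t_null_norf,
        seed=seed,
        n_averages=n_averages,
    )
    return RadialKspace(
        samples=k, trajectory=trajectory, protocol=protocol, scheme=scheme, meta=meta
    )
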