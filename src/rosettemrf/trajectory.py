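"""Rosette k-space trajectory: design, echo splitting, response function,
density compensation, and gradient feasibility checking.

The rosette readout follows the parametrization

    k(t) = kmax * sin(2 pi w1 t / T) * exp(2i pi w2 t / T),  t in [0, T],

where ``w1`` counts radial (in/out) oscillation cycles over the readout and
``w2`` rotational cycles.  With half-integer ``w1`` the envelope has
``2*w1 + 1`` zeros counting both endpoints, i.e. that many k-space-center
crossings ("echoes") and ``2*w1`` petals ("lobes").  The canonical cardiac
design uses kmax = 320 1/m, w1 = 11.5, w2 = 7.5 over an 18.4 ms readout at a
2.5 us dwell: 24 echoes from 23 lobes with a 117.39 deg rotation between
consecutive lobes, which approximates the golden angle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from rosettemrf.nufft import GriddingNUFFT

GAMMA_BAR_HZ_PER_T = 42.577478518e6  # proton gyromagnetic ratio / 2 pi

_SLEW_UNIT_TO_T_M_S = {"T/m/s": 1.0, "mT/m/s": 1e-3}


class InvalidParameterError(ValueError):
    """A trajectory design parameter is out of its valid domain."""


class DegenerateTrajectoryError(ValueError):
    """The trajectory lacks the structure an operation requires."""


class UnsupportedSegmentError(ValueError):
    """Operation requires a full (edge-to-edge) echo segment."""


@dataclass
class RosetteTrajectory:
    """One rosette readout.

    samples are complex k-space positions kx + i*ky in 1/m on a uniform time
    grid ``t_ms`` (ms from readout start), both endpoints included.
    """

    kmax: float
    w1_cycles: float
    w2_cycles: float
    readout_ms: float
    dt_us: float
    samples: np.ndarray = field(repr=False)
    t_ms: np.ndarray = field(repr=False)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def coords(self) -> np.ndarray:
        """(N, 2) array of (kx, ky) in 1/m."""
        return np.stack([self.samples.real, self.samples.imag], axis=1)

    def origin_crossing_times_ms(self) -> np.ndarray:
        """Times of the zeros of the radial envelope, including t=0."""
        n_cross = int(np.floor(2.0 * self.w1_cycles)) + 1
        return np.arange(n_cross) * self.readout_ms / (2.0 * self.w1_cycles)

    @property
    def n_origin_crossings(self) -> int:
        return self.origin_crossing_times_ms().size

    def lobe_rotation_deg(self) -> float:
        """Azimuthal rotation between consecutive lobes (degrees)."""
        return 180.0 * self.w2_cycles / self.w1_cycles


@dataclass
class EchoSegment:
    """Contiguous slice of a rosette readout containing one center crossing."""

    sample_index_range: tuple[int, int]  # half-open [start, stop)
    echo_time_ms: float
    is_full: bool

    def slice(self) -> slice:
        return slice(*self.sample_index_range)


@dataclass
class GradientLimits:
    gmax_mT_m: float = 43.0
    smax: float = 180.0
    smax_units: str = "mT/m/s"

    def __post_init__(self):
        if self.gmax_mT_m <= 0 or self.smax <= 0:
            raise InvalidParameterError("gradient limits must be positive")
        if self.smax_units not in _SLEW_UNIT_TO_T_M_S:
            raise InvalidParameterError(f"unknown slew unit {self.smax_units!r}")

    @property
    def smax_T_m_s(self) -> float:
        return self.smax * _SLEW_UNIT_TO_T_M_S[self.smax_units]


@dataclass
class GradientReport:
    peak_gradient_mT_m: float
    peak_slew_T_m_s: float
    gradient_ok: bool
    slew_ok: bool
    limits: GradientLimits


def generate_rosette(kmax: float = 320.0, w1_cycles: float = 11.5,
                     w2_cycles: float = 7.5, readout_ms: float = 18.4,
                     dt_us: float = 2.5,
                     rotation_deg: float = 0.0) -> RosetteTrajectory:
    """Generate a rosette readout on a uniform time grid.

    ``rotation_deg`` applies a global azimuthal rotation (used to rotate the
    whole trajectory between excitations).
    """
    for name, v in [("kmax", kmax), ("w1_cycles", w1_cycles),
                    ("w2_cycles", w2_cycles), ("readout_ms", readout_ms),
                    ("dt_us", dt_us)]:
        if not np.isfinite(v) or v <= 0:
            raise InvalidParameterError(f"{name} must be positive, got {v}")
    n = int(round(readout_ms * 1000.0 / dt_us))
    # >= 2 samples per lobe
    if n / (2.0 * w1_cycles) < 2.0:
        raise InvalidParameterError("dwell too coarse for the lobe count")
    t_ms = np.arange(n + 1) * dt_us * 1e-3  # include both endpoints
    u = t_ms / readout_ms
    k = kmax * np.sin(2 * np.pi * w1_cycles * u) * np.exp(2j * np.pi * w2_cycles * u)
    if rotation_deg:
        k = k * np.exp(1j * np.deg2rad(rotation_deg))
    return RosetteTrajectory(kmax=kmax, w1_cycles=w1_cycles, w2_cycles=w2_cycles,
                             readout_ms=readout_ms, dt_us=dt_us,
                             samples=k, t_ms=t_ms)


def split_into_echoes(traj: RosetteTrajectory, te1_ms: float = 0.0) -> list[EchoSegment]:
    """Partition the readout at the farthest k-space extents.

    One segment per center crossing; the first and last segments are partial
    (a single half-sweep) and flagged ``is_full=False``.  ``te1_ms`` offsets
    the reported echo times (time from excitation to readout start).
    """
    if traj.n_origin_crossings < 2:
        raise DegenerateTrajectoryError("trajectory has fewer than 2 center crossings")
    cross_ms = traj.origin_crossing_times_ms()
    half_lobe = traj.readout_ms / (2.0 * traj.w1_cycles) / 2.0
    # boundaries at the envelope extrema between crossings
    bounds_ms = cross_ms[:-1] + half_lobe
    bounds_idx = np.searchsorted(traj.t_ms, bounds_ms - 1e-9)
    edges = np.concatenate([[0], bounds_idx, [traj.n_samples]])
    segs = []
    n_seg = len(edges) - 1
    for i in range(n_seg):
        segs.append(EchoSegment(
            sample_index_range=(int(edges[i]), int(edges[i + 1])),
            echo_time_ms=float(te1_ms + cross_ms[i]),
            is_full=(0 < i < n_seg - 1),
        ))
    return segs


def response_function(traj: RosetteTrajectory, freq_hz: float,
                      density_weighted: bool = True,
                      weights: np.ndarray | None = None,
                      full_echoes_only: bool = True,
                      fov_m: float = 0.3) -> float:
    """Relative amplitude of an off-resonant spin after density-compensated
    gridding of the readout.

    The response is the magnitude of the (density-) weighted time average of
    ``exp(2i pi f t)``, normalized to the on-resonance (f=0) value, so it
    always lies in [0, 1] with response(0) = 1.  By default only the portion
    of the readout that enters reconstruction is included (the first and last
    partial echoes are dropped, as they are during gridding); with that
    convention fat at 220 Hz (1.5 T) is attenuated to about 3% for the
    canonical rosette.
    """
    if weights is None:
        if density_weighted:
            weights = _readout_density_weights(traj, fov_m)
        else:
            weights = np.ones(traj.n_samples)
    weights = np.asarray(weights, dtype=float)
    t_s = traj.t_ms * 1e-3
    if full_echoes_only and traj.n_origin_crossings >= 3:
        segs = split_into_echoes(traj)
        sl = slice(segs[1].sample_index_range[0], segs[-1].sample_index_range[0])
        weights, t_s = weights[sl], t_s[sl]
    num = np.abs(np.sum(weights * np.exp(2j * np.pi * freq_hz * t_s)))
    den = np.sum(weights)
    return float(num / den)


_DENSITY_CACHE: dict[tuple, np.ndarray] = {}


def _readout_density_weights(traj: RosetteTrajectory, fov_m: float) -> np.ndarray:
    key = (traj.kmax, traj.w1_cycles, traj.w2_cycles, traj.readout_ms,
           traj.dt_us, fov_m)
    if key not in _DENSITY_CACHE:
        n_grid = int(np.ceil(2.0 * traj.kmax * fov_m / 2.0)) * 2
        _DENSITY_CACHE[key] = compute_dcf_points(traj.coords, n_grid, fov_m)
    return _DENSITY_CACHE[key]


def compute_dcf_points(coords: np.ndarray, grid_size: int, fov_m: float = 0.3,
                       n_iter: int = 25) -> np.ndarray:
    """Iterative (Pipe-Menon style) density compensation for an arbitrary
    point set: w <- w / (C C^H w) with the gridding kernel as C.

    Returned weights are positive and normalized to sum to 1.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    plan = GriddingNUFFT(coords, grid_size, fov_m)
    w = np.ones(coords.shape[0])
    for _ in range(n_iter):
        dens = plan.P @ (plan.PH @ w.astype(plan.dtype))
        dens = np.abs(dens)
        dens[dens < 1e-12 * dens.max()] = 1e-12 * dens.max()
        w = w / dens
    w = np.maximum(np.real(w), 0.0)
    return w / w.sum()


def compute_dcf(segment: EchoSegment, traj: RosetteTrajectory,
                grid_size: int, fov_m: float = 0.3) -> np.ndarray:
    """Density compensation weights for one full echo segment."""
    if not segment.is_full:
        raise UnsupportedSegmentError("DCF is only defined for full segments")
    coords = traj.coords[segment.slice()]
    return compute_dcf_points(coords, grid_size, fov_m)


def check_gradient_feasibility(traj: RosetteTrajectory,
                               limits: GradientLimits,
                               gamma_bar_hz_t: float = GAMMA_BAR_HZ_PER_T) -> GradientReport:
    """Peak gradient and slew of the analytic trajectory by finite differences.

    G(t) = (dk/dt) / gamma_bar with k in 1/m gives G in T/m.
    """
    if traj.n_samples < 3:
        raise DegenerateTrajectoryError("need at least 3 samples for slew estimate")
    dt_s = traj.dt_us * 1e-6
    g = np.diff(traj.samples) / dt_s / gamma_bar_hz_t  # complex T/m
    slew = np.diff(g) / dt_s  # T/m/s
    peak_g = float(np.max(np.abs(g)))
    peak_s = float(np.max(np.abs(slew)))
    return GradientReport(
        peak_gradient_mT_m=peak_g * 1e3,
        peak_slew_T_m_s=peak_s,
        gradient_ok=peak_g * 1e3 <= limits.gmax_mT_m,
        slew_ok=peak_s <= limits.smax_T_m_s,
        limits=limits,
    )


# -- I/O ---------------------------------------------------------------------

def save_trajectory(path: str, traj: RosetteTrajectory) -> None:
    """Write an HDF5 dataset (N x 3: kx, ky, t_ms) plus a JSON sidecar of the
    design parameters (same path with .json suffix)."""
    import h5py

    with h5py.File(path, "w") as f:
        arr = np.column_stack([traj.samples.real, traj.samples.imag, traj.t_ms])
        f.create_dataset("trajectory", data=arr)
    meta = {"kmax": traj.kmax, "w1_cycles": traj.w1_cycles,
            "w2_cycles": traj.w2_cycles, "readout_ms": traj.readout_ms,
            "dt_us": traj.dt_us}
    with open(str(path) + ".json", "w") as f:
        json.dump(meta, f, indent=1)


def load_trajectory(path: str) -> RosetteTrajectory:
    import h5py

    with open(str(path) + ".json") as f:
        meta = json.load(f)
    with h5py.File(path, "r") as f:
        arr = f["trajectory"][:]
    return RosetteTrajectory(samples=arr[:, 0] + 1j * arr[:, 1], t_ms=arr[:, 2],
                             **meta)
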