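"""Multi-echo, subspace-constrained MRI encoding model.

Maps subspace-echo images x[s, e] (s = subspace coefficient from the
dictionary SVD, e = full rosette echo) to multi-coil k-space samples:

    y[n, m, c] = sum_s  phi[n, s] * NUFFT_{n,e(m)} ( C_c * P_e * x[s, e(m)] )

where phi is the temporal subspace basis row for excitation n, C_c the coil
sensitivity, and P_e = exp(2i pi b0 TE_e) the static off-resonance phase at
that echo's nominal time (one phase per echo; intra-echo dephasing is
accepted).  The trajectory of excitation n is the base rosette rotated by a
per-excitation angle, so each echo accumulates a well-distributed set of
petals over the scan.

A Toeplitz embedding of the normal operator A^H A is exposed for fast
iterative use: applying it costs two FFTs per (subspace, coil, echo) instead
of any per-sample interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy.fft import fft2, ifft2

from rosettemrf.nufft import GriddingNUFFT, ToeplitzKernel
from rosettemrf.trajectory import RosetteTrajectory, EchoSegment, split_into_echoes

GOLDEN_ANGLE_DEG = 180.0 * (3.0 - np.sqrt(5.0))  # 111.246...


@dataclass
class EchoImageSet:
    """Complex images indexed (subspace, echo, row, col)."""

    data: np.ndarray          # (rank, n_echoes, n, n)
    echo_times_ms: np.ndarray  # (n_echoes,)
    fov_mm: float = 300.0

    @property
    def rank(self) -> int:
        return self.data.shape[0]

    @property
    def n_echoes(self) -> int:
        return self.data.shape[1]

    @property
    def matrix(self) -> int:
        return self.data.shape[-1]


@dataclass
class KSpaceData:
    """Multi-coil k-space samples for every excitation of the scan."""

    samples: np.ndarray        # (n_exc, n_readout, n_coils) complex
    trajectory: RosetteTrajectory
    rotations_deg: np.ndarray  # (n_exc,) per-excitation trajectory rotation
    te1_ms: float = 1.74
    noise_sd: float = 0.0

    @property
    def n_excitations(self) -> int:
        return self.samples.shape[0]

    @property
    def n_coils(self) -> int:
        return self.samples.shape[2]

    def __post_init__(self):
        if self.samples.shape[1] != self.trajectory.n_samples:
            raise ValueError("sample count per excitation must equal trajectory length")


def default_rotations(n_excitations: int,
                      increment_deg: float = GOLDEN_ANGLE_DEG) -> np.ndarray:
    return (np.arange(n_excitations) * increment_deg) % 360.0


def save_kspace(path: str, ks: KSpaceData) -> None:
    import h5py
    from rosettemrf.trajectory import RosetteTrajectory as _RT

    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=ks.samples)
        f.create_dataset("rotations_deg", data=ks.rotations_deg)
        tr = f.create_group("trajectory")
        tr.create_dataset("samples", data=ks.trajectory.samples)
        tr.create_dataset("t_ms", data=ks.trajectory.t_ms)
        for key in ("kmax", "w1_cycles", "w2_cycles", "readout_ms", "dt_us"):
            tr.attrs[key] = getattr(ks.trajectory, key)
        f.attrs["te1_ms"] = ks.te1_ms
        f.attrs["noise_sd"] = ks.noise_sd


def load_kspace(path: str) -> KSpaceData:
    import h5py
    from rosettemrf.trajectory import RosetteTrajectory as _RT

    with h5py.File(path, "r") as f:
        tr = f["trajectory"]
        traj = _RT(samples=tr["samples"][:], t_ms=tr["t_ms"][:],
                   **{k: float(tr.attrs[k]) for k in
                      ("kmax", "w1_cycles", "w2_cycles", "readout_ms", "dt_us")})
        return KSpaceData(samples=f["samples"][:], trajectory=traj,
                          rotations_deg=f["rotations_deg"][:],
                          te1_ms=float(f.attrs["te1_ms"]),
                          noise_sd=float(f.attrs["noise_sd"]))


def _rotated_segment_coords(traj: RosetteTrajectory, seg: EchoSegment,
                            rotations_deg: np.ndarray) -> np.ndarray:
    """Aggregate (n_exc * m_e, 2) coordinates of one echo over all
    excitations (excitation-major order)."""
    k = traj.samples[seg.slice()]
    rot = np.exp(1j * np.deg2rad(rotations_deg))
    kk = (rot[:, None] * k[None, :]).ravel()
    return np.stack([kk.real, kk.imag], axis=1)


class EncodingOperator:
    """Subspace-echo forward model for a fixed trajectory/basis/field."""

    def __init__(self, traj: RosetteTrajectory, rotations_deg: np.ndarray,
                 basis: np.ndarray, n: int, fov_m: float = 0.3,
                 b0_hz: np.ndarray | None = None,
                 coil_maps: np.ndarray | None = None,
                 te1_ms: float = 1.74,
                 b0_correction: bool = True,
                 dtype=np.complex64):
        self.traj = traj
        self.rotations_deg = np.asarray(rotations_deg, dtype=float)
        self.basis = np.asarray(basis)
        self.n_exc, self.rank = self.basis.shape
        if self.rotations_deg.size != self.n_exc:
            raise ValueError("one rotation per excitation is required")
        self.n = int(n)
        self.fov_m = float(fov_m)
        self.dtype = np.dtype(dtype)
        segs = split_into_echoes(traj, te1_ms=te1_ms)
        self.segments = [s for s in segs if s.is_full]
        self.echo_times_ms = np.array([s.echo_time_ms for s in self.segments])
        self.n_echoes = len(self.segments)
        self.b0_hz = b0_hz if b0_hz is not None else np.zeros((n, n))
        self.b0_correction = bool(b0_correction)
        if coil_maps is None:
            coil_maps = np.ones((1, n, n), dtype=self.dtype)
        self.coil_maps = np.asarray(coil_maps, dtype=self.dtype)
        self.n_coils = self.coil_maps.shape[0]
        self.plans: list[GriddingNUFFT] = []
        for seg in self.segments:
            coords = _rotated_segment_coords(traj, seg, self.rotations_deg)
            self.plans.append(GriddingNUFFT(coords, n, fov_m, dtype=self.dtype))
        self._toeplitz: list[ToeplitzKernel] | None = None

    # -- helpers -----------------------------------------------------------
    def _phase(self, e: int) -> np.ndarray:
        if not self.b0_correction:
            return np.ones((self.n, self.n), dtype=self.dtype)
        te_s = self.echo_times_ms[e] * 1e-3
        return np.exp(2j * np.pi * self.b0_hz * te_s).astype(self.dtype)

    def _check(self, images: np.ndarray) -> None:
        exp = (self.rank, self.n_echoes, self.n, self.n)
        if images.shape != exp:
            raise ValueError(f"expected images of shape {exp}, got {images.shape}")

    # -- A and A^H ---------------------------------------------------------
    def forward(self, images: np.ndarray) -> list[np.ndarray]:
        """x (rank, E, n, n) -> per-echo samples, a list of E arrays of shape
        (n_exc, m_e, n_coils)."""
        self._check(images)
        out = []
        for e, plan in enumerate(self.plans):
            m_e = self.segments[e].sample_index_range[1] - self.segments[e].sample_index_range[0]
            img = images[:, e][:, None] * self.coil_maps[None] * self._phase(e)
            y = plan.forward(img)                    # (rank, C, n_exc * m_e)
            y = y.reshape(self.rank, self.n_coils, self.n_exc, m_e)
            ye = np.einsum("ns,scnm->nmc", self.basis.astype(self.dtype), y)
            out.append(np.ascontiguousarray(ye))
        return out

    def adjoint(self, data: list[np.ndarray],
                dcf: list[np.ndarray] | None = None) -> np.ndarray:
        """Per-echo samples -> images (rank, E, n, n); exact adjoint of
        :meth:`forward` when ``dcf`` is None."""
        img = np.zeros((self.rank, self.n_echoes, self.n, self.n), dtype=self.dtype)
        for e, plan in enumerate(self.plans):
            ye = data[e]
            if dcf is not None:
                ye = ye * dcf[e].reshape(self.n_exc, -1, 1).astype(self.dtype)
            z = np.einsum("ns,nmc->scnm", np.conj(self.basis).astype(self.dtype), ye)
            z = z.reshape(self.rank, self.n_coils, -1)
            im = plan.adjoint(z)                      # (rank, C, n, n)
            im = np.sum(np.conj(self.coil_maps)[None] * im, axis=1)
            img[:, e] = im * np.conj(self._phase(e))
        return img

    # -- Toeplitz normal operator -----------------------------------------
    def build_normal(self, dcf: list[np.ndarray] | None = None) -> None:
        """Precompute per-echo FFT kernels for A^H A (optionally A^H W A)."""
        self._toeplitz = []
        for e, seg in enumerate(self.segments):
            coords = self.plans[e].coords
            m_e = coords.shape[0] // self.n_exc
            # weights per (s, s') pair: conj(phi[n,s]) phi[n,s'] per sample
            phi = self.basis
            w = np.einsum("ns,nt->stn", np.conj(phi), phi)
            w = np.repeat(w[..., None], m_e, axis=-1).reshape(
                self.rank, self.rank, -1)
            if dcf is not None:
                w = w * dcf[e].reshape(1, 1, -1)
            self._toeplitz.append(
                ToeplitzKernel(coords, self.n, self.fov_m, weights=w,
                               dtype=self.dtype))

    def normal(self, images: np.ndarray) -> np.ndarray:
        """A^H A x via the Toeplitz embedding (build_normal first)."""
        if self._toeplitz is None:
            self.build_normal()
        self._check(images)
        out = np.empty_like(images, dtype=self.dtype)
        n, n2 = self.n, 2 * self.n
        for e, tk in enumerate(self._toeplitz):
            ph = self._phase(e)
            acc = np.zeros((self.rank, n, n), dtype=self.dtype)
            for c in range(self.n_coils):
                v = images[:, e] * (self.coil_maps[c] * ph)     # (rank, n, n)
                pad = np.zeros((self.rank, n2, n2), dtype=self.dtype)
                pad[:, :n, :n] = v
                spec = fft2(pad, axes=(-2, -1))
                mixed = np.einsum("styx,tyx->syx", tk.kern, spec)
                w = ifft2(mixed, axes=(-2, -1))[:, :n, :n]
                acc += w * np.conj(self.coil_maps[c] * ph)
            out[:, e] = acc
        return out

    def data_term(self, images: np.ndarray, b: np.ndarray,
                  y_norm_sq: float) -> tuple[float, np.ndarray]:
        """Least-squares data fidelity ||A x - y||^2 and its gradient
        2 (A^H A x - b), given b = A^H y."""
        ax = self.normal(images)
        val = float(np.real(np.vdot(images, ax)) - 2.0 * np.real(np.vdot(images, b))
                    + y_norm_sq)
        return max(val, 0.0), 2.0 * (ax - b)

    # -- convenience -------------------------------------------------------
    def extract_full_echo_data(self, ks: KSpaceData) -> list[np.ndarray]:
        """Slice a full-readout KSpaceData into the per-echo sample lists the
        operator works with."""
        segs_all = split_into_echoes(ks.trajectory)
        out = []
        for seg in segs_all:
            if seg.is_full:
                out.append(np.ascontiguousarray(ks.samples[:, seg.slice(), :]))
        return out


def forward(images: EchoImageSet, field, traj: RosetteTrajectory,
            basis, rotations_deg=None, **kw) -> list[np.ndarray]:
    """Functional wrapper around :class:`EncodingOperator`.forward."""
    op = _make_op(images.matrix, field, traj, basis, rotations_deg,
                  fov_m=images.fov_mm / 1000.0, **kw)
    return op.forward(images.data)


def adjoint(data: list[np.ndarray], field, traj: RosetteTrajectory, basis,
            n: int, rotations_deg=None, dcf=None, **kw) -> EchoImageSet:
    op = _make_op(n, field, traj, basis, rotations_deg, **kw)
    img = op.adjoint(data, dcf=dcf)
    return EchoImageSet(data=img, echo_times_ms=op.echo_times_ms,
                        fov_mm=op.fov_m * 1000.0)


def _make_op(n, field, traj, basis, rotations_deg, fov_m=0.3, **kw):
    if rotations_deg is None:
        rotations_deg = default_rotations(np.asarray(basis).shape[0])
    b0 = getattr(field, "b0_hz", None)
    coils = getattr(field, "coil_maps", None)
    return EncodingOperator(traj, rotations_deg, basis, n, fov_m=fov_m,
                            b0_hz=b0, coil_maps=coils, **kw)
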