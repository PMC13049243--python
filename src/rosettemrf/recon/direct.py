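"""Direct (gridding) reconstruction of subspace-echo images.

The classic MRF reconstruction: project the k-space data of each excitation
onto the temporal subspace, grid each echo's aggregated samples with density
compensation, and combine coils with conjugate sensitivities.
"""

from __future__ import annotations

import warnings

import numpy as np

from rosettemrf.nufft import GriddingNUFFT
from rosettemrf.operators import (EchoImageSet, EncodingOperator, KSpaceData,
                                  default_rotations, _rotated_segment_coords)
from rosettemrf.trajectory import compute_dcf_points, split_into_echoes


def make_echo_dcf(traj, rotations_deg, n: int, fov_m: float = 0.3) -> list[np.ndarray]:
    """Aggregated density-compensation weights for each full echo."""
    segs = [s for s in split_into_echoes(traj) if s.is_full]
    out = []
    for seg in segs:
        coords = _rotated_segment_coords(traj, seg, rotations_deg)
        out.append(compute_dcf_points(coords, n, fov_m))
    return out


def grid_subspace_echoes(kspace: KSpaceData, traj, basis, n: int,
                         fov_m: float = 0.3, rotations_deg=None,
                         dcf: list[np.ndarray] | None = None) -> np.ndarray:
    """Per-coil gridded subspace-echo images, shape (C, rank, E, n, n)."""
    basis = np.asarray(basis)
    if rotations_deg is None:
        rotations_deg = kspace.rotations_deg
    segs = [s for s in split_into_echoes(traj, te1_ms=kspace.te1_ms) if s.is_full]
    if dcf is None:
        dcf = make_echo_dcf(traj, rotations_deg, n, fov_m)
    rank = basis.shape[1]
    n_coils = kspace.n_coils
    out = np.zeros((n_coils, rank, len(segs), n, n), dtype=np.complex64)
    for e, seg in enumerate(segs):
        coords = _rotated_segment_coords(traj, seg, rotations_deg)
        plan = GriddingNUFFT(coords, n, fov_m, dtype=np.complex64)
        ye = kspace.samples[:, seg.slice(), :]          # (n_exc, m_e, C)
        w = dcf[e].reshape(ye.shape[0], ye.shape[1], 1)
        z = np.einsum("ns,nmc->scnm", np.conj(basis), ye * w)
        img = plan.adjoint(z.reshape(rank * n_coils, -1).astype(np.complex64))
        out[:, :, e] = img.reshape(rank, n_coils, n, n).transpose(1, 0, 2, 3)
    return out


def recon_direct(kspace: KSpaceData, field, traj, basis, n: int,
                 fov_m: float = 0.3, rotations_deg=None,
                 dcf: list[np.ndarray] | None = None) -> EchoImageSet:
    """Direct gridding reconstruction with coil combination and per-echo
    B0 demodulation."""
    basis = np.asarray(basis)
    if rotations_deg is None:
        rotations_deg = kspace.rotations_deg
    coil_maps = getattr(field, "coil_maps", None)
    if coil_maps is None:
        warnings.warn("no coil maps supplied; falling back to RSS-style "
                      "unit sensitivities")
        coil_maps = np.ones((kspace.n_coils, n, n), dtype=complex)
    op = EncodingOperator(traj, rotations_deg, basis, n, fov_m=fov_m,
                          b0_hz=getattr(field, "b0_hz", None),
                          coil_maps=coil_maps, te1_ms=kspace.te1_ms,
                          dtype=np.complex64)
    if dcf is None:
        dcf = make_echo_dcf(traj, rotations_deg, n, fov_m)
    data = op.extract_full_echo_data(kspace)
    dcf_exp = [w.reshape(op.n_exc, -1) for w in dcf]
    img = op.adjoint(data, dcf=dcf_exp)
    return EchoImageSet(data=img, echo_times_ms=op.echo_times_ms,
                        fov_mm=fov_m * 1000.0)
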