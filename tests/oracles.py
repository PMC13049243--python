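"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's EPG/NUFFT code paths: the Bloch
oracle integrates individual isochromats; the Fourier oracle is an explicit
non-uniform DFT sum.
"""

from __future__ import annotations

import numpy as np


def isochromat_fingerprint(t1_ms, t2_ms, schedule, n_spins=500):
    """Brute-force FISP fingerprint: n_spins isochromats with a uniform 2*pi
    intra-voxel gradient twist per TR and ideal preparation pulses.

    Returns the complex mean transverse magnetization immediately after each
    RF pulse (rotation about x), matching the package's signal convention.
    """
    theta = 2 * np.pi * (np.arange(n_spins) + 0.5) / n_spins
    M = np.zeros((3, n_spins))
    M[2] = 1.0
    e1 = np.exp(-schedule.tr_ms / t1_ms)
    e2 = np.exp(-schedule.tr_ms / t2_ms)
    eff = schedule.inversion_efficiency
    out = np.empty(schedule.n_excitations, dtype=complex)
    exc = 0
    for h in range(schedule.n_heartbeats):
        prep = schedule.prep_events[h]
        if prep.kind == "inversion":
            M[0] = M[1] = 0.0
            M[2] *= -eff
        elif prep.kind == "t2prep":
            M[0] = M[1] = 0.0
            M[2] *= np.exp(-prep.te_ms / t2_ms)
        for _ in range(schedule.exc_per_heartbeat):
            a = np.deg2rad(schedule.flip_deg[exc])
            ca, sa = np.cos(a), np.sin(a)
            my = ca * M[1] - sa * M[2]
            mz = sa * M[1] + ca * M[2]
            M[1], M[2] = my, mz
            out[exc] = np.mean(M[0] + 1j * M[1])
            # relaxation over TR, then the spoiling twist about z
            M[0] *= e2
            M[1] *= e2
            M[2] = 1.0 + (M[2] - 1.0) * e1
            ct, st = np.cos(theta), np.sin(theta)
            mx = ct * M[0] - st * M[1]
            my = st * M[0] + ct * M[1]
            M[0], M[1] = mx, my
            exc += 1
        trec = schedule.rr_ms[h] - schedule.exc_per_heartbeat * schedule.tr_ms
        M[0] = M[1] = 0.0
        M[2] = 1.0 + (M[2] - 1.0) * np.exp(-trec / t1_ms)
    return out


def nudft2(coords, img, fov_m):
    """Explicit non-uniform DFT of a 2D image (oracle for the gridding NUFFT)."""
    img = np.asarray(img, dtype=complex)
    n = img.shape[-1]
    r = (np.arange(n) - n // 2) * fov_m / n
    ry, rx = np.meshgrid(r, r, indexing="ij")
    ph = np.exp(-2j * np.pi * (coords[:, 0, None] * rx.ravel()[None, :]
                               + coords[:, 1, None] * ry.ravel()[None, :]))
    return img.reshape(-1, n * n) @ ph.T


def brute_force_match(subspace_signals, compressed_dict):
    """Exhaustive normalized-correlation matching, one voxel at a time."""
    winners = []
    for v in subspace_signals.T:
        c = np.abs(np.conj(compressed_dict) @ v)
        winners.append(int(np.argmax(c)))
    return np.array(winners)
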