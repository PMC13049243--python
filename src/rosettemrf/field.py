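"""Static off-resonance (B0) and coil-sensitivity estimation.

Both are pre-computed from direct-gridded echo images of the first cMRF
subspace.  B0 is estimated by a discrete VARPRO-style search over candidate
field offsets with Markov-random-field smoothing (iterated conditional
modes), which resolves the water/fat period ambiguity by preferring spatially
smooth solutions; a final parabolic refinement gives sub-grid accuracy.
Coil maps use Walsh-style adaptive combination: the principal eigenvector of
the local signal covariance, root-sum-of-squares normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
import warnings

import numpy as np
from scipy.ndimage import gaussian_filter, uniform_filter

from rosettemrf.operators import KSpaceData


class InsufficientEchoesError(ValueError):
    pass


@dataclass
class FieldModel:
    b0_hz: np.ndarray                  # (n, n)
    coil_maps: np.ndarray              # (C, n, n) complex, RSS = 1 in mask
    fat_shift_hz: float = 220.0
    mask: np.ndarray | None = None

    def __post_init__(self):
        if not np.all(np.isfinite(self.b0_hz)):
            raise ValueError("b0 map contains non-finite values")


def support_mask(echo_images: np.ndarray, threshold: float = 0.05) -> np.ndarray:
    """Support from thresholding the RSS first-echo image at 5% of max."""
    first = echo_images[..., 0, :, :] if echo_images.ndim == 4 else echo_images[0]
    rss = np.sqrt(np.sum(np.abs(np.atleast_3d(first).reshape(-1, *first.shape[-2:])) ** 2,
                         axis=0))
    return rss > threshold * rss.max()


def echo_images_first_subspace(kspace: KSpaceData, traj, basis,
                               n: int, fov_m: float = 0.3,
                               rotations_deg=None,
                               dcf: list[np.ndarray] | None = None) -> np.ndarray:
    """Direct-gridded per-echo images of the first subspace, per coil.

    Returns (C, E, n, n): the k-space of each full echo, aggregated over all
    excitations with subspace-1 projection weights and density compensation,
    gridded onto the image grid.
    """
    from rosettemrf.recon.direct import grid_subspace_echoes

    imgs = grid_subspace_echoes(kspace, traj, np.asarray(basis)[:, :1], n,
                                fov_m=fov_m, rotations_deg=rotations_deg,
                                dcf=dcf)
    return imgs[:, 0]  # (C, E, n, n)


def _varpro_residual(echo_images: np.ndarray, te_s: np.ndarray,
                     psi_hz: np.ndarray, fat_shift_hz: float,
                     fat_model: bool = True) -> np.ndarray:
    """Residual energy of the (water[, fat]) fit per candidate field.

    echo_images: (E, n, n); returns (n_psi, n, n).
    """
    E = te_s.size
    S = echo_images.reshape(E, -1)
    cols = [np.ones(E, dtype=complex)]
    if fat_model:
        cols.append(np.exp(2j * np.pi * fat_shift_hz * te_s))
    A = np.stack(cols, axis=1)
    Q, _ = np.linalg.qr(A)
    total = np.sum(np.abs(S) ** 2, axis=0)
    out = np.empty((psi_hz.size,) + echo_images.shape[1:])
    for i, p in enumerate(psi_hz):
        D = S * np.exp(-2j * np.pi * p * te_s)[:, None]
        proj = Q.conj().T @ D
        out[i] = (total - np.sum(np.abs(proj) ** 2, axis=0)).reshape(
            echo_images.shape[1:])
    return np.maximum(out, 0.0)


def estimate_b0(echo_images: np.ndarray, echo_times_ms: np.ndarray,
                fat_shift_hz: float = 220.0,
                n_candidates: int = 121,
                smooth_weight: float = 1.0,
                n_icm: int = 20,
                smooth_sigma_px: float = 2.0,
                mask: np.ndarray | None = None) -> np.ndarray:
    """Off-resonance map (Hz) from coil-combined echo images.

    Discrete candidates span the unambiguous band +-1/(2 dTE); the smooth
    solution is selected by ICM on a 4-neighborhood with a quadratic penalty,
    then refined parabolically between candidates.
    """
    echo_images = np.asarray(echo_images)
    if echo_images.shape[0] < 3:
        raise InsufficientEchoesError("at least 3 echoes are required")
    te_s = np.asarray(echo_times_ms, dtype=float) * 1e-3
    dte = float(np.median(np.diff(te_s)))
    band = 1.0 / (2.0 * dte)
    # candidate step divides the fat shift exactly, so the water solution and
    # its fat-swapped twin sit at identical off-grid offsets and the |psi|
    # tie-break acts on equal footing
    approx = 2.0 * band / max(n_candidates - 1, 1)
    step = fat_shift_hz / max(round(fat_shift_hz / approx), 1)
    psi = np.arange(-band, band + step / 2, step)
    R = _varpro_residual(echo_images, te_s, psi, fat_shift_hz)
    if mask is None:
        mask = support_mask(echo_images[None])
    scale = np.mean(R.min(axis=0)[mask]) + np.mean(R.max(axis=0)[mask]) * 1e-3
    U = R / (scale + 1e-30)
    # In the noiseless single-voxel problem the water solution at psi and the
    # swapped (all-fat) solution at psi - fat_shift are exactly degenerate;
    # a small penalty on |psi| breaks the tie toward the water-dominant
    # reading for fields within +-fat_shift/2 of center.
    U = U + 0.02 * (psi[:, None, None] / band) ** 2

    # Propagation runs over the full grid: background voxels carry small
    # residuals, so the smoothness term interpolates the field across gaps
    # between disconnected objects; the mask is applied only at the end.
    allpix = np.ones_like(mask, dtype=bool)
    lab = _region_grow_labels(U, psi, allpix, band, smooth_weight,
                              echo_images)
    n_p = psi.size
    # ICM with a quadratic neighbor penalty; the scale is chosen so that a
    # fat-shift-sized jump between neighbors is comparable to the unary
    # term while smooth gradients of a few Hz are essentially free.
    scale0 = band / 4.0
    for _ in range(n_icm):
        f = psi[lab]
        cost = U.copy()
        for ax, sh in ((0, 1), (0, -1), (1, 1), (1, -1)):
            rolled = np.roll(f, sh, axis=ax)
            # robust (truncated) penalty: disagreeing neighbors saturate
            # instead of dragging the voxel to a mid-branch compromise
            pen = ((psi[:, None, None] - rolled[None]) / scale0) ** 2
            cost += smooth_weight * np.minimum(pen, 2.0)
        new_lab = np.argmin(cost, axis=0)
        if np.array_equal(new_lab, lab):
            break
        lab = new_lab
    # parabolic refinement between neighboring candidates
    l0 = np.clip(lab, 1, n_p - 2)
    ii, jj = np.indices(lab.shape)
    r_m, r_0, r_p = U[l0 - 1, ii, jj], U[l0, ii, jj], U[l0 + 1, ii, jj]
    denom = r_m - 2 * r_0 + r_p
    delta = np.where(np.abs(denom) > 1e-12, 0.5 * (r_m - r_p) / (denom + 1e-30), 0.0)
    delta = np.clip(delta, -0.5, 0.5)
    b0 = psi[l0] + delta * (psi[1] - psi[0])
    # Resolve the global water/fat branch: the whole solution can sit on the
    # swapped sheet (offset by one fat shift).  Pick the global offset under
    # which the water column explains the most signal energy.
    E = te_s.size
    S = echo_images.reshape(E, -1)
    amp2 = (np.abs(S[0]) ** 2) * mask.reshape(-1)
    fat_col = np.exp(2j * np.pi * fat_shift_hz * te_s)
    best_off, best_share = 0.0, -np.inf
    for off in (0.0, -fat_shift_hz, fat_shift_hz):
        dem = S * np.exp(-2j * np.pi * (b0.reshape(-1)[None, :] + off)
                         * te_s[:, None])
        w_amp = np.abs(dem.mean(axis=0))
        f_amp = np.abs((dem * np.conj(fat_col)[:, None]).mean(axis=0))
        share = float(np.sum(amp2 * w_amp**2)
                      / max(np.sum(amp2 * (w_amp**2 + f_amp**2)), 1e-30))
        if share > best_share:
            best_share, best_off = share, off
    b0 = b0 + best_off

    # per-object refinement of the same decision: disconnected structures
    # can sit on their own swapped sheet
    from scipy.ndimage import label as cc_label

    strong = amp2.reshape(b0.shape) > (0.1 ** 2) * amp2.max()
    comps, n_comp = cc_label(strong)
    b0_flat = b0.reshape(-1)
    U_flat = U.reshape(n_p, -1)
    step = psi[1] - psi[0]
    win = max(int(round(40.0 / step)), 2)
    A2 = np.stack([np.ones(E, dtype=complex), fat_col], axis=1)
    Q2, _ = np.linalg.qr(A2)

    def _resid_share(S_sel, w, v):
        dem = S_sel * np.exp(-2j * np.pi * v[None, :] * te_s[:, None])
        proj = Q2.conj().T @ dem
        resid = np.sum(np.abs(S_sel) ** 2, axis=0) - np.sum(np.abs(proj) ** 2,
                                                            axis=0)
        w_amp = np.abs(dem.mean(axis=0))
        f_amp = np.abs((dem * np.conj(fat_col)[:, None]).mean(axis=0))
        share = float(np.sum(w * w_amp**2)
                      / max(np.sum(w * (w_amp**2 + f_amp**2)), 1e-30))
        return float(np.sum(w * np.maximum(resid, 0.0))), share

    for ci in range(1, n_comp + 1):
        sel = (comps == ci).reshape(-1)
        if sel.sum() < 4:
            continue
        w = amp2[sel]
        S_sel = S[:, sel]
        Uc = U_flat[:, sel]
        curve = Uc @ w
        is_min = np.r_[False, (curve[1:-1] < curve[:-2])
                       & (curve[1:-1] <= curve[2:]), False]
        cand = np.where(is_min & (curve <= curve[is_min].min() * 2.0))[0] \
            if np.any(is_min) else np.array([int(np.argmin(curve))])
        # score every candidate single-branch assignment against the current
        # (possibly smooth and correct) one: weighted residual with a water
        # share bonus; the current assignment wins unless a branch clearly
        # explains the data better
        r_cur, s_cur = _resid_share(S_sel, w, b0_flat[sel])
        norm = max(r_cur, 1e-30)
        best_score, best_v = r_cur / norm - 0.3 * s_cur, None
        for c0 in cand:
            lo, hi = max(c0 - win, 0), min(c0 + win + 1, n_p)
            loc = lo + np.argmin(Uc[lo:hi], axis=0)
            l0c = np.clip(loc, 1, n_p - 2)
            cols_c = np.arange(loc.size)
            rm_c, r0_c, rp_c = (Uc[l0c - 1, cols_c], Uc[l0c, cols_c],
                                Uc[l0c + 1, cols_c])
            den_c = rm_c - 2 * r0_c + rp_c
            dd = np.where(np.abs(den_c) > 1e-12,
                          0.5 * (rm_c - rp_c) / (den_c + 1e-30), 0.0)
            v = psi[l0c] + np.clip(dd, -0.5, 0.5) * step
            r_v, s_v = _resid_share(S_sel, w, v)
            score = r_v / norm - 0.3 * s_v
            if score < best_score:
                best_score, best_v = score, v
        if best_v is not None:
            b0_flat[sel] = best_v
    b0 = b0_flat.reshape(b0.shape)

    if smooth_sigma_px > 0:
        # the static field is spatially smooth; signal-amplitude-weighted
        # smoothing removes per-voxel estimation jitter without letting
        # noise-only background voxels bias the field inside objects
        w = (np.abs(echo_images[0]) ** 2) * mask
        num = gaussian_filter(b0 * w, smooth_sigma_px)
        den = gaussian_filter(w, smooth_sigma_px)
        b0 = np.where(den > 1e-12 * den.max(),
                      num / np.maximum(den, 1e-30), b0)
    # weak-signal voxels carry essentially unconstrained estimates; replace
    # them with a smooth extrapolation of the strong-signal field so that
    # downstream phase corrections never see wild values
    amp_img = np.abs(echo_images[0])
    strong2 = amp_img > 0.1 * amp_img.max()
    ws = (amp_img**2) * strong2
    num = gaussian_filter(b0 * ws, 8.0)
    den = gaussian_filter(ws, 8.0)
    bg = np.where(den > 1e-20 * max(den.max(), 1e-30),
                  num / np.maximum(den, 1e-30), 0.0)
    b0 = np.where(strong2, b0, bg)
    b0 = np.where(mask, b0, 0.0)
    return b0


def _region_grow_labels(U: np.ndarray, psi: np.ndarray, mask: np.ndarray,
                        band: float, smooth_weight: float,
                        echo_images: np.ndarray) -> np.ndarray:
    """Greedy seeded growth: starting from the brightest voxel, each voxel
    picks the candidate minimizing its own residual plus a quadratic
    attachment to the mean field of already-assigned neighbors.  This
    resolves the global water/fat swap degeneracy coherently."""
    from collections import deque

    n_p, H, W = U.shape
    scale0 = band / 4.0
    amp = np.abs(echo_images[0])
    lab = np.argmin(U, axis=0)
    assigned = np.zeros((H, W), dtype=bool)
    seed = np.unravel_index(np.argmax(np.where(mask, amp, -1)), amp.shape)
    assigned[seed] = True
    field = psi[lab].astype(float)
    queue = deque([seed])
    offs = ((1, 0), (-1, 0), (0, 1), (0, -1))
    while queue:
        y, x = queue.popleft()
        for dy, dx in offs:
            yy, xx = y + dy, x + dx
            if 0 <= yy < H and 0 <= xx < W and mask[yy, xx] and not assigned[yy, xx]:
                nb = [(yy + a, xx + b) for a, b in offs
                      if 0 <= yy + a < H and 0 <= xx + b < W
                      and assigned[yy + a, xx + b]]
                cost = U[:, yy, xx].copy()
                for p in nb:
                    pen = ((psi - field[p]) / scale0) ** 2
                    cost += smooth_weight * np.minimum(pen, 2.0)
                k = int(np.argmin(cost))
                lab[yy, xx] = k
                field[yy, xx] = psi[k]
                assigned[yy, xx] = True
                queue.append((yy, xx))
    return lab


def estimate_coils(echo_images: np.ndarray, block: int = 7,
                   mask: np.ndarray | None = None) -> np.ndarray:
    """Walsh adaptive-combine coil maps from (C, E, n, n) echo images.

    Principal eigenvector of the spatially smoothed sample covariance over
    echoes, RSS-normalized, phase-referenced to the first coil.
    """
    echo_images = np.asarray(echo_images)
    if echo_images.ndim == 3:
        echo_images = echo_images[None]
    C = echo_images.shape[0]
    n = echo_images.shape[-1]
    if C == 1:
        warnings.warn("single-coil input: returning identity sensitivity map")
        return np.ones((1, n, n), dtype=complex)
    # covariance over echoes, smoothed over a local block
    cov = np.einsum("ceyx,deyx->cdyx", echo_images, np.conj(echo_images))
    cov = uniform_filter(cov.real, size=(1, 1, block, block)) + \
        1j * uniform_filter(cov.imag, size=(1, 1, block, block))
    covm = np.moveaxis(cov, (0, 1), (2, 3)).reshape(-1, C, C)
    vals, vecs = np.linalg.eigh(covm)
    v = vecs[:, :, -1]                       # principal eigenvector per voxel
    ref = v[:, 0]
    phase = np.where(np.abs(ref) > 0, ref / np.maximum(np.abs(ref), 1e-30), 1.0)
    v = v * np.conj(phase)[:, None]
    rss = np.linalg.norm(v, axis=1)
    v = v / np.maximum(rss, 1e-30)[:, None]
    maps = np.moveaxis(v.reshape(n, n, C), 2, 0)
    if mask is not None:
        maps = maps * mask[None]
    return maps


def combine_coils(echo_images: np.ndarray, coil_maps: np.ndarray) -> np.ndarray:
    """Sensitivity-weighted coil combination: sum_c conj(C_c) * img_c."""
    return np.einsum("cyx,c...yx->...yx", np.conj(coil_maps), echo_images)
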