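"""Iterative reconstruction with locally-low-rank and total-variation
regularization.

Minimizes  ||A x - y||^2 + lambda_llr * sum_patches ||P_b x||_*
                         + lambda_tv * TV(x)
by proximal gradient descent with backtracking on the full objective (the
data gradient uses the Toeplitz normal operator; the two proximal maps are
applied sequentially).  With both weights zero the problem is quadratic and
is solved directly by conjugate gradients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from rosettemrf.operators import EchoImageSet, EncodingOperator, KSpaceData


class ConvergenceError(RuntimeError):
    pass


@dataclass
class LowRankConfig:
    lambda_llr: float = 0.0
    lambda_tv: float = 0.0
    patch: int = 8
    iterations: int = 30
    tv_inner: int = 10

    def __post_init__(self):
        if self.lambda_llr < 0 or self.lambda_tv < 0:
            raise ValueError("regularization weights must be non-negative")


def _patchify(x: np.ndarray, p: int) -> np.ndarray:
    """(rank, E, n, n) -> (n_patches, p*p, rank*E)."""
    rank, E, n, _ = x.shape
    q = n // p
    v = x.reshape(rank * E, q, p, q, p)
    v = v.transpose(1, 3, 2, 4, 0).reshape(q * q, p * p, rank * E)
    return v

def _unpatchify(v: np.ndarray, rank: int, E: int, n: int, p: int) -> np.ndarray:
    q = n // p
    x = v.reshape(q, q, p, p, rank * E).transpose(4, 0, 2, 1, 3)
    return x.reshape(rank, E, n, n)


def llr_nuclear_norm(x: np.ndarray, p: int) -> float:
    v = _patchify(x, p)
    s = np.linalg.svd(v, compute_uv=False)
    return float(s.sum())


def prox_llr(x: np.ndarray, tau: float, p: int) -> np.ndarray:
    """Singular-value soft thresholding on non-overlapping patches."""
    rank, E, n, _ = x.shape
    v = _patchify(x, p)
    u, s, vh = np.linalg.svd(v, full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    v = (u * s[:, None, :]) @ vh
    return _unpatchify(v, rank, E, n, p)


def tv_value(x: np.ndarray) -> float:
    gx = np.diff(x, axis=-1)
    gy = np.diff(x, axis=-2)
    return float(np.sum(np.abs(gx)) + np.sum(np.abs(gy)))


def prox_tv(x: np.ndarray, tau: float, n_inner: int = 10) -> np.ndarray:
    """Anisotropic TV proximal map by dual projected gradient (per channel,
    real and imaginary parts treated jointly as complex)."""
    if tau == 0:
        return x
    px = np.zeros_like(x[..., :, :-1])
    py = np.zeros_like(x[..., :-1, :])
    step = 0.25
    z = x
    for _ in range(n_inner):
        gx = np.diff(z, axis=-1)
        gy = np.diff(z, axis=-2)
        px = px + step / tau * gx
        py = py + step / tau * gy
        px = px / np.maximum(1.0, np.abs(px))
        py = py / np.maximum(1.0, np.abs(py))
        div = np.zeros_like(x)
        div[..., :, :-1] -= px
        div[..., :, 1:] += px
        div[..., :-1, :] -= py
        div[..., 1:, :] += py
        z = x - tau * div
    return z


def _cg_solve(op: EncodingOperator, b: np.ndarray, n_iter: int,
              tol: float = 1e-8) -> np.ndarray:
    x = np.zeros_like(b)
    r = b.copy()
    p = r.copy()
    rs = np.real(np.vdot(r, r))
    for _ in range(n_iter):
        ap = op.normal(p)
        alpha = rs / max(np.real(np.vdot(p, ap)), 1e-30)
        x = x + alpha * p
        r = r - alpha * ap
        rs_new = np.real(np.vdot(r, r))
        if rs_new < tol * np.real(np.vdot(b, b)):
            break
        p = r + (rs_new / max(rs, 1e-30)) * p
        rs = rs_new
    return x


def recon_lowrank(kspace: KSpaceData, field, traj, basis, n: int,
                  cfg: LowRankConfig | None = None, fov_m: float = 0.3,
                  rotations_deg=None, op: EncodingOperator | None = None,
                  return_objective: bool = False):
    """Locally-low-rank + TV regularized reconstruction."""
    cfg = cfg or LowRankConfig()
    basis = np.asarray(basis)
    if rotations_deg is None:
        rotations_deg = kspace.rotations_deg
    if op is None:
        op = EncodingOperator(traj, rotations_deg, basis, n, fov_m=fov_m,
                              b0_hz=getattr(field, "b0_hz", None),
                              coil_maps=getattr(field, "coil_maps", None),
                              te1_ms=kspace.te1_ms, dtype=np.complex64)
    data = op.extract_full_echo_data(kspace)
    b = op.adjoint(data)
    y_sq = float(sum(np.sum(np.abs(d) ** 2) for d in data))
    op.build_normal()

    if cfg.lambda_llr == 0 and cfg.lambda_tv == 0:
        x = _cg_solve(op, b, cfg.iterations)
        images = EchoImageSet(data=x, echo_times_ms=op.echo_times_ms,
                              fov_mm=fov_m * 1000.0)
        return (images, None) if return_objective else images

    # Lipschitz estimate of A^H A by power iteration
    rng = np.random.default_rng(0)
    v = (rng.standard_normal(b.shape) + 1j * rng.standard_normal(b.shape)
         ).astype(np.complex64)
    for _ in range(8):
        v = op.normal(v)
        v = v / np.linalg.norm(v)
    lip = float(np.real(np.vdot(v, op.normal(v))))
    tau = 1.0 / (2.0 * lip)

    def objective(x):
        val, _ = op.data_term(x, b, y_sq)
        if cfg.lambda_llr:
            val += cfg.lambda_llr * llr_nuclear_norm(x, cfg.patch)
        if cfg.lambda_tv:
            val += cfg.lambda_tv * tv_value(x)
        return val

    x = np.zeros_like(b)
    obj = [objective(x)]
    for it in range(cfg.iterations):
        _, grad = op.data_term(x, b, y_sq)
        step = tau
        for _ in range(12):
            xn = x - step * grad
            if cfg.lambda_llr:
                xn = prox_llr(xn, step * cfg.lambda_llr, cfg.patch)
            if cfg.lambda_tv:
                xn = prox_tv(xn, step * cfg.lambda_tv, cfg.tv_inner)
            fn = objective(xn)
            if fn <= obj[-1] * (1.0 + 1e-9) + 1e-12:
                break
            step *= 0.5
        else:
            raise ConvergenceError(
                f"objective increased at iteration {it} despite backtracking")
        x = xn.astype(np.complex64)
        obj.append(fn)
    images = EchoImageSet(data=x, echo_times_ms=op.echo_times_ms,
                          fov_mm=fov_m * 1000.0)
    return (images, np.asarray(obj)) if return_objective else images
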