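"""Deep-image-prior reconstruction of subspace-echo images.

A per-scan, untrained convolutional generator maps a fixed 32-channel noise
field to the full set of subspace-echo images (2 real channels per complex
image, subspace-major / echo-minor ordering).  Its parameters are optimized
so that the images, pushed through the cMRF encoding model (coils, per-echo
B0 phase progression, subspace expansion, NUFFT), match the acquired k-space
in the least-squares sense.  No training data or stored weights are
involved; dropout (7%) is active during optimization and disabled for the
final inference pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from rosettemrf.operators import EchoImageSet, EncodingOperator, KSpaceData
from rosettemrf.recon.nn import Adam, DIPUNet


class DivergenceError(RuntimeError):
    pass


@dataclass
class DIPConfig:
    input_channels: int = 32
    conv_channels: int = 128
    levels: int = 5
    dropout_rate: float = 0.07
    iterations: int = 100
    learning_rate: float = 1e-2
    seed: int = 0
    b0_correction: bool = True
    dcf_weighted_loss: bool = True
    output_init_scale: float = 0.01
    precond_power: float = 1.0
    adam_beta2: float = 0.999
    noise_scale: float = 1.0
    warmstart_fraction: float = 0.0
    log_path: str | None = None

    def __post_init__(self):
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def to_complex(channels: np.ndarray, rank: int, n_echoes: int) -> np.ndarray:
    """(2*rank*E, n, n) real channels -> (rank, E, n, n) complex images."""
    n = channels.shape[-1]
    c = channels.reshape(2, rank, n_echoes, n, n)
    return (c[0] + 1j * c[1]).astype(np.complex64)


def to_channels(images: np.ndarray) -> np.ndarray:
    """(rank, E, n, n) complex -> (2*rank*E, n, n) real channels."""
    rank, E, n, _ = images.shape
    out = np.empty((2, rank, E, n, n), dtype=np.float32)
    out[0] = images.real
    out[1] = images.imag
    return out.reshape(2 * rank * E, n, n)


def recon_dip(kspace: KSpaceData, field, traj, basis, n: int,
              cfg: DIPConfig | None = None, fov_m: float = 0.3,
              rotations_deg=None, op: EncodingOperator | None = None,
              return_history: bool = False):
    """Reconstruct subspace-echo images with the deep image prior.

    Deterministic for a fixed ``cfg.seed``.  When ``return_history`` is set,
    also returns the per-iteration loss and the intermediate images saved at
    each iteration (inference passes, dropout off).
    """
    cfg = cfg or DIPConfig()
    basis = np.asarray(basis)
    if rotations_deg is None:
        rotations_deg = kspace.rotations_deg
    if op is None:
        op = EncodingOperator(traj, rotations_deg, basis, n, fov_m=fov_m,
                              b0_hz=getattr(field, "b0_hz", None),
                              coil_maps=getattr(field, "coil_maps", None),
                              te1_ms=kspace.te1_ms,
                              b0_correction=cfg.b0_correction,
                              dtype=np.complex64)
    data = op.extract_full_echo_data(kspace)
    if cfg.dcf_weighted_loss:
        from rosettemrf.recon.direct import make_echo_dcf

        dcf = make_echo_dcf(kspace.trajectory, rotations_deg, n, fov_m)
        dcf_exp = [w.reshape(op.n_exc, -1) for w in dcf]
        b = op.adjoint(data, dcf=dcf_exp)
        y_sq = float(sum(np.sum(w.reshape(op.n_exc, -1, 1) * np.abs(d) ** 2)
                         for w, d in zip(dcf_exp, data)))
        if op._toeplitz is None:
            op.build_normal(dcf=dcf)
    else:
        b = op.adjoint(data)
        y_sq = float(sum(np.sum(np.abs(d) ** 2) for d in data))
        if op._toeplitz is None:
            op.build_normal()
    m_tot = float(sum(d.size for d in data))
    scale = float(np.abs(b).max())
    if scale == 0:
        scale = 1.0
    b = (b / scale).astype(np.complex64)
    y_sq /= scale**2
    # Subspace preconditioning: the generator produces each component in
    # units of that component's own data power (diagonal scaling by the
    # norms of the density-compensated adjoint), so weak high-order
    # subspace coefficients receive comparable effective learning rates.
    # The scaling is applied through the u -> alpha*u change of variables so
    # the (shareable) Toeplitz kernels stay untouched.
    alpha = np.linalg.norm(b.reshape(op.rank, -1), axis=1)
    alpha = np.maximum(alpha / max(alpha.max(), 1e-30), 1e-3) ** cfg.precond_power
    alpha = alpha.astype(np.float32)[:, None, None, None]
    # target of the warm-start phase: the adjoint image in generator units
    ws_target = (b / alpha).astype(np.complex64)
    # renormalize the preconditioned target to unit peak so the generator
    # output works at a consistent scale regardless of the spectrum
    scale2 = float(np.abs(b * alpha).max())
    if scale2 > 0:
        b = (b / scale2).astype(np.complex64)
        ws_target /= scale2
        scale *= scale2
        y_sq /= scale2**2

    rank, E = op.rank, op.n_echoes
    rng = np.random.default_rng(cfg.seed)
    net = DIPUNet(c_in=cfg.input_channels, c_mid=cfg.conv_channels,
                  c_out=2 * rank * E, levels=cfg.levels,
                  dropout=cfg.dropout_rate, rng=rng)
    # start the generator output small so optimization grows into the data
    net.out_conv.W.value *= cfg.output_init_scale
    z = (rng.standard_normal((cfg.input_channels, n, n))
         * cfg.noise_scale).astype(np.float32)
    optim = Adam(net.params, lr=cfg.learning_rate, beta2=cfg.adam_beta2)

    mfac = 1.0 if cfg.dcf_weighted_loss else m_tot
    # The first iterations regress the generator onto the density-compensated
    # adjoint image (the gradient of the weighted data term at zero), which
    # is cheap per step; the remainder minimize the full encoding-model loss.
    n_ws = int(round(cfg.warmstart_fraction * cfg.iterations))
    ws_scale = 1.0 / max(float(np.linalg.norm(ws_target)), 1e-30)
    losses = []
    history = []
    log_rows = []
    for it in range(cfg.iterations):
        if it == n_ws and n_ws > 0:
            optim = Adam(net.params, lr=cfg.learning_rate,
                         beta2=cfg.adam_beta2)
        out = net.forward(z, train=True)
        u = to_complex(out, rank, E)
        if it < n_ws:
            diff = u - ws_target
            loss = float(np.sum(np.abs(diff) ** 2))
            gx = (2.0 * ws_scale) * diff
        else:
            loss, gx = op.data_term(u * alpha, b, y_sq)
            gx = gx * alpha
        loss /= mfac
        if not np.isfinite(loss):
            raise DivergenceError(f"non-finite loss at iteration {it}: {loss}")
        losses.append(loss)
        net.backward(to_channels(gx / mfac))
        optim.step()
        optim.zero_grad()
        log_rows.append((it, loss))
        if return_history:
            xi = to_complex(net.forward(z, train=False), rank, E)
            history.append(xi * alpha * scale)
    final = to_complex(net.forward(z, train=False), rank, E) * alpha * scale
    if cfg.log_path:
        with open(cfg.log_path, "w") as f:
            f.write("iteration,loss\n")
            for it, lo in log_rows:
                f.write(f"{it},{lo:.8e}\n")
    images = EchoImageSet(data=final, echo_times_ms=op.echo_times_ms,
                          fov_mm=fov_m * 1000.0)
    if return_history:
        return images, np.asarray(losses), history
    return images, np.asarray(losses)
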