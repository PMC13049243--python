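"""Extended-phase-graph (EPG) simulation of the FISP cMRF fingerprint.

One fingerprint is the complex transverse signal (the F0 configuration
immediately after each RF pulse) over the 180 excitations of the 15-heartbeat
schedule.  The unbalanced FISP gradient advances the configuration order by
one per TR; magnetization preparations are modeled as instantaneous:
inversion scales longitudinal states by -efficiency, a T2-preparation of
duration TE scales them by exp(-TE/T2).  Echo-dimension effects (T2* decay,
fat chemical shift) are deliberately not part of the fingerprint - they are
applied along the readout by the phantom simulator and removed by the
mapping stages - so the fingerprint carries the T1/T2 contrast only.

The engine is vectorized over dictionary entries; ``simulate_fingerprint``
is the single-entry convenience wrapper.  An independent isochromat-summation
oracle (brute-force Bloch simulation with ideal spoiling) lives in the test
suite and pins this engine to within 1%.
"""

from __future__ import annotations

import numpy as np

from rosettemrf.sequence import AcquisitionSchedule, RFPulseSpec


class ValidityError(ValueError):
    """Requested relaxation pair violates T2 <= T1."""


def _rf_matrix(alpha_rad: np.ndarray, phi_rad: float = 0.0) -> np.ndarray:
    """EPG RF mixing matrices, shape (..., 3, 3) for flip angles ``alpha``."""
    a = np.asarray(alpha_rad)
    co2, si2 = np.cos(a / 2) ** 2, np.sin(a / 2) ** 2
    sa, ca = np.sin(a), np.cos(a)
    e_p = np.exp(1j * phi_rad)
    T = np.empty(a.shape + (3, 3), dtype=complex)
    T[..., 0, 0] = co2
    T[..., 0, 1] = e_p**2 * si2
    T[..., 0, 2] = -1j * e_p * sa
    T[..., 1, 0] = np.conj(e_p) ** 2 * si2
    T[..., 1, 1] = co2
    T[..., 1, 2] = 1j * np.conj(e_p) * sa
    T[..., 2, 0] = -0.5j * np.conj(e_p) * sa
    T[..., 2, 1] = 0.5j * e_p * sa
    T[..., 2, 2] = ca
    return T


def simulate_fingerprints(t1_ms: np.ndarray, t2_ms: np.ndarray,
                          schedule: AcquisitionSchedule,
                          rf: RFPulseSpec | None = None,
                          n_states: int = 36,
                          flip_scales: np.ndarray | None = None,
                          dtype=np.complex128) -> np.ndarray:
    """Simulate fingerprints for a batch of (T1, T2) pairs.

    Parameters
    ----------
    t1_ms, t2_ms : arrays of shape (N,)
    rf : optional pulse spec; when ``rf.n_subslices > 1`` the fingerprint is
        the average over sub-slice fingerprints simulated at the
        slice-profile-scaled flip angles.
    flip_scales : optional explicit per-subslice flip scale factors
        (overrides ``rf``).
    n_states : EPG configuration-order truncation.

    Returns
    -------
    (N, n_excitations) complex array of un-normalized signals
    (unit equilibrium magnetization).
    """
    t1 = np.atleast_1d(np.asarray(t1_ms, dtype=float))
    t2 = np.atleast_1d(np.asarray(t2_ms, dtype=float))
    if np.any(t2 > t1):
        raise ValidityError("entries with T2 > T1 are not physical here")
    if np.any(t2 <= 0):
        raise ValidityError("T2 must be positive")

    if flip_scales is None:
        if rf is not None and rf.n_subslices > 1:
            from rosettemrf.dictionary import slice_profile_weights
            flip_scales = slice_profile_weights(rf, 1.0)
        else:
            flip_scales = np.array([1.0])
    flip_scales = np.atleast_1d(np.asarray(flip_scales, dtype=float))

    sig = np.zeros((t1.size, schedule.n_excitations), dtype=dtype)
    for sc in flip_scales:
        sig += _simulate_once(t1, t2, schedule, sc, n_states, dtype)
    return sig / flip_scales.size


def _simulate_once(t1, t2, schedule, flip_scale, n_states, dtype):
    N = t1.size
    K = n_states
    Fp = np.zeros((K, N), dtype=dtype)
    Fm = np.zeros((K, N), dtype=dtype)
    Z = np.zeros((K, N), dtype=dtype)
    Z[0] = 1.0

    e1_tr = np.exp(-schedule.tr_ms / t1)
    e2_tr = np.exp(-schedule.tr_ms / t2)
    eff = schedule.inversion_efficiency
    out = np.empty((N, schedule.n_excitations), dtype=dtype)

    Ts = _rf_matrix(np.deg2rad(schedule.flip_deg * flip_scale))
    exc = 0
    for h in range(schedule.n_heartbeats):
        prep = schedule.prep_events[h]
        if prep.kind == "inversion":
            Fp[:] = 0.0
            Fm[:] = 0.0
            Z *= -eff
        elif prep.kind == "t2prep":
            Fp[:] = 0.0
            Fm[:] = 0.0
            Z *= np.exp(-prep.te_ms / t2)
        for _ in range(schedule.exc_per_heartbeat):
            T = Ts[exc]
            Fp, Fm, Z = (
                T[0, 0] * Fp + T[0, 1] * Fm + T[0, 2] * Z,
                T[1, 0] * Fp + T[1, 1] * Fm + T[1, 2] * Z,
                T[2, 0] * Fp + T[2, 1] * Fm + T[2, 2] * Z,
            )
            out[:, exc] = Fp[0]
            # relaxation over TR, then the unbalanced-gradient shift
            Fp *= e2_tr
            Fm *= e2_tr
            Z *= e1_tr
            Z[0] += 1.0 - e1_tr
            Fp[1:] = Fp[:-1]
            Fm[:-1] = Fm[1:]
            Fm[-1] = 0.0
            Fp[0] = np.conj(Fm[0])
            exc += 1
        # free recovery to the next R-wave; transverse states are spoiled
        # and decay for many T2 over the several-hundred-ms gap
        trec = schedule.rr_ms[h] - schedule.exc_per_heartbeat * schedule.tr_ms
        e1_rec = np.exp(-trec / t1)
        e2_rec = np.exp(-trec / t2)
        Fp *= e2_rec
        Fm *= e2_rec
        Z *= e1_rec
        Z[0] += 1.0 - e1_rec
    return out


def simulate_fingerprint(t1_ms: float, t2_ms: float,
                         schedule: AcquisitionSchedule,
                         rf: RFPulseSpec | None = None,
                         n_states: int = 36) -> np.ndarray:
    """Fingerprint for a single (T1, T2) pair; see ``simulate_fingerprints``."""
    if t2_ms > t1_ms:
        raise ValidityError(f"T2 ({t2_ms}) exceeds T1 ({t1_ms})")
    return simulate_fingerprints(
        np.array([t1_ms]), np.array([t2_ms]), schedule, rf=rf,
        n_states=n_states,
    )[0]
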