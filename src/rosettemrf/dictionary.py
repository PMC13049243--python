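"""cMRF dictionary: (T1,T2) grid enumeration, fingerprint simulation,
slice-profile correction, and SVD subspace compression.

The canonical grids are T1 = (10:10:2000, 2020:20:3000) ms and
T2 = (6:2:100, 105:5:300, 310:10:500, 540:40:1180) ms; keeping only pairs
with T2 <= T1 yields 28 010 entries.  Stored fingerprints are unit-L2
normalized with the norms kept separately (pattern matching uses the unit
atoms; spin-density estimation divides the projection by the stored norm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from rosettemrf.epg import simulate_fingerprints
from rosettemrf.sequence import AcquisitionSchedule, RFPulseSpec


def _span(start: float, step: float, stop: float) -> np.ndarray:
    """Inclusive range start:step:stop (values exceeding stop are dropped)."""
    n = int(np.floor((stop - start) / step + 1e-9)) + 1
    return start + step * np.arange(n)


def default_t1_grid_ms() -> np.ndarray:
    return np.concatenate([_span(10, 10, 2000), _span(2020, 20, 3000)])


def default_t2_grid_ms() -> np.ndarray:
    return np.concatenate([
        _span(6, 2, 100), _span(105, 5, 300), _span(310, 10, 500),
        _span(540, 40, 1200),
    ])


@dataclass
class DictionaryConfig:
    t1_grid_ms: np.ndarray = field(default_factory=default_t1_grid_ms)
    t2_grid_ms: np.ndarray = field(default_factory=default_t2_grid_ms)
    inversion_efficiency: float = 0.95
    n_states: int = 36

    def __post_init__(self):
        for g in (self.t1_grid_ms, self.t2_grid_ms):
            if len(g) == 0:
                raise ValueError("empty relaxation grid")
            if np.any(np.diff(g) <= 0):
                raise ValueError("grids must be strictly increasing")
        if not (0.0 < self.inversion_efficiency <= 1.0):
            raise ValueError("inversion efficiency must lie in (0, 1]")

    def enumerate_entries(self) -> np.ndarray:
        """All (T1, T2) pairs with T2 <= T1, T1-major order."""
        t1g, t2g = np.meshgrid(self.t1_grid_ms, self.t2_grid_ms, indexing="ij")
        keep = t2g <= t1g
        return np.column_stack([t1g[keep], t2g[keep]])


@dataclass
class Dictionary:
    entries: np.ndarray               # (N, 2) T1, T2 in ms
    signals: np.ndarray               # (N, n_exc) unit-normalized fingerprints
    norms: np.ndarray                 # (N,) original L2 norms
    schedule: AcquisitionSchedule | None = None

    @property
    def n_entries(self) -> int:
        return self.entries.shape[0]


@dataclass
class SubspaceBasis:
    basis: np.ndarray  # (n_exc, rank) orthonormal columns
    rank: int

    def project(self, signals: np.ndarray) -> np.ndarray:
        """(..., n_exc) -> (..., rank) subspace coefficients."""
        return signals @ np.conj(self.basis)

    def expand(self, coeffs: np.ndarray) -> np.ndarray:
        return coeffs @ self.basis.T


def slice_profile_weights(rf: RFPulseSpec, nominal_flip_deg: float = 1.0,
                          n_time: int = 512) -> np.ndarray:
    """Per-subslice effective flip angles from the small-tip Fourier profile
    of a Hann-windowed sinc pulse.

    The slice is discretized at ``rf.n_subslices`` positions uniformly across
    the nominal slice width (the pulse bandwidth TBP / duration mapped through
    the slice-select gradient).  Returns effective flips in the units of
    ``nominal_flip_deg``; their mean never exceeds the nominal flip.
    """
    n_sub = rf.n_subslices
    if n_sub == 1:
        return np.asarray([nominal_flip_deg], dtype=float)
    tau = rf.duration_us * 1e-6
    t = (np.arange(n_time) + 0.5) / n_time * tau - tau / 2
    bw = rf.time_bandwidth / tau
    env = np.sinc(bw * t) * np.hanning(n_time)
    # fractional slice positions; frequency offset f = x * bw across the slice
    x = (np.arange(n_sub) + 0.5) / n_sub - 0.5
    freqs = x * bw
    prof = np.abs(env[None, :] @ np.exp(-2j * np.pi * freqs[:, None] * t[None, :]).T).ravel()
    prof = prof / prof.max()
    return nominal_flip_deg * prof


def build_dictionary(cfg: DictionaryConfig, schedule: AcquisitionSchedule,
                     rf: RFPulseSpec | None = None,
                     dtype=np.complex64) -> Dictionary:
    """Simulate fingerprints for every valid grid pair and normalize them."""
    entries = cfg.enumerate_entries()
    if entries.shape[0] == 0:
        raise ValueError("no valid (T1, T2) entries")
    sched = schedule
    if schedule.inversion_efficiency != cfg.inversion_efficiency:
        from dataclasses import replace
        sched = replace(schedule, inversion_efficiency=cfg.inversion_efficiency)
    sig = simulate_fingerprints(entries[:, 0], entries[:, 1], sched, rf=rf,
                                n_states=cfg.n_states, dtype=dtype)
    norms = np.linalg.norm(sig, axis=1)
    norms[norms == 0] = 1.0
    return Dictionary(entries=entries, signals=sig / norms[:, None],
                      norms=norms, schedule=sched)


def compress(dictionary: Dictionary, rank: int = 10) -> tuple[SubspaceBasis, np.ndarray]:
    """Rank-``rank`` temporal SVD basis of the dictionary and the compressed
    (N, rank) fingerprints."""
    n, t = dictionary.signals.shape
    if rank > min(n, t):
        raise ValueError(f"rank {rank} exceeds dictionary dimensions {n}x{t}")
    # right singular vectors of the N x T signal matrix
    _, _, vh = np.linalg.svd(dictionary.signals.astype(np.complex128),
                             full_matrices=False)
    basis = np.ascontiguousarray(vh[:rank].conj().T)  # (T, rank)
    compressed = dictionary.signals @ np.conj(basis)
    return SubspaceBasis(basis=basis, rank=rank), compressed


def save_dictionary(path: str, dictionary: Dictionary,
                    basis: SubspaceBasis | None = None) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("entries", data=dictionary.entries)
        f.create_dataset("signals", data=dictionary.signals)
        f.create_dataset("norms", data=dictionary.norms)
        if basis is not None:
            f.create_dataset("basis", data=basis.basis)


def load_dictionary(path: str) -> tuple[Dictionary, SubspaceBasis | None]:
    import h5py

    with h5py.File(path, "r") as f:
        d = Dictionary(entries=f["entries"][:], signals=f["signals"][:],
                       norms=f["norms"][:])
        basis = None
        if "basis" in f:
            b = f["basis"][:]
            basis = SubspaceBasis(basis=b, rank=b.shape[1])
    return d, basis
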