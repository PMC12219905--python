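"""Per-acquisition signal databases over a (T1, T2) relaxometry grid.

The training database for the personalized network is built by simulating the
subject's exact MOLLI acquisition for every (T1, T2) combination on a regular
grid spanning the physiological native range (T1 600–2000 ms, T2 20–400 ms),
excluding unrealistic combinations (T1 < T2, T2 < 20 ms).  Each noiseless
signal is then replicated with independent Gaussian noise instances at a
target SNR, and normalized to unit L2 norm per 8-sample vector — the same
normalization applied to scanner pixels at inference time.

Grid endpoint convention: T1 is half-open [t1_min, t1_max), T2 closed
[t2_min, t2_max].  With the defaults this gives 280 x 77 = 21,560 entries at
5 ms steps, 1400 x 381 = 533,400 at 1 ms, and 14 x 77 = 1,078 with a 100 ms
T1 step — the only convention consistent with all three sizes at once.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .bloch import SequenceParams, SignalVector, simulate_molli_signals

__all__ = [
    "GridSpec",
    "NoiseConfig",
    "SignalDatabase",
    "enumerate_grid",
    "build_database",
    "augment_with_noise",
    "normalize_signal",
    "normalize_database",
]


@dataclass(frozen=True)
class GridSpec:
    """Regular (T1, T2) grid with physiological exclusion rules."""

    t1_min: float = 600.0
    t1_max: float = 2000.0
    t1_step: float = 5.0
    t2_min: float = 20.0
    t2_max: float = 400.0
    t2_step: float = 5.0
    #: exclusion rules, fixed: drop T1 < T2 and T2 < 20 ms
    exclude_t1_below_t2: bool = True
    t2_floor: float = 20.0

    def __post_init__(self) -> None:
        if self.t1_step <= 0 or self.t2_step <= 0:
            raise ValueError("grid steps must be positive")
        if self.t1_max <= self.t1_min or self.t2_max < self.t2_min:
            raise ValueError("grid ranges are empty")

    @property
    def t1_values(self) -> np.ndarray:
        n = int(np.ceil((self.t1_max - self.t1_min) / self.t1_step - 1e-9))
        return self.t1_min + self.t1_step * np.arange(n)

    @property
    def t2_values(self) -> np.ndarray:
        n = int(np.floor((self.t2_max - self.t2_min) / self.t2_step + 1e-9)) + 1
        return self.t2_min + self.t2_step * np.arange(n)


@dataclass(frozen=True)
class NoiseConfig:
    """Gaussian noise augmentation: n_instances copies per entry at given SNR.

    The noise standard deviation for an entry is its noiseless maximum sample
    divided by ``snr`` (reference_amplitude rule "max"), matching an
    ROI-measured SNR on the brightest image.
    """

    snr: float = 40.0
    n_instances: int = 10
    seed: int = 0
    reference_amplitude: str = "max"

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.n_instances < 1:
            raise ValueError("n_instances must be >= 1")
        if self.reference_amplitude != "max":
            raise ValueError("only the 'max' reference-amplitude rule is implemented")


@dataclass
class SignalDatabase:
    """Simulated MOLLI signals indexed by ground-truth (T1, T2)."""

    t1: np.ndarray            # (N,) ms
    t2: np.ndarray            # (N,) ms
    signals: np.ndarray       # (N, 8) magnitudes
    tis: np.ndarray           # (8,) effective TIs, acquisition order, ms
    schedule_fingerprint: str
    grid_spec: GridSpec | None = None
    noise_config: NoiseConfig | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.t1 = np.asarray(self.t1, dtype=float)
        self.t2 = np.asarray(self.t2, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        self.tis = np.asarray(self.tis, dtype=float)
        if not (len(self.t1) == len(self.t2) == len(self.signals)):
            raise ValueError("t1, t2 and signals must have equal length")
        if self.signals.ndim != 2 or self.signals.shape[1] != len(self.tis):
            raise ValueError("signals must be (N, n_images) matching the TI vector")

    def __len__(self) -> int:
        return len(self.t1)

    def subset(self, index: np.ndarray) -> "SignalDatabase":
        return replace(self, t1=self.t1[index], t2=self.t2[index],
                       signals=self.signals[index])


def enumerate_grid(spec: GridSpec) -> np.ndarray:
    """All (T1, T2) pairs of the grid, T1-major ascending, exclusions removed.

    Returns an (N, 2) array.  Raises if the grid is empty.
    """
    t1v, t2v = spec.t1_values, spec.t2_values
    T1, T2 = np.meshgrid(t1v, t2v, indexing="ij")
    pairs = np.column_stack([T1.ravel(), T2.ravel()])
    keep = np.ones(len(pairs), dtype=bool)
    if spec.exclude_t1_below_t2:
        keep &= pairs[:, 0] >= pairs[:, 1]
    keep &= pairs[:, 1] >= spec.t2_floor
    pairs = pairs[keep]
    if len(pairs) == 0:
        raise ValueError("grid specification yields no (T1, T2) pairs")
    return pairs


def build_database(schedule, params: SequenceParams, spec: GridSpec,
                   chunk_size: int = 20000) -> SignalDatabase:
    """Simulate the noiseless signal database for one acquisition.

    Entries are produced in grid order; the result records the schedule
    fingerprint so a train/apply mismatch is detectable downstream.  Large
    grids are simulated in chunks to bound the propagator working set.
    """
    pairs = enumerate_grid(spec)
    out = np.empty((len(pairs), schedule.n_images))
    for start in range(0, len(pairs), chunk_size):
        sl = slice(start, start + chunk_size)
        try:
            out[sl] = simulate_molli_signals(schedule, params,
                                             pairs[sl, 0], pairs[sl, 1])
        except ValueError as exc:
            raise RuntimeError(
                f"simulation failed within entries {sl.start}..{sl.stop}: {exc}"
            ) from exc
    return SignalDatabase(
        t1=pairs[:, 0], t2=pairs[:, 1], signals=out,
        tis=schedule.effective_tis,
        schedule_fingerprint=schedule.fingerprint(),
        grid_spec=spec,
    )


def augment_with_noise(db: SignalDatabase, noise: NoiseConfig) -> SignalDatabase:
    """Replace each entry by ``n_instances`` noisy copies (labels preserved).

    Noise is i.i.d. Gaussian on every magnitude sample with standard deviation
    (entry max sample) / snr, clipped at zero since magnitudes cannot go
    negative.  Seeded and reproducible.
    """
    if db.noise_config is not None:
        raise ValueError("database is already noise-augmented")
    n = noise.n_instances
    sigma = db.signals.max(axis=1) / noise.snr       # (N,)
    rng = np.random.default_rng(noise.seed)
    if np.isfinite(noise.snr):
        draws = rng.standard_normal((len(db), n, db.signals.shape[1]))
        noisy = db.signals[:, None, :] + sigma[:, None, None] * draws
        np.clip(noisy, 0.0, None, out=noisy)
    else:
        noisy = np.broadcast_to(db.signals[:, None, :],
                                (len(db), n, db.signals.shape[1])).copy()
    return replace(
        db,
        t1=np.repeat(db.t1, n),
        t2=np.repeat(db.t2, n),
        signals=noisy.reshape(len(db) * n, -1),
        noise_config=noise,
    )


def normalize_rows(signals: np.ndarray) -> np.ndarray:
    """Divide each row by its L2 norm; raises on an all-zero row."""
    signals = np.asarray(signals, dtype=float)
    norms = np.linalg.norm(signals, axis=-1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("cannot normalize an all-zero signal vector")
    return signals / norms


def normalize_signal(v: SignalVector) -> SignalVector:
    """Unit-L2 normalization of one signal vector (scale-invariant input)."""
    if v.normalized:
        return v
    return SignalVector(
        magnitudes=normalize_rows(v.magnitudes[None, :])[0],
        effective_tis=v.effective_tis,
        sorted_by_ti=v.sorted_by_ti,
        normalized=True,
    )


def normalize_database(db: SignalDatabase) -> SignalDatabase:
    if db.normalized:
        return db
    return replace(db, signals=normalize_rows(db.signals), normalized=True)
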