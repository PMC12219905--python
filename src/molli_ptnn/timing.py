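"""ECG trigger series and MOLLI acquisition scheduling.

MOLLI schemes are ECG-gated: every interval in the sequence is expressed in
heartbeats, so the absolute timing of each single-shot image — and hence its
effective inversion time — is dictated by the subject's R-wave trigger times.
This module turns a trigger series plus a scheme label such as ``"5(3)3"``
into an absolute event timeline with one inversion per acquisition group and
one readout per imaged heartbeat.

Conventions: time is in milliseconds, with t = 0 at the first trigger.  The
readout center of an imaged heartbeat sits ``trigger_delay`` ms after its
R-wave (end-diastole); the inversion of group *g* is played
``ti_offsets[g]`` ms before the readout center of the group's first image,
so the k-th image of the group has effective TI equal to the offset plus the
sum of the k intervening RR intervals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TriggerSeries",
    "MolliScheme",
    "TiConfig",
    "ImageEvent",
    "MolliSchedule",
    "synthesize_triggers",
    "build_schedule",
    "read_trigger_csv",
    "write_trigger_csv",
]

#: Shortest physiologically acceptable RR interval (ms); ~300 bpm guard.
MIN_RR_MS = 200.0
#: Truncation floor for synthetic RR draws (ms).
SYNTH_RR_FLOOR_MS = 300.0


@dataclass(frozen=True)
class TriggerSeries:
    """Ordered R-wave instants (ms), strictly increasing."""

    times: tuple[float, ...]
    source: str = "recorded"
    seed: int | None = None

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        object.__setattr__(self, "times", times)
        if len(times) < 2:
            raise ValueError("a trigger series needs at least 2 R-waves")
        rr = np.diff(times)
        if np.any(rr <= MIN_RR_MS):
            raise ValueError(
                f"all RR intervals must exceed {MIN_RR_MS:g} ms; got min {rr.min():g} ms"
            )
        if self.source not in ("recorded", "synthetic"):
            raise ValueError(f"unknown trigger source tag {self.source!r}")

    @property
    def rr_intervals(self) -> np.ndarray:
        """Successive RR intervals, ms."""
        return np.diff(self.times)

    def __len__(self) -> int:
        return len(self.times)


_SCHEME_RE = re.compile(r"^(\d+)(?:\((\d+)\))?(?=(?:\d|$))")


def _parse_scheme_label(label: str) -> tuple[tuple[int, int], ...]:
    """Parse e.g. ``"5(3)3"`` into ((5, 3), (3, 0)) [(n_acq, pause), ...]."""
    groups: list[tuple[int, int]] = []
    rest = label.strip()
    while rest:
        m = _SCHEME_RE.match(rest)
        if not m:
            raise ValueError(f"cannot parse MOLLI scheme label {label!r}")
        n_acq = int(m.group(1))
        pause = int(m.group(2)) if m.group(2) is not None else 0
        groups.append((n_acq, pause))
        rest = rest[m.end():]
    if not groups:
        raise ValueError(f"empty MOLLI scheme label {label!r}")
    return tuple(groups)


@dataclass(frozen=True)
class MolliScheme:
    """A MOLLI scheme: ordered (n_acquisitions, pause_heartbeats) groups.

    The conventional label writes acquisition counts outside parentheses and
    recovery pauses inside, e.g. 5(3)3 = 5 images, 3 pause beats, 3 images.
    """

    groups: tuple[tuple[int, int], ...]
    label: str

    @classmethod
    def from_label(cls, label: str) -> "MolliScheme":
        return cls(groups=_parse_scheme_label(label), label=label.strip())

    def __post_init__(self) -> None:
        if not self.groups or any(n < 1 or p < 0 for n, p in self.groups):
            raise ValueError("every group needs n_acquisitions >= 1 and pause >= 0")
        if _parse_scheme_label(self.label) != tuple(self.groups):
            raise ValueError(f"label {self.label!r} does not round-trip to {self.groups}")

    @property
    def n_images(self) -> int:
        return sum(n for n, _ in self.groups)

    @property
    def heartbeats_spanned(self) -> int:
        """Total heartbeats from first inversion through the last acquisition."""
        return sum(n + p for n, p in self.groups)


@dataclass(frozen=True)
class TiConfig:
    """Scanner-side timing knobs: initial TI offset per group and trigger delay.

    These are not determined by the scheme itself; defaults follow common
    clinical MOLLI settings (minimum TIs of 100/180 ms, readout at
    end-diastole ~500 ms after the R-wave).
    """

    ti_offsets_per_group: tuple[float, ...] = (100.0, 180.0)
    trigger_delay: float = 500.0

    def __post_init__(self) -> None:
        if any(o <= 0 for o in self.ti_offsets_per_group):
            raise ValueError("TI offsets must be positive")
        if self.trigger_delay < 0:
            raise ValueError("trigger delay must be non-negative")


@dataclass(frozen=True)
class ImageEvent:
    """One single-shot image: which group/heartbeat, when, and at what TI."""

    group: int
    heartbeat: int          # global heartbeat index, 0 = first trigger
    readout_center_abs: float  # ms
    effective_ti: float        # ms


@dataclass(frozen=True)
class MolliSchedule:
    """Absolute event timeline for one MOLLI acquisition."""

    scheme: MolliScheme
    triggers: TriggerSeries
    ti_config: TiConfig
    inversion_times_abs: tuple[float, ...]   # one per group, ms
    image_events: tuple[ImageEvent, ...]

    @property
    def effective_tis(self) -> np.ndarray:
        """Effective TIs in acquisition order (group-major), ms."""
        return np.array([e.effective_ti for e in self.image_events])

    @property
    def n_images(self) -> int:
        return len(self.image_events)

    @property
    def heartbeats_spanned(self) -> int:
        return self.scheme.heartbeats_spanned

    def fingerprint(self) -> str:
        """Stable hash of the timing that shapes the signal (scheme + events)."""
        import hashlib

        h = hashlib.sha256()
        h.update(self.scheme.label.encode())
        h.update(np.asarray(self.triggers.times, dtype=np.float64).tobytes())
        h.update(np.asarray(self.inversion_times_abs, dtype=np.float64).tobytes())
        h.update(self.effective_tis.astype(np.float64).tobytes())
        return h.hexdigest()[:16]


def synthesize_triggers(
    mean_rr: float, sd_rr: float, n_beats: int, seed: int
) -> TriggerSeries:
    """Draw a synthetic ECG trigger series with Gaussian RR variability.

    RR intervals are i.i.d. N(mean_rr, sd_rr), truncated below at 300 ms;
    60 bpm with sd 0 reproduces a metronomic simulated ECG.
    """
    if mean_rr <= 300:
        raise ValueError("mean_rr must exceed 300 ms")
    if sd_rr < 0:
        raise ValueError("sd_rr must be non-negative")
    if n_beats < 2:
        raise ValueError("need at least 2 beats")
    rng = np.random.default_rng(seed)
    rr = rng.normal(mean_rr, sd_rr, size=n_beats - 1)
    rr = np.maximum(rr, SYNTH_RR_FLOOR_MS)
    times = np.concatenate([[0.0], np.cumsum(rr)])
    return TriggerSeries(times=tuple(times), source="synthetic", seed=seed)


def build_schedule(
    scheme: MolliScheme | str,
    triggers: TriggerSeries,
    ti_config: TiConfig | None = None,
) -> MolliSchedule:
    """Compile scheme + triggers into the absolute MOLLI event timeline.

    Deterministic in its inputs.  Raises ``ValueError`` if the trigger series
    is too short for the scheme or a computed TI is non-positive.
    """
    if isinstance(scheme, str):
        scheme = MolliScheme.from_label(scheme)
    cfg = ti_config or TiConfig()
    if len(cfg.ti_offsets_per_group) != len(scheme.groups):
        raise ValueError(
            f"{len(scheme.groups)} groups but {len(cfg.ti_offsets_per_group)} TI offsets"
        )
    # heartbeats_spanned beats carry events; one closing trigger bounds the last.
    needed = scheme.heartbeats_spanned + 1
    if len(triggers) < needed:
        raise ValueError(
            f"scheme {scheme.label} needs >= {needed} triggers, got {len(triggers)}"
        )

    t = np.asarray(triggers.times)
    inversions: list[float] = []
    events: list[ImageEvent] = []
    beat = 0
    for g, (n_acq, pause) in enumerate(scheme.groups):
        first_center = t[beat] + cfg.trigger_delay
        inv_time = first_center - cfg.ti_offsets_per_group[g]
        inversions.append(inv_time)
        for k in range(n_acq):
            center = t[beat + k] + cfg.trigger_delay
            ti = center - inv_time
            if ti <= 0:
                raise ValueError(
                    f"non-positive effective TI {ti:g} ms for image {k} of group {g}"
                )
            events.append(
                ImageEvent(
                    group=g,
                    heartbeat=beat + k,
                    readout_center_abs=float(center),
                    effective_ti=float(ti),
                )
            )
        beat += n_acq + pause
    return MolliSchedule(
        scheme=scheme,
        triggers=triggers,
        ti_config=cfg,
        inversion_times_abs=tuple(inversions),
        image_events=tuple(events),
    )


def read_trigger_csv(path) -> TriggerSeries:
    """Read a trigger CSV with one column ``r_wave_ms`` (header required)."""
    df = pd.read_csv(path)
    if "r_wave_ms" not in df.columns:
        raise ValueError("trigger CSV must have a column named 'r_wave_ms'")
    return TriggerSeries(times=tuple(df["r_wave_ms"].astype(float)), source="recorded")


def write_trigger_csv(series: TriggerSeries, path) -> None:
    pd.DataFrame({"r_wave_ms": list(series.times)}).to_csv(path, index=False)
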