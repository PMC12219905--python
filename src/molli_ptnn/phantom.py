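"""Ground-truthed digital relaxometry phantoms and synthetic MOLLI stacks.

The default set emulates a bench validation with 11 agar/CuSO4-style vials:
six "myocardium-like" regions with short T2 (50–65 ms) and five "blood-like"
regions with long T2 (135–200 ms), T1 spanning 700–1600 ms within each set.
The (T1, T2) pairs are this package's own synthetic choices sampling those
ranges — evenly spaced so recovery curves cover the span — not measurements
of any physical phantom.

Phantoms are piecewise constant: all pixels of a region share one simulated
signal (scaled by the region's proton density), with i.i.d. Gaussian noise
per pixel at the requested SNR; the background contains noise only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bloch import SequenceParams, simulate_molli_signals
from .mapping import ImageStack

__all__ = [
    "PhantomRegion",
    "PhantomSpec",
    "default_phantom_set",
    "generate_phantom_stack",
    "central_roi",
]


@dataclass(frozen=True)
class PhantomRegion:
    """One homogeneous region: a disk or rectangle with fixed (T1, T2, PD)."""

    geometry: str                     # "disk" | "rectangle"
    center: tuple[float, float]       # (row, col), fractional [0, 1]
    size: float                       # disk radius or rect half-side, fractional
    t1: float                         # ms
    t2: float                         # ms
    proton_density: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.geometry not in ("disk", "rectangle"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.t2 > self.t1:
            raise ValueError(f"region {self.label!r} violates T2 <= T1")
        if self.proton_density <= 0:
            raise ValueError("proton density must be positive")

    def pixel_mask(self, shape: tuple[int, int]) -> np.ndarray:
        h, w = shape
        rr, cc = np.mgrid[0:h, 0:w]
        cy, cx = self.center[0] * h, self.center[1] * w
        r = self.size * min(h, w)
        if self.geometry == "disk":
            return (rr - cy) ** 2 + (cc - cx) ** 2 <= r ** 2
        return (np.abs(rr - cy) <= r) & (np.abs(cc - cx) <= r)


@dataclass(frozen=True)
class PhantomSpec:
    """A canvas of non-overlapping ground-truth regions."""

    shape: tuple[int, int]
    regions: tuple[PhantomRegion, ...]

    def __post_init__(self) -> None:
        masks = [reg.pixel_mask(self.shape) for reg in self.regions]
        total = np.zeros(self.shape, dtype=int)
        for m in masks:
            total += m
        if np.any(total > 1):
            raise ValueError("phantom regions overlap")

    def region_masks(self) -> list[np.ndarray]:
        return [reg.pixel_mask(self.shape) for reg in self.regions]


# Synthetic default vial set: six low-T2 ("myocardium-like") and five high-T2
# ("blood-like") regions, T1 700-1600 ms in both sets, evenly spaced.
_LOW_T2_SET = [(700.0, 50.0), (880.0, 53.0), (1060.0, 56.0),
               (1240.0, 59.0), (1420.0, 62.0), (1600.0, 65.0)]
_HIGH_T2_SET = [(700.0, 135.0), (925.0, 151.0), (1150.0, 167.0),
                (1375.0, 183.0), (1600.0, 200.0)]


def default_phantom_set(shape: tuple[int, int] = (128, 128),
                        radius_frac: float = 0.055) -> PhantomSpec:
    """The default 11-vial synthetic phantom on a 128 x 128 canvas.

    Deterministic: repeated calls return identical specs.
    """
    pairs = _LOW_T2_SET + _HIGH_T2_SET
    regions = []
    n_cols = 4
    for i, (t1, t2) in enumerate(pairs):
        row, col = divmod(i, n_cols)
        center = ((row + 1) / 4.0, (col + 0.5) / n_cols)
        regions.append(PhantomRegion(
            geometry="disk", center=center, size=radius_frac,
            t1=t1, t2=t2,
            label=f"{'myo' if t2 < 100 else 'blood'}_T1{t1:.0f}_T2{t2:.0f}",
        ))
    return PhantomSpec(shape=shape, regions=tuple(regions))


def generate_phantom_stack(
    spec: PhantomSpec,
    schedule,
    params: SequenceParams,
    snr: float = 40.0,
    seed: int = 0,
) -> tuple[ImageStack, np.ndarray, np.ndarray]:
    """Simulate a complete MOLLI acquisition of a digital phantom.

    Returns (stack, truth_t1_map, truth_t2_map).  Region pixels receive the
    region's Bloch-simulated 8-sample signal (scaled by proton density) plus
    i.i.d. Gaussian noise with sigma = (region max sample)/snr, clipped at
    zero; background pixels are noise only (sigma from the brightest region).
    ``snr=inf`` gives a noiseless stack.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    h, w = spec.shape
    t1s = np.array([r.t1 for r in spec.regions])
    t2s = np.array([r.t2 for r in spec.regions])
    signals = simulate_molli_signals(schedule, params, t1s, t2s)
    signals = signals * np.array([r.proton_density for r in spec.regions])[:, None]

    n_img = signals.shape[1]
    data = np.zeros((n_img, h, w))
    truth_t1 = np.full((h, w), np.nan)
    truth_t2 = np.full((h, w), np.nan)
    for reg, sig, mask in zip(spec.regions, signals, spec.region_masks()):
        data[:, mask] = sig[:, None]
        truth_t1[mask] = reg.t1
        truth_t2[mask] = reg.t2

    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        sigmas = signals.max(axis=1) / snr
        noise_map = np.full((h, w), sigmas.max())
        for sig_sigma, mask in zip(sigmas, spec.region_masks()):
            noise_map[mask] = sig_sigma
        data += noise_map[None, :, :] * rng.standard_normal(data.shape)
        np.clip(data, 0.0, None, out=data)

    stack = ImageStack(
        data=data,
        effective_tis=schedule.effective_tis,
        mask=np.isfinite(truth_t1),
        scheme_label=schedule.scheme.label,
    )
    return stack, truth_t1, truth_t2


def central_roi(region: PhantomRegion, shape: tuple[int, int],
                fraction: float = 0.6) -> np.ndarray:
    """ROI covering the central ``fraction`` of a region's extent."""
    shrunk = PhantomRegion(
        geometry=region.geometry, center=region.center,
        size=region.size * fraction, t1=region.t1, t2=region.t2,
        proton_density=region.proton_density, label=region.label)
    return shrunk.pixel_mask(shape)
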