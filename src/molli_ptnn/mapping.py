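"""Pixelwise T1 maps, ROI statistics and agreement analysis.

A co-registered stack of 8 MOLLI magnitude images plus its effective-TI
vector is mapped pixel by pixel with either estimator: the personalized
network (inputs unit-normalized, exactly as at training) or the conventional
polarity-restored 3-parameter fit.  Agreement with a reference standard is
summarized the way relaxometry validations report it: modified Bland-Altman
bias and 1.96 SD limits (differences plotted against the known reference),
least-squares slope/intercept/R^2, and percent error
(T1_actual - T1_estimated) / T1_actual — positive when the estimator
underestimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .database import normalize_rows
from .fitting import LookLockerFitter
from .network import TrainedNetwork

__all__ = [
    "ImageStack",
    "T1Map",
    "AgreementReport",
    "compute_t1_map",
    "roi_statistics",
    "agreement",
]


@dataclass
class ImageStack:
    """8 co-registered 2-D magnitude images with their effective TIs (ms)."""

    data: np.ndarray                  # (n_images, H, W)
    effective_tis: np.ndarray         # (n_images,)
    mask: np.ndarray | None = None    # (H, W) bool; None = all pixels
    scheme_label: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.effective_tis = np.asarray(self.effective_tis, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("stack data must be (n_images, H, W)")
        if len(self.effective_tis) != self.data.shape[0]:
            raise ValueError("one effective TI per image is required")
        if np.any(self.effective_tis <= 0):
            raise ValueError("effective TIs must be positive")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[1:], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[1:]:
                raise ValueError("mask shape must match the image shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


@dataclass
class T1Map:
    """Pixelwise T1 estimates (ms); NaN marks unmappable/masked-out pixels."""

    values: np.ndarray
    estimator: str                    # "ptnn" | "fit"
    mask: np.ndarray
    provenance: str = ""

    def finite_values(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]


@dataclass(frozen=True)
class AgreementReport:
    """Modified Bland-Altman + correlation + percent-error summary."""

    bias: float                       # mean(estimate - reference), ms
    loa_low: float
    loa_high: float
    sd_diff: float
    slope: float
    intercept: float
    r_squared: float
    percent_error_mean: float         # (ref - est)/ref * 100, mean
    percent_error_sd: float
    n: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "bias", "loa_low", "loa_high", "sd_diff", "slope", "intercept",
            "r_squared", "percent_error_mean", "percent_error_sd", "n")}


def compute_t1_map(stack: ImageStack,
                   estimator: TrainedNetwork | LookLockerFitter) -> T1Map:
    """Estimate T1 for every masked pixel of the stack.

    Network path: each pixel's 8-vector is unit-normalized before prediction;
    all-zero pixels cannot be normalized and become NaN.  Fit path: samples
    are passed TI-sorted to the 3-parameter fit.  Pure function of its
    inputs — identical stacks give identical maps.
    """
    if stack.data.shape[0] != 8:
        raise ValueError("MOLLI stacks carry exactly 8 images")
    if not stack.mask.any():
        raise ValueError("mask is empty")
    h, w = stack.shape
    values = np.full((h, w), np.nan)
    pix = stack.data.reshape(8, -1).T            # (H*W, 8)
    sel = stack.mask.ravel()

    if isinstance(estimator, TrainedNetwork):
        rows = pix[sel]
        norms = np.linalg.norm(rows, axis=1)
        ok = norms > 0
        est = np.full(len(rows), np.nan)
        if ok.any():
            est[ok] = estimator.predict(normalize_rows(rows[ok]))
        values.ravel()[sel] = est
        tag, prov = "ptnn", estimator.schedule_fingerprint
    else:
        fitter = estimator
        if fitter.tis is None:
            fitter = LookLockerFitter(tis=stack.effective_tis)
        fitter.fit()
        rows = pix[sel]
        nz = rows.any(axis=1)
        est = np.full(len(rows), np.nan)
        if nz.any():
            est[nz] = fitter.predict(rows[nz])
        values.ravel()[sel] = est
        tag, prov = "fit", "3-parameter Levenberg-Marquardt"
    return T1Map(values=values, estimator=tag, mask=stack.mask.copy(),
                 provenance=prov)


def roi_statistics(t1_map: T1Map, roi: np.ndarray) -> tuple[float, float, int]:
    """(mean, sample SD, n) of finite map values inside a boolean ROI."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != t1_map.values.shape:
        raise ValueError("ROI shape must match the map")
    sel = roi & t1_map.mask
    vals = t1_map.values[sel]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("ROI does not intersect the mapped region")
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return float(np.mean(vals)), sd, int(len(vals))


def agreement(reference, estimates) -> AgreementReport:
    """Agreement of paired T1 estimates with a reference standard."""
    ref = np.asarray(reference, dtype=float)
    est = np.asarray(estimates, dtype=float)
    if ref.shape != est.shape or ref.ndim != 1:
        raise ValueError("reference and estimates must be equal-length 1-D")
    if len(ref) < 2:
        raise ValueError("need at least 2 pairs")
    diff = est - ref
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    if np.allclose(ref, ref[0]):
        slope, intercept, r2 = np.nan, np.nan, np.nan
    else:
        lin = stats.linregress(ref, est)
        slope, intercept = float(lin.slope), float(lin.intercept)
        r2 = float(lin.rvalue ** 2)
    perr = (ref - est) / ref * 100.0
    return AgreementReport(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        sd_diff=sd,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        percent_error_mean=float(np.mean(perr)),
        percent_error_sd=float(np.std(perr, ddof=1)),
        n=len(ref),
    )
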