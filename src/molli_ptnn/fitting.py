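"""Conventional MOLLI T1 estimation: 3-parameter magnitude fit.

The baseline estimator fits S(TI) = A - B * exp(-TI / T1*) to the 8 samples
sorted by effective TI, with magnitude-polarity restoration: the recorded
images are magnitudes, so the samples acquired before the recovery null have
lost their sign.  Every candidate inversion index p in {0..8} is tried — the
p earliest-TI samples negated — with a signed Levenberg-Marquardt fit, and
the candidate with the smallest residual wins.  The apparent constant is then
corrected with the Look-Locker formula T1 = T1* (B/A - 1), which compensates
the readout-driven acceleration of the observed recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "FitResult",
    "fit_three_parameter",
    "look_locker_correct",
    "LookLockerFitter",
]


@dataclass(frozen=True)
class FitResult:
    """Outcome of one 3-parameter magnitude fit."""

    A: float
    B: float
    t1_star: float
    t1: float
    residual_norm: float
    polarity_index: int
    converged: bool
    degenerate: bool = False


def look_locker_correct(A: float, B: float, t1_star: float) -> float:
    """Look-Locker correction T1 = T1* (B/A - 1)."""
    if A <= 0:
        raise ValueError("Look-Locker correction requires A > 0")
    if t1_star <= 0:
        raise ValueError("t1_star must be positive")
    return t1_star * (B / A - 1.0)


def _decay(tis: np.ndarray, t1_star: float) -> np.ndarray:
    # clipped to keep LM line searches through tiny/negative T1* finite
    return np.exp(-np.clip(tis / t1_star, -700.0, 700.0))


def _model(params: np.ndarray, tis: np.ndarray) -> np.ndarray:
    A, B, t1_star = params
    return A - B * _decay(tis, t1_star)


def _jacobian(params: np.ndarray, tis: np.ndarray) -> np.ndarray:
    _, B, t1_star = params
    e = _decay(tis, t1_star)
    J = np.empty((len(tis), 3))
    J[:, 0] = 1.0
    J[:, 1] = -e
    J[:, 2] = -B * e * tis / t1_star ** 2
    return J


def fit_three_parameter(
    tis: np.ndarray,
    magnitudes: np.ndarray,
    t1_star_starts: tuple[float, ...] = (1000.0, 500.0, 1500.0),
    max_iterations: int = 500,
) -> FitResult:
    """Polarity-restored 3-parameter Levenberg-Marquardt fit of one pixel.

    Samples are sorted ascending by TI internally.  Initialization
    A0 = max|S|, B0 = 2 A0, T1*0 = 1000 ms; additional T1* starts are tried
    only if the first fails to converge.  Never raises on fit failure —
    returns a result with ``converged=False`` instead.
    """
    tis = np.asarray(tis, dtype=float)
    mags = np.asarray(magnitudes, dtype=float)
    if tis.shape != mags.shape or tis.ndim != 1:
        raise ValueError("tis and magnitudes must be matching 1-D arrays")
    n = len(tis)
    if n < 4:
        raise ValueError("need at least 4 samples for a 3-parameter fit")
    order = np.argsort(tis, kind="stable")
    tis, mags = tis[order], mags[order]

    a0 = float(np.max(np.abs(mags)))
    if a0 == 0:
        return FitResult(0.0, 0.0, np.nan, np.nan, np.inf, 0, False, True)

    best: tuple[float, int, np.ndarray, bool] | None = None
    for p in range(n + 1):
        signed = mags.copy()
        signed[:p] *= -1.0
        sol = None
        for t1s0 in t1_star_starts:
            x0 = np.array([a0, 2.0 * a0, t1s0])
            try:
                res = least_squares(
                    lambda x: _model(x, tis) - signed, x0, method="lm",
                    jac=lambda x: _jacobian(x, tis),
                    ftol=1e-10, xtol=1e-12, max_nfev=max_iterations * 4,
                )
            except Exception:
                continue
            if sol is None or res.cost < sol.cost:
                sol = res
            if res.success:
                break
        if sol is None:
            continue
        rnorm = float(np.sqrt(2.0 * sol.cost))
        if best is None or rnorm < best[0]:
            best = (rnorm, p, sol.x, bool(sol.success))
    if best is None:
        return FitResult(np.nan, np.nan, np.nan, np.nan, np.inf, 0, False, True)

    rnorm, p, (A, B, t1_star) = best[0], best[1], best[2]
    converged = best[3]
    degenerate = A <= 0 or t1_star <= 0
    t1 = np.nan if degenerate else look_locker_correct(A, B, t1_star)
    return FitResult(
        A=float(A), B=float(B), t1_star=float(t1_star), t1=float(t1),
        residual_norm=rnorm, polarity_index=int(p), converged=converged,
        degenerate=bool(degenerate),
    )


class LookLockerFitter(BaseEstimator, RegressorMixin):
    """Pixelwise conventional T1 estimator with a fixed TI vector.

    scikit-learn-style wrapper: ``fit`` only records the TI vector (there is
    nothing to learn), ``predict`` runs the polarity-restored 3-parameter fit
    row by row and returns Look-Locker-corrected T1 in ms (NaN where the fit
    is degenerate).
    """

    def __init__(self, tis=None):
        self.tis = tis

    def fit(self, X=None, y=None):
        if self.tis is None:
            raise ValueError("LookLockerFitter requires a TI vector")
        self.tis_ = np.asarray(self.tis, dtype=float)
        return self

    def predict(self, X):
        if not hasattr(self, "tis_"):
            self.fit()
        X = np.asarray(X, dtype=float)
        out = np.empty(len(X))
        for i, row in enumerate(X):
            out[i] = fit_three_parameter(self.tis_, row).t1
        return out

    def fit_details(self, X) -> list[FitResult]:
        """Full per-row diagnostics (A, B, T1*, polarity, residual)."""
        if not hasattr(self, "tis_"):
            self.fit()
        return [fit_three_parameter(self.tis_, row) for row in np.asarray(X, float)]
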