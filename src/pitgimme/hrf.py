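"""Person-specific hemodynamic response estimation.

The BOLD response to a brief neural event is modelled two ways here:

* a canonical two-gamma HRF family (:func:`double_gamma_hrf`) used by the synthetic-data
  generator, parameterized by peak delay and dispersion so simulated subjects can differ
  in hemodynamics; and
* a shape-free smoothed finite impulse response (sFIR, :func:`estimate_sfir`) used on the
  analysis side.  The sFIR solves the penalized least-squares problem

      min_h || y - X h ||^2 + lambda || D h ||^2

  where X is the Toeplitz design of the binary onset vector (columns = lags 0..L-1) and
  D the second-difference operator, i.e. a roughness penalty on the impulse response.
  The smoothing weight lambda is chosen by generalized cross-validation by default.

Estimated HRFs are then convolved with the binary task-onset vectors to produce the
continuous input regressors entering the euSEM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

__all__ = [
    "HRFEstimate",
    "double_gamma_hrf",
    "estimate_sfir",
    "convolve_input",
    "gcv_lambda",
    "HRFError",
]


class HRFError(ValueError):
    """Raised for degenerate HRF-estimation inputs."""


@dataclass(frozen=True)
class HRFEstimate:
    """A TR-sampled impulse response.

    Attributes
    ----------
    coefficients : (L,) array — response at lags 0, TR, 2*TR, ...
    smoothing_lambda : penalty weight actually used (0 for plain FIR).
    tr_s : sampling interval in seconds.
    """

    coefficients: np.ndarray
    smoothing_lambda: float
    tr_s: float

    def __post_init__(self):
        c = np.asarray(self.coefficients, dtype=float)
        if c.ndim != 1 or c.size < 1:
            raise HRFError("coefficients must be a 1-D vector")
        if not np.all(np.isfinite(c)):
            raise HRFError("non-finite HRF coefficients")
        object.__setattr__(self, "coefficients", c)

    @property
    def window_s(self) -> float:
        return len(self.coefficients) * self.tr_s

    @property
    def peak_time_s(self) -> float:
        """Lag (seconds) of the maximum coefficient."""
        return float(np.argmax(self.coefficients) * self.tr_s)

    def to_dict(self) -> dict:
        return {
            "coefficients": [float(c) for c in self.coefficients],
            "smoothing_lambda": float(self.smoothing_lambda),
            "tr_s": float(self.tr_s),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HRFEstimate":
        return cls(np.asarray(d["coefficients"], float), d["smoothing_lambda"], d["tr_s"])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "HRFEstimate":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def double_gamma_hrf(
    t: np.ndarray,
    peak_delay_s: float = 6.0,
    undershoot_delay_s: float = 16.0,
    dispersion: float = 1.0,
    undershoot_dispersion: float = 1.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical two-gamma HRF sampled at times ``t`` (seconds), peak normalized to 1.

    ``peak_delay_s`` and ``dispersion`` are the subject-varying parameters used by the
    synthetic-data generator; larger dispersion widens the response.
    """
    t = np.asarray(t, dtype=float)
    if peak_delay_s <= 0 or dispersion <= 0 or undershoot_dispersion <= 0:
        raise HRFError("HRF shape parameters must be positive")
    # shape = delay/dispersion + 1 puts the gamma mode exactly at the requested delay
    peak = stats.gamma.pdf(t, a=peak_delay_s / dispersion + 1.0, scale=dispersion)
    under = stats.gamma.pdf(
        t, a=undershoot_delay_s / undershoot_dispersion + 1.0, scale=undershoot_dispersion
    )
    h = peak - undershoot_ratio * under
    m = np.max(np.abs(h))
    if m > 0:
        h = h / np.max(h)
    return h


def _toeplitz_design(onsets: np.ndarray, n_lags: int) -> np.ndarray:
    """T x L lagged-onset design: column k is the onset vector shifted down by k."""
    onsets = np.asarray(onsets, dtype=float)
    T = len(onsets)
    X = np.zeros((T, n_lags))
    for k in range(n_lags):
        X[k:, k] = onsets[: T - k]
    return X


def _second_difference(n: int) -> np.ndarray:
    D = np.zeros((max(n - 2, 0), n))
    for i in range(n - 2):
        D[i, i : i + 3] = (1.0, -2.0, 1.0)
    return D


def _sfir_solve(X, y, lam, D):
    A = X.T @ X + lam * (D.T @ D)
    b = X.T @ y
    try:
        c, low = linalg.cho_factor(A)
        return linalg.cho_solve((c, low), b), A
    except linalg.LinAlgError as err:
        raise HRFError(
            "singular penalized normal equations; try a larger smoothing lambda"
        ) from err


def gcv_lambda(
    X: np.ndarray,
    y: np.ndarray,
    D: np.ndarray,
    grid: np.ndarray | None = None,
) -> float:
    """Generalized cross-validation choice of the sFIR penalty over a log grid."""
    T = len(y)
    if grid is None:
        grid = np.logspace(-2, 4, 25)
    best_lam, best_score = float(grid[0]), np.inf
    XtX = X.T @ X
    DtD = D.T @ D
    Xty = X.T @ y
    yty = float(y @ y)
    for lam in grid:
        A = XtX + lam * DtD
        try:
            Ainv = linalg.inv(A)
        except linalg.LinAlgError:
            continue
        h = Ainv @ Xty
        rss = yty - 2 * h @ Xty + h @ (XtX @ h)
        edf = float(np.trace(XtX @ Ainv))
        denom = (1.0 - edf / T) ** 2
        if denom <= 0:
            continue
        score = rss / (T * denom)
        if score < best_score - 1e-12:
            best_score, best_lam = score, float(lam)
    return best_lam


def estimate_sfir(
    y: np.ndarray,
    onsets: np.ndarray,
    n_lags: int = 16,
    smoothing_lambda: float | str = "gcv",
    tr_s: float = 2.0,
) -> HRFEstimate:
    """Estimate a person-specific HRF by smoothed FIR.

    Parameters
    ----------
    y : (T,) ROI series (demeaned internally).
    onsets : (T,) binary event-onset vector on the same TR grid.
    n_lags : FIR window length in TRs (default 16 TRs = 32 s at TR 2 s).
    smoothing_lambda : non-negative penalty weight, or "gcv" for generalized
        cross-validation over a log grid.
    """
    y = np.asarray(y, dtype=float)
    onsets = np.asarray(onsets, dtype=float)
    if y.ndim != 1 or onsets.ndim != 1 or len(y) != len(onsets):
        raise HRFError("y and onsets must be equal-length vectors")
    if np.count_nonzero(onsets) == 0:
        raise HRFError("onset vector contains no events; HRF is unidentified")
    if len(y) <= n_lags:
        raise HRFError(f"series length {len(y)} must exceed the FIR window {n_lags}")
    # unpenalized intercept column absorbs the baseline without biasing the FIR shape
    X = np.column_stack([np.ones(len(y)), _toeplitz_design(onsets, n_lags)])
    D = np.column_stack([np.zeros(max(n_lags - 2, 0)), _second_difference(n_lags)])
    if smoothing_lambda == "gcv":
        lam = gcv_lambda(X, y, D)
    else:
        lam = float(smoothing_lambda)
        if lam < 0:
            raise HRFError("smoothing_lambda must be non-negative")
    if lam == 0.0:
        h, *_ = linalg.lstsq(X, y)
    else:
        h, _ = _sfir_solve(X, y, lam, D)
    return HRFEstimate(h[1:], lam, tr_s)


def convolve_input(onsets: np.ndarray, hrf: HRFEstimate) -> np.ndarray:
    """Causal discrete convolution of a binary onset vector with an HRF, truncated to T."""
    onsets = np.asarray(onsets, dtype=float)
    if onsets.ndim != 1:
        raise HRFError("onsets must be a 1-D vector")
    return np.convolve(onsets, hrf.coefficients)[: len(onsets)]
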