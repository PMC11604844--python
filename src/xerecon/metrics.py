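"""Image-fidelity and agreement metrics for reconstruction comparisons.

SNR follows the background-slice convention of hyperpolarized lung MRI: the
mean magnitude signal inside the lung mask divided by the standard
deviation of the *real* channel over six slices outside the lung (for pure
complex Gaussian noise this ratio converges to sqrt(pi/2), since
E|z| = sigma sqrt(pi/2) while SD(Re z) = sigma).  Map-level fidelity is
summarized by the normalized mean absolute error (NMAE, percent of the mean
reference magnitude), the coefficient of variation, pixelwise ordinary
least squares with the adjusted coefficient of determination, Bland-Altman
agreement of per-subject means, and a log-log power-law fit
``NMAE = a * SNR^k`` describing how fidelity degrades at low SNR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "MetricsReport",
    "PowerLawFit",
    "snr",
    "nmae",
    "cv",
    "pixelwise_regression",
    "bland_altman",
    "fit_power_law",
    "paired_test",
]


@dataclass
class PowerLawFit:
    a: float
    k: float
    rmse: float  # residual RMS in log space
    n_points: int

    def predict(self, snr_values):
        return self.a * np.asarray(snr_values, dtype=float) ** self.k


@dataclass
class MetricsReport:
    """Container for a reconstruction-pair comparison."""

    snr: dict = field(default_factory=dict)
    nmae_pct: dict = field(default_factory=dict)
    cv: dict = field(default_factory=dict)
    regression: dict = field(default_factory=dict)
    bland_altman: dict = field(default_factory=dict)
    n_voxels: int = 0

    def to_dict(self) -> dict:
        return {
            "snr": self.snr,
            "nmae_pct": self.nmae_pct,
            "cv": self.cv,
            "regression": self.regression,
            "bland_altman": self.bland_altman,
            "n_voxels": self.n_voxels,
        }


def _noise_slices(volume: np.ndarray, n_edge: int, axis: int) -> np.ndarray:
    head = np.take(volume, range(n_edge), axis=axis)
    tail = np.take(volume, range(-n_edge, 0), axis=axis)
    return np.concatenate([head.ravel(), tail.ravel()])


def snr(
    image: np.ndarray,
    mask: np.ndarray,
    noise_slices: int = 3,
    slice_axis: int = 2,
) -> float:
    """Mean |signal| in the mask over SD of the real part in outer slices.

    ``noise_slices`` slices are taken from each end of ``slice_axis`` (six
    in total by default); they must not intersect the mask.
    """
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty signal mask")
    noise = _noise_slices(np.real(image), noise_slices, slice_axis)
    sd = noise.std()
    if sd == 0:
        raise ValueError("zero noise SD in the background slices")
    return float(np.abs(image[mask]).mean() / sd)


def nmae(test: np.ndarray, ref: np.ndarray, mask: np.ndarray,
         normalizer: str = "mean") -> float:
    """Normalized mean absolute error in percent over the mask.

    ``100 * mean|test - ref| / mean|ref|`` (default) or, with
    ``normalizer="range"``, divided by the reference range instead.
    """
    test, ref = np.asarray(test), np.asarray(ref)
    if test.shape != ref.shape or test.shape != mask.shape:
        raise ValueError("test, reference and mask must share one grid")
    t, r = test[mask], ref[mask]
    if normalizer == "mean":
        denom = np.abs(r).mean()
    elif normalizer == "range":
        denom = np.abs(r).max() - np.abs(r).min()
    else:
        raise ValueError(f"unknown normalizer {normalizer!r}")
    if denom == 0:
        raise ValueError("degenerate reference: zero normalizer")
    return float(100.0 * np.abs(t - r).mean() / denom)


def cv(values: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Coefficient of variation SD/mean over the mask (sample SD)."""
    v = np.asarray(values)
    if mask is not None:
        v = v[np.asarray(mask, dtype=bool)]
    v = v.ravel()
    mean = v.mean()
    if mean == 0:
        raise ValueError("zero mean: CV undefined")
    sd = v.std(ddof=1) if v.size > 1 else 0.0
    return float(sd / mean)


def pixelwise_regression(x: np.ndarray, y: np.ndarray,
                         mask: np.ndarray | None = None) -> dict:
    """Ordinary least squares y ~ x with the adjusted R^2 for one predictor.

    ``adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - 2)``.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        x, y = x[m], y[m]
    x, y = x.ravel(), y.ravel()
    n = x.size
    if n < 3:
        raise ValueError("regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate regression: constant predictor")
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(r2),
        "adjusted_r2": float(adj),
        "n": int(n),
    }


def bland_altman(x: np.ndarray, y: np.ndarray) -> dict:
    """Bland-Altman agreement: bias and 1.96-SD limits of agreement."""
    x, y = np.asarray(x, dtype=float).ravel(), np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    diff = y - x
    bias = diff.mean()
    sd = diff.std(ddof=1)
    return {
        "bias": float(bias),
        "loa_lower": float(bias - 1.96 * sd),
        "loa_upper": float(bias + 1.96 * sd),
        "sd_diff": float(sd),
        "n": int(x.size),
    }


def fit_power_law(snr_values, nmae_values, method: str = "loglog") -> PowerLawFit:
    """Fit ``NMAE = a * SNR^k`` across an SNR sweep.

    ``"loglog"`` (default) is ordinary least squares on
    ``log NMAE = log a + k log SNR``; ``"nonlinear"`` refines (a, k) by
    direct least squares in the linear domain, seeded by the log-log fit.
    """
    s = np.asarray(snr_values, dtype=float).ravel()
    e = np.asarray(nmae_values, dtype=float).ravel()
    if s.size != e.size or s.size < 3:
        raise ValueError("need at least 3 (SNR, NMAE) pairs")
    if np.any(s <= 0) or np.any(e <= 0):
        raise ValueError("power-law fit requires positive values")
    ls, le = np.log(s), np.log(e)
    res = stats.linregress(ls, le)
    a, k = math.exp(res.intercept), res.slope
    if method == "nonlinear":
        from scipy.optimize import curve_fit

        popt, _ = curve_fit(lambda v, aa, kk: aa * v**kk, s, e, p0=[a, k],
                            maxfev=10000)
        a, k = popt
    elif method != "loglog":
        raise ValueError(f"unknown method {method!r}")
    resid = le - (math.log(a) + k * ls)
    return PowerLawFit(
        a=float(a), k=float(k),
        rmse=float(np.sqrt(np.mean(resid**2))),
        n_points=int(s.size),
    )


def paired_test(x, y) -> dict:
    """Thin paired-comparison utility: Wilcoxon signed-rank plus paired t."""
    x, y = np.asarray(x, float).ravel(), np.asarray(y, float).ravel()
    w = stats.wilcoxon(x, y)
    t = stats.ttest_rel(x, y)
    return {
        "wilcoxon_p": float(w.pvalue),
        "ttest_p": float(t.pvalue),
        "n": int(x.size),
    }
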