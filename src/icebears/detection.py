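"""Detection-probability components.

Two platforms, two detection models:

* Thermal platform: detection probability ``p_us`` of the automated hot-spot
  pipeline, estimated from experimental flyover trials as a simple binomial
  proportion.
* Visual/photographic platform: conventional line-transect distance sampling.
  Perpendicular distances (m) truncated at ``w`` follow a detection function
  ``g(x)``; the average detection probability within the strip is
  ``p_rus = g(0) * (1/w) * int_0^w g(x) dx`` with the trackline probability
  ``g(0)`` supplied as a fixed scenario input (it cannot be estimated from
  single-observer data).

Two detection-function shapes are supported: the half-normal
``g(x) = exp(-x^2 / (2 sigma^2))`` and a uniform--half-normal mixture that is
flat out to a photo-reach breakpoint (photographs were only obtained to a
fixed distance from the aircraft) and declines half-normally beyond it,
continuous at the join.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

#: Default truncation distance for perpendicular distances (m).
DEFAULT_TRUNCATION_M = 600.0
#: Default photo-reach breakpoint for the mixture detection function (m).
DEFAULT_BREAKPOINT_M = 350.0

_SQRT_HALF_PI = np.sqrt(np.pi / 2.0)


@dataclass
class FlyoverTrials:
    """Experimental flyover trials: ``detected`` successes out of ``n``."""

    n: int
    detected: int

    def __post_init__(self) -> None:
        if self.n < 0 or not (0 <= self.detected <= self.n):
            raise ValueError("require 0 <= detected <= n")


@dataclass
class DistanceData:
    """Perpendicular distances (m) with truncation and photo-reach metadata."""

    distances: np.ndarray
    w: float = DEFAULT_TRUNCATION_M
    breakpoint: float = DEFAULT_BREAKPOINT_M

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if not self.w > 0:
            raise ValueError("truncation distance w must be positive")
        if np.any(self.distances < 0) or np.any(self.distances > self.w):
            raise ValueError("distances must lie in [0, w]")


@dataclass
class DetectionParams:
    sigma: float
    g0: float = 1.0
    p_us: float = 0.67

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if not 0 < self.g0 <= 1:
            raise ValueError("g0 must lie in (0, 1]")
        if not 0 <= self.p_us <= 1:
            raise ValueError("p_us must lie in [0, 1]")


def flyover_estimate(trials: FlyoverTrials) -> tuple[float, float]:
    """Binomial MLE of the thermal detection probability, with its SE.

    ``p_hat = D/n``, ``SE = sqrt(p_hat (1 - p_hat) / n)``.
    """
    if trials.n == 0:
        raise ValueError("at least one flyover trial is required")
    p = trials.detected / trials.n
    se = np.sqrt(p * (1.0 - p) / trials.n)
    return float(p), float(se)


def _halfnormal_integral(sigma: float, w: float) -> float:
    """``int_0^w exp(-x^2/(2 sigma^2)) dx`` in closed form."""
    return sigma * _SQRT_HALF_PI * special.erf(w / (sigma * np.sqrt(2.0)))


def halfnormal_p(sigma: float, w: float = DEFAULT_TRUNCATION_M,
                 g0: float = 1.0) -> float:
    """Average in-strip detection probability under a half-normal shape.

    ``p_rus = g0 * (1/w) * int_0^w exp(-x^2/(2 sigma^2)) dx``, evaluated with
    the error function (exact, no quadrature error).
    """
    if not sigma > 0 or not w > 0:
        raise ValueError("sigma and w must be positive")
    return float(g0 * _halfnormal_integral(sigma, w) / w)


def mixture_p(sigma: float, w: float = DEFAULT_TRUNCATION_M,
              breakpoint: float = DEFAULT_BREAKPOINT_M,
              g0: float = 1.0) -> float:
    """Average detection probability under the uniform--half-normal mixture.

    Detection is certain (given g0) out to the breakpoint ``b`` and declines
    as ``exp(-(x^2 - b^2)/(2 sigma^2))`` beyond it, which equals 1 at ``b``
    (continuity) and reduces to the plain half-normal as ``b -> 0``.
    """
    if not sigma > 0 or not w > 0:
        raise ValueError("sigma and w must be positive")
    if not 0 <= breakpoint < w:
        raise ValueError("require 0 <= breakpoint < w")
    b = breakpoint
    tail = np.exp(b * b / (2 * sigma * sigma)) * (
        _halfnormal_integral(sigma, w) - _halfnormal_integral(sigma, b))
    return float(g0 * (b + tail) / w)


def _detection_integral(sigma: float, data: DistanceData, form: str) -> float:
    if form == "halfnormal":
        return _halfnormal_integral(sigma, data.w)
    b = data.breakpoint
    tail = np.exp(b * b / (2 * sigma * sigma)) * (
        _halfnormal_integral(sigma, data.w) - _halfnormal_integral(sigma, b))
    return b + tail


def distance_nll(sigma: float, data: DistanceData,
                 form: str = "halfnormal") -> float:
    """Negative log likelihood of the truncated distance density.

    The density of an observed distance is the detection function normalized
    on ``[0, w]``; ``g(0)`` cancels and does not enter.
    """
    if form not in ("halfnormal", "mixture"):
        raise ValueError(f"unknown detection form {form!r}")
    x = data.distances
    if form == "halfnormal":
        log_g = -x * x / (2 * sigma * sigma)
    else:
        b = data.breakpoint
        log_g = np.where(x <= b, 0.0, -(x * x - b * b) / (2 * sigma * sigma))
    return float(len(x) * np.log(_detection_integral(sigma, data, form))
                 - np.sum(log_g))


def fit_distance(data: DistanceData, form: str = "halfnormal"):
    """Fit the scale of a detection function to truncated distances.

    Maximizes the conditional (truncated) likelihood over ``log sigma`` and
    returns ``(sigma_hat, nll, aic)`` with ``AIC = 2k + 2 nll``, ``k = 1``
    for both shapes.  Raises if fewer than two distances are available or the
    optimizer fails to bracket a minimum.
    """
    if len(data.distances) < 2:
        raise ValueError("need at least two distances to fit a scale")

    def obj(log_sigma):
        return distance_nll(np.exp(log_sigma), data, form)

    res = optimize.minimize_scalar(obj, bounds=(np.log(1e-1), np.log(1e6)),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    if not res.success:
        raise RuntimeError(f"distance fit failed to converge: {res.message}")
    sigma_hat = float(np.exp(res.x))
    nll = float(res.fun)
    aic = 2.0 * 1 + 2.0 * nll
    return sigma_hat, nll, aic


def detection_summary(data: DistanceData, g0_values=(0.6, 0.8, 1.0)) -> str:
    """One-page text summary: fitted scales, AIC table, p_rus per g(0)."""
    lines = [f"Distance sampling summary (n={len(data.distances)}, "
             f"w={data.w:.0f} m, breakpoint={data.breakpoint:.0f} m)", ""]
    fits = {}
    for form in ("halfnormal", "mixture"):
        sigma, nll, aic = fit_distance(data, form)
        fits[form] = (sigma, nll, aic)
    best = min(fits.values(), key=lambda f: f[2])[2]
    lines.append(f"{'form':<12}{'sigma_hat_m':>12}{'nll':>12}{'AIC':>10}"
                 f"{'dAIC':>8}")
    for form, (sigma, nll, aic) in fits.items():
        lines.append(f"{form:<12}{sigma:>12.1f}{nll:>12.2f}{aic:>10.2f}"
                     f"{aic - best:>8.2f}")
    lines.append("")
    sigma_hn = fits["halfnormal"][0]
    lines.append("p_rus under the half-normal fit:")
    for g0 in g0_values:
        lines.append(f"  g(0)={g0:.1f}: "
                     f"{halfnormal_p(sigma_hn, data.w, g0):.3f}")
    return "\n".join(lines)
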