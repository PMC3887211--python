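"""Enzyme-kinetic inference: initial rates, reaction order, and apparent Km.

Three regression problems recur in automethylation studies, and each is
exposed here as a scikit-learn style estimator plus a thin functional
wrapper:

* :class:`LinearRateFit` — ordinary least squares of signal on time; the
  slope is the initial methylation rate (signal units per hour).
* :class:`ReactionOrderFit` — OLS of log10(rate) on log10([E]); the slope is
  the reaction order n in v = k * [E]^n. n near 1 indicates an
  intramolecular (unimolecular in enzyme) mechanism; n near 2 an
  intermolecular one.
* :class:`MichaelisMentenFit` / :class:`SubstrateInhibitionFit` — nonlinear
  least squares of v = Vmax*S/(Km+S), optionally extended with the canonical
  uncompetitive-at-high-S inhibition form v = Vmax*S/(Km + S*(1 + S/Ki)),
  compared by AIC.

Rates are fitted over the full provided window; time courses with visible
curvature should be pre-truncated to the linear regime by the caller.
Densitometry (relative intensity) and scintillation (cpm) series are treated
identically after unit tagging — no inter-unit conversion is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import ConvergenceError, InputError

#: Reaction-order band accepted as "consistent with first order".
FIRST_ORDER_BAND = (0.6, 1.3)
#: AIC difference required to prefer the substrate-inhibition model.
AIC_CALL_THRESHOLD = 2.0


@dataclass
class TimeCourse:
    """A quantified methylation time course for one gel band or pulldown.

    ``signal_kind`` tags the units: ``"cpm"`` (liquid scintillation counts)
    or ``"relative_intensity"`` (fluorogram densitometry).
    """

    t: np.ndarray  # hours
    signal: np.ndarray
    label: str = ""
    signal_kind: str = "relative_intensity"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.t.shape != self.signal.shape or self.t.ndim != 1:
            raise InputError("t and signal must be 1-d arrays of equal length")
        if np.any(self.t < 0):
            raise InputError("time points must be >= 0")
        if np.any(np.diff(self.t) <= 0):
            raise InputError("time points must be strictly increasing")
        if self.signal_kind not in ("cpm", "relative_intensity"):
            raise InputError(f"unknown signal_kind {self.signal_kind!r}")


@dataclass(frozen=True)
class RateEstimate:
    slope: float
    slope_se: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class OrderFit:
    n: float
    n_se: float
    log_k: float
    r_squared: float

    def first_order(self, band: tuple[float, float] = FIRST_ORDER_BAND) -> bool:
        return band[0] <= self.n <= band[1]


@dataclass(frozen=True)
class MMFit:
    vmax: float
    km: float
    vmax_se: float
    km_se: float
    r_squared: float
    aic: float
    model: str  # "MM" or "MM_substrate_inhibition"
    ki: float | None = None
    ki_se: float | None = None
    ill_conditioned: bool = False


def _column(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2 and X.shape[1] == 1:
        X = X[:, 0]
    if X.ndim != 1:
        raise InputError("expected a 1-d array or single-column 2-d array")
    return X


def _aic_ls(n: int, ssr: float, k: int) -> float:
    """AIC of a least-squares fit with k mean parameters (+1 for sigma)."""
    ssr = max(ssr, 1e-300)
    return n * np.log(ssr / n) + 2 * (k + 1)


class LinearRateFit(RegressorMixin, BaseEstimator):
    """OLS of signal on time; the fitted slope is the methylation rate.

    Fitted attributes: ``slope_``, ``slope_se_``, ``intercept_``,
    ``r_squared_``.
    """

    def fit(self, X, y):
        t = _column(X)
        y = np.asarray(y, dtype=float)
        if len(t) < 3:
            raise InputError(f"rate fitting requires >= 3 points, got {len(t)}")
        if np.ptp(t) == 0:
            raise InputError("time points have zero variance")
        res = stats.linregress(t, y)
        self.slope_ = float(res.slope)
        self.slope_se_ = float(res.stderr) if np.isfinite(res.stderr) else 0.0
        self.intercept_ = float(res.intercept)
        self.r_squared_ = float(res.rvalue**2)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        return self.intercept_ + self.slope_ * _column(X)

    def result(self) -> RateEstimate:
        return RateEstimate(self.slope_, self.slope_se_, self.intercept_, self.r_squared_)


class ReactionOrderFit(RegressorMixin, BaseEstimator):
    """Log-log regression of rate on enzyme concentration.

    Fits log10(rate) = n * log10([E]) + log10(k); the slope ``n_`` is the
    reaction order (any log base gives the same slope; base 10 matches the
    conventional display). Fitted attributes: ``n_``, ``n_se_``, ``log_k_``,
    ``r_squared_``. ``predict`` returns rates on the linear scale.
    """

    def fit(self, X, y):
        conc = _column(X)
        rate = np.asarray(y, dtype=float)
        if len(conc) < 3:
            raise InputError(f"order fitting requires >= 3 pairs, got {len(conc)}")
        for i, (c, v) in enumerate(zip(conc, rate)):
            if c <= 0 or v <= 0:
                raise InputError(
                    f"pair {i} (conc={c!r}, rate={v!r}) is non-positive; "
                    "log-log regression requires positive values"
                )
        res = stats.linregress(np.log10(conc), np.log10(rate))
        self.n_ = float(res.slope)
        self.n_se_ = float(res.stderr) if np.isfinite(res.stderr) else 0.0
        self.log_k_ = float(res.intercept)
        self.r_squared_ = float(res.rvalue**2)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        return 10.0**self.log_k_ * _column(X) ** self.n_

    def result(self) -> OrderFit:
        return OrderFit(self.n_, self.n_se_, self.log_k_, self.r_squared_)


def michaelis_menten(s, vmax, km):
    return vmax * s / (km + s)


def substrate_inhibition(s, vmax, km, ki):
    return vmax * s / (km + s * (1.0 + s / ki))


def _mm_p0(s: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    vmax0 = float(np.max(v))
    half = vmax0 / 2.0
    order = np.argsort(s)
    s_sorted, v_sorted = s[order], v[order]
    km0 = float(np.interp(half, v_sorted, s_sorted)) if vmax0 > 0 else float(np.median(s))
    if not np.isfinite(km0) or km0 <= 0:
        km0 = float(np.median(s))
    return vmax0, km0


class MichaelisMentenFit(RegressorMixin, BaseEstimator):
    """Nonlinear least squares of v = Vmax*S/(Km+S).

    Initialization: Vmax0 = max observed rate, Km0 = S at half-max
    (interpolated). Standard errors come from the fit covariance. Fitted
    attributes: ``vmax_``, ``km_``, ``vmax_se_``, ``km_se_``,
    ``r_squared_``, ``aic_``, ``ill_conditioned_``.
    """

    def __init__(self, min_pairs: int = 4):
        self.min_pairs = min_pairs

    _model = staticmethod(michaelis_menten)
    _n_params = 2
    _model_name = "MM"

    def _p0_bounds(self, s, v):
        vmax0, km0 = _mm_p0(s, v)
        return [vmax0, km0], (0.0, np.inf)

    def fit(self, X, y):
        s = _column(X)
        v = np.asarray(y, dtype=float)
        if len(s) < self.min_pairs:
            raise InputError(
                f"{self._model_name} fitting requires >= {self.min_pairs} pairs, "
                f"got {len(s)}"
            )
        if np.any(v < 0):
            raise InputError("rates must be >= 0")
        p0, bounds = self._p0_bounds(s, v)
        try:
            popt, pcov = optimize.curve_fit(
                self._model, s, v, p0=p0, bounds=bounds, maxfev=20000
            )
        except RuntimeError as exc:
            raise ConvergenceError(
                f"{self._model_name} fit did not converge (p0={p0})"
            ) from exc
        resid = v - self._model(s, *popt)
        ssr = float(np.sum(resid**2))
        sst = float(np.sum((v - v.mean()) ** 2))
        se = np.sqrt(np.abs(np.diag(pcov)))
        self._set_params_fitted(popt, se)
        self.r_squared_ = 1.0 - ssr / sst if sst > 0 else 1.0
        self.aic_ = _aic_ls(len(s), ssr, self._n_params)
        # a Km collapsing to the zero boundary (far below the smallest design
        # concentration) is unidentifiable from saturated data
        self.ill_conditioned_ = bool(
            self.km_ < 1e-3 * float(np.min(s)) or not np.all(np.isfinite(se))
        )
        if not (np.min(s) < self.km_ < np.max(s)):
            warnings.warn(
                f"design does not span both sides of the fitted Km "
                f"({self.km_:.3g} outside [{np.min(s):.3g}, {np.max(s):.3g}]); "
                "the estimate may be poorly constrained",
                stacklevel=2,
            )
        self.n_features_in_ = 1
        return self

    def _set_params_fitted(self, popt, se):
        self.vmax_, self.km_ = map(float, popt)
        self.vmax_se_, self.km_se_ = map(float, se)

    def predict(self, X):
        return self._model(_column(X), *self._popt())

    def _popt(self):
        return (self.vmax_, self.km_)

    def result(self) -> MMFit:
        return MMFit(
            vmax=self.vmax_, km=self.km_, vmax_se=self.vmax_se_, km_se=self.km_se_,
            r_squared=self.r_squared_, aic=self.aic_, model=self._model_name,
            ill_conditioned=self.ill_conditioned_,
        )


class SubstrateInhibitionFit(MichaelisMentenFit):
    """Michaelis-Menten with uncompetitive substrate inhibition:
    v = Vmax*S/(Km + S*(1 + S/Ki)).

    Also fits the plain hyperbola on the same data and records both AICs
    (``aic_``, ``aic_mm_``); ``preferred_model_`` is
    ``"MM_substrate_inhibition"`` only when its AIC beats plain MM by more
    than :data:`AIC_CALL_THRESHOLD`.
    """

    def __init__(self, min_pairs: int = 5):
        self.min_pairs = min_pairs

    _model = staticmethod(substrate_inhibition)
    _n_params = 3
    _model_name = "MM_substrate_inhibition"

    def _p0_bounds(self, s, v):
        vmax0, km0 = _mm_p0(s, v)
        return [vmax0, km0, 2.0 * float(np.max(s))], (0.0, np.inf)

    def _set_params_fitted(self, popt, se):
        self.vmax_, self.km_, self.ki_ = map(float, popt)
        self.vmax_se_, self.km_se_, self.ki_se_ = map(float, se)

    def _popt(self):
        return (self.vmax_, self.km_, self.ki_)

    def fit(self, X, y):
        super().fit(X, y)
        mm = MichaelisMentenFit().fit(X, y)
        self.aic_mm_ = mm.aic_
        self.mm_fit_ = mm.result()
        self.preferred_model_ = (
            "MM_substrate_inhibition"
            if self.aic_mm_ - self.aic_ > AIC_CALL_THRESHOLD
            else "MM"
        )
        return self

    def result(self) -> MMFit:
        return MMFit(
            vmax=self.vmax_, km=self.km_, vmax_se=self.vmax_se_, km_se=self.km_se_,
            r_squared=self.r_squared_, aic=self.aic_, model=self._model_name,
            ki=self.ki_, ki_se=self.ki_se_, ill_conditioned=self.ill_conditioned_,
        )


# -- functional wrappers ------------------------------------------------------


def fit_rate(tc: TimeCourse) -> RateEstimate:
    """Initial-rate OLS line through a time course; the slope is the rate."""
    return LinearRateFit().fit(tc.t, tc.signal).result()


def fit_reaction_order(
    conc: Sequence[float], rate: Sequence[float]
) -> OrderFit:
    """Reaction order n from log10(rate) vs log10(concentration)."""
    return ReactionOrderFit().fit(np.asarray(conc), np.asarray(rate)).result()


def fit_mm(conc: Sequence[float], rate: Sequence[float]) -> MMFit:
    """Apparent Km / Vmax by Michaelis-Menten nonlinear least squares."""
    return MichaelisMentenFit().fit(np.asarray(conc), np.asarray(rate)).result()


def fit_substrate_inhibition(
    conc: Sequence[float], rate: Sequence[float]
) -> tuple[MMFit, MMFit, str]:
    """Fit both the substrate-inhibition and plain MM models.

    Returns ``(inhibition_fit, mm_fit, preferred_model)``, the last decided
    by an AIC margin of :data:`AIC_CALL_THRESHOLD`.
    """
    est = SubstrateInhibitionFit().fit(np.asarray(conc), np.asarray(rate))
    return est.result(), est.mm_fit_, est.preferred_model_
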