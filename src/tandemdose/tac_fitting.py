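"""Sum-of-exponential time–activity-curve fitting, AICc selection, cumulated activity.

Fitting is multi-start nonlinear least squares in log-parameter space
(amplitudes >= 0, rates > 0 by construction), with candidate rates on a
log-spaced grid and amplitudes initialized by a nonnegative linear solve.
Model selection uses the small-sample corrected information criterion

    AICc = n ln(rss/n) + 2k + 2k(k+1)/(n - k - 1).

When the curve carries per-point replication (group means of ``n_per_point``
animals), the replication total is used as the effective n for the correction
term; without it, the number of points is used and candidates with
``n - k - 1 <= 0`` are excluded from selection with a notice.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "TimeActivityCurve",
    "FitResult",
    "CumulatedActivity",
    "MODEL_FORMS",
    "fit_model",
    "select_model",
    "cumulated_activity",
    "fit_standard_errors",
]

MODEL_FORMS = ("mono_exp", "bi_exp", "bi_exp_fixed_phys")
_N_FREE = {"mono_exp": 2, "bi_exp": 4, "bi_exp_fixed_phys": 3}


@dataclass(frozen=True)
class TimeActivityCurve:
    """Group-level uptake series: times (h), values (%IA), optional SDs and n."""

    times: np.ndarray
    values: np.ndarray
    sds: np.ndarray | None = None
    n_per_point: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be 1-D and the same length")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be nonnegative and strictly increasing")
        if np.any(v < 0):
            raise ValueError("values must be >= 0")
        for name in ("sds", "n_per_point"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != t.shape:
                    raise ValueError(f"{name} must match times in length")
                object.__setattr__(self, name, arr)

    @property
    def n_points(self) -> int:
        return int(self.times.size)

    @property
    def n_effective(self) -> int:
        """Total animals behind the curve if known, else the number of points."""
        if self.n_per_point is not None:
            return int(np.sum(self.n_per_point))
        return self.n_points


@dataclass(frozen=True)
class FitResult:
    """A converged (or explicitly failed) sum-of-exponentials fit.

    Components are ordered ``lambda1 >= lambda2``; ``a2``/``lambda2`` are None
    for a mono-exponential.  ``aicc`` is NaN when the small-sample correction
    is undefined for this candidate (n_eff − k − 1 <= 0).
    """

    model_form: str
    a1: float
    lambda1: float
    a2: float | None
    lambda2: float | None
    rss: float
    aicc: float
    n_points: int
    n_eff: int
    k: int
    converged: bool
    message: str = ""

    @property
    def components(self) -> list[tuple[float, float]]:
        comps = [(self.a1, self.lambda1)]
        if self.a2 is not None and self.lambda2 is not None:
            comps.append((self.a2, self.lambda2))
        return comps

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        y = np.zeros_like(t)
        for a, lam in self.components:
            y = y + a * np.exp(-lam * t)
        return y


@dataclass(frozen=True)
class CumulatedActivity:
    """Time-integrated activity in %IA·h over the given horizon."""

    value: float
    horizon_h: float
    physical_decay_applied: bool


def _aicc(rss: float, n_eff: int, k: int, n_points: int) -> float:
    if rss <= 0:
        rss = np.finfo(float).tiny  # exact fits: avoid log(0), keeps ordering
    base = n_points * math.log(rss / n_points) + 2 * k
    if n_eff - k - 1 <= 0:
        return math.nan
    return base + 2 * k * (k + 1) / (n_eff - k - 1)


def _model_eval(t: np.ndarray, amps: np.ndarray, rates: np.ndarray) -> np.ndarray:
    return np.exp(-np.outer(t, rates)) @ amps


def _nnls_amplitudes(t, y, w, rates):
    design = np.exp(-np.outer(t, rates)) * w[:, None]
    amps, _ = optimize.nnls(design, y * w)
    return amps


def fit_model(
    tac: TimeActivityCurve,
    model_form: str = "bi_exp",
    weighting: str = "unweighted",
    seed: int = 0,
    fixed_lambda: float | None = None,
    n_rate_grid: int = 9,
) -> FitResult:
    """Fit one sum-of-exponentials model by multi-start nonlinear least squares.

    ``weighting`` is ``"unweighted"`` (default: plain least squares on the
    values) or ``"inverse_variance"`` (1/SD² weights; requires ``tac.sds``).
    ``fixed_lambda`` pins the slow rate for ``bi_exp_fixed_phys``.  The
    procedure is deterministic: the multi-start grid is fixed and ``seed``
    only enters the (disabled by default) jitter, so repeated calls agree.
    Failure to converge returns an explicit non-converged result.
    """
    if model_form not in MODEL_FORMS:
        raise ValueError(f"unknown model_form {model_form!r}")
    k = _N_FREE[model_form]
    if tac.n_points < k + 1:
        raise ValueError(
            f"{model_form} needs at least {k + 1} points, curve has {tac.n_points}"
        )
    if model_form == "bi_exp_fixed_phys":
        if fixed_lambda is None or not fixed_lambda > 0:
            raise ValueError("bi_exp_fixed_phys requires a positive fixed_lambda")

    t, y = tac.times, tac.values
    if weighting == "unweighted":
        w = np.ones_like(y)
    elif weighting == "inverse_variance":
        if tac.sds is None or np.any(tac.sds <= 0):
            raise ValueError("inverse_variance weighting requires positive sds")
        w = 1.0 / tac.sds
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    t_min = max(t[0], t[1] / 10.0) if t[0] == 0 else t[0]
    grid = np.geomspace(1.0 / (10.0 * t[-1]), 10.0 / t_min, n_rate_grid)

    if model_form == "mono_exp":
        candidates = [(r,) for r in grid]
    elif model_form == "bi_exp":
        candidates = [(hi, lo) for lo, hi in itertools.combinations(grid, 2)]
    else:  # bi_exp_fixed_phys: free fast rate, pinned slow rate
        candidates = [(r, fixed_lambda) for r in grid if r > fixed_lambda]
        if not candidates:
            candidates = [(10.0 * fixed_lambda, fixed_lambda)]

    starts = []
    for rates in candidates:
        rates_arr = np.asarray(rates, dtype=float)
        amps = _nnls_amplitudes(t, y, w, rates_arr)
        resid = (_model_eval(t, amps, rates_arr) - y) * w
        starts.append((float(resid @ resid), amps, rates_arr))
    starts.sort(key=lambda s: s[0])

    amp_floor = max(1e-12, 1e-10 * float(np.max(y) if np.max(y) > 0 else 1.0))

    def pack(amps, rates):
        if model_form == "mono_exp":
            return np.log([max(amps[0], amp_floor), rates[0]])
        if model_form == "bi_exp":
            return np.log(
                [max(amps[0], amp_floor), rates[0], max(amps[1], amp_floor), rates[1]]
            )
        return np.log([max(amps[0], amp_floor), rates[0], max(amps[1], amp_floor)])

    def unpack(x):
        # clip so wayward LM steps cannot overflow exp()
        p = np.exp(np.clip(x, -60.0, 60.0))
        if model_form == "mono_exp":
            return p[[0]], p[[1]]
        if model_form == "bi_exp":
            return p[[0, 2]], p[[1, 3]]
        return p[[0, 2]], np.array([p[1], fixed_lambda])

    def residuals(x):
        amps, rates = unpack(x)
        return (_model_eval(t, amps, rates) - y) * w

    best = None
    for _, amps0, rates0 in starts[:5]:
        x0 = pack(amps0, rates0)
        try:
            res = optimize.least_squares(
                residuals, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15,
                max_nfev=2000,
            )
        except Exception:  # noqa: BLE001 - a failed start is not fatal
            continue
        rss = float(res.fun @ res.fun)
        if np.isfinite(rss) and (best is None or rss < best[0] - 1e-15 * (1 + best[0])):
            best = (rss, res.x)

    n_eff = tac.n_effective
    if best is None:
        return FitResult(
            model_form=model_form, a1=math.nan, lambda1=math.nan, a2=None, lambda2=None,
            rss=math.inf, aicc=math.nan, n_points=tac.n_points, n_eff=n_eff, k=k,
            converged=False, message="multi-start least squares did not converge",
        )

    rss, x = best
    amps, rates = unpack(x)
    comps = sorted(zip(amps, rates), key=lambda c: -c[1])  # lambda1 >= lambda2
    if model_form == "mono_exp":
        a1, l1 = comps[0]
        a2 = l2 = None
    else:
        (a1, l1), (a2, l2) = comps
    return FitResult(
        model_form=model_form,
        a1=float(a1), lambda1=float(l1),
        a2=None if a2 is None else float(a2),
        lambda2=None if l2 is None else float(l2),
        rss=rss,
        aicc=_aicc(rss, n_eff, k, tac.n_points),
        n_points=tac.n_points, n_eff=n_eff, k=k,
        converged=True,
    )


def select_model(fits: Sequence[FitResult]) -> FitResult:
    """Return the minimum-AICc fit; ties go to the model with fewer parameters.

    Candidates that did not converge, or whose AICc correction is undefined
    (n_eff − k − 1 <= 0), are excluded with a warning.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("select_model needs at least one candidate")
    n_points = {f.n_points for f in fits}
    if len(n_points) != 1:
        raise ValueError("all candidate fits must be on identical data")
    eligible = []
    for f in fits:
        if not f.converged:
            warnings.warn(f"{f.model_form}: excluded (did not converge)", stacklevel=2)
            continue
        if math.isnan(f.aicc):
            warnings.warn(
                f"{f.model_form}: excluded (AICc undefined, n_eff={f.n_eff} <= k+1={f.k + 1})",
                stacklevel=2,
            )
            continue
        eligible.append(f)
    if not eligible:
        raise ValueError("no candidate fit is eligible for selection")
    best_aicc = min(f.aicc for f in eligible)
    contenders = [f for f in eligible if f.aicc <= best_aicc + 1e-9]
    return min(contenders, key=lambda f: f.k)


def cumulated_activity(
    fit: FitResult,
    physical_lambda: float = 0.0,
    data_is_decay_corrected: bool = True,
    horizon_h: float = math.inf,
) -> CumulatedActivity:
    """Integrate the fitted curve: Ã = Σ A_i / λ_i,eff (%IA·h).

    If the fitted data were decay-corrected, the physical decay constant is
    added back to every fitted (biological) rate before integration.  An
    infinite horizon with any non-positive effective rate is an error.
    """
    if not fit.converged:
        raise ValueError("cannot integrate a non-converged fit")
    if physical_lambda < 0:
        raise ValueError("physical_lambda must be >= 0")
    add = physical_lambda if data_is_decay_corrected else 0.0
    total = 0.0
    for a, lam in fit.components:
        eff = lam + add
        if eff <= 0:
            raise ValueError(f"effective rate {eff} <= 0: integral diverges")
        if math.isinf(horizon_h):
            total += a / eff
        else:
            total += a / eff * (1.0 - math.exp(-eff * horizon_h))
    return CumulatedActivity(
        value=total,
        horizon_h=horizon_h,
        physical_decay_applied=data_is_decay_corrected and physical_lambda > 0,
    )


def fit_standard_errors(
    fit: FitResult, tac: TimeActivityCurve, sigma: np.ndarray | float
) -> np.ndarray:
    """Delta-method standard errors for (A1, λ1[, A2, λ2]) given known noise SDs.

    Uses the Gauss–Newton covariance (Jᵀ Σ⁻¹ J)⁻¹ evaluated at the fitted
    parameters with the supplied per-point noise standard deviations.
    """
    t = tac.times
    sig = np.broadcast_to(np.asarray(sigma, dtype=float), t.shape)
    cols = []
    for a, lam in fit.components:
        e = np.exp(-lam * t)
        cols.append(e)            # d/dA
        cols.append(-a * t * e)   # d/dlambda
    J = np.column_stack(cols) / sig[:, None]
    cov = np.linalg.pinv(J.T @ J)
    return np.sqrt(np.clip(np.diag(cov), 0.0, None))
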