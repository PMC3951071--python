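"""Linear-quadratic dose-response fitting for blood-cell fractions.

The model is y = exp(-a*D - b*D^2): the expected fraction of control y at
dose D Gy, with linear sensitivity a (Gy^-1) and quadratic sensitivity b
(Gy^-2), both constrained non-negative.  Fitting minimizes the weighted sum
of squares on the *untransformed* fraction scale,

    SS(a, b) = sum_g w_g * (y_g - exp(-a*D_g - b*D_g^2))^2,

with weights w_g equal to the number of animals behind each group mean.  For
equal group sizes this is identical to fitting the individual animals,
because the within-group scatter does not depend on (a, b).

The through-origin regression of -log(y) on (D, D^2) provides a closed-form
starting point; a second start at (0, 0) guards against log-scale outliers
pulling the first start into a poor basin.  Degenerate data that are best
described by a flat curve end up at the a = b = 0 boundary.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import f as f_dist

from .datamodel import GroupSummary

__all__ = ["LQFit", "LQFitError", "fit_lq", "fit_lq_groups", "fit_lq_records",
           "evaluate_lq", "dose_response_significance"]

#: Convergence tolerance on parameters for the bounded optimizer.
XTOL = 1e-12
#: Two fits whose weighted SSRs differ by less than this relative amount are
#: considered tied; ties break toward the smaller quadratic coefficient.
SSR_TIE_RTOL = 1e-9


class LQFitError(RuntimeError):
    """Dose-response fit could not be performed."""


@dataclass
class LQFit:
    """Fitted coefficients of y = exp(-a*D - b*D^2) with inference metadata.

    ``cov`` is the Gauss-Newton covariance of (a, b) at the optimum; ``df``
    is n_points - 2 by convention, regardless of active non-negativity
    bounds.  The fit retains its design (doses, weights, observed values) so
    that resampling-based intervals can be computed later.
    """

    a: float
    b: float
    cov: np.ndarray
    ssr: float
    df: int
    n_points: int
    p_value: float
    significant: bool
    doses: np.ndarray
    weights: np.ndarray
    values: np.ndarray
    ssr_unconstrained: float = float("nan")
    alpha: float = 0.05
    cell_type: str | None = None
    timepoint: str | None = None
    arm: str | None = None

    @property
    def residual_variance(self) -> float:
        """Weighted residual mean square, SSR / df (variance of a w=1 unit)."""
        return self.ssr / self.df if self.df > 0 else float("nan")

    def to_dict(self) -> dict:
        return {
            "cell_type": self.cell_type,
            "timepoint": self.timepoint,
            "arm": self.arm,
            "a": self.a,
            "b": self.b,
            "cov": np.asarray(self.cov).tolist(),
            "ssr": self.ssr,
            "df": self.df,
            "n_points": self.n_points,
            "p_value": self.p_value,
            "significant": bool(self.significant),
        }


def _model(params: np.ndarray, doses: np.ndarray) -> np.ndarray:
    a, b = params
    return np.exp(-a * doses - b * doses**2)


def _log_scale_start(doses: np.ndarray, values: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Through-origin weighted regression of -log(y) on (D, D^2)."""
    ly = -np.log(values)
    X = np.column_stack([doses, doses**2])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], ly * sw, rcond=None)
    return np.clip(coef, 0.0, None)


def fit_lq(
    doses: Sequence[float],
    values: Sequence[float],
    weights: Sequence[float] | None = None,
    *,
    alpha: float = 0.05,
    cell_type: str | None = None,
    timepoint: str | None = None,
    arm: str | None = None,
) -> LQFit:
    """Bounded least-squares fit of the linear-quadratic decay model.

    Parameters
    ----------
    doses, values
        Positive doses (Gy) and observed fractions of control.  Group means
        and per-animal observations are both acceptable; pass the group sizes
        as ``weights`` when fitting means.
    weights
        Least-squares weights, default 1 for every observation.
    alpha
        Significance level for the dose-response F-test against the flat
        null y = 1.
    """
    D = np.asarray(doses, dtype=float)
    y = np.asarray(values, dtype=float)
    w = np.ones_like(D) if weights is None else np.asarray(weights, dtype=float)
    if D.shape != y.shape or D.shape != w.shape:
        raise LQFitError("doses, values and weights must have equal length")
    if np.any(D <= 0):
        raise LQFitError("fit_lq expects strictly positive doses (dose 0 is the "
                         "model-forced intercept y(0)=1 and is not a data point)")
    if np.any(y <= 0):
        raise LQFitError("fractions of control must be positive")
    if len(np.unique(D)) < 3:
        raise LQFitError(
            f"need >= 3 distinct positive doses, got {sorted(set(D.tolist()))}"
        )

    sw = np.sqrt(w)

    def resid(p: np.ndarray) -> np.ndarray:
        return sw * (y - _model(p, D))

    starts = [_log_scale_start(D, y, w), np.zeros(2)]
    best: optimize.OptimizeResult | None = None
    for p0 in starts:
        res = optimize.least_squares(
            resid,
            p0,
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            xtol=XTOL,
            ftol=XTOL,
            gtol=XTOL,
        )
        if not res.success:
            continue
        if best is None:
            best = res
        elif res.cost < best.cost * (1.0 - SSR_TIE_RTOL):
            best = res
        elif abs(res.cost - best.cost) <= SSR_TIE_RTOL * max(best.cost, 1e-300):
            if res.x[1] < best.x[1]:
                best = res
    if best is None:
        raise LQFitError(
            "bounded LQ optimization failed to converge from all starts "
            f"(doses={D.tolist()}, values={y.tolist()})"
        )

    # Newton polish with analytic derivatives so equivalent problems (e.g.
    # individuals vs. weighted group means) land on the same optimum to well
    # below 1e-8 in the parameters.
    x_pol = _newton_polish(D, y, w, best.x)
    if float(resid(x_pol) @ resid(x_pol)) <= 2.0 * best.cost + 1e-300:
        best_x = x_pol
    else:
        best_x = best.x

    a, b = (float(v) for v in best_x)
    r = resid(best_x)
    ssr = float(r @ r)
    n = len(D)
    df = n - 2

    # Gauss-Newton covariance at the optimum (weighted Jacobian).
    yhat = _model(best_x, D)
    J = np.column_stack([D * yhat, D**2 * yhat]) * sw[:, None]
    JtJ = J.T @ J
    s2 = ssr / df if df > 0 else float("nan")
    try:
        cov = s2 * np.linalg.inv(JtJ)
    except np.linalg.LinAlgError:
        cov = s2 * np.linalg.pinv(JtJ)

    # The F-test of "any dose response" compares the flat null y = 1 with the
    # *unconstrained* least-squares alternative: classical F distribution
    # theory needs an interior optimum, and testing against the bounded fit
    # would be conservative whenever a non-negativity bound is active.  The
    # reported coefficients themselves remain the bounded estimates.
    ssr_unc = min(ssr, _unconstrained_ssr(D, y, w, starts + [np.asarray(best_x)]))
    p_value, significant = _f_test(ssr_unc, float(w @ (y - 1.0) ** 2), df, alpha)

    return LQFit(
        a=a,
        b=b,
        cov=cov,
        ssr=ssr,
        df=df,
        n_points=n,
        p_value=p_value,
        significant=significant,
        doses=D,
        weights=w,
        values=y,
        ssr_unconstrained=ssr_unc,
        alpha=alpha,
        cell_type=cell_type,
        timepoint=timepoint,
        arm=arm,
    )


def _newton_polish(
    D: np.ndarray, y: np.ndarray, w: np.ndarray, x0: np.ndarray, max_iter: int = 50
) -> np.ndarray:
    """Active-set Newton refinement of the weighted SSR at the trf optimum."""
    x = np.clip(np.asarray(x0, dtype=float), 0.0, None)

    def ssr_of(p: np.ndarray) -> float:
        r = y - _model(p, D)
        return float(w @ (r * r))

    for _ in range(max_iter):
        m = _model(x, D)
        r = y - m
        md = np.column_stack([-D * m, -(D**2) * m])  # dm/da, dm/db
        g = -2.0 * (w * r) @ md
        H = 2.0 * (md.T * w) @ md
        # exact second-order term: d2m/dθdφ = D^(i+j) * m
        H[0, 0] -= 2.0 * (w * r) @ (D**2 * m)
        H[0, 1] -= 2.0 * (w * r) @ (D**3 * m)
        H[1, 0] = H[0, 1]
        H[1, 1] -= 2.0 * (w * r) @ (D**4 * m)
        free = (x > 0) | (g < 0)  # at the bound only a negative gradient frees it
        if not free.any():
            break
        step = np.zeros(2)
        try:
            step[free] = np.linalg.solve(H[np.ix_(free, free)], -g[free])
        except np.linalg.LinAlgError:
            break
        base = ssr_of(x)
        scale = 1.0
        for _ in range(30):
            x_new = np.clip(x + scale * step, 0.0, None)
            if ssr_of(x_new) <= base:
                break
            scale /= 2.0
        else:
            break
        if np.max(np.abs(x_new - x)) < 1e-14:
            x = x_new
            break
        x = x_new
    return x


def _unconstrained_ssr(
    doses: np.ndarray, values: np.ndarray, w: np.ndarray, starts: list[np.ndarray]
) -> float:
    sw = np.sqrt(w)

    def resid(p: np.ndarray) -> np.ndarray:
        return sw * (values - _model(p, doses))

    best = math.inf
    for p0 in starts:
        res = optimize.least_squares(resid, p0, xtol=XTOL, ftol=XTOL, gtol=XTOL)
        if res.success:
            best = min(best, 2.0 * res.cost)
    return best


def _f_test(ssr_model: float, ssr_null: float, df: int, alpha: float) -> tuple[float, bool]:
    if df < 1:
        return float("nan"), False
    if ssr_model <= 0:
        # Perfect fit: significant iff the null leaves any effect to explain.
        return (0.0, True) if ssr_null > 0 else (1.0, False)
    F = max(ssr_null - ssr_model, 0.0) / 2.0 / (ssr_model / df)
    p = float(f_dist.sf(F, 2, df))
    return p, p < alpha


def fit_lq_groups(groups: Iterable[GroupSummary], *, alpha: float = 0.05) -> LQFit:
    """Fit one (cell_type, timepoint, arm) stratum of group summaries.

    Weights equal the group sizes n; pre-irradiation and sham (0 Gy) entries
    are excluded, since the model forces y(0) = 1.
    """
    gs = [g for g in groups if g.timepoint != "pre" and g.dose > 0]
    if not gs:
        raise LQFitError("no positive-dose groups to fit")
    keys = {(g.cell_type, g.timepoint, g.arm) for g in gs}
    if len(keys) != 1:
        raise LQFitError(f"groups span multiple strata: {sorted(keys)}")
    ct, tp, arm = next(iter(keys))
    return fit_lq(
        [g.dose for g in gs],
        [g.mean_fraction for g in gs],
        [g.n for g in gs],
        alpha=alpha,
        cell_type=ct,
        timepoint=tp,
        arm=arm,
    )


def fit_lq_records(records, *, alpha: float = 0.05) -> LQFit:
    """Fit per-animal normalized records of one stratum (weights 1 each)."""
    recs = [r for r in records if r.timepoint != "pre" and r.dose > 0]
    if not recs:
        raise LQFitError("no positive-dose records to fit")
    keys = {(r.cell_type, r.timepoint, r.arm) for r in recs}
    if len(keys) != 1:
        raise LQFitError(f"records span multiple strata: {sorted(keys)}")
    ct, tp, arm = next(iter(keys))
    return fit_lq(
        [r.dose for r in recs],
        [r.fraction_of_control for r in recs],
        alpha=alpha,
        cell_type=ct,
        timepoint=tp,
        arm=arm,
    )


def evaluate_lq(fit: "LQFit | tuple[float, float]", dose: float) -> float:
    """Predicted fraction of control at ``dose`` Gy; in (0, 1] for a,b >= 0."""
    a, b = (fit.a, fit.b) if isinstance(fit, LQFit) else fit
    if dose < 0:
        raise ValueError(f"negative dose {dose}")
    return float(math.exp(-a * dose - b * dose * dose))


def dose_response_significance(fit: LQFit, *, alpha: float | None = None) -> tuple[float, bool]:
    """F-test of the dose-response curve against the flat null y = 1.

    The statistic compares the null weighted SSR (all fractions at 1) with
    the unconstrained-alternative SSR on 2 numerator degrees of freedom.
    Returns (p, p < alpha); with df = 0 the p-value is NaN and the flag
    False (undeterminable).
    """
    alpha = fit.alpha if alpha is None else alpha
    ssr_null = float(fit.weights @ (fit.values - 1.0) ** 2)
    ssr_alt = fit.ssr
    if math.isfinite(fit.ssr_unconstrained):
        ssr_alt = min(ssr_alt, fit.ssr_unconstrained)
    return _f_test(ssr_alt, ssr_null, fit.df, alpha)
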