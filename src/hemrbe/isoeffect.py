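"""Isoeffective-dose inversion and RBE estimation.

The relative biological effectiveness (RBE) of a test radiation is the ratio
of the reference-radiation dose producing a given effect to the test dose
producing the same effect.  Here the effect is a blood-cell fraction of
control: for each test-arm animal the fitted reference curve
y = exp(-a*D - b*D^2) is inverted at the animal's observed fraction, and the
resulting isoeffective reference dose is divided by the test dose actually
delivered.  Per-animal RBE values are then regressed on test dose with a
quadratic trend, RBE(D) = c0 + c1*D + c2*D^2, whose mean-response t-intervals
provide the per-dose 95% confidence limits.

Because the test arm was sampled on Day 4 where the reference arm was sampled
on Day 7, test time-points map to reference time-points through an explicit
pairing map (identity except d4 -> d7).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import t as t_dist

from .datamodel import BloodCountRecord
from .dose_response import LQFit

__all__ = [
    "DEFAULT_PAIRING",
    "IsoeffectError",
    "RBEPoint",
    "RBETrendFit",
    "RBETableRow",
    "invert_lq",
    "rbe_per_animal",
    "fit_rbe_trend",
    "fitted_rbe_with_ci",
    "average_rbe",
]

#: Test-arm time-point -> reference-arm time-point used for its curve.
DEFAULT_PAIRING: dict[str, str] = {
    "4h": "4h",
    "d1": "d1",
    "d4": "d7",
    "d14": "d14",
    "d30": "d30",
}


class IsoeffectError(RuntimeError):
    """Isoeffective dose or RBE cannot be computed."""


def invert_lq(fit: "LQFit | tuple[float, float]", fraction: float) -> float:
    """Dose at which the fitted curve predicts ``fraction`` of control.

    Solves a*D + b*D^2 = -ln(fraction) for the unique non-negative root,
    using the cancellation-free form D = 2L / (a + sqrt(a^2 + 4*b*L)) with
    L = -ln(fraction), which remains accurate when b sits at the zero bound.
    Fractions >= 1 (no effect) map to dose 0.
    """
    a, b = (fit.a, fit.b) if isinstance(fit, LQFit) else fit
    if not fraction > 0:
        raise IsoeffectError(f"fraction must be positive, got {fraction}")
    L = -math.log(fraction)
    if L <= 0:
        return 0.0
    if a == 0 and b == 0:
        raise IsoeffectError("flat curve (a = b = 0) cannot produce the effect")
    return 2.0 * L / (a + math.sqrt(a * a + 4.0 * b * L))


@dataclass(slots=True)
class RBEPoint:
    """Per-animal RBE: isoeffective reference dose over delivered test dose."""

    animal_id: str
    cell_type: str
    timepoint_test: str
    timepoint_reference: str
    dose_test: float
    fraction_observed: float
    dose_isoeffective: float = float("nan")
    rbe: float = float("nan")
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


def rbe_per_animal(
    reference_fit: LQFit,
    test_records: Iterable[BloodCountRecord],
    pairing_map: Mapping[str, str] | None = None,
) -> list[RBEPoint]:
    """One RBE point per test-arm record via reference-curve inversion.

    Records whose inversion fails (e.g. a degenerate curve) are returned
    flagged with an ``error`` message instead of aborting the batch.
    """
    pairing = DEFAULT_PAIRING if pairing_map is None else dict(pairing_map)
    points = []
    for rec in test_records:
        if rec.timepoint not in pairing:
            raise IsoeffectError(
                f"no reference pairing for test timepoint {rec.timepoint!r}"
            )
        tp_ref = pairing[rec.timepoint]
        if reference_fit.timepoint is not None and reference_fit.timepoint != tp_ref:
            raise IsoeffectError(
                f"reference fit is for timepoint {reference_fit.timepoint!r}, "
                f"but test timepoint {rec.timepoint!r} pairs with {tp_ref!r}"
            )
        if rec.fraction_of_control is None:
            raise IsoeffectError(
                f"test record for animal {rec.animal_id} is not normalized"
            )
        if not rec.dose > 0:
            raise IsoeffectError(
                f"test dose must be positive for an RBE ratio (animal {rec.animal_id})"
            )
        point = RBEPoint(
            animal_id=rec.animal_id,
            cell_type=rec.cell_type,
            timepoint_test=rec.timepoint,
            timepoint_reference=tp_ref,
            dose_test=rec.dose,
            fraction_observed=rec.fraction_of_control,
        )
        try:
            iso = invert_lq(reference_fit, rec.fraction_of_control)
            point.dose_isoeffective = iso
            point.rbe = iso / rec.dose
        except IsoeffectError as exc:
            point.error = str(exc)
        points.append(point)
    return points


@dataclass
class RBETrendFit:
    """OLS quadratic of RBE on test dose with coefficient covariance."""

    c0: float
    c1: float
    c2: float
    cov: np.ndarray
    residual_variance: float
    df: int
    n_points: int
    doses: np.ndarray

    @property
    def coef(self) -> np.ndarray:
        return np.array([self.c0, self.c1, self.c2])

    @property
    def ci_available(self) -> bool:
        return self.df >= 1

    def to_dict(self) -> dict:
        return {
            "c0": self.c0,
            "c1": self.c1,
            "c2": self.c2,
            "cov": np.asarray(self.cov).tolist(),
            "residual_variance": self.residual_variance,
            "df": self.df,
            "n_points": self.n_points,
        }


def fit_rbe_trend(
    points: "Sequence[RBEPoint] | Sequence[float]",
    rbes: Sequence[float] | None = None,
) -> RBETrendFit:
    """Fit RBE(D) = c0 + c1*D + c2*D^2 by ordinary least squares.

    Accepts either a collection of :class:`RBEPoint` (flagged points are
    dropped) or parallel dose/RBE arrays.  Requires at least 3 distinct
    doses; with df = 0 (a saturated design) the fit is returned with the
    confidence-interval machinery disabled.
    """
    if rbes is None:
        pts = [p for p in points if isinstance(p, RBEPoint) and p.ok]
        D = np.array([p.dose_test for p in pts], dtype=float)
        R = np.array([p.rbe for p in pts], dtype=float)
    else:
        D = np.asarray(points, dtype=float)
        R = np.asarray(rbes, dtype=float)
    if len(np.unique(D)) < 3:
        raise IsoeffectError(
            f"quadratic RBE trend needs >= 3 distinct test doses, got "
            f"{sorted(set(D.tolist()))}"
        )
    X = np.column_stack([np.ones_like(D), D, D**2])
    beta, *_ = np.linalg.lstsq(X, R, rcond=None)
    resid = R - X @ beta
    n = len(D)
    df = n - 3
    s2 = float(resid @ resid) / df if df > 0 else 0.0
    XtX = X.T @ X
    try:
        cov = s2 * np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        cov = s2 * np.linalg.pinv(XtX)
    return RBETrendFit(
        c0=float(beta[0]),
        c1=float(beta[1]),
        c2=float(beta[2]),
        cov=cov,
        residual_variance=s2,
        df=df,
        n_points=n,
        doses=D,
    )


@dataclass(slots=True)
class RBETableRow:
    """Fitted RBE at one test dose with a two-sided confidence interval."""

    dose_test: float
    rbe_fitted: float
    ci_low: float | None = None
    ci_high: float | None = None
    level: float = 0.95
    gated: bool = False
    cell_type: str | None = None
    timepoint: str | None = None

    def to_dict(self) -> dict:
        return {
            "cell_type": self.cell_type,
            "timepoint": self.timepoint,
            "dose_gy": self.dose_test,
            "rbe_fitted": self.rbe_fitted,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
            "gated": self.gated,
        }


def fitted_rbe_with_ci(
    trend: RBETrendFit, dose_test: float, level: float = 0.95
) -> RBETableRow:
    """Mean-response prediction of the RBE trend at one dose.

    The interval is fitted +/- t(1 - (1-level)/2, df) * sqrt(x' Sigma x)
    with x = (1, D, D^2): a confidence interval for the mean RBE, matching
    the dotted bands around a fitted quadratic trend.  Negative limits (and
    even negative fitted values) are reported as-is, not clamped.
    """
    x = np.array([1.0, dose_test, dose_test**2])
    fitted = float(x @ trend.coef)
    if not trend.ci_available:
        return RBETableRow(dose_test=dose_test, rbe_fitted=fitted, level=level)
    se = float(math.sqrt(max(x @ trend.cov @ x, 0.0)))
    tq = float(t_dist.ppf(0.5 + level / 2.0, trend.df))
    return RBETableRow(
        dose_test=dose_test,
        rbe_fitted=fitted,
        ci_low=fitted - tq * se,
        ci_high=fitted + tq * se,
        level=level,
    )


def average_rbe(
    rows: Sequence[RBETableRow],
    inclusion_rule: Callable[[RBETableRow], bool] | None = None,
) -> tuple[float, float]:
    """Mean and SEM of fitted RBE values over the selected endpoints.

    The default rule keeps every non-gated row (i.e. every dose x time-point
    x cell-type combination where both arms had significant dose responses).
    """
    rule = inclusion_rule if inclusion_rule is not None else (lambda r: not r.gated)
    values = np.array([r.rbe_fitted for r in rows if rule(r)], dtype=float)
    if len(values) < 2:
        raise IsoeffectError(
            f"average RBE needs >= 2 included endpoints, got {len(values)}"
        )
    return float(values.mean()), float(values.std(ddof=1) / math.sqrt(len(values)))
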