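"""Effective doses ED_p with confidence intervals and censoring conventions.

ED_p is the dose at which the fitted fraction of control equals 1 - p/100
(ED10 reduces counts by 10%, ED50 halves them).  It is the inversion of the
linear-quadratic curve at that fraction.  Reporting follows three censoring
conventions:

* a non-significant dose-response slope renders the whole cell as "NM"
  (not meaningful);
* a point estimate beyond the highest dose actually delivered renders as
  ">Dmax" (e.g. ">20.0") rather than extrapolating;
* ED90 is suppressed entirely whenever it exceeds the maximum dose.

Confidence intervals come from the delta method by default (first-order
propagation of the (a, b) covariance through the inversion), with a
parametric bootstrap (resampling group means around the fitted curve and
refitting) available as an independent cross-check.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm

from .dose_response import LQFit, LQFitError, fit_lq
from .isoeffect import IsoeffectError, invert_lq

__all__ = [
    "EDEstimate",
    "effective_dose",
    "ed_confidence_interval",
    "ed_table",
    "ed_table_markdown",
]

STATUS_REPORTED = "reported"
STATUS_EXCEEDS = "exceeds_max_dose"
STATUS_NM = "not_meaningful"


def effective_dose(fit: "LQFit | tuple[float, float]", p: float) -> float:
    """Dose reducing the fitted fraction of control by p percent."""
    if not 0 < p < 100:
        raise ValueError(f"p must be in (0, 100) percent, got {p}")
    a, b = (fit.a, fit.b) if isinstance(fit, LQFit) else fit
    if a + b <= 0:
        raise IsoeffectError("degenerate flat fit: effective dose undefined")
    return invert_lq((a, b), 1.0 - p / 100.0)


def _ed_gradient(a: float, b: float, ed: float) -> np.ndarray:
    # Implicit differentiation of a*D + b*D^2 = L at the estimate.
    denom = a + 2.0 * b * ed
    return np.array([-ed / denom, -(ed**2) / denom])


def ed_confidence_interval(
    fit: LQFit,
    p: float,
    level: float = 0.95,
    method: str = "delta",
    n_boot: int = 2000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Two-sided confidence interval for ED_p.

    ``delta``: variance of the inversion via its gradient and the fit
    covariance, normal quantiles.  ``bootstrap``: parametric resampling of
    the group means from (fitted value, residual variance / weight),
    refitting the bounded model each time, percentile interval;
    deterministic given ``seed``.  A non-finite covariance triggers a
    bootstrap fallback with a warning.
    """
    ed = effective_dose(fit, p)
    if method == "delta":
        if not np.all(np.isfinite(fit.cov)):
            warnings.warn(
                "fit covariance is singular/non-finite; falling back to the "
                "parametric bootstrap",
                RuntimeWarning,
                stacklevel=2,
            )
            method = "bootstrap"
        else:
            grad = _ed_gradient(fit.a, fit.b, ed)
            var = float(grad @ np.asarray(fit.cov) @ grad)
            se = math.sqrt(max(var, 0.0))
            z = float(norm.ppf(0.5 + level / 2.0))
            return ed - z * se, ed + z * se
    if method != "bootstrap":
        raise ValueError(f"unknown CI method {method!r}")

    rng = np.random.default_rng(seed)
    yhat = np.exp(-fit.a * fit.doses - fit.b * fit.doses**2)
    sd = np.sqrt(fit.residual_variance / fit.weights)
    draws = []
    for _ in range(n_boot):
        ystar = yhat + rng.normal(0.0, sd)
        ystar = np.clip(ystar, 1e-9, None)  # fractions must stay positive
        try:
            refit = fit_lq(fit.doses, ystar, fit.weights)
            draws.append(effective_dose(refit, p))
        except (IsoeffectError, LQFitError):
            continue
    if len(draws) < max(50, n_boot // 10):
        raise IsoeffectError("bootstrap produced too few valid replicates")
    lo, hi = np.quantile(draws, [0.5 - level / 2.0, 0.5 + level / 2.0])
    return float(lo), float(hi)


@dataclass(slots=True)
class EDEstimate:
    """One ED_p cell of the effective-dose table, with censoring status."""

    p: float
    value: float
    ci_low: float | None
    ci_high: float | None
    status: str
    max_dose: float
    suppressed: bool = False
    cell_type: str | None = None
    timepoint: str | None = None
    arm: str | None = None

    def render(self) -> str:
        """Human-readable cell: "x.x (lo-hi)", ">Dmax" or "NM"."""
        if self.status == STATUS_NM:
            return "NM"
        if self.status == STATUS_EXCEEDS:
            return f">{self.max_dose:.1f}"
        if self.ci_low is None or self.ci_high is None:
            return f"{self.value:.1f}"
        return f"{self.value:.1f} ({self.ci_low:.1f}-{self.ci_high:.1f})"

    def to_dict(self) -> dict:
        return {
            "cell_type": self.cell_type,
            "timepoint": self.timepoint,
            "arm": self.arm,
            "p": self.p,
            "value": self.value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "status": self.status,
            "max_dose": self.max_dose,
            "suppressed": self.suppressed,
            "rendered": self.render(),
        }


def ed_table(
    fits: Iterable[LQFit],
    p_levels: Sequence[float] = (10.0, 50.0, 90.0),
    max_dose: float = 20.0,
    *,
    ci_level: float = 0.95,
    ci_method: str = "delta",
    n_boot: int = 2000,
    seed: int | None = None,
) -> list[EDEstimate]:
    """Effective-dose grid over strata and percent-reduction levels.

    Non-significant fits yield "NM" for every p.  Point estimates above
    ``max_dose`` are censored as ">Dmax"; for ED90 such cells are
    additionally marked suppressed (conventionally left out of reports to
    avoid extrapolating beyond the delivered dose range).
    """
    out: list[EDEstimate] = []
    for fit in fits:
        for p in p_levels:
            meta = dict(cell_type=fit.cell_type, timepoint=fit.timepoint, arm=fit.arm)
            if not fit.significant:
                out.append(
                    EDEstimate(
                        p=p,
                        value=float("nan"),
                        ci_low=None,
                        ci_high=None,
                        status=STATUS_NM,
                        max_dose=max_dose,
                        **meta,
                    )
                )
                continue
            value = effective_dose(fit, p)
            if value > max_dose:
                out.append(
                    EDEstimate(
                        p=p,
                        value=value,
                        ci_low=None,
                        ci_high=None,
                        status=STATUS_EXCEEDS,
                        max_dose=max_dose,
                        suppressed=(p == 90),
                        **meta,
                    )
                )
                continue
            lo, hi = ed_confidence_interval(
                fit, p, level=ci_level, method=ci_method, n_boot=n_boot, seed=seed
            )
            out.append(
                EDEstimate(
                    p=p,
                    value=value,
                    ci_low=lo,
                    ci_high=hi,
                    status=STATUS_REPORTED,
                    max_dose=max_dose,
                    **meta,
                )
            )
    return out


def ed_table_markdown(estimates: Sequence[EDEstimate]) -> str:
    """Markdown table shaped like a published effective-dose summary.

    Rows are cell_type x timepoint, columns arm x p-level; suppressed ED90
    cells are left blank.
    """
    cols: list[tuple[str, float]] = []
    for e in estimates:
        key = (e.arm or "", e.p)
        if key not in cols:
            cols.append(key)
    rows: dict[tuple[str, str], dict[tuple[str, float], str]] = {}
    for e in estimates:
        rkey = (e.cell_type or "", e.timepoint or "")
        rows.setdefault(rkey, {})[(e.arm or "", e.p)] = (
            "" if e.suppressed else e.render()
        )
    header = "| cell type | timepoint | " + " | ".join(
        f"{arm} ED{p:g}" for arm, p in cols
    ) + " |"
    sep = "|" + "---|" * (2 + len(cols))
    lines = [header, sep]
    for (ct, tp), cells in rows.items():
        lines.append(
            f"| {ct} | {tp} | "
            + " | ".join(cells.get(c, "") for c in cols)
            + " |"
        )
    return "\n".join(lines)
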