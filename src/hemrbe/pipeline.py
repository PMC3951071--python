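"""End-to-end orchestration: normalize, fit, effective doses, RBE, report.

The pipeline mirrors the full analysis sequence: per-experiment
normalization to fraction of control, per-stratum linear-quadratic fits with
significance tests, effective-dose tables with censoring, and — when a test
arm with per-animal data is present — isoeffective-dose inversion, per-animal
RBE, quadratic dose trends with 95% intervals, and the cross-endpoint average
RBE.  Every gating decision (insignificant strata, censored EDs, skipped RBE
strata) is recorded in the report log with its reason.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .datamodel import (
    BloodCountRecord,
    Experiment,
    GroupSummary,
    normalize_to_fraction,
    summarize_groups,
)
from .dose_response import LQFit, LQFitError, fit_lq_groups
from .effective_dose import EDEstimate, ed_table, ed_table_markdown
from .isoeffect import (
    DEFAULT_PAIRING,
    IsoeffectError,
    RBETableRow,
    RBETrendFit,
    average_rbe,
    fit_rbe_trend,
    fitted_rbe_with_ci,
    rbe_per_animal,
)

__all__ = ["RunConfig", "ReportBundle", "run_pipeline"]


@dataclass
class RunConfig:
    """Tunable settings of one analysis run."""

    alpha: float = 0.05
    p_levels: tuple[float, ...] = (10.0, 50.0, 90.0)
    ci_level: float = 0.95
    ci_method: str = "delta"
    bootstrap_reps: int = 2000
    seed: int = 0
    reference_arm: str = "reference"
    test_arm: str = "test"
    pairing_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_PAIRING))
    max_dose: Mapping[str, float] = field(
        default_factory=lambda: {"reference": 20.0, "test": 10.0}
    )

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if any(not 0 < p < 100 for p in self.p_levels):
            raise ValueError("p_levels must lie in (0, 100) percent")


@dataclass
class ReportBundle:
    """All estimates of one run plus the gating log."""

    fits: dict[tuple[str, str, str], LQFit]
    effective_doses: list[EDEstimate]
    rbe_trends: dict[tuple[str, str], RBETrendFit]
    rbe_rows: list[RBETableRow]
    rbe_average: tuple[float, float] | None
    log: list[str]
    config: RunConfig

    def to_json(self) -> str:
        """Machine-readable report; byte-identical for identical runs."""
        payload = {
            "config": {
                "alpha": self.config.alpha,
                "p_levels": list(self.config.p_levels),
                "ci_level": self.config.ci_level,
                "ci_method": self.config.ci_method,
                "bootstrap_reps": self.config.bootstrap_reps,
                "seed": self.config.seed,
                "pairing_map": dict(self.config.pairing_map),
                "max_dose": dict(self.config.max_dose),
            },
            "fits": [self.fits[k].to_dict() for k in sorted(self.fits)],
            "effective_doses": [e.to_dict() for e in self.effective_doses],
            "rbe": {
                "trends": {
                    f"{ct}/{tp}": t.to_dict()
                    for (ct, tp), t in sorted(self.rbe_trends.items())
                },
                "rows": [r.to_dict() for r in self.rbe_rows],
                "average": (
                    None
                    if self.rbe_average is None
                    else {"mean": self.rbe_average[0], "sem": self.rbe_average[1]}
                ),
            },
            "log": self.log,
        }
        return json.dumps(payload, indent=2, sort_keys=True, allow_nan=True)

    def ed_markdown(self) -> str:
        return ed_table_markdown(self.effective_doses)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(self.to_json())
        (outdir / "ed_table.md").write_text(self.ed_markdown() + "\n")
        rows = "\n".join(
            "{cell_type},{timepoint},{dose_gy},{rbe_fitted},{ci_low},{ci_high},{gated}".format(
                **r.to_dict()
            )
            for r in self.rbe_rows
        )
        (outdir / "rbe_table.csv").write_text(
            "cell_type,timepoint,dose_gy,rbe_fitted,ci_low,ci_high,gated\n" + rows + "\n"
        )
        (outdir / "log.txt").write_text("\n".join(self.log) + "\n")


def run_pipeline(
    experiments: Sequence[Experiment] = (),
    summaries: Sequence[GroupSummary] = (),
    config: RunConfig | None = None,
) -> ReportBundle:
    """Run the full analysis on per-animal experiments and/or group tables.

    Group summaries supplied directly (e.g. published reference-arm tables)
    are merged with summaries computed from the normalized experiments.
    The RBE stage needs per-animal test-arm records; without them it is
    skipped with a logged reason rather than failing.
    """
    config = config or RunConfig()
    log: list[str] = []

    normalized = [normalize_to_fraction(e) for e in experiments]
    all_records: list[BloodCountRecord] = [r for e in normalized for r in e.records]
    all_summaries = list(summaries) + (
        summarize_groups(all_records) if all_records else []
    )

    by_stratum: dict[tuple[str, str, str], list[GroupSummary]] = {}
    for g in all_summaries:
        if g.timepoint == "pre" or g.dose <= 0:
            continue
        by_stratum.setdefault((g.arm, g.cell_type, g.timepoint), []).append(g)

    fits: dict[tuple[str, str, str], LQFit] = {}
    for key, groups in sorted(by_stratum.items()):
        arm, ct, tp = key
        try:
            fit = fit_lq_groups(groups, alpha=config.alpha)
        except LQFitError as exc:
            log.append(f"fit skipped for {arm}/{ct}/{tp}: {exc}")
            continue
        fits[key] = fit
        if not fit.significant:
            log.append(
                f"dose response not significant for {arm}/{ct}/{tp} "
                f"(p={fit.p_value:.4f}); ED cells will render as NM"
            )

    effective_doses: list[EDEstimate] = []
    for arm in sorted({k[0] for k in fits}):
        arm_fits = [fits[k] for k in sorted(fits) if k[0] == arm]
        max_dose = dict(config.max_dose).get(arm, max(f.doses.max() for f in arm_fits))
        estimates = ed_table(
            arm_fits,
            p_levels=config.p_levels,
            max_dose=max_dose,
            ci_level=config.ci_level,
            ci_method=config.ci_method,
            n_boot=config.bootstrap_reps,
            seed=config.seed,
        )
        for e in estimates:
            if e.status == "exceeds_max_dose":
                log.append(
                    f"ED{e.p:g} for {e.arm}/{e.cell_type}/{e.timepoint} censored: "
                    f"estimate {e.value:.2f} Gy exceeds max dose {max_dose:g} Gy"
                )
        effective_doses.extend(estimates)

    rbe_trends: dict[tuple[str, str], RBETrendFit] = {}
    rbe_rows: list[RBETableRow] = []
    rbe_average = None

    test_records = [
        r
        for r in all_records
        if r.arm == config.test_arm and r.dose > 0 and r.timepoint != "pre"
    ]
    if not test_records:
        log.append("RBE stage skipped: no per-animal test-arm records supplied")
    else:
        strata = sorted({(r.cell_type, r.timepoint) for r in test_records})
        pairing = dict(config.pairing_map)
        for ct, tp_test in strata:
            if tp_test not in pairing:
                log.append(f"RBE skipped for {ct}/{tp_test}: no timepoint pairing")
                continue
            tp_ref = pairing[tp_test]
            ref_fit = fits.get((config.reference_arm, ct, tp_ref))
            if ref_fit is None:
                log.append(
                    f"RBE skipped for {ct}/{tp_test}: no reference fit at {tp_ref}"
                )
                continue
            test_fit = fits.get((config.test_arm, ct, tp_test))
            gated = False
            if not ref_fit.significant:
                gated = True
                log.append(
                    f"RBE gated for {ct}/{tp_test}: reference dose response "
                    f"not significant (p={ref_fit.p_value:.4f})"
                )
            if test_fit is not None and not test_fit.significant:
                gated = True
                log.append(
                    f"RBE gated for {ct}/{tp_test}: test dose response "
                    f"not significant (p={test_fit.p_value:.4f})"
                )
            if ref_fit.a + ref_fit.b <= 0:
                log.append(
                    f"RBE skipped for {ct}/{tp_test}: flat reference curve"
                )
                continue
            records = [
                r for r in test_records if r.cell_type == ct and r.timepoint == tp_test
            ]
            points = rbe_per_animal(ref_fit, records, pairing)
            for p in points:
                if not p.ok:
                    log.append(
                        f"RBE point flagged for animal {p.animal_id} "
                        f"({ct}/{tp_test}): {p.error}"
                    )
            try:
                trend = fit_rbe_trend(points)
            except IsoeffectError as exc:
                log.append(f"RBE trend skipped for {ct}/{tp_test}: {exc}")
                continue
            rbe_trends[(ct, tp_test)] = trend
            for dose in sorted(set(p.dose_test for p in points if p.ok)):
                row = fitted_rbe_with_ci(trend, dose, level=config.ci_level)
                row.cell_type = ct
                row.timepoint = tp_test
                row.gated = gated
                rbe_rows.append(row)
        try:
            rbe_average = average_rbe(rbe_rows)
        except IsoeffectError as exc:
            log.append(f"average RBE not computed: {exc}")

    return ReportBundle(
        fits=fits,
        effective_doses=effective_doses,
        rbe_trends=rbe_trends,
        rbe_rows=rbe_rows,
        rbe_average=rbe_average,
        log=log,
        config=config,
    )
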