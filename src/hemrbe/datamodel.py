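"""Data containers and ingestion for two-arm blood-count experiments.

The analysis operates on longitudinal complete-blood-count measurements from
irradiated animals.  Each animal is sampled before irradiation and at a fixed
set of post-irradiation time-points; counts are normalized per experiment to a
*fraction of control*: the count divided by the mean pre-irradiation count of
that cell type over all animals in the experiment.  All downstream
dose-response fitting consumes either per-animal fractions or per-group
summaries (mean +/- SE at each dose).
"""
from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import studentized_range

logger = logging.getLogger(__name__)

ARMS = ("reference", "test")
#: Ordered sampling schedule.  "d4" is used by the test (proton) arm only,
#: "d7" by the reference (electron) arm only; the isoeffect stage aliases
#: them through an explicit pairing map rather than renaming data.
TIMEPOINTS = ("pre", "4h", "d1", "d4", "d7", "d14", "d30")
CELL_TYPES = (
    "WBC",
    "lymphocyte",
    "neutrophil",
    "monocyte",
    "eosinophil",
    "RBC",
    "platelet",
)

#: Significance tiers used to annotate count tables, highest threshold first.
TUKEY_TIERS = ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.10, "#"))
NOT_TESTABLE = "NT"


class DataModelError(ValueError):
    """Invalid record, experiment, or input file."""


@dataclass(slots=True)
class BloodCountRecord:
    """One animal x time-point x cell-type measurement.

    Exactly one of ``count`` (absolute cells per unit volume) or
    ``fraction_of_control`` must be populated on input; normalization fills
    the fraction from the count.
    """

    experiment_id: str
    arm: str
    animal_id: str
    dose: float
    timepoint: str
    cell_type: str
    count: float | None = None
    fraction_of_control: float | None = None

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise DataModelError(f"unknown arm {self.arm!r}; expected one of {ARMS}")
        if self.timepoint not in TIMEPOINTS:
            raise DataModelError(
                f"unknown timepoint {self.timepoint!r}; expected one of {TIMEPOINTS}"
            )
        if self.cell_type not in CELL_TYPES:
            raise DataModelError(
                f"unknown cell type {self.cell_type!r}; expected one of {CELL_TYPES}"
            )
        if self.dose < 0:
            raise DataModelError(f"negative dose {self.dose} for animal {self.animal_id}")
        if (self.count is None) == (self.fraction_of_control is None):
            raise DataModelError(
                "exactly one of count / fraction_of_control must be set "
                f"(animal {self.animal_id}, {self.cell_type} @ {self.timepoint})"
            )
        value = self.count if self.count is not None else self.fraction_of_control
        if not (value > 0) or not math.isfinite(value):
            raise DataModelError(
                f"non-positive measurement {value!r} for animal {self.animal_id}"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.animal_id, self.timepoint, self.cell_type)


@dataclass(slots=True)
class GroupSummary:
    """Mean +/- SE of the fraction of control for one dose group."""

    arm: str
    dose: float
    timepoint: str
    cell_type: str
    n: int
    mean_fraction: float
    se_fraction: float
    se_defined: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DataModelError("group with n < 1")
        if not self.mean_fraction > 0:
            raise DataModelError("group mean fraction must be positive")
        if self.se_fraction < 0:
            raise DataModelError("negative SE")


@dataclass
class Experiment:
    """A cohort of animals irradiated together in one arm.

    ``baseline`` maps cell type -> mean pre-irradiation count over *all*
    animals of the experiment; it is populated by :func:`normalize_to_fraction`
    when records carry absolute counts.
    """

    experiment_id: str
    arm: str
    records: list[BloodCountRecord] = field(default_factory=list)
    baseline: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        for rec in self.records:
            if rec.key in seen:
                raise DataModelError(
                    f"duplicate (animal, timepoint, cell_type) {rec.key} "
                    f"in experiment {self.experiment_id}"
                )
            seen.add(rec.key)

    @property
    def is_normalized(self) -> bool:
        return all(r.fraction_of_control is not None for r in self.records)


def normalize_to_fraction(experiment: Experiment) -> Experiment:
    """Express every record as a fraction of the pre-irradiation control.

    The baseline for each cell type is the mean pre-irradiation count over all
    animals of the experiment; each record's fraction is count / baseline.
    Records that already carry a fraction pass through unchanged, so the
    operation is idempotent.
    """
    if experiment.is_normalized:
        return experiment

    pre_counts: dict[str, list[float]] = defaultdict(list)
    for rec in experiment.records:
        if rec.timepoint == "pre" and rec.count is not None:
            pre_counts[rec.cell_type].append(rec.count)

    cell_types_needed = {r.cell_type for r in experiment.records if r.count is not None}
    baseline: dict[str, float] = dict(experiment.baseline)
    for ct in sorted(cell_types_needed):
        if ct not in baseline:
            if not pre_counts[ct]:
                raise DataModelError(
                    f"no pre-irradiation baseline for cell type {ct!r} "
                    f"in experiment {experiment.experiment_id}"
                )
            baseline[ct] = float(np.mean(pre_counts[ct]))
        if not baseline[ct] > 0:
            raise DataModelError(
                f"non-positive baseline {baseline[ct]} for cell type {ct!r} "
                f"in experiment {experiment.experiment_id}"
            )

    new_records = []
    for rec in experiment.records:
        if rec.count is None:
            new_records.append(rec)
        else:
            new_records.append(
                replace(
                    rec,
                    count=None,
                    fraction_of_control=rec.count / baseline[rec.cell_type],
                )
            )
    return Experiment(experiment.experiment_id, experiment.arm, new_records, baseline)


def percent_change(fraction: float) -> float:
    """Change relative to baseline in percent; a decrease is negative."""
    if not fraction > 0:
        raise DataModelError("fraction of control must be positive")
    return (fraction - 1.0) * 100.0


def summarize_groups(records: Iterable[BloodCountRecord]) -> list[GroupSummary]:
    """Per (arm, dose, timepoint, cell_type) group: n, mean fraction, SE.

    SE is the sample standard deviation over sqrt(n); a single-record group
    gets SE 0 with ``se_defined=False``.
    """
    groups: dict[tuple[str, float, str, str], list[float]] = defaultdict(list)
    for rec in records:
        if rec.fraction_of_control is None:
            raise DataModelError(
                f"record for animal {rec.animal_id} is not normalized; "
                "call normalize_to_fraction first"
            )
        groups[(rec.arm, rec.dose, rec.timepoint, rec.cell_type)].append(
            rec.fraction_of_control
        )

    out = []
    for (arm, dose, tp, ct), values in sorted(groups.items()):
        n = len(values)
        mean = float(np.mean(values))
        if n >= 2:
            se = float(np.std(values, ddof=1) / math.sqrt(n))
            out.append(GroupSummary(arm, dose, tp, ct, n, mean, se))
        else:
            out.append(GroupSummary(arm, dose, tp, ct, n, mean, 0.0, se_defined=False))
    return out


CSV_COLUMNS = (
    "experiment_id",
    "arm",
    "animal_id",
    "dose_gy",
    "timepoint",
    "cell_type",
    "count",
    "fraction",
)


def load_counts_csv(path: str | Path) -> list[Experiment]:
    """Read a per-animal blood-count CSV into validated experiments.

    Expected columns: experiment_id, arm, animal_id, dose_gy, timepoint,
    cell_type and one (or both, mutually exclusive per row) of count /
    fraction.  Malformed rows are reported with their 1-based file row number.
    """
    df = pd.read_csv(path)
    missing = {"experiment_id", "arm", "animal_id", "dose_gy", "timepoint", "cell_type"} - set(
        df.columns
    )
    if missing:
        raise DataModelError(f"{path}: missing required columns {sorted(missing)}")
    if "count" not in df.columns and "fraction" not in df.columns:
        raise DataModelError(f"{path}: need a 'count' or 'fraction' column")

    by_exp: dict[tuple[str, str], list[BloodCountRecord]] = defaultdict(list)
    for idx, row in df.iterrows():
        rownum = idx + 2  # 1-based, after header
        count = row.get("count")
        fraction = row.get("fraction")
        count = None if count is None or pd.isna(count) else float(count)
        fraction = None if fraction is None or pd.isna(fraction) else float(fraction)
        try:
            rec = BloodCountRecord(
                experiment_id=str(row["experiment_id"]),
                arm=str(row["arm"]),
                animal_id=str(row["animal_id"]),
                dose=float(row["dose_gy"]),
                timepoint=str(row["timepoint"]),
                cell_type=str(row["cell_type"]),
                count=count,
                fraction_of_control=fraction,
            )
        except (DataModelError, ValueError) as exc:
            raise DataModelError(f"{path}: row {rownum}: {exc}") from exc
        by_exp[(rec.experiment_id, rec.arm)].append(rec)

    experiments = []
    for (exp_id, arm), recs in sorted(by_exp.items()):
        try:
            experiments.append(Experiment(exp_id, arm, recs))
        except DataModelError as exc:
            raise DataModelError(f"{path}: {exc}") from exc
    return experiments


def write_counts_csv(experiments: Sequence[Experiment], path: str | Path) -> None:
    rows = []
    for exp in experiments:
        for rec in exp.records:
            rows.append(
                {
                    "experiment_id": rec.experiment_id,
                    "arm": rec.arm,
                    "animal_id": rec.animal_id,
                    "dose_gy": rec.dose,
                    "timepoint": rec.timepoint,
                    "cell_type": rec.cell_type,
                    "count": rec.count,
                    "fraction": rec.fraction_of_control,
                }
            )
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def summaries_to_frame(groups: Iterable[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "arm": g.arm,
                "cell_type": g.cell_type,
                "timepoint": g.timepoint,
                "dose_gy": g.dose,
                "n": g.n,
                "mean_fraction": g.mean_fraction,
                "se_fraction": g.se_fraction,
            }
            for g in groups
        ]
    )


def tukey_vs_baseline(
    groups: Sequence[GroupSummary],
) -> dict[tuple[float, str], str]:
    """Tukey HSD tiers for each dose group against the pre-irradiation value.

    Works from summary statistics (mean, SE, n): within each time-point the
    family is all dose groups plus the pre-irradiation summary; the pooled
    error variance comes from the group SDs (SE * sqrt(n)).  Returns the tier
    symbol per (dose, timepoint): "***", "**", "*", "#", "" or "NT" when any
    group in the family has n < 2 (not testable rather than an error).
    """
    cell_types = {g.cell_type for g in groups}
    if len(cell_types) != 1:
        raise DataModelError(
            f"tukey_vs_baseline expects one cell type, got {sorted(cell_types)}"
        )
    pre = [g for g in groups if g.timepoint == "pre"]
    if not pre:
        raise DataModelError("no pre-irradiation summary supplied")
    base = pre[0]

    result: dict[tuple[float, str], str] = {}
    by_tp: dict[str, list[GroupSummary]] = defaultdict(list)
    for g in groups:
        if g.timepoint != "pre":
            by_tp[g.timepoint].append(g)

    for tp, fam in by_tp.items():
        family = fam + [base]
        if any(g.n < 2 or not g.se_defined for g in family):
            for g in fam:
                result[(g.dose, tp)] = NOT_TESTABLE
            continue
        k = len(family)
        df = sum(g.n - 1 for g in family)
        mse = sum((g.n - 1) * (g.se_fraction**2 * g.n) for g in family) / df
        for g in fam:
            if mse == 0:
                tier = "***" if g.mean_fraction != base.mean_fraction else ""
            else:
                q = abs(g.mean_fraction - base.mean_fraction) / math.sqrt(
                    mse / 2.0 * (1.0 / g.n + 1.0 / base.n)
                )
                p = float(studentized_range.sf(q, k, df))
                tier = ""
                for threshold, symbol in TUKEY_TIERS:
                    if p < threshold:
                        tier = symbol
                        break
            result[(g.dose, tp)] = tier
    return result
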