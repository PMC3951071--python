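"""Synthetic two-arm blood-count experiments with known ground truth.

The generator runs the analysis's own model forward: each animal draws a
pre-irradiation absolute count from a lognormal baseline distribution (per
cell type: mean and inter-animal CV), and each post-irradiation fraction is
exp(-a*D - b*D^2) multiplied by lognormal noise, exp(N(0, noise_sigma^2)).
Absolute post counts are the fraction times that animal's own baseline, so
the normalization stage (divide by the cohort pre-irradiation mean) is
exercised exactly as with real data.

A stratum's *true* RBE links the two arms: a_test = RBE * a_reference and
b_test = RBE^2 * b_reference make the isoeffect ratio independent of dose,
so the generator's RBE is recoverable at every test dose.

The default designs mirror a two-arm minipig study: test (proton) groups of
n = 3 at 5, 7.7 and 10 Gy, reference (electron) groups of n = 3 at 5, 7.5,
7.7, 10, 15 and 20 Gy, plus sham (0 Gy) animals that contribute to the
baseline but not to fits.  Time-points are treated independently (no
within-animal correlation across time), matching the analysis's assumptions
rather than hematopoietic kinetics.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .datamodel import ARMS, CELL_TYPES, TIMEPOINTS, BloodCountRecord, Experiment
from .isoeffect import DEFAULT_PAIRING, invert_lq

__all__ = [
    "ArmDesign",
    "SimulationConfig",
    "SyntheticDataset",
    "SimulationError",
    "generate_dataset",
    "true_rbe",
    "DEFAULT_BASELINES",
]

REFERENCE_DOSES = (5.0, 7.5, 7.7, 10.0, 15.0, 20.0)
TEST_DOSES = (5.0, 7.7, 10.0)

#: Baseline absolute counts (10^3 cells/uL except RBC in 10^6/uL) and
#: inter-animal CV.  CVs are sized so cohort-level SEs come out around the
#: few-percent to tens-of-percent range typical of n=3 minipig groups.
DEFAULT_BASELINES: dict[str, tuple[float, float]] = {
    "WBC": (14.0, 0.17),
    "lymphocyte": (9.0, 0.17),
    "neutrophil": (4.0, 0.35),
    "monocyte": (0.4, 0.28),
    "eosinophil": (0.2, 0.45),
    "platelet": (350.0, 0.17),
    "RBC": (6.5, 0.07),
}


class SimulationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(slots=True)
class ArmDesign:
    """Dose groups of one arm: positive distinct doses, n animals each."""

    doses: tuple[float, ...]
    n_per_group: int = 3
    max_dose: float | None = None

    def __post_init__(self) -> None:
        if len(set(self.doses)) != len(self.doses) or any(d <= 0 for d in self.doses):
            raise SimulationError(f"doses must be positive and distinct: {self.doses}")
        if self.n_per_group < 1:
            raise SimulationError("n_per_group must be >= 1")
        if self.max_dose is None:
            self.max_dose = max(self.doses)


@dataclass
class SimulationConfig:
    """Generative description of a two-arm experiment.

    ``strata`` maps (cell_type, timepoint, arm) to the true (a, b) of that
    stratum's dose-response curve.
    """

    seed: int
    arms: dict[str, ArmDesign]
    strata: dict[tuple[str, str, str], tuple[float, float]]
    noise_sigma: float = 0.2
    baseline_counts: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES)
    )
    pairing_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_PAIRING))
    include_sham: bool = True

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise SimulationError("noise_sigma must be >= 0")
        for arm in self.arms:
            if arm not in ARMS:
                raise SimulationError(f"unknown arm {arm!r}")
        gaps = []
        for (ct, tp, arm) in self.strata:
            if ct not in CELL_TYPES or tp not in TIMEPOINTS or arm not in ARMS:
                raise SimulationError(f"invalid stratum key ({ct}, {tp}, {arm})")
            if arm not in self.arms:
                gaps.append((ct, tp, arm))
            if ct not in self.baseline_counts:
                raise SimulationError(f"no baseline distribution for {ct!r}")
        if gaps:
            raise SimulationError(f"strata configured for undesigned arms: {gaps}")
        for arm in self.arms:
            if not any(key[2] == arm for key in self.strata):
                raise SimulationError(f"arm {arm!r} has no configured strata")

    @classmethod
    def two_arm(
        cls,
        seed: int,
        *,
        true_rbe: float = 2.5,
        a_reference: float = 0.058,
        b_reference: float = 0.0,
        cell_type: str = "WBC",
        timepoint_test: str = "d1",
        noise_sigma: float = 0.2,
        n_per_group: int = 3,
        reference_doses: Sequence[float] = REFERENCE_DOSES,
        test_doses: Sequence[float] = TEST_DOSES,
    ) -> "SimulationConfig":
        """Study-sized two-arm design for one cell type and time-point.

        The test-arm curve is a_test = RBE * a_ref, b_test = RBE^2 * b_ref,
        so the configured RBE holds at every dose.
        """
        tp_ref = DEFAULT_PAIRING.get(timepoint_test, timepoint_test)
        strata = {
            (cell_type, tp_ref, "reference"): (a_reference, b_reference),
            (cell_type, timepoint_test, "test"): (
                true_rbe * a_reference,
                true_rbe**2 * b_reference,
            ),
        }
        return cls(
            seed=seed,
            arms={
                "reference": ArmDesign(tuple(reference_doses), n_per_group),
                "test": ArmDesign(tuple(test_doses), n_per_group),
            },
            strata=strata,
            noise_sigma=noise_sigma,
        )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "arms": {
                arm: {"doses": list(d.doses), "n_per_group": d.n_per_group,
                      "max_dose": d.max_dose}
                for arm, d in self.arms.items()
            },
            "strata": [
                {"cell_type": ct, "timepoint": tp, "arm": arm, "a": a, "b": b}
                for (ct, tp, arm), (a, b) in sorted(self.strata.items())
            ],
            "noise_sigma": self.noise_sigma,
            "baseline_counts": {ct: list(mc) for ct, mc in
                                self.baseline_counts.items()},
            "pairing_map": dict(self.pairing_map),
            "include_sham": self.include_sham,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        return cls(
            seed=int(data["seed"]),
            arms={
                arm: ArmDesign(tuple(spec["doses"]),
                               int(spec.get("n_per_group", 3)),
                               spec.get("max_dose"))
                for arm, spec in data["arms"].items()
            },
            strata={
                (s["cell_type"], s["timepoint"], s["arm"]):
                    (float(s["a"]), float(s["b"]))
                for s in data["strata"]
            },
            noise_sigma=float(data.get("noise_sigma", 0.2)),
            baseline_counts={
                ct: tuple(mc) for ct, mc in
                data.get("baseline_counts", DEFAULT_BASELINES).items()
            },
            pairing_map=dict(data.get("pairing_map", DEFAULT_PAIRING)),
            include_sham=bool(data.get("include_sham", True)),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class SyntheticDataset:
    """Generated records (one experiment per arm) plus the generating truth."""

    experiments: list[Experiment]
    config: SimulationConfig

    @property
    def records(self) -> list[BloodCountRecord]:
        return [r for exp in self.experiments for r in exp.records]


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + cv * cv)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw one dataset; bit-for-bit reproducible from (config, seed)."""
    rng = np.random.default_rng(config.seed)
    experiments = []
    for arm in sorted(config.arms):  # fixed order keeps the stream stable
        design = config.arms[arm]
        strata = {
            (ct, tp): ab for (ct, tp, a), ab in sorted(config.strata.items()) if a == arm
        }
        cell_types = sorted({ct for ct, _ in strata})
        doses = ((0.0,) if config.include_sham else ()) + tuple(design.doses)
        records: list[BloodCountRecord] = []
        exp_id = f"sim-{arm}"
        for dose in doses:
            for i in range(design.n_per_group):
                animal = f"{arm}-{dose:g}Gy-{i + 1}"
                baselines = {}
                for ct in cell_types:
                    mu, sig = _lognormal_params(*config.baseline_counts[ct])
                    baselines[ct] = float(rng.lognormal(mu, sig))
                    records.append(
                        BloodCountRecord(
                            exp_id, arm, animal, dose, "pre", ct, count=baselines[ct]
                        )
                    )
                for (ct, tp), (a, b) in strata.items():
                    frac = math.exp(-a * dose - b * dose * dose)
                    if config.noise_sigma > 0:
                        frac *= math.exp(rng.normal(0.0, config.noise_sigma))
                    records.append(
                        BloodCountRecord(
                            exp_id, arm, animal, dose, tp, ct,
                            count=frac * baselines[ct],
                        )
                    )
        experiments.append(Experiment(exp_id, arm, records))
    return SyntheticDataset(experiments, config)


def true_rbe(config: SimulationConfig, cell_type: str, timepoint_test: str) -> float:
    """Ground-truth RBE of a stratum, a_test / a_reference.

    Requires the proportional configuration b_test = RBE^2 * b_reference,
    under which the isoeffect ratio is the same at every dose.  Otherwise a
    :class:`SimulationError` is raised carrying the dose-resolved ratios.
    """
    tp_ref = config.pairing_map.get(timepoint_test, timepoint_test)
    key_t = (cell_type, timepoint_test, "test")
    key_r = (cell_type, tp_ref, "reference")
    for key in (key_t, key_r):
        if key not in config.strata:
            raise SimulationError(f"stratum {key} is not configured")
    a_t, b_t = config.strata[key_t]
    a_r, b_r = config.strata[key_r]
    if a_r <= 0:
        raise SimulationError("reference stratum has a = 0; RBE undefined")
    rbe = a_t / a_r
    if abs(b_t - rbe * rbe * b_r) > 1e-12 * max(1.0, abs(b_r) * rbe * rbe):
        doses = config.arms["test"].doses
        ratios = {
            D: invert_lq((a_r, b_r), math.exp(-a_t * D - b_t * D * D)) / D
            for D in doses
        }
        raise SimulationError(
            "true RBE is dose-dependent (b_test != RBE^2 * b_reference); "
            f"dose-resolved isoeffect ratios: {ratios}"
        )
    return rbe
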