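"""Shipped reference-arm (electron) group-summary tables.

The package bundles the published electron-irradiation blood-count tables as
CSV files: per cell type, the group mean +/- SE of the fraction of control at
each dose (5, 7.5, 7.7, 10, 15, 20 Gy; n = 3 animals per dose group, pooled
from two experiments after per-experiment normalization) and time-point
(4 h, Day 1, 7, 14, 30), plus the pooled pre-irradiation baseline row.
Per-animal electron data were not published; every least-squares fit in this
package therefore runs on these group means with weights equal to n, which
is equivalent to fitting individuals for dose-only predictors.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from ..datamodel import GroupSummary

__all__ = ["available_cell_types", "load_reference_summaries", "load_reference_frame"]

_FILES = {
    "WBC": "electron_wbc.csv",
    "lymphocyte": "electron_lymphocyte.csv",
    "neutrophil": "electron_neutrophil.csv",
    "monocyte": "electron_monocyte.csv",
    "eosinophil": "electron_eosinophil.csv",
    "platelet": "electron_platelet.csv",
    "RBC": "electron_rbc.csv",
}


def available_cell_types() -> tuple[str, ...]:
    return tuple(_FILES)


def load_reference_frame(cell_type: str | None = None) -> pd.DataFrame:
    """Raw fixture table(s) as a DataFrame."""
    names = [cell_type] if cell_type is not None else list(_FILES)
    frames = []
    for name in names:
        if name not in _FILES:
            raise KeyError(f"no fixture table for cell type {name!r}")
        ref = resources.files("hemrbe.fixtures") / _FILES[name]
        with ref.open("r") as fh:
            frames.append(pd.read_csv(fh))
    return pd.concat(frames, ignore_index=True)


def load_reference_summaries(
    cell_type: str | None = None, *, include_pre: bool = True
) -> list[GroupSummary]:
    """Fixture tables as :class:`GroupSummary` objects ready for fitting."""
    df = load_reference_frame(cell_type)
    out = []
    for _, row in df.iterrows():
        if not include_pre and row["timepoint"] == "pre":
            continue
        out.append(
            GroupSummary(
                arm=row["arm"],
                dose=float(row["dose_gy"]),
                timepoint=row["timepoint"],
                cell_type=row["cell_type"],
                n=int(row["n"]),
                mean_fraction=float(row["mean_fraction"]),
                se_fraction=float(row["se_fraction"]),
            )
        )
    return out
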