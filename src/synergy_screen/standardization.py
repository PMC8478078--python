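"""Round-standardized growth indices.

Every experimental round carries its own mock-inoculum control.  A plant's
response to a treatment is expressed as a *standardized growth index* (SG):
the raw trait value minus the control mean of the plant's own round,
divided by the control standard deviation of that round,

    SG_T(i) = (X_T(i) - mean(X_C)) / sd(X_C),

with the mean and SD taken over the round's control replicates (sample SD,
n−1 denominator).  SG is dimensionless and comparable across rounds and
traits; under a Gaussian control model, |SG| > 1.96 marks performance
outside the controls' two-sided 95% range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .datamodel import (
    TRAIT_COLUMNS,
    TRAITS,
    PlantRecord,
    SynergyScreenError,
    Trait,
    plant_records_to_frame,
)

#: two-sided 95% standard-normal bound used to flag plants outside the
#: control range (scipy.stats.norm.isf(0.025) to printed precision)
SG_THRESHOLD_95 = 1.96

#: below this many control replicates a round's baseline is considered shaky
DEFAULT_CONTROL_WARN_THRESHOLD = 5

SG_COLUMNS = [
    "plant_id",
    "treatment",
    "treatment_kind",
    "isolate_a",
    "isolate_b",
    "round_id",
    "trait",
    "sg",
]


class StandardizationError(SynergyScreenError, ValueError):
    """Control statistics are missing or degenerate for a round/trait."""


@dataclass(frozen=True)
class ControlStats:
    """Per-round, per-trait control baseline (mean and sample SD)."""

    round_id: str
    trait: Trait
    n_controls: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise StandardizationError(
                f"round {self.round_id!r}, trait {self.trait.value!r}: "
                f"{self.n_controls} usable control replicate(s); need >= 2"
            )
        if not self.sd > 0:
            raise StandardizationError(
                f"round {self.round_id!r}, trait {self.trait.value!r}: "
                f"control SD is {self.sd}; standardization undefined"
            )


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return plant_records_to_frame(records)


def control_stats(
    records: Iterable[PlantRecord] | pd.DataFrame, round_id: str, trait: Trait
) -> ControlStats:
    """Control mean and sample SD for one round and trait.

    Only control replicates with a non-missing trait value count; fewer
    than two, or an SD of zero, is an error because the index is undefined.
    """
    df = _as_frame(records)
    col = TRAIT_COLUMNS[Trait(trait)]
    mask = (df["round_id"] == round_id) & (df["treatment_kind"] == "control")
    values = pd.to_numeric(df.loc[mask, col], errors="coerce").dropna()
    n = len(values)
    if n < 2:
        raise StandardizationError(
            f"round {round_id!r}, trait {Trait(trait).value!r}: "
            f"{n} usable control replicate(s); need >= 2"
        )
    return ControlStats(
        round_id=round_id,
        trait=Trait(trait),
        n_controls=n,
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
    )


def standardized_growth(x: float, stats: ControlStats) -> float:
    """Standardized growth index of a single measurement: (x − mean)/sd."""
    return (x - stats.mean) / stats.sd


def standardize_dataset(
    records: Iterable[PlantRecord] | pd.DataFrame,
    traits: Iterable[Trait] = TRAITS,
    min_controls: int = 2,
    warn_threshold: int = DEFAULT_CONTROL_WARN_THRESHOLD,
) -> pd.DataFrame:
    """Standardize every plant against its own round's controls.

    Returns a long table with one row per (plant, trait) that has a
    non-missing measurement: chlorophyll rows exist only for plants in the
    SPAD subsample.  Columns: ``plant_id, treatment, treatment_kind,
    isolate_a, isolate_b, round_id, trait, sg``.

    Raises :class:`StandardizationError`, naming the round and trait, when
    a round has fewer than ``min_controls`` usable control replicates or a
    zero control SD.  Rounds with fewer than ``warn_threshold`` controls
    trigger a :class:`UserWarning` but are still standardized.
    """
    import warnings

    df = _as_frame(records)
    traits = [Trait(t) for t in traits]
    min_controls = max(2, int(min_controls))

    pieces = []
    for trait in traits:
        col = TRAIT_COLUMNS[trait]
        sub = df[
            ["plant_id", "treatment_kind", "isolate_a", "isolate_b", "round_id", col]
        ].copy()
        sub[col] = pd.to_numeric(sub[col], errors="coerce")
        sub = sub.dropna(subset=[col])

        ctrl = sub[sub["treatment_kind"] == "control"]
        stats = ctrl.groupby("round_id")[col].agg(["count", "mean", "std"])
        for round_id in sub["round_id"].unique():
            if round_id not in stats.index or stats.loc[round_id, "count"] < min_controls:
                n = int(stats.loc[round_id, "count"]) if round_id in stats.index else 0
                raise StandardizationError(
                    f"round {round_id!r}, trait {trait.value!r}: "
                    f"{n} usable control replicate(s); need >= {min_controls}"
                )
            if not stats.loc[round_id, "std"] > 0:
                raise StandardizationError(
                    f"round {round_id!r}, trait {trait.value!r}: control SD is "
                    f"{stats.loc[round_id, 'std']}; standardization undefined"
                )
            if stats.loc[round_id, "count"] < warn_threshold:
                warnings.warn(
                    f"round {round_id!r}, trait {trait.value!r}: only "
                    f"{int(stats.loc[round_id, 'count'])} control replicates",
                    UserWarning,
                    stacklevel=2,
                )

        merged = sub.merge(
            stats.rename(columns={"mean": "_mean", "std": "_sd"}),
            left_on="round_id",
            right_index=True,
            how="left",
        )
        merged["trait"] = trait.value
        merged["sg"] = (merged[col] - merged["_mean"]) / merged["_sd"]
        pieces.append(merged.drop(columns=[col, "count", "_mean", "_sd"]))

    out = pd.concat(pieces, ignore_index=True)
    label = np.where(
        out["treatment_kind"] == "control",
        "control",
        np.where(
            out["isolate_b"].astype(str).str.len() > 0,
            out["isolate_a"].astype(str) + "+" + out["isolate_b"].astype(str),
            out["isolate_a"].astype(str),
        ),
    )
    out["treatment"] = label
    return out[SG_COLUMNS]
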