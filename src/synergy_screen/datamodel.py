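"""Core data types and tidy-table I/O for pairwise inoculation screens.

The experimental design modelled here is a combinatorial plant-inoculation
assay: a panel of microbial isolates is tested alone (single inoculation)
and in every unordered pair (dual inoculation), alongside mock-inoculum
controls.  Because the full screen is too large to grow at once, treatments
are split into *experimental rounds*; every round carries its own control
treatment, which later serves as the standardization baseline for that
round.

Replicate-level plant measurements (shoot dry weight, mature-leaf count,
and a SPAD chlorophyll reading taken on a subsample of plants) and
per-treatment germination counts are exchanged as tidy CSV tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


class Trait(str, Enum):
    """The three plant-performance variables measured per replicate."""

    SHOOT_DRY_WEIGHT = "shoot_dry_weight"
    N_MATURE_LEAVES = "n_mature_leaves"
    CHLOROPHYLL = "chlorophyll"


TRAITS: tuple[Trait, ...] = (
    Trait.SHOOT_DRY_WEIGHT,
    Trait.N_MATURE_LEAVES,
    Trait.CHLOROPHYLL,
)

#: raw-measurement column backing each trait (chlorophyll is read as SPAD)
TRAIT_COLUMNS: dict[Trait, str] = {
    Trait.SHOOT_DRY_WEIGHT: "shoot_dry_weight",
    Trait.N_MATURE_LEAVES: "n_mature_leaves",
    Trait.CHLOROPHYLL: "spad",
}

PLANT_CSV_COLUMNS = [
    "plant_id",
    "treatment_kind",
    "isolate_a",
    "isolate_b",
    "round_id",
    "shoot_dry_weight",
    "n_mature_leaves",
    "spad",
]

GERMINATION_CSV_COLUMNS = [
    "treatment_kind",
    "isolate_a",
    "isolate_b",
    "round_id",
    "seeds_introduced",
    "seeds_germinated",
    "rate",
]


class SynergyScreenError(Exception):
    """Base class for errors raised by this package."""


class DataValidationError(SynergyScreenError, ValueError):
    """A record or table violates a data-model invariant."""


class DesignError(SynergyScreenError, ValueError):
    """An experimental design violates a structural constraint."""


@dataclass(frozen=True, order=True)
class Treatment:
    """A control, single-, or dual-inoculation treatment.

    Dual pairs are unordered: ``Treatment.dual("b", "a")`` and
    ``Treatment.dual("a", "b")`` compare equal because isolates are stored
    in lexicographic order.
    """

    kind: str  # "control" | "single" | "dual"
    isolates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        expected = {"control": 0, "single": 1, "dual": 2}
        if self.kind not in expected:
            raise DataValidationError(f"unknown treatment kind {self.kind!r}")
        if len(self.isolates) != expected[self.kind]:
            raise DataValidationError(
                f"{self.kind} treatment must have {expected[self.kind]} "
                f"isolate(s), got {self.isolates!r}"
            )
        if any(not iso for iso in self.isolates):
            raise DataValidationError("isolate ids must be non-empty")
        if self.kind == "dual":
            a, b = self.isolates
            if a == b:
                raise DataValidationError(f"dual treatment with identical isolates {a!r}")
            if a > b:
                object.__setattr__(self, "isolates", (b, a))

    @classmethod
    def control(cls) -> "Treatment":
        return cls("control")

    @classmethod
    def single(cls, isolate: str) -> "Treatment":
        return cls("single", (isolate,))

    @classmethod
    def dual(cls, a: str, b: str) -> "Treatment":
        return cls("dual", (a, b))

    @property
    def label(self) -> str:
        """Human-readable label: ``control``, ``ver_0232``, ``a+b``."""
        if self.kind == "control":
            return "control"
        return "+".join(self.isolates)


@dataclass(frozen=True)
class ExperimentalRound:
    """A batch of treatments grown together, including its own control.

    The round is the standardization block: plant responses in its
    treatments are later expressed relative to this round's control mean
    and SD.
    """

    round_id: str
    treatments: tuple[Treatment, ...]
    max_treatments: int = 13

    def __post_init__(self) -> None:
        n_control = sum(1 for t in self.treatments if t.kind == "control")
        if n_control != 1:
            raise DesignError(
                f"round {self.round_id!r} must contain exactly one control "
                f"treatment, found {n_control}"
            )
        if len(self.treatments) > self.max_treatments:
            raise DesignError(
                f"round {self.round_id!r} has {len(self.treatments)} treatments, "
                f"exceeding the maximum of {self.max_treatments}"
            )
        if len(set(self.treatments)) != len(self.treatments):
            raise DesignError(f"round {self.round_id!r} lists a treatment twice")


@dataclass(frozen=True)
class PlantRecord:
    """One replicate plant's raw measurements.

    ``spad`` is ``None`` for plants outside the chlorophyll subsample
    (only a random subset of plants per treatment is SPAD-measured).
    """

    plant_id: str
    treatment: Treatment
    round_id: str
    shoot_dry_weight: float
    n_mature_leaves: int
    spad: float | None = None

    def __post_init__(self) -> None:
        if self.shoot_dry_weight < 0:
            raise DataValidationError(
                f"plant {self.plant_id!r}: negative shoot dry weight"
            )
        if self.n_mature_leaves < 0:
            raise DataValidationError(
                f"plant {self.plant_id!r}: negative mature-leaf count"
            )


@dataclass(frozen=True)
class GerminationRecord:
    """Germination outcome of one treatment: germinated / introduced seeds."""

    treatment: Treatment
    round_id: str
    seeds_introduced: int
    seeds_germinated: int

    def __post_init__(self) -> None:
        if self.seeds_introduced < 1:
            raise DataValidationError("seeds_introduced must be >= 1")
        if not 0 <= self.seeds_germinated <= self.seeds_introduced:
            raise DataValidationError(
                f"seeds_germinated = {self.seeds_germinated} outside "
                f"[0, {self.seeds_introduced}]"
            )

    @property
    def rate(self) -> float:
        return germination_rate(self.seeds_germinated, self.seeds_introduced)


def germination_rate(seeds_germinated: int, seeds_introduced: int) -> float:
    """Fraction of introduced seeds that germinated."""
    if seeds_introduced < 1:
        raise DataValidationError("seeds_introduced must be >= 1")
    if not 0 <= seeds_germinated <= seeds_introduced:
        raise DataValidationError(
            f"seeds_germinated = {seeds_germinated} outside [0, {seeds_introduced}]"
        )
    return seeds_germinated / seeds_introduced


def enumerate_pairs(isolates: Sequence[str]) -> list[tuple[str, str]]:
    """All N(N−1)/2 unordered isolate pairs, each sorted, in lexicographic order."""
    ids = list(isolates)
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DataValidationError(f"duplicate isolate ids: {dupes}")
    return [tuple(sorted(p)) for p in itertools.combinations(sorted(ids), 2)]


# ---------------------------------------------------------------------------
# row-level conversion helpers


def _treatment_from_row(kind: str, isolate_a: str, isolate_b: str, where: str) -> Treatment:
    kind = (kind or "").strip()
    a = (isolate_a or "").strip()
    b = (isolate_b or "").strip()
    isolates = tuple(x for x in (a, b) if x)
    try:
        if kind == "control":
            if isolates:
                raise DataValidationError("control row lists isolates")
            return Treatment.control()
        if kind == "single":
            if len(isolates) != 1:
                raise DataValidationError("single row must name exactly one isolate")
            return Treatment.single(isolates[0])
        if kind == "dual":
            if len(isolates) != 2:
                raise DataValidationError("dual row must name two isolates")
            return Treatment.dual(*isolates)
        raise DataValidationError(f"unknown treatment kind {kind!r}")
    except DataValidationError as exc:
        raise DataValidationError(f"{where}: {exc}") from None


def _parse_number(value, field: str, where: str, *, integer: bool = False):
    if value is None or (isinstance(value, str) and not value.strip()) or pd.isna(value):
        return None
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise DataValidationError(f"{where}: field {field!r} is not numeric: {value!r}")
    if integer:
        if out != int(out):
            raise DataValidationError(f"{where}: field {field!r} must be an integer")
        return int(out)
    return out


def read_plant_records(path: str | Path) -> list[PlantRecord]:
    """Read replicate plant measurements from a tidy CSV.

    Expected header: ``plant_id, treatment_kind, isolate_a, isolate_b,
    round_id, shoot_dry_weight, n_mature_leaves, spad``.  Empty ``spad``
    cells denote plants outside the chlorophyll subsample.  Dual pairs are
    canonicalized on read; row order is preserved.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PLANT_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing columns {missing}")
    records: list[PlantRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        where = f"{path} row {i}"
        treatment = _treatment_from_row(
            row.treatment_kind, row.isolate_a, row.isolate_b, where
        )
        sdw = _parse_number(row.shoot_dry_weight, "shoot_dry_weight", where)
        leaves = _parse_number(row.n_mature_leaves, "n_mature_leaves", where, integer=True)
        if sdw is None or leaves is None:
            raise DataValidationError(f"{where}: shoot_dry_weight and n_mature_leaves are required")
        spad = _parse_number(row.spad, "spad", where)
        if not row.plant_id.strip():
            raise DataValidationError(f"{where}: empty plant_id")
        if not row.round_id.strip():
            raise DataValidationError(f"{where}: empty round_id")
        try:
            records.append(
                PlantRecord(
                    plant_id=row.plant_id.strip(),
                    treatment=treatment,
                    round_id=row.round_id.strip(),
                    shoot_dry_weight=sdw,
                    n_mature_leaves=leaves,
                    spad=spad,
                )
            )
        except DataValidationError as exc:
            raise DataValidationError(f"{where}: {exc}") from None
    return records


def plant_records_to_frame(records: Iterable[PlantRecord]) -> pd.DataFrame:
    """Tidy DataFrame view of plant records (one row per plant)."""
    rows = []
    for r in records:
        iso = r.treatment.isolates
        rows.append(
            {
                "plant_id": r.plant_id,
                "treatment_kind": r.treatment.kind,
                "isolate_a": iso[0] if len(iso) >= 1 else "",
                "isolate_b": iso[1] if len(iso) == 2 else "",
                "round_id": r.round_id,
                "shoot_dry_weight": r.shoot_dry_weight,
                "n_mature_leaves": r.n_mature_leaves,
                "spad": r.spad,
            }
        )
    return pd.DataFrame(rows, columns=PLANT_CSV_COLUMNS)


def frame_to_plant_records(df: pd.DataFrame) -> list[PlantRecord]:
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        where = f"frame row {i}"
        treatment = _treatment_from_row(
            str(row.treatment_kind), str(row.isolate_a or ""), str(row.isolate_b or ""), where
        )
        spad = None if pd.isna(row.spad) else float(row.spad)
        records.append(
            PlantRecord(
                plant_id=str(row.plant_id),
                treatment=treatment,
                round_id=str(row.round_id),
                shoot_dry_weight=float(row.shoot_dry_weight),
                n_mature_leaves=int(row.n_mature_leaves),
                spad=spad,
            )
        )
    return records


def write_plant_records(records: Iterable[PlantRecord] | pd.DataFrame, path: str | Path) -> None:
    """Write plant records as CSV (empty cell for missing SPAD)."""
    df = records if isinstance(records, pd.DataFrame) else plant_records_to_frame(records)
    df = df[PLANT_CSV_COLUMNS].copy()
    df.to_csv(path, index=False)


def read_germination_records(path: str | Path) -> list[GerminationRecord]:
    """Read per-treatment germination counts from a tidy CSV.

    A ``rate`` column, if present, is checked against the count quotient.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = [c for c in GERMINATION_CSV_COLUMNS if c != "rate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        where = f"{path} row {i}"
        treatment = _treatment_from_row(
            row.treatment_kind, row.isolate_a, row.isolate_b, where
        )
        introduced = _parse_number(row.seeds_introduced, "seeds_introduced", where, integer=True)
        germinated = _parse_number(row.seeds_germinated, "seeds_germinated", where, integer=True)
        if introduced is None or germinated is None:
            raise DataValidationError(f"{where}: seed counts are required")
        try:
            rec = GerminationRecord(
                treatment=treatment,
                round_id=row.round_id.strip(),
                seeds_introduced=introduced,
                seeds_germinated=germinated,
            )
        except DataValidationError as exc:
            raise DataValidationError(f"{where}: {exc}") from None
        if "rate" in df.columns and str(getattr(row, "rate", "")).strip():
            stated = float(row.rate)
            if abs(stated - rec.rate) > 1e-6:
                raise DataValidationError(
                    f"{where}: stated rate {stated} != "
                    f"{rec.seeds_germinated}/{rec.seeds_introduced}"
                )
        records.append(rec)
    return records


def germination_records_to_frame(records: Iterable[GerminationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        iso = r.treatment.isolates
        rows.append(
            {
                "treatment_kind": r.treatment.kind,
                "isolate_a": iso[0] if len(iso) >= 1 else "",
                "isolate_b": iso[1] if len(iso) == 2 else "",
                "round_id": r.round_id,
                "seeds_introduced": r.seeds_introduced,
                "seeds_germinated": r.seeds_germinated,
                "rate": r.rate,
            }
        )
    return pd.DataFrame(rows, columns=GERMINATION_CSV_COLUMNS)


def write_germination_records(
    records: Iterable[GerminationRecord] | pd.DataFrame, path: str | Path
) -> None:
    df = (
        records
        if isinstance(records, pd.DataFrame)
        else germination_records_to_frame(records)
    )
    df.to_csv(path, index=False)


def infer_rounds(
    records: Iterable[PlantRecord], max_treatments_per_round: int = 13
) -> list[ExperimentalRound]:
    """Reconstruct the round structure from plant records and validate it.

    Each treatment must appear in exactly one round and each round must
    contain control replicates.
    """
    by_round: dict[str, set[Treatment]] = {}
    for r in records:
        by_round.setdefault(r.round_id, set()).add(r.treatment)
    seen: dict[Treatment, str] = {}
    rounds = []
    for round_id in sorted(by_round):
        treatments = by_round[round_id]
        for t in treatments:
            if t.kind == "control":
                continue
            if t in seen:
                raise DesignError(
                    f"treatment {t.label!r} appears in rounds {seen[t]!r} and "
                    f"{round_id!r}; each treatment must belong to exactly one round"
                )
            seen[t] = round_id
        rounds.append(
            ExperimentalRound(
                round_id=round_id,
                treatments=tuple(sorted(treatments)),
                max_treatments=max_treatments_per_round,
            )
        )
    return rounds
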