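"""Synthetic pairwise-inoculation screens with known ground truth.

The generator reproduces the structure of the laboratory screen — 13
isolates tested alone and in all 78 pairs plus mock controls, treatments
split into rounds of at most 13 (each round with its own control), 20–35
replicate cells per treatment with 2 seeds each, SPAD chlorophyll measured
on a random 15-plant subsample as the mean of 3 readings — while making
the effect structure explicit:

* each round r and trait has a control baseline ``mu_r`` drawn once;
* a single inoculation with isolate k shifts the trait mean by ``a_k``;
* a dual inoculation with isolates A and B shifts it by
  ``(a_A + a_B)/2 + gamma_AB``, so the per-pair deviation ``gamma_AB`` is
  exactly the quantity the intermediate-deviation index (DI) estimates;
* replicate noise is Gaussian with trait-specific SD ``sigma``.

Single effects default to a shifted-exponential draw in control-SD units
(most isolates near neutral, a thin right tail of strong growth
promoters, a floor allowing mildly negative effects), matching the
reported spread of single-inoculation outcomes in screens of this kind.

Everything is driven by one RNG stream seeded from ``rng_seed`` with a
fixed generation order, so a config reproduces its dataset exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .datamodel import (
    GERMINATION_CSV_COLUMNS,
    PLANT_CSV_COLUMNS,
    DataValidationError,
    ExperimentalRound,
    Trait,
    TRAITS,
    Treatment,
    enumerate_pairs,
)

#: isolate labels used by default (genus prefix + culture-collection digits)
DEFAULT_ISOLATES: tuple[str, ...] = (
    "alt_1239",
    "asp_0917",
    "cla_0230",
    "col_0223",
    "cur_0077",
    "fus_0983",
    "muc_0113",
    "pho_0052",
    "set_0031",
    "ste_0804",
    "tol_0289",
    "tri_0218",
    "ver_0232",
)

TRUTH_COLUMNS = ["kind", "isolate_a", "isolate_b", "trait", "effect_sd_units", "effect_raw"]


@dataclass(frozen=True)
class TraitModel:
    """Generative model for one trait, in that trait's raw units.

    ``baseline_mean``/``baseline_sd`` describe the across-round spread of
    control baselines; ``residual_sd`` is the within-treatment replicate
    SD (sigma).  Effect distributions are parameterized in sigma units.
    Single effects are ``single_effect_loc + Exponential(single_effect_scale)``
    (right-skewed: most isolates near neutral, a thin tail of strong
    promoters).  A dual treatment's mean shift is

        dual_midpoint_weight * (a_A + a_B)/2
        + dual_effect_loc + Normal(0, dual_deviation_sd),

    and the realized pair deviation gamma is that shift minus the
    midpoint.  The default weight of 0 makes dual outcomes independent of
    the partners' single strengths, matching screens where single- and
    dual-inoculation effects are uncorrelated; a weight of 1 recovers a
    purely additive midpoint model with independent noise.
    """

    baseline_mean: float
    baseline_sd: float
    residual_sd: float
    single_effect_loc: float
    single_effect_scale: float
    dual_deviation_sd: float
    dual_effect_loc: float = 0.0
    dual_midpoint_weight: float = 0.0
    integer_valued: bool = False

    def __post_init__(self) -> None:
        if not self.residual_sd > 0:
            raise DataValidationError("residual_sd must be > 0")
        if self.baseline_sd < 0 or self.single_effect_scale < 0 or self.dual_deviation_sd < 0:
            raise DataValidationError("scale parameters must be >= 0")


def default_trait_models() -> dict[Trait, TraitModel]:
    """Default per-trait models: mg-scale biomass, leaf counts, SPAD units."""
    return {
        Trait.SHOOT_DRY_WEIGHT: TraitModel(
            baseline_mean=100.0, baseline_sd=10.0, residual_sd=15.0,
            single_effect_loc=-2.0, single_effect_scale=3.5,
            dual_effect_loc=1.5, dual_deviation_sd=2.0,
        ),
        Trait.N_MATURE_LEAVES: TraitModel(
            baseline_mean=6.0, baseline_sd=0.6, residual_sd=1.2,
            single_effect_loc=-2.0, single_effect_scale=3.0,
            dual_effect_loc=1.0, dual_deviation_sd=1.75,
            integer_valued=True,
        ),
        Trait.CHLOROPHYLL: TraitModel(
            baseline_mean=35.0, baseline_sd=2.0, residual_sd=4.0,
            single_effect_loc=-1.5, single_effect_scale=1.5,
            dual_effect_loc=0.25, dual_deviation_sd=1.0,
        ),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Design constants and effect structure of a simulated screen."""

    n_isolates: int = 13
    isolates: tuple[str, ...] | None = None
    replicates_min: int = 20
    replicates_max: int = 35
    max_treatments_per_round: int = 13
    traits: tuple[Trait, ...] = TRAITS
    trait_models: Mapping[Trait, TraitModel] = field(default_factory=default_trait_models)
    germination_p: Mapping[str, float] = field(
        default_factory=lambda: {"control": 0.9, "single": 0.7, "dual": 0.85}
    )
    seeds_per_cell: int = 2
    spad_subsample: int = 15
    spad_readings_per_plant: int = 3
    spad_reading_sd: float = 1.5
    single_effects: Mapping[Trait, Mapping[str, float]] | None = None
    dual_deviations: Mapping[Trait, Mapping[tuple[str, str], float]] | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_isolates < 2:
            raise DataValidationError("n_isolates must be >= 2")
        if not (2 <= self.replicates_min <= self.replicates_max <= 1000):
            raise DataValidationError("replicate range must satisfy 2 <= min <= max <= 1000")
        if self.max_treatments_per_round < 2:
            raise DataValidationError("max_treatments_per_round must be >= 2 (control + 1)")
        for kind, p in self.germination_p.items():
            if not 0 <= p <= 1:
                raise DataValidationError(f"germination_p[{kind!r}] = {p} outside [0, 1]")
        traits = tuple(Trait(t) for t in self.traits)
        object.__setattr__(self, "traits", traits)
        for t in traits:
            if t not in self.trait_models:
                raise DataValidationError(f"no TraitModel for trait {t.value!r}")
        if self.isolates is None:
            if self.n_isolates <= len(DEFAULT_ISOLATES):
                iso = DEFAULT_ISOLATES[: self.n_isolates]
            else:
                extra = tuple(
                    f"iso_{i:03d}" for i in range(self.n_isolates - len(DEFAULT_ISOLATES))
                )
                iso = DEFAULT_ISOLATES + extra
            object.__setattr__(self, "isolates", tuple(sorted(iso)))
        else:
            iso = tuple(self.isolates)
            if len(iso) != self.n_isolates:
                raise DataValidationError(
                    f"{len(iso)} isolate ids given for n_isolates = {self.n_isolates}"
                )
            if len(set(iso)) != len(iso):
                raise DataValidationError("isolate ids must be unique")
            object.__setattr__(self, "isolates", tuple(sorted(iso)))

    # -- JSON round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "n_isolates": self.n_isolates,
            "isolates": list(self.isolates),
            "replicates_min": self.replicates_min,
            "replicates_max": self.replicates_max,
            "max_treatments_per_round": self.max_treatments_per_round,
            "traits": [t.value for t in self.traits],
            "trait_models": {
                t.value: vars(m).copy() for t, m in self.trait_models.items()
            },
            "germination_p": dict(self.germination_p),
            "seeds_per_cell": self.seeds_per_cell,
            "spad_subsample": self.spad_subsample,
            "spad_readings_per_plant": self.spad_readings_per_plant,
            "spad_reading_sd": self.spad_reading_sd,
            "rng_seed": self.rng_seed,
        }
        if self.single_effects is not None:
            d["single_effects"] = {
                Trait(t).value: dict(v) for t, v in self.single_effects.items()
            }
        if self.dual_deviations is not None:
            d["dual_deviations"] = {
                Trait(t).value: {"+".join(sorted(k)): v for k, v in m.items()}
                for t, m in self.dual_deviations.items()
            }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "traits" in d:
            d["traits"] = tuple(Trait(t) for t in d["traits"])
        if "trait_models" in d:
            d["trait_models"] = {
                Trait(t): TraitModel(**m) for t, m in d["trait_models"].items()
            }
        if "isolates" in d and d["isolates"] is not None:
            d["isolates"] = tuple(d["isolates"])
        if d.get("single_effects") is not None:
            d["single_effects"] = {
                Trait(t): dict(v) for t, v in d["single_effects"].items()
            }
        if d.get("dual_deviations") is not None:
            d["dual_deviations"] = {
                Trait(t): {tuple(k.split("+")): v for k, v in m.items()}
                for t, m in d["dual_deviations"].items()
            }
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def null_config(rng_seed: int = 0, **overrides) -> SimulationConfig:
    """A config with every effect zeroed (a_k = 0, gamma_AB = 0).

    Useful for calibration: under this config, every treatment behaves
    like a control and any detected synergy, offset, or interaction is a
    false positive.
    """
    models = {
        t: replace(
            m,
            single_effect_loc=0.0,
            single_effect_scale=0.0,
            dual_effect_loc=0.0,
            dual_deviation_sd=0.0,
        )
        for t, m in default_trait_models().items()
    }
    return SimulationConfig(rng_seed=rng_seed, trait_models=models, **overrides)


def di_recovery_fit(
    indices_df: pd.DataFrame,
    truth: pd.DataFrame,
    trait: Trait,
) -> dict[str, float]:
    """Regress estimated mean DI on the true pair deviation gamma (in
    residual-SD units) across the screen's pairs.

    Since the generator defines the dual effect as midpoint + gamma, an
    unbiased pipeline gives slope ~1 and intercept ~0.
    """
    trait = Trait(trait)
    idx = indices_df[indices_df["trait"] == trait.value]
    g = truth[(truth["kind"] == "dual") & (truth["trait"] == trait.value)]
    merged = idx.merge(
        g[["isolate_a", "isolate_b", "effect_sd_units"]],
        left_on=["pair_a", "pair_b"],
        right_on=["isolate_a", "isolate_b"],
    )
    if len(merged) != len(idx):
        raise DataValidationError("truth table does not cover the pair set")
    slope, intercept = np.polyfit(
        merged["effect_sd_units"].to_numpy(), merged["di_mean"].to_numpy(), 1
    )
    return {"slope": float(slope), "intercept": float(intercept), "n_pairs": len(merged)}


@dataclass(frozen=True)
class Design:
    """Treatments partitioned into rounds, with per-treatment replicate counts."""

    rounds: tuple[ExperimentalRound, ...]
    replicates: Mapping[tuple[str, Treatment], int]

    @property
    def treatments(self) -> list[Treatment]:
        """All distinct non-control treatments plus one control entry."""
        seen = {t for r in self.rounds for t in r.treatments}
        return sorted(seen)


def _rng(config: SimulationConfig, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(config.rng_seed)


def build_design(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> Design:
    """Partition 1 control + N single + N(N−1)/2 dual treatments into rounds.

    Rounds hold at most ``max_treatments_per_round`` treatments *including*
    the round's own control, so each round carries up to
    ``max_treatments_per_round − 1`` single/dual treatments.  Replicate
    counts per treatment are drawn uniformly from
    [replicates_min, replicates_max].
    """
    rng = _rng(config, rng)
    singles = [Treatment.single(i) for i in config.isolates]
    duals = [Treatment.dual(a, b) for a, b in enumerate_pairs(config.isolates)]
    non_control = sorted(singles + duals)
    per_round = config.max_treatments_per_round - 1
    chunks = [non_control[i : i + per_round] for i in range(0, len(non_control), per_round)]
    rounds = []
    replicates: dict[tuple[str, Treatment], int] = {}
    for k, chunk in enumerate(chunks, start=1):
        round_id = f"R{k:02d}"
        treatments = (Treatment.control(), *chunk)
        rounds.append(
            ExperimentalRound(
                round_id=round_id,
                treatments=treatments,
                max_treatments=config.max_treatments_per_round,
            )
        )
        for t in treatments:
            replicates[(round_id, t)] = int(
                rng.integers(config.replicates_min, config.replicates_max + 1)
            )
    return Design(rounds=tuple(rounds), replicates=replicates)


def draw_effects(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Ground-truth single effects a_k and pair deviations gamma_AB.

    Returns a long table (``kind, isolate_a, isolate_b, trait,
    effect_sd_units, effect_raw``); ``effect_raw`` is the shift of the
    treatment's trait mean in raw units, ``effect_sd_units`` the same in
    residual-SD units.  Explicit values in ``config.single_effects`` /
    ``config.dual_deviations`` (sigma units) override the random draw.
    """
    rng = _rng(config, rng)
    pairs = enumerate_pairs(config.isolates)
    rows = []
    for trait in config.traits:
        model = config.trait_models[trait]
        sigma = model.residual_sd
        fixed_single = (config.single_effects or {}).get(trait)
        fixed_dual = (config.dual_deviations or {}).get(trait)
        singles: dict[str, float] = {}
        for isolate in config.isolates:
            a = model.single_effect_loc + rng.exponential(model.single_effect_scale)
            if fixed_single is not None and isolate in fixed_single:
                a = float(fixed_single[isolate])
            singles[isolate] = a
            rows.append(("single", isolate, "", trait.value, a, a * sigma))
        for pa, pb in pairs:
            mid = (singles[pa] + singles[pb]) / 2.0
            effect = (
                model.dual_midpoint_weight * mid
                + model.dual_effect_loc
                + rng.normal(0.0, model.dual_deviation_sd)
            )
            g = effect - mid  # realized deviation from the midpoint
            if fixed_dual is not None and (pa, pb) in fixed_dual:
                g = float(fixed_dual[(pa, pb)])
            rows.append(("dual", pa, pb, trait.value, g, g * sigma))
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def _effect_lookup(truth: pd.DataFrame) -> dict[tuple[str, str, str, str], float]:
    return {
        (r.kind, r.isolate_a, r.isolate_b, r.trait): r.effect_raw
        for r in truth.itertuples(index=False)
    }


def treatment_effect_raw(
    truth: pd.DataFrame, treatment: Treatment, trait: Trait
) -> float:
    """Raw-unit mean shift of one treatment: 0, a_k, or (a_A+a_B)/2 + gamma."""
    lut = _effect_lookup(truth)
    return _effect_from_lut(lut, treatment, Trait(trait).value)


def _effect_from_lut(lut, treatment: Treatment, trait_value: str) -> float:
    if treatment.kind == "control":
        return 0.0
    if treatment.kind == "single":
        return lut[("single", treatment.isolates[0], "", trait_value)]
    a, b = treatment.isolates
    mid = (
        lut[("single", a, "", trait_value)] + lut[("single", b, "", trait_value)]
    ) / 2.0
    return mid + lut[("dual", a, b, trait_value)]


def simulate_measurements(
    design: Design,
    config: SimulationConfig,
    truth: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Replicate-level plant measurements for a design.

    Each plant's trait value is ``mu_r + effect + Normal(0, sigma)``.
    Leaf counts are rounded to the nearest integer and floored at zero;
    shoot dry weight is floored at zero.  SPAD is generated for a random
    subsample of ``spad_subsample`` plants per treatment as the mean of
    ``spad_readings_per_plant`` noisy readings; other plants get a missing
    SPAD cell.  Deterministic for a given RNG state.
    """
    rng = _rng(config, rng)
    if truth is None:
        truth = draw_effects(config, rng)
    lut = _effect_lookup(truth)
    measure_chl = Trait.CHLOROPHYLL in config.traits

    baselines: dict[tuple[str, str], float] = {}
    for rnd in design.rounds:
        for trait in config.traits:
            model = config.trait_models[trait]
            baselines[(rnd.round_id, trait.value)] = rng.normal(
                model.baseline_mean, model.baseline_sd
            )

    rows: list[pd.DataFrame] = []
    for rnd in design.rounds:
        for treatment in sorted(rnd.treatments):
            n = design.replicates[(rnd.round_id, treatment)]
            data: dict[str, object] = {
                "plant_id": [
                    f"{rnd.round_id}_{treatment.label}_{j + 1:03d}" for j in range(n)
                ],
                "treatment_kind": treatment.kind,
                "isolate_a": treatment.isolates[0] if treatment.isolates else "",
                "isolate_b": treatment.isolates[1] if len(treatment.isolates) == 2 else "",
                "round_id": rnd.round_id,
            }
            for trait in config.traits:
                model = config.trait_models[trait]
                mean = baselines[(rnd.round_id, trait.value)] + _effect_from_lut(
                    lut, treatment, trait.value
                )
                values = rng.normal(mean, model.residual_sd, size=n)
                if trait is Trait.CHLOROPHYLL:
                    k = min(config.spad_subsample, n)
                    chosen = np.sort(rng.choice(n, size=k, replace=False))
                    readings = values[chosen, None] + rng.normal(
                        0.0, config.spad_reading_sd, size=(k, config.spad_readings_per_plant)
                    )
                    spad = np.full(n, np.nan)
                    spad[chosen] = readings.mean(axis=1)
                    data["spad"] = spad
                elif model.integer_valued:
                    data[trait.value] = np.maximum(np.rint(values), 0).astype(int)
                else:
                    data[trait.value] = np.maximum(values, 0.0)
            if not measure_chl:
                data["spad"] = np.full(n, np.nan)
            for trait in TRAITS:
                col = "spad" if trait is Trait.CHLOROPHYLL else trait.value
                if col not in data:
                    data[col] = np.zeros(n)
            rows.append(pd.DataFrame(data))
    return pd.concat(rows, ignore_index=True)[PLANT_CSV_COLUMNS]


def simulate_germination(
    design: Design,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-treatment germination counts: Binomial(2 × cells, p_kind)."""
    rng = _rng(config, rng)
    rows = []
    for rnd in design.rounds:
        for treatment in sorted(rnd.treatments):
            n_cells = design.replicates[(rnd.round_id, treatment)]
            introduced = config.seeds_per_cell * n_cells
            p = config.germination_p[treatment.kind]
            germinated = int(rng.binomial(introduced, p))
            rows.append(
                {
                    "treatment_kind": treatment.kind,
                    "isolate_a": treatment.isolates[0] if treatment.isolates else "",
                    "isolate_b": treatment.isolates[1]
                    if len(treatment.isolates) == 2
                    else "",
                    "round_id": rnd.round_id,
                    "seeds_introduced": introduced,
                    "seeds_germinated": germinated,
                    "rate": germinated / introduced,
                }
            )
    return pd.DataFrame(rows, columns=GERMINATION_CSV_COLUMNS)


@dataclass(frozen=True)
class SimulatedScreen:
    """A complete simulated experiment and its ground truth."""

    config: SimulationConfig
    design: Design
    truth: pd.DataFrame
    plants: pd.DataFrame
    germination: pd.DataFrame


def simulate_screen(
    config: SimulationConfig | None = None, rng_seed: int | None = None
) -> SimulatedScreen:
    """Run the full generator: design, ground truth, plants, germination.

    One RNG stream seeded from ``rng_seed`` (falling back to the config's
    seed) drives every draw in a fixed order, so the same seed reproduces
    the screen exactly.
    """
    config = config or SimulationConfig()
    if rng_seed is not None:
        config = replace(config, rng_seed=rng_seed)
    rng = np.random.default_rng(config.rng_seed)
    design = build_design(config, rng)
    truth = draw_effects(config, rng)
    plants = simulate_measurements(design, config, truth, rng)
    germination = simulate_germination(design, config, rng)
    return SimulatedScreen(
        config=config, design=design, truth=truth, plants=plants, germination=germination
    )
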