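"""End-to-end analysis: standardize, score pairs, test, summarize.

`run_analysis` ties the stages together on in-memory tables and returns
every output table plus a machine-readable summary; `write_analysis`
persists them as CSV/JSON.  The command-line interface in
:mod:`synergy_screen.cli` is a thin wrapper over these functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .datamodel import (
    PLANT_CSV_COLUMNS,
    TRAIT_COLUMNS,
    TRAITS,
    PlantRecord,
    Trait,
    frame_to_plant_records,
    infer_rounds,
    plant_records_to_frame,
)
from .inference import (
    AnalysisError,
    nonlinearity_alignment,
    screen_interaction_anovas,
    single_dual_correlation,
    treatment_anova,
    welch_germination_test,
)
from .pair_indices import screen_pair_indices, treatment_summaries
from .standardization import standardize_dataset

log = logging.getLogger("synergy_screen")


@dataclass
class AnalysisResult:
    """All tables produced by one analysis run."""

    standardized: pd.DataFrame
    summaries: pd.DataFrame
    pair_indices: pd.DataFrame
    treatment_anova: pd.DataFrame
    pair_anova: pd.DataFrame
    welch: pd.DataFrame | None
    correlations: pd.DataFrame
    alignment: pd.DataFrame
    summary: dict = field(default_factory=dict)


def _raw_long(plants: pd.DataFrame, traits: Iterable[Trait]) -> pd.DataFrame:
    """Raw trait values reshaped like the standardized table (sg = raw value)."""
    pieces = []
    for trait in traits:
        col = TRAIT_COLUMNS[Trait(trait)]
        sub = plants[
            ["plant_id", "treatment_kind", "isolate_a", "isolate_b", "round_id", col]
        ].copy()
        sub[col] = pd.to_numeric(sub[col], errors="coerce")
        sub = sub.dropna(subset=[col])
        sub["trait"] = Trait(trait).value
        sub = sub.rename(columns={col: "sg"})
        pieces.append(sub)
    out = pd.concat(pieces, ignore_index=True)
    out["treatment"] = out.apply(
        lambda r: "control"
        if r["treatment_kind"] == "control"
        else "+".join(x for x in (r["isolate_a"], r["isolate_b"]) if x),
        axis=1,
    )
    return out


def run_analysis(
    plants: pd.DataFrame | Iterable[PlantRecord],
    germination: pd.DataFrame | None = None,
    traits: Iterable[Trait] = TRAITS,
    alpha: float = 0.05,
    control_pool: str = "round",
    correlation: str = "pearson",
    anova_on: str = "standardized",
    top_n: int = 5,
) -> AnalysisResult:
    """Run the full screen analysis.

    Parameters mirror the reporting choices of the method: ``alpha`` is
    the FDR threshold used in the summary, ``control_pool`` decides which
    control replicates feed the (0,0) cell of the pair ANOVAs,
    ``correlation`` picks Pearson or Spearman for the single-vs-dual
    comparison, and ``anova_on`` lets the treatment-level ANOVA run on raw
    trait values instead of standardized indices.
    """
    if not 0 < alpha < 1:
        raise AnalysisError(f"alpha must be in (0, 1), got {alpha}")
    if anova_on not in ("standardized", "raw"):
        raise AnalysisError(f"anova_on must be 'standardized' or 'raw', got {anova_on!r}")
    plants_df = (
        plants if isinstance(plants, pd.DataFrame) else plant_records_to_frame(plants)
    )
    traits = [Trait(t) for t in traits]

    # validates the round structure (one control per round, unique assignment)
    infer_rounds(frame_to_plant_records(plants_df))

    log.info("plant records in: %d", len(plants_df))
    sg = standardize_dataset(plants_df, traits=traits)
    log.info("standardized records out: %d", len(sg))

    summaries = treatment_summaries(sg)
    indices = screen_pair_indices(sg)
    log.info("pair-index rows: %d", len(indices))

    anova_input = sg if anova_on == "standardized" else _raw_long(plants_df, traits)
    anova_rows = []
    for trait in traits:
        for scope in ("single", "dual"):
            try:
                res = treatment_anova(anova_input, trait, scope)
            except AnalysisError as exc:
                log.warning("treatment ANOVA skipped (%s, %s): %s", trait.value, scope, exc)
                continue
            anova_rows.append(
                {
                    "trait": trait.value,
                    "scope": scope,
                    "df_between": res.df_between,
                    "df_within": res.df_within,
                    "F": res.F,
                    "p": res.p,
                }
            )
    anova_df = pd.DataFrame(anova_rows)

    pair_anova = screen_interaction_anovas(sg, control_pool=control_pool)

    welch_df = None
    if germination is not None:
        g = germination
        single_rates = g[g["treatment_kind"] == "single"]["rate"].astype(float).tolist()
        dual_rates = g[g["treatment_kind"] == "dual"]["rate"].astype(float).tolist()
        w = welch_germination_test(single_rates, dual_rates)
        welch_df = pd.DataFrame(
            [
                {
                    "comparison": "single_vs_dual_rates",
                    "n_single": len(single_rates),
                    "n_dual": len(dual_rates),
                    "t": w.t,
                    "df": w.df,
                    "p": w.p,
                }
            ]
        )

    corr_rows = []
    for trait in traits:
        try:
            c = single_dual_correlation(sg, trait, method=correlation)
        except AnalysisError as exc:
            log.warning("correlation skipped (%s): %s", trait.value, exc)
            continue
        corr_rows.append(
            {"trait": trait.value, "method": c.method, "r": c.r, "p": c.p, "n": c.n}
        )
    corr_df = pd.DataFrame(corr_rows)

    align_rows = []
    for trait in traits:
        try:
            rho, p = nonlinearity_alignment(indices, pair_anova, trait)
        except AnalysisError as exc:
            log.warning("alignment skipped (%s): %s", trait.value, exc)
            continue
        align_rows.append({"trait": trait.value, "spearman_rho": rho, "p": p})
    align_df = pd.DataFrame(align_rows)

    summary: dict = {"alpha": alpha, "traits": [t.value for t in traits]}
    for trait in traits:
        ti = indices[indices["trait"] == trait.value]
        ta = pair_anova[pair_anova["trait"] == trait.value]
        top = ti.sort_values("dmx_mean", ascending=False).head(top_n)
        summary[trait.value] = {
            "top_pairs_by_dmx_mean": [
                {"pair": f"{r.pair_a}+{r.pair_b}", "dmx_mean": round(r.dmx_mean, 4)}
                for r in top.itertuples(index=False)
            ],
            "synergistic_pairs": [
                f"{r.pair_a}+{r.pair_b}"
                for r in ti[ti["synergistic"]].itertuples(index=False)
            ],
            "offset_pairs": [
                f"{r.pair_a}+{r.pair_b}" for r in ti[ti["offset"]].itertuples(index=False)
            ],
            "pairs_q_below_alpha": [
                f"{r.pair_a}+{r.pair_b}" for r in ta[ta["q"] < alpha].itertuples(index=False)
            ],
        }
    if welch_df is not None:
        summary["germination_welch"] = {
            "t": round(float(welch_df["t"].iloc[0]), 4),
            "df": round(float(welch_df["df"].iloc[0]), 2),
            "p": float(welch_df["p"].iloc[0]),
        }

    return AnalysisResult(
        standardized=sg,
        summaries=summaries,
        pair_indices=indices,
        treatment_anova=anova_df,
        pair_anova=pair_anova,
        welch=welch_df,
        correlations=corr_df,
        alignment=align_df,
        summary=summary,
    )


def write_analysis(result: AnalysisResult, out_dir: str | Path) -> list[Path]:
    """Write every analysis table to ``out_dir``; returns the paths written."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    tables = {
        "standardized.csv": result.standardized,
        "treatment_summaries.csv": result.summaries,
        "pair_indices.csv": result.pair_indices,
        "treatment_anova.csv": result.treatment_anova,
        "pair_anova.csv": result.pair_anova,
        "correlations.csv": result.correlations,
        "alignment.csv": result.alignment,
    }
    if result.welch is not None:
        tables["welch.csv"] = result.welch
    for name, df in tables.items():
        path = out / name
        df.to_csv(path, index=False)
        written.append(path)
    path = out / "summary.json"
    with open(path, "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(path)
    return written
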