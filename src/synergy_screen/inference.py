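"""Statistical tests over standardized growth indices.

Covers four analyses of a pairwise inoculation screen:

* one-way treatment ANOVAs asking whether plant responses differ across
  the single (or dual) inoculation treatments;
* per-pair 2×2 factorial ANOVAs on isolate presence/absence, whose
  interaction F measures how non-additively a pair acts, with
  Benjamini–Hochberg FDR across the pair set;
* Welch's unequal-variance t-test comparing per-treatment germination
  rates between single and dual inoculations;
* correlations relating single-inoculation effects to dual-inoculation
  averages, and the alignment between |mean DI| and the interaction F.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .datamodel import SynergyScreenError, Trait
from .pair_indices import single_inoculation_means


class AnalysisError(SynergyScreenError, ValueError):
    """An analysis precondition is violated (empty cell, degenerate data)."""


@dataclass(frozen=True)
class TreatmentAnovaResult:
    trait: Trait
    scope: str  # "single" | "dual"
    df_between: int
    df_within: int
    F: float
    p: float


@dataclass(frozen=True)
class PairAnovaResult:
    pair: tuple[str, str]
    trait: Trait
    F_interaction: float
    df_num: int
    df_den: int
    p: float
    q: float | None = None


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class CorrelationResult:
    trait: Trait
    r: float
    p: float
    n: int
    method: str = "pearson"


def treatment_anova(sg_df: pd.DataFrame, trait: Trait, scope: str) -> TreatmentAnovaResult:
    """One-way fixed-effects ANOVA of SG across treatments of one kind.

    ``scope`` selects the single- or dual-inoculation treatments; every
    treatment group needs >= 2 replicates and the pooled within-group
    variance must be positive.
    """
    trait = Trait(trait)
    if scope not in ("single", "dual"):
        raise AnalysisError(f"scope must be 'single' or 'dual', got {scope!r}")
    sub = sg_df[(sg_df["treatment_kind"] == scope) & (sg_df["trait"] == trait.value)]
    groups = [g["sg"].to_numpy(dtype=float) for _, g in sub.groupby("treatment")]
    if len(groups) < 2:
        raise AnalysisError(
            f"treatment ANOVA needs >= 2 {scope} treatments for trait "
            f"{trait.value!r}, found {len(groups)}"
        )
    for label, g in zip(sub.groupby("treatment").groups, groups):
        if len(g) < 2:
            raise AnalysisError(
                f"treatment {label!r} has {len(g)} replicate(s); need >= 2"
            )
    if all(np.var(g) == 0 for g in groups):
        raise AnalysisError("zero within-group variance; F undefined")
    stat = scipy.stats.f_oneway(*groups)
    n_total = sum(len(g) for g in groups)
    return TreatmentAnovaResult(
        trait=trait,
        scope=scope,
        df_between=len(groups) - 1,
        df_within=n_total - len(groups),
        F=float(stat.statistic),
        p=float(stat.pvalue),
    )


def _pair_cells(
    sg_df: pd.DataFrame, pair: tuple[str, str], trait: Trait, control_pool: str
) -> dict[tuple[int, int], np.ndarray]:
    a, b = sorted(pair)
    t = sg_df[sg_df["trait"] == Trait(trait).value]
    dual = t[(t["treatment_kind"] == "dual") & (t["isolate_a"] == a) & (t["isolate_b"] == b)]
    single_a = t[(t["treatment_kind"] == "single") & (t["isolate_a"] == a)]
    single_b = t[(t["treatment_kind"] == "single") & (t["isolate_a"] == b)]
    controls = t[t["treatment_kind"] == "control"]
    if control_pool == "round":
        rounds = set(dual["round_id"]) | set(single_a["round_id"]) | set(single_b["round_id"])
        controls = controls[controls["round_id"].isin(rounds)]
    elif control_pool != "all":
        raise AnalysisError(f"control_pool must be 'round' or 'all', got {control_pool!r}")
    return {
        (0, 0): controls["sg"].to_numpy(dtype=float),
        (1, 0): single_a["sg"].to_numpy(dtype=float),
        (0, 1): single_b["sg"].to_numpy(dtype=float),
        (1, 1): dual["sg"].to_numpy(dtype=float),
    }


def pair_interaction_anova(
    sg_df: pd.DataFrame,
    pair: tuple[str, str],
    trait: Trait,
    control_pool: str = "round",
) -> PairAnovaResult:
    """2×2 presence/absence ANOVA for one pair: SG ~ A + B + A:B.

    The four cells are the control replicates (absence/absence), the two
    single inoculations, and the dual inoculation.  The interaction F
    (numerator df 1) is computed by Type II model comparison — residual
    sum of squares of the main-effects model minus that of the full model
    — which reduces to the classical two-way ANOVA when cells are
    balanced.  ``control_pool="round"`` restricts the control cell to the
    rounds in which the pair's treatments were grown; ``"all"`` pools
    every control replicate.
    """
    trait = Trait(trait)
    cells = _pair_cells(sg_df, pair, trait, control_pool)
    names = {(0, 0): "control", (1, 0): "single A", (0, 1): "single B", (1, 1): "dual AB"}
    for key, values in cells.items():
        if len(values) < 2:
            raise AnalysisError(
                f"pair {tuple(sorted(pair))}, trait {trait.value!r}: cell "
                f"{names[key]!r} has {len(values)} replicate(s); need >= 2"
            )

    y = np.concatenate([cells[k] for k in ((0, 0), (1, 0), (0, 1), (1, 1))])
    a = np.concatenate([np.full(len(cells[k]), k[0], dtype=float) for k in ((0, 0), (1, 0), (0, 1), (1, 1))])
    b = np.concatenate([np.full(len(cells[k]), k[1], dtype=float) for k in ((0, 0), (1, 0), (0, 1), (1, 1))])

    X_full = np.column_stack([np.ones_like(y), a, b, a * b])
    X_main = X_full[:, :3]
    full = sm.OLS(y, X_full).fit()
    main = sm.OLS(y, X_main).fit()
    df_den = int(full.df_resid)
    if df_den <= 0 or full.ssr <= 0 or not np.isfinite(full.ssr) or np.isclose(full.ssr, 0):
        raise AnalysisError(
            f"pair {tuple(sorted(pair))}, trait {trait.value!r}: zero residual "
            "variance; interaction F undefined"
        )
    F = float((main.ssr - full.ssr) / (full.ssr / df_den))
    F = max(F, 0.0)  # guard tiny negative round-off
    p = float(scipy.stats.f.sf(F, 1, df_den))
    return PairAnovaResult(
        pair=tuple(sorted(pair)), trait=trait, F_interaction=F, df_num=1, df_den=df_den, p=p
    )


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise AnalysisError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen_interaction_anovas(
    sg_df: pd.DataFrame, control_pool: str = "round"
) -> pd.DataFrame:
    """Interaction ANOVA for every pair and trait, with per-trait BH FDR.

    Returns one row per (pair, trait): ``pair_a, pair_b, trait, F_interaction,
    df_num, df_den, p, q`` with q-values adjusted across the pair set within
    each trait.
    """
    dual = sg_df[sg_df["treatment_kind"] == "dual"]
    rows = []
    for (a, b, trait), _ in dual.groupby(["isolate_a", "isolate_b", "trait"]):
        res = pair_interaction_anova(sg_df, (a, b), Trait(trait), control_pool)
        rows.append(
            {
                "pair_a": a,
                "pair_b": b,
                "trait": trait,
                "F_interaction": res.F_interaction,
                "df_num": res.df_num,
                "df_den": res.df_den,
                "p": res.p,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(
            columns=["pair_a", "pair_b", "trait", "F_interaction", "df_num", "df_den", "p", "q"]
        )
    out["q"] = np.nan
    for trait, idx in out.groupby("trait").groups.items():
        out.loc[idx, "q"] = fdr_adjust(out.loc[idx, "p"].to_numpy())
    return out.sort_values(["trait", "pair_a", "pair_b"], ignore_index=True)


def welch_germination_test(
    single_rates: Sequence[float], dual_rates: Sequence[float]
) -> WelchResult:
    """Welch's unequal-variance t-test on per-treatment germination rates.

    Groups are ordered (single, dual), so dual-higher rates give a
    negative t.  Degrees of freedom follow Welch–Satterthwaite; p is
    two-sided.
    """
    x = np.asarray(single_rates, dtype=float)
    y = np.asarray(dual_rates, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise AnalysisError("both groups need >= 2 per-treatment rates")
    if np.var(x) == 0 and np.var(y) == 0:
        raise AnalysisError("zero variance in both groups; t undefined")
    res = scipy.stats.ttest_ind(x, y, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def single_dual_correlation(
    sg_df: pd.DataFrame, trait: Trait, method: str = "pearson"
) -> CorrelationResult:
    """Correlate each isolate's single-inoculation mean SG with its
    average effect across all the dual inoculations it participates in.

    The dual average is the unweighted mean of the isolate's dual
    *treatment* means (12 per isolate in a full 13-isolate design).
    """
    trait = Trait(trait)
    if method not in ("pearson", "spearman"):
        raise AnalysisError(f"method must be 'pearson' or 'spearman', got {method!r}")
    singles = single_inoculation_means(sg_df)
    singles = singles[singles["trait"] == trait.value].set_index("isolate")["sg_mean"]

    dual = sg_df[(sg_df["treatment_kind"] == "dual") & (sg_df["trait"] == trait.value)]
    pair_means = dual.groupby(["isolate_a", "isolate_b"])["sg"].mean()
    dual_avg: dict[str, list[float]] = {}
    for (a, b), m in pair_means.items():
        dual_avg.setdefault(a, []).append(m)
        dual_avg.setdefault(b, []).append(m)

    isolates = sorted(set(singles.index) & set(dual_avg))
    if len(isolates) < 3:
        raise AnalysisError(
            f"need >= 3 isolates with both single and dual data, found {len(isolates)}"
        )
    x = np.array([singles[i] for i in isolates])
    y = np.array([np.mean(dual_avg[i]) for i in isolates])
    if method == "pearson":
        r, p = scipy.stats.pearsonr(x, y)
    else:
        r, p = scipy.stats.spearmanr(x, y)
    return CorrelationResult(trait=trait, r=float(r), p=float(p), n=len(isolates), method=method)


def nonlinearity_alignment(
    pair_indices: pd.DataFrame, pair_anovas: pd.DataFrame, trait: Trait
) -> tuple[float, float]:
    """Spearman rank correlation between |mean DI| and the interaction F.

    A positive rank correlation means pairs whose dual response deviates
    further from the single-inoculation midpoint also score higher on the
    factorial nonlinearity test.  Returns ``(rho, p)``.
    """
    trait = Trait(trait)
    idx = pair_indices[pair_indices["trait"] == trait.value][
        ["pair_a", "pair_b", "di_mean"]
    ]
    anova = pair_anovas[pair_anovas["trait"] == trait.value][
        ["pair_a", "pair_b", "F_interaction"]
    ]
    pairs_idx = set(zip(idx["pair_a"], idx["pair_b"]))
    pairs_anova = set(zip(anova["pair_a"], anova["pair_b"]))
    if pairs_idx != pairs_anova:
        raise AnalysisError(
            "pair sets differ between index and ANOVA tables: "
            f"{sorted(pairs_idx ^ pairs_anova)[:5]} ..."
        )
    merged = idx.merge(anova, on=["pair_a", "pair_b"])
    x = merged["di_mean"].abs().to_numpy()
    y = merged["F_interaction"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AnalysisError("zero rank variance; Spearman correlation undefined")
    rho, p = scipy.stats.spearmanr(x, y)
    return float(rho), float(p)
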