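"""Synergy, offset, and intermediate-deviation indices for isolate pairs.

For a pair of isolates (A, B), let ``m_A`` and ``m_B`` be the mean
standardized growth (SG) of their single-inoculation treatments, and let
``SG_AB(i)`` be the SG of dual-inoculation replicate *i*.  Three
replicate-level indices compare the dual response with the singles:

* ``DMX_AB(i) = SG_AB(i) − max(m_A, m_B)`` — deviation above the *better*
  single inoculation; a positive replicate mean flags a synergistic pair
  (the pair outperforms both isolates alone).
* ``DMN_AB(i) = min(m_A, m_B) − SG_AB(i)`` — deviation below the *worse*
  single inoculation; a positive replicate mean flags an offset pair (the
  pair underperforms both isolates alone).
* ``DI_AB(i) = SG_AB(i) − (m_A + m_B)/2`` — deviation from the midpoint of
  the two single effects; |mean DI| tracks how non-additive the pair is.

Two identities tie the indices together for every replicate:
``DMX + DMN = −|m_A − m_B|`` and ``DI − DMX = |m_A − m_B| / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import SynergyScreenError, Trait

PAIR_INDEX_COLUMNS = [
    "pair_a",
    "pair_b",
    "trait",
    "n_dual",
    "sg_ab_mean",
    "dmx_mean",
    "dmx_sd",
    "dmn_mean",
    "dmn_sd",
    "di_mean",
    "di_sd",
    "synergistic",
    "offset",
]


class PairIndexError(SynergyScreenError, ValueError):
    """A pair lacks the dual replicates or single summaries it needs."""


def synergy_deviation(sg_ab_i, sg_a_mean: float, sg_b_mean: float):
    """DMX: dual-replicate SG minus the larger single-inoculation mean."""
    return np.asarray(sg_ab_i) - max(sg_a_mean, sg_b_mean)


def offset_deviation(sg_ab_i, sg_a_mean: float, sg_b_mean: float):
    """DMN: the smaller single-inoculation mean minus the dual-replicate SG."""
    return min(sg_a_mean, sg_b_mean) - np.asarray(sg_ab_i)


def intermediate_deviation(sg_ab_i, sg_a_mean: float, sg_b_mean: float):
    """DI: dual-replicate SG minus the midpoint of the two single means."""
    return np.asarray(sg_ab_i) - (sg_a_mean + sg_b_mean) / 2.0


def treatment_summaries(sg_df: pd.DataFrame) -> pd.DataFrame:
    """Per-treatment, per-trait SG summaries (n, mean, sample SD)."""
    grouped = (
        sg_df.groupby(
            ["treatment", "treatment_kind", "isolate_a", "isolate_b", "trait"],
            as_index=False,
        )["sg"]
        .agg(n="count", sg_mean="mean", sg_sd=lambda s: s.std(ddof=1))
        .sort_values(["trait", "treatment_kind", "treatment"], ignore_index=True)
    )
    return grouped


def single_inoculation_means(sg_df: pd.DataFrame) -> pd.DataFrame:
    """Mean SG per isolate and trait across all single-inoculation replicates.

    Single means are pooled over every round in which the isolate's single
    treatment was grown; standardization has already removed round effects.
    """
    singles = sg_df[sg_df["treatment_kind"] == "single"]
    return (
        singles.groupby(["isolate_a", "trait"], as_index=False)["sg"]
        .agg(n="count", sg_mean="mean")
        .rename(columns={"isolate_a": "isolate"})
    )


@dataclass(frozen=True)
class PairIndices:
    """Replicate-level and summarized indices for one pair and trait."""

    pair: tuple[str, str]
    trait: Trait
    sg_a_mean: float
    sg_b_mean: float
    dmx: np.ndarray = field(repr=False)
    dmn: np.ndarray = field(repr=False)
    di: np.ndarray = field(repr=False)

    @property
    def n_dual(self) -> int:
        return len(self.dmx)

    @property
    def dmx_mean(self) -> float:
        return float(np.mean(self.dmx))

    @property
    def dmn_mean(self) -> float:
        return float(np.mean(self.dmn))

    @property
    def di_mean(self) -> float:
        return float(np.mean(self.di))

    @property
    def dmx_sd(self) -> float:
        return float(np.std(self.dmx, ddof=1)) if self.n_dual >= 2 else float("nan")

    @property
    def dmn_sd(self) -> float:
        return float(np.std(self.dmn, ddof=1)) if self.n_dual >= 2 else float("nan")

    @property
    def di_sd(self) -> float:
        return float(np.std(self.di, ddof=1)) if self.n_dual >= 2 else float("nan")

    @property
    def sg_ab_mean(self) -> float:
        return self.dmx_mean + max(self.sg_a_mean, self.sg_b_mean)

    @property
    def synergistic(self) -> bool:
        """Strictly positive mean DMX: dual beats both singles on average."""
        return self.dmx_mean > 0

    @property
    def offset(self) -> bool:
        """Strictly positive mean DMN: dual falls below both singles on average."""
        return self.dmn_mean > 0


def summarize_pair(
    sg_df: pd.DataFrame,
    pair: tuple[str, str],
    trait: Trait,
    single_means: pd.DataFrame | None = None,
) -> PairIndices:
    """Compute replicate-level DMX/DMN/DI for one pair and trait.

    ``single_means`` may be precomputed with
    :func:`single_inoculation_means`; otherwise it is derived from
    ``sg_df``.  Raises :class:`PairIndexError` if the pair has no dual
    replicates or either isolate lacks a single-inoculation summary.
    """
    a, b = sorted(pair)
    trait = Trait(trait)
    if single_means is None:
        single_means = single_inoculation_means(sg_df)

    means = {}
    for isolate in (a, b):
        row = single_means[
            (single_means["isolate"] == isolate) & (single_means["trait"] == trait.value)
        ]
        if row.empty:
            raise PairIndexError(
                f"no single-inoculation summary for isolate {isolate!r}, "
                f"trait {trait.value!r}"
            )
        means[isolate] = float(row["sg_mean"].iloc[0])

    dual = sg_df[
        (sg_df["treatment_kind"] == "dual")
        & (sg_df["isolate_a"] == a)
        & (sg_df["isolate_b"] == b)
        & (sg_df["trait"] == trait.value)
    ]
    if dual.empty:
        raise PairIndexError(
            f"no dual replicates for pair ({a!r}, {b!r}), trait {trait.value!r}"
        )
    sg_ab = dual["sg"].to_numpy(dtype=float)
    return PairIndices(
        pair=(a, b),
        trait=trait,
        sg_a_mean=means[a],
        sg_b_mean=means[b],
        dmx=synergy_deviation(sg_ab, means[a], means[b]),
        dmn=offset_deviation(sg_ab, means[a], means[b]),
        di=intermediate_deviation(sg_ab, means[a], means[b]),
    )


def pair_trend_slopes(
    indices_df: pd.DataFrame, single_means: pd.DataFrame, trait: Trait
) -> dict[str, float]:
    """Least-squares slopes of mean DMX and mean DMN against the pair's
    mean single-inoculation effect (m_A + m_B)/2.

    A negative DMX slope with a positive DMN slope reproduces the
    screen-level pattern that synergy weakens — and offset strengthens —
    as the combined strength of the two partners grows.
    """
    trait = Trait(trait)
    idx = indices_df[indices_df["trait"] == trait.value]
    m = single_means[single_means["trait"] == trait.value].set_index("isolate")["sg_mean"]
    mid = (idx["pair_a"].map(m).to_numpy() + idx["pair_b"].map(m).to_numpy()) / 2.0
    if len(idx) < 3 or np.ptp(mid) == 0:
        raise PairIndexError("need >= 3 pairs with varying single means for a trend fit")
    dmx_slope = np.polyfit(mid, idx["dmx_mean"].to_numpy(), 1)[0]
    dmn_slope = np.polyfit(mid, idx["dmn_mean"].to_numpy(), 1)[0]
    return {"dmx_slope": float(dmx_slope), "dmn_slope": float(dmn_slope)}


def screen_pair_indices(sg_df: pd.DataFrame) -> pd.DataFrame:
    """Pair-index summary table across every dual treatment and trait.

    One row per (pair, trait): replicate counts, mean/SD of each index,
    and the strict-inequality synergy/offset flags.  All pairs present as
    dual treatments must have single summaries for both members.
    """
    dual = sg_df[sg_df["treatment_kind"] == "dual"]
    if dual.empty:
        return pd.DataFrame(columns=PAIR_INDEX_COLUMNS)
    singles = single_inoculation_means(sg_df)

    need = dual[["isolate_a", "isolate_b", "trait"]].drop_duplicates()
    have = set(zip(singles["isolate"], singles["trait"]))
    for _, row in need.iterrows():
        for isolate in (row["isolate_a"], row["isolate_b"]):
            if (isolate, row["trait"]) not in have:
                raise PairIndexError(
                    f"no single-inoculation summary for isolate {isolate!r}, "
                    f"trait {row['trait']!r}"
                )

    m = singles.rename(columns={"sg_mean": "m"})[["isolate", "trait", "m"]]
    merged = dual.merge(
        m.rename(columns={"isolate": "isolate_a", "m": "m_a"}), on=["isolate_a", "trait"]
    ).merge(
        m.rename(columns={"isolate": "isolate_b", "m": "m_b"}), on=["isolate_b", "trait"]
    )
    hi = np.maximum(merged["m_a"], merged["m_b"])
    lo = np.minimum(merged["m_a"], merged["m_b"])
    merged["dmx"] = merged["sg"] - hi
    merged["dmn"] = lo - merged["sg"]
    merged["di"] = merged["sg"] - (merged["m_a"] + merged["m_b"]) / 2.0

    sd1 = lambda s: s.std(ddof=1)  # noqa: E731
    out = merged.groupby(["isolate_a", "isolate_b", "trait"], as_index=False).agg(
        n_dual=("sg", "count"),
        sg_ab_mean=("sg", "mean"),
        dmx_mean=("dmx", "mean"),
        dmx_sd=("dmx", sd1),
        dmn_mean=("dmn", "mean"),
        dmn_sd=("dmn", sd1),
        di_mean=("di", "mean"),
        di_sd=("di", sd1),
    )
    out["synergistic"] = out["dmx_mean"] > 0
    out["offset"] = out["dmn_mean"] > 0
    out = out.rename(columns={"isolate_a": "pair_a", "isolate_b": "pair_b"})
    return out.sort_values(["trait", "pair_a", "pair_b"], ignore_index=True)[
        PAIR_INDEX_COLUMNS
    ]
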