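"""Population comparison: summary tables, Welch's t-tests with Bonferroni
correction, percent gains relative to the initial population, and gain
trajectories."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .index import SelectionIndexModel, index_scores

__all__ = [
    "PopulationSummary",
    "PairwiseComparison",
    "summarize_populations",
    "percent_gain",
    "welch_test",
    "welch_test_raw",
    "pairwise_comparisons",
    "compact_letters",
    "gain_trajectory",
]


@dataclass
class PopulationSummary:
    population_label: str
    n: int
    means: pd.Series
    sds: pd.Series
    percent_of_initial: pd.Series | None = None

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("population summaries need n >= 2")
        if (self.sds < 0).any():
            raise ValueError("negative SD")


@dataclass(frozen=True)
class PairwiseComparison:
    population_a: str
    population_b: str
    trait: str
    t_statistic: float
    df: float
    p_raw: float
    p_adjusted: float
    significant_at_05: bool


def summarize_populations(
    phenotypes_by_population: dict[str, pd.DataFrame],
    index_model: SelectionIndexModel | None = None,
    initial_label: str = "initial",
) -> list[PopulationSummary]:
    """Per-trait (and selection-index) means/SDs per population, with percent
    of the initial-population mean when an ``initial_label`` population exists."""
    summaries = {}
    for label, df in phenotypes_by_population.items():
        df = df.copy()
        if index_model is not None and "selection_index" not in df.columns:
            df["selection_index"] = index_scores(df, index_model)
        if len(df) < 2:
            raise ValueError(f"population {label!r} has n < 2")
        summaries[label] = PopulationSummary(
            label, len(df), df.mean(), df.std(ddof=1)
        )
    if initial_label in summaries:
        base = summaries[initial_label].means
        for s in summaries.values():
            s.percent_of_initial = 100.0 * s.means / base
    return list(summaries.values())


def percent_gain(mean_value: float, initial_mean: float, decimals: int | None = None) -> float:
    """Percent increase over the initial mean: 100*(m - m0)/m0."""
    if initial_mean == 0:
        raise ValueError("initial mean is zero")
    g = 100.0 * (mean_value - initial_mean) / initial_mean
    return round(g, decimals) if decimals is not None else g


def welch_test(mean_a, sd_a, n_a, mean_b, sd_b, n_b) -> tuple[float, float, float]:
    """Welch's t-test from summary statistics: returns (t, df, two-sided p).

    t is signed as (mean_b - mean_a)/se; df by Welch-Satterthwaite.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 in both groups")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("negative SD")
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    se2 = va + vb
    if se2 == 0:
        raise ValueError("zero pooled variance")
    t = (mean_b - mean_a) / np.sqrt(se2)
    df = se2**2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def welch_test_raw(a, b) -> tuple[float, float, float]:
    """Welch's t-test on raw vectors; matches the summary-statistic path."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return welch_test(a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b))


def pairwise_comparisons(
    summaries: list[PopulationSummary],
    trait: str,
    alpha: float = 0.05,
) -> list[PairwiseComparison]:
    """All population pairs for one trait, Bonferroni-adjusted within the trait
    (m = number of population pairs)."""
    if len(summaries) < 2:
        raise ValueError("need at least two populations")
    m = len(summaries) * (len(summaries) - 1) // 2
    out = []
    for sa, sb in combinations(summaries, 2):
        t, df, p = welch_test(
            sa.means[trait], sa.sds[trait], sa.n,
            sb.means[trait], sb.sds[trait], sb.n,
        )
        p_adj = min(1.0, m * p)
        out.append(
            PairwiseComparison(sa.population_label, sb.population_label, trait,
                               t, df, p, p_adj, p_adj < alpha)
        )
    return out


def compact_letters(comparisons: list[PairwiseComparison],
                    labels: list[str]) -> dict[str, str]:
    """Insert-and-absorb compact letter display from adjusted significances.

    Presentation-level convenience; the significance matrix is canonical.
    """
    sig = {(c.population_a, c.population_b) for c in comparisons if c.significant_at_05}
    sig |= {(b, a) for a, b in sig}
    groups: list[set[str]] = [set(labels)]
    for a, b in sorted(sig):
        for g in [g for g in groups if a in g and b in g]:
            groups.remove(g)
            ga, gb = g - {b}, g - {a}
            for cand in (ga, gb):
                if not any(cand <= other for other in groups):
                    groups.append(cand)
    groups.sort(key=lambda g: sorted(labels.index(x) for x in g))
    letters = {lab: "" for lab in labels}
    for i, g in enumerate(groups):
        ch = chr(ord("a") + i)
        for lab in labels:
            if lab in g:
                letters[lab] += ch
    return letters


def gain_trajectory(
    summaries: list[PopulationSummary],
    order: list[str],
    trait: str = "selection_index",
) -> pd.DataFrame:
    """Per-cycle deltas and cumulative percent gain of a trait mean, in the
    given cycle order (first label is the baseline)."""
    by_label = {s.population_label: s for s in summaries}
    missing = [o for o in order if o not in by_label]
    if missing:
        raise ValueError(f"unknown population labels in order: {missing}")
    base = by_label[order[0]].means[trait]
    rows = []
    prev = None
    for label in order:
        m = by_label[label].means[trait]
        rows.append({
            "population": label,
            "mean": m,
            "delta": np.nan if prev is None else m - prev,
            "cumulative_percent_gain": percent_gain(m, base),
        })
        prev = m
    return pd.DataFrame(rows)


def scheme_contrast(a: PopulationSummary, b: PopulationSummary,
                    trait: str = "selection_index") -> tuple[float, float, float]:
    """Welch contrast between two scheme endpoints for one trait."""
    return welch_test(a.means[trait], a.sds[trait], a.n,
                      b.means[trait], b.sds[trait], b.n)
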