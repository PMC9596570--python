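"""Detection-threshold sensitivity study with corrected nonparametric tests.

The detector's threshold preference z is a free parameter; the sensitivity
study asks over which z range the biological contrast between treatment
conditions is significant.  For every (cell line, unordered condition pair,
z) triple, per-cell counts (dual puncta, or mitochondria-associated dual
puncta) are compared with the Kruskal–Wallis rank test, and significance is
declared at the Bonferroni-corrected level alpha / m, where m is the full
size of the hypothesis grid — for the canonical design of 4 conditions,
2 cell lines and 21 z-values, m = C(4,2) * 2 * 21 = 252.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Default z grid: 21 values spanning (0, 2].
DEFAULT_Z_GRID = tuple(np.round(np.linspace(0.1, 2.0, 21), 10))


@dataclass(frozen=True)
class SweepConfig:
    conditions: tuple[str, ...] = ("DMSO", "DMSO+BafA1", "CCCP", "CCCP+BafA1")
    cell_lines: tuple[str, ...] = ("WT", "KO")
    z_values: tuple[float, ...] = DEFAULT_Z_GRID
    alpha: float = 0.05
    response: str = "n_dual"  # or "n_dual_near_mito"

    def __post_init__(self) -> None:
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("duplicate condition labels")
        if len(self.conditions) < 2 or len(self.cell_lines) < 1 or len(self.z_values) < 1:
            raise ValueError("need >= 2 conditions, >= 1 cell line, >= 1 z value")
        zs = list(self.z_values)
        if any(z <= 0 for z in zs) or zs != sorted(zs) or len(set(zs)) != len(zs):
            raise ValueError("z_values must be positive and strictly increasing")

    @property
    def m(self) -> int:
        """Total hypothesis count: C(n_cond, 2) * n_lines * n_z (never user-set)."""
        return (
            math.comb(len(self.conditions), 2) * len(self.cell_lines) * len(self.z_values)
        )

    @property
    def corrected_alpha(self) -> float:
        return self.alpha / self.m


@dataclass
class SweepTestResult:
    cell_line: str
    condition_pair: tuple[str, str]
    z: float
    group_sizes: tuple[int, ...]
    h_statistic: float | None
    p_value: float | None
    corrected_alpha: float
    significant: bool
    group_means: tuple[float, ...] = field(default_factory=tuple)


def build_hypothesis_grid(config: SweepConfig) -> list[tuple[str, tuple[str, str], float]]:
    """All (cell line, unordered condition pair, z) triples; length = config.m."""
    pairs = list(combinations(config.conditions, 2))
    grid = [
        (line, pair, float(z))
        for line in config.cell_lines
        for pair in pairs
        for z in config.z_values
    ]
    assert len(grid) == config.m
    return grid


def kruskal_test(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) and chi-squared p-value.

    Degenerate input with all observations identical yields H = 0, p = 1
    rather than an error.
    """
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.unique(pooled).size < 2:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def run_sweep(
    counts: pd.DataFrame,
    config: SweepConfig,
) -> list[SweepTestResult]:
    """Pairwise Kruskal tests over the full hypothesis grid.

    ``counts`` holds one row per (cell, z) with columns ``cell_line``,
    ``condition``, ``z`` and ``count`` — per-cell dual-puncta (or associated
    dual-puncta) counts recomputed at each z of the grid.  Grid entries with
    a missing or single-cell group are emitted with absent statistics.
    Significance: p < alpha / m.
    """
    required = {"cell_line", "condition", "z", "count"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts must have columns {sorted(required)}")
    results: list[SweepTestResult] = []
    grouped = {
        key: sub["count"].to_numpy(dtype=float)
        for key, sub in counts.groupby(["cell_line", "condition", "z"])
    }
    for line, (cond_a, cond_b), z in build_hypothesis_grid(config):
        a = grouped.get((line, cond_a, z))
        b = grouped.get((line, cond_b, z))
        if a is None or b is None or len(a) < 2 or len(b) < 2:
            results.append(
                SweepTestResult(
                    cell_line=line,
                    condition_pair=(cond_a, cond_b),
                    z=z,
                    group_sizes=(0 if a is None else len(a), 0 if b is None else len(b)),
                    h_statistic=None,
                    p_value=None,
                    corrected_alpha=config.corrected_alpha,
                    significant=False,
                )
            )
            continue
        h, p = kruskal_test([a, b])
        results.append(
            SweepTestResult(
                cell_line=line,
                condition_pair=(cond_a, cond_b),
                z=z,
                group_sizes=(len(a), len(b)),
                h_statistic=h,
                p_value=p,
                corrected_alpha=config.corrected_alpha,
                significant=p < config.corrected_alpha,
                group_means=(float(a.mean()), float(b.mean())),
            )
        )
    return results


def mean_counts_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-z mean count per (cell line, condition) group — the sweep curves."""
    return (
        counts.groupby(["cell_line", "condition", "z"])["count"]
        .mean()
        .rename("mean_count")
        .reset_index()
    )


def results_frame(results: Sequence[SweepTestResult]) -> pd.DataFrame:
    """Flatten sweep results into a tidy DataFrame for CSV export."""
    return pd.DataFrame(
        {
            "cell_line": [r.cell_line for r in results],
            "condition_a": [r.condition_pair[0] for r in results],
            "condition_b": [r.condition_pair[1] for r in results],
            "z": [r.z for r in results],
            "n_a": [r.group_sizes[0] for r in results],
            "n_b": [r.group_sizes[1] for r in results],
            "H": [r.h_statistic for r in results],
            "p": [r.p_value for r in results],
            "corrected_alpha": [r.corrected_alpha for r in results],
            "significant": [r.significant for r in results],
        }
    )


def counts_from_summaries(summaries: Mapping[float, Sequence], response: str = "n_dual") -> pd.DataFrame:
    """Build the run_sweep input table from per-z lists of CellSummary."""
    rows = []
    for z, cells in summaries.items():
        for s in cells:
            rows.append(
                {
                    "cell_line": s.cell_line,
                    "condition": s.condition,
                    "z": float(z),
                    "count": getattr(s, response),
                }
            )
    return pd.DataFrame(rows)
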