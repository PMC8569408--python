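"""Repeated-measures statistics over the robustness measures.

A two-way within-subject ANOVA over the factors *number of channels*
(3 levels) and *classification algorithm* (5 levels) is run per window
length and measure (ACA or RES), without sphericity correction, so a
complete 21-subject table yields the design degrees of freedom (2, 40),
(4, 80) and (8, 160).  Post-hoc contrasts are two-sided paired t-tests
with Bonferroni correction, the family being all level pairs of the
tested factor (3 pairs for channels, 10 for algorithms).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.anova import AnovaRM

from .dataio import ValidationError

__all__ = [
    "AnovaEffect",
    "validate_measure_table",
    "rm_anova_two_way",
    "paired_t_bonferroni",
]

FACTORS = ("n_channels", "algorithm")


@dataclass
class AnovaEffect:
    effect: str
    f_value: float
    df: int
    df_error: int
    p_value: float


def validate_measure_table(table: pd.DataFrame, value_col: str = "value") -> None:
    """Check the long-format table is a complete balanced within-subject crossing."""
    required = {"subject_id", "n_channels", "algorithm", value_col}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"measure table missing columns {sorted(missing)}")
    if not np.all(np.isfinite(table[value_col])):
        raise ValidationError("measure table contains non-finite values")
    counts = table.groupby(["subject_id", "n_channels", "algorithm"]).size()
    if counts.empty or (counts != 1).any():
        raise ValidationError("table is not a complete one-observation-per-cell crossing")
    n_cells = table.groupby("subject_id").size()
    expected = table["n_channels"].nunique() * table["algorithm"].nunique()
    if (n_cells != expected).any():
        raise ValidationError("incomplete crossing: some subject misses cells")


def rm_anova_two_way(table: pd.DataFrame,
                     value_col: str = "value") -> dict[str, AnovaEffect]:
    """Two-way repeated-measures ANOVA (channels x algorithm).

    ``table`` is long-format with one row per (subject, n_channels,
    algorithm) cell.  Returns the two main effects and the interaction
    with uncorrected integer degrees of freedom.
    """
    validate_measure_table(table, value_col)
    fit = AnovaRM(
        data=table,
        depvar=value_col,
        subject="subject_id",
        within=list(FACTORS),
    ).fit()
    out: dict[str, AnovaEffect] = {}
    for row in fit.anova_table.itertuples():
        name = row.Index.replace(":", " x ")
        out[name] = AnovaEffect(
            effect=name,
            f_value=float(row._1),
            df=int(round(row._2)),
            df_error=int(round(row._3)),
            p_value=float(row._4),
        )
    return out


def paired_t_bonferroni(
    table: pd.DataFrame,
    factor: str,
    comparisons: list[tuple] | None = None,
    value_col: str = "value",
) -> pd.DataFrame:
    """Bonferroni-corrected two-sided paired t-tests over factor levels.

    Values are averaged over the other factor per subject before
    pairing.  The correction family is the full set of tested pairs;
    corrected p-values are capped at 1.  Zero-variance differences are
    reported as non-significant with ``degenerate = True`` instead of
    raising, so pipelines on constant synthetic data never crash.
    """
    if factor not in table.columns:
        raise ValidationError(f"factor {factor!r} not in table")
    levels = sorted(table[factor].unique())
    if comparisons is None:
        comparisons = list(itertools.combinations(levels, 2))
    family = len(comparisons)
    cell = table.groupby(["subject_id", factor])[value_col].mean().unstack(factor)
    rows = []
    for a, b in comparisons:
        if a not in cell.columns or b not in cell.columns:
            raise ValidationError(f"level pair ({a}, {b}) missing from table")
        diff = cell[a] - cell[b]
        if diff.isna().any():
            raise ValidationError(f"subjects mismatched for pair ({a}, {b})")
        degenerate = bool(np.isclose(diff.std(ddof=1), 0.0))
        if degenerate:
            t_stat, p_raw = np.nan, 1.0
        else:
            t_stat, p_raw = scipy.stats.ttest_rel(cell[a], cell[b])
        p_corr = min(1.0, float(p_raw) * family)
        rows.append(
            {
                "factor": factor,
                "level_a": a,
                "level_b": b,
                "t": float(t_stat) if np.isfinite(t_stat) else np.nan,
                "df": len(diff) - 1,
                "p_raw": float(p_raw),
                "p_bonferroni": p_corr,
                "sign": int(np.sign(diff.mean())),
                "degenerate": degenerate,
                "significant": (not degenerate) and p_corr < 0.05,
            }
        )
    return pd.DataFrame(rows)
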