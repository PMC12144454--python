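"""Group-level inference: one-sample/paired t-tests and 2-way RM-ANOVA.

The t statistics are formed directly from the classical definitions
(t = (mean - mu0) / (sd / sqrt(n)), two-tailed p from Student's t) so that
degenerate inputs fail loudly.  The repeated-measures ANOVA partitions
within-subject sums of squares via statsmodels' AnovaRM, testing each factor
against its own subject-by-factor interaction; for the study's 3 conditions
x 3 speeds x 30 observers layout this yields the df triplets (2, 58),
(2, 58) and (4, 116).  No sphericity correction is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM


class ZeroVarianceError(ValueError):
    """Sample has no variance; the t statistic is undefined."""


class UnbalancedDesignError(ValueError):
    """RM-ANOVA requires every subject in every factor cell exactly once."""


@dataclass(frozen=True)
class TestResult:
    effect_label: str
    statistic: float
    df: tuple[float, ...]      # (df,) for t, (df1, df2) for F
    p: float


def one_sample_t(values: Sequence[float], mu0: float = 0.0,
                 label: str = "") -> TestResult:
    """Two-tailed one-sample t-test of mean(values) against mu0."""
    x = np.asarray(values, float)
    if len(x) < 2:
        raise ValueError("need at least two values")
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise ZeroVarianceError(f"zero variance in sample ({label or 'values'})")
    n = len(x)
    t = (float(x.mean()) - mu0) / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), n - 1))
    return TestResult(label, t, (float(n - 1),), p)


def paired_t(a: Sequence[float], b: Sequence[float],
             label: str = "") -> TestResult:
    """Paired t-test: one-sample test of the differences against zero."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    return one_sample_t(a - b, 0.0, label=label)


def rm_anova_2way(table: pd.DataFrame, dv: str = "value",
                  subject: str = "observer_id",
                  within: tuple[str, str] = ("condition", "pursuit_speed")
                  ) -> list[TestResult]:
    """Two-way fully-within-subject ANOVA (balanced designs only).

    Returns TestResults for factor A, factor B and the A x B interaction
    with dfs (a-1, (a-1)(n-1)), (b-1, (b-1)(n-1)) and
    ((a-1)(b-1), (a-1)(b-1)(n-1)).  Raises UnbalancedDesignError when any
    subject is missing a cell (impute upstream).
    """
    counts = table.groupby([subject, *within]).size()
    a = table[within[0]].nunique()
    b = table[within[1]].nunique()
    n_subj = table[subject].nunique()
    if a < 2 or b < 2:
        raise ValueError("each within factor needs >= 2 levels")
    if len(counts) != a * b * n_subj or (counts != 1).any():
        raise UnbalancedDesignError(
            "every subject must contribute exactly one value per "
            "condition x speed cell")
    res = AnovaRM(table, depvar=dv, subject=subject,
                  within=list(within)).fit()
    tab = res.anova_table
    out = []
    for effect in tab.index:
        row = tab.loc[effect]
        out.append(TestResult(
            effect_label=str(effect),
            statistic=float(row["F Value"]),
            df=(float(row["Num DF"]), float(row["Den DF"])),
            p=float(row["Pr > F"])))
    return out


def stats_table(results: Sequence[TestResult]) -> pd.DataFrame:
    """CSV-ready table: effect_label, statistic, df1, df2, p."""
    rows = []
    for r in results:
        rows.append({"effect_label": r.effect_label,
                     "statistic": r.statistic,
                     "df1": r.df[0],
                     "df2": r.df[1] if len(r.df) > 1 else np.nan,
                     "p": r.p})
    return pd.DataFrame(rows, columns=["effect_label", "statistic",
                                       "df1", "df2", "p"])
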