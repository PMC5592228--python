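"""Clinical-score arithmetic and cohort summary tables.

The disease burden score (DBS) is the standard cumulative-toxicity index in
Huntington's disease: age times the CAG expansion beyond the 35.5-repeat
threshold on the larger allele.  Group summaries report per-group mean/SD
and a Welch (unequal-variance, unpaired) t-test between premanifest
carriers and manifest patients; pairing is undefined across distinct
individuals, so an unpaired test is used deliberately.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

CAG_THRESHOLD = 35.5


def disease_burden_score(age_years: float, cag_repeats: float) -> float:
    """DBS = age * (CAG repeats - 35.5).

    Negative values (CAG below threshold) are returned as-is; they are
    flagged downstream, not clipped here.
    """
    if not age_years > 0:
        raise ValueError("age_years must be positive")
    if cag_repeats < 1:
        raise ValueError("cag_repeats must be >= 1")
    return float(age_years) * (float(cag_repeats) - CAG_THRESHOLD)


def group_summary(
    cohort: pd.DataFrame,
    variables: tuple[str, ...] = ("age_years", "cag_repeats", "dbs"),
    compare: tuple[str, str] = ("premanifest", "manifest"),
) -> pd.DataFrame:
    """Per-group n/mean/SD table with a Welch t-test between two groups.

    One row per (variable, group); the test statistic and p-value for the
    ``compare`` pair are attached to every row of the corresponding
    variable (NaN when fewer than two finite values exist in either group).
    Invariant under row permutation of the cohort.
    """
    missing = [v for v in variables if v not in cohort.columns]
    if missing:
        raise ValueError(f"variables absent from cohort table: {missing}")
    groups = sorted(cohort["group"].unique())
    rows = []
    for var in variables:
        col = pd.to_numeric(cohort[var], errors="coerce")
        tstat = pval = np.nan
        if all(g in groups for g in compare):
            a = col[cohort["group"] == compare[0]].dropna()
            b = col[cohort["group"] == compare[1]].dropna()
            if len(a) >= 2 and len(b) >= 2:
                res = stats.ttest_ind(a, b, equal_var=False)
                tstat, pval = float(res.statistic), float(res.pvalue)
                if not np.isfinite(tstat):  # identical constant groups
                    tstat, pval = 0.0, 1.0
        for g in groups:
            vals = col[cohort["group"] == g].dropna()
            rows.append(
                {
                    "variable": var,
                    "group": g,
                    "n": int(len(vals)),
                    "mean": float(vals.mean()) if len(vals) else np.nan,
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                    "welch_t": tstat,
                    "welch_p": pval,
                }
            )
    return pd.DataFrame(rows)
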