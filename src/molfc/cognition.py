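"""Site-referenced cognitive z-scores and the global composite score.

Seven measures common to all cohorts: logical memory immediate and delayed
recall (LM-IR, LM-DR), letter fluency, similarities, Stroop
time-interference, digit span forwards and backwards. Each raw score is
standardized against the mean and SD of the *same site's* cognitively
unimpaired (CU) group, so the CU group at each site has mean 0 / SD 1 by
construction. The composite score (CS) averages the available z-scores and
is left missing for participants with three or fewer measures.

Stroop time-interference is a completion time, so higher raw scores mean
worse performance; by default its z-score is sign-flipped before averaging
so that higher CS uniformly means better cognition. The flip set is
explicit and configurable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MEASURES = ["lm_ir", "lm_dr", "letter_fluency", "similarities",
            "stroop_time", "digit_span_f", "digit_span_b"]

#: measures where a larger raw score indicates worse performance
DEFAULT_DIRECTION_FLIPS = frozenset({"stroop_time"})

MIN_MEASURES_FOR_CS = 4  # composite undefined with three or fewer


def zscore_by_site(cohort: pd.DataFrame, measures: list[str] | None = None,
                   group_col: str = "group", site_col: str = "site",
                   cu_label: str = "CU") -> pd.DataFrame:
    """Standardize each measure against the site's CU group.

    Returns a copy of the table with added ``z_<measure>`` columns;
    missing raw scores propagate to missing z-scores. CU SDs use the
    sample (n−1) formula.
    """
    if measures is None:
        measures = [m for m in MEASURES if m in cohort.columns]
    out = cohort.copy()
    for site, site_rows in cohort.groupby(site_col, sort=False):
        cu = site_rows[site_rows[group_col] == cu_label]
        for m in measures:
            vals = cu[m].dropna()
            if len(vals) < 2:
                raise ValueError(
                    f"site '{site}' has fewer than 2 CU values for "
                    f"measure '{m}'")
            sd = vals.std(ddof=1)
            if sd == 0:
                raise ValueError(
                    f"site '{site}' CU group has zero SD on '{m}'")
            idx = site_rows.index
            out.loc[idx, f"z_{m}"] = (cohort.loc[idx, m] - vals.mean()) / sd
    return out


def composite(zscores: pd.Series | dict[str, float],
              direction_flips: frozenset[str] = DEFAULT_DIRECTION_FLIPS
              ) -> tuple[float, int]:
    """Composite score: mean of available (sign-corrected) z-scores.

    ``zscores`` maps measure name → z (NaN for missing). Returns
    ``(value, n_used)``; the value is NaN when fewer than
    :data:`MIN_MEASURES_FOR_CS` measures are available.
    """
    items = dict(zscores)
    vals = []
    for name, z in items.items():
        if z is None or (isinstance(z, float) and np.isnan(z)):
            continue
        vals.append(-z if name in direction_flips else z)
    n_used = len(vals)
    if n_used < MIN_MEASURES_FOR_CS:
        return float("nan"), n_used
    return float(np.mean(vals)), n_used


def add_composite(cohort: pd.DataFrame,
                  measures: list[str] | None = None,
                  direction_flips: frozenset[str] = DEFAULT_DIRECTION_FLIPS
                  ) -> pd.DataFrame:
    """Add ``cs`` and ``cs_n_measures`` columns to a z-scored table."""
    if measures is None:
        measures = [m for m in MEASURES if f"z_{m}" in cohort.columns]
    out = cohort.copy()
    cs_vals, cs_n = [], []
    for _, row in cohort.iterrows():
        value, n_used = composite(
            {m: row[f"z_{m}"] for m in measures}, direction_flips)
        cs_vals.append(value)
        cs_n.append(n_used)
    out["cs"] = cs_vals
    out["cs_n_measures"] = cs_n
    return out
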