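"""Within-interval normalization of the importance measures.

Two schemes, both applied independently per time interval:

- *percent normalization* divides each indegree by the interval's indegree
  sum, giving an AOI's share of all received transitions (values sum to 1).
  It is meaningful for indegree only — closeness and betweenness are not
  shares of a conserved total — and is refused for the other measures.
- *distance normalization* maps each measure affinely onto [0, 1] via
  (v - min) / (max - min), so the most important AOI of the interval reads
  1 and the least important 0.  It applies to all three measures.  When all
  values coincide (max = min) every value maps to 0, keeping the
  "distance below the maximum" reading, with a warning.
"""

from __future__ import annotations

import logging

import pandas as pd

__all__ = ["percent_normalize_indegree", "distance_normalize", "normalize_measures"]

log = logging.getLogger(__name__)

MEASURES = ("indegree", "closeness", "betweenness")


def _require_single_interval(records: pd.DataFrame) -> None:
    if "interval" in records.columns and records["interval"].nunique() > 1:
        raise ValueError(f"records span multiple intervals: {sorted(records['interval'].unique())}")


def percent_normalize_indegree(records: pd.DataFrame, measure: str = "indegree") -> pd.Series:
    """Indegree share per AOI for one interval's records; sums to 1 when nonzero.

    Percent normalization is defined for indegree only; asking for another
    measure is an error rather than a silently meaningless ratio.
    """
    if measure != "indegree":
        raise ValueError("percent normalization applies to indegree only")
    _require_single_interval(records)
    values = records["indegree"].astype(float)
    total = values.sum()
    if total <= 0:
        log.warning("interval has zero total indegree; percent normalization returns zeros")
        return pd.Series(0.0, index=records.index, name="percent_norm")
    return (values / total).rename("percent_norm")


def distance_normalize(records: pd.DataFrame, measure: str) -> pd.Series:
    """Min-max map of one measure onto [0, 1] within one interval."""
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    _require_single_interval(records)
    if records.empty:
        raise ValueError("cannot distance-normalize an empty record set")
    values = records[measure].astype(float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        log.warning("all %s values equal (%.6g); distance normalization returns zeros", measure, lo)
        return pd.Series(0.0, index=records.index, name=f"{measure}_distnorm")
    return ((values - lo) / (hi - lo)).rename(f"{measure}_distnorm")


def normalize_measures(table: pd.DataFrame) -> pd.DataFrame:
    """Extend a measure table with both normalizations, computed per interval.

    Adds ``indegree_pctnorm`` plus ``<measure>_distnorm`` for each of the
    three measures.
    """
    out = table.copy()
    out["indegree_pctnorm"] = 0.0
    for measure in MEASURES:
        out[f"{measure}_distnorm"] = 0.0
    for _, idx in out.groupby("interval").groups.items():
        sub = out.loc[idx]
        out.loc[idx, "indegree_pctnorm"] = percent_normalize_indegree(sub)
        for measure in MEASURES:
            out.loc[idx, f"{measure}_distnorm"] = distance_normalize(sub, measure)
    return out
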