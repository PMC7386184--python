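"""Simpson's Faunal Resemblance Index over fail-point sets.

FRI = |X intersect Y| / min(|X|, |Y|), in [0, 1]; higher means the two
fail-point distributions agree more closely.  Because the denominator is
the smaller set, the index is insensitive to a size imbalance between
the two comparisons.

A comparison with no fail points (a 100% passing rate) makes the index
undefined; such cases carry an explicit *excluded* marker rather than a
0 or 1, and cohort summaries average over non-excluded cases only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .comparison_metrics import FailPointSet

__all__ = ["FriResult", "simpson_fri", "fri_table"]


@dataclass(frozen=True)
class FriResult:
    value: float | None
    n_intersection: int
    n_min: int
    pair_label: str = ""
    excluded: bool = False

    def __post_init__(self):
        if not self.excluded:
            if self.value is None or not (0.0 <= self.value <= 1.0):
                raise ValueError("FRI must lie in [0, 1]")
            if self.n_intersection > self.n_min:
                raise ValueError("intersection cannot exceed the smaller set")


def _as_index_set(s) -> frozenset[int]:
    if isinstance(s, FailPointSet):
        return s.indices
    return frozenset(int(i) for i in s)


def simpson_fri(x, y, pair_label: str = "") -> FriResult:
    """Simpson similarity of two fail-point sets on a shared layout.

    If either set is empty the case is *excluded* (value ``None``,
    ``excluded=True``) — an undefined index, not a zero.
    """
    xs, ys = _as_index_set(x), _as_index_set(y)
    if len(xs) == 0 or len(ys) == 0:
        return FriResult(None, 0, min(len(xs), len(ys)), pair_label, excluded=True)
    n_min = min(len(xs), len(ys))
    n_int = len(xs & ys)
    return FriResult(n_int / n_min, n_int, n_min, pair_label)


def _normalize_cohort(arg) -> list[Mapping[str, FailPointSet]]:
    """Accept a single case (criterion -> fail set) or a cohort of them."""
    if isinstance(arg, Mapping):
        return [arg]
    return list(arg)


def fri_table(
    pattern1_fails,
    pattern2_fails,
    pattern3_fails,
    criteria_names: Sequence[str],
) -> pd.DataFrame:
    """Pairwise FRI summary over a cohort.

    Each ``pattern*_fails`` argument is either one mapping
    ``criterion name -> FailPointSet`` (single case) or a sequence of
    such mappings (one per case).  For every criterion the table reports
    FRI(pattern1, pattern2) and FRI(pattern1, pattern3): per-case values
    when the cohort has one case, and mean/SD/max/min over non-excluded
    cases plus the number excluded otherwise.
    """
    cohorts = [_normalize_cohort(a) for a in (pattern1_fails, pattern2_fails, pattern3_fails)]
    n_cases = {len(c) for c in cohorts}
    if len(n_cases) != 1:
        raise ValueError("pattern fail-set cohorts must have equal length")

    rows = []
    for crit in criteria_names:
        for other, label in ((1, "pattern1-vs-pattern2"), (2, "pattern1-vs-pattern3")):
            results = [
                simpson_fri(case1[crit], case_other[crit], pair_label=label)
                for case1, case_other in zip(cohorts[0], cohorts[other])
            ]
            vals = np.array([r.value for r in results if not r.excluded], dtype=float)
            rows.append(
                {
                    "criterion": crit,
                    "pair": label,
                    "mean": float(vals.mean()) if vals.size else np.nan,
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                    "max": float(vals.max()) if vals.size else np.nan,
                    "min": float(vals.min()) if vals.size else np.nan,
                    "n": int(vals.size),
                    "n_excluded": sum(r.excluded for r in results),
                }
            )
    return pd.DataFrame(rows)
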