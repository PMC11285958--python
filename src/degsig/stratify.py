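"""Mean±SEM dichotomization and the combined four-group assignment.

A cohort is split on any per-sample score (anchor expression or a
signature z-score) into a high group (score >= mean + SEM), a low group
(score <= mean - SEM) and an excluded middle band.  Two such splits
combine into the HH/HL/LH/LL four-group assignment used for combined
survival analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import DegenerateStratificationError, DegsigError, logger


@dataclass
class StratifyResult:
    high_ids: list[str]
    low_ids: list[str]
    excluded_ids: list[str]
    mean: float
    sem: float

    @property
    def threshold_high(self) -> float:
        return self.mean + self.sem

    @property
    def threshold_low(self) -> float:
        return self.mean - self.sem

    def sample_universe(self) -> set[str]:
        return set(self.high_ids) | set(self.low_ids) | set(self.excluded_ids)

    def to_frame(self) -> pd.DataFrame:
        """Two-column audit table sample_id -> group."""
        rows = [(s, "high") for s in self.high_ids]
        rows += [(s, "low") for s in self.low_ids]
        rows += [(s, "excluded") for s in self.excluded_ids]
        return pd.DataFrame(rows, columns=["sample_id", "group"])


def mean_sem_split(values: pd.Series) -> StratifyResult:
    """Split samples on mean ± SEM of `values` (index = sample ids).

    SEM uses the n-1 sample standard deviation.  Boundaries are inclusive:
    high = {v >= mean+SEM}, low = {v <= mean-SEM}; the middle band is
    excluded.  Raises if the input is constant or either group is empty.
    """
    if not isinstance(values, pd.Series):
        values = pd.Series(values)
    v = values.to_numpy(dtype=float)
    if v.size < 4:
        raise DegsigError(f"mean±SEM split needs >= 4 samples, got {v.size}")
    if not np.isfinite(v).all():
        raise DegsigError("mean±SEM split given non-finite values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0.0:
        raise DegenerateStratificationError("all values identical; cannot stratify")
    sem = sd / np.sqrt(v.size)
    hi, lo = mean + sem, mean - sem
    ids = values.index.astype(str)
    high = list(ids[v >= hi])
    low = list(ids[v <= lo])
    excluded = list(ids[(v > lo) & (v < hi)])
    if not high or not low:
        raise DegenerateStratificationError(
            f"empty group with thresholds low={lo:.6g}, high={hi:.6g} (mean={mean:.6g}, sem={sem:.6g})"
        )
    logger.info("mean±SEM split: %d high / %d low / %d excluded", len(high), len(low), len(excluded))
    return StratifyResult(high_ids=high, low_ids=low, excluded_ids=excluded, mean=mean, sem=float(sem))


FOUR_GROUPS = ("HH", "HL", "LH", "LL")


def four_group_assign(a: StratifyResult, b: StratifyResult) -> dict[str, str]:
    """Combine two stratifications into HH/HL/LH/LL.

    Defined only on samples that are non-excluded in both inputs; the first
    letter is the status in `a`, the second in `b`.  Raises if any of the
    four groups is empty (the combined survival comparison is undefined).
    """
    a_high, a_low = set(a.high_ids), set(a.low_ids)
    b_high, b_low = set(b.high_ids), set(b.low_ids)
    assignment: dict[str, str] = {}
    for s in sorted((a_high | a_low) & (b_high | b_low)):
        first = "H" if s in a_high else "L"
        second = "H" if s in b_high else "L"
        assignment[s] = first + second
    sizes = {g: sum(1 for v in assignment.values() if v == g) for g in FOUR_GROUPS}
    empty = [g for g, n in sizes.items() if n == 0]
    if empty:
        raise DegsigError(f"empty four-group cell(s) {empty}; group sizes {sizes}")
    logger.info("four-group sizes: %s", sizes)
    return assignment
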