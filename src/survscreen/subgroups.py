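"""Per-probe min–max scaling and low/high expresser subgrouping.

Each probe's expression is rescaled affinely so its observed minimum maps to
0 and its maximum to 1.  Patients whose scaled value falls in [0, low] are
"low expressers", those in [high, 1] are "high expressers", and the middle of
the range is excluded.  The cut is on the expression *range*, not on
percentiles, so group sizes are generally unequal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_LOW = 0.3
DEFAULT_HIGH = 0.7
DEFAULT_MIN_GROUP = 10


class DegenerateProbeError(ValueError):
    """The probe has zero expression range (max == min) and cannot be scaled."""


@dataclass
class SubgroupAssignment:
    """Partition of samples into low/high expressers for one probe."""

    probe_id: str
    scaled: pd.Series
    low_ids: list[str]
    high_ids: list[str]
    low_threshold: float = DEFAULT_LOW
    high_threshold: float = DEFAULT_HIGH
    min_group: int = DEFAULT_MIN_GROUP
    underpowered: bool = field(init=False)

    def __post_init__(self) -> None:
        if not 0 <= self.low_threshold < self.high_threshold <= 1:
            raise ValueError("need 0 <= low_threshold < high_threshold <= 1")
        if set(self.low_ids) & set(self.high_ids):
            raise ValueError("low and high groups overlap")
        self.underpowered = (
            len(self.low_ids) < self.min_group or len(self.high_ids) < self.min_group
        )

    @property
    def n_low(self) -> int:
        return len(self.low_ids)

    @property
    def n_high(self) -> int:
        return len(self.high_ids)

    def labels(self) -> pd.Series:
        """Per-sample label in {'low', 'high', 'mid'} (missing values excluded)."""
        lab = pd.Series("mid", index=self.scaled.dropna().index, dtype=object)
        lab.loc[self.low_ids] = "low"
        lab.loc[self.high_ids] = "high"
        return lab


def scale_probe(values: pd.Series) -> pd.Series:
    """Affinely map one probe's values onto [0, 1]; missing stays missing.

    Raises
    ------
    DegenerateProbeError
        If fewer than 2 values are non-missing or the range is zero.  The
        screen skips (and logs) such probes rather than failing.
    """
    v = values.astype(float)
    obs = v.dropna()
    if len(obs) < 2:
        raise DegenerateProbeError(f"probe needs >=2 non-missing values, got {len(obs)}")
    lo, hi = obs.min(), obs.max()
    if hi == lo:
        raise DegenerateProbeError(f"constant probe (all values {lo!r})")
    return (v - lo) / (hi - lo)


def assign_subgroups(
    scaled: pd.Series,
    low_threshold: float = DEFAULT_LOW,
    high_threshold: float = DEFAULT_HIGH,
    min_group: int = DEFAULT_MIN_GROUP,
    probe_id: str = "",
) -> SubgroupAssignment:
    """Classify samples by scaled expression: <= low → low, >= high → high.

    Both boundary values are inclusive (the intervals are closed).  Groups
    smaller than ``min_group`` on either side mark the probe underpowered;
    the screen excludes such probes but still reports them.
    """
    obs = scaled.dropna()
    if ((obs < 0) | (obs > 1)).any():
        raise ValueError("scaled values must lie in [0, 1]")
    low_ids = list(obs.index[obs <= low_threshold])
    high_ids = list(obs.index[obs >= high_threshold])
    return SubgroupAssignment(
        probe_id=probe_id,
        scaled=scaled,
        low_ids=low_ids,
        high_ids=high_ids,
        low_threshold=low_threshold,
        high_threshold=high_threshold,
        min_group=min_group,
    )


def rank_scale_probe(values: pd.Series) -> pd.Series:
    """Rank-based alternative scaling (sensitivity analysis only).

    Maps mid-ranks onto [0, 1]; unlike min–max scaling this is invariant to
    monotone transforms of the input.
    """
    v = values.astype(float)
    obs = v.dropna()
    if len(obs) < 2:
        raise DegenerateProbeError(f"probe needs >=2 non-missing values, got {len(obs)}")
    if obs.nunique() == 1:
        raise DegenerateProbeError("constant probe")
    ranks = obs.rank(method="average") - 1
    out = pd.Series(np.nan, index=v.index)
    out.loc[obs.index] = ranks / (len(obs) - 1)
    return out
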