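"""The genome-wide biomarker screen: subgroup every probe, test survival, rank.

For each probe the cohort is min–max scaled, split into low/high expressers
at the configured range thresholds, and the two subgroups are compared on
overall survival (and event-free survival when available).  Probes with zero
range are flagged degenerate; probes whose subgroups fall below the minimum
size are flagged underpowered; both are excluded from the candidate list but
still appear in the output so no probe is silently dropped.

The default comparison is the Wilcoxon rank-sum test on observed follow-up
times; raw p-values are thresholded at alpha (no multiple-testing correction
by default) but a Benjamini–Hochberg q-value column is always emitted
alongside for hygiene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexp import bh_adjust
from .io import ClinicalTable, ExpressionMatrix, join_samples
from .subgroups import DegenerateProbeError, assign_subgroups, scale_probe
from .survival import km_estimate, survival_test

log = logging.getLogger(__name__)


@dataclass
class ScreenConfig:
    low_threshold: float = 0.3
    high_threshold: float = 0.7
    min_group: int = 10
    test: str = "ranksum"  # ranksum | logrank | gehan
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return vars(self).copy()


@dataclass
class ScreenResult:
    """Per-probe screen statistics plus the parameters that produced them."""

    table: pd.DataFrame
    config: ScreenConfig
    has_efs: bool = False
    notes: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", na_rep="NA")


_COLUMNS = [
    "n_low",
    "n_high",
    "p_os",
    "q_os",
    "p_efs",
    "median_os_low",
    "median_os_high",
    "median_efs_low",
    "median_efs_high",
    "direction",
    "degenerate",
    "underpowered",
    "skipped",
]


def _direction(median_low, median_high) -> str:
    if median_low is None or median_high is None or median_low == median_high:
        return "mixed"
    return "high_worse" if median_high < median_low else "low_worse"


def screen_all_probes(
    matrix: ExpressionMatrix, clinical: ClinicalTable, config: ScreenConfig | None = None
) -> ScreenResult:
    """Run the survival screen over every probe of the matrix.

    The output table has one row per input probe in input order; skipped
    probes (degenerate or underpowered) carry NA statistics and a flag.
    """
    config = config or ScreenConfig()
    matrix, clinical, join = join_samples(matrix, clinical)
    has_efs = clinical.has_efs
    rows = []
    for probe_id in matrix.probe_ids:
        rec: dict = {c: np.nan for c in _COLUMNS}
        rec["degenerate"] = rec["underpowered"] = rec["skipped"] = False
        rec["direction"] = "mixed"
        try:
            scaled = scale_probe(matrix.probe(probe_id))
        except DegenerateProbeError:
            rec["degenerate"] = rec["skipped"] = True
            rows.append(rec)
            continue
        groups = assign_subgroups(
            scaled, config.low_threshold, config.high_threshold, config.min_group, probe_id
        )
        rec["n_low"], rec["n_high"] = groups.n_low, groups.n_high
        if groups.underpowered:
            rec["underpowered"] = rec["skipped"] = True
            rows.append(rec)
            continue
        t_lo, e_lo = clinical.survival(groups.low_ids, "os")
        t_hi, e_hi = clinical.survival(groups.high_ids, "os")
        rec["p_os"] = survival_test(t_lo, e_lo, t_hi, e_hi, config.test).p_value
        km_lo, km_hi = km_estimate(t_lo, e_lo), km_estimate(t_hi, e_hi)
        rec["median_os_low"], rec["median_os_high"] = km_lo.median, km_hi.median
        rec["direction"] = _direction(km_lo.median, km_hi.median)
        if has_efs:
            ft_lo, fe_lo = clinical.survival(groups.low_ids, "efs")
            ft_hi, fe_hi = clinical.survival(groups.high_ids, "efs")
            rec["p_efs"] = survival_test(ft_lo, fe_lo, ft_hi, fe_hi, config.test).p_value
            rec["median_efs_low"] = km_estimate(ft_lo, fe_lo).median
            rec["median_efs_high"] = km_estimate(ft_hi, fe_hi).median
        rows.append(rec)
    table = pd.DataFrame(rows, index=pd.Index(matrix.probe_ids, name="probe_id"), columns=_COLUMNS)
    tested = table["p_os"].notna()
    q = pd.Series(np.nan, index=table.index)
    if tested.any():
        q[tested] = bh_adjust(table.loc[tested, "p_os"].to_numpy())
    table["q_os"] = q
    if not tested.any():
        log.warning("no probe survived the degeneracy/power filters")
    return ScreenResult(table=table, config=config, has_efs=has_efs, notes=join)


def select_hits(
    result: ScreenResult,
    alpha: float | None = None,
    require_both: bool = True,
    allowlist=None,
) -> pd.DataFrame:
    """Significant probes ranked by ascending OS p-value.

    ``require_both`` additionally demands EFS significance when the cohort
    has an EFS endpoint; ``allowlist`` intersects with a user-supplied probe
    list (the screen's literature-curation step is manual and enters only
    through this filter).
    """
    if result.table.empty:
        raise ValueError("empty screen result")
    alpha = result.config.alpha if alpha is None else alpha
    tab = result.table[~result.table["skipped"]]
    keep = tab["p_os"] < alpha
    if require_both and result.has_efs:
        keep &= tab["p_efs"] < alpha
    hits = tab[keep]
    if allowlist is not None:
        hits = hits.loc[hits.index.intersection(list(allowlist))]
    return hits.sort_values("p_os", kind="stable")
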