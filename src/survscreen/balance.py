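"""Covariate-imbalance detection and seeded randomized rebalancing.

After a probe's low/high expresser subgroups are formed, known mutation,
karyotype and demographic covariates may be unevenly distributed between
them (high expressers of a prognostic gene are often enriched for specific
lesions).  Each covariate level is tested one-vs-rest in a 2x2 Fisher exact
test against group membership; if any level is significant at ``alpha``,
patients are shuffled out of (and occasionally back into) the groups until
no level remains significant.  The procedure is greedy and fully seeded so a
report can be reproduced byte-for-byte.

Age, the only continuous covariate, is dichotomized at the pooled median so
it enters the same exact-test framework; missing covariate labels form their
own "unknown" level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ClinicalTable

DEFAULT_ALPHA = 0.05
DEFAULT_MAX_ITER = 1000
AGE_COVARIATE = "age_above_median"


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    The p-value sums hypergeometric probabilities of all tables with the
    same margins whose point probability does not exceed the observed
    table's.  A zero margin makes the table degenerate and returns p = 1.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided").pvalue)


@dataclass
class ImbalanceRecord:
    covariate: str
    level: str
    count_low: int
    count_high: int
    n_low: int
    n_high: int
    p: float

    @property
    def table(self) -> list[list[int]]:
        return [
            [self.count_low, self.n_low - self.count_low],
            [self.count_high, self.n_high - self.count_high],
        ]


def _covariate_levels(clinical: ClinicalTable, covariates=None) -> pd.DataFrame:
    """Per-sample categorical frame: declared covariates plus dichotomized age."""
    cols = clinical.covariate_columns if covariates is None else list(covariates)
    frame = {}
    for col in cols:
        if col == "age":
            continue
        if col not in clinical.data.columns:
            continue
        frame[col] = clinical.data[col].astype(str)
    if "age" in clinical.data.columns and (covariates is None or "age" in covariates):
        age = clinical.data["age"]
        med = age.median()
        frame[AGE_COVARIATE] = pd.Series(
            np.where(age.isna(), "unknown", np.where(age > med, "yes", "no")),
            index=clinical.data.index,
        )
    return pd.DataFrame(frame, index=clinical.data.index)


def imbalance_scan(
    low_ids,
    high_ids,
    clinical: ClinicalTable,
    alpha: float = DEFAULT_ALPHA,
    covariates=None,
) -> list[ImbalanceRecord]:
    """Fisher-test every covariate level one-vs-rest against low/high membership.

    Returns all level records sorted by ascending p (the caller applies the
    alpha threshold).  Binary yes/no covariates contribute a single 'yes'
    record to avoid testing the same 2x2 table twice.
    """
    low_ids, high_ids = list(low_ids), list(high_ids)
    if set(low_ids) & set(high_ids):
        raise ValueError("low and high groups overlap")
    if not low_ids or not high_ids:
        raise ValueError("both groups must be non-empty")
    cov = _covariate_levels(clinical, covariates)
    n_low, n_high = len(low_ids), len(high_ids)
    records = []
    for col in cov.columns:
        low_vals = cov.loc[low_ids, col]
        high_vals = cov.loc[high_ids, col]
        levels = sorted(set(low_vals) | set(high_vals))
        if set(levels) <= {"yes", "no"}:
            levels = ["yes"] if "yes" in levels else levels[:1]
        for level in levels:
            a = int((low_vals == level).sum())
            b = int((high_vals == level).sum())
            p = fisher_exact_2x2([[a, n_low - a], [b, n_high - b]])
            records.append(ImbalanceRecord(col, level, a, b, n_low, n_high, p))
    records.sort(key=lambda r: (r.p, r.covariate, r.level))
    return records


@dataclass
class BalanceReport:
    low_ids: list[str]
    high_ids: list[str]
    removed_low: list[str]
    removed_high: list[str]
    iterations: int
    converged: bool
    seed: int
    alpha: float
    scan_before: list[ImbalanceRecord]
    scan_after: list[ImbalanceRecord]
    audit: list[dict] = field(default_factory=list)

    @property
    def p_min_after(self) -> float:
        return min((r.p for r in self.scan_after), default=1.0)

    def to_dict(self) -> dict:
        return {
            "low_ids": self.low_ids,
            "high_ids": self.high_ids,
            "removed_low": self.removed_low,
            "removed_high": self.removed_high,
            "iterations": self.iterations,
            "converged": self.converged,
            "seed": self.seed,
            "alpha": self.alpha,
            "p_min_after": self.p_min_after,
            "scan_before": [vars(r) for r in self.scan_before],
            "scan_after": [vars(r) for r in self.scan_after],
            "audit": self.audit,
        }


def rebalance(
    low_ids,
    high_ids,
    clinical: ClinicalTable,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    max_iter: int = DEFAULT_MAX_ITER,
    covariates=None,
) -> BalanceReport:
    """Shuffle patients out of / back into the subgroups until balanced.

    Greedy, seeded iteration: find the most significant covariate level;
    from the group where it is over-represented, remove one random carrier —
    or, with probability 0.5 when previously-removed non-carriers of that
    level exist on the under-represented side, re-admit one of them instead.
    Patients never enter a group they did not originally belong to.  Hitting
    ``max_iter`` returns the best groups found with ``converged=False``.
    """
    rng = np.random.default_rng(seed)
    low = list(low_ids)
    high = list(high_ids)
    removed_low: list[str] = []
    removed_high: list[str] = []
    cov = _covariate_levels(clinical, covariates)
    scan_before = imbalance_scan(low, high, clinical, alpha, covariates)
    audit: list[dict] = []
    converged = False
    iterations = 0
    scan = scan_before
    for iterations in range(1, max_iter + 1):
        offenders = [r for r in scan if r.p < alpha]
        if not offenders:
            converged = True
            iterations -= 1
            break
        worst = offenders[0]
        carrier = cov[worst.covariate] == worst.level
        frac_low = worst.count_low / worst.n_low
        frac_high = worst.count_high / worst.n_high
        over, over_removed = (low, removed_low) if frac_low > frac_high else (high, removed_high)
        under_removed = removed_high if frac_low > frac_high else removed_low
        under = high if frac_low > frac_high else low
        readmit_pool = [s for s in under_removed if not carrier.get(s, False)]
        action: dict = {
            "iteration": iterations,
            "covariate": worst.covariate,
            "level": worst.level,
            "p": worst.p,
        }
        if readmit_pool and rng.random() < 0.5:
            pick = readmit_pool[rng.integers(len(readmit_pool))]
            under_removed.remove(pick)
            under.append(pick)
            action["move"] = "readmit"
        else:
            carriers_here = [s for s in over if carrier.get(s, False)]
            if not carriers_here:  # over-representation by absence; remove a non-carrier opposite
                carriers_here = over
            pick = carriers_here[rng.integers(len(carriers_here))]
            over.remove(pick)
            over_removed.append(pick)
            action["move"] = "remove"
        action["sample_id"] = pick
        audit.append(action)
        if not low or not high:
            break
        scan = imbalance_scan(low, high, clinical, alpha, covariates)
    scan_after = imbalance_scan(low, high, clinical, alpha, covariates) if (low and high) else []
    return BalanceReport(
        low_ids=low,
        high_ids=high,
        removed_low=removed_low,
        removed_high=removed_high,
        iterations=iterations,
        converged=converged,
        seed=seed,
        alpha=alpha,
        scan_before=scan_before,
        scan_after=scan_after,
        audit=audit,
    )
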