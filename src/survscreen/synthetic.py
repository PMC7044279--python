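"""Synthetic AML-like survival cohorts with planted, fully known structure.

Each patient carries a latent disease-state level z ~ Uniform(0, 1) which
drives (i) the expression of one planted biomarker probe, (ii) a
proportional-hazards survival disadvantage, (iii) the prevalence of binary
mutation-like confounders, and (iv) a co-expressed downstream gene module.
Everything else is noise.  The generator therefore reproduces the joint
structure the screening pipeline assumes — a prognostic transcript whose
low/high expresser subgroups differ in survival, are confounded with
mutation status, and carry a coherent downstream expression signature —
while every quantity the pipeline estimates has a recorded ground truth.

Survival is exponential with hazard ``baseline_hazard * exp(hazard_log_hr *
z)`` (an optional Weibull shape generalizes this) under independent
exponential censoring; event-free survival shares z but has its own noise
and a 1.3x baseline hazard.  The module effect size ``module_log2fc`` is
parameterized directly as the planted expression contrast between the
biomarker's high and low expresser subgroups: module genes are linear in z
and their slope is calibrated at generation time so the expected high-vs-low
group difference equals ``module_log2fc`` exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .io import ClinicalTable, ExpressionMatrix
from .subgroups import assign_subgroups, scale_probe

#: EFS events occur at this multiple of the OS baseline hazard
EFS_HAZARD_FACTOR = 1.3
BASELINE_MEAN = 7.0  # typical log2 array intensity
FAB_PREFIX = "M"


@dataclass
class SyntheticCohortSpec:
    """Full generative parameterization of a synthetic cohort."""

    n_patients: int = 200
    n_probes: int = 2000
    biomarker_beta: float = 3.0  # log2-units slope of the biomarker probe on z
    baseline_sd: float = 0.7  # per-probe Gaussian noise, log2 units
    hazard_log_hr: float = 1.1  # log hazard ratio per unit z
    baseline_hazard: float = 0.02  # events per month at z = 0
    censor_hazard: float = 0.01  # censoring events per month
    weibull_shape: float = 1.0
    module_size: int = 30
    module_log2fc: float = 2.0  # planted high-vs-low expression contrast
    confounders: list = field(
        default_factory=lambda: [("NPM1c_like", 0.15, 0.30), ("CEBPA_like", 0.12, -0.12)]
    )
    n_covariate_levels: int = 5  # survival-neutral FAB-like factor
    low_threshold: float = 0.3
    high_threshold: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_patients, self.n_probes) < 1 or self.module_size < 0:
            raise ValueError("counts must be positive")
        if self.n_probes < 1 + self.module_size:
            raise ValueError("n_probes must fit biomarker and module probes")
        if min(self.baseline_sd, self.baseline_hazard, self.censor_hazard) <= 0:
            raise ValueError("scale parameters must be positive")
        self.confounders = [tuple(c) for c in self.confounders]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticCohortSpec":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class CohortTruth:
    """Ground truth recorded at generation time."""

    spec: SyntheticCohortSpec
    z: pd.Series
    biomarker_probe: str
    module_probes: list[str]
    null_probes: list[str]
    module_slope: float
    sample_ids: list[str]

    def to_dict(self) -> dict:
        return {
            "spec": dataclasses.asdict(self.spec),
            "z": {k: float(v) for k, v in self.z.items()},
            "biomarker_probe": self.biomarker_probe,
            "module_probes": self.module_probes,
            "null_probes": self.null_probes,
            "module_slope": self.module_slope,
            "sample_ids": self.sample_ids,
        }


def _exponential_survival(rng, rate: np.ndarray, shape: float) -> np.ndarray:
    """Event times with hazard rate(z); Weibull shape 1 = exponential."""
    u = rng.uniform(size=rate.size)
    return (-np.log(u) / rate) ** (1.0 / shape)


def generate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[ExpressionMatrix, ClinicalTable, CohortTruth]:
    """Draw one cohort: expression matrix, clinical table, and ground truth.

    Probe layout: probe 0 is the planted biomarker, probes 1..module_size
    the downstream module, the rest pure noise.  The clinical table carries
    OS and EFS endpoints, age, sex, a survival-neutral FAB-like factor and
    the configured binary confounders whose prevalence rises (or falls)
    with z.
    """
    # independent named streams: each cohort component is reproducible on its
    # own, and e.g. the clinical realization does not change with n_probes
    root = np.random.SeedSequence(spec.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("latent", "baseline", "noise", "survival", "covariates"), root.spawn(5)
        )
    }
    n, p = spec.n_patients, spec.n_probes
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    probe_ids = [f"P{j + 1:05d}" for j in range(p)]

    z = streams["latent"].uniform(size=n)
    mu = streams["baseline"].normal(BASELINE_MEAN, 1.0, size=p)

    expr = mu[:, None] + streams["noise"].normal(0.0, spec.baseline_sd, size=(p, n))
    expr[0] += spec.biomarker_beta * z

    # calibrate the module slope so the expected high-vs-low contrast over the
    # biomarker's realized subgroups equals module_log2fc exactly
    biomarker = pd.Series(expr[0], index=sample_ids)
    scaled = scale_probe(biomarker)
    groups = assign_subgroups(
        scaled, spec.low_threshold, spec.high_threshold, min_group=1, probe_id=probe_ids[0]
    )
    z_ser = pd.Series(z, index=sample_ids)
    dz = float(z_ser.loc[groups.high_ids].mean() - z_ser.loc[groups.low_ids].mean())
    module_slope = spec.module_log2fc / dz if (spec.module_size and dz != 0) else 0.0
    if spec.module_size:
        expr[1 : 1 + spec.module_size] += module_slope * z[None, :]

    surv_rng = streams["survival"]
    hazard = spec.baseline_hazard * np.exp(spec.hazard_log_hr * z)
    os_event_t = _exponential_survival(surv_rng, hazard, spec.weibull_shape)
    os_censor_t = surv_rng.exponential(1.0 / spec.censor_hazard, size=n)
    efs_event_t = _exponential_survival(surv_rng, EFS_HAZARD_FACTOR * hazard, spec.weibull_shape)
    efs_censor_t = surv_rng.exponential(1.0 / spec.censor_hazard, size=n)

    clin = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    clin["os_time"] = np.minimum(os_event_t, os_censor_t)
    clin["os_event"] = (os_event_t <= os_censor_t).astype(int)
    clin["efs_time"] = np.minimum(efs_event_t, efs_censor_t)
    clin["efs_event"] = (efs_event_t <= efs_censor_t).astype(int)
    cov_rng = streams["covariates"]
    clin["age"] = np.clip(cov_rng.normal(52.0, 12.0, size=n), 18.0, 90.0).round(1)
    clin["sex"] = np.where(cov_rng.uniform(size=n) < 0.5, "M", "F")
    clin["FAB"] = [
        f"{FAB_PREFIX}{k}" for k in cov_rng.integers(0, spec.n_covariate_levels, size=n)
    ]
    for name, base, slope in spec.confounders:
        prob = np.clip(base + slope * z, 0.0, 1.0)
        if ((base + slope * z) != prob).any():
            import logging

            logging.getLogger(__name__).warning(
                "confounder %s: prevalence clipped to [0, 1]", name
            )
        clin[name] = np.where(cov_rng.uniform(size=n) < prob, "yes", "no")

    matrix = ExpressionMatrix(pd.DataFrame(expr, index=probe_ids, columns=sample_ids))
    clinical = ClinicalTable(clin)
    truth = CohortTruth(
        spec=spec,
        z=z_ser,
        biomarker_probe=probe_ids[0],
        module_probes=probe_ids[1 : 1 + spec.module_size],
        null_probes=probe_ids[1 + spec.module_size :],
        module_slope=module_slope,
        sample_ids=sample_ids,
    )
    return matrix, clinical, truth


def truth_report(
    truth: CohortTruth,
    screen_table: pd.DataFrame | None = None,
    de_up: list[str] | None = None,
    de_down: list[str] | None = None,
    de_records: pd.DataFrame | None = None,
    balance_report=None,
    gsea_result=None,
) -> dict:
    """Summarize how well each pipeline stage recovered the planted truth.

    Accepts whichever stage outputs are available; unavailable entries are
    simply absent from the summary.  All outputs must come from the cohort
    the truth record describes (checked via probe ids).
    """
    out: dict = {"biomarker_probe": truth.biomarker_probe, "module_size": len(truth.module_probes)}
    if screen_table is not None:
        if truth.biomarker_probe not in screen_table.index:
            raise ValueError("screen output does not match this cohort's probes")
        tested = screen_table[~screen_table["skipped"]]
        ranked = tested.sort_values("p_os", kind="stable")
        out["biomarker_rank"] = int(np.nonzero(ranked.index == truth.biomarker_probe)[0][0]) + 1
        out["biomarker_p_os"] = float(screen_table.loc[truth.biomarker_probe, "p_os"])
    module = set(truth.module_probes)
    if de_up is not None and de_down is not None:
        selected = set(de_up) | set(de_down)
        if selected and not (selected <= set(truth.sample_ids) | module | set(truth.null_probes) | {truth.biomarker_probe}):
            raise ValueError("DE gene list does not match this cohort's probes")
        hit = selected & module
        out["module_recall"] = len(hit) / len(module) if module else None
        out["module_precision"] = (
            len(hit) / len(selected - {truth.biomarker_probe}) if selected - {truth.biomarker_probe} else None
        )
    if de_records is not None and module:
        present = [g for g in truth.module_probes if g in de_records.index]
        out["module_log2fc_true"] = truth.spec.module_log2fc
        out["module_log2fc_estimated"] = float(de_records.loc[present, "log2fc"].mean())
    if balance_report is not None:
        out["balance_converged"] = bool(balance_report.converged)
        out["balance_p_min_after"] = float(balance_report.p_min_after)
    if gsea_result is not None:
        out["gsea_es"] = float(gsea_result.es)
        out["gsea_p_perm"] = float(gsea_result.p_perm)
    return out
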