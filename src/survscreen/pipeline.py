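"""End-to-end orchestration of the biomarker screen as one reproducible run.

Stages: genome-wide screen → hit selection → covariate balancing of the
designated probe's subgroups → post-balance survival re-test (rank-sum and
log-rank) → quantile normalization → moderated differential expression →
patient / gene clustering on the differential genes → gene-set enrichment.
Every stage's output is written under the run directory in the same format
the standalone entry points use, and a JSON manifest records the resolved
configuration, derived per-stage seeds, row counts and wall-clock times.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import balance as balance_mod
from . import diffexp, downstream
from .io import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    join_samples,
    read_clinical_table,
    read_expression_matrix,
    read_gmt,
)
from .screen import ScreenConfig, screen_all_probes, select_hits
from .subgroups import assign_subgroups, scale_probe
from .survival import km_estimate, logrank_test, ranksum_test

log = logging.getLogger(__name__)

#: fixed offsets deriving per-stage seeds from the run seed
STAGE_SEED_OFFSETS = {"balance": 101, "gsea": 202}


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    out_dir: str
    matrix_path: str | None = None
    clinical_path: str | None = None
    gmt_path: str | None = None
    probe: str | None = None  # designated biomarker; default = top screen hit
    low_threshold: float = 0.3
    high_threshold: float = 0.7
    min_group: int = 10
    test: str = "ranksum"
    alpha: float = 0.05
    require_both: bool = True
    allowlist: list | None = None
    balance_covariates: list | None = None
    balance_max_iter: int = 1000
    fc_cut: float = 1.0
    q_cut: float = 0.05
    n_perm: int = 1000
    seed: int = 0

    def validate_paths(self) -> None:
        for name in ("matrix_path", "clinical_path", "gmt_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage_seed(seed: int, stage: str) -> int:
    return (seed + STAGE_SEED_OFFSETS[stage]) % (2**31)


def run_pipeline(
    config: RunConfig,
    matrix: ExpressionMatrix | None = None,
    clinical: ClinicalTable | None = None,
    gene_sets: GeneSetCollection | None = None,
) -> dict:
    """Execute the full workflow; returns the manifest (also written to disk).

    Inputs may be passed in memory or read from the configured paths.  Any
    stage failure aborts with the stage name while earlier outputs remain on
    disk.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if matrix is None:
        if config.matrix_path is None:
            raise ValueError("no expression matrix given")
        matrix = read_expression_matrix(config.matrix_path)
    if clinical is None:
        if config.clinical_path is None:
            raise ValueError("no clinical table given")
        clinical = read_clinical_table(config.clinical_path)
    if gene_sets is None and config.gmt_path is not None:
        gene_sets = read_gmt(config.gmt_path)

    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        "stages": [],
        "seeds": {s: _stage_seed(config.seed, s) for s in STAGE_SEED_OFFSETS},
    }

    def stage(name):
        t0 = time.perf_counter()

        def done(**counts):
            manifest["stages"].append(
                {"name": name, "seconds": round(time.perf_counter() - t0, 3), **counts}
            )

        return done

    current = "screen"
    try:
        done = stage("screen")
        scfg = ScreenConfig(
            config.low_threshold, config.high_threshold, config.min_group, config.test, config.alpha
        )
        screen_res = screen_all_probes(matrix, clinical, scfg)
        screen_res.to_tsv(out / "screen.tsv")
        done(n_probes=int(len(screen_res.table)))

        current = "select_hits"
        done = stage("select_hits")
        hits = select_hits(screen_res, require_both=config.require_both, allowlist=config.allowlist)
        hits.to_csv(out / "hits.tsv", sep="\t", na_rep="NA")
        done(n_hits=int(len(hits)))
        probe = config.probe or (hits.index[0] if len(hits) else None)
        manifest["designated_probe"] = probe
        if probe is None:
            log.warning("no hits and no designated probe: stopping after the screen")
            manifest["status"] = "no_hits"
            _write_manifest(out, manifest)
            return manifest

        current = "balance"
        done = stage("balance")
        joined_m, joined_c, _ = join_samples(matrix, clinical)
        scaled = scale_probe(joined_m.probe(probe))
        groups = assign_subgroups(
            scaled, config.low_threshold, config.high_threshold, config.min_group, probe
        )
        report = balance_mod.rebalance(
            groups.low_ids,
            groups.high_ids,
            joined_c,
            alpha=config.alpha,
            seed=_stage_seed(config.seed, "balance"),
            max_iter=config.balance_max_iter,
            covariates=config.balance_covariates,
        )
        (out / "balance.json").write_text(json.dumps(report.to_dict(), indent=2))
        done(n_low=len(report.low_ids), n_high=len(report.high_ids), converged=report.converged)

        current = "survival_retest"
        done = stage("survival_retest")
        retest = {}
        for endpoint in ["os"] + (["efs"] if joined_c.has_efs else []):
            t_lo, e_lo = joined_c.survival(report.low_ids, endpoint)
            t_hi, e_hi = joined_c.survival(report.high_ids, endpoint)
            rs = ranksum_test(t_lo, t_hi)
            lr = logrank_test(t_lo, e_lo, t_hi, e_hi)
            retest[endpoint] = {
                "p_ranksum": rs.p_value,
                "p_logrank": lr.p_value,
                "median_low": km_estimate(t_lo, e_lo).median,
                "median_high": km_estimate(t_hi, e_hi).median,
                "n_low": len(report.low_ids),
                "n_high": len(report.high_ids),
            }
        (out / "survival_retest.json").write_text(json.dumps(retest, indent=2))
        manifest["survival_retest"] = retest
        done()

        current = "diffexp"
        done = stage("diffexp")
        norm = diffexp.quantile_normalize(joined_m)
        de = diffexp.moderated_t_test(norm, report.low_ids, report.high_ids)
        de.to_csv(out / "diffexp.tsv", sep="\t", na_rep="NA")
        up, down = diffexp.select_de_genes(de, config.fc_cut, config.q_cut)
        (out / "de_up.txt").write_text("\n".join(up) + ("\n" if up else ""))
        (out / "de_down.txt").write_text("\n".join(down) + ("\n" if down else ""))
        done(n_up=len(up), n_down=len(down))

        current = "clustering"
        done = stage("clustering")
        de_genes = up + down
        if len(de_genes) >= 2:
            sub = norm.restrict_probes(de_genes).restrict_samples(
                report.low_ids + report.high_ids
            )
            dendro, corr = downstream.patient_cluster(sub)
            (out / "patients.nwk").write_text(dendro.to_newick() + "\n")
            corr.to_csv(out / "patient_correlation.tsv", sep="\t")
            gene_dendro = downstream.gene_zscore_cluster(sub)
            (out / "genes.nwk").write_text(gene_dendro.to_newick() + "\n")
        done(n_de_genes=len(de_genes))

        current = "gsea"
        done = stage("gsea")
        gsea_out = []
        if gene_sets is not None:
            for name, members in gene_sets.sets.items():
                res = downstream.gsea_permutation_p(
                    joined_m,
                    report.low_ids,
                    report.high_ids,
                    members,
                    set_name=name,
                    n_perm=config.n_perm,
                    seed=_stage_seed(config.seed, "gsea"),
                )
                gsea_out.append(res.to_dict())
            (out / "gsea.json").write_text(json.dumps(gsea_out, indent=2))
        manifest["gsea"] = gsea_out
        done(n_sets=len(gsea_out))
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = current
        _write_manifest(out, manifest)
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    manifest["status"] = "ok"
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
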