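"""End-to-end pipeline: cohort -> filter -> normalize -> graph -> gLPCA ->
mixed model -> report, with plain-file stage outputs and a run manifest.

Configuration is a YAML mapping with either an ``inputs`` block (paths to a
cohort table and a raw volume table) or a ``synthetic`` block (cohort and
truth parameter overrides), plus optional ``graph``, ``glpca``, ``model``
sections. Every random draw derives from the single top-level ``seed``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_stats import filter_cohort, genotype_table, pearson_chi2, summary_table
from .glpca import component_correlations, fit_glpca, standardize
from .graph import build_correlation_graph, build_template_graph, laplacian, write_edge_list
from .lmm import ModelSpec, build_design, education_slope, fit_lmm, slope_dose_monotonicity
from .parcellation import default_scheme
from .simulate import (
    CohortConfig,
    TruthParams,
    generate_cohort,
    generate_outcome_and_volumes,
    write_sidecar,
)
from .volumes import normalize_to_tiv, read_volume_table

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "make_report"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    cohort_path: str | None = None
    volumes_path: str | None = None
    synthetic_cohort: CohortConfig | None = None
    synthetic_truth: TruthParams | None = None
    graph_mode: str = "template"  # or "correlation"
    tau: float = 0.5
    k: int = 1
    beta: float = 0.5
    beta_sweep: tuple = ()
    reml: bool = False
    output_dir: str = "runs/latest"

    def __post_init__(self) -> None:
        has_paths = self.cohort_path is not None or self.volumes_path is not None
        has_synth = self.synthetic_cohort is not None
        if has_paths == has_synth:
            raise ValueError("config must contain exactly one of input paths or a synthetic block")
        if has_paths and (self.cohort_path is None or self.volumes_path is None):
            raise ValueError("both cohort and volumes paths are required")
        if self.graph_mode not in ("template", "correlation"):
            raise ValueError(f"unknown graph mode {self.graph_mode!r}")


def load_config(path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    synth = raw.get("synthetic")
    cohort_cfg = truth = None
    if synth is not None:
        cohort_cfg = CohortConfig(**synth.get("cohort", {}))
        truth = TruthParams(**synth.get("truth", {}))
    inputs = raw.get("inputs", {})
    for key in ("cohort", "volumes"):
        p = inputs.get(key)
        if p is not None and not Path(p).exists():
            raise ValueError(f"configured input file does not exist: {p}")
    glpca_cfg = raw.get("glpca", {})
    return PipelineConfig(
        seed=int(raw.get("seed", 0)),
        cohort_path=inputs.get("cohort"),
        volumes_path=inputs.get("volumes"),
        synthetic_cohort=cohort_cfg,
        synthetic_truth=truth,
        graph_mode=raw.get("graph", {}).get("mode", "template"),
        tau=float(raw.get("graph", {}).get("tau", 0.5)),
        k=int(glpca_cfg.get("k", 1)),
        beta=float(glpca_cfg.get("beta", 0.5)),
        beta_sweep=tuple(glpca_cfg.get("beta_sweep", ())),
        reml=bool(raw.get("model", {}).get("reml", False)),
        output_dir=raw.get("output_dir", "runs/latest"),
    )


def _sha256_of(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")


def _fit_and_export(frame, spec, out_dir: Path, suffix: str = "") -> "tuple":
    fit = fit_lmm(frame, spec)
    fixed = fit.fixed_effects.copy()
    fixed.to_csv(out_dir / f"fixed_effects{suffix}.csv", index=False)
    meta = {
        "var_pedigree": fit.var_pedigree,
        "var_site": fit.var_site,
        "var_resid": fit.var_resid,
        "var_pedigree_se": fit.var_pedigree_se,
        "var_site_se": fit.var_site_se,
        "loglik": fit.loglik,
        "converged": fit.converged,
        "n_subjects": fit.n_subjects,
        "n_pedigrees": fit.n_pedigrees,
        "n_sites": fit.n_sites,
        "education_center": fit.education_center,
        "tmem_center": fit.tmem_center,
        "reml": fit.reml,
        "n_dropped": fit.n_dropped,
    }
    _write_json(out_dir / f"model_meta{suffix}.json", meta)
    return fit, fixed


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory. Idempotent given seed."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scheme = default_scheme()
    rng_seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2**31)

    stage = "ingest"
    try:
        if config.synthetic_cohort is not None:
            truth = config.synthetic_truth or TruthParams()
            cohort = generate_cohort(config.synthetic_cohort, seed=int(rng_seeds[0]))
            latent, volumes = generate_outcome_and_volumes(
                cohort, truth, scheme, seed=int(rng_seeds[1])
            )
            cohort.to_csv(out_dir / "cohort.csv", index=False)
            volumes.to_csv(out_dir / "volumes.csv", index=False)
            write_sidecar(out_dir / "synthetic_sidecar.json", config.synthetic_cohort, truth,
                          config.seed)
        else:
            cohort = pd.read_csv(config.cohort_path)
            volumes = read_volume_table(config.volumes_path, scheme)
            cohort.to_csv(out_dir / "cohort.csv", index=False)
            volumes.to_csv(out_dir / "volumes.csv", index=False)
        log.info("stage %s: %d subjects in, %d volume rows", stage, len(cohort), len(volumes))

        stage = "filter"
        report, cohort = filter_cohort(cohort)
        report.to_frame().to_csv(out_dir / "filter_report.csv", index=False)
        volumes = volumes.loc[volumes["subject_id"].isin(cohort["subject_id"])]
        log.info("stage %s: %d -> %d subjects", stage, report.n_initial, report.n_final)

        stage = "normalize"
        normalized = normalize_to_tiv(volumes, scheme)
        normalized.to_csv(out_dir / "normalized_volumes.csv", index=False)

        stage = "graph"
        if config.graph_mode == "template":
            graph = build_template_graph(scheme)
        else:
            graph = build_correlation_graph(normalized, scheme, tau=config.tau)
        write_edge_list(graph, out_dir / "graph_edges.tsv")
        L = laplacian(graph)
        log.info("stage %s: %d nodes, %d edges", stage, len(graph.nodes), graph.n_edges)

        stage = "glpca"
        data = standardize(normalized, scheme.names)
        model = fit_glpca(data, L, k=config.k, beta=config.beta)
        _write_json(out_dir / "glpca_model.json", model.to_dict())
        scores = model.scores_frame()
        scores.to_csv(out_dir / "pc_scores.csv", index=False)
        correlations = component_correlations(model, data)
        correlations.to_csv(out_dir / "pc_correlations.csv", index=False)

        stage = "mixed_model"
        frame = cohort.merge(scores[["subject_id", "pc1"]], on="subject_id")
        spec = ModelSpec(outcome="pc1", reml=config.reml)
        fit, _ = _fit_and_export(build_design(frame, spec), spec, out_dir)
        for b in config.beta_sweep:
            sweep_model = fit_glpca(data, L, k=config.k, beta=float(b))
            sweep_scores = sweep_model.scores_frame()
            sweep_frame = cohort.merge(sweep_scores[["subject_id", "pc1"]], on="subject_id")
            _fit_and_export(build_design(sweep_frame, spec), spec, out_dir,
                            suffix=f"_beta{b:g}".replace(".", "p"))

        stage = "slopes"
        slope_rows = []
        for gs in (0, 1):
            dose = slope_dose_monotonicity(fit, gs=gs)
            for _, r in dose.iterrows():
                slope_rows.append(
                    {"gs": gs, "genotype": r["genotype"], "t_alleles": int(r["t_alleles"]),
                     "slope": r["slope"], "verdict": dose.attrs["verdict"]}
                )
        pd.DataFrame(slope_rows).to_csv(out_dir / "education_slopes.csv", index=False)

        stage = "summary"
        summary_table(cohort).to_csv(out_dir / "cohort_summary.csv", index=False)

        stage = "report"
        make_report(out_dir)

        stage = "manifest"
        artifacts = sorted(
            p.name for p in out_dir.iterdir() if p.is_file() and p.name != "manifest.json"
        )
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "artifacts": {name: _sha256_of(out_dir / name) for name in artifacts},
        }
        _write_json(out_dir / "manifest.json", manifest)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return out_dir


def make_report(run_dir) -> str:
    """One-page human-readable summary, regenerated deterministically from the
    stage artifacts. Returns the text and writes ``report.txt``."""
    run_dir = Path(run_dir)
    needed = ["cohort.csv" , "fixed_effects.csv", "education_slopes.csv",
              "pc_correlations.csv", "model_meta.json"]
    missing = [n for n in needed if not (run_dir / n).exists()]
    if missing:
        raise PipelineError(f"run directory {run_dir} is missing artifacts: {', '.join(missing)}")

    cohort = pd.read_csv(run_dir / "cohort.csv")
    _, retained = filter_cohort(cohort) if {"has_mri", "has_genotype"} <= set(cohort.columns) else (None, cohort)
    fixed = pd.read_csv(run_dir / "fixed_effects.csv")
    slopes = pd.read_csv(run_dir / "education_slopes.csv")
    correlations = pd.read_csv(run_dir / "pc_correlations.csv")
    meta = json.loads((run_dir / "model_meta.json").read_text())

    lines = ["Grey-matter composite interaction analysis", "=" * 43, ""]
    n1 = int((retained["gs"] == 1).sum())
    n0 = int((retained["gs"] == 0).sum())
    lines.append(f"Subjects analysed: {len(retained)} (carriers {n1}, non-carriers {n0})")
    geno = genotype_table(retained)
    chi2 = pearson_chi2(geno)
    lines.append(
        f"TMEM106B genotype by carrier status: chi2={chi2.statistic:.3f}, "
        f"df={chi2.df}, p={chi2.p:.3f}"
    )
    lines.append("")
    top = correlations.loc[correlations["component"] == 1].nsmallest(5, "abs_rank")
    lines.append("Measures most correlated with PC1:")
    for _, r in top.iterrows():
        lines.append(f"  {r['measure']:<16s} r = {r['r']:+.3f}")
    lines.append("")
    lines.append("Fixed effects (estimate, SE, z, p):")
    for _, r in fixed.iterrows():
        lines.append(
            f"  {r['term']:<28s} {r['estimate']:+.4f}  {r['se']:.4f}  "
            f"{r['z']:+.3f}  {r['p']:.4f}"
        )
    lines.append(
        f"Random-intercept variances: pedigree {meta['var_pedigree']:.4f} "
        f"({meta['n_pedigrees']} families), site {meta['var_site']:.4f} "
        f"({meta['n_sites']} sites); residual {meta['var_resid']:.4f}"
    )
    lines.append("")
    lines.append("Education slopes by genotype (composite units per year):")
    for gs in (0, 1):
        sub = slopes.loc[slopes["gs"] == gs]
        verdict = sub["verdict"].iloc[0]
        vals = ", ".join(f"{r['genotype']} {r['slope']:+.4f}" for _, r in sub.iterrows())
        lines.append(f"  GS={gs}: {vals}  [dose ordering: {verdict}]")
    text = "\n".join(lines) + "\n"
    (run_dir / "report.txt").write_text(text)
    return text
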