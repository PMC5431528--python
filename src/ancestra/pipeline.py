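"""End-to-end orchestration: simulate -> QC -> fit -> call -> stats -> report.

``run_full_analysis`` drives the whole synthetic-to-report flow with one
global seed fanned out deterministically per stage, writing every stage's
output plus a single JSON report.  Stages mirror the analysis order of the
underlying study: quality control, unsupervised clustering with K selection,
bootstrap ancestry calling, F_ST and stability statistics, migration-graph
inference, language correlations, and the power analysis.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import admixture, calls, fst, language, migration, synthgen
from ._util import child_seed
from .genotype_io import qc_filter, write_genotypes

__all__ = ["PipelineConfig", "run_full_analysis"]


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML."""

    K_true: int = 5
    m: int = 3000
    n_per_sample: int = 25
    samples_per_ancestry: int = 2
    drift: float = 0.08
    concentration: float = 0.2
    migrations: list[tuple[str, str, float]] = field(default_factory=list)
    missing_rate: float = 0.002
    replacement_rate: float = 0.0
    K_min: int = 2
    K_max: int = 7
    folds: int = 5
    cv_replicates: int = 3
    mode_runs: int = 0
    B: int = 100
    m_max: int = 2
    n_orders: int = 10
    root: str = "A1"
    Ne: float = 20000.0
    gen_years: tuple[float, float] = (25.0, 30.0)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        if cfg.K_min > cfg.K_max:
            raise ValueError("empty K range")
        return cfg


def _simulate(cfg: PipelineConfig):
    model = synthgen.simulate_frequency_tree(
        cfg.K_true, cfg.m, drift=cfg.drift, seed=child_seed(cfg.seed, "tree")
    )
    for src, tgt, w in cfg.migrations:
        model = synthgen.plant_migration(model, src, tgt, w)
    samples = []
    for k in range(cfg.K_true):
        for s in range(cfg.samples_per_ancestry):
            alpha = np.full(cfg.K_true, cfg.concentration / max(cfg.K_true - 1, 1))
            alpha[k] = 2.0
            samples.append((f"S{k + 1}_{s + 1}", cfg.n_per_sample, alpha))
    G, truth = synthgen.simulate_admixed_genotypes(
        model, samples, missing_rate=cfg.missing_rate,
        seed=child_seed(cfg.seed, "genotypes"),
    )
    synthgen.simulate_language_labels(
        truth, replacement_rate=cfg.replacement_rate,
        seed=child_seed(cfg.seed, "language"),
    )
    return G, truth


def run_full_analysis(cfg: PipelineConfig, outdir, log=print) -> dict:
    """Run every stage and write a JSON report; deterministic given cfg.seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: v for k, v in vars(cfg).items()}, "stages": {}}
    t0 = time.time()

    def stage(name):
        log(f"[{time.time() - t0:7.1f}s] {name}")

    # 1. synthesize + QC
    stage("simulate")
    G, truth = _simulate(cfg)
    truth.write(outdir / "truth")
    write_genotypes(G, outdir / "genotypes.tsv")
    stage("qc")
    G = qc_filter(G, log=log)
    report["stages"]["qc"] = {"individuals": G.n_individuals, "markers": G.n_markers}

    # 2. K selection by cross-validated clustering
    stage("cross-validation")
    cv = admixture.CVTable()
    for rep in range(cfg.cv_replicates):
        for K in range(cfg.K_min, cfg.K_max + 1):
            err = admixture.cross_validation_error(
                G, K, folds=cfg.folds, seed=child_seed(cfg.seed, f"cv-{rep}-{K}")
            )
            cv.add(K, rep, err)
    cv.write(outdir / "cv.tsv")
    mode_cv = cv
    if cfg.mode_runs:
        mode_cv = admixture.CVTable()
        for run in range(cfg.mode_runs):
            for K in range(cfg.K_min, cfg.K_max + 1):
                err = admixture.cross_validation_error(
                    G, K, folds=cfg.folds, seed=child_seed(cfg.seed, f"mode-{run}-{K}")
                )
                mode_cv.add(K, run, err)
    K_mean, K_mode, hpd = admixture.select_K(cv, mode_cv)
    if K_mean in (cfg.K_min, cfg.K_max):
        log(f"warning: CV minimum at K-range boundary ({K_mean})")
        report["stages"]["cv_boundary_minimum"] = True
    report["stages"]["K_selection"] = {
        "posterior_mean": K_mean, "posterior_mode": K_mode, "hpd": list(hpd),
    }

    # 3. reference fit + bootstrap calling
    stage(f"fit K={K_mean}")
    ref = admixture.fit_admixture(G, K_mean, seed=child_seed(cfg.seed, "ref-fit"))
    ref.write(outdir / "fit")
    stage(f"bootstrap B={cfg.B}")
    ens = ref.bootstrap(B=cfg.B, seed=child_seed(cfg.seed, "bootstrap"))
    called = calls.call_ancestry(ens, truth.sample_map)
    called.write(outdir / "called")
    mix = calls.mixed_ancestry_stats(called)
    report["stages"]["mixed_ancestry"] = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in mix.items()
        if not isinstance(v, np.ndarray)
    }
    exemplars = calls.designate_exemplars(called.sample_props, log=log)
    report["stages"]["exemplars"] = exemplars

    # 4. F_ST and stability
    stage("fst")
    fst_mat = ref.component_fst()
    fst_mat.write(outdir / "component_fst.tsv")
    true_fst = fst.component_fst(truth.model.ancestral_freqs, truth.model.ancestry_labels)
    if fst_mat.values.shape == true_fst.values.shape:
        perm = admixture.align_components(truth.model.ancestral_freqs, ref.F)
        aligned = fst.FstMatrix(
            true_fst.labels, fst_mat.values[np.ix_(perm, perm)], "component"
        )
        med, ci = fst.compare_fst_matrices(true_fst, aligned)
        r, p_bounds, p_perm = fst.mantel_test(
            true_fst, aligned, n_perm=999, seed=child_seed(cfg.seed, "mantel")
        )
        report["stages"]["fst_stability"] = {
            "median_difference": med, "difference_ci": list(ci),
            "mantel_r": r, "mantel_p_bounds": list(p_bounds), "mantel_p_perm": p_perm,
        }

    # 5. migration graph
    stage("migration graph")
    counts = migration.ancestry_allele_counts(
        ref.Q, ref.F, labels=[f"comp{k + 1}" for k in range(ref.K)]
    )
    counts.write(outdir / "treemix_input.txt.gz")
    graph_model = migration.MigrationGraphModel(counts)
    if cfg.root in truth.model.ancestry_labels and ref.K == truth.model.K:
        # root on the fitted component aligned to the requested true ancestry
        perm = admixture.align_components(truth.model.ancestral_freqs, ref.F)
        root = f"comp{1 + perm[truth.model.ancestry_labels.index(cfg.root)]}"
    else:
        root = graph_model.labels[0]
    results_by_m, chosen_m = graph_model.fit_range(
        m_max=cfg.m_max, root_label=root, n_orders=cfg.n_orders,
        seed=child_seed(cfg.seed, "migration"),
    )
    best = results_by_m[chosen_m]["best"]
    best.write(outdir / "migration_graph")
    boots = migration.bootstrap_trees(
        counts, root, n_boot=min(100, 25), seed=child_seed(cfg.seed, "tree-boot")
    )
    cons = migration.consensus_tree(boots)
    report["stages"]["migration"] = {
        "chosen_m": chosen_m,
        "loglik_by_m": [r["best"].loglik for r in results_by_m],
        "edges": [
            {"source": list(s), "target": list(t), "w": w}
            for s, t, w in best.migration_edges
        ],
        "consensus_support": {"+".join(k): v for k, v in cons.support.items()},
    }

    # 6. language correlations
    stage("language battery")
    if truth.language_map:
        ann = language.LanguageAnnotation.from_map(truth.language_map)
        hyps = [
            (comp, {fam})
            for comp in called.sample_props.columns
            for fam in sorted(set(truth.language_map.values()))
        ]
        batt = language.run_hypothesis_battery(called.sample_props, ann, hyps)
        language.battery_frame(batt).to_csv(outdir / "language_battery.tsv",
                                            sep="\t", index=False)
        ok = [c for c in batt if c.error is None]
        report["stages"]["language"] = {
            "n_hypotheses": len(batt),
            "best_r": max((c.r for c in ok), default=float("nan")),
        }

    # 7. power analysis
    stage("power")
    power = fst.power_analysis(ref.Q, G.n_markers, Ne=cfg.Ne, gen_years=cfg.gen_years)
    power.to_json(outdir / "power.json")
    report["stages"]["power"] = json.loads(power.to_json())

    report["elapsed_seconds"] = round(time.time() - t0, 2)
    with open(outdir / "report.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    _write_markdown(report, outdir / "report.md")
    return report


def _write_markdown(report: dict, path) -> None:
    lines = ["# Ancestry analysis report", ""]
    for name, stage in report["stages"].items():
        lines.append(f"## {name}")
        lines.append("```json")
        lines.append(json.dumps(stage, indent=2, sort_keys=True, default=str))
        lines.append("```")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")
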