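"""Run configuration, orchestration and the run manifest.

A run is driven by a plain-text key-value (YAML) config naming the stages
to execute, the input paths and the thresholds. Identical config + inputs
+ seed produce byte-identical outputs; the manifest records the tool
version, a config echo, input checksums and per-stage row counts, which is
enough to reproduce a run.
"""
from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__, cross, enrich, io, screen, simulate
from .errors import ConfigurationError

log = logging.getLogger(__name__)

STAGES = ("simulate", "crossqtl", "concord", "enrich")


@dataclass
class RunConfig:
    stages: list[str]
    out_dir: Path
    seed: int = 0
    # stage inputs (paths; produced by the simulate stage when absent)
    phenotypes: Optional[Path] = None
    vcf: Optional[Path] = None
    sample_panel: Optional[Path] = None
    genome: Optional[Path] = None
    expression: Optional[Path] = None
    groups: Optional[Path] = None
    gene_sets: Optional[Path] = None
    # analysis parameters
    alpha: float = 0.05
    n_perm: int = 10_000
    pseudocount: float = 1.0
    expression_floor: float = 1.0
    thresholds: screen.FilterThresholds = field(default_factory=screen.FilterThresholds)
    recombinant_spec: Optional[cross.RecombinantSpec] = None
    simulate_params: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path, out_dir: str | Path, seed: int | None = None):
        cfg = io.read_config(path)
        stages = cfg.get("stages", list(STAGES))
        bad = [s for s in stages if s not in STAGES]
        if bad:
            raise ConfigurationError(f"unknown stage(s) {bad}; valid: {STAGES}")
        thr = screen.FilterThresholds(**cfg.get("thresholds", {}))
        rspec = None
        if "recombinant_spec" in cfg:
            rs = cfg["recombinant_spec"]
            rspec = cross.RecombinantSpec(
                left_marker=rs["left_marker"],
                right_marker=rs["right_marker"],
                recombinant_haplotypes=frozenset(
                    tuple(h) for h in rs.get("recombinant_haplotypes", [["M", "B"]])
                ),
            )
        paths = {}
        for key in ("phenotypes", "vcf", "sample_panel", "genome", "expression",
                    "groups", "gene_sets"):
            if cfg.get(key):
                p = Path(cfg[key])
                if not p.exists():
                    raise ConfigurationError(f"configured path does not exist: {p}")
                paths[key] = p
        return cls(
            stages=stages,
            out_dir=Path(out_dir),
            seed=int(cfg.get("seed", 0) if seed is None else seed),
            alpha=float(cfg.get("alpha", 0.05)),
            n_perm=int(cfg.get("n_perm", 10_000)),
            pseudocount=float(cfg.get("pseudocount", 1.0)),
            expression_floor=float(cfg.get("expression_floor", 1.0)),
            thresholds=thr,
            recombinant_spec=rspec,
            simulate_params=cfg.get("simulate", {}),
            **paths,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _rel(path: Path, out_dir: Path) -> str:
    """Paths under the output directory are recorded relative to it, so a rerun
    into a different directory yields a byte-identical manifest."""
    try:
        return str(Path(path).relative_to(out_dir))
    except ValueError:
        return str(path)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages in dependency order; returns the manifest."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "stickleqtl",
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "inputs": {},
        "counts": {},
        "warnings": [],
        "outputs": {},
    }
    for key in ("phenotypes", "vcf", "sample_panel", "genome", "expression",
                "groups", "gene_sets"):
        p = getattr(config, key)
        if p is not None:
            manifest["inputs"][key] = {"path": _rel(p, out), "sha256": _sha256(Path(p))}

    try:
        if "simulate" in config.stages:
            _stage_simulate(config, manifest)
        if "crossqtl" in config.stages:
            _stage_crossqtl(config, manifest)
        if "concord" in config.stages:
            _stage_concord(config, manifest)
        if "enrich" in config.stages:
            _stage_enrich(config, manifest)
    except Exception as e:  # partial outputs retained, failure flagged
        manifest["failed"] = f"{type(e).__name__}: {e}"
        io.write_json(manifest, out / "run_manifest.json")
        raise
    io.write_json(manifest, out / "run_manifest.json")
    return manifest


def _stage_simulate(config: RunConfig, manifest: dict) -> None:
    out = config.out_dir
    sp = dict(config.simulate_params)
    kinds = sp.pop("kinds", ["cross", "panel", "expression"])
    if "cross" in kinds:
        params = simulate.CrossSimParams(**sp.get("cross", {}), seed=config.seed)
        fish = simulate.simulate_cross(params)
        io.write_phenotypes(fish, out / "phenotypes.tsv")
        if config.phenotypes is None:
            config.phenotypes = out / "phenotypes.tsv"
        manifest["counts"]["simulated_fish"] = len(fish)
    if "panel" in kinds:
        params = simulate.VariantPanelParams(**sp.get("panel", {}), seed=config.seed)
        variants, panel, genome, truth = simulate.simulate_variant_panel(params)
        io.write_vcf(variants, panel.samples, out / "panel.vcf",
                     contig_lengths={params.chrom: params.genome_bp})
        io.write_sample_panel(panel, out / "samples.tsv")
        io.write_fasta(genome, out / "genome.fa")
        io.write_json(truth, out / "panel_truth.json")
        config.vcf = config.vcf or out / "panel.vcf"
        config.sample_panel = config.sample_panel or out / "samples.tsv"
        config.genome = config.genome or out / "genome.fa"
        manifest["counts"]["simulated_variants"] = len(variants)
    if "expression" in kinds:
        ep = sp.get("expression", {})
        if "sets" in ep:
            ep = dict(ep)
            ep["sets"] = [tuple(s) for s in ep["sets"]]
        params = simulate.ExprSimParams(**ep, seed=config.seed)
        expr, groups, sets, truth = simulate.simulate_expression(params)
        io.write_expression(expr, out / "expression.tsv")
        io.write_groups(groups, out / "groups.tsv")
        io.write_gmt(sets, out / "sets.gmt")
        io.write_json(truth, out / "expression_truth.json")
        config.expression = config.expression or out / "expression.tsv"
        config.groups = config.groups or out / "groups.tsv"
        config.gene_sets = config.gene_sets or out / "sets.gmt"
        manifest["counts"]["simulated_genes"] = len(expr)


def _stage_crossqtl(config: RunConfig, manifest: dict) -> None:
    if config.phenotypes is None:
        raise ConfigurationError("crossqtl stage needs a phenotype table")
    out = config.out_dir
    fish = io.read_phenotypes(config.phenotypes)
    corrected = cross.size_correct(fish, alpha=config.alpha)
    manifest["warnings"].extend(corrected.warnings)
    pd.DataFrame(
        {"fish_id": corrected.corrected.index, "corrected_tooth_total": corrected.corrected.values}
    ).to_csv(out / "corrected_phenotypes.tsv", sep="\t", index=False)

    results: dict = {
        "covariates_used": corrected.covariates_used,
        "reference_length": corrected.reference_length,
    }
    spec = config.recombinant_spec
    if spec is not None and spec.left_marker in fish.columns:
        classes, excluded = cross.assign_genotype_class(fish, spec)
        if len(excluded):
            manifest["warnings"].append(f"{len(excluded)} fish excluded from class assignment")
        corr = corrected.corrected.loc[classes.index]
        lrt = cross.recombinant_direction_lrt(corr, classes, alpha=config.alpha)
        results["direction_lrt"] = {
            "statistic": lrt.statistic,
            "df": lrt.df,
            "p_value": lrt.p_value,
            "supported_direction": lrt.supported_direction,
            **lrt.details,
        }
        nonrec = classes[classes.isin(["MM", "MB", "BB"])]
        if nonrec.nunique() >= 2:
            an = cross.genotype_anova(corr.loc[nonrec.index], nonrec)
            results["anova"] = an.__dict__
        manifest["counts"]["fish_classified"] = len(classes)
    elif "genotype_class" in fish.columns:
        classes = pd.Series(fish["genotype_class"].values, index=fish["fish_id"])
        lrt = cross.recombinant_direction_lrt(corrected.corrected, classes, alpha=config.alpha) \
            if any("R" in c for c in classes) else None
        if lrt is not None:
            results["direction_lrt"] = {
                "statistic": lrt.statistic,
                "df": lrt.df,
                "p_value": lrt.p_value,
                "supported_direction": lrt.supported_direction,
                **lrt.details,
            }
        else:
            an = cross.genotype_anova(corrected.corrected, classes)
            results["anova"] = an.__dict__
    io.write_json(results, out / "cross_results.json")
    manifest["counts"]["fish_phenotyped"] = len(fish)
    manifest["outputs"]["cross_results"] = _rel(out / "cross_results.json", out)


def _stage_concord(config: RunConfig, manifest: dict) -> None:
    if config.vcf is None or config.sample_panel is None:
        raise ConfigurationError("concord stage needs a VCF and a sample manifest")
    out = config.out_dir
    variants = io.read_vcf(config.vcf)
    panel = io.read_sample_panel(config.sample_panel)
    genome = io.read_fasta(config.genome) if config.genome else None
    res = screen.run_screen(variants, panel, genome, config.thresholds)
    io.write_vcf(res["retained"], panel.samples, out / "filtered.vcf")
    io.write_concordance(res["records"], out / "concordance.tsv")
    report = res["cluster"]
    io.write_json(
        {
            "count": report.count,
            "snp_count": report.snp_count,
            "indel_count": report.indel_count,
            "min_pos": report.min_pos,
            "max_pos": report.max_pos,
            "span_bp": report.span_bp,
            "variants": [list(k) for k in report.variants],
            "filter_tally": dict(res["tally"]),
        },
        out / "cluster_report.json",
    )
    if report.count:
        io.write_cluster_bed(report, report.variants[0][0], out / "perfect_cluster.bed")
    manifest["counts"]["variants_in"] = len(variants)
    manifest["counts"]["variants_retained"] = len(res["retained"])
    manifest["counts"]["perfect_variants"] = report.count
    manifest["outputs"]["cluster_report"] = _rel(out / "cluster_report.json", out)


def _stage_enrich(config: RunConfig, manifest: dict) -> None:
    if config.expression is None or config.groups is None or config.gene_sets is None:
        raise ConfigurationError("enrich stage needs expression, groups and gene sets")
    out = config.out_dir
    expr = io.read_expression(config.expression)
    groups = io.read_groups(config.groups)
    sets = io.read_gmt(config.gene_sets)
    zs = enrich.per_gene_z(expr, groups, pseudocount=config.pseudocount,
                           expression_floor=config.expression_floor)
    zs.z.rename_axis("gene_id").reset_index().to_csv(out / "gene_z.tsv", sep="\t", index=False)
    results = enrich.evaluate_gene_sets(
        expr, sets, groups, n_perm=config.n_perm, seed=config.seed,
        alpha=config.alpha, pseudocount=config.pseudocount,
        expression_floor=config.expression_floor,
    )
    enrich.results_frame(results).to_csv(out / "set_results.tsv", sep="\t", index=False, na_rep="NA")
    io.write_json(
        {"seed": config.seed, "n_perm": config.n_perm, "n_sets": len(sets),
         "pseudocount": config.pseudocount, "expression_floor": config.expression_floor},
        out / "enrich_manifest.json",
    )
    manifest["counts"]["genes_scored"] = len(zs.z)
    manifest["counts"]["sets_tested"] = len(sets)
    manifest["counts"]["sets_significant"] = sum(r.significant for r in results)
    manifest["outputs"]["set_results"] = _rel(out / "set_results.tsv", out)
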