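"""End-to-end orchestration: config, staged analysis, serialization, report.

The pipeline mirrors the analysis order of a cis-regulation study: per
dataset, standardize expression, drop intron probes, measure probe
correlation, choose a representative probe set, average it into a composite
signal; LD-prune the variant panel and run forward-entry selection of the
composite on the pruned candidates; then exchange best models across
datasets (cross-check grid), evaluate functional-polymorphism-only models,
phase tag variants, and relate haplotype dosages to expression and to the
best models.  Every stage writes TSV/JSON artifacts plus a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association_analysis import (
    HaplotypeAssociation,
    allele_association,
    associations_to_tsv,
    haplotype_association,
    model_haplotype_r2,
)
from .expression_core import (
    CompositeSignal,
    ExpressionDataset,
    combine_composites,
    filter_intron_probes,
    make_composite,
    probe_r2_matrix,
    read_expression_tsv,
    read_probe_meta_tsv,
    select_representative_group,
    standardize,
    write_expression_tsv,
)
from .genetics_core import (
    GenotypeMatrix,
    HaplotypeSet,
    em_phase,
    haplotype_dosage,
    prune_by_ld,
    read_genotypes,
    write_genotypes_tsv,
    write_genotypes_vcf,
    write_haplotypes_tsv,
)
from .model_selection import (
    CrossCheckGrid,
    SelectionTrace,
    cross_check,
    forward_select,
    functional_panel_models,
    render_best_models_table,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid analysis configuration."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class DatasetConfig:
    name: str
    expression: str
    genotypes: str
    genotype_format: str = "tsv"  # tsv | vcf
    probe_annotation: str | None = None
    # representative-signal rule: {"method": "group"} (default), or
    # {"method": "target", "target": <label>}, or
    # {"method": "correlate", "with": <dataset>, "min_r2": <float>}, or
    # {"method": "probes", "probes": [...]}
    representative: dict = field(default_factory=lambda: {"method": "group"})


@dataclass
class AnalysisConfig:
    datasets: list[DatasetConfig]
    ld_prune_threshold: float = 0.90
    alpha_entry: float = 0.05
    alpha_stay: float = 0.05
    min_mean_r2: float = 0.5
    functional_ids: list[str] = field(default_factory=list)
    tag_ids: list[str] = field(default_factory=list)
    haplotype_table: str | None = None  # TSV: hap_id + allele per tag column
    report_alleles: list[str] = field(default_factory=list)
    combine: dict | None = None  # {"name": ..., "members": [...]}
    allow_partial: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ConfigError("at least one dataset required")
        for thr, label in (
            (self.ld_prune_threshold, "ld_prune_threshold"),
            (self.alpha_entry, "alpha_entry"),
            (self.alpha_stay, "alpha_stay"),
            (self.min_mean_r2, "min_mean_r2"),
        ):
            if not (0.0 < thr <= 1.0):
                raise ConfigError(f"{label} must be in (0, 1], got {thr}")
        names = [d.name for d in self.datasets]
        if len(set(names)) != len(names):
            raise ConfigError("dataset names must be unique")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            datasets = [DatasetConfig(**d) for d in raw.pop("datasets")]
            return cls(datasets=datasets, **raw)
        except TypeError as exc:
            raise ConfigError(f"bad config structure: {exc}") from exc

    def to_dict(self) -> dict:
        out = {k: v for k, v in self.__dict__.items() if k != "datasets"}
        out["datasets"] = [dict(d.__dict__) for d in self.datasets]
        return out

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def read_haplotype_table(path) -> tuple[list[str], dict[tuple[int, ...], str]]:
    """Haplotype definition TSV: hap_id column + one 0/1 column per tag."""
    df = pd.read_csv(path, sep="\t", index_col="hap_id")
    tags = list(df.columns)
    name_map = {tuple(int(a) for a in row): hid for hid, row in df.iterrows()}
    return tags, name_map


# ---------------------------------------------------------------------------
# Result bundle
# ---------------------------------------------------------------------------

@dataclass
class DatasetResult:
    name: str
    expression: ExpressionDataset  # standardized, intron-filtered
    genotypes: GenotypeMatrix
    composite: CompositeSignal
    probe_r2: pd.DataFrame | None
    representative_probes: list[str]
    pruned_ids: list[str]
    prune_report: pd.DataFrame
    trace: SelectionTrace
    haplotypes: HaplotypeSet | None = None
    functional_table: pd.DataFrame | None = None


@dataclass
class ResultBundle:
    config: AnalysisConfig
    results: dict[str, DatasetResult]
    grid: CrossCheckGrid | None
    combined_trace: SelectionTrace | None
    associations: list[HaplotypeAssociation]
    allele_associations: list[HaplotypeAssociation]
    model_hap_r2: pd.DataFrame
    manifest: dict


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def _stage(name: str, dataset: str):
    logger.info("[%s] %s", dataset, name)


def _select_representative(
    cfg: DatasetConfig,
    expr: ExpressionDataset,
    min_mean_r2: float,
    previous: dict[str, CompositeSignal],
) -> tuple[CompositeSignal, list[str], pd.DataFrame | None]:
    rule = dict(cfg.representative)
    method = rule.get("method", "group")
    r2 = probe_r2_matrix(expr) if expr.n_probes >= 2 else None

    if expr.n_probes == 1 or method == "probes":
        members = rule.get("probes", list(expr.probe_ids[:1]))
    elif method == "group":
        members, mean_r2, excluded = select_representative_group(r2, min_mean_r2)
        if not members:
            raise RuntimeError(
                f"dataset {cfg.name}: no probe group reaches mean r2 "
                f">= {min_mean_r2}"
            )
        logger.info(
            "[%s] representative group: %d of %d probes (mean r2 %.2f)",
            cfg.name, len(members), expr.n_probes, mean_r2,
        )
    elif method == "target":
        label = rule["target"]
        members = [
            p for p in expr.probe_ids if expr.probe_meta.loc[p, "target"] == label
        ]
        if not members:
            raise RuntimeError(f"dataset {cfg.name}: no probe targets {label!r}")
    elif method == "correlate":
        ref = previous[rule["with"]]
        min_r2 = float(rule.get("min_r2", 0.5))
        ref_series = ref.as_series()
        members = []
        for p in expr.probe_ids:
            s = pd.Series(expr.probe(p), index=expr.sample_ids)
            shared = s.index.intersection(ref_series.index)
            r = np.corrcoef(s.loc[shared], ref_series.loc[shared])[0, 1]
            if r * r >= min_r2:
                members.append(p)
        if not members:
            raise RuntimeError(
                f"dataset {cfg.name}: no probe correlates with {ref.name} "
                f"at r2 >= {min_r2}"
            )
    else:
        raise ConfigError(f"unknown representative method {method!r}")
    return make_composite(expr, members, cfg.name), members, r2


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: AnalysisConfig, outdir) -> ResultBundle:
    """Run the full staged analysis and write all artifacts under outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag_ids = list(config.tag_ids)
    name_map = None
    if config.haplotype_table:
        table_tags, name_map = read_haplotype_table(config.haplotype_table)
        if tag_ids and tag_ids != table_tags:
            raise ConfigError("tag_ids disagree with haplotype_table columns")
        tag_ids = table_tags

    results: dict[str, DatasetResult] = {}
    composites: dict[str, CompositeSignal] = {}

    for dcfg in config.datasets:
        name = dcfg.name
        _stage("read inputs", name)
        probe_meta = (
            read_probe_meta_tsv(dcfg.probe_annotation) if dcfg.probe_annotation else None
        )
        expr = read_expression_tsv(dcfg.expression, probe_meta=probe_meta)
        geno = read_genotypes(dcfg.genotypes, fmt=dcfg.genotype_format)

        _stage("standardize + intron filter", name)
        expr = filter_intron_probes(expr)
        expr = standardize(expr)

        _stage("representative signal", name)
        composite, members, r2 = _select_representative(
            dcfg, expr, config.min_mean_r2, composites
        )
        composites[name] = composite

        _stage("LD pruning", name)
        protected = [v for v in config.functional_ids if v in geno.variant_ids]
        pruned_ids, prune_report = prune_by_ld(
            geno, threshold=config.ld_prune_threshold, protected=protected
        )

        _stage("forward selection", name)
        g_cc = geno.subset_samples(composite.sample_ids)
        y = composite.as_series()
        trace = forward_select(
            y, g_cc, candidate_ids=pruned_ids,
            alpha_entry=config.alpha_entry, alpha_stay=config.alpha_stay,
            response_name=name,
        )
        logger.info("[%s] best model: %s (adj r2 %.2f)", name,
                    trace.selected or "(empty)", trace.final.adj_r2)

        hs = None
        if tag_ids:
            _stage("EM phasing", name)
            hs = em_phase(geno, tag_ids, name_map=name_map)

        results[name] = DatasetResult(
            name=name, expression=expr, genotypes=geno, composite=composite,
            probe_r2=r2, representative_probes=members, pruned_ids=pruned_ids,
            prune_report=prune_report, trace=trace, haplotypes=hs,
        )

    # combined composite (e.g. an average over same-collection studies)
    combined_trace = None
    if config.combine:
        cname = config.combine["name"]
        members = [composites[m] for m in config.combine["members"]]
        combined = combine_composites(members, cname, allow_partial=config.allow_partial)
        composites[cname] = combined
        ref = results[config.combine["members"][0]]
        g_cc = ref.genotypes.subset_samples(combined.sample_ids)
        combined_trace = forward_select(
            combined.as_series(), g_cc, candidate_ids=ref.pruned_ids,
            alpha_entry=config.alpha_entry, alpha_stay=config.alpha_stay,
            response_name=cname,
        )

    # cross-check grid over the per-dataset best models
    grid = None
    if len(results) >= 2:
        best_models = {n: r.trace.selected for n, r in results.items()}
        cc_datasets = {
            n: (
                r.composite.as_series()
                .reindex(r.composite.sample_ids)
                .to_numpy(dtype=float),
                r.genotypes.subset_samples(r.composite.sample_ids),
            )
            for n, r in results.items()
        }
        grid = cross_check(best_models, cc_datasets)

    # functional-polymorphism panels
    for n, r in results.items():
        panel = [v for v in config.functional_ids if v in r.genotypes.variant_ids]
        if panel and r.trace.selected:
            g_cc = r.genotypes.subset_samples(r.composite.sample_ids)
            r.functional_table = functional_panel_models(
                r.composite.as_series(), g_cc, panel, r.trace.selected,
                dataset_name=n,
            )

    # haplotype and allele associations; model-haplotype correlation
    associations: list[HaplotypeAssociation] = []
    allele_assocs: list[HaplotypeAssociation] = []
    hap_r2_rows = []
    for n, r in results.items():
        y = r.composite.as_series()
        if r.haplotypes is not None:
            hs = r.haplotypes
            for hap in hs.haplotype_ids:
                d = pd.Series(
                    haplotype_dosage(hs, hap, mode="hard"), index=hs.sample_ids
                )
                if d.loc[y.index.intersection(d.index)].nunique() < 2:
                    continue  # monomorphic in the analysed samples
                associations.append(
                    haplotype_association(y, d, haplotype_id=hap, dataset=n)
                )
                if r.trace.selected:
                    corr = model_haplotype_r2(
                        r.trace.final,
                        d.reindex(r.trace.final.sample_ids),
                        haplotype_id=hap,
                    )
                    hap_r2_rows.append(
                        {"dataset": n, "model": corr.model_id,
                         "haplotype": hap, "r2": corr.r2}
                    )
        for v in config.report_alleles:
            if v in r.genotypes.variant_ids:
                g_cc = r.genotypes.subset_samples(r.composite.sample_ids)
                allele_assocs.append(allele_association(y, g_cc, v, dataset=n))

    manifest = {
        "tool": "cisreg",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "datasets": {
            n: {
                "n_samples": r.composite.as_series().size,
                "n_probes_used": len(r.representative_probes),
                "n_variants": r.genotypes.n_variants,
                "n_pruned": len(r.pruned_ids),
                "best_model": r.trace.selected,
                "stop_reason": r.trace.stop_reason,
            }
            for n, r in results.items()
        },
    }

    bundle = ResultBundle(
        config=config, results=results, grid=grid, combined_trace=combined_trace,
        associations=associations, allele_associations=allele_assocs,
        model_hap_r2=pd.DataFrame(hap_r2_rows), manifest=manifest,
    )
    _write_bundle(bundle, outdir)
    return bundle


def _write_bundle(bundle: ResultBundle, outdir: Path) -> None:
    for n, r in bundle.results.items():
        ddir = outdir / n
        ddir.mkdir(exist_ok=True)
        write_expression_tsv(r.expression, ddir / "expression_standardized.tsv")
        r.prune_report.to_csv(ddir / "prune_report.tsv", sep="\t", index=False)
        r.trace.to_frame().to_csv(ddir / "selection_trace.tsv", sep="\t", index=False)
        r.trace.final.to_json(ddir / "best_model.json")
        r.trace.final.term_table().to_csv(ddir / "best_model_terms.tsv",
                                          sep="\t", index=False)
        r.composite.as_series().rename("composite").to_csv(
            ddir / "composite.tsv", sep="\t"
        )
        if r.probe_r2 is not None:
            r.probe_r2.to_csv(ddir / "probe_r2.tsv", sep="\t")
        if r.haplotypes is not None:
            write_haplotypes_tsv(r.haplotypes, ddir / "diplotypes.tsv")
            pd.Series(r.haplotypes.frequencies).rename("frequency").to_csv(
                ddir / "haplotype_frequencies.tsv", sep="\t"
            )
        if r.functional_table is not None:
            r.functional_table.to_csv(ddir / "functional_models.tsv",
                                      sep="\t", index=False)
    if bundle.grid is not None:
        bundle.grid.to_frame().to_csv(outdir / "crosscheck_grid.tsv",
                                      sep="\t", index=False)
    associations_to_tsv(bundle.associations, outdir / "haplotype_associations.tsv")
    associations_to_tsv(bundle.allele_associations, outdir / "allele_associations.tsv")
    if len(bundle.model_hap_r2):
        bundle.model_hap_r2.to_csv(outdir / "model_haplotype_r2.tsv",
                                   sep="\t", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2)
    with open(outdir / "report.txt", "w") as fh:
        fh.write(report(bundle))


def report(bundle: ResultBundle) -> str:
    """Human-readable summary of best models, cross-check grid, haplotypes."""
    lines = ["Best cis-regulatory models", "=" * 60]
    traces = {n: r.trace for n, r in bundle.results.items()}
    if bundle.combined_trace is not None:
        traces[bundle.combined_trace.response_name] = bundle.combined_trace
    lines.append(render_best_models_table(traces))
    lines.append("")
    lines.append("Cross-check grid (verdict vs each dataset's proper best)")
    lines.append("=" * 60)
    if bundle.grid is None or not bundle.grid.cells:
        lines.append("(no grid: fewer than two datasets)")
    else:
        lines.append(bundle.grid.verdicts().to_string())
        lines.append("")
        lines.append("-log10 fit P of each composition on each dataset:")
        lines.append(bundle.grid.neglog10_fit_p().round(2).to_string())
    lines.append("")
    lines.append("Haplotype associations (beta [95% CI], P)")
    lines.append("=" * 60)
    if not bundle.associations:
        lines.append("(no haplotype associations: no tag variants configured)")
    else:
        for a in bundle.associations:
            lines.append(
                f"{a.dataset:>6} {a.haplotype_id:>4}: {a.beta:+.3f} "
                f"[{a.ci_lo:+.3f}, {a.ci_hi:+.3f}]  P={a.p_value:.2e}  n={a.n}"
            )
    if len(bundle.model_hap_r2):
        lines.append("")
        lines.append("Best-model vs haplotype-dosage r2")
        lines.append("=" * 60)
        pivot = bundle.model_hap_r2.pivot(index="dataset", columns="haplotype",
                                          values="r2")
        lines.append(pivot.round(3).to_string())
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Fixture input writer (used by the `simulate` CLI subcommand and tests)
# ---------------------------------------------------------------------------

def write_fixture_inputs(fixture, outdir) -> Path:
    """Serialize a four-study fixture as pipeline input files + config.yaml.

    Genotypes are written both as unphased dosage TSV (analysis input) and
    as truth-phased VCF; ground truth goes to JSON sidecars.
    """
    from .synthetic_data import write_truth_json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for coll, g in fixture.genotypes.items():
        write_genotypes_tsv(g, outdir / f"genotypes_{coll}.tsv")
        write_genotypes_vcf(
            g, outdir / f"genotypes_{coll}_phased.vcf",
            phased_haplotypes=fixture.genotype_truth[coll].phased,
        )
        write_truth_json(fixture.genotype_truth[coll], outdir / f"truth_{coll}.json")

    tags = fixture.tag_variant_ids
    hap_rows = {
        hid: {t: a for t, a in zip(tags, alleles)}
        for alleles, hid in fixture.pool.tag_name_map().items()
        for hid in [hid]
    }
    hap_df = pd.DataFrame(hap_rows).T.loc[sorted(hap_rows)]
    hap_df.index.name = "hap_id"
    hap_df.to_csv(outdir / "haplotypes.tsv", sep="\t")

    dataset_cfgs = []
    representative = {
        "K": {"method": "group"},
        "S": {"method": "correlate", "with": "K", "min_r2": 0.15},
        "C": {"method": "probes"},
        "D": {"method": "target", "target": "exon9_utr"},
    }
    for name, expr in fixture.datasets.items():
        write_expression_tsv(expr, outdir / f"expression_{name}.tsv")
        expr.probe_meta.to_csv(outdir / f"probes_{name}.tsv", sep="\t")
        coll = fixture.study_collection[name]
        dataset_cfgs.append(
            {
                "name": name,
                "expression": str(outdir / f"expression_{name}.tsv"),
                "genotypes": str(outdir / f"genotypes_{coll}.tsv"),
                "genotype_format": "tsv",
                "probe_annotation": str(outdir / f"probes_{name}.tsv"),
                "representative": representative.get(name, {"method": "group"}),
            }
        )
    config = {
        "datasets": dataset_cfgs,
        "ld_prune_threshold": 0.90,
        "alpha_entry": 0.001,
        "alpha_stay": 0.001,
        "min_mean_r2": 0.5,
        "functional_ids": list(fixture.functional_ids),
        "haplotype_table": str(outdir / "haplotypes.tsv"),
        "report_alleles": ["t6"],
        "combine": {"name": "KSC", "members": ["K", "S", "C"]},
        "allow_partial": True,
        "seed": fixture.seed,
    }
    cfg_path = outdir / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return cfg_path
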