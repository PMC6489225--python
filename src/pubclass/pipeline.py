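"""End-to-end orchestration: classify, catalog structure, phylogeny, expression.

A run is described by a plain key/value config (YAML). Every output file
carries the seed and a hash of the config in a header comment, and a fixed
seed makes the whole run byte-reproducible. The phylogeny and expression
stages are optional: a missing input skips the stage with a warning. Any
stage failure removes that stage's partial outputs and aborts with a
stage-named error.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import classify as _classify
from . import expression as _expression
from . import io as _io
from . import phylo as _phylo
from . import synth as _synth

logger = logging.getLogger(__name__)

#: stage name -> process exit code used by the CLI
STAGE_EXIT_CODES = {"config": 2, "classify": 3, "catalog": 4,
                    "phylogeny": 5, "expression": 6, "report": 7}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All knobs of a pipeline run, with the published defaults."""

    seed: int = 1
    # inputs; "synthetic:barley-table1" generates the packaged composition,
    # "builtin:barley" loads the packaged 67-gene catalog
    domains: Optional[str] = "synthetic:barley-table1"
    domains_format: str = "simple_tsv"
    catalog: Optional[str] = "builtin:barley"
    alignment: Optional[str] = None
    cq: Optional[str] = None
    reference_gene: str = "HvActin"
    control_condition: str = "control"
    # classifier thresholds
    und_fraction: float = 0.25
    arm_like_counts_as_arm: bool = False
    ubox_point: str = "midpoint"
    tandem_max_gap_bp: int = 100_000
    # phylogeny
    bootstrap: int = 1000
    gap_mode: str = "pairwise_deletion"
    distance_correction: str = "p"
    # expression thresholds
    up_fold: float = 2.0
    strong_down_fold: float = 3.0
    require_significance: bool = True

    def rule_config(self) -> _classify.RuleConfig:
        return _classify.RuleConfig(
            und_fraction=self.und_fraction,
            arm_like_counts_as_arm=self.arm_like_counts_as_arm,
            ubox_point=self.ubox_point,
            tandem_max_gap_bp=self.tandem_max_gap_bp)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def load_run_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    unknown = set(data) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise _io.UsageError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**data)


def summarize_est_categories(catalog, class_of: Optional[dict] = None
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene EST counts and per-class totals over the four library categories.

    Classes come from ``class_of`` (gene name -> class) when given, falling
    back to the catalog's printed class labels. Genes with no matching EST in
    any category are flagged.
    """
    rows = []
    for e in catalog:
        cls = (class_of or {}).get(e.name) or (e.class_label or "?")
        a, b, g, v = e.est_counts
        rows.append({"gene": e.name, "class": cls, "abiotic": a, "biotic": b,
                     "generative": g, "vegetative": v,
                     "zero_est": sum(e.est_counts) == 0})
    per_gene = pd.DataFrame(rows).sort_values("gene", kind="stable").reset_index(drop=True)
    per_class = (per_gene.groupby("class", sort=True)
                 [["abiotic", "biotic", "generative", "vegetative"]]
                 .sum().reset_index())
    return per_gene, per_class


def _write_tsv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig, outdir) -> dict[str, Path]:
    """Run all configured stages; returns the map of written outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# pubclass seed={config.seed} config={config.hash()}\n"
    outputs: dict[str, Path] = {}

    def emit(name: str, fname: str, df: pd.DataFrame):
        path = outdir / fname
        _write_tsv(df, path, header)
        outputs[name] = path

    def fail(stage: str, exc: Exception, *partial: Path):
        for p in partial:
            Path(p).unlink(missing_ok=True)
        raise StageError(stage, exc)

    # --- catalog structure ---------------------------------------------------
    catalog = None
    if config.catalog:
        try:
            catalog = (_io.load_barley_catalog() if config.catalog == "builtin:barley"
                       else _io.read_gene_catalog(config.catalog))
            clusters = _classify.find_tandem_clusters(catalog, config.tandem_max_gap_bp)
            emit("clusters", "clusters.tsv", pd.DataFrame(
                [(i + 1, ",".join(c)) for i, c in enumerate(clusters)],
                columns=["cluster", "genes"]))
            logger.info("catalog: %d genes, %d tandem/cluster group(s)",
                        len(catalog), len(clusters))
        except Exception as e:
            fail("catalog", e, outdir / "clusters.tsv")

    # --- classification -----------------------------------------------------
    try:
        if config.domains and config.domains.startswith("synthetic:"):
            preset = config.domains.split(":", 1)[1]
            if preset not in _synth.COMPOSITION_PRESETS:
                raise _io.UsageError(f"unknown composition preset {preset!r}")
            if catalog is not None:
                # name synthetic proteins after the catalog genes so the
                # report joins per gene
                records = _synth.generate_from_catalog(catalog, seed=config.seed)
            else:
                records = _synth.generate_architectures(
                    _synth.COMPOSITION_PRESETS[preset](), seed=config.seed)
        elif config.domains:
            records = _io.read_domain_annotations(config.domains, config.domains_format)
        else:
            raise _io.UsageError("config must name a domains input")
        result = _classify.classify_proteome(records, config.rule_config())
        emit("assignments", "assignments.tsv", result.to_frame())
        emit("summary", "summary.tsv", result.summary_frame())
        logger.info("classified %d proteins", len(records))
    except StageError:
        raise
    except Exception as e:
        fail("classify", e, outdir / "assignments.tsv", outdir / "summary.tsv")

    # --- phylogeny (optional) ------------------------------------------------
    if config.alignment:
        try:
            aln = _io.read_aligned_fasta(config.alignment)
            tree = _phylo.bootstrap_support(
                aln, n_replicates=config.bootstrap, seed=config.seed,
                gap_mode=config.gap_mode, correction=config.distance_correction)
            path = outdir / "tree.nwk"
            path.write_text(header + tree.to_newick() + "\n", encoding="utf-8")
            outputs["tree"] = path
            logger.info("phylogeny: %d taxa, %d bootstrap replicates",
                        aln.n_taxa, config.bootstrap)
        except Exception as e:
            fail("phylogeny", e, outdir / "tree.nwk")
    else:
        logger.warning("no alignment configured; phylogeny stage skipped")

    # --- expression (optional) -----------------------------------------------
    calls_frame = None
    if config.cq:
        try:
            cq = _io.read_cq_table(config.cq, config.reference_gene)
            results = _expression.analyze_expression(
                cq, control_condition=config.control_condition)
            results, _ = _expression.call_stress_response(
                results, up_fold=config.up_fold,
                strong_down_fold=config.strong_down_fold,
                require_significance=config.require_significance)
            calls_frame = _expression.results_frame(results)
            emit("calls", "calls.tsv", calls_frame)
            logger.info("expression: %d genes called", len(results))
        except Exception as e:
            fail("expression", e, outdir / "calls.tsv")
    else:
        logger.warning("no Cq table configured; expression stage skipped")

    # --- joined report --------------------------------------------------------
    try:
        assignments = result.to_frame()
        if catalog is not None:
            per_gene, _ = summarize_est_categories(catalog)
            cluster_of = {g: i + 1
                          for i, c in enumerate(
                              _classify.find_tandem_clusters(
                                  catalog, config.tandem_max_gap_bp))
                          for g in c}
            report = per_gene.drop(columns=["zero_est"]).rename(
                columns={"class": "catalog_class"})
            report["cluster"] = report["gene"].map(cluster_of).astype("Int64")
            report = report.merge(assignments.rename(columns={"protein": "gene"}),
                                  on="gene", how="left")
        else:
            report = assignments.rename(columns={"protein": "gene"})
        if calls_frame is not None:
            report = report.merge(
                calls_frame[["gene", "fold", "p_value", "stars", "call"]],
                on="gene", how="left")
        emit("report", "report.tsv", report)
    except StageError:
        raise
    except Exception as e:
        fail("report", e, outdir / "report.tsv")

    return outputs
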