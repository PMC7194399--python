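"""End-to-end pipeline orchestration with logging and a provenance manifest.

The pipeline chains the analysis stages in order — total-sum scaling,
prevalence partition, Pareto scaling, common components analysis, S-plot
selection, richness, domain overview, cladogram export and the correlation
report — writing every artifact plus a ``manifest.json`` recording the
configuration, package version, input checksums and per-stage table sizes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, cca, interpret, io_formats, preprocess, synthetic

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run; mirrors the CLI flags."""

    out_dir: str = "results"
    otu_table: str | None = None
    taxonomy: str | None = None
    metadata: str | None = None
    markers: str | None = None
    dialect: str = "tsv"
    min_samples: int = 2
    n_components: int = 2
    tol: float = 1e-10
    max_iter: int = 500
    splot_center: str = "zero"
    splot_against: str = "working"
    overview_threshold: float = 0.01
    seed: int | None = None  # synthetic mode only

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise io_formats.ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.min_samples < 1:
            raise io_formats.ValidationError("min_samples must be >= 1")
        if self.n_components < 1:
            raise io_formats.ValidationError("n_components must be >= 1")
        if not 0 <= self.overview_threshold < 1:
            raise io_formats.ValidationError("overview_threshold must lie in [0, 1)")
        if self.splot_center not in ("zero", "mean"):
            raise io_formats.ValidationError("splot_center must be 'zero' or 'mean'")
        if self.splot_against not in ("working", "original"):
            raise io_formats.ValidationError("splot_against must be 'working' or 'original'")
        for name in ("otu_table", "taxonomy", "metadata", "markers"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise io_formats.ValidationError(f"{name} path does not exist: {p}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def setup_logging(out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    root = logging.getLogger("microcca")
    root.setLevel(logging.INFO)
    root.handlers = []
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    for handler in (logging.StreamHandler(sys.stderr),
                    logging.FileHandler(out_dir / "pipeline.log", mode="w")):
        handler.setFormatter(fmt)
        root.addHandler(handler)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    config: PipelineConfig
    files: dict[str, Path] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def write_inputs(data: synthetic.SyntheticData, in_dir) -> dict[str, Path]:
    """Persist a synthetic dataset in the formats the readers expect."""
    in_dir = Path(in_dir)
    in_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "otu_table": in_dir / "otu_table.tsv",
        "taxonomy": in_dir / "taxonomy.tsv",
        "metadata": in_dir / "metadata.tsv",
        "markers": in_dir / "markers.tsv",
    }
    io_formats.write_otu_table(data.otu_table, paths["otu_table"])
    io_formats.write_taxonomy(data.taxonomy, paths["taxonomy"])
    io_formats.write_metadata(data.metadata, paths["metadata"])
    io_formats.write_markers(data.markers, paths["markers"])
    truth_path = in_dir / "truth_groups.tsv"
    out = data.truth.otu_groups.rename("group").to_frame()
    out.index.name = "otu_id"
    out.to_csv(truth_path, sep="\t")
    paths["truth_groups"] = truth_path
    return paths


def fit_stage(cfg: PipelineConfig, table: io_formats.OtuTable, out_dir: Path):
    """Steps 1a-2b plus S-plot selection; writes the model artifact set."""
    abund = preprocess.total_sum_scale(table)
    part = preprocess.prevalence_partition(abund, min_samples=cfg.min_samples)
    logger.info("prevalence partition: %d ubiquitous, %d scarce (min_samples=%d)",
                len(part.ubiquitous), len(part.scarce), cfg.min_samples)
    scaled = preprocess.pareto_scale(abund, part.ubiquitous)
    if scaled.dropped:
        logger.info("dropped %d zero-variance OTUs before CCA", len(scaled.dropped))
    model = cca.fit_cca(scaled, n_components=cfg.n_components,
                        tol=cfg.tol, max_iter=cfg.max_iter)
    selection = cca.select_components(model, center=cfg.splot_center,
                                      against=cfg.splot_against)
    for c in sorted(selection.tables):
        logger.info("CC%d: explained=%.4f, %d OTUs selected",
                    c, model.explained.iloc[c - 1], len(selection.otus(c)))

    files = io_formats.write_results(model, selection, out_dir)
    info = pd.DataFrame(
        {
            "explained": model.explained,
            "iterations": model.iterations,
            "converged": model.converged,
        }
    )
    info.index.name = "component"
    info_path = out_dir / "model_info.tsv"
    info.to_csv(info_path, sep="\t", float_format=io_formats.FLOAT_FORMAT)
    files["model_info"] = info_path

    part_path = out_dir / "partition.tsv"
    with open(part_path, "w") as fh:
        fh.write("otu_id\tstatus\n")
        for otu in part.ubiquitous:
            fh.write(f"{otu}\tubiquitous\n")
        for otu in part.scarce:
            fh.write(f"{otu}\tscarce\n")
    files["partition"] = part_path
    return abund, part, scaled, model, selection, files


def report_stage(
    cfg: PipelineConfig,
    abund: preprocess.AbundanceMatrix,
    part: preprocess.PrevalencePartition,
    model: cca.CcaModel,
    selection: cca.SelectionResult,
    taxonomy: io_formats.TaxonomyTable,
    metadata: io_formats.SampleMetadata,
    markers: io_formats.PerformanceTable,
    out_dir: Path,
) -> dict[str, Path]:
    """Steps 3a-4 plus the traditional overview; writes the report files."""
    files: dict[str, Path] = {}

    rich = interpret.richness(abund, restrict_to=part.ubiquitous)
    p = out_dir / "richness.tsv"
    out = rich.rename("richness").to_frame()
    out.index.name = "sample_id"
    out.to_csv(p, sep="\t")
    files["richness"] = p

    overview = interpret.traditional_overview(abund, taxonomy,
                                              threshold=cfg.overview_threshold)
    for domain, ov in overview.items():
        p = out_dir / f"overview_{domain.split()[0].lower()}.tsv"
        tab = ov.table.copy()
        tab.insert(0, "label", ov.labels)
        tab.to_csv(p, sep="\t", float_format=io_formats.FLOAT_FORMAT)
        files[f"overview_{domain}"] = p

    summaries = interpret.clade_summary(selection, model, taxonomy)
    for cs in summaries:
        if cs.is_empty:
            logger.info("CC%d: empty selection, no cladogram", cs.component)
            continue
        nwk, annot = interpret.export_cladogram(cs, out_dir)
        files[f"cladogram_CC{cs.component}"] = nwk
        files[f"annotation_CC{cs.component}"] = annot

    report = interpret.correlation_report(model, abund, taxonomy, metadata, markers,
                                          ubiquitous=part.ubiquitous)
    p = out_dir / "correlations.tsv"
    report.table.to_csv(p, sep="\t", index=False,
                        float_format=io_formats.FLOAT_FORMAT)
    files["correlations"] = p
    return files


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline from a config; returns the artifact set.

    In synthetic mode (``cfg.seed`` set and no ``otu_table`` path) the
    inputs are generated first and written under ``<out_dir>/inputs``.
    """
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    setup_logging(out_dir)

    if cfg.otu_table is None:
        if cfg.seed is None:
            raise io_formats.ValidationError(
                "either input paths or a synthetic seed must be provided"
            )
        logger.info("generating synthetic inputs (seed=%d)", cfg.seed)
        data = synthetic.generate(synthetic.SyntheticScenario(seed=cfg.seed))
        input_paths = write_inputs(data, out_dir / "inputs")
        cfg.otu_table = str(input_paths["otu_table"])
        cfg.taxonomy = str(input_paths["taxonomy"])
        cfg.metadata = str(input_paths["metadata"])
        cfg.markers = str(input_paths["markers"])

    for name in ("otu_table", "taxonomy", "metadata", "markers"):
        if getattr(cfg, name) is None:
            raise io_formats.ValidationError(f"missing required input: {name}")

    table = io_formats.read_otu_table(cfg.otu_table, dialect=cfg.dialect)
    taxonomy = io_formats.read_taxonomy(cfg.taxonomy)
    metadata = io_formats.read_metadata(cfg.metadata, otu_table=table)
    markers = io_formats.read_markers(cfg.markers)
    logger.info("inputs: %d OTUs x %d samples", table.n_otus, table.n_samples)

    abund, part, scaled, model, selection, files = fit_stage(cfg, table, out_dir)
    files.update(
        report_stage(cfg, abund, part, model, selection,
                     taxonomy, metadata, markers, out_dir)
    )

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(cfg),
        "inputs": {
            name: {"path": str(getattr(cfg, name)), "sha256": _sha256(getattr(cfg, name))}
            for name in ("otu_table", "taxonomy", "metadata", "markers")
        },
        "stages": {
            "input": {"n_otus": table.n_otus, "n_samples": table.n_samples},
            "prevalence_partition": {
                "n_ubiquitous": len(part.ubiquitous),
                "n_scarce": len(part.scarce),
            },
            "pareto_scale": {
                "n_kept": scaled.values.shape[1],
                "n_dropped_zero_variance": len(scaled.dropped),
            },
            "cca": {
                "n_components": model.n_components,
                "explained": [float(x) for x in model.explained],
                "converged": [bool(x) for x in model.converged],
            },
            "selection": {
                f"CC{c}": len(selection.otus(c)) for c in sorted(selection.tables)
            },
        },
        "outputs": {k: str(v) for k, v in sorted(files.items())},
    }
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    files["manifest"] = manifest_path
    return PipelineResult(config=cfg, files=files, manifest=manifest)


# ---------------------------------------------------------------------------
# Model re-loading (for the report-only entry point)
# ---------------------------------------------------------------------------

def load_model(model_dir) -> tuple[cca.CcaModel, cca.SelectionResult]:
    """Re-read a fitted model and its selection from a fit-stage directory."""
    model_dir = Path(model_dir)
    scores = pd.read_csv(model_dir / "scores.tsv", sep="\t", index_col=0)
    loadings = pd.read_csv(model_dir / "loadings.tsv", sep="\t", index_col=0)
    saliences = pd.read_csv(model_dir / "saliences.tsv", sep="\t", index_col=0)
    info = pd.read_csv(model_dir / "model_info.tsv", sep="\t", index_col=0)
    model = cca.CcaModel(
        scores=scores,
        loadings=loadings,
        saliences=saliences,
        explained=info["explained"],
        iterations=info["iterations"],
        converged=info["converged"],
        tol=float("nan"),
        max_iter=0,
        working_matrices=[],
    )
    sel_df = pd.read_csv(model_dir / "selection.tsv", sep="\t",
                         dtype={"otu_id": str})
    tables = {}
    for c in range(1, scores.shape[1] + 1):
        sub = sel_df[sel_df["component"] == c]
        tables[c] = sub[["otu_id", "covariance", "correlation", "sign"]].reset_index(drop=True)
    return model, cca.SelectionResult(tables=tables, thresholds={})
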