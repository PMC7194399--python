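"""Downstream interpretation of a fitted model: richness, abundance
overview, taxonomy-cladogram loading summaries and performance-marker
correlations."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cca import CcaModel, SelectionResult
from .io_formats import (
    RANKS,
    UNKNOWN,
    KNOWN_DOMAINS,
    PerformanceTable,
    SampleMetadata,
    TaxonomyTable,
    ValidationError,
)
from .preprocess import AbundanceMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Richness
# ---------------------------------------------------------------------------

def richness(abund: AbundanceMatrix, restrict_to: list[str] | None = None) -> pd.Series:
    """Number of detected (abundance > 0) OTUs per sample.

    ``restrict_to`` limits the count to a subset of OTUs, typically the
    ubiquitous set.
    """
    if restrict_to is None:
        sub = abund.values
    else:
        unknown = set(restrict_to) - set(abund.otu_ids)
        if unknown:
            raise ValidationError(f"restrict_to contains unknown OTUs: {sorted(unknown)}")
        sub = abund.values.loc[:, list(restrict_to)]
    return (sub > 0).sum(axis=1).astype(int)


# ---------------------------------------------------------------------------
# Traditional overview (1 % aggregation per domain)
# ---------------------------------------------------------------------------

@dataclass
class DomainOverview:
    """Aggregated per-domain abundance table for the traditional analysis."""

    domain: str
    table: pd.DataFrame   # rows: kept otu ids + "Other <domain>"; cols: samples
    labels: pd.Series     # row -> display-rank label


DISPLAY_RANKS = {"Archaea": "genus", "Bacteria": "order"}


def traditional_overview(
    abund: AbundanceMatrix,
    taxonomy: TaxonomyTable,
    threshold: float = 0.01,
    display_ranks: dict[str, str] | None = None,
) -> dict[str, DomainOverview]:
    """Domain-split abundance overview with sub-threshold OTUs pooled.

    Within each domain, OTUs whose relative abundance (fraction of the whole
    sample) exceeds ``threshold`` in at least one sample are kept as
    individual rows labelled by the domain's display rank; all remaining
    OTUs are summed into one ``Other <domain>`` row.  OTUs with an
    unrecognised domain go to a flagged ``unclassified domain`` table.
    """
    if not taxonomy.covers(abund.otu_ids):
        missing = sorted(set(abund.otu_ids) - set(taxonomy.lineages.index))
        raise ValidationError(f"taxonomy does not cover OTUs: {missing[:5]} ...")
    ranks = dict(DISPLAY_RANKS)
    if display_ranks:
        ranks.update(display_ranks)

    domains = taxonomy.lineages.loc[abund.otu_ids, "domain"]
    out: dict[str, DomainOverview] = {}
    for domain in list(KNOWN_DOMAINS) + ["unclassified domain"]:
        if domain == "unclassified domain":
            members = [o for o, d in domains.items() if d not in KNOWN_DOMAINS]
            if members:
                logger.warning(
                    "%d OTUs with unrecognised domain pooled into a flagged row", len(members)
                )
                sub = abund.values.loc[:, members]
                table = pd.DataFrame(
                    [sub.sum(axis=1)], index=pd.Index([domain], name="row")
                )
                out[domain] = DomainOverview(
                    domain=domain,
                    table=table,
                    labels=pd.Series({domain: domain}),
                )
            continue
        members = [o for o, d in domains.items() if d == domain]
        if not members:
            continue
        sub = abund.values.loc[:, members]  # samples x member otus
        keep_mask = (sub > threshold).any(axis=0)
        kept = list(sub.columns[keep_mask])
        pooled = list(sub.columns[~keep_mask])
        rows = {}
        labels = {}
        rank = ranks.get(domain, "genus")
        for otu in kept:
            rows[otu] = sub[otu]
            labels[otu] = taxonomy.lineages.at[otu, rank]
        other = f"Other {domain}"
        rows[other] = sub[pooled].sum(axis=1) if pooled else pd.Series(0.0, index=sub.index)
        labels[other] = other
        table = pd.DataFrame(rows).T
        table.index.name = "row"
        out[domain] = DomainOverview(domain=domain, table=table, labels=pd.Series(labels))
    return out


# ---------------------------------------------------------------------------
# Clade summaries and cladogram export
# ---------------------------------------------------------------------------

@dataclass
class CladeNode:
    """One node of the multifurcating taxonomy cladogram."""

    name: str
    path: tuple[str, ...]
    children: dict[str, "CladeNode"] = field(default_factory=dict)
    otu_id: str | None = None  # set on leaves

    @property
    def is_leaf(self) -> bool:
        return self.otu_id is not None

    def leaves(self) -> list["CladeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for child in self.children.values():
            out.extend(child.leaves())
        return out

    def internal_nodes(self) -> list["CladeNode"]:
        out = [] if (self.is_leaf or not self.path) else [self]
        for child in self.children.values():
            out.extend(child.internal_nodes())
        return out


@dataclass
class CladeSummary:
    """Per-component loading summary over the shared taxonomy cladogram.

    The tree spans the union of OTUs selected in any component, so the
    layout is identical across components; leaves not selected in this
    component carry NaN.  Internal node values are the arithmetic mean of
    the loadings of their selected descendant leaves.
    """

    component: int
    root: CladeNode
    leaf_values: pd.Series   # otu_id -> loading (NaN where not selected here)
    node_means: dict[tuple[str, ...], float]

    @property
    def is_empty(self) -> bool:
        return not self.root.children


def _build_tree(otu_ids: list[str], taxonomy: TaxonomyTable) -> CladeNode:
    root = CladeNode(name="root", path=())
    for otu in otu_ids:
        if otu in taxonomy.lineages.index:
            names = [taxonomy.lineages.at[otu, r] for r in RANKS]
        else:
            logger.warning("OTU %s missing taxonomy; attached under an unknown chain", otu)
            names = [UNKNOWN] * len(RANKS)
        node = root
        for name in names:
            if name not in node.children:
                node.children[name] = CladeNode(name=name, path=node.path + (name,))
            node = node.children[name]
        node.children[otu] = CladeNode(name=otu, path=node.path + (otu,), otu_id=otu)
    return root


def clade_summary(
    selection: SelectionResult,
    model: CcaModel,
    taxonomy: TaxonomyTable,
) -> list[CladeSummary]:
    """Build the shared cladogram and per-component loading summaries."""
    union: list[str] = []
    seen = set()
    for c in sorted(selection.tables):
        for otu in selection.otus(c):
            if otu not in seen:
                seen.add(otu)
                union.append(otu)
    root = _build_tree(union, taxonomy)

    summaries = []
    for c in sorted(selection.tables):
        selected = set(selection.otus(c))
        vals = pd.Series(np.nan, index=pd.Index(union, name="otu_id"), dtype=float)
        for otu in selected:
            vals[otu] = model.loadings.at[otu, f"CC{c}"]
        means: dict[tuple[str, ...], float] = {}

        def walk(node: CladeNode) -> list[float]:
            if node.is_leaf:
                v = vals[node.otu_id]
                return [v] if not np.isnan(v) else []
            acc: list[float] = []
            for child in node.children.values():
                acc.extend(walk(child))
            if node.path:
                means[node.path] = float(np.mean(acc)) if acc else np.nan
            return acc

        walk(root)
        summaries.append(
            CladeSummary(component=c, root=root, leaf_values=vals, node_means=means)
        )
    return summaries


POSITIVE_COLOR = "#ff0000"  # red
NEGATIVE_COLOR = "#00ffff"  # cyan


def _alpha_hex(alpha: float) -> str:
    return f"{int(round(np.clip(alpha, 0, 1) * 255)):02x}"


def export_cladogram(cs: CladeSummary, out_dir) -> tuple[Path, Path]:
    """Write the cladogram (Newick) and a GraPhlAn-style annotation file.

    Annotation rows: one per leaf (sign colour for leaves selected in this
    component, blank otherwise) and one per shaded clade, i.e. internal node
    with at least one selected descendant; clade shading is the sign colour
    with alpha scaled linearly from [0, max |mean loading|].
    """
    if cs.is_empty:
        raise ValidationError("cannot export an empty cladogram")
    import dendropy

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    tree = dendropy.Tree()

    def attach(node: CladeNode, parent) -> None:
        child = parent.new_child()
        if node.is_leaf:
            taxon = dendropy.Taxon(label=node.otu_id)
            tree.taxon_namespace.add_taxon(taxon)
            child.taxon = taxon
        else:
            child.label = node.name
        for sub in node.children.values():
            attach(sub, child)

    for top in cs.root.children.values():
        attach(top, tree.seed_node)

    newick_path = out_dir / f"cladogram_CC{cs.component}.nwk"
    tree.write(path=str(newick_path), schema="newick",
               suppress_rooting=True, unquoted_underscores=True)

    shaded = {p: m for p, m in cs.node_means.items() if not np.isnan(m)}
    max_mean = max((abs(m) for m in shaded.values()), default=0.0)

    annot_path = out_dir / f"annotation_CC{cs.component}.txt"
    with open(annot_path, "w") as fh:
        for leaf in cs.root.leaves():
            v = cs.leaf_values[leaf.otu_id]
            if np.isnan(v):
                fh.write(f"{leaf.otu_id}\tclade_marker_color\t#ffffff\n")
            else:
                color = POSITIVE_COLOR if v > 0 else NEGATIVE_COLOR
                fh.write(f"{leaf.otu_id}\tclade_marker_color\t{color}\n")
        for path, mean in shaded.items():
            alpha = abs(mean) / max_mean if max_mean > 0 else 0.0
            color = (POSITIVE_COLOR if mean > 0 else NEGATIVE_COLOR) + _alpha_hex(alpha)
            fh.write(f"{path[-1]}\tannotation_background_color\t{color}\n")
    return newick_path, annot_path


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def correlate(series_a, series_b) -> tuple[float, int]:
    """Pearson correlation over pairwise-complete observations.

    Returns ``(r, n)`` where ``n`` is the number of complete pairs used.
    Raises :class:`ValidationError` with fewer than 3 complete pairs or when
    either series has zero variance on the complete pairs.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("series have different lengths")
    mask = ~(np.isnan(a) | np.isnan(b))
    n = int(mask.sum())
    if n < 3:
        raise ValidationError(f"need >= 3 complete pairs, got {n}")
    a, b = a[mask], b[mask]
    if a.std() == 0 or b.std() == 0:
        raise ValidationError("zero variance in a correlated series")
    r, _ = stats.pearsonr(a, b)
    return float(r), n


@dataclass
class CorrelationReport:
    """Long-format Pearson-correlation report.

    ``table`` columns: series (score column or aggregate name), target
    (marker or metadata gradient), r, n, error (empty when computed).
    """

    table: pd.DataFrame

    def r(self, series: str, target: str) -> float:
        row = self.table[(self.table["series"] == series) & (self.table["target"] == target)]
        if row.empty:
            raise KeyError((series, target))
        return float(row["r"].iloc[0])


def correlation_report(
    model: CcaModel,
    abund: AbundanceMatrix,
    taxonomy: TaxonomyTable,
    metadata: SampleMetadata,
    markers: PerformanceTable,
    ubiquitous: list[str] | None = None,
) -> CorrelationReport:
    """Correlate CC scores with markers, and community aggregates with the
    co-substrate gradient.

    Rows produced: every score column against every marker; the Archaea
    fraction of total abundance against percent co-substrate; ubiquitous
    richness against percent co-substrate.
    """
    samples = model.sample_ids
    pct = metadata.percent().reindex(samples).to_numpy(dtype=float)
    rows = []

    def add(series_name, target_name, a, b):
        try:
            r, n = correlate(a, b)
            rows.append((series_name, target_name, r, n, ""))
        except ValidationError as exc:
            rows.append((series_name, target_name, np.nan, 0, str(exc)))

    marker_vals = markers.values.reindex(samples)
    for cc in model.scores.columns:
        t = model.scores[cc].to_numpy()
        for m in markers.marker_names:
            add(cc, m, t, marker_vals[m].to_numpy())

    domains = taxonomy.lineages.loc[abund.otu_ids, "domain"]
    arch = [o for o, d in domains.items() if d == "Archaea"]
    arch_frac = abund.values.loc[samples, arch].sum(axis=1).to_numpy() if arch else np.zeros(len(samples))
    add("archaea_fraction", "percent_cosubstrate", arch_frac, pct)

    rich = richness(abund, restrict_to=ubiquitous).reindex(samples).to_numpy(dtype=float)
    add("ubiquitous_richness", "percent_cosubstrate", rich, pct)

    table = pd.DataFrame(rows, columns=["series", "target", "r", "n", "error"])
    return CorrelationReport(table=table)
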