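"""Readers, writers and validation for the four input tables and result files.

External conventions follow the FROGS-style export: OTU count tables are
tab-separated with OTUs as rows and samples as columns, taxonomy lineages are
semicolon-separated rank chains, and missing marker values are the literal
``NA``.  BIOM 2.1 (HDF5) count tables are also readable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical taxonomy ranks, highest to lowest.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

#: Sentinel used for missing / unparseable taxonomy names.
UNKNOWN = "unknown"

KNOWN_DOMAINS = ("Archaea", "Bacteria")


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(ValueError):
    """A parsed object violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class OtuTable:
    """Non-negative integer OTU counts, externally oriented OTUs x samples.

    Attributes
    ----------
    counts : pandas.DataFrame
        Integer counts, index = OTU ids, columns = sample ids.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def validate(self) -> None:
        idx = self.counts.index
        cols = self.counts.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate OTU ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise FormatError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            raise FormatError("counts must be non-negative")
        totals = values.sum(axis=0)
        empty = [s for s, t in zip(cols, totals) if t == 0]
        if empty:
            raise ValidationError(f"samples with zero total count: {empty}")


@dataclass
class TaxonomyTable:
    """Per-OTU ranked lineage, ranks domain..genus, ``unknown`` where absent."""

    lineages: pd.DataFrame  # index otu_id, columns RANKS

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.lineages.columns]
        if missing:
            raise FormatError(f"taxonomy missing ranks: {missing}")
        self.lineages = self.lineages.loc[:, list(RANKS)].astype(str)
        if self.lineages.index.has_duplicates:
            raise FormatError("duplicate OTU ids in taxonomy")
        bad = set(self.lineages["domain"]) - set(KNOWN_DOMAINS) - {UNKNOWN}
        if bad:
            logger.warning("unrecognised domains treated as unclassified: %s", sorted(bad))

    def lineage(self, otu_id: str) -> list[tuple[str, str]]:
        row = self.lineages.loc[otu_id]
        return [(rank, row[rank]) for rank in RANKS]

    def domain_of(self, otu_id: str) -> str:
        return self.lineages.at[otu_id, "domain"]

    def covers(self, otu_ids) -> bool:
        return set(otu_ids) <= set(self.lineages.index)


@dataclass
class SampleMetadata:
    """Per-sample design factors: co-substrate, mixture level and day."""

    table: pd.DataFrame  # index sample_id; cosubstrate, percent_cosubstrate, day, dataset

    REQUIRED = ("cosubstrate", "percent_cosubstrate", "day")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"metadata missing columns: {missing}")
        if self.table.index.has_duplicates:
            raise FormatError("duplicate sample ids in metadata")
        pct = self.table["percent_cosubstrate"].astype(float)
        if ((pct < 0) | (pct > 100)).any():
            raise ValidationError("percent_cosubstrate must lie in [0, 100]")
        self.table["percent_cosubstrate"] = pct
        self.table["day"] = self.table["day"].astype(int)
        if (self.table["day"] <= 0).any():
            raise ValidationError("day must be a positive integer")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def percent(self) -> pd.Series:
        return self.table["percent_cosubstrate"]

    def check_against(self, otu_table: OtuTable) -> None:
        extra = set(self.sample_ids) - set(otu_table.sample_ids)
        if extra:
            raise ValidationError(f"metadata samples absent from OTU table: {sorted(extra)}")


@dataclass
class PerformanceTable:
    """Digester performance markers, samples x markers, NaN = not measured."""

    values: pd.DataFrame  # index sample_id, columns marker names, float
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise FormatError("duplicate sample ids in marker table")
        if self.values.columns.has_duplicates:
            raise FormatError("duplicate marker names")
        self.values = self.values.astype(float)

    @property
    def marker_names(self) -> list[str]:
        return list(self.values.columns)

    def usable(self, marker: str, min_n: int = 3) -> bool:
        """Whether a marker has enough non-missing values for correlation."""
        return int(self.values[marker].notna().sum()) >= min_n


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_otu_table(path, dialect: str = "tsv") -> OtuTable:
    """Read an OTU count table.

    Parameters
    ----------
    path : str or Path
        Input file.  ``tsv`` dialect expects a header row, first column OTU
        ids and one column per sample; ``biom`` expects a BIOM 2.1 HDF5 file.
    dialect : {"tsv", "biom"}
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_otu_tsv(path)
    if dialect == "biom":
        return _read_otu_biom(path)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _read_otu_tsv(path: Path) -> OtuTable:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            bad = df.index[coerced.isna()][0]
            raise FormatError(f"{path}: non-numeric count for OTU {bad!r}, sample {col!r}")
        df[col] = coerced
    df.index = df.index.astype(str)
    return OtuTable(counts=df)


def _read_otu_biom(path: Path) -> OtuTable:
    import h5py
    from scipy import sparse

    with h5py.File(path, "r") as h5:
        otu_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in h5["observation/ids"][:]]
        sample_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in h5["sample/ids"][:]]
        grp = h5["observation/matrix"]
        mat = sparse.csr_matrix(
            (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
            shape=(len(otu_ids), len(sample_ids)),
        )
    dense = np.asarray(mat.todense())
    df = pd.DataFrame(dense, index=otu_ids, columns=sample_ids)
    return OtuTable(counts=df)


def read_taxonomy(path) -> TaxonomyTable:
    """Read a two-column TSV (otu_id, semicolon-separated lineage)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected otu_id and lineage columns")
    otu_col, lin_col = df.columns[0], df.columns[1]
    rows = {}
    for _, rec in df.iterrows():
        otu = str(rec[otu_col])
        rows[otu] = parse_lineage(rec[lin_col])
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
    return TaxonomyTable(lineages=table)


def parse_lineage(text) -> list[str]:
    """Split a semicolon lineage into exactly six ranks, padding with unknown."""
    if text is None or (isinstance(text, float) and np.isnan(text)):
        names = []
    else:
        names = [n.strip() for n in str(text).split(";")]
    cleaned = []
    for name in names[: len(RANKS)]:
        if not name or name.lower() in {"na", "unknown", "unclassified", "multi-affiliation"}:
            if name and name.lower() not in {"unknown", ""}:
                logger.warning("unparseable rank name %r replaced by %r", name, UNKNOWN)
            cleaned.append(UNKNOWN)
        else:
            cleaned.append(name)
    cleaned += [UNKNOWN] * (len(RANKS) - len(cleaned))
    return cleaned


def read_metadata(path, otu_table: OtuTable | None = None) -> SampleMetadata:
    """Read sample metadata TSV; validate against an OtuTable if given."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    meta = SampleMetadata(table=df)
    if otu_table is not None:
        meta.check_against(otu_table)
    return meta


def read_markers(path) -> PerformanceTable:
    """Read a performance-marker TSV (samples x markers, ``NA`` = missing).

    An optional row indexed ``#units`` carries free-text units per marker.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], dtype={0: str})
    df.index = df.index.astype(str)
    units: dict[str, str] = {}
    if "#units" in df.index:
        units = {c: str(v) for c, v in df.loc["#units"].items() if pd.notna(v)}
        df = df.drop(index="#units")
    return PerformanceTable(values=df.astype(float), units=units)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

#: 10 significant digits for all real-valued result files.
FLOAT_FORMAT = "%.10g"


def write_otu_table(table: OtuTable, path, dialect: str = "tsv") -> None:
    path = Path(path)
    if dialect == "tsv":
        out = table.counts.copy()
        out.index.name = "otu_id"
        out.to_csv(path, sep="\t")
    elif dialect == "biom":
        _write_otu_biom(table, path)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")


def _write_otu_biom(table: OtuTable, path: Path) -> None:
    import datetime

    import h5py
    from scipy import sparse

    counts = table.counts.to_numpy()
    csr_obs = sparse.csr_matrix(counts)
    csc = sparse.csc_matrix(counts)
    with h5py.File(path, "w") as h5:
        h5.attrs["id"] = "No Table ID"
        h5.attrs["type"] = "OTU table"
        h5.attrs["format-url"] = "http://biom-format.org"
        h5.attrs["format-version"] = (2, 1)
        h5.attrs["generated-by"] = "microcca"
        h5.attrs["creation-date"] = datetime.datetime.now().isoformat()
        h5.attrs["shape"] = counts.shape
        h5.attrs["nnz"] = int(csr_obs.nnz)
        for name, ids, mat in (
            ("observation", table.otu_ids, csr_obs),
            ("sample", table.sample_ids, sparse.csr_matrix(csc.T)),
        ):
            grp = h5.create_group(name)
            grp.create_dataset("ids", data=np.array(ids, dtype="S"))
            sub = grp.create_group("matrix")
            sub.create_dataset("data", data=mat.data.astype(np.float64))
            sub.create_dataset("indices", data=mat.indices.astype(np.int32))
            sub.create_dataset("indptr", data=mat.indptr.astype(np.int32))
            grp.create_group("metadata")
            grp.create_group("group-metadata")


def write_taxonomy(taxonomy: TaxonomyTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("otu_id\tlineage\n")
        for otu, row in taxonomy.lineages.iterrows():
            fh.write(f"{otu}\t{';'.join(row[r] for r in RANKS)}\n")


def write_metadata(meta: SampleMetadata, path) -> None:
    out = meta.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def write_markers(markers: PerformanceTable, path) -> None:
    out = markers.values.copy()
    out.index.name = "sample_id"
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(out.columns) + "\n")
        if markers.units:
            fh.write(
                "#units\t" + "\t".join(markers.units.get(c, "") for c in out.columns) + "\n"
            )
        for sid, row in out.iterrows():
            cells = ["NA" if pd.isna(v) else FLOAT_FORMAT % v for v in row]
            fh.write(str(sid) + "\t" + "\t".join(cells) + "\n")


def write_results(model, selection, out_dir) -> dict[str, Path]:
    """Write scores/loadings/saliences/selection TSVs for a fitted model.

    Returns a mapping of artifact name to the written path.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"cannot write to {out_dir}: {exc}") from exc

    paths: dict[str, Path] = {}
    for name, df in (
        ("scores", model.scores),
        ("loadings", model.loadings),
        ("saliences", model.saliences),
    ):
        p = out_dir / f"{name}.tsv"
        out = df.copy()
        out.index.name = "id"
        out.to_csv(p, sep="\t", float_format=FLOAT_FORMAT)
        paths[name] = p

    p = out_dir / "selection.tsv"
    with open(p, "w") as fh:
        fh.write("otu_id\tcomponent\tcovariance\tcorrelation\tsign\n")
        for comp in sorted(selection.tables):
            tab = selection.tables[comp]
            for _, row in tab.iterrows():
                fh.write(
                    f"{row['otu_id']}\t{comp}\t"
                    f"{FLOAT_FORMAT % row['covariance']}\t"
                    f"{FLOAT_FORMAT % row['correlation']}\t"
                    f"{int(row['sign'])}\n"
                )
    paths["selection"] = p
    return paths


def read_scores(path) -> pd.DataFrame:
    """Re-read a scores/loadings/saliences TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", index_col=0)
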