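"""Data model and TSV/GraphML I/O for ASV tables, taxonomy, metadata, networks.

Tables are tab-separated UTF-8 text with samples as rows and ASVs as columns,
the mainstream amplicon-table convention.  Networks are exchanged as GraphML
or as a plain CSV edge list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

DOMAINS = ("bacteria", "eukaryote")
SUBSTRATES = ("granite", "gneiss", "marble", "moraine")
SAMPLE_ROLES = ("sample", "blank", "mock", "replicate")

#: Geochemical / geophysical variables carried in sample metadata,
#: with (min, max) sanity ranges (None = unbounded).
METADATA_VARIABLES = {
    "elevation": (None, None),      # m a.s.l.
    "pH": (0.0, 14.0),              # unitless
    "conductivity": (0.0, None),    # uS/cm
    "TOC": (0.0, 100.0),            # %
    "TN": (0.0, 100.0),             # %
    "TP": (0.0, 100.0),             # %
    "N_NO3": (0.0, None),           # mg/kg
    "N_NH4": (0.0, None),           # mg/kg
    "P_PO4": (0.0, None),           # mg/kg
    "dry_weight": (0.0, 100.0),     # %
}

METADATA_COLUMNS = (
    ["substrate", "site", "latitude", "longitude", "sample_role"]
    + list(METADATA_VARIABLES)
)


class TableFormatError(ValueError):
    """Malformed or inconsistent table input."""


@dataclass
class AsvTable:
    """A samples x ASVs abundance matrix with a domain tag per ASV.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id, columns are ASV ids.  Raw tables
        hold non-negative integers; ``relative`` and ``css`` tables hold
        non-negative reals.
    domain_of_asv
        Series mapping every ASV id to ``"bacteria"`` or ``"eukaryote"``.
    kind
        One of ``raw_counts``, ``relative``, ``css``.
    """

    counts: pd.DataFrame
    domain_of_asv: pd.Series
    kind: str = "raw_counts"

    def __post_init__(self) -> None:
        if self.kind not in ("raw_counts", "relative", "css"):
            raise TableFormatError(f"unknown table kind {self.kind!r}")
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise TableFormatError(f"duplicate sample id(s): {dups}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise TableFormatError(f"duplicate ASV id(s): {dups}")
        vals = self.counts.to_numpy()
        if vals.size and (np.nanmin(vals) < 0 or np.isnan(vals).any()):
            raise TableFormatError("counts must be non-negative and non-missing")
        self.domain_of_asv = pd.Series(self.domain_of_asv)
        missing = self.counts.columns.difference(self.domain_of_asv.index)
        if len(missing):
            raise TableFormatError(f"ASV(s) without a domain tag: {missing.tolist()}")
        self.domain_of_asv = self.domain_of_asv.loc[self.counts.columns]
        bad = set(self.domain_of_asv.unique()) - set(DOMAINS)
        if bad:
            raise TableFormatError(f"unknown domain tag(s): {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> pd.Series:
        """Total count per sample."""
        return self.counts.sum(axis=1)

    def domain_columns(self, domain: str) -> list[str]:
        return list(self.counts.columns[self.domain_of_asv.to_numpy() == domain])

    def select_asvs(self, asv_ids) -> "AsvTable":
        return AsvTable(
            self.counts.loc[:, list(asv_ids)],
            self.domain_of_asv.loc[list(asv_ids)],
            self.kind,
        )

    def select_samples(self, sample_ids) -> "AsvTable":
        return AsvTable(
            self.counts.loc[list(sample_ids)], self.domain_of_asv, self.kind
        )


@dataclass
class TaxonomyTable:
    """Ranked lineages per ASV (domain, phylum, ..., genus)."""

    lineage_of_asv: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.lineage_of_asv.index.has_duplicates:
            dups = self.lineage_of_asv.index[
                self.lineage_of_asv.index.duplicated()
            ].tolist()
            raise TableFormatError(f"duplicate ASV id(s) in taxonomy: {dups}")

    def lineage_string(self, asv_id: str) -> str:
        if asv_id not in self.lineage_of_asv.index:
            raise KeyError(f"ASV {asv_id!r} missing from taxonomy")
        row = self.lineage_of_asv.loc[asv_id]
        return ";".join(str(v) for v in row if pd.notna(v))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_asv_table(path, domain_tag=None) -> AsvTable:
    """Read a TSV abundance table (samples as rows, ASVs as columns).

    ``domain_tag`` either assigns a single domain to every ASV, or is a
    mapping ASV id -> domain for mixed (merged) tables.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=None)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    if len(df):
        for col in df.columns:
            if not pd.api.types.is_numeric_dtype(df[col]):
                raise TableFormatError(
                    f"{path}: non-numeric values in ASV column {col!r}"
                )
    if domain_tag is None or isinstance(domain_tag, str):
        tag = domain_tag or "bacteria"
        domain = pd.Series(tag, index=df.columns)
    else:
        domain = pd.Series(domain_tag).loc[df.columns]
    kind = "raw_counts"
    arr = df.to_numpy()
    if arr.size and not np.allclose(arr, np.round(arr)):
        kind = "relative" if np.nanmax(arr) <= 1.0 + 1e-9 else "css"
    return AsvTable(df, domain, kind)


def write_asv_table(table: AsvTable, path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="sample_id")


def read_taxonomy(path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return TaxonomyTable(df)


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    tax.lineage_of_asv.to_csv(path, sep="\t", index_label="asv_id")


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata and validate ranges.

    Returns a DataFrame indexed by sample id with the columns in
    :data:`METADATA_COLUMNS` (extra columns are preserved).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].tolist()
        raise TableFormatError(f"duplicate sample id(s) in metadata: {dups}")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"metadata missing column(s): {missing}")
    return validate_metadata(df)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    for sid, sub in df["substrate"].items():
        if sub not in SUBSTRATES:
            raise TableFormatError(
                f"sample {sid!r}: unknown substrate {sub!r}"
            )
    if "sample_role" in df.columns:
        bad = set(df["sample_role"].unique()) - set(SAMPLE_ROLES)
        if bad:
            raise TableFormatError(f"unknown sample_role value(s): {sorted(bad)}")
    bounds = {"latitude": (-90.0, 90.0), "longitude": (-180.0, 180.0)}
    bounds.update(METADATA_VARIABLES)
    for col, (lo, hi) in bounds.items():
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            sid = df.index[vals.isna()][0]
            raise TableFormatError(f"sample {sid!r}: non-numeric {col!r}")
        if lo is not None and (vals < lo).any():
            sid = df.index[vals < lo][0]
            raise TableFormatError(
                f"sample {sid!r}: {col} = {vals[sid]} below {lo}"
            )
        if hi is not None and (vals > hi).any():
            sid = df.index[vals > hi][0]
            raise TableFormatError(
                f"sample {sid!r}: {col} = {vals[sid]} above {hi}"
            )
    return df


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def merge_domains(bac: AsvTable, euk: AsvTable) -> AsvTable:
    """Concatenate per-domain relative-abundance tables over shared samples.

    Both inputs must be ``relative`` tables (normalized within their own
    domain after per-domain rare-ASV filtering).  Columns are concatenated
    over the intersection of sample ids; within each sample the bacterial
    columns and the eukaryotic columns each sum to at most 1.
    """
    for name, t in (("bacterial", bac), ("eukaryotic", euk)):
        if t.kind != "relative":
            raise TableFormatError(
                f"{name} table must be relative (kind = {t.kind!r})"
            )
    shared = [s for s in bac.sample_ids if s in set(euk.sample_ids)]
    if not shared:
        raise TableFormatError("no samples shared between the two tables")
    overlap = set(bac.asv_ids) & set(euk.asv_ids)
    if overlap:
        raise TableFormatError(f"ASV id(s) present in both tables: {sorted(overlap)}")
    counts = pd.concat(
        [bac.counts.loc[shared], euk.counts.loc[shared]], axis=1
    )
    domain = pd.concat([bac.domain_of_asv, euk.domain_of_asv])
    return AsvTable(counts, domain, "relative")


# ---------------------------------------------------------------------------
# network exchange
# ---------------------------------------------------------------------------

NETWORK_FORMATS = ("graphml", "edge_list")


def write_network(net: nx.Graph, path, fmt: str = "graphml",
                  partition=None, metrics: pd.DataFrame | None = None) -> None:
    """Write a correlation network with node annotations.

    Node attributes written: domain, lineage (if present on the graph),
    module id (from ``partition``), degree and betweenness (from ``metrics``,
    a DataFrame indexed by node with those columns).  The edge attribute is
    the Spearman rho stored as ``weight``.
    """
    if fmt not in NETWORK_FORMATS:
        raise ValueError(
            f"unknown network format {fmt!r}; supported: {NETWORK_FORMATS}"
        )
    g = net.copy()
    if partition is not None:
        module_of = getattr(partition, "module_of_node", partition)
        nx.set_node_attributes(g, {n: int(module_of[n]) for n in g}, "module")
    if metrics is not None:
        for col in metrics.columns:
            nx.set_node_attributes(g, metrics[col].to_dict(), col)
    if fmt == "graphml":
        nx.write_graphml(g, path)
        return
    rows = [
        {"source": u, "target": v, "weight": d.get("weight", 1.0)}
        for u, v, d in g.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        path, index=False
    )


def read_edge_list(path) -> nx.Graph:
    """Re-read a CSV edge list written by :func:`write_network`."""
    df = pd.read_csv(path)
    g = nx.Graph()
    for _, row in df.iterrows():
        g.add_edge(str(row["source"]), str(row["target"]),
                   weight=float(row["weight"]))
    return g
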