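"""Reference expression panel: ingestion, filtering, ortholog mapping,
enrichment scoring and cell-type specificity classification.

The reference panel is a genes x cell-types matrix of fpkm values from
cell-sorted RNA-seq (e.g. the seven-cell-type mouse cerebral cortex panel:
neurons N, astrocytes A, microglia M, myelinating oligodendrocytes MO,
newly formed oligodendrocytes NFO, oligodendrocyte precursors OPC and
endothelial cells EC).

For each gene and cell type the enrichment score (ES) is the fpkm in that
cell type divided by the mean fpkm across all other cell types.  With
ES_high the maximum ES of the gene, a cell type is "high" when its
ES >= alpha_high * ES_high and "low" when ES <= alpha_low * ES_high
(defaults 0.75 and 0.25).  A gene is cell-specific when exactly one cell
type is high and all others are low, multiple-cell-specific when several
are high and the rest low, and mixed when at least one ES falls strictly
between the two bounds (or when every cell type is high, i.e. uniform
expression).  The three oligodendrocyte subtypes and their pairwise
combinations collapse into a pan-oligodendrocyte class O.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from eshrd.errors import DataValueError, FormatError, StructureError

logger = logging.getLogger("eshrd.panel")

#: Canonical cell-type order of the seven-cell-type reference panel.
REFERENCE_CELL_TYPES: tuple[str, ...] = ("N", "A", "M", "MO", "NFO", "OPC", "EC")

#: Oligodendrocyte subtypes collapsed into the pan-oligodendrocyte class.
OLIGO_SUBTYPES: frozenset[str] = frozenset({"MO", "NFO", "OPC"})

#: Pan-oligodendrocyte collapsed class label.
PAN_OLIGO = "O"

#: Sentinel label for genes that cannot be assigned to a small set of cells.
MIXED = "mixed"

#: Sentinel for genes absent from a classification table (used downstream).
UNCLASSIFIED = "UNCLASSIFIED"

Label = str | frozenset[str]  # MIXED sentinel or a non-empty set of cell types


# ---------------------------------------------------------------------------
# containers


@dataclass
class ExpressionPanel:
    """Genes x cell-types matrix of non-negative expression values (fpkm).

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier with one numeric column per
        cell type.
    namespace
        Tag of the gene-ID system, e.g. ``"mouse_symbol"`` or
        ``"human_ensembl"``.
    """

    values: pd.DataFrame
    namespace: str

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise StructureError(
                f"panel needs >= 2 cell-type columns, got {self.values.shape[1]}"
            )
        if self.values.columns.duplicated().any():
            raise StructureError("duplicate cell-type column labels")
        if self.values.index.duplicated().any():
            raise StructureError("duplicate gene rows; resolve before constructing")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise DataValueError("non-numeric expression values in panel")
        if np.isnan(arr).any() or (arr < 0).any():
            bad = np.argwhere(np.isnan(arr) | (arr < 0))[0]
            raise DataValueError(
                f"negative or missing expression at gene "
                f"{self.values.index[bad[0]]!r}, cell type "
                f"{self.values.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_types(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def content_hash(self) -> str:
        """SHA-256 over gene IDs, cell types and values (provenance)."""
        h = hashlib.sha256()
        h.update("\x00".join(map(str, self.values.index)).encode())
        h.update("\x00".join(map(str, self.values.columns)).encode())
        h.update(np.ascontiguousarray(self.values.to_numpy(dtype=float)).tobytes())
        return h.hexdigest()


@dataclass
class EnrichmentProfile:
    """Per-gene enrichment scores: one ES per cell type and their maximum."""

    gene_id: str
    es: dict[str, float]
    es_high: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not self.es:
            raise DataValueError(f"empty ES vector for gene {self.gene_id!r}")
        self.es_high = max(self.es.values())


@dataclass(frozen=True)
class CellClassLabel:
    """A gene's specificity class: MIXED or a non-empty set of cell types,
    plus the pan-oligodendrocyte collapsed view."""

    gene_id: str
    label: Label
    collapsed_label: Label


@dataclass
class ClassificationTable:
    """Gene -> specificity class mapping with the thresholds that produced it.

    ``df`` is indexed by gene_id with columns ``label`` and
    ``collapsed_label`` holding formatted label strings (multi-cell sets
    slash-joined in canonical cell order, MIXED spelled ``mixed``).
    """

    df: pd.DataFrame
    cell_types: tuple[str, ...]
    floor: float
    alpha_low: float
    alpha_high: float
    panel_hash: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.alpha_low < self.alpha_high <= 1:
            raise DataValueError(
                f"need 0 < alpha_low < alpha_high <= 1, got "
                f"({self.alpha_low}, {self.alpha_high})"
            )
        if self.df.index.duplicated().any():
            raise StructureError("duplicate gene_id in classification table")

    def __len__(self) -> int:
        return len(self.df)

    def collapsed_labels(self) -> dict[str, str]:
        """gene_id -> collapsed label string (the downstream join key)."""
        return self.df["collapsed_label"].to_dict()

    def class_proportions(self, collapsed: bool = True) -> pd.Series:
        """Fraction of classified genes per (collapsed) class; sums to 1."""
        col = "collapsed_label" if collapsed else "label"
        return self.df[col].value_counts(normalize=True).sort_index()

    def to_tsv(self, path) -> None:
        out = self.df.reset_index()
        out.columns = ["gene_id", "label", "collapsed_label"]
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, floor: float = 0.1, alpha_low: float = 0.25,
                 alpha_high: float = 0.75) -> "ClassificationTable":
        # keep_default_na: the {N, A} label serializes as "N/A"
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        for col in ("gene_id", "label", "collapsed_label"):
            if col not in df.columns:
                raise FormatError(f"classification TSV missing column {col!r}")
        df = df.set_index("gene_id")
        cells = _cells_from_labels(df["label"])
        return cls(df=df, cell_types=cells, floor=floor,
                   alpha_low=alpha_low, alpha_high=alpha_high)


def _cells_from_labels(labels: pd.Series) -> tuple[str, ...]:
    cells: list[str] = []
    for lab in labels:
        if lab == MIXED:
            continue
        for c in lab.split("/"):
            if c not in cells:
                cells.append(c)
    return tuple(cells)


def format_label(label: Label, cell_order: Sequence[str]) -> str:
    """Serialize a label: MIXED -> ``mixed``; sets slash-joined in
    canonical cell order (e.g. ``MO/NFO``)."""
    if label == MIXED:
        return MIXED
    order = {c: i for i, c in enumerate(cell_order)}
    return "/".join(sorted(label, key=lambda c: order.get(c, len(order))))


def parse_label(text: str) -> Label:
    return MIXED if text == MIXED else frozenset(text.split("/"))


def collapsed_cell_order(cell_order: Sequence[str]) -> tuple[str, ...]:
    """Cell order with the oligodendrocyte subtypes replaced by O (once,
    at the position of the first subtype)."""
    out: list[str] = []
    for c in cell_order:
        if c in OLIGO_SUBTYPES:
            if PAN_OLIGO not in out:
                out.append(PAN_OLIGO)
        else:
            out.append(c)
    return tuple(out)


# ---------------------------------------------------------------------------
# ingestion


def load_expression_panel(path, namespace: str,
                          gene_id_column: str | None = None) -> ExpressionPanel:
    """Read a panel TSV (header ``gene_id<TAB><cell1><TAB>...``).

    Duplicate gene rows are resolved by per-column arithmetic mean with a
    logged warning.  Negative or non-numeric values raise
    :class:`DataValueError` naming the offending row and column.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.columns.size < 2:
        raise StructureError("panel needs a gene-ID column and >= 2 cell types")
    if any(str(c).startswith("Unnamed") for c in df.columns):
        raise FormatError(f"{path}: malformed or missing header row")
    gene_col = gene_id_column or df.columns[0]
    if gene_col not in df.columns:
        raise FormatError(f"{path}: gene-ID column {gene_col!r} not found")
    cell_cols = [c for c in df.columns if c != gene_col]
    if len(cell_cols) < 2:
        raise StructureError(
            f"{path}: fewer than 2 cell-type columns ({len(cell_cols)})"
        )
    values = pd.DataFrame(index=df[gene_col].astype(str))
    for col in cell_cols:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() | (parsed < 0)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataValueError(
                f"{path}: negative or non-numeric value {df[col].iloc[i]!r} "
                f"at row {i + 2} (gene {df[gene_col].iloc[i]!r}), column {col!r}"
            )
        values[col] = parsed.to_numpy()

    n_dup = int(values.index.duplicated().sum())
    if n_dup:
        logger.warning(
            "%s: %d duplicate gene row(s) averaged per column", path, n_dup
        )
        values = values.groupby(level=0, sort=False).mean()

    logger.info("%s: loaded %d genes x %d cell types", path, *values.shape)
    return ExpressionPanel(values=values, namespace=namespace)


def load_ortholog_map(path) -> pd.DataFrame:
    """Read an ortholog map TSV (header ``source_id<TAB>target_id``).

    Exact duplicate pairs are dropped; empty IDs rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("source_id", "target_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: ortholog map missing column {col!r}")
    df = df[["source_id", "target_id"]].astype(str)
    if (df["source_id"].str.len() == 0).any() or (df["target_id"].str.len() == 0).any():
        raise DataValueError(f"{path}: empty ID in ortholog map")
    return df.drop_duplicates(ignore_index=True)


# ---------------------------------------------------------------------------
# filtering and mapping


def filter_low_expression(panel: ExpressionPanel, floor: float = 0.1) -> ExpressionPanel:
    """Drop genes whose expression is at or below ``floor`` in every cell type.

    The floor (default 0.1 fpkm) is the panel's detection floor: a gene at
    the floor everywhere is unexpressed and would only add false-positive
    noise to the specificity assessment.
    """
    if floor <= 0:
        raise DataValueError(f"floor must be > 0, got {floor}")
    keep = (panel.values > floor).any(axis=1)
    n_removed = int((~keep).sum())
    if not keep.any():
        raise DataValueError(
            f"floor filter at {floor} removed every gene "
            "(wrong units or wrong floor?)"
        )
    logger.info(
        "floor filter at %g: removed %d genes, retained %d",
        floor, n_removed, int(keep.sum()),
    )
    return ExpressionPanel(values=panel.values.loc[keep], namespace=panel.namespace)


def map_orthologs(panel: ExpressionPanel, omap: pd.DataFrame,
                  target_namespace: str = "human_ensembl") -> ExpressionPanel:
    """Translate the panel into the target gene-ID namespace.

    Mapping policy:

    * unmapped source genes are dropped (logged);
    * many-to-many entries (a source with several targets where any of
      those targets is also hit by another source) are dropped entirely —
      the ambiguity cannot be resolved without external evidence;
    * one-to-many: the source row is duplicated under each target ID;
    * many-to-one: colliding source rows are averaged per column.
    """
    pairs = omap.drop_duplicates()
    pairs = pairs[pairs["source_id"].isin(panel.values.index)]

    src_out = pairs.groupby("source_id")["target_id"].nunique()
    tgt_in = pairs.groupby("target_id")["source_id"].nunique()
    ambiguous_pair = (
        (pairs["source_id"].map(src_out) > 1)
        & (pairs["target_id"].map(tgt_in) > 1)
    )
    ambiguous_sources = set(pairs.loc[ambiguous_pair, "source_id"])
    if ambiguous_sources:
        logger.info(
            "dropping %d ambiguously mapped (many-to-many) source genes",
            len(ambiguous_sources),
        )
        pairs = pairs[~pairs["source_id"].isin(ambiguous_sources)]

    n_unmapped = panel.n_genes - pairs["source_id"].nunique() - len(
        ambiguous_sources & set(panel.values.index)
    )
    if n_unmapped:
        logger.info("%d panel genes absent from ortholog map, dropped", n_unmapped)

    if pairs.empty:
        raise DataValueError(
            "zero genes mapped: ortholog-map namespace likely does not match panel"
        )

    expanded = panel.values.loc[pairs["source_id"]].set_index(
        pairs["target_id"].to_numpy()
    )
    mapped = expanded.groupby(level=0, sort=False).mean()
    n_collisions = len(expanded) - len(mapped)
    if n_collisions:
        logger.warning(
            "%d many-to-one ortholog collisions averaged per column", n_collisions
        )
    logger.info("ortholog mapping: %d target genes in namespace %s",
                len(mapped), target_namespace)
    return ExpressionPanel(values=mapped, namespace=target_namespace)


# ---------------------------------------------------------------------------
# enrichment scores and classification


def enrichment_score_frame(panel: ExpressionPanel, floor: float = 0.1) -> pd.DataFrame:
    """ES matrix (genes x cell types).

    ES_c(g) = x_c(g) / mean_{c' != c} x_{c'}(g).  Values below ``floor``
    are raised to the floor first, so denominators are strictly positive;
    the panel must already be floor-filtered (every gene has at least one
    value above the floor).
    """
    x = panel.values.clip(lower=floor).to_numpy(dtype=float)
    if (x <= 0).any():
        raise DataValueError("non-positive expression after flooring")
    k = x.shape[1]
    if k < 2:
        raise StructureError("ES needs >= 2 cell types")
    other_mean = (x.sum(axis=1, keepdims=True) - x) / (k - 1)
    es = x / other_mean
    return pd.DataFrame(es, index=panel.values.index, columns=panel.values.columns)


def compute_enrichment_scores(panel: ExpressionPanel,
                              floor: float = 0.1) -> list[EnrichmentProfile]:
    """One :class:`EnrichmentProfile` per gene (see :func:`enrichment_score_frame`)."""
    es = enrichment_score_frame(panel, floor=floor)
    cols = list(es.columns)
    return [
        EnrichmentProfile(gene_id=str(g), es=dict(zip(cols, row)))
        for g, row in zip(es.index, es.to_numpy())
    ]


def classify_gene(profile: EnrichmentProfile | Mapping[str, float],
                  alpha_low: float = 0.25,
                  alpha_high: float = 0.75,
                  gene_id: str | None = None) -> CellClassLabel:
    """Assign a gene its cell-type specificity class from its ES vector.

    With H = {c : ES_c >= alpha_high * ES_high} and
    L = {c : ES_c <= alpha_low * ES_high}: if H and L together cover all
    cell types the label is H (cell-specific when |H| = 1, multiple-cell-
    specific when |H| > 1, relabeled MIXED when H is the full set);
    otherwise some ES lies strictly inside the open band and the gene is
    MIXED.  Boundary values belong to H/L, making the classes a partition.
    """
    if isinstance(profile, EnrichmentProfile):
        es = profile.es
        gid = profile.gene_id
    else:
        es = dict(profile)
        gid = gene_id if gene_id is not None else ""
    if not 0 < alpha_low < alpha_high <= 1:
        raise DataValueError(
            f"need 0 < alpha_low < alpha_high <= 1, got ({alpha_low}, {alpha_high})"
        )
    es_high = max(es.values())
    if es_high <= 0:
        raise DataValueError(f"gene {gid!r}: ES_high must be > 0")
    high = frozenset(c for c, v in es.items() if v >= alpha_high * es_high)
    low = frozenset(c for c, v in es.items() if v <= alpha_low * es_high)
    if high | low == set(es):
        label: Label = MIXED if high == set(es) else high
    else:
        label = MIXED
    return CellClassLabel(gene_id=gid, label=label,
                          collapsed_label=_collapse(label))


def _collapse(label: Label) -> Label:
    if label == MIXED:
        return MIXED
    if label <= OLIGO_SUBTYPES:
        return frozenset({PAN_OLIGO})
    if label & OLIGO_SUBTYPES:
        return frozenset({PAN_OLIGO}) | (label - OLIGO_SUBTYPES)
    return label


def collapse_oligo(label: CellClassLabel,
                   known_cells: Iterable[str] = REFERENCE_CELL_TYPES) -> CellClassLabel:
    """Collapse oligodendrocyte subtypes (MO, NFO, OPC and combinations)
    into the pan-oligodendrocyte class O.

    A label wholly inside the subtypes becomes the O singleton; subtypes
    inside a set with other cells are collectively renamed O within the
    set; MIXED and oligo-free labels are unchanged.
    """
    lab = label.label
    if lab != MIXED:
        unknown = set(lab) - set(known_cells)
        if unknown:
            raise DataValueError(f"unknown cell-type label(s): {sorted(unknown)}")
    return CellClassLabel(gene_id=label.gene_id, label=lab,
                          collapsed_label=_collapse(lab))


def build_classification(panel: ExpressionPanel,
                         omap: pd.DataFrame | None = None,
                         floor: float = 0.1,
                         alpha_low: float = 0.25,
                         alpha_high: float = 0.75) -> ClassificationTable:
    """Full reference pipeline: floor-filter, (optionally) map orthologs,
    score, classify, collapse.  Returns a table covering every retained gene.
    """
    if panel.n_genes == 0:
        raise DataValueError("empty panel")
    filtered = filter_low_expression(panel, floor=floor)
    if omap is not None:
        filtered = map_orthologs(filtered, omap)
    es = enrichment_score_frame(filtered, floor=floor)
    cell_order = tuple(es.columns)
    collapsed_order = collapsed_cell_order(cell_order)

    labels: list[str] = []
    collapsed: list[str] = []
    cols = list(es.columns)
    for row in es.to_numpy():
        lab = classify_gene(dict(zip(cols, row)),
                            alpha_low=alpha_low, alpha_high=alpha_high)
        labels.append(format_label(lab.label, cell_order))
        collapsed.append(format_label(lab.collapsed_label, collapsed_order))

    df = pd.DataFrame(
        {"label": labels, "collapsed_label": collapsed}, index=es.index
    )
    table = ClassificationTable(
        df=df, cell_types=cell_order, floor=floor,
        alpha_low=alpha_low, alpha_high=alpha_high,
        panel_hash=filtered.content_hash(),
    )
    props = table.class_proportions()
    logger.info(
        "classified %d genes; class proportions: %s",
        len(table),
        ", ".join(f"{c}={p:.1%}" for c, p in props.items()),
    )
    return table
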