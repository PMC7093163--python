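"""Join bulk differential-expression results with the specificity
classification and summarize class prevalence and direction per dataset."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from eshrd.errors import DataValueError, FormatError
from eshrd.panel import UNCLASSIFIED, ClassificationTable

logger = logging.getLogger("eshrd.deg")

#: Canonical column names of a DE table.
DE_COLUMNS = ("gene_id", "log2fc", "pvalue", "fdr")


@dataclass(frozen=True)
class DERecord:
    """One gene's differential-expression result in a named dataset/region."""

    gene_id: str
    log2fc: float
    pvalue: float
    fdr: float
    dataset: str


@dataclass
class ClassifiedDEGSummary:
    """Per-class DEG counts and direction for one dataset.

    ``table`` has one row per collapsed class with columns ``n`` (DEG
    count), ``n_up`` (log2fc > 0), ``pct_up`` and ``prevalence_pct``
    (share of classified DEGs; UNCLASSIFIED genes are excluded from the
    denominator and counted separately).
    """

    dataset: str
    table: pd.DataFrame
    n_classified: int
    n_unclassified: int


def validate_de_frame(df: pd.DataFrame, source: str = "DE table") -> pd.DataFrame:
    """Contract checks on a canonical-column DE frame."""
    for col in DE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{source}: missing required column {col!r}")
    out = df.copy()
    out["gene_id"] = out["gene_id"].astype(str)
    for col in ("log2fc", "pvalue", "fdr"):
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = vals.isna()
        if col == "log2fc":
            bad |= ~np.isfinite(vals.fillna(0.0))
        else:
            bad |= (vals < 0) | (vals > 1)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataValueError(
                f"{source}: invalid {col} value {out[col].iloc[i]!r} at row "
                f"{i + 2} (gene {out['gene_id'].iloc[i]!r})"
            )
        out[col] = vals
    dup = out["gene_id"].duplicated()
    if dup.any():
        raise DataValueError(
            f"{source}: duplicate gene_id {out.loc[dup, 'gene_id'].iloc[0]!r} "
            "(ambiguous)"
        )
    return out


def load_de_results(path, dataset: str,
                    column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a DE result TSV into canonical columns.

    ``column_map`` renames alternative headers to the canonical names,
    e.g. ``{"ensembl_gene_id": "gene_id", "logFC": "log2fc",
    "P.Value": "pvalue", "adj.P.Val": "fdr"}``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if column_map:
        df = df.rename(columns=column_map)
    df = validate_de_frame(df, source=str(path))
    df = df[list(DE_COLUMNS)]
    df["dataset"] = dataset
    logger.info("%s: loaded %d DE records for dataset %s", path, len(df), dataset)
    return df


def filter_degs(records: pd.DataFrame, fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Keep records with FDR strictly below the threshold (DEG selection)."""
    if not 0 < fdr_threshold <= 1:
        raise DataValueError(f"fdr_threshold must be in (0, 1], got {fdr_threshold}")
    return records.loc[records["fdr"] < fdr_threshold].copy()


def annotate_degs(degs: pd.DataFrame,
                  classification: ClassificationTable | dict[str, str]) -> pd.DataFrame:
    """Attach the collapsed class label to each DEG.

    Genes absent from the classification table get the UNCLASSIFIED
    sentinel.
    """
    labels = (classification.collapsed_labels()
              if isinstance(classification, ClassificationTable)
              else classification)
    out = degs.copy()
    out["label"] = out["gene_id"].map(labels).fillna(UNCLASSIFIED)
    n_un = int((out["label"] == UNCLASSIFIED).sum())
    logger.info("annotated %d DEGs: %d classified, %d unclassified",
                len(out), len(out) - n_un, n_un)
    return out


def summarize_classes(annotated: pd.DataFrame, dataset: str) -> ClassifiedDEGSummary:
    """Per-class prevalence and direction-of-change summary.

    ``pct_up`` is the percentage of DEGs in the class with log2fc > 0
    (exactly 0 counts as not-up); ``prevalence_pct`` is the class share of
    classified DEGs.  Empty classes are omitted; an all-UNCLASSIFIED input
    yields an empty table.
    """
    classified = annotated.loc[annotated["label"] != UNCLASSIFIED]
    n_unclassified = len(annotated) - len(classified)
    rows = []
    total = len(classified)
    for label, grp in classified.groupby("label", sort=True):
        n = len(grp)
        n_up = int((grp["log2fc"] > 0).sum())
        rows.append({
            "dataset": dataset,
            "class": label,
            "n": n,
            "n_up": n_up,
            "pct_up": 100.0 * n_up / n if n else np.nan,
            "prevalence_pct": 100.0 * n / total if total else np.nan,
        })
    table = pd.DataFrame(
        rows, columns=["dataset", "class", "n", "n_up", "pct_up", "prevalence_pct"]
    )
    return ClassifiedDEGSummary(dataset=dataset, table=table,
                                n_classified=total, n_unclassified=n_unclassified)
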