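"""Validate homogenate-derived cell-specific DE calls against an
independent cell-resolved DE table (LCM- or snRNA-seq-style).

Two comparisons are supported: an FDR sweep (cutoffs from 0.05 to 1.00 in
0.001 steps, sign concordance and Spearman rank correlation of the log2
fold-changes among overlapping focal-class genes at each cutoff) and a
|log2FC|-cutoff comparison with no p-value filter (cutoffs 0, 0.25, 0.50,
1.00), where points with fewer than 10 overlapping genes are flagged as
low-support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from eshrd.errors import DataValueError
from eshrd.panel import ClassificationTable

logger = logging.getLogger("eshrd.concordance")

#: Points with fewer overlapping genes than this are flagged low-support.
LOW_SUPPORT_N = 10


@dataclass
class ConcordancePoint:
    """Concordance metrics at one cutoff of the sweep."""

    cutoff: float
    n_overlap: int
    concordance_pct: float  # NaN when undefined (no sign-comparable pairs)
    rho: float              # NaN when n_overlap < 3 or a vector is constant
    rho_p: float
    low_support: bool = False


def sign_concordance(lfc_a: Sequence[float], lfc_b: Sequence[float]) -> float:
    """Percentage of gene pairs whose log2 fold-changes agree in sign.

    Pairs where either value is exactly 0 have no sign and are excluded
    from the denominator; returns NaN when no comparable pair remains.
    """
    a = np.asarray(lfc_a, dtype=float)
    b = np.asarray(lfc_b, dtype=float)
    if a.shape != b.shape:
        raise DataValueError(f"length mismatch: {a.shape} vs {b.shape}")
    valid = (a != 0) & (b != 0)
    if not valid.any():
        return float("nan")
    same = np.sign(a[valid]) == np.sign(b[valid])
    return 100.0 * same.mean()


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with two-sided p.

    Returns (NaN, NaN) for constant vectors, where the correlation is
    undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise DataValueError(f"need >= 3 paired values, got {x.size}")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def _class_genes(classification: ClassificationTable | dict[str, str],
                 cell_class: str) -> set[str]:
    labels = (classification.collapsed_labels()
              if isinstance(classification, ClassificationTable)
              else classification)
    genes = {g for g, lab in labels.items() if lab == cell_class}
    if not genes:
        raise DataValueError(
            f"class {cell_class!r} absent from the classification"
        )
    return genes


def _point(de_a: pd.DataFrame, de_b: pd.DataFrame, genes: set[str],
           cutoff: float) -> ConcordancePoint:
    a = de_a[de_a["gene_id"].isin(genes)].set_index("gene_id")["log2fc"]
    b = de_b[de_b["gene_id"].isin(genes)].set_index("gene_id")["log2fc"]
    shared = a.index.intersection(b.index)
    n = len(shared)
    if n == 0:
        return ConcordancePoint(cutoff, 0, float("nan"), float("nan"),
                                float("nan"), low_support=True)
    va, vb = a.loc[shared].to_numpy(), b.loc[shared].to_numpy()
    conc = sign_concordance(va, vb)
    rho, rho_p = (spearman_rho(va, vb) if n >= 3
                  else (float("nan"), float("nan")))
    return ConcordancePoint(cutoff, n, conc, rho, rho_p,
                            low_support=n < LOW_SUPPORT_N)


def fdr_grid(start: float = 0.05, end: float = 1.00,
             step: float = 0.001) -> np.ndarray:
    """Inclusive cutoff grid; the default spans 0.05..1.00 in 951 points."""
    n = int(round((end - start) / step)) + 1
    return start + step * np.arange(n)


def concordance_sweep(de_a: pd.DataFrame, de_b: pd.DataFrame,
                      classification: ClassificationTable | dict[str, str],
                      cell_class: str,
                      grid_start: float = 0.05, grid_end: float = 1.00,
                      grid_step: float = 0.001,
                      filter_side: str = "both") -> list[ConcordancePoint]:
    """Sign concordance and Spearman rho of focal-class log2FC across an
    FDR-cutoff grid.

    At each cutoff f, tables are restricted to genes with fdr < f (strict;
    applied to both tables by default, or to side "a"/"b" only) and to
    genes of ``cell_class``; metrics are computed on the intersection.
    """
    if filter_side not in ("both", "a", "b"):
        raise DataValueError(f"filter_side must be both/a/b, got {filter_side!r}")
    genes = _class_genes(classification, cell_class)
    points = []
    for cutoff in fdr_grid(grid_start, grid_end, grid_step):
        sub_a = de_a[de_a["fdr"] < cutoff] if filter_side in ("both", "a") else de_a
        sub_b = de_b[de_b["fdr"] < cutoff] if filter_side in ("both", "b") else de_b
        points.append(_point(sub_a, sub_b, genes, float(cutoff)))
    logger.info("FDR sweep %s: %d points, class %s",
                f"{grid_start}..{grid_end}", len(points), cell_class)
    return points


def lfc_cutoff_concordance(de_a: pd.DataFrame, de_b: pd.DataFrame,
                           classification: ClassificationTable | dict[str, str],
                           cell_class: str,
                           lfc_cutoffs: Sequence[float] = (0.0, 0.25, 0.50, 1.00),
                           fdr_a: float = 0.05) -> list[ConcordancePoint]:
    """Concordance at |log2FC| cutoffs on table b, with no p-value filter
    on b (snRNA-seq-style comparison).

    Table a contributes its DEGs (fdr < ``fdr_a``) of the focal class;
    at each cutoff L table b is restricted to |log2fc| >= L.  Points with
    fewer than 10 overlapping genes are flagged low-support, not removed.
    """
    genes = _class_genes(classification, cell_class)
    sub_a = de_a[de_a["fdr"] < fdr_a]
    points = []
    for L in lfc_cutoffs:
        sub_b = de_b[de_b["log2fc"].abs() >= L]
        points.append(_point(sub_a, sub_b, genes, float(L)))
    return points


def points_to_frame(points: Sequence[ConcordancePoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"cutoff": p.cutoff, "n_overlap": p.n_overlap,
          "concordance_pct": p.concordance_pct, "rho": p.rho,
          "rho_p": p.rho_p, "low_support": p.low_support}
         for p in points]
    )
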