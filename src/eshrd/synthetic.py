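"""Synthetic reference panels and DE tables with known ground truth.

The panel generator plants genes of each specificity class on a constant
fpkm background:

* cell-specific genes carry ``specificity_fold`` x background in one cell;
* multiple-cell-specific genes carry the fold in each member cell;
* mixed genes carry the fold in one cell plus a second cell placed so its
  enrichment score sits at exactly half of ES_high — the interior of the
  mixed band for the default 0.25/0.75 thresholds.

Multiplicative log-normal noise (coefficient of variation ``noise_cv``)
emulates scale-proportional expression noise; values are floored at the
panel's detection floor.  The DE generator draws a DEG set from the
classified genes (optionally enriched for chosen classes), plants
per-class direction probabilities and effect sizes, gives non-DEGs
uniform null p-values, and computes the FDR column with the
Benjamini-Hochberg step-up rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from eshrd.errors import DataValueError
from eshrd.panel import MIXED, REFERENCE_CELL_TYPES, ExpressionPanel

#: Default planted class mix: mixed dominates, as in brain reference panels.
DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "N": 0.04, "A": 0.04, "M": 0.04, "EC": 0.04,
    "MO": 0.03, "NFO": 0.03, "OPC": 0.03,
    "MO/NFO": 0.05,
    MIXED: 0.70,
}


@dataclass
class PanelScenario:
    """Stated world for a synthetic reference panel."""

    n_genes: int = 1000
    cell_types: tuple[str, ...] = REFERENCE_CELL_TYPES
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    specificity_fold: float = 50.0
    noise_cv: float = 0.2
    background: float = 1.0
    floor: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise DataValueError(f"class proportions sum to {total}, expected 1")
        if self.specificity_fold <= 1:
            raise DataValueError("specificity_fold must be > 1")
        if self.noise_cv < 0:
            raise DataValueError("noise_cv must be >= 0")
        cells = set(self.cell_types)
        for label in self.class_proportions:
            if label == MIXED:
                continue
            unknown = set(label.split("/")) - cells
            if unknown:
                raise DataValueError(
                    f"class label {label!r} uses unknown cell type(s) {unknown}"
                )


@dataclass
class DEScenario:
    """Stated world for a synthetic differential-expression table."""

    truth_labels: Mapping[str, str]  # gene_id -> class label (ground truth)
    n_degs: int = 200
    up_probability: Mapping[str, float] | float = 0.5
    lfc_mean: float = 1.0
    lfc_sd: float = 0.5
    null_lfc_sd: float = 0.2
    class_enrichment: Mapping[str, float] | None = None
    dataset: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_degs > len(self.truth_labels):
            raise DataValueError("n_degs exceeds number of genes")
        probs = (self.up_probability.values()
                 if isinstance(self.up_probability, Mapping)
                 else [self.up_probability])
        if any(not 0 <= p <= 1 for p in probs):
            raise DataValueError("up_probability must be in [0, 1]")

    def up_prob(self, label: str) -> float:
        if isinstance(self.up_probability, Mapping):
            return self.up_probability.get(label, 0.5)
        return self.up_probability


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise DataValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _apportion(n: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n genes across classes."""
    labels = list(proportions)
    exact = np.array([proportions[c] * n for c in labels])
    counts = np.floor(exact).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(exact - counts)[::-1]
    for i in order[:remainder]:
        counts[i] += 1
    return dict(zip(labels, counts))


def _mixed_intermediate(focal: float, background: float, n_cells: int,
                        ratio: float = 0.5) -> float:
    """Second-cell value whose ES is ``ratio`` x the focal cell's ES.

    Solves m^2 + c m - ratio * A (A + c) = 0 with A the focal value and
    c = (n_cells - 2) * background.
    """
    c = (n_cells - 2) * background
    return (-c + math.sqrt(c * c + 4 * ratio * focal * (focal + c))) / 2


def generate_panel(scenario: PanelScenario) -> tuple[ExpressionPanel, dict[str, str]]:
    """Build a synthetic panel; returns (panel, gene -> planted label).

    With ``noise_cv = 0`` the construction is exact: classification at the
    default thresholds recovers every planted label.
    """
    rng = np.random.default_rng(scenario.seed)
    cells = list(scenario.cell_types)
    n_cells = len(cells)
    counts = _apportion(scenario.n_genes, scenario.class_proportions)
    bg = scenario.background
    focal = scenario.specificity_fold * bg

    gene_ids: list[str] = []
    truth: dict[str, str] = {}
    rows: list[np.ndarray] = []
    g = 0
    for label, n in counts.items():
        for _ in range(n):
            gid = f"gene{g:05d}"
            g += 1
            vals = np.full(n_cells, bg, dtype=float)
            if label == MIXED:
                # anchor cell + interior cell chosen at random
                i, j = rng.choice(n_cells, size=2, replace=False)
                vals[i] = focal
                vals[j] = _mixed_intermediate(focal, bg, n_cells)
            else:
                for cell in label.split("/"):
                    vals[cells.index(cell)] = focal
            gene_ids.append(gid)
            truth[gid] = label
            rows.append(vals)

    values = np.array(rows)
    if scenario.noise_cv > 0:
        sigma = math.sqrt(math.log(1 + scenario.noise_cv ** 2))
        noise = rng.lognormal(mean=-sigma * sigma / 2, sigma=sigma,
                              size=values.shape)
        values = values * noise
    values = np.maximum(values, scenario.floor)

    df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                      columns=cells)
    return ExpressionPanel(values=df, namespace="synthetic"), truth


def generate_de_table(scenario: DEScenario) -> pd.DataFrame:
    """Build a synthetic DE table with truth flags.

    Returns a frame with canonical DE columns plus ``is_deg`` and
    ``true_direction`` (+1 up, -1 down, 0 for non-DEGs).  DEG p-values are
    drawn from Beta(0.05, 1) so nearly all planted DEGs survive BH
    selection at FDR < 0.05; non-DEG p-values are uniform.
    """
    rng = np.random.default_rng(scenario.seed)
    genes = list(scenario.truth_labels)
    labels = np.array([scenario.truth_labels[g] for g in genes])
    n = len(genes)

    weights = np.ones(n)
    if scenario.class_enrichment:
        for cls, w in scenario.class_enrichment.items():
            weights[labels == cls] = w
    weights = weights / weights.sum()
    deg_idx = rng.choice(n, size=scenario.n_degs, replace=False, p=weights)
    is_deg = np.zeros(n, dtype=bool)
    is_deg[deg_idx] = True

    log2fc = rng.normal(0.0, scenario.null_lfc_sd, size=n)
    pvalue = rng.uniform(0.0, 1.0, size=n)
    direction = np.zeros(n, dtype=int)
    for i in deg_idx:
        up = rng.random() < scenario.up_prob(labels[i])
        direction[i] = 1 if up else -1
        magnitude = abs(rng.normal(scenario.lfc_mean, scenario.lfc_sd))
        log2fc[i] = direction[i] * magnitude
        pvalue[i] = rng.beta(0.05, 1.0)

    return pd.DataFrame({
        "gene_id": genes,
        "log2fc": log2fc,
        "pvalue": pvalue,
        "fdr": bh_fdr(pvalue),
        "dataset": scenario.dataset,
        "is_deg": is_deg,
        "true_direction": direction,
    })
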