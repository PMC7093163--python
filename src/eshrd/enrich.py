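"""Permutation test for over-representation of a cell class among DEGs.

For each dataset and cell class, the observed number of DEGs carrying the
class is compared with a null distribution built by repeatedly (default
50,000 times) drawing |DEG set| genes without replacement from the gene
universe and counting class members.  Enrichment is significant when the
observed count exceeds the resampled count in at least 95% of
permutations; the empirical p-value carries the +1 correction so it is
never exactly zero.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from eshrd.errors import DataValueError
from eshrd.panel import UNCLASSIFIED

logger = logging.getLogger("eshrd.enrich")

#: Fraction of permutations the observed count must exceed for significance.
SIGNIFICANCE_FRACTION = 0.95

#: Default number of permutations.
DEFAULT_N_PERM = 50_000


@dataclass
class PermutationResult:
    """Outcome of one class-enrichment permutation test."""

    dataset: str
    cell_class: str
    observed: int
    n_perm: int
    null_counts: np.ndarray = field(repr=False)  # histogram: index = count
    null_mean: float = 0.0
    null_sd: float = 0.0
    empirical_p: float = 1.0
    significant: bool = False
    seed: int = 0

    def as_row(self) -> dict:
        return {
            "dataset": self.dataset,
            "class": self.cell_class,
            "observed": self.observed,
            "expected_mean": self.null_mean,
            "empirical_p": self.empirical_p,
            "significant": self.significant,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


def _null_counts(class_flags: np.ndarray, k: int, n_perm: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Counts of focal-class members in n_perm draws of k genes without
    replacement, vectorized in chunks."""
    n = class_flags.size
    counts = np.empty(n_perm, dtype=np.int64)
    chunk = max(1, min(n_perm, 8_000_000 // n))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        keys = rng.random((m, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        counts[done:done + m] = class_flags[idx].sum(axis=1)
        done += m
    return counts


def permutation_enrichment(universe_labels: Mapping[str, str],
                           deg_gene_ids: Iterable[str],
                           cell_class: str,
                           n_perm: int = DEFAULT_N_PERM,
                           seed: int = 0,
                           dataset: str = "") -> PermutationResult:
    """Permutation enrichment test of ``cell_class`` among the DEG set.

    Parameters
    ----------
    universe_labels
        gene_id -> collapsed class label for every gene in the universe
        (typically: all classified genes measurable in the DE dataset).
    deg_gene_ids
        The DEG set; must be a subset of the universe.
    """
    degs = set(deg_gene_ids)
    if not degs:
        raise DataValueError("empty DEG set")
    universe = list(universe_labels)
    if not universe:
        raise DataValueError("empty universe")
    missing = degs - set(universe)
    if missing:
        raise DataValueError(
            f"{len(missing)} DEG(s) not in universe (e.g. {sorted(missing)[0]!r})"
        )
    if len(degs) > len(universe):
        raise DataValueError("DEG set larger than universe")

    labels = np.array([universe_labels[g] for g in universe])
    class_flags = (labels == cell_class)
    if not class_flags.any():
        raise DataValueError(f"universe contains no gene of class {cell_class!r}")
    observed = sum(1 for g in degs if universe_labels[g] == cell_class)

    rng = np.random.default_rng(seed)
    counts = _null_counts(class_flags.astype(np.int8), len(degs), n_perm, rng)

    empirical_p = (1 + int((counts >= observed).sum())) / (n_perm + 1)
    significant = (counts < observed).mean() >= SIGNIFICANCE_FRACTION
    hist = np.bincount(counts, minlength=observed + 1)
    return PermutationResult(
        dataset=dataset, cell_class=cell_class, observed=observed,
        n_perm=n_perm, null_counts=hist,
        null_mean=float(counts.mean()), null_sd=float(counts.std(ddof=1)),
        empirical_p=empirical_p, significant=bool(significant), seed=seed,
    )


def derive_class_seed(master_seed: int, cell_class: str) -> int:
    """Deterministic per-class sub-seed; adding a class never perturbs the
    draws of another."""
    ss = np.random.SeedSequence([master_seed, zlib.crc32(cell_class.encode())])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def enrichment_scan(annotated_degs: pd.DataFrame,
                    universe_labels: Mapping[str, str],
                    classes: Sequence[str] | None = None,
                    n_perm: int = DEFAULT_N_PERM,
                    seed: int = 0,
                    dataset: str = "") -> list[PermutationResult]:
    """Run :func:`permutation_enrichment` for each cell class of one dataset.

    The DEG set is every gene of ``annotated_degs`` that is present in the
    universe (UNCLASSIFIED genes are outside the universe by construction
    and are ignored).  Per-class seeds are derived from the master seed
    and the class name.
    """
    deg_ids = [g for g in annotated_degs["gene_id"].astype(str)
               if g in universe_labels]
    if classes is None:
        classes = sorted({c for c in universe_labels.values()
                          if c != UNCLASSIFIED})
    results = []
    for cls in classes:
        res = permutation_enrichment(
            universe_labels, deg_ids, cls, n_perm=n_perm,
            seed=derive_class_seed(seed, cls), dataset=dataset,
        )
        logger.info(
            "%s / %s: observed %d, null mean %.2f, p = %.3g%s",
            dataset, cls, res.observed, res.null_mean, res.empirical_p,
            " *" if res.significant else "",
        )
        results.append(res)
    return results


def results_to_frame(results: Sequence[PermutationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in results])
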