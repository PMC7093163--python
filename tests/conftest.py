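import numpy as np
import pandas as pd
import pytest

from eshrd import ExpressionPanel, build_classification, generate_panel
from eshrd.synthetic import PanelScenario

CELLS = ("N", "A", "M", "MO", "NFO", "OPC", "EC")


def make_panel(rows: dict[str, list[float]], cells=CELLS,
               namespace="mouse_symbol") -> ExpressionPanel:
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(cells))
    df.index.name = "gene_id"
    return ExpressionPanel(values=df.astype(float), namespace=namespace)


def write_panel_tsv(path, rows: dict[str, list[str]], cells=CELLS) -> None:
    """Write a raw panel TSV, values as given strings (for malformed fixtures)."""
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(cells) + "\n")
        for gid, vals in rows.items():
            fh.write(gid + "\t" + "\t".join(map(str, vals)) + "\n")


def write_de_tsv(path, rows: list[tuple]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlog2fc\tpvalue\tfdr\n")
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")


@pytest.fixture
def tiny_panel() -> ExpressionPanel:
    """Three genes over the seven reference cell types."""
    return make_panel({
        "Gfap":  [1.0, 300.0, 1.0, 1.0, 1.0, 1.0, 1.0],   # astrocyte marker
        "Snap25": [200.0, 2.0, 1.0, 1.0, 1.0, 1.0, 1.0],  # neuron marker
        "Actb": [50.0, 50.0, 50.0, 50.0, 50.0, 50.0, 50.0],  # housekeeping
    })


@pytest.fixture(scope="session")
def noise_free_classified():
    """A noise-free 300-gene synthetic panel with its classification."""
    scenario = PanelScenario(n_genes=300, noise_cv=0.0, seed=11)
    panel, truth = generate_panel(scenario)
    table = build_classification(panel)
    return panel, truth, table


def brute_force_classify(es: dict[str, float], alpha_low=0.25, alpha_high=0.75):
    """Independent re-derivation of the three-class rule, straight from the
    definition: mixed iff any ES lies strictly between the bounds (or all
    cells are high); otherwise the set of high cells."""
    es_high = max(es.values())
    lo, hi = alpha_low * es_high, alpha_high * es_high
    if any(lo < v < hi for v in es.values()):
        return "mixed"
    high = frozenset(c for c, v in es.items() if v >= hi)
    if high == frozenset(es):
        return "mixed"
    return high


def brute_force_es(values: np.ndarray) -> np.ndarray:
    """Per-definition ES: value over the plain mean of the other cells."""
    k = len(values)
    return np.array([
        values[i] / (sum(values[j] for j in range(k) if j != i) / (k - 1))
        for i in range(k)
    ])
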