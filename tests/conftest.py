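import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from methyltide.sim import SyntheticDesign, generate_annotation, generate_counts, generate_methylome


@pytest.fixture(scope="session")
def small_design():
    """Compact synthetic study reused across tests (400 genes, 8 subjects)."""
    return SyntheticDesign(n_genes=400, chrom_length=40_000_000, seed=11)


@pytest.fixture(scope="session")
def small_study(small_design):
    genes, islands, truth = generate_annotation(small_design)
    tables, groups = generate_methylome(islands, small_design)
    counts, metadata = generate_counts(truth, small_design)
    return {
        "design": small_design, "genes": genes, "islands": islands,
        "truth": truth, "tables": tables, "groups": groups,
        "counts": counts, "metadata": metadata,
    }


@pytest.fixture
def toy_sites():
    """Two samples per group over three shared CpGs."""
    def mk(m, u):
        return pd.DataFrame({
            "chrom": "chr1", "pos": [100, 200, 300],
            "count_M": m, "count_U": u,
        })
    tables = {
        "a1": mk([3, 10, 0], [2, 0, 0]),
        "a2": mk([5, 10, 1], [0, 5, 1]),
        "b1": mk([1, 2, 3], [4, 8, 3]),
        "b2": mk([2, 3, 4], [5, 7, 2]),
    }
    groups = pd.DataFrame({"sample_id": list(tables), "group": ["A", "A", "B", "B"]})
    return tables, groups


def bh_stepup(pvals):
    """Textbook Benjamini-Hochberg step-up, independent of statsmodels."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj
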