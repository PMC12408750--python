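import numpy as np
import pytest

import httrpod as h


@pytest.fixture(scope="session")
def small_truths():
    return h.make_truths(200, 30, seed=1)


@pytest.fixture(scope="session")
def small_experiment(small_truths):
    """200-probe, 30-responsive clean experiment on the default design."""
    design = h.SimDesign(n_probes=200)
    exp, truth = h.generate_experiment(design, small_truths, seed=1)
    return exp, truth


@pytest.fixture(scope="session")
def small_responses(small_experiment):
    exp, _ = small_experiment
    resp, conc = h.response_matrix(exp, "chemA")
    return resp, conc


@pytest.fixture(scope="session")
def small_bmc_table(small_responses):
    """Gene-level BMC table from the small experiment's full analysis."""
    resp, conc = small_responses
    trend = h.trend_prefilter(resp, conc, n_perm=500, seed=1)
    passing = trend.index[trend["passes_prefilter"]]
    results = h.analyze_probes(resp, conc, probe_ids=passing)
    gene_table, _ = h.postfilter(results, 50.0, {p: p for p in results.index})
    return gene_table


def rank_table(bmcs, bmcls=None, bmcus=None, genes=None):
    """Helper: assemble a minimal gene-level BMC table."""
    import pandas as pd

    bmcs = np.asarray(bmcs, dtype=float)
    n = len(bmcs)
    return pd.DataFrame(
        {
            "gene_id": genes if genes is not None else [f"g{i}" for i in range(n)],
            "bmc": bmcs,
            "bmcl": bmcls if bmcls is not None else bmcs / 2,
            "bmcu": bmcus if bmcus is not None else bmcs * 2,
        }
    ).set_index("gene_id")
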