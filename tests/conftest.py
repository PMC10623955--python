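import numpy as np
import pandas as pd
import pytest

from bileaxis import SimulationConfig, simulate_ba_panel, simulate_metagenome


@pytest.fixture(scope="session")
def metagenome():
    """A small synthetic metagenome cohort with default planted effects."""
    cfg = SimulationConfig.metagenome_default(seed=11, n_genes=150)
    table, hits, taxhits, truth = simulate_metagenome(cfg)
    return {"config": cfg, "table": table, "hits": hits,
            "taxhits": taxhits, "truth": truth}


@pytest.fixture(scope="session")
def ba_cohort():
    """The 23/23 BA panel cohort with the default 12-up/4-down effect map."""
    cfg = SimulationConfig.ba_panel_default(seed=12)
    panel, truth = simulate_ba_panel(cfg)
    return {"config": cfg, "panel": panel, "truth": truth}


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def brute_force_filter(evalues, factor=10.0):
    """Reference 10x-rule filter: compare every hit to factor x min."""
    ev = np.maximum(np.asarray(evalues, dtype=float), 1e-308)
    return ev <= factor * ev.min()


def brute_force_lca(lineages):
    """Reference LCA: pairwise longest-common-prefix intersection."""
    prefix = [v for v in lineages[0] if v != ""]
    for lin in lineages[1:]:
        lin = [v for v in lin if v != ""]
        depth = 0
        for a, b in zip(prefix, lin):
            if a != b:
                break
            depth += 1
        prefix = prefix[:depth]
    return tuple(prefix)


def exhaustive_wilcoxon_p(x, y):
    """Exact two-sided rank-sum p by enumerating all label assignments."""
    from itertools import combinations

    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1 = len(x)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * len(y) / 2
    count = total = 0
    for combo in combinations(range(len(pooled)), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


def brute_force_auc(cases, controls):
    """AUC by all-pairs concordance counting with ties worth one half."""
    c = np.asarray(cases, dtype=float)[:, None]
    k = np.asarray(controls, dtype=float)[None, :]
    return ((c > k).sum() + 0.5 * (c == k).sum()) / (c.size * k.size)
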