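"""Shared fixtures: simulated datasets at the two study regimes.

Session-scoped so the all-vs-all searches run once.  The 5-species balanced
tree and the rate settings (all rates 0 for the strict regime; duplication,
loss and substitution all at 0.05 for the easy regime; 100 families) are the
study conditions every recovery test uses.
"""

from __future__ import annotations

import pytest

from orthokit.brh import cluster_at_level
from orthokit.core import parse_newick
from orthokit.homology import all_vs_all
from orthokit.sim import SimConfig, simulate

TREE5 = "(((A:0.1,B:0.1)L1:0.1,C:0.2)L2:0.1,(D:0.15,E:0.15)L3:0.15)root;"


@pytest.fixture(scope="session")
def tree5():
    return parse_newick(TREE5)


def _run_regime(seed: int, dup: float, loss: float, sub: float, n_families: int = 100):
    config = SimConfig(
        seed=seed, tree_newick=TREE5, n_families=n_families,
        dup_rate=dup, loss_rate=loss, sub_scale=sub,
    )
    proteomes, truth, _log = simulate(config)
    hits = all_vs_all(proteomes)
    return config, proteomes, truth, hits


@pytest.fixture(scope="session")
def strict_run():
    """No duplication, loss or divergence: every family single-copy everywhere."""
    return _run_regime(seed=11, dup=0.0, loss=0.0, sub=0.0)


@pytest.fixture(scope="session")
def easy_run():
    """Moderate duplication/loss/divergence (all rates 0.05)."""
    return _run_regime(seed=11, dup=0.05, loss=0.05, sub=0.05)


@pytest.fixture(scope="session")
def easy_root_ogs(easy_run, tree5):
    _config, _proteomes, _truth, hits = easy_run
    ogs, _unassigned = cluster_at_level(hits, tree5, "root")
    return ogs
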