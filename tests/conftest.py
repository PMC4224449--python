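import numpy as np
import pandas as pd
import pytest

from toxmod import (SyntheticConfig, generate_study, generate_network,
                    DiseaseModuleModel)


@pytest.fixture(scope="session")
def default_cfg():
    return SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def default_study(default_cfg):
    return generate_study(default_cfg)


@pytest.fixture(scope="session")
def default_net(default_cfg, default_study):
    return generate_network(default_cfg, default_study.truth)


@pytest.fixture(scope="session")
def default_fit(default_study, default_net):
    """Full pipeline fit on the reference-scale study (shared; ~20 s)."""
    return DiseaseModuleModel.from_study(default_study, default_net).fit(seed=1)


@pytest.fixture(scope="session")
def small_cfg():
    """A fast study for unit-level tests (seconds, not minutes)."""
    # planted_module_edge_prob scaled up so the 25-node module keeps the same
    # density contrast to the attachment background as the reference scale
    return SyntheticConfig(
        n_genes=300, n_conditions=30, n_planted_deg=40, n_coexpr_blocks=4,
        block_size=20, network_nodes=400, planted_module_size=25,
        planted_module_edge_prob=0.5, n_absent_genes=20,
        n_unannotated_probes=10, n_duplicate_probes=10, seed=11)


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return generate_study(small_cfg)


@pytest.fixture(scope="session")
def small_net(small_cfg, small_study):
    return generate_network(small_cfg, small_study.truth)


@pytest.fixture()
def toy_samples():
    """Two treated conditions with matched controls, two replicates each."""
    rows = []
    for cid, score in (("condA", 2), ("condB", 0)):
        for r in range(2):
            rows.append((f"{cid}_t{r}", cid, "chem", 10.0, 5.0, "treated",
                         f"ctrl_{cid}", score))
            rows.append((f"{cid}_c{r}", f"ctrl_{cid}", "chem", 0.0, 5.0,
                         "control", "", score))
    return pd.DataFrame(
        rows, columns=["sample_id", "condition_id", "chemical", "dose",
                       "duration", "group", "control_condition_id",
                       "histopath_score"]).set_index("sample_id")


def make_block_matrix(n_per_block, n_cond, r, seed, n_noise=0):
    """Two correlated gene blocks (+ optional independent noise genes)."""
    rng = np.random.default_rng(seed)
    rows, names = [], []
    for b in range(2):
        factor = rng.standard_normal(n_cond)
        lam = np.sqrt(r / (1 - r))
        for i in range(n_per_block):
            rows.append(lam * factor + rng.standard_normal(n_cond))
            names.append(f"b{b}_g{i:02d}")
    for i in range(n_noise):
        rows.append(rng.standard_normal(n_cond))
        names.append(f"noise_{i:02d}")
    return pd.DataFrame(rows, index=names,
                        columns=[f"c{j:02d}" for j in range(n_cond)])
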