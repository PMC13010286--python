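import numpy as np
import pandas as pd
import pytest

from parstoich import quantio, simulate as sim, stoichiometry as st


@pytest.fixture(scope="session")
def noiseless_cfg() -> sim.SimConfig:
    return sim.SimConfig(n_proteins=40, seed=11, ratio_cv=0.0)


@pytest.fixture(scope="session")
def noiseless_truth(noiseless_cfg):
    return sim.simulate_ground_truth(noiseless_cfg)


@pytest.fixture(scope="session")
def noiseless_titration(noiseless_truth, noiseless_cfg) -> pd.DataFrame:
    return sim.simulate_titration_experiment(
        noiseless_truth, sim.TABLE1_DESIGN, noiseless_cfg, replicate_label="set1"
    )


@pytest.fixture(scope="session")
def truth_map(noiseless_truth) -> dict[str, float]:
    return {p.protein_id: p.true_stoichiometry for p in noiseless_truth}


@pytest.fixture(scope="session")
def refs_for(noiseless_truth) -> quantio.ReferenceLists:
    return quantio.ReferenceLists(
        frozenset(p.protein_id for p in noiseless_truth)
    )


def run_estimation(
    quant: pd.DataFrame,
    refs: quantio.ReferenceLists,
    designs=None,
    filter_cfg: st.FilterConfig | None = None,
    merge_mode: str = "union_mean",
):
    """Full estimation pass: filter → rollup → invert → finalize → merge."""
    designs = designs if designs is not None else sim.TABLE1_DESIGN
    filtered, _ = st.filter_peptides(quant, refs, filter_cfg or st.FilterConfig())
    rollup = st.rollup_protein_ratios(filtered)
    per_replicate = st.estimate_stoichiometries(rollup, designs)
    return st.combine_replicates(per_replicate, mode=merge_mode)


def relative_errors(estimates, truth: dict[str, float]) -> np.ndarray:
    return np.array([abs(e.final / truth[e.protein_id] - 1.0) for e in estimates])
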