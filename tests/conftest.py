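import pytest

from promarch import DepletionScenario, SimConfig


@pytest.fixture
def small_sim_config():
    """A miniature study: fast, but exercises every simulated layer."""
    return SimConfig(
        n_per_class=4, mean_cage_tags=300, fragments_per_promoter=60,
        n_genes=80, depth=80_000, n_replicates=2, seed=11,
        scenario=DepletionScenario(target_classes=("TATA", "DPE", "INR"),
                                   fold_change=0.25))
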