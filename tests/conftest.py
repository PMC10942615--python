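import hypothesis
import pytest

import hdxtherm as ht

hypothesis.settings.register_profile(
    "deterministic", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def study_run():
    """One default synthetic study, shared across tests: ground truth,
    digest, replicate tables and the full differential analysis."""
    truth = ht.simulate_system(length=470, seed=1)
    pmap = ht.simulate_digestion(truth.protein, seed=1)
    design = ht.ExperimentDesign(seed=1)
    free_table, bound_table = ht.simulate_uptake_tables(truth, pmap, design)
    deltas, params = ht.differential_analysis(free_table, bound_table)
    return {
        "truth": truth,
        "pmap": pmap,
        "design": design,
        "free": free_table,
        "bound": bound_table,
        "deltas": deltas,
        "params": params,
    }


@pytest.fixture()
def small_protein():
    return ht.ProteinSequence("toy", "ACDEFGHIKL")
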