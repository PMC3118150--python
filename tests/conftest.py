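import pytest

from belpao._rng import substream
from belpao.domains import build_class_profiles
from belpao.metrics import match_intervals
from belpao.pipeline import PipelineConfig, run_pipeline
from belpao.scenarios import (class_scenario, ht_scenario, recovery_scenario,
                              small_genome_config)
from belpao.simulate import generate_reference_panels, make_template_set

SEED = 1


@pytest.fixture(scope="session")
def template_set():
    return make_template_set(SEED)


@pytest.fixture(scope="session")
def panels(template_set):
    return generate_reference_panels(template_set, 2)


@pytest.fixture(scope="session")
def library(panels):
    return build_class_profiles(panels, seed=5)


@pytest.fixture(scope="session")
def recovery_run():
    """Full pipeline on the 3-species recovery scenario (the heavyweight
    shared fixture: detection, classification, merge, families, phylogeny,
    screens all come from this one run)."""
    spec = recovery_scenario(SEED)
    result = run_pipeline(spec, PipelineConfig(seed=SEED))
    full = [r for r in result.truth if not r.is_fragment]
    matching = match_intervals(full, result.elements)
    return {"spec": spec, "result": result, "full_truth": full,
            "matching": matching}


@pytest.fixture(scope="session")
def class_run():
    spec = class_scenario(SEED)
    result = run_pipeline(spec, PipelineConfig(seed=SEED))
    full = [r for r in result.truth if not r.is_fragment]
    matching = match_intervals(full, result.elements)
    return {"spec": spec, "result": result, "full_truth": full,
            "matching": matching}


@pytest.fixture(scope="session")
def ht_run():
    spec = ht_scenario(SEED)
    result = run_pipeline(spec, small_genome_config(seed=SEED))
    return {"spec": spec, "result": result}
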