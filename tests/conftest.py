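import pytest

from drugrepo import CohortSpec, PipelineConfig, generate_cohort, run_pipeline

#: Study conditions used by the deeper end-to-end tests: 10 therapeutic
#: classes of 12 drugs with strong, coherent signal in all three layers.
CLEAN_SPEC = CohortSpec(seed=7)
PLANTED_SPEC = CohortSpec(seed=7, mislabel_fraction=0.05)  # 6 of 120 drugs
PIPELINE_CONFIG = PipelineConfig(iterations=500, seed=11)


@pytest.fixture(scope="session")
def clean_cohort():
    return generate_cohort(CLEAN_SPEC)


@pytest.fixture(scope="session")
def clean_result(clean_cohort):
    return run_pipeline(clean_cohort.profiles, clean_cohort.ppi, PIPELINE_CONFIG)


@pytest.fixture(scope="session")
def planted_cohort():
    return generate_cohort(PLANTED_SPEC)


@pytest.fixture(scope="session")
def planted_result(planted_cohort):
    return run_pipeline(planted_cohort.profiles, planted_cohort.ppi, PIPELINE_CONFIG)
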