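import pandas as pd
import pytest
from hypothesis import settings

from epiconcord import concord, methylome, synth, transcriptome

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_config():
    """The benchmark study conditions (12 vs 12, planted effects)."""
    return synth.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def groups(sim_config):
    sheet = sim_config.sample_sheet()
    return pd.Series(sheet["group"].to_numpy(), index=sheet["sample_id"].to_numpy())


@pytest.fixture(scope="session")
def annotation(sim_config):
    return synth.simulate_annotation(sim_config)


@pytest.fixture(scope="session")
def methylation(sim_config, annotation):
    return synth.simulate_methylation(sim_config, annotation)


@pytest.fixture(scope="session")
def pipeline_run(sim_config, annotation, methylation, groups):
    """Full seeded run: dm -> de -> integrate, with the planted truth."""
    matrix, truth = methylation
    masked = methylome.mask_low_detection(matrix, groups)
    probe_results = methylome.test_probe_dm(masked, groups)
    dmgs = methylome.call_dmgs(probe_results, annotation)
    expr = synth.simulate_expression(sim_config, truth)
    prior = transcriptome.fit_intensity_prior(expr, groups)
    de_results = transcriptome.moderated_t(expr, groups, prior)
    degs = transcriptome.call_degs(de_results, fdr=0.10)
    records = concord.build_epigene_records(dmgs, degs)
    summary = concord.summarize_integration(dmgs, degs, records)
    return {
        "config": sim_config,
        "truth": truth,
        "probe_results": probe_results,
        "dmgs": dmgs,
        "de_results": de_results,
        "degs": degs,
        "records": records,
        "summary": summary,
    }
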