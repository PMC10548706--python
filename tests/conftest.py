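import warnings

import pytest

from cypkit import simulate


@pytest.fixture(scope="session")
def default_genome():
    """The default synthetic genome (seed 1), shared across the session."""
    return simulate.simulate_genome(seed=1)


@pytest.fixture(scope="session")
def default_expression(default_genome):
    return simulate.simulate_expression(default_genome.truth, seed=2)


@pytest.fixture(scope="session")
def survey_result(default_genome, default_expression):
    """Full pipeline run over the default synthetic genome."""
    from cypkit import pipeline

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pipeline.run_survey(
            default_genome.proteins,
            default_genome.cds,
            default_genome.models,
            default_genome.references,
            counts=default_expression.counts,
            lengths=default_expression.lengths,
            replicate_map=default_expression.replicate_map,
            metabolites=default_expression.metabolites,
        )
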