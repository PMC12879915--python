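"""Shared fixtures.

The expensive MCMC fits are session-scoped and shared across the tests that
interrogate them; problem sizes are chosen so the whole suite runs on one
CPU in well under half an hour.
"""

import warnings

import numpy as np
import pytest

from cortrhythm import (SamplerConfig, default_study_config, default_truth,
                        fit_model, generate_dataset, prepare_model_data)


@pytest.fixture(scope="session")
def study_config():
    return default_study_config()


@pytest.fixture(scope="session")
def small_tables(study_config):
    """A small synthetic study exercising every exclusion rule."""
    truth = default_truth(seed=7, n_participants=30, n_pregnant=2,
                          n_missing_age=1, n_incomplete_questionnaire=2)
    return generate_dataset(truth, study_config)


@pytest.fixture(scope="session")
def small_model0_data(small_tables, study_config):
    samples, participants, questionnaire, _ = small_tables
    data, log = prepare_model_data(samples, participants, questionnaire,
                                   study_config, "model0")
    return data


@pytest.fixture(scope="session")
def small_model1_data(small_tables, study_config):
    samples, participants, questionnaire, _ = small_tables
    data, _ = prepare_model_data(samples, participants, questionnaire,
                                 study_config, "model1")
    return data


@pytest.fixture(scope="session")
def paper_scale_fit(study_config):
    """Model 0 fitted to a synthetic study generated at the published point
    estimates (n = 129, 2-3 samples each). Shared by the recovery checks."""
    truth = default_truth(seed=20230915)
    samples, participants, questionnaire, record = generate_dataset(
        truth, study_config)
    data, _ = prepare_model_data(samples, participants, questionnaire,
                                 study_config, "model0")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws = fit_model("model0", data, cfg=SamplerConfig(
            chains=3, warmup_draws=400, kept_draws=400, seed=101,
            target_accept=0.9))
    return draws, record, data


@pytest.fixture(scope="session")
def null_correlation_fit(study_config):
    """Model 1 fitted to a synthetic study whose latent correlations are all
    zero (n = 200): the null-calibration surface."""
    truth = default_truth(seed=42, n_participants=200,
                          corr_matrix=np.eye(8), n_pregnant=0,
                          n_missing_age=0, n_incomplete_questionnaire=0)
    samples, participants, questionnaire, _ = generate_dataset(
        truth, study_config)
    data, _ = prepare_model_data(samples, participants, questionnaire,
                                 study_config, "model1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws = fit_model("model1", data, cfg=SamplerConfig(
            chains=2, warmup_draws=400, kept_draws=250, seed=9,
            target_accept=0.9))
    return draws


@pytest.fixture(scope="session")
def prior_only_fit(small_model0_data):
    """Model 0 with the likelihood switched off: samples the priors."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_model("model0", small_model0_data, likelihood=False,
                         cfg=SamplerConfig(chains=2, warmup_draws=300,
                                           kept_draws=2000, seed=31,
                                           target_accept=0.9))
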