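import numpy as np
import pytest

import tendonmetrics as tm


def noiseless_config(**overrides) -> tm.GeneratorConfig:
    base = dict(
        landmark_noise_sd_mm=0.0,
        force_noise_sd_n=0.0,
        marker_noise_sd_mm=0.0,
        force_within_subject_rel_sd=0.0,
        day_bias_mm_sd=0.0,
        stiffness_between_subject_sd=0.0,
        force_between_subject_sd=0.0,
        resting_length_between_subject_sd=0.0,
        moment_arm_between_subject_sd=0.0,
    )
    base.update(overrides)
    return tm.GeneratorConfig(**base)


@pytest.fixture
def clean_trial():
    """One noiseless trial with its truth, subject parameters and constants."""
    cfg = noiseless_config()
    rng = np.random.default_rng(11)
    subject = tm.draw_subject(cfg, "s01", rng)
    record, truth = tm.simulate_trial(cfg, subject, rng)
    constants = tm.AnatomicalConstants(
        moment_arm_mm=subject.moment_arm_mm,
        resting_length_mm=subject.resting_length_mm,
        load_cell_positions_m=cfg.load_cell_positions_m,
    )
    return cfg, record, truth, constants


@pytest.fixture(scope="session")
def default_cohort():
    """The 11-subject x 8-trial test-retest cohort with default noise,
    analyzed by both methods (shared across tests for speed)."""
    cfg = tm.GeneratorConfig(seed=1)
    dataset, truth = tm.simulate_cohort(cfg)
    results, failures = tm.analyze_session(dataset, method="both")
    assert not failures
    return dataset, truth, results
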