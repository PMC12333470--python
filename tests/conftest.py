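"""Shared fixtures: synthetic AR data generators and expensive shared fits."""

import numpy as np
import pytest

from syllakin.segmentation import ARHMMHyper, fit_arhmm
from syllakin.synthetic import build_transition_model, sample_markov_chain


def make_ar_data(n_frames, seed=0, noise_sd=0.3, mean_duration_s=0.4):
    """3 well-separated AR(1) states in 2 latent dims with sticky switching.

    Returns (latents, true_labels, true_transition_matrix, state_params).
    State params are (A_k, b_k, sd_k) triples.
    """
    rng = np.random.default_rng(seed)
    angles = (0.0, 0.5, -0.5)
    As = [0.95 * np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]]) for a in angles]
    bs = [np.array([0.0, 0.0]), np.array([3.0, 0.0]), np.array([-3.0, 0.0])]
    sds = [noise_sd] * 3
    P = build_transition_model(3, mean_duration_s, 30.0, seed=seed)
    z = sample_markov_chain(P, n_frames, rng)
    y = np.zeros((n_frames, 2))
    for t in range(1, n_frames):
        k = z[t]
        y[t] = As[k] @ y[t - 1] + bs[k] + sds[k] * rng.standard_normal(2)
    return y, z, P, list(zip(As, bs, sds))


def greedy_match_accuracy(true_labels, fitted_labels, n_true, n_fitted):
    """Fraction of frames correct after mapping each fitted state to its
    majority true state (greedy confusion-matrix matching)."""
    conf = np.zeros((n_true, n_fitted))
    np.add.at(conf, (true_labels, fitted_labels), 1)
    mapping = conf.argmax(axis=0)
    return sum(conf[mapping[k], k] for k in range(n_fitted)) / len(true_labels)


@pytest.fixture(scope="session")
def three_state_data():
    return make_ar_data(20_000, seed=0)


@pytest.fixture(scope="session")
def dissociation_result():
    """Lesion vs velocity-only-rescue experiment (ground-truth labels mode)."""
    from syllakin.config import CohortSpec, ExperimentConfig
    from syllakin.pipeline import run_experiment

    cfg = ExperimentConfig(
        cohorts={
            "lesion": CohortSpec("lesion", 7, 0.8),
            "treated": CohortSpec("lesion+treatment", 7, 0.8),
        },
        n_syllables=12,
        session_duration_s=180.0,
        labels_source="ground_truth",
        seed=21,
    )
    return run_experiment(cfg)


@pytest.fixture(scope="session")
def three_state_fit(three_state_data):
    """Shared Gibbs fit of the 3-state data (the slow shared resource)."""
    y, z, P, params = three_state_data
    hyper = ARHMMHyper(kappa=1e4, K_max=8, ar_order=1, n_iter=50, burn_in=25, seed=0)
    model, seqs = fit_arhmm(y, hyper)
    return {"model": model, "labels": seqs[0].labels, "hyper": hyper,
            "y": y, "z": z, "P": P, "params": params}
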