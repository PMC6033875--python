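"""Shared fixtures: configurations and simulated cohorts reused across tests."""

import numpy as np
import pandas as pd
import pytest

import msite


@pytest.fixture(scope="session")
def default_config():
    return msite.DesignConfig()


@pytest.fixture(scope="session")
def full_cohort():
    """Default-size cohort: 4 experiments x 30 subjects x 1008 main trials."""
    return msite.generate_cohort(msite.DesignConfig(), master_seed=20240501)


@pytest.fixture(scope="session")
def full_analysis(full_cohort):
    """Annotated, filtered analysis set plus scores/selections/MSF for the full cohort."""
    trials, truth = full_cohort
    annotated = msite.annotate_previous_trial(trials)
    filtered, tally = msite.apply_filters(annotated)
    scores = msite.score_conditions(filtered)
    selections = msite.select_all_subjects(scores)
    msf = msite.build_msf_records(
        scores, frequencies=truth[["subject_id", "freq_a", "freq_v"]], selections=selections
    )
    return {
        "trials": trials,
        "truth": truth,
        "filtered": filtered,
        "tally": tally,
        "scores": scores,
        "selections": selections,
        "msf": msf,
    }


@pytest.fixture(scope="session")
def small_cohort():
    """Two subjects per experiment; fast input for structural/unit checks."""
    cfg = msite.DesignConfig(n_subjects_per_experiment=2)
    return msite.generate_cohort(cfg, master_seed=11)


def toy_trial_table(rows):
    """Minimal trial table from a list of dicts, with schema defaults filled in."""
    defaults = {
        "subject_id": 1,
        "experiment_id": 1,
        "spatial_uncertainty": "low",
        "target_uncertainty": "low",
        "block_index": 3,
        "block_type": "expect_early",
        "sequence_modality": "A",
        "target_modality": "A",
        "target_position": "early",
        "target_onset_ms": 400,
        "target_direction": "higher",
        "response": "higher",
        "rt_ms": 1000.0,
        "correct": True,
    }
    filled = []
    for i, row in enumerate(rows):
        r = {**defaults, "trial_index": i, **row}
        r["correct"] = r["response"] == r["target_direction"] and r["response"] != "none"
        filled.append(r)
    return pd.DataFrame(filled)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
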