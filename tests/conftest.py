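"""Shared fixtures: one synthetic study and trained scorers per session."""

import pytest

from mslinc.annotation import filter_novel_lincrnas
from mslinc.codepot import train_scorers
from mslinc.pipeline import run_panel
from mslinc.syndata import SimulationDesign, generate_training_sequences, simulate


@pytest.fixture(scope="session")
def design():
    return SimulationDesign(seed=1)


@pytest.fixture(scope="session")
def study(design):
    return simulate(design)


@pytest.fixture(scope="session")
def scorer(design):
    seqs, labels = generate_training_sequences(design, n_per_class=500)
    return train_scorers(seqs, labels)


@pytest.fixture(scope="session")
def discovery(study, scorer):
    return filter_novel_lincrnas(study.novel, study.known, study.sequences, scorer)


@pytest.fixture(scope="session")
def panel(study):
    return run_panel(study)
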