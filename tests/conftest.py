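"""Shared fixtures.

``full_study`` is the expensive session-scoped end-to-end fixture: the
full 27,578-probe universe with the default planted effects, a 20-sample
design (old/young male blister epidermis plus sun-exposed/protected young
female punch epidermis), simulated to bead level and preprocessed to a
beta matrix. Everything else is small and cheap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from methylskin import (
    default_design,
    make_annotation,
    make_true_betas,
    preprocess_beads,
    simulate_beads,
)

SESSION_SEED = 11


@pytest.fixture(scope="session")
def full_study():
    annotation = make_annotation(27578, seed=SESSION_SEED)
    design = default_design()
    keep = (design["sampling"] == "suction_blister") | (
        (design["tissue"] == "epidermis")
        & (design["age_group"] == "young")
        & (design["sex"] == "female")
    )
    design = design[keep]
    assert len(design) == 20
    true_betas, truth = make_true_betas(annotation, design, seed=SESSION_SEED)
    beads = simulate_beads(true_betas, design, seed=SESSION_SEED)
    matrix = preprocess_beads(beads)
    del beads
    groups = {
        "old_blister": design.loc[design["age_group"] == "old",
                                  "sample_id"].to_list(),
        "young_blister": design.loc[
            (design["age_group"] == "young") & (design["sex"] == "male"),
            "sample_id"].to_list(),
        "sun_exposed": design.loc[design["sun"] == "exposed",
                                  "sample_id"].to_list(),
        "sun_protected": design.loc[
            (design["sun"] == "protected") & (design["sex"] == "female"),
            "sample_id"].to_list(),
    }
    return {
        "annotation": annotation,
        "design": design,
        "true_betas": true_betas,
        "truth": truth,
        "matrix": matrix,
        "groups": groups,
        "seed": SESSION_SEED,
    }


@pytest.fixture()
def small_annotation():
    return make_annotation(200, island_fraction=0.7, x_fraction=0.05, seed=3)


@pytest.fixture()
def small_design():
    design = default_design()
    return design[design["sampling"] == "suction_blister"]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
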