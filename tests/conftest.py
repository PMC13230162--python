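import numpy as np
import pandas as pd
import pytest

import boargut as bg


@pytest.fixture(scope="session")
def balanced_cohort():
    """Three breeds on one farm, planted breed effect, moderate noise."""
    design = bg.CohortDesign(
        groups=[("Duroc", "F1", 30), ("Landrace", "F1", 30),
                ("LargeWhite", "F1", 30)], seed=42, n_batches=2)
    model = bg.EffectModel.community(n_taxa=80, dispersion=1.0, seed=42)
    model.add_effect("breed", "Duroc", [0, 1, 2, 3, 4], 1.5)
    return bg.simulate_cohort(design, model)


@pytest.fixture(scope="session")
def null_cohort():
    """No planted effects anywhere: exchangeable labels."""
    design = bg.CohortDesign(
        groups=[("Duroc", "F1", 20), ("Landrace", "F1", 25),
                ("LargeWhite", "F1", 30)], seed=7, n_batches=2)
    model = bg.EffectModel.community(n_taxa=60, dispersion=1.0, seed=7)
    return bg.simulate_cohort(design, model)


@pytest.fixture(scope="session")
def tiny_tab():
    """Hand-sized normalised table with easy closed-form diversity."""
    raw = pd.DataFrame(
        [[1.0, 1.0, 1.0, 1.0],
         [2.0, 1.0, 1.0, 0.0],
         [0.0, 0.0, 0.0, 5.0]],
        index=["a", "b", "c"], columns=["t1", "t2", "t3", "t4"])
    return bg.normalize_tpm(raw)


@pytest.fixture()
def small_meta():
    frame = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(6)],
        "breed": ["D", "D", "D", "L", "L", "L"],
        "farm": ["F1"] * 6,
        "company": ["A"] * 6,
        "batch": ["b1", "b2", "b1", "b2", "b1", "b2"],
        "age_days": [300, 400, 500, 600, 1200, 1500],
    })
    return bg.SampleMetadata(frame)
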