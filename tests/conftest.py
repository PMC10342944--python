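import numpy as np
import pandas as pd
import pytest

from microfast import synthetic
from microfast.records import CohortDesign


@pytest.fixture(scope="session")
def small_reference():
    """20 species, 200 nt, within-genus pairwise divergence 0.2."""
    return synthetic.generate_reference(20, 200, 0.2, seed=7)


@pytest.fixture(scope="session")
def tiny_reference():
    """8 well-separated species for fast clustering tests."""
    return synthetic.generate_reference(8, 120, 0.5, seed=3)


@pytest.fixture(scope="session")
def small_cohort():
    return synthetic.generate_cohort(n_ra=4, n_mets=3, seed=11)


@pytest.fixture()
def toy_panel():
    """Hand-built 2-group frequency panel for filter tests."""
    from microfast.community import GroupedFrequencyPanel

    freq = pd.DataFrame(
        {
            "sp_a": [0.5, 0.4, 0.6, 0.5],
            "sp_b": [0.5, 0.3, 0.4, 0.5],
            "sp_x": [0.0, 0.3, 0.0, 0.0],  # present in RA2.T0 only
        },
        index=["RA1.T0.16S", "RA2.T0.16S", "M1.T0.16S", "M1.T3.16S"],
    )
    meta = pd.DataFrame(
        {
            "donor": ["RA1", "RA2", "M1", "M1"],
            "group": ["RA", "RA", "MetS", "MetS"],
            "timepoint": ["T0", "T0", "T0", "T3"],
            "marker": ["16S"] * 4,
            "bmi": [22.0, 30.0, 35.0, 35.0],
        },
        index=freq.index,
    )
    return GroupedFrequencyPanel(frequencies=freq, meta=meta)


@pytest.fixture(scope="session")
def null_cytometry():
    """Cytometry table with no injected effect (pure null)."""
    design = synthetic.generate_cohort(n_ra=20, n_mets=10, seed=5)
    effect = synthetic.CytometryEffect(
        target_population="none", ra_baseline_factor=1.0, fasting_factors={}
    )
    return synthetic.generate_cytometry_table(
        design, n_populations=60, effect=effect, seed=17
    )
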