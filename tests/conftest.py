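import warnings

import numpy as np
import pandas as pd
import pytest

from vitalgluten.aggregation import DataQualityWarning
from vitalgluten.classify import load_reference_volumes, records_from_frame
from vitalgluten.pipeline import extract_features
from vitalgluten.synthetic import PanelConfig, generate_panel


@pytest.fixture(scope="session")
def reference_volumes() -> pd.DataFrame:
    return load_reference_volumes()


@pytest.fixture
def reference_records(reference_volumes):
    # fresh records each test: clustering mutates quality_class
    return records_from_frame(reference_volumes.drop(columns=["quality_class"]))


@pytest.fixture(scope="session")
def default_panel():
    """One panel under the default study conditions (46 samples)."""
    return generate_panel(PanelConfig(n_samples=46, rng_seed=1))


@pytest.fixture(scope="session")
def noisefree_panel():
    """A small panel with every noise source switched off."""
    return generate_panel(PanelConfig(n_samples=12, rng_seed=5).scaled_noise(0.0))


@pytest.fixture(scope="session")
def default_features(default_panel):
    """Feature table of the default panel (generating CCE parameters are
    used in place of per-curve fits to keep the suite fast; the fit
    itself is exercised separately)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DataQualityWarning)
        feats = extract_features(default_panel.aggregation_curves,
                                 default_panel.extension_curves,
                                 default_panel.chromatograms, fit_cce=False)
    for col in ("y0", "xc1", "a", "w", "k2", "xc2", "b", "k3", "xc3"):
        feats[col] = default_panel.truth[col]
    return feats


@pytest.fixture(scope="session")
def default_volumes(default_panel):
    recs = default_panel.records
    return pd.DataFrame(
        {"volume_A_ml_per_g": [r.specific_volume_a for r in recs],
         "volume_B_ml_per_g": [r.specific_volume_b for r in recs]},
        index=pd.Index([r.sample_id for r in recs], name="sample_id"))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
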