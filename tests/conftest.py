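import numpy as np
import pandas as pd
import pytest

from capscreen.ingest import DESIGN_COLUMNS, ExperimentDesign, IntensityMatrix
from capscreen.pipeline import RunConfig, analyze_screen
from capscreen.synthetic import SyntheticConfig, generate_screen


def make_design(rows):
    return ExperimentDesign(pd.DataFrame(rows, columns=list(DESIGN_COLUMNS)))


@pytest.fixture
def toy_design():
    """Minimal valid design: one condition, 2 case + 2 control runs."""
    return make_design(
        [
            ("e1", "NCBP1", "NCBP1", "7", 1, "multiwell", "case"),
            ("e2", "NCBP1", "NCBP1", "7", 2, "multiwell", "case"),
            ("c1", "control", "NCBP1", "7", 1, "multiwell", "control"),
            ("c2", "control", "NCBP1", "7", 2, "multiwell", "control"),
        ]
    )


def make_matrix(data, layer="LFQ", scale="log2", columns=None):
    frame = pd.DataFrame(data).T if isinstance(data, dict) else pd.DataFrame(data)
    if columns is not None:
        frame.columns = columns
    return IntensityMatrix(frame, layer=layer, scale=scale)


@pytest.fixture(scope="session")
def spiked_screen():
    """A default spiked screen (effect 4, 20 interactors) analyzed end to end."""
    cfg = SyntheticConfig(seed=2024, n_interactors=20, effect_range=(4.0, 4.0))
    design, frame, truth = generate_screen(cfg)
    analysis = analyze_screen(design, frame, RunConfig(n_trials=100, base_seed=7))
    return design, frame, truth, analysis
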