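import numpy as np
import pandas as pd
import pytest

import isotroph as it


@pytest.fixture
def aa_long_csv(tmp_path):
    """Write a minimal valid long-format amino-acid table; returns its path."""

    def _write(rows, name="aa.csv"):
        path = tmp_path / name
        pd.DataFrame(
            rows,
            columns=[
                "sample_id", "role", "species", "ecological_group",
                "litter_treatment", "replicate", "amino_acid", "value",
            ],
        ).to_csv(path, index=False)
        return path

    return _write


@pytest.fixture
def small_library():
    """Well-separated 3-class endmember library (n=8/class, 5-eAA panel)."""
    cfg = it.SyntheticConfig(seed=11, n_endmembers_per_class=8, source_sd=0.5)
    return it.simulate_endmembers(cfg)


@pytest.fixture
def study_bundle():
    """Default-noise synthetic study at a reduced design (2 species, 2 reps)."""
    cfg = it.SyntheticConfig(seed=7, n_species=2, n_reps=2)
    return it.simulate_study(cfg)
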