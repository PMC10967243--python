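import numpy as np
import pandas as pd
import pytest

from stemtherm.simdata import MarkerPanel, gen_marker_panel


@pytest.fixture(scope="session")
def small_panel() -> MarkerPanel:
    """120-genotype structured panel used across genetics tests."""
    return gen_marker_panel(120, 5, 60, (0.05, 0.5), n_subpop=2, fst=0.15,
                            seed=42)


@pytest.fixture(scope="session")
def tiny_panel() -> MarkerPanel:
    """Hand-inspectable 6 x 10 dosage panel."""
    rng = np.random.default_rng(7)
    g = rng.integers(0, 3, size=(6, 10)).astype(float)
    m = pd.DataFrame({"chrom": ["chr1"] * 5 + ["chr2"] * 5,
                      "pos": list(range(1, 6)) * 2})
    m["marker"] = [f"m{j}" for j in range(10)]
    return MarkerPanel([f"g{i}" for i in range(6)], g, m)
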