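import numpy as np
import pandas as pd
import pytest

import indelpop as ip


@pytest.fixture(scope="session")
def table1():
    """Bundled 42-marker reference panel: definitions + published statistics."""
    return ip.load_table1()


@pytest.fixture(scope="session")
def toy_markers():
    """Three hand-built markers: codominant biallelic, triallelic, dominant."""
    return [
        ip.MarkerDef("R2M37", 2, (211, 151), 211, 151, 60),
        ip.MarkerDef("R3M37", 3, (282, 240, 194), 194, 282, 42),
        ip.MarkerDef("R1M37", 1, (167,), None, 167, 0, is_dominant=True),
    ]


def make_panel(rows: dict[str, list[str]], markers) -> ip.GenotypeMatrix:
    calls = pd.DataFrame.from_dict(
        rows, orient="index", columns=[m.marker_id for m in markers]
    )
    return ip.GenotypeMatrix(markers=markers, calls=calls)


@pytest.fixture
def biallelic_markers():
    """Ten plain codominant markers for arithmetic-focused tests."""
    return [
        ip.MarkerDef(f"M{k:02d}", (k % 12) + 1, (200 + k, 150 + k), 200 + k, 150 + k, 50)
        for k in range(10)
    ]


@pytest.fixture(scope="session")
def preset_panel():
    """One seeded study-scale simulated panel shared across tests."""
    return ip.simulate_panel(ip.study_scale_preset(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
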