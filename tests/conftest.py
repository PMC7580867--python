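import numpy as np
import pytest

import phlux as px


@pytest.fixture(scope="session")
def acid_titration():
    """Modelled acid-mode titration curve of the default assay medium."""
    return px.make_titration_table(mode="acid")


@pytest.fixture(scope="session")
def base_titration():
    return px.make_titration_table(mode="base")


@pytest.fixture(scope="session")
def fluorophore():
    """Exact forward calibration curve used by the simulator."""
    return px.default_fluorophore()


@pytest.fixture(scope="session")
def sigmoid_standards():
    """Noiseless standards generated from a known sigmoid."""
    cal = px.CalibrationCurve(
        r_min=2000.0, r_max=50000.0, apparent_pka=6.4, hill_slope=1.0,
        valid_ph_range=(4.0, 7.0),
    )
    ph = np.array([4.0, 5.0, 5.5, 6.0, 6.5, 7.0])
    return cal, [(p, cal.ph_to_rfu(p)) for p in ph]


def random_buffer_system(rng):
    """A small random but well-posed buffer system."""
    species = []
    for _ in range(rng.integers(1, 4)):
        n_pka = int(rng.integers(1, 4))
        pkas = np.sort(rng.uniform(2.0, 12.0, size=n_pka))
        while np.any(np.diff(pkas) < 0.2):  # keep pKas separated
            pkas = np.sort(rng.uniform(2.0, 12.0, size=n_pka))
        species.append(
            px.ProtolyteSpecies(
                name=f"sp{len(species)}",
                pka_values=tuple(pkas),
                total_concentration=float(rng.uniform(0.001, 0.05)),
                charge_fully_protonated=int(rng.integers(0, 2)),
            )
        )
    return px.BufferSystem(
        species=tuple(species),
        strong_acid_added=float(rng.uniform(-0.02, 0.02)),
    )
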