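import numpy as np
import pytest

import alexfret as af


@pytest.fixture(scope="session")
def factors_and_background():
    """Correction factors and background estimated from simulated calibration sets."""
    return af.pipeline.calibrate_factors(seed=11)


@pytest.fixture
def noise_free_double():
    """One double-labelled molecule, E=0.5, no distortions at all."""
    cfg = af.SimulationConfig(
        n_molecules=1, n_cycles=50,
        species_fractions={"donor_only": 0.0, "acceptor_only": 0.0, "double": 1.0},
        states=((0.5, 1.0),), I_D0=1000.0, I_A0=800.0,
        l_true=0.0, d_true=0.0, shot_noise=False,
        camera=af.CameraModel(gain=1.0, excess_noise=1.0, read_noise_sd=0.0),
        seed=0)
    return af.simulate_traces(cfg)[0]


def write_synthetic_pdb(path, coords):
    """Write CA-only ATOM records for {resnum: (x, y, z)} (synthetic structure)."""
    with open(path, "w") as fh:
        for i, (resnum, xyz) in enumerate(sorted(coords.items()), start=1):
            x, y, z = xyz
            fh.write(f"ATOM  {i:5d}  CA  ALA A{resnum:4d}    "
                     f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n")
        fh.write("END\n")
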