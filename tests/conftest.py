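import numpy as np
import pytest

from quenchbind import GeneratorConfig, make_titration

# Published assay values used across tests: temperature-resolved Stern-Volmer
# and association constants for the hemoglobin-nilvadipine pair, the donor
# lifetime, and the derived thermodynamic parameters.
TABLE1_T_K = (298.0, 303.0, 310.0)
TABLE1_KSV_PER_M = (1.080e4, 1.014e4, 0.937e4)
TABLE1_KA_PER_M = (0.3380e4, 0.6467e4, 1.4667e4)
TABLE1_N = (0.8809, 0.9530, 1.0456)
TAU0_S = 5.71e-9
DH_KCAL = 22.42
DS_CAL = 91.39


@pytest.fixture(scope="session")
def noiseless_cfg() -> GeneratorConfig:
    """Ground truth matching the published thermodynamics, zero noise."""
    return GeneratorConfig(seed=42, dH_kcal=DH_KCAL, dS_cal=DS_CAL, noise_rel_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_titrations(noiseless_cfg):
    return make_titration(noiseless_cfg)


@pytest.fixture()
def fixed_affinity_cfg() -> GeneratorConfig:
    """Single-temperature generator pinned at the 303 K association constant."""
    return GeneratorConfig(
        seed=7,
        dH_kcal=None,
        dS_cal=None,
        Ka_ref_per_M=6467.0,
        temperatures_K=(303.0,),
    )
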