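import numpy as np
import pytest
from hypothesis import settings

import foldtherm as ft

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def fi_transition():
    """Three-state flavodoxin F-to-I step, experimental parameters."""
    return ft.TransitionThermo(dH_Tm=32.0, dCp=1.35, Tm=316.2,
                               se_dH=1.1, se_dCp=0.3, label="F-to-I")


def exact_dg_transition(dg, T=298.15, label="F-to-U", se_dH=0.0):
    """Transition whose Gibbs-Helmholtz dG at T equals ``dg`` exactly:
    dCp = 0 and Tm = 2T make dG(T) = dH_Tm / 2."""
    return ft.TransitionThermo(dH_Tm=2.0 * dg, dCp=0.0, Tm=2.0 * T,
                               se_dH=se_dH, label=label)


@pytest.fixture
def small_chain_ensemble():
    spec = ft.ChainGeneratorSpec(n_residues=25, n_models=30, seed=7)
    return ft.gen_chain_ensemble(spec)
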