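import numpy as np
import pytest

from shellsaxs import ShellSpec, make_solvated_system, make_toy_solute


@pytest.fixture(scope="session")
def toy_solute():
    """150 carbon atoms quasi-uniform in a 5 A ball (rigid protein stand-in)."""
    return make_toy_solute(n_atoms=150, radius=5.0, seed=42)


@pytest.fixture(scope="session")
def small_system(toy_solute):
    """A small solvated sample + matched buffer (no shell perturbation)."""
    shell = ShellSpec(epsilon=0.0, shell_width=3.0, seed=7)
    sample, buffer = make_solvated_system(
        toy_solute, np.full(3, 30.0), shell, n_frames=30
    )
    return sample, buffer
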