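import numpy as np
import pytest

from hemexas import (
    ChiSpectrum,
    ScatteringFunctions,
    default_scattering_map,
    preset_shell_model,
    simulate_chi,
)


@pytest.fixture(scope="session")
def funcs():
    return default_scattering_map()


@pytest.fixture(scope="session")
def k_grid():
    return np.arange(2.5, 11.0 + 1e-9, 0.05)


@pytest.fixture(scope="session")
def ligand_free_model():
    """EXAFS-refined ligand-free heme-site model (the best-fit geometry)."""
    return preset_shell_model("exafs_4plus1")


@pytest.fixture(scope="session")
def drug_bound_model():
    return preset_shell_model("drug_5plus1")


@pytest.fixture(scope="session")
def chi_ligand_free(ligand_free_model, funcs, k_grid):
    return simulate_chi(ligand_free_model, funcs, k_grid)


@pytest.fixture(scope="session")
def chi_wide(ligand_free_model, funcs):
    """Same model on the generator's wide fine grid (for embedding into
    full scans; the fit grid starts at 2.5 A^-1 and would leave a
    truncation step in mu)."""
    return simulate_chi(ligand_free_model, funcs, np.arange(0.5, 12.0, 0.02))


@pytest.fixture(scope="session")
def chi_drug_bound(drug_bound_model, funcs, k_grid):
    return simulate_chi(drug_bound_model, funcs, k_grid)


@pytest.fixture()
def ideal_funcs():
    """|f| = 1, phi = 0, lambda = infinity: the bare shell-sum kernel."""
    ideal = ScatteringFunctions(
        "X", amplitude_params=(1.0, 0.0, 0.0), phase_params=(0.0, 0.0),
        lambda_params=(1e12, 0.0),
    )
    return {el: ideal for el in ("N", "O", "C")}


def noisy_copy(chi, noise, seed):
    rng = np.random.default_rng(seed)
    return ChiSpectrum(
        chi.k, chi.chi + rng.normal(0.0, noise, chi.k.size), kweight=chi.kweight
    )
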