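import numpy as np
import pytest

from ensemblevs.fixtures import ScreenSimConfig, gen_score_table, gen_toy_complex


@pytest.fixture(scope="session")
def small_screen():
    """80 actives vs 1,600 decoys over 10 conformations, AUC-0.75-ish features."""
    # per-conformation AUC 0.75 <=> delta = Phi^-1(0.75) * sigma * sqrt(2)
    from scipy.stats import norm

    delta = norm.ppf(0.75) * np.sqrt(2.0)
    cfg = ScreenSimConfig(
        n_active=80, n_decoy=1600, n_conformations=10,
        mu_active=-7.0 - delta, mu_decoy=-7.0, sigma=1.0, rho=0.0, seed=7,
    )
    return gen_score_table(cfg)


@pytest.fixture(scope="session")
def toy_complex_near():
    return gen_toy_complex(n_residues=12, hot_positions=(5,), ligand_near=True, seed=3)


@pytest.fixture(scope="session")
def toy_complex_far():
    return gen_toy_complex(n_residues=12, hot_positions=(5,), ligand_near=False, seed=3)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR with positive diagonal."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
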