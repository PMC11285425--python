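import numpy as np
import pytest

from aerophage import SpeciesParams, run, stability_report
from aerophage.config import validate_config
from aerophage.constants import DESK, make_fixture


@pytest.fixture(scope="session")
def workhorse():
    """Small analytically convenient parameter set: fixed point (1, 9)."""
    bact = SpeciesParams.bacterium(g=1.0, K=10.0)
    phage = SpeciesParams.phage(eta=0.1, beta=11.0, delta_s=1.0)
    return bact, phage


@pytest.fixture(scope="session")
def desk_species():
    bact = SpeciesParams.bacterium(g=DESK["g"], K=DESK["K"])
    phage = SpeciesParams.phage(eta=DESK["eta"], beta=DESK["beta"], delta_s=DESK["delta_s"])
    return bact, phage


@pytest.fixture(scope="session")
def fig4_result():
    """One full connected-mosaic run at L=0.5, shared by the migration
    statistic and the structural-invariant tests."""
    cfg = validate_config(make_fixture("fig4", "desk")["config"])
    return run(cfg, 1)


@pytest.fixture(scope="session")
def fig4_attribution(fig4_result):
    cfg = fig4_result.config
    rep = stability_report(
        cfg.bacterium, cfg.phages[0], loss_rate=cfg.transport.p * cfg.transport.j0
    )
    return 20.0 * rep.tau_per


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
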