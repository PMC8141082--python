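import numpy as np
import pytest

import kinktrap as kt


@pytest.fixture(scope="session")
def default_params():
    return kt.ElectrostaticParams()


@pytest.fixture(scope="session")
def eq_ensemble_small():
    """300 freely equilibrated 2D chains, P=53, L=900 (shared across tests)."""
    return kt.wlc2d_ensemble(300, 53.0, 900.0, 1.0, seed=11)


@pytest.fixture(scope="session")
def eq_traces_small(eq_ensemble_small):
    return kt.chains_to_traces(eq_ensemble_small, seed=11)


@pytest.fixture(scope="session")
def template_field(default_params):
    tmpl = kt.LamellarTemplate(extent=600.0)
    return kt.SurfaceChargeField(template=tmpl, params=default_params)


@pytest.fixture(scope="session")
def film_field(default_params):
    """Two-layer AL/L film: lamellar template plus granular adlayer."""
    return kt.two_layer_film(params=default_params, extent=350.0, seed=13)


@pytest.fixture(scope="session")
def trapped_small(film_field):
    """40 film-trapped chains, L=450 (shared across tests)."""
    cfg = kt.SimulationConfig(P=53.0, L=450.0, a=1.0)
    return kt.trap_ensemble(40, film_field, cfg, seed=21)


@pytest.fixture(scope="session")
def sim_cfg():
    return kt.SimulationConfig(P=53.0, L=450.0, a=1.0)


def between_molecule_dev(curve, theory):
    """|measured - theory| in units of the curve's standard errors."""
    se = np.where(np.isfinite(curve.se) & (curve.se > 0), curve.se, np.inf)
    return np.abs(curve.R2 - theory.R2) / se
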