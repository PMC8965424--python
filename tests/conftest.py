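import numpy as np
import pandas as pd
import pytest

from avivuln.demographic_model import (
    ConstraintLevel,
    DemographicPriors,
    MCMCConfig,
    MatrixModelSpec,
    PosteriorDraws,
    build_projection_matrix,
    dominant_lambda,
    fit_demographic_model,
    stable_stage_distribution,
)
from avivuln.pipeline_io import demo_config, run_pipeline
from avivuln.synthetic_world import (
    TrueDemography,
    WorldConfig,
    generate_isoscape,
    generate_region_map,
    simulate_index_series,
)


@pytest.fixture(scope="session")
def demog():
    """2-age truth with lambda exactly 1 (phi_a + f*phi_1 = 0.8 + 0.2)."""
    return TrueDemography(phi_by_age=(0.5, 0.8), fecundity=0.4, n_ages=2)


@pytest.fixture(scope="session")
def priors():
    return DemographicPriors(
        survival={"phi_1": (0.5, 0.05), "phi_a": (0.8, 0.04)},
        fecundity=(0.4, 0.1),
    )


@pytest.fixture(scope="session")
def series(demog):
    return simulate_index_series(demog, 48, 0.05, 0.05, 2000, seed=11)


@pytest.fixture(scope="session")
def fits_by_level(series, priors, demog):
    """Desk-scale fits of the three candidate constraint levels."""
    return {
        lv: fit_demographic_model(
            series, priors, ConstraintLevel(lv), demog.model_spec(), MCMCConfig(seed=21)
        )
        for lv in (1, 2, 3)
    }


@pytest.fixture(scope="session")
def chosen_fit(fits_by_level):
    from avivuln.demographic_model import select_model

    sel = select_model(list(fits_by_level.values()))
    assert sel.status == "ok"
    return sel.chosen


def make_point_posterior(params, spec, n=25):
    """Degenerate posterior: every draw equal to one parameter vector."""
    full = dict(params)
    full.setdefault("q", 1.0)
    full.setdefault("sigma", 0.05)
    full.setdefault("n0", 100.0)
    full["lambda"] = dominant_lambda(build_projection_matrix(params, spec))
    df = pd.DataFrame([{"chain": 0, "iter": i, **full} for i in range(n)])
    a = build_projection_matrix(params, spec)
    return PosteriorDraws(
        draws=df,
        loglik=np.zeros(n),
        rhat={},
        dic=0.0,
        level=3,
        converged=True,
        spec=spec,
        priors=None,
        mcmc=MCMCConfig(),
        ssd=stable_stage_distribution(a),
    )


@pytest.fixture(scope="session")
def gradient_world():
    """10x10 world: one-row BCR bands, a clear latitudinal d2H gradient."""
    cfg = WorldConfig(
        grid_rows=10,
        grid_cols=10,
        isoscape_slope=-4.0,
        isoscape_intercept=-30.0,
        cell_sd=3.0,
        n_bcrs=10,
        local_bcr_id=3,
        flyway_members=frozenset(range(8)),
        seed=0,
    )
    return cfg, generate_isoscape(cfg), generate_region_map(cfg)


@pytest.fixture(scope="session")
def demo_runs(tmp_path_factory):
    """Full demo pipeline across three seeds (shared by smoke + acceptance)."""
    out = {}
    for seed in (0, 1, 2):
        d = tmp_path_factory.mktemp(f"demo_seed{seed}")
        out[seed] = (run_pipeline(demo_config(seed=seed), d), d)
    return out
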