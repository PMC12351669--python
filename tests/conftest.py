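import numpy as np
import pandas as pd
import pytest

import lepitrend as lt
from lepitrend.design import DesignSpec
from lepitrend.model import CommunityTrendModel, TrendResults


@pytest.fixture(scope="session")
def small_survey():
    """A small but structurally complete synthetic survey."""
    cfg = lt.SurveyConfig(
        n_sites=6,
        year_range=(2000, 2009),
        n_species=20,
        nights_per_site_year=8,
        seed=11,
    )
    sites, nights, records, species = lt.generate_survey(cfg)
    return cfg, sites, nights, records, species


@pytest.fixture(scope="session")
def small_community(small_survey):
    cfg, sites, nights, records, species = small_survey
    table = lt.build_community_table(
        records, nights, species.assign(dry_mass_mg=1.0)
    )
    return table, nights


def intercept_only_design(n, elev_mean=1000.0, elev_sd=500.0, year_mean=1996.5,
                          year_sd=14.4) -> DesignSpec:
    """Minimal design: intercept, year_z, elev_z, interaction columns."""
    X = np.zeros((n, 4))
    X[:, 0] = 1.0
    return DesignSpec(
        X=X,
        x_names=["intercept", "year_z", "elev_z", "year_z:elev_z"],
        B_doy=np.zeros((n, 0)),
        B_dur=np.zeros((n, 0)),
        group_idx={},
        group_n={},
        standardization={
            "year": (year_mean, year_sd),
            "elev": (elev_mean, elev_sd),
            "temp2d": (0.0, 1.0),
            "precip2d": (0.0, 1.0),
        },
        interaction_col=3,
        year_col=1,
        elev_col=2,
        observed_elev_range=(193.0, 2454.0),
        observed_year_range=(1972, 2021),
    )


def make_results(
    coefs: dict[str, float] | dict[str, np.ndarray],
    pi=0.0,
    n_draws=1,
    design: DesignSpec | None = None,
    family: str = "zinb",
) -> TrendResults:
    """Fabricate a TrendResults with prescribed coefficient draws."""
    from scipy.special import logit

    design = design or intercept_only_design(10)
    y = np.ones(design.n_obs) if family != "zinb" else np.ones(design.n_obs, dtype=int)
    model = CommunityTrendModel(
        y, design, family=family, include_random=False, include_smooths=False
    )
    d = model.layout.size
    draws = np.zeros((2, n_draws, d))
    for name, val in coefs.items():
        j = design.x_names.index(name)
        draws[:, :, model.layout["beta"].start + j] = val
    pi_arr = np.clip(np.asarray(pi, dtype=float), 1e-12, 1 - 1e-12)
    if "logit_pi" in model.layout:
        draws[:, :, model.layout["logit_pi"].start] = logit(pi_arr)
    return TrendResults(model, draws, [], seed=0)
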