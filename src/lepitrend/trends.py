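"""Posterior trend quantities: conditional predictions at elevation
quantiles, change factors and percent changes, threshold elevations,
trait-group tables, and single-species interaction summaries.

All quantities are computed draw-wise from a fitted model's posterior, so
identities such as ``percent = 100 * (factor - 1)`` hold exactly for every
posterior draw, and credible intervals are symmetric quantile intervals
(2.5%, 97.5%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import build_design
from .model import CommunityTrendModel, TrendResults

ELEVATION_QUANTILES = (0.0, 0.25, 0.5, 0.75, 1.0)


def _ci(draws, level=0.95):
    lo, hi = np.percentile(draws, [50 * (1 - level), 100 - 50 * (1 - level)])
    return float(lo), float(hi)


def elevation_at_quantile(fit: TrendResults, q: float) -> float:
    """Elevation (m asl) at quantile ``q`` of the observed elevational range."""
    if not (0.0 <= q <= 1.0):
        raise ValueError("quantile must lie in [0, 1]")
    lo, hi = fit.model.design.observed_elev_range
    return lo + q * (hi - lo)


def conditional_trend(
    fit: TrendResults,
    elevation_quantiles=ELEVATION_QUANTILES,
    n_years: int = 50,
) -> dict[float, pd.DataFrame]:
    """Expected response over the study years at fixed elevations.

    Other continuous covariates sit at their standardized mean (0), factors
    at the sum-to-zero level average, smooths and random effects at 0.  For
    both families the expectation on the natural scale includes the
    ``(1 - pi)`` factor.  Returns per quantile a frame with columns
    ``year``, ``mean``, ``ci2.5``, ``ci97.5``.
    """
    d = fit.model.design
    y0, y1 = d.observed_year_range
    years = np.linspace(y0, y1, min(n_years, y1 - y0 + 1))
    zy = d.standardize("year", years)
    icpt = fit.intercept
    by = fit.beta_year
    be = fit.beta_elev
    byx = fit.beta_yx
    pi = fit.pi
    out = {}
    for q in elevation_quantiles:
        elev = elevation_at_quantile(fit, q)
        ze = float(d.standardize("elev", elev))
        eta = icpt[:, None] + np.outer(by, zy) + be[:, None] * ze + np.outer(byx, zy * ze)
        pred = (1.0 - pi)[:, None] * np.exp(eta)
        lo, hi = np.percentile(pred, [2.5, 97.5], axis=0)
        out[q] = pd.DataFrame(
            {"year": years, "mean": pred.mean(axis=0), "ci2.5": lo, "ci97.5": hi}
        )
    return out


def change_factor(fit: TrendResults, elevation: float) -> dict:
    """Posterior change from the first to the last study year at one
    elevation: multiplicative factor and percent change.

    The ratio of natural-scale predictions leaves only the year terms, so
    ``factor = exp((beta_year + beta_yx * z_e) * (z_last - z_first))``;
    ``percent = 100 * (factor - 1)`` draw-wise.
    """
    d = fit.model.design
    lo, hi = d.observed_elev_range
    if not (lo <= elevation <= hi):
        warnings.warn(
            f"elevation {elevation} m outside observed range [{lo}, {hi}]",
            stacklevel=2,
        )
    ze = float(d.standardize("elev", elevation))
    y0, y1 = d.observed_year_range
    dz = float(d.standardize("year", y1) - d.standardize("year", y0))
    factor = np.exp((fit.beta_year + fit.beta_yx * ze) * dz)
    percent = 100.0 * (factor - 1.0)
    f_lo, f_hi = _ci(factor)
    p_lo, p_hi = _ci(percent)
    return {
        "elevation_m": float(elevation),
        "factor_draws": factor,
        "percent_draws": percent,
        "factor_mean": float(factor.mean()),
        "factor_ci": (f_lo, f_hi),
        "percent_mean": float(percent.mean()),
        "percent_ci": (p_lo, p_hi),
    }


def threshold_elevation(fit: TrendResults) -> dict:
    """Elevation at which year and year x elevation terms cancel.

    Draw-wise ``z* = -beta_year / beta_yx`` back-transformed to metres; a
    zero interaction draw maps to signed infinity.  ``label`` (and the CI
    labels) clip values outside the observed elevational range to
    ``"<min"`` / ``">max"``.
    """
    by = fit.beta_year
    byx = fit.beta_yx
    with np.errstate(divide="ignore", invalid="ignore"):
        z_star = np.where(byx != 0, -by / byx, np.sign(by) * np.inf)
    z_star = np.where((byx == 0) & (by == 0), 0.0, z_star)
    d = fit.model.design
    elev = d.destandardize("elev", z_star)
    lo, hi = d.observed_elev_range

    def _label(v):
        if v < lo:
            return "<min"
        if v > hi:
            return ">max"
        return f"{v:.0f}"

    mean = float(np.mean(elev))
    ci_lo, ci_hi = _ci(elev)
    return {
        "draws_m": elev,
        "mean_m": mean,
        "ci_m": (ci_lo, ci_hi),
        "label": _label(mean),
        "ci_labels": (_label(ci_lo), _label(ci_hi)),
    }


def trend_summary(
    fit: TrendResults,
    response: str,
    group: str = "all",
    elevation_quantiles=ELEVATION_QUANTILES,
) -> pd.DataFrame:
    """Tidy per-elevation-quantile change summary with threshold columns."""
    thr = threshold_elevation(fit)
    rows = []
    for q in elevation_quantiles:
        elev = elevation_at_quantile(fit, q)
        cf = change_factor(fit, elev)
        rows.append(
            {
                "response": response,
                "group": group,
                "elev_quantile": q,
                "elevation_m": elev,
                "factor_mean": cf["factor_mean"],
                "factor_ci2.5": cf["factor_ci"][0],
                "factor_ci97.5": cf["factor_ci"][1],
                "percent_mean": cf["percent_mean"],
                "percent_ci2.5": cf["percent_ci"][0],
                "percent_ci97.5": cf["percent_ci"][1],
                "threshold_mean_m": thr["mean_m"],
                "threshold_label": thr["label"],
                "threshold_ci2.5": thr["ci_labels"][0],
                "threshold_ci97.5": thr["ci_labels"][1],
            }
        )
    return pd.DataFrame(rows)


def run_trait_group_models(
    community: pd.DataFrame,
    nights: pd.DataFrame,
    responses=("abundance", "richness_cc", "biomass_mg"),
    groups=None,
    fit_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Fit one model per trait group x response; assemble a long summary.

    Groups whose response is zero on every night are skipped with a
    warning.  ``fit_kwargs`` are passed to :meth:`CommunityTrendModel.fit`
    (e.g. reduced chains for scaled runs).
    """
    fit_kwargs = dict(fit_kwargs or {})
    if groups is None:
        groups = [g for g in community["group"].unique() if g != "all"]
    frames = []
    for group in groups:
        for response in responses:
            sub = community[community["group"] == group]
            if sub.empty or (sub[response] == 0).all():
                warnings.warn(
                    f"group {group!r}: all-zero {response}; skipped", stacklevel=2
                )
                continue
            model = CommunityTrendModel.from_tables(
                community, nights, response=response, group=group
            )
            fit = model.fit(**fit_kwargs)
            frames.append(trend_summary(fit, response, group))
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# single-species models
# ---------------------------------------------------------------------------


@dataclass
class SpeciesCoefficient:
    """Posterior of one species' year x elevation interaction."""

    species_id: str
    draws: np.ndarray
    total_abundance: int
    rescaled_factor: float
    traits: dict = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(np.mean(self.draws))

    @property
    def ci(self) -> tuple[float, float]:
        return _ci(self.draws)


def rescale_interaction(beta_yx, sd_year: float, sd_elev: float):
    """Per-decade-per-1000 m change factor of the interaction:
    ``exp(beta_yx * (10 / sd_year) * (1000 / sd_elev))``.

    A value of 2 means a species whose 10-year change factor is 0.5 at some
    elevation has factor 1.0 at an elevation 1000 m higher.
    """
    if sd_year <= 0 or sd_elev <= 0:
        raise ValueError("standardization SDs must be > 0")
    return np.exp(np.asarray(beta_yx, dtype=float) * (10.0 / sd_year) * (1000.0 / sd_elev))


def species_site_year_occupancy(records: pd.DataFrame, nights: pd.DataFrame) -> pd.Series:
    """Unique (site, year) combinations in which each species was recorded."""
    j = records.merge(nights[["night_id", "site_id", "year"]], on="night_id")
    return j.groupby("species_id").apply(
        lambda g: g[["site_id", "year"]].drop_duplicates().shape[0],
        include_groups=False,
    )


def single_species_models(
    records: pd.DataFrame,
    nights: pd.DataFrame,
    species: pd.DataFrame | None = None,
    min_site_years: int = 100,
    fit_kwargs: dict | None = None,
) -> list[SpeciesCoefficient]:
    """Abundance models per species (zeros filled) with the community
    model's structure; species recorded in fewer than ``min_site_years``
    unique site-year combinations are excluded."""
    fit_kwargs = dict(fit_kwargs or {})
    occ = species_site_year_occupancy(records, nights)
    keep = occ[occ >= min_site_years].index
    design = build_design(nights)
    trait_lookup = {}
    if species is not None:
        trait_cols = [
            c for c in ("size_group", "temp_group", "food_spec", "overwinter", "trait_group")
            if c in species.columns
        ]
        trait_lookup = species.set_index("species_id")[trait_cols].to_dict("index")
    sd_year = design.standardization["year"][1]
    sd_elev = design.standardization["elev"][1]
    out = []
    night_order = nights["night_id"].to_numpy()
    for sp in keep:
        counts = (
            records.loc[records["species_id"] == sp]
            .set_index("night_id")["count"]
            .reindex(night_order, fill_value=0)
            .to_numpy()
        )
        model = CommunityTrendModel(counts, design, family="zinb")
        try:
            fit = model.fit(**fit_kwargs)
        except Exception as err:  # fit failures logged, not fatal
            warnings.warn(f"species {sp}: fit failed ({err})", stacklevel=2)
            continue
        draws = fit.beta_yx
        out.append(
            SpeciesCoefficient(
                species_id=sp,
                draws=draws,
                total_abundance=int(counts.sum()),
                rescaled_factor=float(rescale_interaction(np.mean(draws), sd_year, sd_elev)),
                traits=trait_lookup.get(sp, {}),
            )
        )
    return out


def proportion_positive(
    coefficients: list[SpeciesCoefficient], seed: int = 0
) -> dict:
    """Fraction of species with a positive interaction coefficient.

    Per posterior draw (independent fits, so draws are permuted within each
    species first), the fraction of species whose coefficient draw is
    positive; summarized by the mean and symmetric 95% interval over draws.
    """
    if not coefficients:
        raise ValueError("no species coefficients")
    rng = np.random.default_rng(seed)
    n_draws = min(len(c.draws) for c in coefficients)
    mat = np.stack([rng.permutation(c.draws)[:n_draws] for c in coefficients])
    frac = 100.0 * np.mean(mat > 0, axis=0)
    lo, hi = _ci(frac)
    return {"mean_pct": float(frac.mean()), "ci_pct": (lo, hi), "draws_pct": frac}


def weighted_mean_interaction(
    coefficients: list[SpeciesCoefficient],
    trait: str | None = None,
) -> pd.DataFrame:
    """Abundance-weighted mean rescaled interaction per trait class.

    Weights are each species' total abundance in the dataset; the CI comes
    from the posterior draws of the weighted mean.  With ``trait=None`` a
    single "all" class is summarized.
    """
    if not coefficients:
        raise ValueError("no species coefficients")

    def _classes():
        if trait is None:
            return {"all": coefficients}
        grouped: dict[str, list[SpeciesCoefficient]] = {}
        for c in coefficients:
            label = c.traits.get(trait)
            if label is None or (isinstance(label, float) and np.isnan(label)):
                continue
            grouped.setdefault(str(label), []).append(c)
        return grouped

    rows = []
    for label, coefs in _classes().items():
        w = np.array([c.total_abundance for c in coefs], dtype=float)
        if np.all(w == 0):
            raise ValueError(f"all-zero weights in class {label!r}")
        n_draws = min(len(c.draws) for c in coefs)
        mat = np.stack([c.draws[:n_draws] for c in coefs])
        wmean_draws = (w[:, None] * mat).sum(axis=0) / w.sum()
        lo, hi = _ci(wmean_draws)
        rows.append(
            {
                "class": label,
                "n_species": len(coefs),
                "weighted_mean": float(wmean_draws.mean()),
                "ci2.5": lo,
                "ci97.5": hi,
            }
        )
    return pd.DataFrame(rows)


def sign_change_point(
    coefficients: list[SpeciesCoefficient],
    n_boot: int = 10_000,
    seed: int = 0,
) -> dict:
    """Position where species sorted by posterior-mean coefficient switch
    from negative to positive, with a bootstrap 95% CI over species.

    The crossing equals the count of species with negative posterior mean;
    the bootstrap resamples species with replacement.  All-one-sign inputs
    give a degenerate, flagged result.
    """
    if len(coefficients) < 2:
        raise ValueError("need at least 2 species")
    means = np.array([c.mean for c in coefficients])
    crossing = int(np.sum(means < 0))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(means), size=(n_boot, len(means)))
    boot = np.sum(means[idx] < 0, axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    degenerate = crossing == 0 or crossing == len(means)
    return {
        "crossing": crossing,
        "ci": (float(lo), float(hi)),
        "degenerate": degenerate,
        "n_species": len(means),
    }
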