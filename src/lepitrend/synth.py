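"""Synthetic light-trap surveys with known ground truth.

The generator emulates a 50-year alpine light-trapping scheme: sites spread
over an elevational gradient, each active in a contiguous block of years;
trap nights with design covariates (trap type, lamp type, number of traps,
previous-night indicator, sampling duration for manual traps) and weather
(two-day mean temperature / precipitation sum); and per-night x species
counts drawn from a zero-inflated negative binomial whose log-mean carries a
year x elevation interaction, a seasonal activity curve, and nested random
effects (site, site-year, night group, spatio-temporal cluster).

Every quantity is driven by a single integer seed, so identical
configurations reproduce byte-identical tables.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .design import build_spatiotemporal_clusters

TRAP_TYPES = ("fixed1", "fixed2", "manual")
LAMP_TYPES = ("mercury", "actinic", "blacklight", "mixed")


def gaussian_season(doy, peak: float = 190.0, sd: float = 45.0, amplitude: float = 1.5):
    """Default seasonal activity curve: log-scale Gaussian bump peaking in
    mid-summer (day 190, sd 45 d), minus its annual mean so it is centred."""
    doy = np.asarray(doy, dtype=float)
    raw = amplitude * np.exp(-0.5 * ((doy - peak) / sd) ** 2)
    grid = np.arange(1, 367, dtype=float)
    mean = np.mean(amplitude * np.exp(-0.5 * ((grid - peak) / sd) ** 2))
    return raw - mean


@dataclass
class GenerativeParams:
    """Ground-truth parameters of the count process (log link).

    Slopes act on standardized year/elevation; ``group_modifiers`` adds
    per-trait-group offsets to ``beta_year``/``beta_yx`` so that groups can
    be given contrasting trends.  ``sigma_species`` spreads species' base
    abundances (log scale) to create realistic rank-abundance variation.
    """

    beta0: float = -1.0
    beta_year: float = 0.0
    beta_elev: float = 0.3
    beta_yx: float = 0.3
    pi0: float = 0.4
    phi: float = 0.6
    sigma_site: float = 0.5
    sigma_siteyear: float = 0.3
    sigma_night: float = 0.3
    sigma_cluster: float = 0.2
    sigma_species: float = 0.75
    season_curve: Callable = gaussian_season
    group_modifiers: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.phi <= 0:
            raise ValueError("phi must be > 0")
        if not (0.0 <= self.pi0 <= 1.0):
            raise ValueError("pi0 must lie in [0, 1]")
        for name in ("sigma_site", "sigma_siteyear", "sigma_night", "sigma_cluster", "sigma_species"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SurveyConfig:
    """Layout of a synthetic survey: how many sites/species/nights, which
    years and elevations, and the generative truth."""

    n_sites: int = 20
    year_range: tuple[int, int] = (1972, 2021)
    elev_range: tuple[float, float] = (193.0, 2454.0)
    n_species: int = 60
    nights_per_site_year: int = 30
    seed: int = 0
    true_params: GenerativeParams = field(default_factory=GenerativeParams)

    def __post_init__(self):
        if self.n_sites < 2:
            raise ValueError("need at least 2 sites")
        if self.year_range[1] < self.year_range[0]:
            raise ValueError("empty year range")
        lo, hi = self.elev_range
        if not (0 <= lo < hi <= 5000):
            raise ValueError("elevation range must be within [0, 5000] m")
        if self.n_species < 1:
            raise ValueError("need at least 1 species")


def _stratified(levels, n, weights, rng):
    """Deterministically cover every level, allocating ~proportionally to
    ``weights``, then permute."""
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    alloc = np.maximum(np.round(weights * n).astype(int), 1 if n >= len(levels) else 0)
    while alloc.sum() > n:
        alloc[np.argmax(alloc)] -= 1
    while alloc.sum() < n:
        alloc[np.argmax(weights - alloc / max(n, 1))] += 1
    arr = np.repeat(np.arange(len(levels)), alloc)
    rng.shuffle(arr)
    return np.asarray(levels, dtype=object)[arr]


def generate_species(config: SurveyConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Species pool with latent thermal niches, wingspans, overwintering
    stages and the trait-group labels the group modifiers key on."""
    n = config.n_species
    ids = [f"sp{i:04d}" for i in range(n)]
    n_genera = max(n // 3, 1)
    genera = [f"Genus{rng.integers(0, n_genera):03d}" for _ in range(n)]
    wingspan = np.round(np.exp(rng.normal(np.log(32.0), 0.35, n)), 1)
    # a few species lack wingspan data, like real trait compilations
    miss = rng.random(n) < 0.05
    wingspan = np.where(miss, np.nan, wingspan)
    niche = rng.normal(8.0, 3.0, n)
    overwinter = _stratified(["egg", "larva", "pupa", "adult"], n, [0.15, 0.45, 0.3, 0.1], rng)
    base = rng.normal(0.0, 1.0, n)  # unit-scale species effect, scaled by sigma_species
    df = pd.DataFrame(
        {
            "species_id": ids,
            "genus": genera,
            "wingspan_mm": wingspan,
            "latent_niche_degC": niche,
            "overwinter": overwinter,
            "species_effect_raw": base,
        }
    )
    # trait groups from niche tertiles (cold-adapted = low)
    q33, q66 = np.quantile(niche, [0.33, 0.66])
    df["trait_group"] = np.where(niche <= q33, "low", np.where(niche <= q66, "mid", "high"))
    return df


def generate_sites(config: SurveyConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sites uniformly spread over the elevation range, with planar km
    coordinates and contiguous random activity windows."""
    n = config.n_sites
    lo, hi = config.elev_range
    elev = np.linspace(lo, hi, n) if n > 1 else np.array([(lo + hi) / 2])
    elev = elev + rng.uniform(-1, 1, n) * (hi - lo) / (4 * max(n - 1, 1))
    elev = np.clip(elev, lo, hi)
    y0, y1 = config.year_range
    n_years = y1 - y0 + 1
    starts = rng.integers(0, n_years, n)
    lengths = rng.integers(max(1, n_years // 4), n_years + 1, n)
    ends = np.minimum(starts + lengths - 1, n_years - 1)
    return pd.DataFrame(
        {
            "site_id": [f"site{i:03d}" for i in range(n)],
            "elev_m": np.round(elev, 0),
            "x_km": np.round(rng.uniform(0, 300, n), 2),
            "y_km": np.round(rng.uniform(0, 200, n), 2),
            "year_start": y0 + starts,
            "year_end": y0 + ends,
        }
    )


def _dates_for(year: int, n: int, rng: np.random.Generator) -> list[_dt.date]:
    doys = np.sort(rng.choice(np.arange(1, 366), size=min(n, 365), replace=False))
    return [_dt.date(year, 1, 1) + _dt.timedelta(days=int(d) - 1) for d in doys]


def generate_nights(config: SurveyConfig, sites: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Trap nights for each active site-year with design covariates and
    elevation-coupled weather (lapse rate -0.0055 degC/m, AR(1) day noise)."""
    rows = []
    for site in sites.itertuples(index=False):
        for year in range(site.year_start, site.year_end + 1):
            dates = _dates_for(year, config.nights_per_site_year, rng)
            k = len(dates)
            if k == 0:
                continue
            trap = _stratified(TRAP_TYPES, k, [0.50, 0.39, 0.11], rng)
            lamp = _stratified(LAMP_TYPES, k, [0.4, 0.3, 0.2, 0.1], rng)
            ntraps = _stratified([1, 2, 3, 4], k, [0.55, 0.25, 0.12, 0.08], rng)
            # AR(1) temperature noise across the site-year's night sequence
            noise = np.empty(k)
            noise[0] = rng.normal(0, 3.0)
            for i in range(1, k):
                noise[i] = 0.6 * noise[i - 1] + rng.normal(0, 3.0 * np.sqrt(1 - 0.36))
            for i, date in enumerate(dates):
                doy = date.timetuple().tm_yday
                seasonal = 10.0 * np.sin(2 * np.pi * (doy - 105) / 365.0)
                temp = 14.0 - 0.0055 * site.elev_m + seasonal + noise[i]
                precip = float(np.round(rng.gamma(1.2, 8.0), 1))
                is_manual = trap[i] == "manual"
                if is_manual:
                    dur = float(np.round(rng.uniform(1.0, 13.0), 1))
                    if rng.random() < 0.30:  # ~30% of manual nights lack duration info
                        dur = np.nan
                else:
                    dur = np.nan
                rows.append(
                    {
                        "site_id": site.site_id,
                        "date": date.isoformat(),
                        "year": year,
                        "day_of_year": doy,
                        "trap_type": trap[i],
                        "lamp_type": lamp[i],
                        "n_traps": int(ntraps[i]),
                        "duration_h": dur,
                        "temp2d_degC": float(np.round(temp, 2)),
                        "precip2d_mm": precip,
                    }
                )
    nights = pd.DataFrame(rows)
    if nights.empty:
        return pd.DataFrame(
            columns=[
                "night_id", "site_id", "date", "year", "day_of_year", "trap_type",
                "lamp_type", "n_traps", "prev_night_sampled", "duration_h",
                "temp2d_degC", "precip2d_mm",
            ]
        )
    nights = nights.sort_values(["site_id", "date"], kind="stable").reset_index(drop=True)
    nights["night_id"] = [f"n{i:06d}" for i in range(len(nights))]
    # previous-night indicator from actual date sequences per site
    prev = []
    by_site = {s: set(g["date"]) for s, g in nights.groupby("site_id")}
    for r in nights.itertuples(index=False):
        d = _dt.date.fromisoformat(r.date) - _dt.timedelta(days=1)
        prev.append("yes" if d.isoformat() in by_site[r.site_id] else "no")
    nights["prev_night_sampled"] = prev
    cols = [
        "night_id", "site_id", "date", "year", "day_of_year", "trap_type", "lamp_type",
        "n_traps", "prev_night_sampled", "duration_h", "temp2d_degC", "precip2d_mm",
    ]
    return nights[cols]


def attach_groupings(nights: pd.DataFrame, sites: pd.DataFrame, radius_km: float = 20.0) -> pd.DataFrame:
    """Add spatio-temporal cluster and night-group ids to a nights table.

    Clusters chain sites within ``radius_km`` of each other within a year;
    nights on the same date at sites of the same cluster share a night
    group (simultaneously operated sites)."""
    out = nights.copy()
    coords = sites.set_index("site_id")[["x_km", "y_km"]]
    site_years = out[["site_id", "year"]].drop_duplicates()
    clusters = build_spatiotemporal_clusters(coords, site_years, radius_km=radius_km)
    out["st_cluster"] = [
        clusters[(s, y)] for s, y in zip(out["site_id"], out["year"])
    ]
    out["night_group"] = out["st_cluster"].astype(str) + "|" + out["date"].astype(str)
    out["site_year"] = out["site_id"] + "|" + out["year"].astype(str)
    return out


def simulate_counts(
    nights: pd.DataFrame,
    species: pd.DataFrame,
    params: GenerativeParams,
    seed: int,
) -> pd.DataFrame:
    """Draw per-night x species ZINB counts and return the nonzero records.

    ``log mu = beta0 + (beta_year + g_year) z_year + beta_elev z_elev +
    (beta_yx + g_yx) z_year z_elev + season(doy) + u_site + u_siteyear +
    u_night + u_cluster + sigma_species * species_effect``; each cell is
    zeroed with probability ``pi0`` before the NB draw.  Standardization
    constants are the mean/SD of the nights actually passed in.
    """
    if params.phi <= 0:
        raise ValueError("phi must be > 0")
    rng = np.random.default_rng(seed)
    if nights.empty or species.empty:
        return pd.DataFrame(columns=["night_id", "species_id", "count"])
    need = {"st_cluster", "night_group", "site_year"}
    if not need.issubset(nights.columns):
        raise ValueError("nights must carry grouping columns (use attach_groupings)")

    elev = nights["elev_m"].to_numpy(dtype=float)
    year = nights["year"].to_numpy(dtype=float)
    zy = (year - year.mean()) / (year.std() if year.std() > 0 else 1.0)
    ze = (elev - elev.mean()) / (elev.std() if elev.std() > 0 else 1.0)
    season = params.season_curve(nights["day_of_year"].to_numpy())

    def _re(col, sigma):
        levels, idx = np.unique(nights[col].to_numpy(), return_inverse=True)
        u = rng.normal(0.0, 1.0, len(levels)) * sigma
        return u[idx]

    u = (
        _re("site_id", params.sigma_site)
        + _re("site_year", params.sigma_siteyear)
        + _re("night_group", params.sigma_night)
        + _re("st_cluster", params.sigma_cluster)
    )
    night_part = season + u  # (n_nights,)

    g_year = np.zeros(len(species))
    g_yx = np.zeros(len(species))
    if params.group_modifiers:
        for i, g in enumerate(species["trait_group"]):
            dy, dyx = params.group_modifiers.get(g, (0.0, 0.0))
            g_year[i] = dy
            g_yx[i] = dyx
    sp_eff = params.sigma_species * species["species_effect_raw"].to_numpy(dtype=float)

    eta = (
        params.beta0
        + night_part[:, None]
        + np.outer(zy, params.beta_year + g_year)
        + params.beta_elev * ze[:, None]
        + np.outer(zy * ze, params.beta_yx + g_yx)
        + sp_eff[None, :]
    )
    mu = np.exp(eta)
    p_nb = params.phi / (params.phi + mu)
    y = rng.negative_binomial(params.phi, p_nb)
    if params.pi0 > 0:
        y = np.where(rng.random(mu.shape) < params.pi0, 0, y)

    nz = np.nonzero(y)
    return pd.DataFrame(
        {
            "night_id": nights["night_id"].to_numpy()[nz[0]],
            "species_id": species["species_id"].to_numpy()[nz[1]],
            "count": y[nz].astype(int),
        }
    )


def generate_survey(config: SurveyConfig):
    """Full synthetic survey: ``(sites, nights, records, species)``.

    Nights carry elevation, grouping ids and covariates; records hold only
    nonzero counts.  Identical config (incl. seed) gives identical output.
    """
    rng = np.random.default_rng(config.seed)
    species = generate_species(config, rng)
    sites = generate_sites(config, rng)
    nights = generate_nights(config, sites, rng)
    if nights.empty:
        records = pd.DataFrame(columns=["night_id", "species_id", "count"])
        return sites, nights, records, species
    nights = nights.merge(sites[["site_id", "elev_m"]], on="site_id", how="left")
    nights = attach_groupings(nights, sites)
    records = simulate_counts(
        nights, species, config.true_params, seed=int(rng.integers(0, 2**31 - 1))
    )
    return sites, nights, records, species


def generate_host_records(species: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Synthetic larval host-plant records for food-specialisation classes.

    Roughly a third of species each get hosts from one genus, several genera
    of one family, or several families."""
    rng = np.random.default_rng(seed)
    families = [f"Fam{i:02d}" for i in range(12)]
    genera = {f: [f"{f}_Gen{j}" for j in range(4)] for f in families}
    rows = []
    for i, sp in enumerate(species["species_id"]):
        mode = rng.integers(0, 3)
        if mode == 0:  # monophagous
            fam = families[rng.integers(0, len(families))]
            gen = genera[fam][rng.integers(0, 4)]
            rows.append((sp, gen, fam))
        elif mode == 1:  # oligophagous
            fam = families[rng.integers(0, len(families))]
            gs = rng.choice(4, size=2, replace=False)
            for g in gs:
                rows.append((sp, genera[fam][g], fam))
        else:  # polyphagous
            fs = rng.choice(len(families), size=2, replace=False)
            for f in fs:
                fam = families[f]
                rows.append((sp, genera[fam][rng.integers(0, 4)], fam))
    return pd.DataFrame(rows, columns=["species_id", "plant_genus", "plant_family"])


def generate_occurrence_grid(
    species: pd.DataFrame, n_cells: int, seed: int
) -> tuple[pd.Series, pd.DataFrame]:
    """Occurrence-by-grid-cell table with cell mean temperatures.

    Cells span a 0-14 degC gradient; each species occupies cells with
    probability decaying in the distance between the cell temperature and
    its latent niche, so the plain cell-mean STI recovers the niche ranking.
    Species occupying no cell are simply absent from the table (no STI).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    temps = np.round(np.sort(rng.uniform(0.0, 14.0, n_cells)), 2)
    cells = pd.Series(temps, index=[f"cell{i:04d}" for i in range(n_cells)], name="temp_degC")
    rows = []
    for sp, niche in zip(species["species_id"], species["latent_niche_degC"]):
        p = 0.85 * np.exp(-0.5 * ((temps - niche) / 1.5) ** 2)
        occ = rng.random(n_cells) < p
        for cid in cells.index[occ]:
            rows.append((sp, cid))
    occurrences = pd.DataFrame(rows, columns=["species_id", "cell_id"])
    return cells, occurrences


def default_survey(seed: int = 0, **overrides) -> SurveyConfig:
    """Convenience constructor for the standard study-scale configuration."""
    cfg = SurveyConfig(seed=seed)
    if overrides:
        params = overrides.pop("true_params", cfg.true_params)
        cfg = replace(cfg, true_params=params, **overrides)
    return cfg
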