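"""Model design: standardization, sum-to-zero contrasts, spline bases and
grouping structures for the hierarchical community models.

Continuous predictors are standardized to mean 0 / SD 1 (constants kept for
back-transformation to calendar years and metres); nominal factors get
sum-to-zero contrasts so the intercept is the grand mean across levels; the
seasonal term is a cyclic cubic B-spline in day of year; sampling duration
gets a small B-spline applied only to manual-trap nights with known
duration, with a separate indicator for manual nights lacking the
information.  Sites within 20 km of each other in the same year are chained
into spatio-temporal clusters (connected components, single linkage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import distance_matrix

FACTOR_COLUMNS = ("trap_type", "lamp_type", "n_traps", "prev_night_sampled")


# ---------------------------------------------------------------------------
# spatio-temporal clustering
# ---------------------------------------------------------------------------


def _pairwise_km(coords: pd.DataFrame, geodesic: bool) -> np.ndarray:
    xy = coords.to_numpy(dtype=float)
    if not geodesic:
        return distance_matrix(xy, xy)
    # great-circle distance on (lon, lat) in degrees
    lon = np.radians(xy[:, 0])[:, None]
    lat = np.radians(xy[:, 1])[:, None]
    dlon = lon - lon.T
    dlat = lat - lat.T
    a = np.sin(dlat / 2) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2) ** 2
    return 6371.0 * 2 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def build_spatiotemporal_clusters(
    site_coords: pd.DataFrame,
    site_years: pd.DataFrame,
    radius_km: float = 20.0,
    geodesic: bool = False,
    clique: bool = False,
) -> dict:
    """Cluster ids per (site, year): within each year, sites linked whenever
    <= ``radius_km`` apart are merged transitively (connected components).

    ``site_coords``: indexed by site_id with two coordinate columns (planar
    km, or lon/lat with ``geodesic=True``).  ``clique=True`` instead keeps
    only maximal groups in which *every* pair is within the radius (greedy).
    Returns ``{(site_id, year): "year|c<k>"}``.
    """
    missing = set(site_years["site_id"]) - set(site_coords.index)
    if missing:
        raise KeyError(f"sites without coordinates: {sorted(missing)[:5]}")
    out = {}
    for year, grp in site_years.groupby("year"):
        ids = sorted(grp["site_id"].unique())
        sub = site_coords.loc[ids]
        d = _pairwise_km(sub, geodesic)
        adj = d <= radius_km
        if clique:
            labels = np.full(len(ids), -1)
            nxt = 0
            for i in range(len(ids)):
                if labels[i] >= 0:
                    continue
                members = [i]
                for j in range(i + 1, len(ids)):
                    if labels[j] < 0 and all(adj[j, m] for m in members):
                        members.append(j)
                for m in members:
                    labels[m] = nxt
                nxt += 1
        else:
            _, labels = connected_components(csr_matrix(adj), directed=False)
        for sid, lab in zip(ids, labels):
            out[(sid, int(year))] = f"{year}|c{lab}"
    return out


# ---------------------------------------------------------------------------
# bases and contrasts
# ---------------------------------------------------------------------------


def sum_to_zero_contrasts(levels) -> tuple[list, np.ndarray]:
    """Contrast matrix (n_levels x n_levels-1) whose rows sum to zero:
    levels 1..L-1 are indicator columns, the last level is -1 everywhere."""
    levels = list(levels)
    L = len(levels)
    if L < 2:
        raise ValueError(f"factor needs >= 2 levels, got {levels}")
    C = np.vstack([np.eye(L - 1), -np.ones((1, L - 1))])
    return levels, C


def encode_factor(values: pd.Series, name: str) -> tuple[np.ndarray, list[str]]:
    levels = sorted(pd.unique(values.astype(str)))
    levels, C = sum_to_zero_contrasts(levels)
    idx = pd.Categorical(values.astype(str), categories=levels).codes
    X = C[idx]
    names = [f"{name}[S.{lv}]" for lv in levels[:-1]]
    return X, names


def bspline_basis(x, n_basis: int, lo: float, hi: float) -> np.ndarray:
    """Clamped cubic B-spline basis with ``n_basis`` columns on [lo, hi]."""
    if n_basis < 4:
        raise ValueError("cubic basis needs >= 4 functions")
    n_inner = n_basis - 4
    inner = np.linspace(lo, hi, n_inner + 2)[1:-1] if n_inner > 0 else np.array([])
    t = np.concatenate([[lo] * 4, inner, [hi] * 4])
    x = np.clip(np.asarray(x, dtype=float), lo, hi)
    return BSpline.design_matrix(x, t, 3).toarray()


def cyclic_bspline_basis(x, n_basis: int, lo: float = 0.5, hi: float = 366.5) -> np.ndarray:
    """Periodic cubic B-spline basis: ``n_basis`` columns, wrap-around at
    the period boundary (values at lo and hi coincide)."""
    period = hi - lo
    k = n_basis
    step = period / k
    knots = lo + np.arange(-3, k + 4) * step
    xm = lo + np.mod(np.asarray(x, dtype=float) - lo, period)
    n_ext = len(knots) - 4  # k + 3 unwrapped functions
    M = BSpline.design_matrix(xm, knots, 3).toarray()
    if M.shape[1] < n_ext:  # design_matrix trims trailing empty columns
        M = np.pad(M, ((0, 0), (0, n_ext - M.shape[1])))
    B = M[:, :k].copy()
    B[:, :3] += M[:, k : k + 3]
    return B


# ---------------------------------------------------------------------------
# the assembled design
# ---------------------------------------------------------------------------


@dataclass
class DesignSpec:
    """Model matrices plus everything needed to interpret them."""

    X: np.ndarray
    x_names: list[str]
    B_doy: np.ndarray
    B_dur: np.ndarray
    group_idx: dict[str, np.ndarray]
    group_n: dict[str, int]
    standardization: dict[str, tuple[float, float]]
    interaction_col: int
    year_col: int
    elev_col: int
    observed_elev_range: tuple[float, float]
    observed_year_range: tuple[int, int]
    doy_centre: np.ndarray = field(default=None)

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    def standardize(self, name: str, value):
        m, s = self.standardization[name]
        return (np.asarray(value, dtype=float) - m) / s

    def destandardize(self, name: str, z):
        m, s = self.standardization[name]
        return m + s * np.asarray(z, dtype=float)


def _zscore(values: np.ndarray, name: str) -> tuple[np.ndarray, tuple[float, float]]:
    m = float(np.mean(values))
    s = float(np.std(values))
    if s == 0:
        raise ValueError(f"cannot standardize constant covariate {name!r} (SD = 0)")
    return (values - m) / s, (m, s)


def build_design(
    nights: pd.DataFrame,
    n_doy_basis: int = 8,
    n_dur_basis: int = 4,
) -> DesignSpec:
    """Build the fixed-effect matrix, spline bases and grouping indices.

    ``nights`` must carry elevation (``elev_m``), the design covariates of a
    trap night, and the grouping ids ``site_id``/``site_year``/``night_group``
    /``st_cluster`` (see ``synth.attach_groupings`` for synthetic surveys).
    """
    if nights.empty:
        raise ValueError("nights table is empty")
    cols = {}
    consts = {}
    for name, col in [
        ("year", "year"),
        ("elev", "elev_m"),
        ("temp2d", "temp2d_degC"),
        ("precip2d", "precip2d_mm"),
    ]:
        z, ms = _zscore(nights[col].to_numpy(dtype=float), col)
        cols[name] = z
        consts[name] = ms

    parts = [np.ones((len(nights), 1)), cols["year"][:, None], cols["elev"][:, None]]
    names = ["intercept", "year_z", "elev_z"]
    parts.append((cols["year"] * cols["elev"])[:, None])
    names.append("year_z:elev_z")
    parts.append(cols["temp2d"][:, None])
    names.append("temp2d_z")
    parts.append(cols["precip2d"][:, None])
    names.append("precip2d_z")

    for fac in FACTOR_COLUMNS:
        Xf, fnames = encode_factor(nights[fac], fac)
        parts.append(Xf)
        names.extend(fnames)

    manual = (nights["trap_type"].astype(str) == "manual").to_numpy()
    dur = nights["duration_h"].to_numpy(dtype=float)
    dur_known = manual & ~np.isnan(dur)
    dur_missing = manual & np.isnan(dur)
    parts.append(dur_missing.astype(float)[:, None])
    names.append("duration_missing")

    X = np.hstack(parts)

    B_doy = cyclic_bspline_basis(nights["day_of_year"].to_numpy(), n_doy_basis)
    doy_centre = B_doy.mean(axis=0)
    B_doy = B_doy - doy_centre

    B_dur = np.zeros((len(nights), n_dur_basis))
    if dur_known.any():
        Bd = bspline_basis(dur[dur_known], n_dur_basis, 1.0, 13.0)
        Bd = Bd - Bd.mean(axis=0)
        B_dur[dur_known] = Bd

    group_idx = {}
    group_n = {}
    for gname, col in [
        ("site", "site_id"),
        ("site_year", "site_year"),
        ("night", "night_group"),
        ("cluster", "st_cluster"),
    ]:
        levels, idx = np.unique(nights[col].astype(str).to_numpy(), return_inverse=True)
        group_idx[gname] = idx
        group_n[gname] = len(levels)

    elev = nights["elev_m"].to_numpy(dtype=float)
    return DesignSpec(
        X=X,
        x_names=names,
        B_doy=B_doy,
        B_dur=B_dur,
        group_idx=group_idx,
        group_n=group_n,
        standardization=consts,
        interaction_col=names.index("year_z:elev_z"),
        year_col=names.index("year_z"),
        elev_col=names.index("elev_z"),
        observed_elev_range=(float(elev.min()), float(elev.max())),
        observed_year_range=(int(nights["year"].min()), int(nights["year"].max())),
        doy_centre=doy_centre,
    )
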