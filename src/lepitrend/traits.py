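"""Species trait derivation: body mass allometry, temperature niche,
food specialisation, overwintering stage and quantile trait groups.

Dry mass is estimated in two steps: wingspan (widely catalogued) is mapped
to forewing length with an ordinary least-squares line fitted on species
with both measurements, and forewing length enters a log-log power law
``mass = a * FL**b``.  Species without wingspan data receive the mean
estimated mass of their congeners; singleton genera are flagged unresolved.

The Species Temperature Index (STI) summarises a species' realised thermal
niche as the unweighted mean temperature of the distinct 50x50 km grid
cells holding at least one occurrence record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

FOOD_CLASSES = ("monophagous", "oligophagous", "polyphagous")
OVERWINTER_STAGES = ("egg", "larva", "pupa", "adult")
GROUP_LABELS = ("low", "mid", "high")


@dataclass(frozen=True)
class AllometryParams:
    """Wingspan -> forewing line and forewing -> dry-mass power law.

    ``ws_to_fl``: (intercept, slope) in mm; ``fl_to_mass``: (ln_a, b) of
    ``mass_mg = exp(ln_a) * FL_mm**b``.  The power-law coefficients ship as
    configuration; the default is a generic lepidopteran allometry
    (ln a = -3.2, b = 2.63) and should be overridden when calibrated
    coefficients are available.
    """

    ws_to_fl: tuple[float, float] = (0.0, 0.47)
    fl_to_mass: tuple[float, float] = (-3.2, 2.63)

    def __post_init__(self):
        if self.ws_to_fl[1] <= 0:
            raise ValueError("wingspan->forewing slope must be > 0")
        if self.fl_to_mass[1] <= 0:
            raise ValueError("mass exponent b must be > 0")


def fit_wingspan_to_forewing(
    pairs: Sequence[tuple[float, float]],
) -> tuple[float, float, float]:
    """OLS fit of forewing length on wingspan.

    Returns ``(intercept, slope, residual_sd)``.  Requires at least three
    pairs and a non-constant predictor.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (wingspan, forewing) pairs")
    ws, fl = arr[:, 0], arr[:, 1]
    if np.ptp(ws) == 0:
        raise ValueError("singular fit: wingspan is constant")
    X = np.column_stack([np.ones_like(ws), ws])
    coef, _, _, _ = np.linalg.lstsq(X, fl, rcond=None)
    resid = fl - X @ coef
    dof = max(len(ws) - 2, 1)
    resid_sd = float(np.sqrt(np.sum(resid**2) / dof))
    return float(coef[0]), float(coef[1]), resid_sd


def estimate_forewing(wingspan_mm, ws_to_fl: tuple[float, float]):
    intercept, slope = ws_to_fl
    return intercept + slope * np.asarray(wingspan_mm, dtype=float)


def estimate_dry_mass(forewing_mm, fl_to_mass: tuple[float, float]):
    """Power-law dry mass ``exp(ln_a) * FL**b`` in mg."""
    fl = np.asarray(forewing_mm, dtype=float)
    if np.any(fl <= 0):
        raise ValueError("forewing length must be > 0")
    ln_a, b = fl_to_mass
    return np.exp(ln_a) * fl**b


def impute_missing_mass(species: pd.DataFrame) -> pd.DataFrame:
    """Fill missing ``dry_mass_mg`` with the congeneric mean.

    Adds a boolean ``mass_imputed`` column; species with no congeneric
    estimates keep NaN and are flagged ``mass_unresolved``.
    """
    out = species.copy()
    if "genus" not in out.columns:
        raise ValueError("species table must have a 'genus' column")
    genus_mean = out.groupby("genus")["dry_mass_mg"].transform("mean")
    missing = out["dry_mass_mg"].isna()
    out["mass_imputed"] = missing & genus_mean.notna()
    out["mass_unresolved"] = missing & genus_mean.isna()
    out.loc[out["mass_imputed"], "dry_mass_mg"] = genus_mean[out["mass_imputed"]]
    return out


def compute_sti(
    occurrences: pd.DataFrame, cell_temperatures: pd.Series | dict
) -> pd.Series:
    """Species Temperature Index: plain mean over distinct occupied cells.

    ``occurrences`` has columns ``species_id`` and ``cell_id``; duplicate
    records within a cell count once.  Species absent from ``occurrences``
    simply do not appear in the result (no STI).
    """
    temps = pd.Series(cell_temperatures, dtype=float)
    occ = occurrences[["species_id", "cell_id"]].drop_duplicates()
    unknown = set(occ["cell_id"]) - set(temps.index)
    if unknown:
        raise KeyError(f"cells without temperature: {sorted(unknown)[:5]}")
    joined = occ.assign(temp=occ["cell_id"].map(temps))
    sti = joined.groupby("species_id")["temp"].mean()
    sti.name = "sti_degC"
    return sti


def classify_food_specialisation(host_records: pd.DataFrame) -> pd.Series:
    """Larval feeding-niche breadth from host-plant records.

    One plant genus -> monophagous; several genera within one family ->
    oligophagous; several families -> polyphagous.  Species with no host
    records are absent from the result (unclassified).
    """
    req = {"species_id", "plant_genus", "plant_family"}
    if not req.issubset(host_records.columns):
        raise ValueError(f"host records need columns {sorted(req)}")

    def _one(grp: pd.DataFrame) -> str:
        n_gen = grp["plant_genus"].nunique()
        n_fam = grp["plant_family"].nunique()
        if n_fam > 1:
            return "polyphagous"
        if n_gen > 1:
            return "oligophagous"
        return "monophagous"

    cls = host_records.groupby("species_id")[["plant_genus", "plant_family"]].apply(_one)
    cls.name = "food_spec"
    return cls


def assign_quantile_groups(
    values: pd.Series, labels: tuple[str, str, str] = GROUP_LABELS
) -> pd.Series:
    """Tertile trait groups cut at the 33% and 66% sample quantiles.

    Quantiles use the linear-interpolation (type-7) convention; values tied
    with a cut point fall in the lower group, which keeps labels independent
    of input order.  Missing values get missing labels.
    """
    vals = pd.Series(values, dtype=float)
    obs = vals.dropna()
    if len(obs) < 3:
        raise ValueError("need at least 3 non-missing values")
    if obs.nunique() == 1:
        raise ValueError("degenerate grouping: all values equal")
    q33, q66 = np.quantile(obs.to_numpy(), [0.33, 0.66])
    out = pd.Series(pd.NA, index=vals.index, dtype="object")
    out[vals.notna() & (vals <= q33)] = labels[0]
    out[vals.notna() & (vals > q33) & (vals <= q66)] = labels[1]
    out[vals.notna() & (vals > q66)] = labels[2]
    return out


def derive_trait_table(
    species: pd.DataFrame,
    wingspan_forewing_pairs: Sequence[tuple[float, float]] | None,
    host_records: pd.DataFrame | None,
    occurrences: pd.DataFrame | None,
    cell_temperatures=None,
    allometry: AllometryParams | None = None,
) -> pd.DataFrame:
    """Assemble the full per-species trait table.

    Starts from a table with ``species_id``, ``genus``, ``wingspan_mm`` (and
    optionally ``overwinter``); derives forewing length, dry mass (with
    congeneric imputation), STI, food specialisation and the size/temperature
    tertile groups.
    """
    out = species.copy().set_index("species_id", drop=False)
    if wingspan_forewing_pairs is not None:
        ic, sl, _ = fit_wingspan_to_forewing(wingspan_forewing_pairs)
        ws_to_fl = (ic, sl)
    else:
        ws_to_fl = (allometry or AllometryParams()).ws_to_fl
    fl_to_mass = (allometry or AllometryParams()).fl_to_mass

    ws = out["wingspan_mm"]
    out["forewing_mm"] = np.where(ws.notna(), estimate_forewing(ws.fillna(1.0), ws_to_fl), np.nan)
    fl = out["forewing_mm"]
    out["dry_mass_mg"] = np.where(
        fl.notna() & (fl > 0), estimate_dry_mass(fl.where(fl > 0, 1.0), fl_to_mass), np.nan
    )
    out = impute_missing_mass(out)

    if occurrences is not None and cell_temperatures is not None:
        out["sti_degC"] = compute_sti(occurrences, cell_temperatures).reindex(out.index)
    if host_records is not None:
        out["food_spec"] = classify_food_specialisation(host_records).reindex(out.index)

    if out["dry_mass_mg"].notna().sum() >= 3 and out["dry_mass_mg"].dropna().nunique() > 1:
        out["size_group"] = assign_quantile_groups(out["dry_mass_mg"])
    if "sti_degC" in out and out["sti_degC"].notna().sum() >= 3 and out["sti_degC"].dropna().nunique() > 1:
        out["temp_group"] = assign_quantile_groups(out["sti_degC"])
    return out.reset_index(drop=True)
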