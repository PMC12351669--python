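"""Per-night community response variables: abundance, coverage-corrected
richness, and biomass — overall and per trait group."""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .coverage import AbundanceVector, coverage_corrected_richness

#: Default common coverage to which richness is standardized.
DEFAULT_TARGET_COVERAGE = 0.90


def night_abundance(counts: Mapping[str, int]) -> int:
    """Total individuals across species on one night."""
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be non-negative")
    return int(sum(counts.values()))


def night_biomass(counts: Mapping[str, int], dry_mass_mg: Mapping[str, float]) -> float:
    """Estimated total dry biomass (mg): sum of count x species mass."""
    missing = [s for s in counts if s not in dry_mass_mg or pd.isna(dry_mass_mg[s])]
    if missing:
        raise KeyError(f"species without dry mass: {sorted(missing)}")
    return float(sum(c * dry_mass_mg[s] for s, c in counts.items()))


def _night_row(night_id, group, counts, masses, target_coverage):
    n = night_abundance(counts)
    if n == 0:
        rich = 0.0
        bio = 0.0
    else:
        av = AbundanceVector(night_id, counts)
        rich = coverage_corrected_richness(av, target_coverage)
        bio = night_biomass(counts, masses)
    return {
        "night_id": night_id,
        "group": group,
        "abundance": n,
        "richness_cc": rich,
        "biomass_mg": bio,
    }


def build_community_table(
    records: pd.DataFrame,
    nights: pd.DataFrame,
    species: pd.DataFrame,
    group_column: str | None = None,
    target_coverage: float = DEFAULT_TARGET_COVERAGE,
) -> pd.DataFrame:
    """Tidy per-night response table, one row per night x group.

    ``records`` holds (night_id, species_id, count) with zeros implicit;
    every night in ``nights`` appears in the output even when empty.  With
    ``group_column`` set (a column of ``species``, e.g. ``size_group``),
    additional rows per trait-group label are emitted, restricted to species
    with a non-missing label; the ``"all"`` rows always cover every species.
    """
    masses = species.set_index("species_id")["dry_mass_mg"].to_dict()
    by_night: dict[object, dict[str, int]] = {nid: {} for nid in nights["night_id"]}
    for nid, sp, cnt in records[["night_id", "species_id", "count"]].itertuples(index=False):
        by_night.setdefault(nid, {})[sp] = by_night.get(nid, {}).get(sp, 0) + int(cnt)

    rows = []
    for nid in nights["night_id"]:
        counts = by_night.get(nid, {})
        rows.append(_night_row(nid, "all", counts, masses, target_coverage))

    if group_column is not None:
        labels = species.set_index("species_id")[group_column]
        for glabel in labels.dropna().unique():
            members = set(labels[labels == glabel].index)
            for nid in nights["night_id"]:
                counts = {s: c for s, c in by_night.get(nid, {}).items() if s in members}
                rows.append(_night_row(nid, str(glabel), counts, masses, target_coverage))

    out = pd.DataFrame(rows)
    return out.sort_values(["group", "night_id"], kind="stable").reset_index(drop=True)
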