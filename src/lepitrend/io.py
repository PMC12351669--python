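"""CSV readers/writers with provenance headers, plus pipeline configuration.

All stage outputs are plain UTF-8 CSV.  Every file written here starts with
a single ``#``-prefixed provenance line (stage, package version, seed,
config hash) that the readers skip transparently.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__

RECORD_COLUMNS = ("night_id", "species_id", "count")
#: accepted Darwin-Core-like aliases for record columns
_DWC_ALIASES = {
    "species": "species_id",
    "scientificName": "species_id",
    "eventID": "night_id",
    "individualCount": "count",
}


@dataclass
class PipelineConfig:
    """Settings for a pipeline run; read from a TOML file.

    Unknown keys are rejected so typos fail loudly.
    """

    nights_csv: str = "nights.csv"
    records_csv: str = "records.csv"
    traits_csv: str = "traits.csv"
    occurrence_csv: str = "occurrences.csv"
    target_coverage: float = 0.90
    quantile_cuts: tuple[float, float] = (0.33, 0.66)
    cluster_radius_km: float = 20.0
    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000
    seed: int = 0
    min_site_years: int = 100
    allometry_ln_a: float = -3.2
    allometry_b: float = 2.63

    def __post_init__(self):
        if not (0 < self.target_coverage < 1):
            raise ValueError("target_coverage must lie in (0, 1)")
        if self.cluster_radius_km <= 0:
            raise ValueError("cluster_radius_km must be > 0")
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be smaller than iterations")
        if self.chains < 1 or self.min_site_years < 1:
            raise ValueError("chains and min_site_years must be >= 1")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        if "quantile_cuts" in raw:
            raw["quantile_cuts"] = tuple(raw["quantile_cuts"])
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def provenance_line(stage: str, seed: int, config_hash: str = "-") -> str:
    return (
        f"# lepitrend {__version__} stage={stage} seed={seed} "
        f"config={config_hash} written={_dt.date.today().isoformat()}"
    )


def write_csv(df: pd.DataFrame, path, stage: str, seed: int, config_hash: str = "-") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(provenance_line(stage, seed, config_hash) + "\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


@dataclass
class ValidationReport:
    """Rows rejected while reading records, with reasons."""

    rejected: list = field(default_factory=list)

    def add(self, row_index: int, reason: str) -> None:
        self.rejected.append({"row": row_index, "reason": reason})

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def read_records(path) -> tuple[pd.DataFrame, ValidationReport]:
    """Read count records from CSV, accepting Darwin-Core-like headers.

    Rows with non-positive or non-integer counts are rejected into the
    report; missing mandatory columns raise a schema error naming them.
    """
    df = read_csv(path)
    df = df.rename(columns={k: v for k, v in _DWC_ALIASES.items() if k in df.columns})
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records file missing mandatory columns: {missing}")
    report = ValidationReport()
    keep = []
    for i, row in enumerate(df.itertuples(index=False)):
        cnt = getattr(row, "count")
        try:
            cval = float(cnt)
        except (TypeError, ValueError):
            report.add(i, f"unparseable count {cnt!r}")
            continue
        if not (cval > 0 and cval == int(cval)):
            report.add(i, f"non-positive or non-integer count {cnt!r}")
            continue
        if "eventDate" in df.columns:
            try:
                _dt.date.fromisoformat(str(getattr(row, "eventDate")))
            except ValueError:
                report.add(i, f"unparseable date {getattr(row, 'eventDate')!r}")
                continue
        keep.append(i)
    out = df.iloc[keep].copy()
    out["count"] = out["count"].astype(int)
    return out[list(RECORD_COLUMNS)].reset_index(drop=True), report


def write_records(records: pd.DataFrame, path, seed: int = 0, config_hash: str = "-") -> None:
    write_csv(records[list(RECORD_COLUMNS)], path, "records", seed, config_hash)
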