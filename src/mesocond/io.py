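"""Tabular I/O for gas-exchange records and pot-weight lysimetry.

Canonical internal units are mol, m, s, K, and umol mol-1 for CO2 mole
fractions; any unit coercion happens here at the boundary.  Instrument
exports (LI-6800 style) carry hundreds of columns; unknown columns are kept
as opaque metadata and never interpreted.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Iterable, Mapping

import pandas as pd
import yaml

log = logging.getLogger("mesocond.io")

#: canonical record fields that must be present in any column map
MANDATORY_FIELDS = ("An", "Ca", "Ci_raw", "gsw", "El", "Wi", "Wa", "PPFD", "Tleaf_C")

#: optional fields with defaults
OPTIONAL_FIELDS = {
    "O2_frac": 0.21,
    "Ft": None,
    "Fm_prime": None,
    "genotype": "",
    "plant_id": "",
    "day": 0,
    "curve_id": "",
}

#: multiplicative unit coercions understood by ``read_gasex_table``
_UNIT_FACTORS = {
    "mmol": 1e-3,  # mmol m-2 s-1 -> mol m-2 s-1 (or mmol mol-1 -> mol mol-1)
    "mol": 1.0,
}


class ConfigError(ValueError):
    """A configuration problem (missing column, bad unit hint)."""


@dataclass
class GasExchangeRecord:
    """One instrument observation of combined gas exchange and fluorescence.

    Units: fluxes in umol CO2 m-2 s-1 (An) or mol H2O m-2 s-1 (El);
    conductance in mol H2O m-2 s-1; mole fractions of CO2 in umol mol-1 and of
    water vapor in mol mol-1; PPFD in umol photons m-2 s-1.
    """

    An: float
    Ca: float
    Ci_raw: float
    gsw: float
    El: float
    Wi: float
    Wa: float
    PPFD: float
    Tleaf_C: float
    O2_frac: float = 0.21
    Ft: float | None = None
    Fm_prime: float | None = None
    genotype: str = ""
    plant_id: str = ""
    day: int = 0
    curve_id: str = ""
    extra: dict = field(default_factory=dict)

    @property
    def has_fluorescence(self) -> bool:
        return self.Ft is not None and self.Fm_prime is not None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty if the record is valid)."""
        problems = []
        if not math.isfinite(self.An):
            problems.append("An is not finite")
        if not self.Ca > 0:
            problems.append("Ca must be positive")
        if self.Wa < 0 or self.Wi < self.Wa:
            problems.append("requires Wi >= Wa >= 0")
        if self.gsw < 0:
            problems.append("gsw must be non-negative")
        if self.El < 0:
            problems.append("El must be non-negative")
        if self.PPFD < 0:
            problems.append("PPFD must be non-negative")
        if not 0.0 < self.O2_frac <= 0.25:
            problems.append("O2_frac must lie in (0, 0.25]")
        if (self.Ft is None) != (self.Fm_prime is None):
            problems.append("Ft and Fm_prime must be given together")
        if self.has_fluorescence and not (self.Fm_prime > self.Ft > 0):
            problems.append("requires Fm_prime > Ft > 0")
        return problems


def read_gasex_table(
    path: str | Path,
    column_map: Mapping[str, str],
    unit_hints: Mapping[str, str] | None = None,
    sep: str = ",",
) -> list[GasExchangeRecord]:
    """Read a delimited text table into validated :class:`GasExchangeRecord` rows.

    ``column_map`` maps canonical field names to file headers; it must cover
    all of :data:`MANDATORY_FIELDS`.  ``unit_hints`` optionally maps canonical
    field names to the unit the file uses (e.g. ``{"El": "mmol"}``), coerced
    to canonical units on ingest.  Rows violating record invariants are
    excluded and logged with their row index.
    """
    unit_hints = dict(unit_hints or {})
    for fld in MANDATORY_FIELDS:
        if fld not in column_map:
            raise ConfigError(f"column_map is missing mandatory field {fld!r}")
    df = pd.read_csv(path, sep=sep)
    for fld, col in column_map.items():
        if col not in df.columns:
            raise ConfigError(f"file {path} has no column {col!r} (field {fld!r})")

    known_cols = set(column_map.values())
    records: list[GasExchangeRecord] = []
    for idx, row in df.iterrows():
        kwargs: dict[str, Any] = {}
        bad_cell = None
        for fld, col in column_map.items():
            raw = row[col]
            if fld in ("genotype", "plant_id", "curve_id"):
                kwargs[fld] = "" if pd.isna(raw) else str(raw)
                continue
            if fld == "day":
                kwargs[fld] = 0 if pd.isna(raw) else int(raw)
                continue
            if pd.isna(raw):
                if fld in ("Ft", "Fm_prime"):
                    kwargs[fld] = None
                    continue
                bad_cell = (col, raw)
                break
            try:
                value = float(raw)
            except (TypeError, ValueError):
                bad_cell = (col, raw)
                break
            if fld in unit_hints:
                hint = unit_hints[fld]
                if hint not in _UNIT_FACTORS:
                    raise ConfigError(f"unknown unit hint {hint!r} for field {fld!r}")
                value *= _UNIT_FACTORS[hint]
            kwargs[fld] = value
        if bad_cell is not None:
            log.warning("row %d excluded: unparseable value %r in column %r", idx, bad_cell[1], bad_cell[0])
            continue
        rec = GasExchangeRecord(**kwargs)
        rec.extra = {c: row[c] for c in df.columns if c not in known_cols}
        problems = rec.validate()
        if problems:
            log.warning("row %d excluded: %s", idx, "; ".join(problems))
            continue
        records.append(rec)
    return records


def records_to_frame(records: Iterable[GasExchangeRecord]) -> pd.DataFrame:
    """Canonical-field DataFrame view of a record list (drops opaque extras)."""
    rows = []
    for r in records:
        d = asdict(r)
        d.pop("extra")
        rows.append(d)
    return pd.DataFrame(rows)


def write_gasex_table(records: Iterable[GasExchangeRecord], path: str | Path) -> None:
    """Write records as CSV with canonical headers (round-trips with identity column map)."""
    records_to_frame(records).to_csv(path, index=False)


def identity_column_map() -> dict[str, str]:
    """Column map for files written by :func:`write_gasex_table`."""
    return {f: f for f in MANDATORY_FIELDS} | {f: f for f in OPTIONAL_FIELDS}


@dataclass(frozen=True)
class PotWeights:
    """Pot weights for lysimetric relative soil water content (kg)."""

    PW: float
    DW: float
    t0W: float

    def __post_init__(self) -> None:
        if not self.t0W > self.DW > 0:
            raise ValueError("requires t0W > DW > 0")
        if self.PW < self.DW:
            raise ValueError("PW below dry weight: record rejected")


def compute_rswc(w: PotWeights) -> float:
    """Relative soil water content, RSWC (%) = 100*(PW - DW)/(t0W - DW).

    Values above 100% (pot heavier than on day 0) are allowed with a warning.
    """
    denom = w.t0W - w.DW
    rswc = 100.0 * (w.PW - w.DW) / denom
    if rswc > 100.0:
        log.warning("RSWC %.1f%% exceeds 100%% (PW > t0W)", rswc)
    return rswc


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON analysis configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        return json.loads(text)
    return yaml.safe_load(text)


def write_manifest(path: str | Path, config: Mapping, seed: int | None = None) -> None:
    """Write a JSON run manifest (config, package version, seed)."""
    from mesocond import __version__

    manifest = {"config": dict(config), "version": __version__, "seed": seed}
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
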