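"""Data model and I/O for 384-well drug screens.

The screen design follows the standard ex vivo sensitivity layout: each
compound (or fixed-molar combination) occupies one well per concentration of
a log10-spaced series, with vehicle (DMSO) wells defining 100% viability and
full-kill (benzethonium chloride) wells defining 0%.
"""

from __future__ import annotations

import logging
import math
import re
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Plate geometry: 16 rows (A-P) x 24 columns (1-24) = 384 wells.
PLATE_ROWS = string.ascii_uppercase[:16]
PLATE_COLS = tuple(range(1, 25))

_WELL_RE = re.compile(r"^([A-Pa-p])([1-9]|1[0-9]|2[0-4])$")

ROLE_TREATMENT = "treatment"
ROLE_NEGATIVE = "negative_control"
ROLE_POSITIVE = "positive_control"
ROLE_EMPTY = "empty"
_ROLES = {ROLE_TREATMENT, ROLE_NEGATIVE, ROLE_POSITIVE, ROLE_EMPTY}


def normalize_well(address: str) -> str:
    """Canonicalize a well address ("b02"/"B2" -> "B2").

    Raises
    ------
    ValueError
        If the address is outside the 16x24 (A1..P24) grid.
    """
    addr = str(address).strip()
    # tolerate a single leading zero in the column ("A01")
    m = re.match(r"^([A-Pa-p])0?([1-9]|1[0-9]|2[0-4])$", addr)
    if not m:
        raise ValueError(f"invalid 384-well address: {address!r}")
    return m.group(1).upper() + m.group(2)


def all_wells() -> list[str]:
    """All 384 well addresses in row-major order (A1..A24, B1, ..., P24)."""
    return [f"{r}{c}" for r in PLATE_ROWS for c in PLATE_COLS]


@dataclass(frozen=True)
class ConcentrationSeries:
    """An ordered, strictly increasing set of tested doses in nM.

    The log10 grid derived from it defines the DSS integration window
    [x_lo, x_hi] = [log10(min dose), log10(max dose)].
    """

    values_nM: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values_nM)
        if len(vals) < 2:
            raise ValueError("concentration series needs at least 2 doses")
        if any(v <= 0 for v in vals):
            raise ValueError("all concentrations must be > 0 nM")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("concentrations must be strictly increasing")
        object.__setattr__(self, "values_nM", vals)

    @property
    def log10_values(self) -> np.ndarray:
        return np.log10(np.asarray(self.values_nM))

    @property
    def x_lo(self) -> float:
        return float(math.log10(self.values_nM[0]))

    @property
    def x_hi(self) -> float:
        return float(math.log10(self.values_nM[-1]))

    def __len__(self) -> int:
        return len(self.values_nM)

    @classmethod
    def log_spaced(
        cls, min_nM: float, max_nM: float, n_points: int = 5, label: str = ""
    ) -> "ConcentrationSeries":
        """n_points log10-equispaced doses from min_nM to max_nM.

        The default screen design is five ten-fold steps, 1-10,000 nM.
        """
        if min_nM >= max_nM:
            raise ValueError(f"min_nM ({min_nM}) must be < max_nM ({max_nM})")
        vals = np.logspace(math.log10(min_nM), math.log10(max_nM), int(n_points))
        return cls(tuple(float(v) for v in vals), label=label)


#: The standard series: 1-10,000 nM in ten-fold increments.
DEFAULT_SERIES = ConcentrationSeries.log_spaced(1.0, 10_000.0, 5, label="standard")


@dataclass(frozen=True)
class LibraryEntry:
    """One screened treatment: a single agent or a fixed-molar combination.

    Combinations carry exactly two component compounds dosed together on one
    shared concentration axis (each component at the stated molarity); there
    is no per-component dose grid.
    """

    entry_id: str
    kind: str  # "single" | "combination"
    components: tuple[str, ...]
    series: ConcentrationSeries

    def __post_init__(self) -> None:
        if self.kind not in ("single", "combination"):
            raise ValueError(f"unknown entry kind: {self.kind!r}")
        n = 2 if self.kind == "combination" else 1
        if len(self.components) != n:
            raise ValueError(
                f"{self.kind} entry {self.entry_id!r} must have exactly "
                f"{n} component(s), got {len(self.components)}"
            )


@dataclass(frozen=True)
class WellRole:
    """Role of one well: treatment (entry + dose index) or a control."""

    role: str
    entry_id: str | None = None
    conc_index: int | None = None

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"unknown well role: {self.role!r}")
        if self.role == ROLE_TREATMENT:
            if not self.entry_id or self.conc_index is None or self.conc_index < 0:
                raise ValueError("treatment wells need entry_id and conc_index >= 0")


@dataclass
class PlateMap:
    """Assignment of every used well of one 384-well plate to its role."""

    plate_id: str
    wells: dict[str, WellRole] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wells = {normalize_well(w): r for w, r in self.wells.items()}

    def wells_with_role(self, role: str) -> list[str]:
        return [w for w, r in self.wells.items() if r.role == role]

    @property
    def n_negative(self) -> int:
        return len(self.wells_with_role(ROLE_NEGATIVE))

    @property
    def n_positive(self) -> int:
        return len(self.wells_with_role(ROLE_POSITIVE))

    def treatment_wells(self) -> dict[str, tuple[str, int]]:
        """well -> (entry_id, conc_index) for all treatment wells."""
        return {
            w: (r.entry_id, r.conc_index)
            for w, r in self.wells.items()
            if r.role == ROLE_TREATMENT
        }

    def validate(self) -> None:
        if self.n_negative < 2 or self.n_positive < 2:
            raise ValueError(
                f"plate {self.plate_id}: need >=2 negative and >=2 positive "
                f"control wells (got {self.n_negative}/{self.n_positive})"
            )


@dataclass
class RawPlate:
    """Raw luminescence readout (RLU) for one plate, keyed by well address."""

    plate_id: str
    luminescence: dict[str, float]

    def __post_init__(self) -> None:
        clean: dict[str, float] = {}
        for w, v in self.luminescence.items():
            v = float(v)
            if not math.isfinite(v):
                raise ValueError(f"non-finite luminescence at well {w}")
            if v < 0:
                raise ValueError(f"negative luminescence at well {w}: {v}")
            clean[normalize_well(w)] = v
        self.luminescence = clean


def read_plate_map(path: str | Path, plate_id: str | None = None) -> PlateMap:
    """Read a plate map CSV with columns well,role,entry_id,conc_index.

    Roles are parsed case-insensitively; duplicate wells and invalid
    addresses are errors.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"well", "role"}
    if not required.issubset(df.columns):
        raise ValueError(f"plate map {path} must have columns well,role")
    wells: dict[str, WellRole] = {}
    for _, row in df.iterrows():
        w = normalize_well(row["well"])
        if w in wells:
            raise ValueError(f"duplicate well {w} in plate map {path}")
        role = str(row["role"]).strip().lower()
        if role not in _ROLES:
            raise ValueError(f"unknown role {row['role']!r} at well {w}")
        entry = str(row.get("entry_id", "")).strip() or None
        ci_raw = str(row.get("conc_index", "")).strip()
        ci = int(ci_raw) if ci_raw else None
        wells[w] = WellRole(role=role, entry_id=entry, conc_index=ci)
    # "plate_1.map.csv" and "plate_1.csv" identify the same plate
    default_id = path.stem.removesuffix(".map")
    return PlateMap(plate_id=plate_id or default_id, wells=wells)


def write_plate_map(pm: PlateMap, path: str | Path) -> None:
    """Write a plate map CSV; round-trips exactly through read_plate_map."""
    rows = [
        {
            "well": w,
            "role": r.role,
            "entry_id": r.entry_id or "",
            "conc_index": "" if r.conc_index is None else r.conc_index,
        }
        for w, r in sorted(pm.wells.items(), key=lambda kv: _well_sort_key(kv[0]))
    ]
    pd.DataFrame(rows, columns=["well", "role", "entry_id", "conc_index"]).to_csv(
        path, index=False
    )


def _well_sort_key(w: str) -> tuple[int, int]:
    return (PLATE_ROWS.index(w[0]), int(w[1:]))


def read_library(path: str | Path) -> list[LibraryEntry]:
    """Read a drug-library TSV.

    Columns: entry_id, kind, component_1, component_2, min_nM, max_nM,
    n_points. Each entry's series is built as n_points log-equispaced doses
    from min_nM to max_nM (default design: 5 points, 1-10,000 nM).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    needed = {"entry_id", "kind", "component_1", "min_nM", "max_nM", "n_points"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"library {path} missing columns: {sorted(missing)}")
    entries: list[LibraryEntry] = []
    for _, row in df.iterrows():
        kind = row["kind"].strip().lower()
        comps = [row["component_1"].strip()]
        c2 = str(row.get("component_2", "")).strip()
        if kind == "combination":
            if not c2:
                raise ValueError(
                    f"combination entry {row['entry_id']!r} lacks component_2"
                )
            comps.append(c2)
        elif c2:
            raise ValueError(f"single entry {row['entry_id']!r} has component_2")
        series = ConcentrationSeries.log_spaced(
            float(row["min_nM"]),
            float(row["max_nM"]),
            int(row["n_points"]),
            label=row["entry_id"],
        )
        entries.append(
            LibraryEntry(
                entry_id=row["entry_id"],
                kind=kind,
                components=tuple(comps),
                series=series,
            )
        )
    return entries


def write_library(entries: Sequence[LibraryEntry], path: str | Path) -> None:
    rows = []
    for e in entries:
        rows.append(
            {
                "entry_id": e.entry_id,
                "kind": e.kind,
                "component_1": e.components[0],
                "component_2": e.components[1] if len(e.components) > 1 else "",
                "min_nM": e.series.values_nM[0],
                "max_nM": e.series.values_nM[-1],
                "n_points": len(e.series),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_raw_plate(path: str | Path, plate_map: PlateMap | None = None) -> RawPlate:
    """Read raw luminescence, auto-detecting long (well,value) or 16x24 matrix
    layout from the header shape.

    Wells present in the file but absent from the plate map are warned
    about, never dropped.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = [c.strip().lower() for c in df.columns]
    lum: dict[str, float] = {}
    if "well" in cols and "value" in cols:
        df.columns = cols
        for _, row in df.iterrows():
            w = normalize_well(row["well"])
            lum[w] = _parse_lum(row["value"], w)
    elif len(df.columns) == 25:
        # matrix dialect: first column holds the row letters A..P
        first = df.columns[0]
        col_labels = [str(c).strip() for c in df.columns[1:]]
        for _, row in df.iterrows():
            letter = str(row[first]).strip().upper()
            for lab, orig in zip(col_labels, df.columns[1:]):
                w = normalize_well(f"{letter}{lab}")
                lum[w] = _parse_lum(row[orig], w)
    else:
        raise ValueError(
            f"cannot detect plate layout of {path}: expected columns "
            "(well,value) or a 16x24 matrix with row letters"
        )
    if plate_map is not None:
        extra = sorted(set(lum) - set(plate_map.wells), key=_well_sort_key)
        if extra:
            logger.warning(
                "plate %s: %d wells absent from plate map (e.g. %s)",
                path.stem,
                len(extra),
                ", ".join(extra[:5]),
            )
    return RawPlate(plate_id=path.stem, luminescence=lum)


def _parse_lum(value: str, well: str) -> float:
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise ValueError(f"non-numeric luminescence {value!r} at well {well}")
    if v < 0:
        raise ValueError(f"negative luminescence at well {well}: {v}")
    return v


def example_library() -> list[LibraryEntry]:
    """The bundled example drug library (structure of a real CLL screen
    library: named singles and fixed-molar combinations, ten-fold series)."""
    from importlib.resources import files

    return read_library(files("cllscreen").joinpath("data/library_example.tsv"))


def write_raw_plate(plate: RawPlate, path: str | Path) -> None:
    rows = [
        {"well": w, "value": repr(v)}
        for w, v in sorted(plate.luminescence.items(), key=lambda kv: _well_sort_key(kv[0]))
    ]
    pd.DataFrame(rows, columns=["well", "value"]).to_csv(path, index=False)
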