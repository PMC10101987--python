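"""Screen orchestration: normalize -> QC -> fit -> score -> compare.

One call takes a screen's plates from raw luminescence to a ranked DSS
table with per-plate Z' quality flags; a second aligns the DSS tables of
serial samples (T0, T1, ...) into an entries x time-points matrix with
deltas against a baseline draw and a clustered ordering for heatmap export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import qc as qc_mod
from .doseresponse import DSSConfig, score_screen
from .phosphoflow import _leaf_order
from .plates import (
    LibraryEntry,
    PlateMap,
    RawPlate,
    read_library,
    read_plate_map,
    read_raw_plate,
)

logger = logging.getLogger(__name__)


class QCFailure(RuntimeError):
    """Raised in strict mode when a plate fails the Z' gate."""


def analyze_screen(
    plate_maps: Sequence[PlateMap],
    plates: Sequence[RawPlate],
    library: Sequence[LibraryEntry],
    cfg: DSSConfig | None = None,
    zprime_min: float = qc_mod.DEFAULT_ZPRIME_MIN,
    strict: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full in-memory pipeline for one screen.

    Returns (dss_table, qc_report). The DSS table is ranked by descending
    score (ties broken by entry_id) and carries a qc_fail flag for entries
    with any source plate below the Z' threshold; with strict=True such a
    plate aborts the run instead.
    """
    cfg = cfg or DSSConfig()
    maps_by_id = {pm.plate_id: pm for pm in plate_maps}
    qc_rows, viab_parts = [], []
    failed_plates = set()
    for plate in plates:
        pm = maps_by_id.get(plate.plate_id)
        if pm is None:
            raise ValueError(f"no plate map for plate {plate.plate_id}")
        cs = qc_mod.summarize_controls(plate, pm)
        z = qc_mod.zprime(cs)
        passed = z >= zprime_min
        if not passed:
            failed_plates.add(plate.plate_id)
            if strict:
                raise QCFailure(
                    f"plate {plate.plate_id} failed QC: Z'={z:.3f} < {zprime_min}"
                )
        qc_rows.append(
            {"plate_id": plate.plate_id, "zprime": z, "passed": passed,
             "mu_neg": cs.mu_neg, "sigma_neg": cs.sigma_neg,
             "mu_pos": cs.mu_pos, "sigma_pos": cs.sigma_pos}
        )
        viab_parts.append(qc_mod.normalize_viability(plate, pm, cs, list(library)))
    viab = pd.concat(viab_parts, ignore_index=True)
    dss_table = score_screen(viab, list(library), cfg)

    # entries touching a failed plate inherit a qc_fail flag
    entry_plates = viab.groupby("entry_id")["plate_id"].agg(set)
    qc_fail = dss_table["entry_id"].map(
        lambda e: bool(entry_plates.get(e, set()) & failed_plates)
    )
    dss_table = dss_table.assign(qc_fail=qc_fail)
    return dss_table, pd.DataFrame(qc_rows)


def run_pipeline(
    platemap_paths: Sequence[str | Path],
    plate_paths: Sequence[str | Path],
    library_path: str | Path,
    cfg: DSSConfig | None = None,
    zprime_min: float = qc_mod.DEFAULT_ZPRIME_MIN,
    strict: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """File-based wrapper around analyze_screen; plate files are matched to
    plate maps by file stem."""
    plate_maps = [read_plate_map(p) for p in platemap_paths]
    maps_by_id = {pm.plate_id: pm for pm in plate_maps}
    plates = [read_raw_plate(p, maps_by_id.get(Path(p).stem)) for p in plate_paths]
    library = read_library(library_path)
    return analyze_screen(plate_maps, plates, library, cfg, zprime_min, strict)


@dataclass
class ScreenComparison:
    """DSS matrix across time-points with deltas against a baseline.

    Restricted to entries shared by all tables; missing scores stay NaN,
    never imputed. delta[tp] = score[tp] - score[baseline], so the baseline
    column of delta is identically zero.
    """

    matrix: pd.DataFrame  # entries x time-points
    delta: pd.DataFrame
    baseline: str
    flags: pd.DataFrame
    row_order: list[int]
    row_linkage: np.ndarray | None

    def ordered(self) -> pd.DataFrame:
        return self.matrix.iloc[self.row_order]


def compare_screens(
    tables: Mapping[str, pd.DataFrame], baseline: str
) -> ScreenComparison:
    """Align >= 2 DSS tables (time-point id -> score_screen output).

    Column order is the sorted time-point ids, so the result does not
    depend on the order the tables are supplied in. Rows are clustered
    with Manhattan distance and Ward linkage for heatmap export.
    """
    if baseline not in tables:
        raise ValueError(f"baseline time-point {baseline!r} not among tables")
    if len(tables) < 2:
        raise ValueError("need at least 2 tables to compare")
    tps = sorted(tables)
    shared = None
    for tp in tps:
        ids = set(tables[tp]["entry_id"])
        shared = ids if shared is None else shared & ids
    if not shared:
        raise ValueError("no shared entries across tables")
    index = sorted(shared)
    matrix = pd.DataFrame(
        {tp: tables[tp].set_index("entry_id")["score"].reindex(index) for tp in tps},
        index=pd.Index(index, name="entry_id"),
    )
    flag_col = lambda df: df.set_index("entry_id").get(
        "flags", pd.Series("", index=df["entry_id"])
    )
    flags = pd.DataFrame(
        {tp: flag_col(tables[tp]).reindex(index).fillna("") for tp in tps},
        index=matrix.index,
    )
    delta = matrix.sub(matrix[baseline], axis=0)
    row_order, row_link = _leaf_order(np.nan_to_num(matrix.to_numpy()))
    return ScreenComparison(
        matrix=matrix, delta=delta, baseline=baseline, flags=flags,
        row_order=row_order, row_linkage=row_link,
    )


def timecourse_normalize(signals, anchor_day) -> pd.Series:
    """Normalize a per-day viability series to its anchor day (anchor -> 1.0).

    Re-anchoring a restimulation series (e.g. at R0) is the same call with
    a different anchor label.
    """
    s = pd.Series(signals, dtype=float)
    if anchor_day not in s.index:
        raise ValueError(f"anchor day {anchor_day!r} not in series")
    anchor = s[anchor_day]
    if not np.isfinite(anchor) or anchor <= 0:
        raise ValueError(f"anchor value must be > 0, got {anchor}")
    return s / anchor
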