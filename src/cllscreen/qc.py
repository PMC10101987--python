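"""Control-anchored viability normalization and Z'-factor plate QC.

Raw luminescence is mapped to percent viability against the per-plate
vehicle (negative, 100% viability) and full-kill (positive, 0% viability)
controls:

    viability% = 100 * (L - mu_pos) / (mu_neg - mu_pos)

Plate quality is the Z'-factor of Zhang, Chung & Oldenburg (1999):

    Z' = 1 - 3*(sigma_pos + sigma_neg) / |mu_neg - mu_pos|

with the conventional pass threshold Z' >= 0.5. Controls are summarized per
plate (not pooled across plates) so each plate carries its own QC. Viability
is deliberately not clipped here: values above 100% or below 0% stay
visible for QC; clipping happens inside DSS scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plates import (
    ROLE_NEGATIVE,
    ROLE_POSITIVE,
    ROLE_TREATMENT,
    LibraryEntry,
    PlateMap,
    RawPlate,
)

DEFAULT_ZPRIME_MIN = 0.5


@dataclass(frozen=True)
class ControlSummary:
    """Per-plate control statistics (sample SD, n-1 denominator)."""

    mu_neg: float
    sigma_neg: float
    mu_pos: float
    sigma_pos: float
    n_neg: int
    n_pos: int


@dataclass(frozen=True)
class QCResult:
    plate_id: str
    zprime: float
    passed: bool


def summarize_controls(plate: RawPlate, pmap: PlateMap) -> ControlSummary:
    """Mean and sample SD of the negative and positive control wells.

    At least two wells of each role are required so the SDs are defined.
    """
    neg = [plate.luminescence[w] for w in pmap.wells_with_role(ROLE_NEGATIVE)
           if w in plate.luminescence]
    pos = [plate.luminescence[w] for w in pmap.wells_with_role(ROLE_POSITIVE)
           if w in plate.luminescence]
    if len(neg) < 2 or len(pos) < 2:
        raise ValueError(
            f"insufficient controls on plate {plate.plate_id}: "
            f"{len(neg)} negative / {len(pos)} positive wells (need >=2 each)"
        )
    neg_a, pos_a = np.asarray(neg, float), np.asarray(pos, float)
    return ControlSummary(
        mu_neg=float(neg_a.mean()),
        sigma_neg=float(neg_a.std(ddof=1)),
        mu_pos=float(pos_a.mean()),
        sigma_pos=float(pos_a.std(ddof=1)),
        n_neg=len(neg),
        n_pos=len(pos),
    )


def zprime(cs: ControlSummary) -> float:
    """Z'-factor: 1 - 3(sigma_pos + sigma_neg)/|mu_neg - mu_pos|; always <= 1."""
    sep = abs(cs.mu_neg - cs.mu_pos)
    if sep == 0:
        raise ValueError("degenerate controls: mu_neg == mu_pos")
    return 1.0 - 3.0 * (cs.sigma_pos + cs.sigma_neg) / sep


def qc_plate(
    plate: RawPlate, pmap: PlateMap, threshold: float = DEFAULT_ZPRIME_MIN
) -> QCResult:
    z = zprime(summarize_controls(plate, pmap))
    return QCResult(plate_id=plate.plate_id, zprime=z, passed=z >= threshold)


def normalize_viability(
    plate: RawPlate,
    pmap: PlateMap,
    cs: ControlSummary | None = None,
    library: list[LibraryEntry] | None = None,
) -> pd.DataFrame:
    """Convert a raw plate to a viability table.

    Returns a DataFrame with one row per (entry_id, conc_index) after
    averaging replicate wells, columns: plate_id, entry_id, conc_index,
    conc_nM, viability_percent, n_wells, wells. conc_nM is resolved from
    the library when given, else NaN.

    Normalization is affine in the readout, so any L -> a*L + b rescaling
    (a > 0) applied to the whole plate leaves the output unchanged.
    """
    if cs is None:
        cs = summarize_controls(plate, pmap)
    if cs.mu_neg <= cs.mu_pos:
        raise ValueError(
            f"plate {plate.plate_id}: inverted signal polarity "
            f"(mu_neg={cs.mu_neg} <= mu_pos={cs.mu_pos})"
        )
    span = cs.mu_neg - cs.mu_pos
    series_by_entry = {e.entry_id: e.series for e in library} if library else {}

    grouped: dict[tuple[str, int], list[str]] = {}
    for w, role in pmap.wells.items():
        if role.role != ROLE_TREATMENT or w not in plate.luminescence:
            continue
        grouped.setdefault((role.entry_id, role.conc_index), []).append(w)

    rows = []
    for (entry_id, ci), wells in sorted(grouped.items()):
        viab = [100.0 * (plate.luminescence[w] - cs.mu_pos) / span for w in wells]
        series = series_by_entry.get(entry_id)
        conc = (
            series.values_nM[ci]
            if series is not None and ci < len(series)
            else float("nan")
        )
        rows.append(
            {
                "plate_id": plate.plate_id,
                "entry_id": entry_id,
                "conc_index": ci,
                "conc_nM": conc,
                "viability_percent": float(np.mean(viab)),
                "n_wells": len(wells),
                "wells": ";".join(sorted(wells)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "plate_id",
            "entry_id",
            "conc_index",
            "conc_nM",
            "viability_percent",
            "n_wells",
            "wells",
        ],
    )
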