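"""Synthetic screens, serial samples and flow tables.

The generator emulates the statistical structure of an ex vivo CLL drug
screen so the whole pipeline is testable without patient data: 94 single
agents and 87 fixed-molar combinations on five ten-fold doses (1-10,000 nM),
laid out across at most four 384-well plates with vehicle and full-kill
control columns; luminescence proportional to true 4PL viability with
multiplicative lognormal noise (luminescence assays are scale-noise
dominated); control wells drawn from stated normals.

Serial samples model a patient followed across therapies: acquired
resistance and its reversal appear as additive shifts of each entry's
log-EC50 per time-point, and phospho-marker medians as per-time-point
multiplicative changes over a constant reference.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .doseresponse import logistic4
from .plates import (
    DEFAULT_SERIES,
    PLATE_COLS,
    PLATE_ROWS,
    ROLE_NEGATIVE,
    ROLE_POSITIVE,
    ConcentrationSeries,
    LibraryEntry,
    PlateMap,
    RawPlate,
    WellRole,
)

MAX_PLATES = 4
# columns 1 and 24 are control columns (16 wells each); 22 columns remain
TREATMENT_COLS = tuple(c for c in PLATE_COLS if c not in (1, 24))
TREATMENT_CAPACITY = len(PLATE_ROWS) * len(TREATMENT_COLS)  # 352 per plate

# CellTiter-Glo-scale control truth; sigma = 5% of the dynamic range / 3
# puts the expected Z' near 0.7, consistent with screens that pass the
# conventional >= 0.5 gate with margin.
DEFAULT_MU_NEG = 200_000.0
DEFAULT_MU_POS = 10_000.0
DEFAULT_SIGMA = 0.05 * (DEFAULT_MU_NEG - DEFAULT_MU_POS) / 3.0


@dataclass(frozen=True)
class SimScreenConfig:
    """Generating parameters for one synthetic screen.

    Per-entry truth (top, bottom, log_ec50, slope) is drawn once per
    config+seed unless an explicit truth table is supplied; identical
    config and seed reproduce identical output.
    """

    seed: int
    n_singles: int = 94
    n_combos: int = 87
    series: ConcentrationSeries = DEFAULT_SERIES
    noise_cv: float = 0.05
    mu_neg: float = DEFAULT_MU_NEG
    sigma_neg: float = DEFAULT_SIGMA
    mu_pos: float = DEFAULT_MU_POS
    sigma_pos: float = DEFAULT_SIGMA
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.sigma_neg < 0 or self.sigma_pos < 0 or self.noise_cv < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.mu_neg <= self.mu_pos:
            raise ValueError("mu_neg must exceed mu_pos")


@dataclass
class SimulatedScreen:
    """A synthetic screen: inputs for the pipeline plus the generating truth."""

    library: list[LibraryEntry]
    plate_maps: list[PlateMap]
    plates: list[RawPlate]
    truth: pd.DataFrame


def _draw_truth(cfg: SimScreenConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-entry 4PL truth: near-complete top asymptote, modest residual
    viability, potency uniform over the tested log-dose window."""
    ids, kinds = [], []
    for i in range(cfg.n_singles):
        ids.append(f"drug_{i:03d}")
        kinds.append("single")
    for j in range(cfg.n_combos):
        ids.append(f"combo_{j:03d}")
        kinds.append("combination")
    n = len(ids)
    return pd.DataFrame(
        {
            "entry_id": ids,
            "kind": kinds,
            "top": np.clip(rng.normal(100.0, 3.0, n), 90.0, 110.0),
            "bottom": rng.uniform(0.0, 15.0, n),
            "log_ec50": rng.uniform(cfg.series.x_lo, cfg.series.x_hi, n),
            "slope": rng.uniform(0.8, 2.0, n),
        }
    )


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)


def simulate_screen(cfg: SimScreenConfig) -> SimulatedScreen:
    """Generate plate maps, raw plates, a library and the truth table.

    Treatment wells carry luminescence
    mu_pos + (mu_neg - mu_pos) * v_true(x)/100 times lognormal noise with
    CV = noise_cv; control columns are drawn from the stated normals
    (truncated at zero). Raises if the design needs more than four plates.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = cfg.truth if cfg.truth is not None else _draw_truth(cfg, rng)
    n_points = len(cfg.series)
    n_wells = len(truth) * n_points
    n_plates = -(-n_wells // TREATMENT_CAPACITY)
    if n_plates > MAX_PLATES:
        raise ValueError(
            f"design needs {n_plates} plates for {n_wells} treatment wells; "
            f"at most {MAX_PLATES} supported"
        )

    library = [
        LibraryEntry(
            entry_id=row.entry_id,
            kind=row.kind,
            components=(
                (row.entry_id,)
                if row.kind == "single"
                else (f"{row.entry_id}_a", f"{row.entry_id}_b")
            ),
            series=cfg.series,
        )
        for row in truth.itertuples()
    ]

    x = cfg.series.log10_values
    span = cfg.mu_neg - cfg.mu_pos
    plate_maps: list[PlateMap] = []
    plates: list[RawPlate] = []
    assignments = [
        (row.entry_id, ci, logistic4(x[ci], row.top, row.bottom, row.log_ec50, row.slope))
        for row in truth.itertuples()
        for ci in range(n_points)
    ]
    pos = 0
    for p in range(n_plates):
        plate_id = f"plate_{p + 1}"
        wells: dict[str, WellRole] = {}
        lum: dict[str, float] = {}
        for r in PLATE_ROWS:
            wells[f"{r}1"] = WellRole(role=ROLE_NEGATIVE)
            lum[f"{r}1"] = max(rng.normal(cfg.mu_neg, cfg.sigma_neg), 0.0)
            wells[f"{r}24"] = WellRole(role=ROLE_POSITIVE)
            lum[f"{r}24"] = max(rng.normal(cfg.mu_pos, cfg.sigma_pos), 0.0)
        chunk = assignments[pos : pos + TREATMENT_CAPACITY]
        noise = _lognormal_factors(rng, cfg.noise_cv, len(chunk))
        slots = [f"{r}{c}" for r in PLATE_ROWS for c in TREATMENT_COLS]
        for (well, (entry_id, ci, v_true), nz) in zip(slots, chunk, noise):
            wells[well] = WellRole(role="treatment", entry_id=entry_id, conc_index=ci)
            lum[well] = max((cfg.mu_pos + span * float(v_true) / 100.0) * nz, 0.0)
        pos += len(chunk)
        plate_maps.append(PlateMap(plate_id=plate_id, wells=wells))
        plates.append(RawPlate(plate_id=plate_id, luminescence=lum))
    return SimulatedScreen(library=library, plate_maps=plate_maps, plates=plates,
                           truth=truth)


@dataclass(frozen=True)
class SimSerialConfig:
    """Serial-sample structure: per-time-point potency drift and marker model.

    potency_drift : entry_id -> {time_point: shift in log10 EC50 units};
        positive shifts model acquired resistance, return toward zero its
        reversal after therapy stop.
    marker_baseline : marker -> baseline median intensity.
    marker_multipliers : marker -> {time_point: multiplicative change}.
    reference : marker -> constant reference (isotype) median.
    """

    time_points: tuple[str, ...] = ("T0", "T1", "T2", "T3", "T4")
    potency_drift: dict = field(default_factory=dict)
    marker_baseline: dict = field(default_factory=lambda: {
        "Bcl-2 (pS70)": 15.0, "Bcl-2": 60.0, "Mcl-1": 18.0, "Bcl-xL": 55.0,
    })
    marker_multipliers: dict = field(default_factory=dict)
    reference: dict | None = None
    flow_noise_cv: float = 0.0
    cofactor: float = 150.0

    def __post_init__(self) -> None:
        for entry, shifts in self.potency_drift.items():
            for tp, d in shifts.items():
                if not np.isfinite(d):
                    raise ValueError(f"non-finite drift for {entry} at {tp}")
        for m, mults in self.marker_multipliers.items():
            for tp, f in mults.items():
                if f <= 0:
                    raise ValueError(f"multiplier must be > 0 ({m} at {tp})")


@dataclass
class SerialSimulation:
    screens: dict[str, SimulatedScreen]
    flow: "object"  # FlowMarkerTable; late import avoids a module cycle


def simulate_serial(
    cfg: SimSerialConfig, screen_cfg: SimScreenConfig
) -> SerialSimulation:
    """One screen per time-point with drifted potency, plus a flow table.

    The base truth is drawn once from screen_cfg; each time-point's screen
    shifts log_ec50 by the configured drift and re-draws plate noise from a
    seed derived from the base seed. Flow medians are baseline times the
    per-time-point multiplier with optional lognormal noise; reference
    medians are constant across time-points.
    """
    from .phosphoflow import FlowMarkerTable

    base = simulate_screen(dataclasses.replace(screen_cfg, noise_cv=0.0))
    truth0 = base.truth
    screens: dict[str, SimulatedScreen] = {}
    for i, tp in enumerate(cfg.time_points):
        truth = truth0.copy()
        for entry_id, shifts in cfg.potency_drift.items():
            if tp in shifts:
                truth.loc[truth["entry_id"] == entry_id, "log_ec50"] += shifts[tp]
        sub_seed = (screen_cfg.seed * 1009 + i) % (2**31 - 1)
        screens[tp] = simulate_screen(
            dataclasses.replace(screen_cfg, seed=sub_seed, truth=truth)
        )

    markers = list(cfg.marker_baseline)
    rng = np.random.default_rng((screen_cfg.seed * 1013 + 97) % (2**31 - 1))
    med = np.empty((len(cfg.time_points), len(markers)))
    for i, tp in enumerate(cfg.time_points):
        for j, m in enumerate(markers):
            mult = cfg.marker_multipliers.get(m, {}).get(tp, 1.0)
            med[i, j] = cfg.marker_baseline[m] * mult
    med *= _lognormal_factors(rng, cfg.flow_noise_cv, med.size).reshape(med.shape)
    ref = cfg.reference or {m: 10.0 for m in markers}
    flow = FlowMarkerTable(
        medians=pd.DataFrame(med, index=list(cfg.time_points), columns=markers),
        reference=pd.Series(ref).reindex(markers),
        cofactor=cfg.cofactor,
    )
    return SerialSimulation(screens=screens, flow=flow)
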