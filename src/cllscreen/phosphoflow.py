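"""Arcsinh-ratio statistics for phospho-flow marker medians.

Phospho-flow readouts (median fluorescence intensities per sample and
marker) are expressed on the standard effect scale of the field: the
arcsinh-transformed signal relative to a reference (isotype control or
unstimulated control), which by construction maps the reference itself to
zero:

    ratio = asinh(signal / cofactor) - asinh(reference / cofactor)

The cofactor sets where the transform bends from linear to logarithmic;
150 is the common choice for conventional fluorescence cytometry. For
signals well below the cofactor the ratio reduces to
(signal - reference)/cofactor, so fold-changes of small signals pass
through almost linearly.

Longitudinal marker shifts are reported the way clinicians read them: the
later value as an integer percent of the earlier one (half away from zero),
e.g. 0.28 -> 1.97 is 704%.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

DEFAULT_COFACTOR = 150.0


def arcsinh_ratio(signal, reference, cofactor: float = DEFAULT_COFACTOR):
    """asinh(signal/cofactor) - asinh(reference/cofactor) (vectorized).

    Strictly increasing in signal, strictly decreasing in reference, zero
    when they coincide, antisymmetric under swapping them.
    """
    if cofactor <= 0:
        raise ValueError(f"cofactor must be > 0, got {cofactor}")
    s = np.asarray(signal, dtype=float)
    r = np.asarray(reference, dtype=float)
    out = np.arcsinh(s / cofactor) - np.arcsinh(r / cofactor)
    return float(out) if out.ndim == 0 else out


def percent_relative(later: float, earlier: float) -> int:
    """later as integer percent of earlier, rounded half away from zero."""
    if not (math.isfinite(later) and math.isfinite(earlier)):
        raise ValueError("values must be finite")
    if earlier == 0:
        raise ValueError("undefined relative change: earlier value is 0")
    pct = 100.0 * later / earlier
    return int(math.copysign(math.floor(abs(pct) + 0.5), pct))


@dataclass
class FlowMarkerTable:
    """Sample x marker median intensities plus per-marker reference medians.

    medians : DataFrame indexed by sample id (e.g. T0..T4), columns are
        marker names (e.g. "Bcl-2 (pS70)").
    reference : Series of reference medians (isotype/unstimulated control),
        one per marker.
    """

    medians: pd.DataFrame
    reference: pd.Series
    cofactor: float = DEFAULT_COFACTOR

    def __post_init__(self) -> None:
        if self.cofactor <= 0:
            raise ValueError("cofactor must be > 0")
        missing = set(self.medians.columns) - set(self.reference.index)
        if missing:
            raise ValueError(f"reference median missing for markers: {sorted(missing)}")
        if (self.medians.to_numpy() < 0).any() or (self.reference < 0).any():
            raise ValueError("median intensities must be >= 0")

    def arcsinh_ratios(self) -> pd.DataFrame:
        ref = self.reference.reindex(self.medians.columns)
        return pd.DataFrame(
            np.arcsinh(self.medians.to_numpy() / self.cofactor)
            - np.arcsinh(ref.to_numpy() / self.cofactor)[None, :],
            index=self.medians.index,
            columns=self.medians.columns,
        )


@dataclass
class ArcsinhRatioMatrix:
    """Arcsinh-ratio matrix with heatmap row/column leaf orders."""

    values: pd.DataFrame
    row_order: list[int]
    col_order: list[int]
    cofactor: float
    row_linkage: np.ndarray | None = None
    col_linkage: np.ndarray | None = None

    def ordered(self) -> pd.DataFrame:
        return self.values.iloc[self.row_order, self.col_order]


def _leaf_order(matrix: np.ndarray) -> tuple[list[int], np.ndarray | None]:
    """Hierarchical leaf order by Ward linkage on Manhattan distance.

    The Lance-Williams Ward update is applied to the raw Manhattan
    dissimilarities (hclust ward.D behavior, as used by ClustVis) rather
    than their squares; scipy's ward squares its input, so the distances
    are pre-square-rooted, which preserves the ward.D merge order. A
    zero-dispersion (constant) matrix keeps the input order.
    """
    n = matrix.shape[0]
    if n < 2:
        return list(range(n)), None
    d = pdist(matrix, metric="cityblock")
    if np.all(d == 0):
        logger.warning("constant matrix: clustering skipped, input order kept")
        return list(range(n)), None
    link = hierarchy.linkage(np.sqrt(d), method="ward")
    return [int(i) for i in hierarchy.leaves_list(link)], link


def marker_heatmap_matrix(table: FlowMarkerTable) -> ArcsinhRatioMatrix:
    """Arcsinh-ratio matrix plus clustered row/column orders for a heatmap.

    Rows (samples) and columns (markers) are each clustered with Manhattan
    distance and Ward linkage; orders are deterministic given input order
    (scipy breaks ties by input index). A dimension with fewer than 2
    elements, or a constant matrix, keeps its input order with a warning.
    """
    if table.medians.shape[0] < 2 and table.medians.shape[1] < 2:
        raise ValueError("need at least 2 samples or 2 markers to cluster")
    for axis, n in (("samples", table.medians.shape[0]),
                    ("markers", table.medians.shape[1])):
        if n < 2:
            logger.warning("only %d %s: clustering skipped for that axis", n, axis)
    ratios = table.arcsinh_ratios()
    m = ratios.to_numpy()
    row_order, row_link = _leaf_order(m)
    col_order, col_link = _leaf_order(m.T)
    return ArcsinhRatioMatrix(
        values=ratios,
        row_order=row_order,
        col_order=col_order,
        cofactor=table.cofactor,
        row_linkage=row_link,
        col_linkage=col_link,
    )


def read_flow_tables(
    medians_path, reference_path, cofactor: float = DEFAULT_COFACTOR
) -> FlowMarkerTable:
    """Read long-format CSVs: medians (sample,marker,median) and reference
    (marker,median)."""
    med = pd.read_csv(medians_path)
    ref = pd.read_csv(reference_path)
    wide = med.pivot(index="sample", columns="marker", values="median")
    if wide.isna().any().any():
        raise ValueError("medians table has missing sample x marker cells")
    # preserve first-appearance order of samples and markers
    wide = wide.reindex(
        index=med["sample"].drop_duplicates(),
        columns=med["marker"].drop_duplicates(),
    )
    return FlowMarkerTable(
        medians=wide,
        reference=ref.set_index("marker")["median"],
        cofactor=cofactor,
    )
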