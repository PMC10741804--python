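"""Geometric comparison of structure masks: DSC, Hausdorff distance,
and relative volume difference.

DSC(a, b) = 2|a ∩ b| / (|a| + |b|) measures volumetric overlap in
[0, 1]. The Hausdorff distance is the classic bidirectional maximum
surface-to-surface separation HD = max(h(a, b), h(b, a)) with
h(a, b) = max_{p ∈ surf(a)} min_{q ∈ surf(b)} ||p − q|| in mm, computed
between surface-voxel centers so values are reported in patient-space
millimetres on anisotropic grids. RVD = (V_test − V_ref) / V_ref is the
signed relative volume difference; cohort tables conventionally print
its magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .volumes import (
    EmptyStructureError,
    GridMismatchError,
    StructureMask,
    StructureSet,
    surface_points,
)

__all__ = [
    "dice",
    "directed_hausdorff",
    "hausdorff",
    "hausdorff_percentile",
    "rvd",
    "compare_structure_sets",
    "GeometryReport",
    "UndefinedMetricError",
]


class UndefinedMetricError(ValueError):
    """Both masks are empty: the metric is undefined."""


def _check_grids(a: StructureMask, b: StructureMask) -> None:
    if a.grid != b.grid:
        raise GridMismatchError(
            f"{a.name} and {b.name} live on different grids"
        )


def dice(a: StructureMask, b: StructureMask) -> float:
    """Dice similarity coefficient of two masks on one grid."""
    _check_grids(a, b)
    na, nb = a.voxel_count, b.voxel_count
    if na == 0 and nb == 0:
        raise UndefinedMetricError("DSC undefined for two empty masks")
    inter = int(np.count_nonzero(a.occupancy & b.occupancy))
    return 2.0 * inter / (na + nb)


def directed_hausdorff(a: StructureMask, b: StructureMask) -> float:
    """h(a, b): max over a's surface of the distance to b's surface, mm."""
    _check_grids(a, b)
    pa = surface_points(a)
    pb = surface_points(b)
    d, _ = cKDTree(pb).query(pa, k=1)
    return float(d.max())


def hausdorff(a: StructureMask, b: StructureMask) -> float:
    """Bidirectional Hausdorff distance max(h(a,b), h(b,a)) in mm."""
    return max(directed_hausdorff(a, b), directed_hausdorff(b, a))


def hausdorff_percentile(a: StructureMask, b: StructureMask, q: float = 95.0) -> float:
    """Percentile variant (e.g. HD95); not used by default reports."""
    _check_grids(a, b)
    pa, pb = surface_points(a), surface_points(b)
    dab, _ = cKDTree(pb).query(pa, k=1)
    dba, _ = cKDTree(pa).query(pb, k=1)
    return float(max(np.percentile(dab, q), np.percentile(dba, q)))


def rvd(test: StructureMask, ref: StructureMask) -> float:
    """Signed relative volume difference (V_test − V_ref) / V_ref."""
    _check_grids(test, ref)
    if ref.is_empty:
        raise EmptyStructureError(f"{ref.name}: reference volume is zero")
    return (test.volume_cc - ref.volume_cc) / ref.volume_cc


@dataclass
class GeometryReport:
    """Per-structure geometric comparison of two structure sets.

    Rows carry dsc, hd_mm, signed and absolute rvd, plus flags for
    structures present in only one set or empty in one or both. Flagged
    rows carry NaN metric values where the metric is undefined.
    """

    rows: list[dict] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        cols = ["structure", "dsc", "hd_mm", "rvd_signed", "rvd_abs", "flags"]
        if not self.rows:
            return pd.DataFrame(columns=cols)
        return pd.DataFrame(self.rows)[cols]

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9g")


def compare_structure_sets(a: StructureSet, b: StructureSet) -> GeometryReport:
    """Compare every structure present in both sets; flag the rest.

    Set ``a`` is the test set, ``b`` the reference (the RVD
    denominator). Empty-structure conventions: both empty -> all
    metrics undefined (flag ``both-empty``, excluded from summaries);
    one empty -> DSC 0, HD undefined, RVD −1 when the test is empty and
    undefined when the reference is empty.
    """
    report = GeometryReport(metadata={
        "hausdorff": "classic (100th percentile), surface voxel centers, mm",
        "comparison_grid": "shared structure grid",
    })
    names = sorted(set(a.names()) | set(b.names()))
    for name in names:
        row = {"structure": name, "dsc": np.nan, "hd_mm": np.nan,
               "rvd_signed": np.nan, "rvd_abs": np.nan, "flags": ""}
        if name not in a.structures:
            row["flags"] = "missing-in-A"
            report.rows.append(row)
            continue
        if name not in b.structures:
            row["flags"] = "missing-in-B"
            report.rows.append(row)
            continue
        ma, mb = a.structures[name], b.structures[name]
        if ma.is_empty and mb.is_empty:
            row["flags"] = "both-empty"
        elif ma.is_empty or mb.is_empty:
            row["dsc"] = 0.0
            row["flags"] = "empty-in-A" if ma.is_empty else "empty-in-B"
            if not mb.is_empty:  # reference nonempty: RVD defined, = −1
                row["rvd_signed"] = -1.0
                row["rvd_abs"] = 1.0
        else:
            row["dsc"] = dice(ma, mb)
            row["hd_mm"] = hausdorff(ma, mb)
            s = rvd(ma, mb)
            row["rvd_signed"] = s
            row["rvd_abs"] = abs(s)
        report.rows.append(row)
    return report
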