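"""Dose grids, cumulative DVHs, and dosimetric indices.

A :class:`DoseGrid` carries absorbed dose in cGy on a
:class:`~contourqa.volumes.VoxelGrid` together with the prescription
dose. Structure dosimetry goes through the cumulative dose-volume
histogram (DVH), from which the standard indices are read:

* ``D_x%`` — the minimum dose received by the hottest x% of the
  structure (so D_2% is a near-maximum, D_98% a near-minimum);
* ``D_v cc`` — the minimum dose received by the hottest v cc
  (D_0.03cc is the conventional near-maximum point dose);
* ``V_d`` — the volume (% or cc) receiving at least dose d;
* homogeneity index HI = (D_2% − D_98%) / D_50%, 0 for a perfectly
  uniform target dose;
* Paddick-style conformity index CI = TV_PV² / (V_PTV × V_TV), where
  V_TV is the volume covered by 95% of the prescription and TV_PV its
  intersection with the PTV; CI = 1 iff the 95% isodose coincides with
  the PTV.

The default DVH bin width is 1 cGy; inverse lookups (D_x%, D_v) are
read off the cumulative curve at bin-edge resolution, so bin-aligned
dose values are recovered exactly and any value is within one bin width
of direct voxel sorting. Near-maximum D_cc statistics are computed from
descending-sorted voxel doses with fractional-voxel interpolation,
which is the usual planning-system convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import (
    EmptyStructureError,
    GridMismatchError,
    StructureMask,
    VoxelGrid,
)

__all__ = [
    "DoseGrid",
    "DVH",
    "DoseMetrics",
    "resample_dose",
    "compute_dvh",
    "dose_at_volume_percent",
    "dose_at_absolute_volume",
    "dose_at_cc_sorted",
    "volume_at_dose",
    "mean_min_dose",
    "homogeneity_index",
    "conformity_index",
    "relative_difference",
    "compute_dose_metrics",
    "write_dose_text",
    "read_dose_text",
    "read_rtdose",
]

DEFAULT_BIN_WIDTH_CGY = 1.0


@dataclass
class DoseGrid:
    """Scalar dose field in cGy with its prescription dose."""

    grid: VoxelGrid
    dose: np.ndarray
    prescription_cgy: float

    def __post_init__(self):
        d = np.asarray(self.dose, dtype=float)
        if d.shape != tuple(self.grid.dims):
            raise ValueError("dose shape does not match grid dims")
        if (d < 0).any():
            raise ValueError("dose must be nonnegative everywhere")
        if self.prescription_cgy <= 0:
            raise ValueError("prescription must be > 0")
        self.dose = d


@dataclass
class DVH:
    """Cumulative dose-volume histogram: V(>= dose) per bin edge.

    ``edges`` are ascending dose values in cGy; ``cum_cc[i]`` is the
    structure volume receiving at least ``edges[i]``. The curve is
    non-increasing, starts at the full structure volume at 0 cGy, and
    reaches 0 past the maximum dose.
    """

    structure: str
    edges: np.ndarray
    cum_cc: np.ndarray
    bin_width: float = DEFAULT_BIN_WIDTH_CGY

    @property
    def total_cc(self) -> float:
        return float(self.cum_cc[0])

    @property
    def cum_pct(self) -> np.ndarray:
        return 100.0 * self.cum_cc / self.total_cc

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({
            "dose_cGy": self.edges,
            "volume_cc": self.cum_cc,
            "volume_pct": self.cum_pct,
        }).to_csv(path, index=False, float_format="%.9g")


@dataclass
class DoseMetrics:
    """Bundle of per-structure dosimetric indices (all doses in cGy)."""

    structure: str
    d_mean: float
    d_min: float
    d_max: float
    d_0_03cc: float
    hi: float | None = None
    ci: float | None = None
    extra: dict = field(default_factory=dict)


def write_dose_text(dose: DoseGrid, path) -> None:
    """Plain-text dose exchange format: grid header + one cGy value per
    voxel in C order."""
    g = dose.grid
    with open(path, "w") as fh:
        fh.write("# contourqa dose v1\n")
        fh.write("dims: {} {} {}\n".format(*g.dims))
        fh.write("spacing: {:.9g} {:.9g} {:.9g}\n".format(*g.spacing))
        fh.write("origin: {:.9g} {:.9g} {:.9g}\n".format(*g.origin))
        fh.write(f"posterior: {g.posterior}\n")
        fh.write(f"prescription_cgy: {dose.prescription_cgy:.9g}\n")
        np.savetxt(fh, dose.dose.ravel(order="C")[None, :], fmt="%.6g")


def read_dose_text(path) -> DoseGrid:
    header: dict[str, str] = {}
    body: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" in line and not body:
                key, _, val = line.partition(":")
                header[key.strip()] = val.strip()
            else:
                body.append(line)
    dims = tuple(int(v) for v in header["dims"].split())
    grid = VoxelGrid(
        origin=tuple(float(v) for v in header["origin"].split()),
        spacing=tuple(float(v) for v in header["spacing"].split()),
        dims=dims,
        posterior=header.get("posterior", "+y"),
    )
    vals = np.array(" ".join(body).split(), dtype=float)
    return DoseGrid(grid, vals.reshape(dims, order="C"),
                    float(header["prescription_cgy"]))


def read_rtdose(path, prescription_cgy: float) -> DoseGrid:
    """Read a DICOM RT DOSE grid, applying the dose-grid scaling so the
    result is in cGy (DICOM doses are stored in Gy)."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    arr = ds.pixel_array.astype(float) * scaling * 100.0  # Gy -> cGy
    # DICOM pixel_array is (frames, rows, cols) = (z, y, x); ours is (x, y, z)
    dose = np.transpose(arr, (2, 1, 0))
    ipp = [float(v) for v in ds.ImagePositionPatient]
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)
    offsets = [float(v) for v in ds.GridFrameOffsetVector]
    dz = offsets[1] - offsets[0] if len(offsets) > 1 else 1.0
    grid = VoxelGrid(
        origin=(ipp[0], ipp[1], ipp[2] + offsets[0]),
        spacing=(col_sp, row_sp, dz),
        dims=dose.shape,
    )
    return DoseGrid(grid, dose, prescription_cgy)


def resample_dose(dose: DoseGrid, target: VoxelGrid) -> DoseGrid:
    """Trilinear resample onto the target grid's voxel centers.

    Target centers outside the source grid get 0 with a warning; the
    prescription is preserved. Raises if the grids do not overlap.
    """
    if dose.grid == target:
        return DoseGrid(target, dose.dose.copy(), dose.prescription_cgy)
    src = dose.grid
    # target voxel centers expressed in source index coordinates
    axes_idx = []
    inside = []
    for a in range(3):
        coord = target.axis_coords(a)
        idx = (coord - src.origin[a]) / src.spacing[a]
        axes_idx.append(idx)
        inside.append((idx >= -0.5) & (idx <= src.dims[a] - 0.5))
    if not all(i.any() for i in inside):
        raise GridMismatchError("dose grid and target grid do not overlap")
    gi, gj, gk = np.meshgrid(*axes_idx, indexing="ij")
    vals = ndimage.map_coordinates(
        dose.dose, [gi.ravel(), gj.ravel(), gk.ravel()],
        order=1, mode="constant", cval=0.0,
    ).reshape(target.dims)
    out_mask = ~(inside[0][:, None, None] & inside[1][None, :, None] & inside[2][None, None, :])
    if out_mask.any():
        warnings.warn(
            f"{int(out_mask.sum())} target voxels fall outside the dose grid; set to 0",
            stacklevel=2,
        )
    vals = np.clip(vals, 0.0, None)
    return DoseGrid(target, vals, dose.prescription_cgy)


def _structure_doses(dose: DoseGrid, mask: StructureMask) -> np.ndarray:
    if dose.grid != mask.grid:
        raise GridMismatchError("dose and mask must share one grid")
    if mask.is_empty:
        raise EmptyStructureError(f"{mask.name}: empty structure has no DVH")
    return dose.dose[mask.occupancy]


def compute_dvh(
    dose: DoseGrid,
    mask: StructureMask,
    bin_width: float = DEFAULT_BIN_WIDTH_CGY,
) -> DVH:
    """Cumulative DVH of a structure with the given bin width (cGy)."""
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    doses = _structure_doses(dose, mask)
    vv = mask.grid.voxel_volume_cc
    n_bins = int(np.ceil((doses.max() + bin_width) / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(doses, bins=edges)
    # V(>= edges[i]) = total − (voxels in bins strictly below edge i)
    cum = (doses.size - np.concatenate([[0], np.cumsum(counts)])) * vv
    return DVH(mask.name, edges, cum, bin_width)


def dose_at_volume_percent(dvh: DVH, x: float) -> float:
    """D_x%: the largest dose D with V(>= D) >= x% of the structure,
    read off the DVH at bin resolution; non-increasing in x.
    """
    if not 0 < x <= 100:
        raise ValueError("percentile x must be in (0, 100]")
    return dose_at_absolute_volume(dvh, x / 100.0 * dvh.total_cc)


def dose_at_absolute_volume(dvh: DVH, v_cc: float) -> float:
    """D_v: dose such that v cc receives at least that dose."""
    if not 0 < v_cc <= dvh.total_cc + 1e-9:
        raise ValueError(f"volume {v_cc} cc outside (0, {dvh.total_cc}] cc")
    v_cc = min(v_cc, dvh.total_cc)
    cum = dvh.cum_cc
    # largest edge whose cumulative volume still covers v_cc (the curve
    # is a non-increasing step function; doses are quantized to the bin
    # grid, so the answer is exact for bin-aligned dose values and
    # within one bin width of direct voxel sorting otherwise)
    j = int(np.nonzero(cum >= v_cc - 1e-12)[0][-1])
    return float(dvh.edges[j])


def dose_at_cc_sorted(dose: DoseGrid, mask: StructureMask, v_cc: float) -> float:
    """Near-maximum D_v from descending-sorted voxel doses with
    fractional-voxel linear interpolation at the v cc boundary.

    This is the convention used for D_0.03cc-style point-dose metrics.
    """
    doses = np.sort(_structure_doses(dose, mask))[::-1]
    vv = mask.grid.voxel_volume_cc
    total = doses.size * vv
    if not 0 < v_cc <= total + 1e-9:
        raise ValueError(f"volume {v_cc} cc outside (0, {total}] cc")
    k = v_cc / vv  # fractional voxel count
    if k <= 1.0:
        return float(doses[0])
    lo = int(np.floor(k))
    if lo >= doses.size:
        return float(doses[-1])
    frac = k - lo
    return float(doses[lo - 1] * (1 - frac) + doses[lo] * frac)


def volume_at_dose(dvh: DVH, d_cgy: float, as_percent: bool = False) -> float:
    """V_d: volume receiving at least ``d_cgy``, in cc or % of total."""
    if d_cgy < 0:
        raise ValueError("dose must be >= 0")
    v = float(np.interp(d_cgy, dvh.edges, dvh.cum_cc))
    return 100.0 * v / dvh.total_cc if as_percent else v


def mean_min_dose(dose: DoseGrid, mask: StructureMask) -> tuple[float, float]:
    """(D_mean, D_min) over the structure's voxels, in cGy."""
    doses = _structure_doses(dose, mask)
    return float(doses.mean()), float(doses.min())


def homogeneity_index(dvh: DVH) -> float:
    """HI = (D_2% − D_98%) / D_50%; 0 for a perfectly uniform dose."""
    d2 = dose_at_volume_percent(dvh, 2)
    d98 = dose_at_volume_percent(dvh, 98)
    d50 = dose_at_volume_percent(dvh, 50)
    if d50 == 0:
        raise ValueError("degenerate dose: D_50% is zero")
    return (d2 - d98) / d50


def conformity_index(dose: DoseGrid, ptv: StructureMask) -> float:
    """Paddick-style CI = TV_PV² / (V_PTV × V_TV) at the 95% isodose."""
    if dose.grid != ptv.grid:
        raise GridMismatchError("dose and PTV must share one grid")
    if ptv.is_empty:
        raise EmptyStructureError("PTV is empty")
    iso = dose.dose >= 0.95 * dose.prescription_cgy
    vv = ptv.grid.voxel_volume_cc
    v_tv = float(iso.sum()) * vv
    if v_tv == 0:
        raise ValueError("no voxel receives 95% of the prescription")
    v_ptv = ptv.volume_cc
    tv_pv = float((iso & ptv.occupancy).sum()) * vv
    return tv_pv ** 2 / (v_ptv * v_tv)


def relative_difference(test: float, ref: float) -> float:
    """Signed relative difference (test − ref) / ref.

    Applied uniformly to D_X, HI, CI and interobserver comparisons.
    """
    if ref == 0:
        raise ZeroDivisionError("relative difference undefined for ref = 0")
    return (test - ref) / ref


def compute_dose_metrics(
    dose: DoseGrid,
    mask: StructureMask,
    is_target: bool = False,
    bin_width: float = DEFAULT_BIN_WIDTH_CGY,
) -> DoseMetrics:
    """All standard indices for one structure; HI/CI for targets only."""
    doses = _structure_doses(dose, mask)
    vv = mask.grid.voxel_volume_cc
    d003 = dose_at_cc_sorted(dose, mask, min(0.03, doses.size * vv))
    m = DoseMetrics(
        structure=mask.name,
        d_mean=float(doses.mean()),
        d_min=float(doses.min()),
        d_max=float(doses.max()),
        d_0_03cc=d003,
    )
    if is_target:
        dvh = compute_dvh(dose, mask, bin_width)
        m.hi = homogeneity_index(dvh)
        m.ci = conformity_index(dose, mask)
    return m
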