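"""Voxel grids, structure masks, and contour rasterization.

The geometric substrate for contour comparison: everything downstream
(overlap metrics, DVHs, scorecards) operates on binary occupancy masks
defined on a shared :class:`VoxelGrid`. Coordinates are patient-space
millimetres in the radiological LPS convention by default: +x patient
left, +y posterior, +z superior, with axial slices stacked along the
third axis. Voxel centers sit at ``origin + index * spacing``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from scipy import ndimage
from shapely import contains_xy
from shapely.geometry import Polygon

__all__ = [
    "VoxelGrid",
    "ContourSet",
    "StructureMask",
    "StructureSet",
    "CoordinateMismatchError",
    "InvalidContourError",
    "EmptyStructureError",
    "GridMismatchError",
    "rasterize_contours",
    "expand_margin",
    "volume_cc",
    "surface_points",
    "standardize_name",
    "load_name_table",
    "write_mask_text",
    "read_mask_text",
    "write_rtstruct",
    "read_rtstruct",
]

IN_PLANE_DIRECTIONS = ("+x", "-x", "+y", "-y")


class CoordinateMismatchError(ValueError):
    """A contour's z position cannot be attributed to any slice plane."""


class InvalidContourError(ValueError):
    """A polygon is degenerate (fewer than 3 vertices)."""


class EmptyStructureError(ValueError):
    """An operation that requires a nonempty mask received an empty one."""


class GridMismatchError(ValueError):
    """Two masks or a dose and a mask do not share a voxel grid."""


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3D voxel lattice in patient space.

    Parameters
    ----------
    origin : sequence of 3 floats
        Center of voxel (0, 0, 0) in mm.
    spacing : sequence of 3 floats
        Voxel pitch per axis in mm, all > 0. The third component is the
        slice thickness.
    dims : sequence of 3 ints
        Voxel counts per axis, all >= 1.
    posterior : str
        Which in-plane signed axis points posterior ("+y" by default,
        matching DICOM LPS). Superior is always +z.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    dims: tuple[int, int, int]
    posterior: str = "+y"

    def __post_init__(self):
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "dims", tuple(int(v) for v in self.dims))
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.dims) != 3:
            raise ValueError("origin, spacing and dims must be 3-vectors")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("all spacings must be > 0")
        if any(d < 1 for d in self.dims):
            raise ValueError("all dims must be >= 1")
        if self.posterior not in IN_PLANE_DIRECTIONS:
            raise ValueError(f"posterior must be one of {IN_PLANE_DIRECTIONS}")

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cc (mm^3 / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along one axis, in mm."""
        return self.origin[axis] + np.arange(self.dims[axis]) * self.spacing[axis]

    @property
    def z_positions(self) -> np.ndarray:
        return self.axis_coords(2)

    def centers(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of voxel-center coordinates in mm."""
        xs, ys, zs = (self.axis_coords(a) for a in range(3))
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    def direction_axis(self, direction: str) -> tuple[int, int]:
        """Map an anatomical direction to (axis, sign).

        Directions: left, right, anterior, posterior, superior, inferior.
        """
        post_axis = 0 if self.posterior[1] == "x" else 1
        post_sign = 1 if self.posterior[0] == "+" else -1
        lat_axis = 1 - post_axis
        mapping = {
            "posterior": (post_axis, post_sign),
            "anterior": (post_axis, -post_sign),
            # patient left is +x in LPS; if posterior occupies x, left is +y
            "left": (lat_axis, 1),
            "right": (lat_axis, -1),
            "superior": (2, 1),
            "inferior": (2, -1),
        }
        try:
            return mapping[direction]
        except KeyError:
            raise ValueError(f"unknown direction {direction!r}") from None


@dataclass
class ContourSet:
    """Planar closed polygons per axial slice for one structure.

    ``slices`` maps z position (mm) to a list of polygons, each an
    (n, 2) array of (x, y) vertices in mm. The first vertex is implicitly
    joined to the last. Holes are carried as separate polygons and
    resolved by the even-odd rule at rasterization time.
    """

    name: str
    slices: list[tuple[float, list[np.ndarray]]]

    def __post_init__(self):
        cleaned = []
        for z, polys in self.slices:
            arrs = []
            for p in polys:
                a = np.asarray(p, dtype=float)
                if a.ndim != 2 or a.shape[1] != 2 or a.shape[0] < 3:
                    raise InvalidContourError(
                        f"{self.name}: polygon at z={z} needs >= 3 (x, y) vertices"
                    )
                arrs.append(a)
            cleaned.append((float(z), arrs))
        self.slices = cleaned


@dataclass
class StructureMask:
    """A named binary occupancy volume on a :class:`VoxelGrid`."""

    name: str
    grid: VoxelGrid
    occupancy: np.ndarray

    def __post_init__(self):
        occ = np.asarray(self.occupancy, dtype=bool)
        if occ.shape != tuple(self.grid.dims):
            raise ValueError(
                f"occupancy shape {occ.shape} does not match grid dims {self.grid.dims}"
            )
        self.occupancy = occ

    @property
    def voxel_count(self) -> int:
        return int(self.occupancy.sum())

    @property
    def is_empty(self) -> bool:
        return not self.occupancy.any()

    @property
    def volume_cc(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_cc

    def centroid_mm(self) -> np.ndarray:
        if self.is_empty:
            raise EmptyStructureError(f"{self.name}: empty mask has no centroid")
        idx = np.argwhere(self.occupancy)
        return np.asarray(self.grid.origin) + idx.mean(axis=0) * np.asarray(self.grid.spacing)


PROVENANCE_LABELS = ("manual", "ai", "ai_adjusted")


@dataclass
class StructureSet:
    """A collection of masks on one grid with a provenance label.

    Provenance distinguishes manually drawn contours, raw AI output, and
    AI contours after physician review (per-observer via ``observer``).
    Structure names are standardized on insertion.
    """

    provenance: str
    structures: dict[str, StructureMask] = field(default_factory=dict)
    observer: str = ""

    def __post_init__(self):
        if self.provenance not in PROVENANCE_LABELS:
            raise ValueError(f"provenance must be one of {PROVENANCE_LABELS}")
        std: dict[str, StructureMask] = {}
        grid = None
        for name, mask in self.structures.items():
            key = standardize_name(name)
            if key in std:
                raise ValueError(f"duplicate structure after standardization: {key}")
            if grid is None:
                grid = mask.grid
            elif mask.grid != grid:
                raise GridMismatchError("all member masks must share one grid")
            std[key] = mask
        self.structures = std

    @property
    def grid(self) -> VoxelGrid | None:
        for m in self.structures.values():
            return m.grid
        return None

    def __getitem__(self, name: str) -> StructureMask:
        return self.structures[standardize_name(name)]

    def __contains__(self, name: str) -> bool:
        return standardize_name(name) in self.structures

    def names(self) -> list[str]:
        return list(self.structures)


# ---------------------------------------------------------------------------
# Structure-name standardization
# ---------------------------------------------------------------------------

_NAME_TABLE: dict[str, str] | None = None


def load_name_table() -> dict[str, str]:
    """Alias -> canonical structure-name table (bundled defaults)."""
    global _NAME_TABLE
    if _NAME_TABLE is None:
        text = resources.files("contourqa.data").joinpath("structure_names.yaml").read_text()
        raw = yaml.safe_load(text)
        table: dict[str, str] = {}
        for canonical, aliases in raw.items():
            table[_normkey(canonical)] = canonical
            for alias in aliases or []:
                table[_normkey(alias)] = canonical
        _NAME_TABLE = table
    return _NAME_TABLE


def _normkey(name: str) -> str:
    return re.sub(r"[\s_\-]+", "", name).lower()


def standardize_name(name: str) -> str:
    """Resolve a clinical structure name to its canonical form.

    Unknown names pass through stripped but otherwise unchanged, so the
    table only needs to cover names that appear under several spellings.
    """
    return load_name_table().get(_normkey(name), name.strip())


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def rasterize_contours(contours: ContourSet, grid: VoxelGrid) -> StructureMask:
    """Convert planar contour polygons to a binary mask on ``grid``.

    A voxel is set iff its center lies inside an odd number of the
    slice's polygons (even-odd rule), so holes supplied as separate
    polygons are carved out. Slices with no polygon are empty.

    Raises
    ------
    CoordinateMismatchError
        If a contour's z lies farther than half a slice thickness from
        every grid slice plane.
    """
    occ = np.zeros(grid.dims, dtype=bool)
    z0, dz = grid.origin[2], grid.spacing[2]
    xs = grid.axis_coords(0)
    ys = grid.axis_coords(1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    for z, polys in contours.slices:
        k = int(round((z - z0) / dz))
        if k < 0 or k >= grid.dims[2] or abs(z - (z0 + k * dz)) > dz / 2 + 1e-9:
            raise CoordinateMismatchError(
                f"{contours.name}: contour z={z} mm matches no slice plane"
            )
        parity = np.zeros(gx.shape, dtype=bool)
        for poly in polys:
            shp = Polygon(poly)
            if not shp.is_valid:
                shp = shp.buffer(0)
            inside = contains_xy(shp, gx.ravel(), gy.ravel()).reshape(gx.shape)
            parity ^= inside
        occ[:, :, k] |= parity
    return StructureMask(contours.name, grid, occ)


# ---------------------------------------------------------------------------
# Margin expansion
# ---------------------------------------------------------------------------

def expand_margin(
    mask: StructureMask,
    margin_mm: float | Mapping[str, float],
) -> StructureMask:
    """Expand a mask by anisotropic anatomical margins.

    ``margin_mm`` is either a single isotropic margin or a mapping with
    keys from {left, right, anterior, posterior, superior, inferior}
    (missing keys default to 0). A voxel of the output is set iff some
    set voxel of the input lies within the direction-dependent
    ellipsoidal reach: each half-axis uses its own radius, so e.g. a
    5 mm margin with 3 mm posterior reaches 3 mm in the posterior
    half-space only. This mirrors the usual planning-system behaviour
    for target-volume margins (clinical target volume -> planning
    target volume).
    """
    if isinstance(margin_mm, (int, float)):
        margins = {d: float(margin_mm) for d in
                   ("left", "right", "anterior", "posterior", "superior", "inferior")}
    else:
        margins = {d: 0.0 for d in
                   ("left", "right", "anterior", "posterior", "superior", "inferior")}
        for k, v in margin_mm.items():
            if k not in margins:
                raise ValueError(f"unknown margin direction {k!r}")
            margins[k] = float(v)
    if any(v < 0 for v in margins.values()):
        raise ValueError("margins must be >= 0")
    if all(v == 0 for v in margins.values()):
        return StructureMask(mask.name, mask.grid, mask.occupancy.copy())

    grid = mask.grid
    # radius per (axis, sign): +1 offset along axis -> which direction's margin
    radius = np.zeros((3, 2))  # [axis, 0 -> negative offsets, 1 -> positive]
    for direction, r in margins.items():
        axis, sign = grid.direction_axis(direction)
        radius[axis, 1 if sign > 0 else 0] = r
    # structuring element on the voxel lattice
    half = [int(np.floor(radius[a].max() / grid.spacing[a])) for a in range(3)]
    offs = [np.arange(-h, h + 1) for h in half]
    oi, oj, ok = np.meshgrid(*offs, indexing="ij")
    total = np.zeros(oi.shape)
    for a, o in enumerate((oi, oj, ok)):
        d = o * grid.spacing[a]
        r = np.where(o > 0, radius[a, 1], radius[a, 0])
        term = np.zeros_like(total)
        nz = o != 0
        with np.errstate(divide="ignore", invalid="ignore"):
            term[nz] = np.where(r[nz] > 0, (d[nz] / np.where(r[nz] > 0, r[nz], 1.0)) ** 2, np.inf)
        total += term
    kernel = total <= 1.0 + 1e-12
    out = ndimage.binary_dilation(mask.occupancy, structure=kernel)
    return StructureMask(mask.name, mask.grid, out)


def volume_cc(mask: StructureMask) -> float:
    """Absolute volume in cc: set-voxel count times voxel volume."""
    return mask.volume_cc


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def surface_points(mask: StructureMask) -> np.ndarray:
    """Centers (mm) of set voxels with a 6-connected unset or
    out-of-grid neighbor; the discrete surface used for Hausdorff
    distances.
    """
    if mask.is_empty:
        raise EmptyStructureError(f"{mask.name}: empty mask has no surface")
    interior = ndimage.binary_erosion(
        mask.occupancy, structure=_FACE_STRUCT, border_value=0
    )
    surf = mask.occupancy & ~interior
    idx = np.argwhere(surf)
    return np.asarray(mask.grid.origin) + idx * np.asarray(mask.grid.spacing)


# ---------------------------------------------------------------------------
# Plain-text mask exchange format
# ---------------------------------------------------------------------------

def write_mask_text(mask: StructureMask, path) -> None:
    """Write a mask in the run-length-encoded text exchange format.

    Header lines carry name/dims/spacing/origin/posterior; the body is a
    single line of run lengths over the C-order flattened occupancy,
    alternating False/True runs and starting with a False run (possibly
    of length 0).
    """
    g = mask.grid
    flat = mask.occupancy.ravel(order="C")
    runs = _rle_encode(flat)
    with open(path, "w") as fh:
        fh.write("# contourqa mask v1\n")
        fh.write(f"name: {mask.name}\n")
        fh.write("dims: {} {} {}\n".format(*g.dims))
        fh.write("spacing: {:.9g} {:.9g} {:.9g}\n".format(*g.spacing))
        fh.write("origin: {:.9g} {:.9g} {:.9g}\n".format(*g.origin))
        fh.write(f"posterior: {g.posterior}\n")
        fh.write("rle: " + " ".join(str(r) for r in runs) + "\n")


def read_mask_text(path) -> StructureMask:
    header: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition(":")
            header[key.strip()] = val.strip()
    dims = tuple(int(v) for v in header["dims"].split())
    grid = VoxelGrid(
        origin=tuple(float(v) for v in header["origin"].split()),
        spacing=tuple(float(v) for v in header["spacing"].split()),
        dims=dims,
        posterior=header.get("posterior", "+y"),
    )
    runs = [int(v) for v in header["rle"].split()] if header["rle"] else []
    flat = _rle_decode(runs, int(np.prod(dims)))
    return StructureMask(header["name"], grid, flat.reshape(dims, order="C"))


def _rle_encode(flat: np.ndarray) -> list[int]:
    if flat.size == 0:
        return []
    change = np.nonzero(np.diff(flat))[0] + 1
    bounds = np.concatenate([[0], change, [flat.size]])
    runs = np.diff(bounds).tolist()
    if flat[0]:  # leading zero-length False run keeps parity fixed
        runs = [0] + runs
    return runs


def _rle_decode(runs: Sequence[int], n: int) -> np.ndarray:
    flat = np.zeros(n, dtype=bool)
    pos = 0
    val = False
    for r in runs:
        if val:
            flat[pos : pos + r] = True
        pos += r
        val = not val
    if pos != n:
        raise ValueError(f"RLE length {pos} does not match voxel count {n}")
    return flat


# ---------------------------------------------------------------------------
# DICOM RT STRUCT adapter
# ---------------------------------------------------------------------------

def write_rtstruct(contour_sets: Iterable[ContourSet], path) -> None:
    """Write contour sets as a minimal DICOM RT Structure Set file."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UID("1.2.840.10008.5.1.4.1.1.481.3")
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = pydicom.dataset.FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.StructureSetLabel = "contourqa"

    roi_seq = []
    contour_seq = []
    for i, cs in enumerate(contour_sets, start=1):
        roi = Dataset()
        roi.ROINumber = i
        roi.ROIName = cs.name
        roi.ReferencedFrameOfReferenceUID = generate_uid()
        roi_seq.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = i
        items = []
        for z, polys in cs.slices:
            for poly in polys:
                item = Dataset()
                item.ContourGeometricType = "CLOSED_PLANAR"
                item.NumberOfContourPoints = len(poly)
                data = []
                for x, y in poly:
                    data += [float(x), float(y), float(z)]
                item.ContourData = data
                items.append(item)
        rc.ContourSequence = items
        contour_seq.append(rc)
    ds.StructureSetROISequence = roi_seq
    ds.ROIContourSequence = contour_seq
    ds.save_as(str(path), enforce_file_format=True)


def read_rtstruct(path) -> list[ContourSet]:
    """Read ROI contour sequences from a DICOM RT Structure Set."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    names = {int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence}
    out = []
    for rc in ds.ROIContourSequence:
        name = names[int(rc.ReferencedROINumber)]
        by_z: dict[float, list[np.ndarray]] = {}
        for item in getattr(rc, "ContourSequence", []):
            pts = np.asarray(item.ContourData, dtype=float).reshape(-1, 3)
            z = float(pts[0, 2])
            by_z.setdefault(z, []).append(pts[:, :2])
        slices = [(z, polys) for z, polys in sorted(by_z.items())]
        out.append(ContourSet(name, slices))
    return out
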