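"""Synthetic phantom cohorts for exercising the QA pipeline.

Real structure sets and plans are protected clinical data, so tests and
worked examples run on geometric phantoms: anatomically arranged organ
primitives (ellipsoids, tubes, cylinders) on a shared grid, AI-style
contour perturbations with controllable disagreement, and conformal
dose fields around the target.

The boundary perturbation is a smooth random radial displacement of the
signed distance field (a coarse Gaussian random field upsampled to the
grid), not voxel noise, so Hausdorff distances behave like observer
disagreement rather than speckle. When a target Dice coefficient is
requested, the displacement amplitude is calibrated by bisection.

Cohorts mirror the three-arm study design: a "manual" set per patient,
an "ai" set perturbed from it with a larger disagreement, and two
observer-adjusted sets perturbed from the AI set with a much smaller
one — so by construction the adjusted contours agree better with the
AI output than with the manual contours. Timing records and four-level
review ratings are drawn from stated distributions. Everything is
deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import volumes as vol
from .dose_metrics import DoseGrid
from .geometry_metrics import dice
from .volumes import StructureMask, StructureSet, VoxelGrid, expand_margin

__all__ = [
    "PhantomSpec",
    "PerturbationSpec",
    "PatientRecord",
    "Cohort",
    "SpecInfeasibleError",
    "CalibrationError",
    "default_roster",
    "make_phantom",
    "perturb_structure",
    "make_dose",
    "make_ideal_plan",
    "make_cohort",
    "LIKERT_LEVELS",
    "LIKERT_DISTRIBUTION",
    "PTV_MARGINS_MM",
]

SITES = ("prostate", "head-and-neck")

PRESCRIPTION_CGY = {"prostate": 6000.0, "head-and-neck": 7095.0}

#: Clinical-target-to-planning-target margin: 5 mm everywhere, 3 mm posterior.
PTV_MARGINS_MM = {
    "left": 5.0, "right": 5.0, "anterior": 5.0,
    "posterior": 3.0, "superior": 5.0, "inferior": 5.0,
}

LIKERT_LEVELS = (
    "severe correction", "medium correction", "slight correction", "no correction"
)
#: Categorical distribution the simulated reviewer draws ratings from.
LIKERT_DISTRIBUTION = (0.08, 0.17, 0.30, 0.45)


class SpecInfeasibleError(ValueError):
    """A phantom primitive does not fit inside the grid."""


class CalibrationError(RuntimeError):
    """The requested target DSC is unreachable for this shape."""


@dataclass(frozen=True)
class PhantomSpec:
    """Site, grid geometry and organ roster for one phantom patient.

    ``roster`` maps structure name to a primitive description:
    ``{kind: ellipsoid|tube|cylinder, center: mm, radii: mm, z: (lo, hi)}``.
    ``jitter_mm`` is the s.d. of the per-patient random displacement and
    radius perturbation applied to every primitive.
    """

    site: str = "prostate"
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    dims: tuple[int, int, int] = (64, 64, 44)
    roster: dict = field(default_factory=dict)
    jitter_mm: float = 1.5
    seed: int = 0

    def grid(self) -> VoxelGrid:
        return VoxelGrid(origin=(0.0, 0.0, 0.0), spacing=self.spacing, dims=self.dims)


@dataclass(frozen=True)
class PerturbationSpec:
    """Contour disagreement model.

    ``amplitude_mm`` scales the smooth random boundary displacement;
    ``offset_mm`` is a systematic whole-structure shift;
    ``bias_mm`` a uniform dilation (> 0) or erosion (< 0);
    ``target_dsc`` if set overrides the amplitude by bisection
    calibration; ``crop_probability`` truncates the superior portion of
    the structure with the given probability, emulating structures the
    AI omits or cuts short.
    """

    amplitude_mm: float = 1.0
    offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    bias_mm: float = 0.0
    target_dsc: float | None = None
    crop_probability: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.amplitude_mm < 0:
            raise ValueError("amplitude must be >= 0")
        if self.target_dsc is not None and not 0 < self.target_dsc <= 1:
            raise ValueError("target DSC must be in (0, 1]")
        if not 0 <= self.crop_probability <= 1:
            raise ValueError("crop probability must be in [0, 1]")


def default_roster(site: str) -> dict:
    """Organ primitives per site, in mm (LPS; +y posterior, +z superior).

    The prostate-like phantom places a bladder superior-anterior of the
    target, a rectum tube posterior, femoral-head cylinders lateral and
    an anal-canal tube inferior. The head-and-neck-like roster is a
    reduced set spanning the large / small / paired structure regimes.
    """
    if site == "prostate":
        return {
            "CTV": {"kind": "ellipsoid", "center": (78, 80, 52), "radii": (20, 17, 15)},
            "Bladder": {"kind": "ellipsoid", "center": (78, 66, 82), "radii": (26, 22, 18)},
            "Rectum": {"kind": "tube", "center": (78, 107), "radii": (11, 9), "z": (30, 75)},
            "Anal Canal": {"kind": "tube", "center": (78, 86), "radii": (8, 8), "z": (10, 28)},
            "Left Femur": {"kind": "cylinder", "center": (126, 80), "radii": (13, 13), "z": (20, 70)},
            "Right Femur": {"kind": "cylinder", "center": (30, 80), "radii": (13, 13), "z": (20, 70)},
        }
    if site == "head-and-neck":
        return {
            "CTV": {"kind": "tube", "center": (63, 70), "radii": (14, 12), "z": (20, 60)},
            "Brain": {"kind": "ellipsoid", "center": (63, 60, 86), "radii": (40, 38, 15)},
            "Brainstem": {"kind": "tube", "center": (63, 88), "radii": (8, 7), "z": (58, 84)},
            "Spinal Cord": {"kind": "tube", "center": (63, 92), "radii": (5, 5), "z": (4, 58)},
            "Left Parotid": {"kind": "ellipsoid", "center": (101, 66, 52), "radii": (10, 12, 14)},
            "Right Parotid": {"kind": "ellipsoid", "center": (25, 66, 52), "radii": (10, 12, 14)},
            "Left Cochlea": {"kind": "ellipsoid", "center": (95, 70, 70), "radii": (3.2, 3.2, 3.2)},
            "Right Cochlea": {"kind": "ellipsoid", "center": (31, 70, 70), "radii": (3.2, 3.2, 3.2)},
            "Oral Cavity": {"kind": "ellipsoid", "center": (63, 36, 44), "radii": (20, 14, 12)},
        }
    raise ValueError(f"unknown site {site!r}; expected one of {SITES}")


def phantom_spec(site: str, seed: int = 0) -> PhantomSpec:
    """Default PhantomSpec for a site."""
    if site == "prostate":
        return PhantomSpec(site=site, spacing=(2.5, 2.5, 2.5), dims=(64, 64, 44),
                           roster=default_roster(site), seed=seed)
    if site == "head-and-neck":
        return PhantomSpec(site=site, spacing=(2.0, 2.0, 2.0), dims=(64, 64, 52),
                           roster=default_roster(site), seed=seed)
    raise ValueError(f"unknown site {site!r}; expected one of {SITES}")


def _primitive_mask(grid: VoxelGrid, prim: dict) -> np.ndarray:
    xs = grid.axis_coords(0)[:, None, None]
    ys = grid.axis_coords(1)[None, :, None]
    zs = grid.axis_coords(2)[None, None, :]
    kind = prim["kind"]
    if kind == "ellipsoid":
        cx, cy, cz = prim["center"]
        rx, ry, rz = prim["radii"]
        return ((xs - cx) / rx) ** 2 + ((ys - cy) / ry) ** 2 + ((zs - cz) / rz) ** 2 <= 1.0
    if kind in ("tube", "cylinder"):
        cx, cy = prim["center"]
        rx, ry = prim["radii"]
        zlo, zhi = prim["z"]
        inplane = ((xs - cx) / rx) ** 2 + ((ys - cy) / ry) ** 2 <= 1.0
        return inplane & (zs >= zlo) & (zs <= zhi)
    raise ValueError(f"unknown primitive kind {kind!r}")


def _check_fits(grid: VoxelGrid, name: str, prim: dict) -> None:
    lo = np.asarray(grid.origin)
    hi = lo + (np.asarray(grid.dims) - 1) * np.asarray(grid.spacing)
    if prim["kind"] == "ellipsoid":
        c = np.asarray(prim["center"], dtype=float)
        r = np.asarray(prim["radii"], dtype=float)
    else:
        c = np.array([*prim["center"], (prim["z"][0] + prim["z"][1]) / 2])
        r = np.array([*prim["radii"], (prim["z"][1] - prim["z"][0]) / 2])
    if (c - r < lo - 1e-9).any() or (c + r > hi + 1e-9).any():
        raise SpecInfeasibleError(f"{name}: primitive extends outside the grid")


def _jittered(prim: dict, jitter_mm: float, rng: np.random.Generator) -> dict:
    p = dict(prim)
    ndim = 3 if prim["kind"] == "ellipsoid" else 2
    shift = rng.normal(0.0, jitter_mm, size=ndim)
    scale = np.exp(rng.normal(0.0, jitter_mm / 30.0, size=ndim))
    p["center"] = tuple(np.asarray(prim["center"], dtype=float) + shift)
    p["radii"] = tuple(np.asarray(prim["radii"], dtype=float) * scale)
    if "z" in prim:
        dz = rng.normal(0.0, jitter_mm, size=2)
        p["z"] = (prim["z"][0] + dz[0], prim["z"][1] + dz[1])
    return p


def make_phantom(spec: PhantomSpec) -> tuple[StructureSet, VoxelGrid]:
    """Build one phantom patient: a manual structure set and its grid.

    Structures are carved in roster order so they never overlap each
    other (the PTV, derived later by margin expansion, may of course
    overlap neighbouring organs). Deterministic per ``spec.seed``.
    """
    grid = spec.grid()
    rng = np.random.default_rng(spec.seed)
    roster = spec.roster or default_roster(spec.site)
    taken = np.zeros(grid.dims, dtype=bool)
    masks: dict[str, StructureMask] = {}
    for name, prim in roster.items():
        p = _jittered(prim, spec.jitter_mm, rng)
        _check_fits(grid, name, p)
        occ = _primitive_mask(grid, p) & ~taken
        if not occ.any():
            raise SpecInfeasibleError(f"{name}: primitive rasterized to an empty mask")
        taken |= occ
        masks[name] = StructureMask(name, grid, occ)
    sset = StructureSet(provenance="manual", structures=masks)
    return sset, grid


def _signed_distance_mm(occ: np.ndarray, spacing) -> np.ndarray:
    """Positive inside, negative outside, in mm.

    Shifted by half a voxel so the zero level sits on the mask boundary
    rather than between voxel layers; without the shift, displacements
    smaller than one voxel pitch could never flip any voxel.
    """
    inside = ndimage.distance_transform_edt(occ, sampling=spacing)
    outside = ndimage.distance_transform_edt(~occ, sampling=spacing)
    half = 0.5 * float(np.mean(spacing))
    return np.where(occ, inside - half, -(outside - half))


def _smooth_field(shape, rng: np.random.Generator, coarse: int = 5) -> np.ndarray:
    """Unit-variance smooth random field (coarse normals upsampled)."""
    coarse_shape = [max(2, min(coarse, s)) for s in shape]
    f = rng.standard_normal(coarse_shape)
    zoom = [s / c for s, c in zip(shape, coarse_shape)]
    field = ndimage.zoom(f, zoom, order=3)
    field = field[: shape[0], : shape[1], : shape[2]]
    field -= field.mean()
    sd = field.std()
    return field / sd if sd > 0 else field


def perturb_structure(
    mask: StructureMask,
    spec: PerturbationSpec,
    rng: np.random.Generator | None = None,
) -> StructureMask:
    """Apply a smooth random boundary displacement to a mask.

    The new surface is the zero level set of
    ``sdt(shifted) + bias + amplitude * field`` where ``field`` is a
    smooth unit-variance random field. With a requested ``target_dsc``
    the amplitude is found by bisection so the achieved Dice
    coefficient lands within ±0.05 of the target.
    """
    if mask.is_empty:
        raise vol.EmptyStructureError(f"{mask.name}: cannot perturb an empty mask")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    grid = mask.grid
    sdt = _signed_distance_mm(mask.occupancy, grid.spacing)
    if any(o != 0 for o in spec.offset_mm):
        shift_vox = [o / s for o, s in zip(spec.offset_mm, grid.spacing)]
        sdt = ndimage.shift(sdt, shift_vox, order=1, mode="nearest")
    field = _smooth_field(grid.dims, rng)

    def build(amp: float) -> np.ndarray:
        return (sdt + spec.bias_mm + amp * field) > 0

    if spec.target_dsc is None:
        occ = build(spec.amplitude_mm)
    else:
        occ = _calibrate_amplitude(mask, build, spec.target_dsc, grid)
    if spec.crop_probability > 0 and rng.random() < spec.crop_probability:
        occ = _crop_superior(occ, rng)
    return StructureMask(mask.name, grid, occ)


def _calibrate_amplitude(mask, build, target, grid) -> np.ndarray:
    def measured(amp):
        occ = build(amp)
        if not occ.any():
            return 0.0, occ
        d = dice(mask, StructureMask(mask.name, grid, occ))
        return d, occ

    d0, occ0 = measured(0.0)
    if d0 < target - 0.05:
        raise CalibrationError(
            f"{mask.name}: DSC without noise is {d0:.3f}, below target {target}"
        )
    hi = 2.0
    d_hi, occ_hi = measured(hi)
    while d_hi > target and hi < 256.0:
        hi *= 2.0
        d_hi, occ_hi = measured(hi)
    if d_hi > target:
        raise CalibrationError(
            f"{mask.name}: cannot push DSC down to {target} (floor {d_hi:.3f})"
        )
    lo, best_occ, best_err = 0.0, occ_hi, abs(d_hi - target)
    for _ in range(40):
        mid = (lo + hi) / 2
        d_mid, occ_mid = measured(mid)
        if abs(d_mid - target) < best_err:
            best_err, best_occ = abs(d_mid - target), occ_mid
        if d_mid > target:
            lo = mid
        else:
            hi = mid
        if best_err < 0.005:
            break
    if best_err > 0.05:
        raise CalibrationError(
            f"{mask.name}: calibration missed target {target} by {best_err:.3f}"
        )
    return best_occ


def _crop_superior(occ: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    zs = np.nonzero(occ.any(axis=(0, 1)))[0]
    if zs.size < 2:
        return occ
    frac = rng.uniform(0.3, 0.6)
    cut = zs[0] + int(np.ceil(zs.size * (1 - frac)))
    out = occ.copy()
    out[:, :, cut:] = False
    return out if out.any() else occ


def make_dose(
    target: StructureMask,
    prescription_cgy: float,
    falloff_mm: float = 6.0,
    noise_frac: float = 0.02,
    shell_mm: float = 3.0,
    rng: np.random.Generator | None = None,
) -> DoseGrid:
    """Conformal dose field around a target volume.

    The dose equals the prescription inside the target and out to
    ``shell_mm`` beyond its surface (emulating the coverage margin a
    real optimizer leaves), then decays as ``exp(−d / falloff)``. A
    smooth low-amplitude modulation inside the target makes the
    homogeneity index > 0. The 95% isodose therefore wraps the target
    snugly and the conformity index is high but below 1.
    """
    if target.is_empty:
        raise vol.EmptyStructureError("dose target is empty")
    if prescription_cgy <= 0 or falloff_mm <= 0:
        raise ValueError("prescription and falloff must be > 0")
    grid = target.grid
    d_out = ndimage.distance_transform_edt(~target.occupancy, sampling=grid.spacing)
    dose = prescription_cgy * np.exp(-np.clip(d_out - shell_mm, 0.0, None) / falloff_mm)
    if noise_frac > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        field = np.clip(_smooth_field(grid.dims, rng), -2.0, 2.0)
        dose = dose * np.where(target.occupancy, 1.0 + noise_frac * field, 1.0)
    return DoseGrid(grid, np.clip(dose, 0.0, None), prescription_cgy)


def make_ideal_plan(site: str = "prostate", seed: int = 0) -> tuple[DoseGrid, StructureSet]:
    """A phantom plan that meets every objective of the site's scorecard:
    a noise-free prescription dose inside the PTV with a very sharp
    falloff, so target objectives sit at their ideal thresholds and all
    organ-at-risk doses are far below their limits.
    """
    sset, grid = make_phantom(phantom_spec(site, seed))
    full = _with_ptv(sset, site)
    dose = make_dose(full["PTV"], PRESCRIPTION_CGY[site], falloff_mm=1.0,
                     noise_frac=0.0, shell_mm=0.0)
    return dose, full


def _with_ptv(sset: StructureSet, site: str) -> StructureSet:
    """Derive the PTV from the CTV by margin expansion and add it."""
    ctv = sset["CTV"]
    ptv = expand_margin(ctv, PTV_MARGINS_MM)
    ptv.name = "PTV"
    masks = dict(sset.structures)
    masks["PTV"] = ptv
    return StructureSet(provenance=sset.provenance, structures=masks,
                        observer=sset.observer)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class PatientRecord:
    """One synthetic patient: structure sets per arm, doses, timing,
    and the reviewer's rating of the AI contours."""

    pid: str
    sets: dict[str, StructureSet]      # manual | ai | adj1 | adj2
    doses: dict[str, DoseGrid]         # manual | adj1 | adj2
    timing_min: dict[str, float]       # manual | adj1 | adj2
    likert: str


@dataclass
class Cohort:
    site: str
    seed: int
    patients: list[PatientRecord]


#: Default disagreement levels: the AI-vs-manual perturbation is much
#: larger than the physician-adjustment perturbation, which yields the
#: study's characteristic ordering DSC(ai, adj) > DSC(manual, adj).
AI_AMPLITUDE_MM = 2.5
ADJUST_AMPLITUDE_MM = 0.7

#: Manual contouring time (mean, sd) in minutes, and the adjusted-arm
#: time as a fraction of the same patient's manual time (mean, sd) —
#: drawing the fraction keeps the time saving positive for every
#: patient, as observed in the study workflow.
TIMING_MIN = {
    "prostate": {"manual": (23.0, 4.0), "adjusted_frac": (0.279, 0.05)},
    "head-and-neck": {"manual": (150.0, 20.0), "adjusted_frac": (0.157, 0.04)},
}


def make_cohort(n: int, site: str = "prostate", seed: int = 0) -> Cohort:
    """Generate a full n-patient fixture for one site.

    Per patient: a manual phantom set; an AI set perturbed from it; two
    observer-adjusted sets perturbed (slightly) from the AI set; a
    conformal dose per planning arm built on that arm's PTV; contouring
    times with the adjusted workflow far faster than manual; and a
    four-level review rating. For the head-and-neck site the clinical
    target is not AI-contoured, so every arm carries the manual CTV.
    All randomness derives from ``seed`` via spawned per-patient
    streams.
    """
    if n < 1:
        raise ValueError("cohort needs at least one patient")
    if site not in SITES:
        raise ValueError(f"unknown site {site!r}; expected one of {SITES}")
    root = np.random.SeedSequence(seed)
    patients = []
    for i, ss in enumerate(root.spawn(n)):
        rng = np.random.default_rng(ss)
        pspec = phantom_spec(site, seed=int(rng.integers(2**31)))
        manual, grid = make_phantom(pspec)

        ai_masks, adj1_masks, adj2_masks = {}, {}, {}
        for name, mask in manual.structures.items():
            if site == "head-and-neck" and name == "CTV":
                # target is drawn by hand in every arm
                for d in (ai_masks, adj1_masks, adj2_masks):
                    d[name] = StructureMask(name, grid, mask.occupancy.copy())
                continue
            ai_spec = PerturbationSpec(
                amplitude_mm=AI_AMPLITUDE_MM,
                offset_mm=tuple(rng.normal(0.0, 0.6, size=3)),
                seed=int(rng.integers(2**31)),
            )
            ai_masks[name] = perturb_structure(mask, ai_spec)
            for d in (adj1_masks, adj2_masks):
                adj_spec = PerturbationSpec(
                    amplitude_mm=ADJUST_AMPLITUDE_MM,
                    seed=int(rng.integers(2**31)),
                )
                d[name] = perturb_structure(ai_masks[name], adj_spec)

        sets = {
            "manual": _with_ptv(manual, site),
            "ai": _with_ptv(StructureSet("ai", ai_masks), site),
            "adj1": _with_ptv(StructureSet("ai_adjusted", adj1_masks, observer="1"), site),
            "adj2": _with_ptv(StructureSet("ai_adjusted", adj2_masks, observer="2"), site),
        }
        rx = PRESCRIPTION_CGY[site]
        doses = {
            arm: make_dose(sets[arm]["PTV"], rx,
                           rng=np.random.default_rng(int(rng.integers(2**31))))
            for arm in ("manual", "adj1", "adj2")
        }
        t_man = _draw_minutes(rng, TIMING_MIN[site]["manual"])
        f_mean, f_sd = TIMING_MIN[site]["adjusted_frac"]
        timing = {
            "manual": t_man,
            "adj1": t_man * float(np.clip(rng.normal(f_mean, f_sd), 0.05, 0.9)),
            "adj2": t_man * float(np.clip(rng.normal(f_mean, f_sd), 0.05, 0.9)),
        }
        likert = str(rng.choice(LIKERT_LEVELS, p=LIKERT_DISTRIBUTION))
        patients.append(PatientRecord(
            pid=f"{site[:2]}{i + 1:03d}", sets=sets, doses=doses,
            timing_min=timing, likert=likert,
        ))
    return Cohort(site=site, seed=seed, patients=patients)


def _draw_minutes(rng: np.random.Generator, mean_sd: tuple[float, float]) -> float:
    mean, sd = mean_sd
    return float(np.clip(rng.normal(mean, sd), mean / 4, None))
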