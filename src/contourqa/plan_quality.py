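"""Scorecard-driven plan-quality metric (PQM / nPQM).

A scorecard is a declarative list of dose-volume objectives, each
awarding points through one of two scoring functions:

* **threshold** — full points if the objective is met, 0 otherwise;
* **linear** — two (value, score) thresholds, the *ideal* one carrying
  the peak score and the *minimally acceptable* one a lower score, with
  linear interpolation between them. Under the default ``"table"``
  convention a plan sitting exactly at the acceptable threshold earns
  that threshold's printed score; under the stricter ``"prose"``
  convention the acceptable threshold is worth 0. Beyond the
  acceptable threshold (on the failing side) the award is always 0, and
  at or beyond the ideal threshold it is the peak score. The active
  convention is recorded in every result.

The total PQM is the sum of awarded points and
``nPQM = 100 * PQM / PQM_max``, where PQM_max is the peak score
achievable — each objective counted once at its maximum. Fractional
points are kept (rounding would distort the ratio).

Statistic keywords: ``Dmean``, ``Dmedian``, ``Dmin``, ``Dmax``,
``D<x>%``, ``D<v>cc``, ``V<d>cGy%``, ``V<d>cGycc``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from . import dose_metrics as dm
from .volumes import StructureMask, StructureSet, standardize_name

__all__ = [
    "Objective",
    "Scorecard",
    "PQMResult",
    "ScorecardError",
    "parse_statistic",
    "evaluate_statistic",
    "load_scorecard",
    "bundled_scorecard",
    "load_constraints",
    "bundled_constraints",
    "score_objective",
    "evaluate_pqm",
    "check_constraints",
]

_BUNDLED_CARDS = {"prostate": "prostate_pqm.yaml", "head-and-neck": "hn_pqm.yaml"}
_BUNDLED_CONSTRAINTS = {
    "prostate": "prostate_constraints.yaml",
    "head-and-neck": "hn_constraints.yaml",
}


class ScorecardError(ValueError):
    """Malformed scorecard or constraint configuration."""


_STAT_RE = re.compile(
    r"^(?:"
    r"(?P<named>Dmean|Dmedian|Dmin|Dmax)"
    r"|D(?P<dpct>[0-9.]+)%"
    r"|D(?P<dcc>[0-9.]+)cc"
    r"|V(?P<vdose>[0-9.]+)cGy(?P<vunit>%|cc)"
    r")$"
)


def parse_statistic(stat: str) -> tuple[str, float | None]:
    """Parse a statistic keyword into (kind, argument).

    Kinds: ``mean``, ``median``, ``min``, ``max``, ``d_pct`` (x%),
    ``d_cc`` (v cc), ``v_pct`` / ``v_cc`` (dose in cGy).
    """
    m = _STAT_RE.match(stat.replace(" ", ""))
    if not m:
        raise ScorecardError(f"unknown statistic keyword {stat!r}")
    if m["named"]:
        return m["named"][1:].lower(), None  # mean/median/min/max
    if m["dpct"]:
        return "d_pct", float(m["dpct"])
    if m["dcc"]:
        return "d_cc", float(m["dcc"])
    return ("v_pct" if m["vunit"] == "%" else "v_cc"), float(m["vdose"])


def evaluate_statistic(
    stat: str,
    dose: dm.DoseGrid,
    mask: StructureMask,
    bin_width: float = dm.DEFAULT_BIN_WIDTH_CGY,
) -> float:
    """Extract a dose-volume statistic for one structure.

    ``D<v>cc`` uses descending-sorted voxel doses (near-maximum
    convention); ``Dmax`` is the plain maximum voxel dose.
    """
    kind, arg = parse_statistic(stat)
    doses = dose.dose[mask.occupancy]
    if kind == "mean":
        return float(doses.mean())
    if kind == "median":
        return float(np.median(doses))
    if kind == "min":
        return float(doses.min())
    if kind == "max":
        return float(doses.max())
    if kind == "d_cc":
        total = mask.volume_cc
        return dm.dose_at_cc_sorted(dose, mask, min(arg, total))
    dvh = dm.compute_dvh(dose, mask, bin_width)
    if kind == "d_pct":
        return dm.dose_at_volume_percent(dvh, arg)
    if kind == "v_pct":
        return dm.volume_at_dose(dvh, arg, as_percent=True)
    return dm.volume_at_dose(dvh, arg, as_percent=False)


@dataclass
class Objective:
    """One scorecard row: a dose-volume objective with a scoring rule."""

    structure: str
    statistic: str
    direction: str  # "at-least" | "at-most"
    function: str  # "threshold" | "linear"
    thresholds: list[tuple[float, float]]  # (value, score) pairs

    def __post_init__(self):
        parse_statistic(self.statistic)  # validate keyword
        if self.direction not in ("at-least", "at-most"):
            raise ScorecardError(
                f"{self.structure}/{self.statistic}: bad direction {self.direction!r}"
            )
        if self.function not in ("threshold", "linear"):
            raise ScorecardError(
                f"{self.structure}/{self.statistic}: bad function {self.function!r}"
            )
        n = {"threshold": 1, "linear": 2}[self.function]
        if len(self.thresholds) != n:
            raise ScorecardError(
                f"{self.structure}/{self.statistic}: {self.function} scoring needs "
                f"{n} threshold(s), got {len(self.thresholds)}"
            )
        self.thresholds = [(float(v), float(s)) for v, s in self.thresholds]
        if any(s < 0 for _, s in self.thresholds):
            raise ScorecardError(f"{self.structure}/{self.statistic}: scores must be >= 0")
        if self.function == "linear":
            (v1, s1), (v2, s2) = self.thresholds
            if v1 == v2 or s1 == s2:
                raise ScorecardError(
                    f"{self.structure}/{self.statistic}: linear thresholds must be distinct"
                )
        if self.max_score <= 0:
            raise ScorecardError(f"{self.structure}/{self.statistic}: nonpositive max score")

    @property
    def max_score(self) -> float:
        return max(s for _, s in self.thresholds)

    @property
    def ideal(self) -> tuple[float, float]:
        """(value, score) of the threshold carrying the peak score."""
        return max(self.thresholds, key=lambda t: t[1])

    @property
    def acceptable(self) -> tuple[float, float]:
        """(value, score) of the minimally acceptable threshold."""
        return min(self.thresholds, key=lambda t: t[1])

    def _met(self, achieved: float, value: float) -> bool:
        return achieved >= value if self.direction == "at-least" else achieved <= value


@dataclass
class Scorecard:
    """An ordered list of objectives for one treatment site."""

    site: str
    objectives: list[Objective]
    prescription_cgy: float | None = None

    @property
    def pqm_max(self) -> float:
        return sum(o.max_score for o in self.objectives)

    def to_config(self) -> dict:
        return {
            "site": self.site,
            "prescription_cgy": self.prescription_cgy,
            "objectives": [
                {
                    "structure": o.structure,
                    "statistic": o.statistic,
                    "direction": o.direction,
                    "function": o.function,
                    "thresholds": [{"value": v, "score": s} for v, s in o.thresholds],
                }
                for o in self.objectives
            ],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_config(), fh, sort_keys=False)


@dataclass
class PQMResult:
    """Achieved statistics and awarded points for one plan."""

    site: str
    rows: list[dict]
    pqm: float
    pqm_max: float
    convention: str

    @property
    def npqm(self) -> float:
        return 100.0 * self.pqm / self.pqm_max

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def load_scorecard(config) -> Scorecard:
    """Build a Scorecard from a parsed config dict or a YAML path."""
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    objectives = []
    for i, row in enumerate(config.get("objectives", [])):
        try:
            thresholds = [(t["value"], t["score"]) for t in row["thresholds"]]
            objectives.append(
                Objective(
                    structure=row["structure"],
                    statistic=row["statistic"],
                    direction=row["direction"],
                    function=row["function"],
                    thresholds=thresholds,
                )
            )
        except (KeyError, TypeError) as exc:
            raise ScorecardError(f"objective row {i}: missing field {exc}") from exc
    if not objectives:
        raise ScorecardError("scorecard has no objectives")
    return Scorecard(
        site=config.get("site", ""),
        objectives=objectives,
        prescription_cgy=config.get("prescription_cgy"),
    )


def bundled_scorecard(site: str) -> Scorecard:
    """One of the two shipped scorecards: 'prostate' or 'head-and-neck'."""
    try:
        fname = _BUNDLED_CARDS[site]
    except KeyError:
        raise ScorecardError(f"no bundled scorecard for site {site!r}") from None
    text = resources.files("contourqa.data").joinpath(fname).read_text()
    return load_scorecard(yaml.safe_load(text))


def score_objective(obj: Objective, achieved: float, convention: str = "table") -> float:
    """Points awarded for one objective given the achieved statistic.

    ``convention`` selects the score at the minimally acceptable
    threshold of linear objectives: its printed score ("table",
    default) or zero ("prose"). Output is clamped to [0, max score].
    """
    if not np.isfinite(achieved):
        raise ValueError(f"{obj.structure}/{obj.statistic}: achieved value not finite")
    if convention not in ("table", "prose"):
        raise ValueError(f"unknown linear-scoring convention {convention!r}")
    if obj.function == "threshold":
        value, score = obj.thresholds[0]
        return score if obj._met(achieved, value) else 0.0
    v_ideal, s_ideal = obj.ideal
    v_acc, s_acc = obj.acceptable
    if convention == "prose":
        s_acc = 0.0
    if obj._met(achieved, v_ideal):
        return s_ideal
    if not obj._met(achieved, v_acc):
        return 0.0
    frac = (achieved - v_acc) / (v_ideal - v_acc)
    return float(np.clip(s_acc + frac * (s_ideal - s_acc), 0.0, obj.max_score))


def evaluate_pqm(
    card: Scorecard,
    dose: dm.DoseGrid,
    structures: StructureSet,
    convention: str = "table",
    bin_width: float = dm.DEFAULT_BIN_WIDTH_CGY,
) -> PQMResult:
    """Score a plan against a scorecard.

    The dose is resampled to the structure grid if needed. Objectives
    whose structure is missing or empty contribute 0 points and are
    flagged; the evaluation continues.
    """
    grid = structures.grid
    if grid is None:
        raise ValueError("structure set is empty")
    if dose.grid != grid:
        dose = dm.resample_dose(dose, grid)
    rows = []
    total = 0.0
    for obj in card.objectives:
        key = standardize_name(obj.structure)
        row = {
            "structure": key,
            "statistic": obj.statistic,
            "max_score": obj.max_score,
            "achieved": np.nan,
            "awarded": 0.0,
            "flag": "",
        }
        if key not in structures.structures:
            row["flag"] = "missing-structure"
        elif structures.structures[key].is_empty:
            row["flag"] = "empty-structure"
        else:
            achieved = evaluate_statistic(obj.statistic, dose, structures.structures[key], bin_width)
            row["achieved"] = achieved
            row["awarded"] = score_objective(obj, achieved, convention)
        total += row["awarded"]
        rows.append(row)
    return PQMResult(card.site, rows, pqm=total, pqm_max=card.pqm_max, convention=convention)


# ---------------------------------------------------------------------------
# Planning constraint sets (descriptive pass/fail, no points)
# ---------------------------------------------------------------------------

@dataclass
class ConstraintSet:
    site: str
    constraints: list[dict] = field(default_factory=list)
    prescription_cgy: float | None = None


def load_constraints(config) -> ConstraintSet:
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    rows = []
    for i, c in enumerate(config.get("constraints", [])):
        try:
            parse_statistic(c["statistic"])
            if c["comparator"] not in ("<", ">"):
                raise ScorecardError(f"constraint row {i}: comparator must be < or >")
            rows.append(
                {
                    "structure": c["structure"],
                    "statistic": c["statistic"],
                    "comparator": c["comparator"],
                    "limit": float(c["limit"]),
                }
            )
        except KeyError as exc:
            raise ScorecardError(f"constraint row {i}: missing field {exc}") from exc
    return ConstraintSet(
        site=config.get("site", ""),
        constraints=rows,
        prescription_cgy=config.get("prescription_cgy"),
    )


def bundled_constraints(site: str) -> ConstraintSet:
    try:
        fname = _BUNDLED_CONSTRAINTS[site]
    except KeyError:
        raise ScorecardError(f"no bundled constraint set for site {site!r}") from None
    text = resources.files("contourqa.data").joinpath(fname).read_text()
    return load_constraints(yaml.safe_load(text))


def check_constraints(
    cset: ConstraintSet,
    dose: dm.DoseGrid,
    structures: StructureSet,
    bin_width: float = dm.DEFAULT_BIN_WIDTH_CGY,
) -> pd.DataFrame:
    """Evaluate each planning constraint; returns achieved value and
    pass/fail per row. Missing structures are flagged, not scored.
    """
    grid = structures.grid
    if grid is None:
        raise ValueError("structure set is empty")
    if dose.grid != grid:
        dose = dm.resample_dose(dose, grid)
    rows = []
    for c in cset.constraints:
        key = standardize_name(c["structure"])
        row = dict(c, structure=key, achieved=np.nan, passed=pd.NA, flag="")
        if key not in structures.structures or structures.structures[key].is_empty:
            row["flag"] = "missing-structure"
        else:
            achieved = evaluate_statistic(c["statistic"], dose, structures.structures[key], bin_width)
            row["achieved"] = achieved
            row["passed"] = achieved < c["limit"] if c["comparator"] == "<" else achieved > c["limit"]
        rows.append(row)
    return pd.DataFrame(rows)
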