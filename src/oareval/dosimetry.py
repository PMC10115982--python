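"""DVH engine, PTV construction, evaluation-region rule and plan quality.

Implements the dosimetric side of the evaluation: a planning target volume
is the clinical target volume plus a uniform Euclidean margin cropped to the
body surface; the dose to an organ-at-risk is assessed on the part of the
OAR not overlapping any PTV (contours leaving < 0.1 cc outside the targets
are excluded); Dmean and D0.03cc come from an exact voxel-sample DVH with no
histogram binning; and a configurable DVH-objective scoring template yields
the normalized plan quality metric

    NPQM = 100 x achieved points / maximum attainable points,

where the maximum counts only objectives whose structures are present and
not excluded, so cases with different structure rosters remain comparable.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import (
    EmptyTemplateError,
    GridMismatchError,
    InvalidParameterError,
    InvalidQueryError,
    UndefinedDVHError,
)
from .grid import (
    MM3_PER_CC,
    BinaryMask,
    StructureSet,
    VoxelGrid,
    mask_boolean,
    mask_volume_cc,
)
from .rosters import DEFAULT_LIMITS_GY, OAR_ROSTER_42

logger = logging.getLogger(__name__)

#: An OAR whose volume outside the targets falls below this is excluded from
#: dosimetric analysis.
MIN_EVAL_VOLUME_CC = 0.1


@dataclass
class DoseGrid:
    """Scalar absorbed-dose field (Gy) on a voxel grid."""

    grid: VoxelGrid
    dose: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.dose, dtype=float)
        if d.shape != tuple(self.grid.shape):
            raise GridMismatchError(
                f"dose shape {d.shape} != grid shape {self.grid.shape}"
            )
        if not np.isfinite(d).all():
            raise InvalidParameterError("dose must be finite everywhere")
        if (d < 0).any():
            raise InvalidParameterError("dose must be non-negative")
        self.dose = d

    def sample_at(self, grid: VoxelGrid) -> np.ndarray:
        """Trilinear interpolation of dose at another grid's voxel centers.

        Dose is a smooth field, so linear interpolation (rather than nearest
        neighbour) avoids aliasing the DVH tails.  Points outside the dose
        grid extent evaluate to 0 Gy.
        """
        if grid == self.grid:
            return self.dose
        coords = [
            (grid.axis_centers(a) - self.grid.origin[a]) / self.grid.spacing[a]
            for a in range(3)
        ]
        ci, cj, ck = np.meshgrid(*coords, indexing="ij")
        pts = np.stack([ci.ravel(), cj.ravel(), ck.ravel()])
        out = ndimage.map_coordinates(self.dose, pts, order=1, mode="constant", cval=0.0)
        return out.reshape(grid.shape)


@dataclass
class DVHCurve:
    """Exact cumulative dose-volume histogram of one region.

    Every foreground voxel contributes its voxel volume at its dose; the
    cumulative curve V(>= d) is evaluated on the sorted voxel-dose profile
    with no binning loss.
    """

    structure: str
    doses_desc: np.ndarray  # per-voxel doses, sorted descending, Gy
    voxel_volume_cc: float

    def __post_init__(self) -> None:
        d = np.sort(np.asarray(self.doses_desc, dtype=float))[::-1]
        if d.size == 0:
            raise UndefinedDVHError("DVH of an empty region is undefined")
        self.doses_desc = d

    @property
    def total_volume_cc(self) -> float:
        return self.doses_desc.size * self.voxel_volume_cc

    def volume_at_or_above(self, dose_gy: float) -> float:
        """V(>= d): volume (cc) receiving at least ``dose_gy``."""
        return float((self.doses_desc >= dose_gy).sum()) * self.voxel_volume_cc

    def dmean(self) -> float:
        """Volume-weighted mean dose (voxels are equal-volume samples)."""
        return float(self.doses_desc.mean())

    def dose_to_hottest(self, volume_cc: float) -> float:
        """D_xcc: minimum dose received by the hottest ``volume_cc`` cc.

        Linearly interpolated on the sorted voxel-dose profile against
        cumulative volume; for volumes within the single hottest voxel the
        hottest dose is returned.
        """
        if volume_cc <= 0:
            raise InvalidQueryError("Dxcc requires x > 0")
        if volume_cc > self.total_volume_cc + 1e-12:
            raise InvalidQueryError(
                f"Dxcc with x={volume_cc} cc exceeds region volume "
                f"{self.total_volume_cc} cc"
            )
        cumvol = (np.arange(self.doses_desc.size) + 1) * self.voxel_volume_cc
        return float(
            np.interp(volume_cc, cumvol, self.doses_desc, left=self.doses_desc[0])
        )


def cumulative_dvh(region: BinaryMask, dose: DoseGrid, structure: str = "") -> DVHCurve:
    """Exact voxel-sample DVH of a region (dose interpolated to region grid)."""
    if region.is_empty():
        raise UndefinedDVHError("DVH of an empty region is undefined")
    dose_on_grid = dose.sample_at(region.grid)
    values = dose_on_grid[region.occupancy]
    return DVHCurve(structure, values, region.grid.voxel_volume_mm3 / MM3_PER_CC)


_DCC_RE = re.compile(r"^D(?P<x>\d*\.?\d+)cc$", re.IGNORECASE)
_VGY_RE = re.compile(r"^V(?P<x>\d*\.?\d+)Gy$", re.IGNORECASE)


def dose_stat(curve: DVHCurve, statistic: str) -> float:
    """Evaluate a named DVH statistic on a curve.

    Supported: ``"Dmean"`` (Gy), ``"D<x>cc"`` e.g. ``"D0.03cc"`` (Gy),
    ``"V<x>Gy"`` (cc).
    """
    if statistic == "Dmean":
        return curve.dmean()
    m = _DCC_RE.match(statistic)
    if m:
        return curve.dose_to_hottest(float(m.group("x")))
    m = _VGY_RE.match(statistic)
    if m:
        return curve.volume_at_or_above(float(m.group("x")))
    raise InvalidQueryError(f"unknown DVH statistic {statistic!r}")


# ---------------------------------------------------------------------------
# PTV construction and the evaluation-region rule


def expand_ptv(ctv: BinaryMask, margin_mm: float, body: BinaryMask) -> BinaryMask:
    """Uniform Euclidean expansion of a CTV, cropped to the body surface.

    A voxel belongs to the expansion iff its center lies within ``margin_mm``
    of some CTV foreground voxel center (exact anisotropic Euclidean
    distance transform); the result is intersected with the body mask.
    """
    if margin_mm < 0:
        raise InvalidParameterError("PTV margin must be >= 0")
    if ctv.grid != body.grid:
        raise GridMismatchError("CTV and body must share a grid")
    if margin_mm == 0 or ctv.is_empty():
        return mask_boolean(ctv, body, "intersect")
    dist = ndimage.distance_transform_edt(~ctv.occupancy, sampling=ctv.grid.spacing)
    expanded = BinaryMask(ctv.grid, dist <= margin_mm)
    return mask_boolean(expanded, body, "intersect")


@dataclass
class EvalRegion:
    """Outcome of the OAR evaluation-region rule.

    ``mask`` is the OAR minus the union of PTVs, or ``None`` with
    ``excluded=True`` when the remaining volume is below 0.1 cc.
    """

    structure: str
    mask: Optional[BinaryMask]
    volume_cc: float

    @property
    def excluded(self) -> bool:
        return self.mask is None


def oar_eval_region(
    oar: BinaryMask, ptvs: Sequence[BinaryMask], structure: str = ""
) -> EvalRegion:
    """OAR minus all PTVs; excluded when less than 0.1 cc remains."""
    region = oar
    for ptv in ptvs:
        region = mask_boolean(region, ptv, "subtract")
    vol = mask_volume_cc(region)
    if vol < MIN_EVAL_VOLUME_CC:
        return EvalRegion(structure, None, vol)
    return EvalRegion(structure, region, vol)


# ---------------------------------------------------------------------------
# plan quality metric


@dataclass(frozen=True)
class PQMObjective:
    """One DVH-objective scoring rule.

    Full credit (``points``) when the statistic satisfies ``direction``
    against ``threshold``; zero credit at/beyond ``zero_threshold`` (which
    must lie on the failing side); linear partial credit between the two
    when ``zero_threshold`` is set, binary scoring otherwise.
    ``use_eval_region`` applies the OAR minus-PTV / 0.1 cc rule before
    evaluating (disable for target-volume objectives).
    """

    structure: str
    statistic: str
    direction: str  # "<=" or ">="
    threshold: float
    points: float
    zero_threshold: Optional[float] = None
    use_eval_region: bool = True

    def __post_init__(self) -> None:
        if self.direction not in ("<=", ">="):
            raise InvalidParameterError("direction must be '<=' or '>='")
        if self.points <= 0:
            raise InvalidParameterError("objective point value must be > 0")
        if self.zero_threshold is not None:
            bad = (
                self.zero_threshold <= self.threshold
                if self.direction == "<="
                else self.zero_threshold >= self.threshold
            )
            if bad:
                raise InvalidParameterError(
                    "zero-credit threshold must lie on the failing side of the "
                    "full-credit threshold"
                )

    def score(self, value: float) -> float:
        """Achieved points for a measured statistic value."""
        sign = 1.0 if self.direction == "<=" else -1.0
        v, full = sign * value, sign * self.threshold
        if v <= full:
            return self.points
        if self.zero_threshold is None:
            return 0.0
        zero = sign * self.zero_threshold
        if v >= zero:
            return 0.0
        return self.points * (zero - v) / (zero - full)


@dataclass
class PQMTemplate:
    """A named list of DVH-objective scoring rules."""

    objectives: List[PQMObjective]
    template_id: str = "custom"

    def __post_init__(self) -> None:
        if not self.objectives:
            raise EmptyTemplateError("a PQM template needs at least one objective")


def default_hn_template() -> PQMTemplate:
    """Illustrative head-and-neck template over the 42-OAR roster.

    Serial organs are scored on D0.03cc, parallel organs on Dmean, one point
    each, with a 10 Gy linear partial-credit ramp.  The limits are
    illustrative defaults, not institutional guidance: clinical use requires
    a configured template.
    """
    objectives = []
    for name, organ_class in OAR_ROSTER_42.items():
        stat = "D0.03cc" if organ_class == "serial" else "Dmean"
        limit = DEFAULT_LIMITS_GY[organ_class]
        objectives.append(
            PQMObjective(
                structure=name,
                statistic=stat,
                direction="<=",
                threshold=limit,
                points=1.0,
                zero_threshold=limit + 10.0,
            )
        )
    return PQMTemplate(objectives, template_id="hn-default-illustrative")


@dataclass
class ObjectiveScore:
    structure: str
    statistic: str
    value: Optional[float]
    achieved: float
    maximum: float
    status: str  # "scored" | "absent" | "excluded"


def score_objectives(
    structset: StructureSet,
    dose: DoseGrid,
    template: PQMTemplate,
    ptvs: Sequence[BinaryMask] = (),
) -> List[ObjectiveScore]:
    """Per-objective achieved/maximum points for one structure set and dose.

    Objectives whose structure is absent (or empty), or excluded by the
    evaluation-region rule, contribute to neither achieved nor maximum.
    """
    scores: List[ObjectiveScore] = []
    for obj in template.objectives:
        if not structset.is_present(obj.structure):
            scores.append(
                ObjectiveScore(obj.structure, obj.statistic, None, 0.0, 0.0, "absent")
            )
            continue
        mask = structset.get(obj.structure)
        if obj.use_eval_region:
            region = oar_eval_region(mask, ptvs, obj.structure)
            if region.excluded:
                scores.append(
                    ObjectiveScore(
                        obj.structure, obj.statistic, None, 0.0, 0.0, "excluded"
                    )
                )
                continue
            mask = region.mask
        curve = cumulative_dvh(mask, dose, obj.structure)
        value = dose_stat(curve, obj.statistic)
        scores.append(
            ObjectiveScore(
                obj.structure, obj.statistic, value, obj.score(value), obj.points,
                "scored",
            )
        )
    return scores


def pqm_score(
    structset: StructureSet,
    dose: DoseGrid,
    template: PQMTemplate,
    ptvs: Sequence[BinaryMask] = (),
) -> Tuple[float, float]:
    """(achieved points, maximum attainable points) for one set and dose."""
    scores = score_objectives(structset, dose, template, ptvs)
    achieved = sum(s.achieved for s in scores if s.status == "scored")
    maximum = sum(s.maximum for s in scores if s.status == "scored")
    if maximum == 0:
        raise EmptyTemplateError(
            "no template objective resolves to a present, non-excluded structure"
        )
    return achieved, maximum


def npqm(
    structset: StructureSet,
    dose: DoseGrid,
    template: PQMTemplate,
    ptvs: Sequence[BinaryMask] = (),
) -> float:
    """Normalized plan quality metric: 100 x achieved / maximum, in [0, 100]."""
    achieved, maximum = pqm_score(structset, dose, template, ptvs)
    return 100.0 * achieved / maximum


# ---------------------------------------------------------------------------
# per-arm dosimetric deltas


def dosimetric_deltas(
    arm: StructureSet,
    gs: StructureSet,
    dose: DoseGrid,
    ptvs: Sequence[BinaryMask] = (),
    template: Optional[PQMTemplate] = None,
) -> Tuple[pd.DataFrame, Optional[float]]:
    """|ΔDmean| and |ΔD0.03cc| per structure, and the case |ΔNPQM|.

    Both structure sets are evaluated on one shared (reference-plan) dose
    grid.  Structures absent, empty, or excluded by the 0.1 cc rule in
    either set are skipped and logged.  Returns a long-format DataFrame
    (case, structure, arm, metric, value) and |ΔNPQM| in percentage points
    (``None`` when no template is given).
    """
    rows: List[Dict[str, object]] = []
    for name in gs.names():
        if not (gs.is_present(name) and arm.is_present(name)):
            logger.info("structure %s absent in one set; no dose delta", name)
            continue
        reg_gs = oar_eval_region(gs.get(name), ptvs, name)
        reg_arm = oar_eval_region(arm.get(name), ptvs, name)
        if reg_gs.excluded or reg_arm.excluded:
            logger.info(
                "structure %s excluded by the 0.1 cc rule (gs=%s, arm=%s)",
                name, reg_gs.excluded, reg_arm.excluded,
            )
            continue
        curve_gs = cumulative_dvh(reg_gs.mask, dose, name)
        curve_arm = cumulative_dvh(reg_arm.mask, dose, name)
        for metric, stat in (("abs_dDmean_Gy", "Dmean"), ("abs_dD0.03cc_Gy", "D0.03cc")):
            delta = abs(dose_stat(curve_arm, stat) - dose_stat(curve_gs, stat))
            rows.append(
                {
                    "case": gs.case_id,
                    "structure": name,
                    "arm": arm.arm,
                    "metric": metric,
                    "value": delta,
                }
            )
    df = pd.DataFrame(rows, columns=["case", "structure", "arm", "metric", "value"])
    dnpqm: Optional[float] = None
    if template is not None:
        dnpqm = abs(
            npqm(arm, dose, template, ptvs) - npqm(gs, dose, template, ptvs)
        )
    return df, dnpqm
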