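"""Plant-parasitoid trait matching for nectar availability and accessibility.

The mechanistic core of the package: a geometric decision tree deciding, for a
plant species x parasitoid pair, whether floral (or extrafloral) nectar can be
reached by the insect, and the aggregation of verdicts to the percent plant
cover providing available and accessible nectar in a community.

Geometry convention (all lengths in mm):

* the insect head, of radius ``r = head_width / 2``, can enter the flower iff
  the flower opening is at least as wide as the head, ``w >= 2 r``;
* corolla height ``h`` and nectar depth ``p`` are disjoint segments measured
  along the flower axis, so the total depth from the opening to the nectar is
  ``h + p``; an insect whose head enters the corolla "spends" ``h`` and only
  needs its proboscis (length ``x``) to span the nectar holder, ``x >= p``;
  an excluded insect must span both, ``x >= h + p``;
* where nectar sits in a narrow tube of diameter ``d``, the proboscis must
  also fit into the tube, ``z <= d``; open nectaries (``tube_diameter=None``)
  skip this check;
* extrafloral nectar, produced on bracts or stipules outside the perianth, is
  accessible to every insect.

Missing flower morphology never raises: the species is conservatively scored
inaccessible with a ``fail_missing_trait`` verdict and a warning, so that
community aggregation degrades gracefully.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "NectarType",
    "InsectMorphology",
    "FlowerMorphology",
    "Reason",
    "AccessibilityVerdict",
    "nectar_accessible",
    "nectar_available",
    "accessible_cover",
    "accessible_species",
    "trait_coverage_report",
    "verdict_matrix",
    "FLOWERING_STAGES",
]

#: Stages of the 11-point (0-10) phenological scale that count as "in flower"
#: when availability is judged from a survey snapshot.
FLOWERING_STAGES: tuple[int, int] = (5, 8)


class NectarType(str, Enum):
    FLORAL = "floral"
    EXTRAFLORAL = "extrafloral"
    BOTH = "both"
    NONE = "none"


class Reason(str, Enum):
    """Terminal outcomes of the accessibility decision tree."""

    EXTRAFLORAL = "extrafloral"
    OPEN_REACH = "open_reach"  # head excluded, proboscis spans corolla + tube
    HEAD_ENTRY_REACH = "head_entry_reach"  # head enters, proboscis spans tube
    FAIL_PENETRATION_REACH = "fail_penetration_reach"
    FAIL_TUBE_WIDTH = "fail_tube_width"
    FAIL_NO_NECTAR = "fail_no_nectar"
    FAIL_MISSING_TRAIT = "fail_missing_trait"


_ACCESSIBLE_REASONS = frozenset(
    {Reason.EXTRAFLORAL, Reason.OPEN_REACH, Reason.HEAD_ENTRY_REACH}
)


@dataclass(frozen=True)
class InsectMorphology:
    """Parasitoid mouthpart and head morphology plus adult activity window.

    Lengths in mm; ``head_width`` is the maximum dorsal width including the
    eyes, ``proboscis_width`` is measured at mid-length.  The activity window
    is an inclusive day-of-year interval.
    """

    taxon: str
    head_width: float
    proboscis_length: float
    proboscis_width: float
    activity_start: int = 1
    activity_end: int = 365

    def __post_init__(self) -> None:
        for name in ("head_width", "proboscis_length", "proboscis_width"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v!r}")
        if self.activity_start > self.activity_end:
            raise ValueError("activity window start must be <= end")

    @property
    def head_radius(self) -> float:
        return self.head_width / 2.0


@dataclass(frozen=True)
class FlowerMorphology:
    """Flower morphology, nectar type and phenology for one plant species.

    ``tube_diameter=None`` means the nectar is not held in a narrow tube (the
    tube-width constraint is skipped).  Other morphology fields may be
    ``None`` (unknown); the species is then conservatively inaccessible.
    ``nectar_quantity`` is an ordinal score used only as a functional trait,
    never in the matching itself.
    """

    species: str
    opening_width: float | None = None
    corolla_height: float | None = None
    nectar_depth: float | None = None
    tube_diameter: float | None = None
    nectar_type: NectarType | str = NectarType.FLORAL
    flower_start: int = 1
    flower_end: int = 365
    # Extrafloral nectar production window; defaults to the full season since
    # extrafloral nectaries are not tied to anthesis.
    efn_start: int = 1
    efn_end: int = 365
    nectar_quantity: int | None = None

    def __post_init__(self) -> None:
        for name in ("opening_width", "corolla_height", "nectar_depth", "tube_diameter"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v!r}")
        if self.flower_start > self.flower_end:
            raise ValueError("flowering window start must be <= end")
        object.__setattr__(self, "nectar_type", NectarType(self.nectar_type))


@dataclass(frozen=True)
class AccessibilityVerdict:
    accessible: bool
    reason: Reason

    def __post_init__(self) -> None:
        if self.accessible != (self.reason in _ACCESSIBLE_REASONS):
            raise ValueError(f"reason {self.reason} inconsistent with accessible={self.accessible}")

    def __bool__(self) -> bool:
        return self.accessible


def nectar_accessible(insect: InsectMorphology, flower: FlowerMorphology) -> AccessibilityVerdict:
    """Run the geometric decision tree for one insect x flower pair.

    Deterministic and pure.  Returns a verdict, never raises for missing
    flower traits (``fail_missing_trait``); invalid negative lengths are
    rejected at construction time.
    """
    ntype = NectarType(flower.nectar_type)
    if ntype is NectarType.NONE:
        return AccessibilityVerdict(False, Reason.FAIL_NO_NECTAR)
    if ntype in (NectarType.EXTRAFLORAL, NectarType.BOTH):
        # Extrafloral nectar is exposed on bracts/stipules: accessible to all.
        return AccessibilityVerdict(True, Reason.EXTRAFLORAL)

    w, h, p = flower.opening_width, flower.corolla_height, flower.nectar_depth
    if w is None or h is None or p is None:
        return AccessibilityVerdict(False, Reason.FAIL_MISSING_TRAIT)

    x = insect.proboscis_length
    z = insect.proboscis_width
    head_enters = w >= 2.0 * insect.head_radius

    if head_enters:
        reach_ok = x >= p
        success = Reason.HEAD_ENTRY_REACH
    else:
        reach_ok = x >= h + p
        success = Reason.OPEN_REACH
    if not reach_ok:
        return AccessibilityVerdict(False, Reason.FAIL_PENETRATION_REACH)
    if flower.tube_diameter is not None and z > flower.tube_diameter:
        return AccessibilityVerdict(False, Reason.FAIL_TUBE_WIDTH)
    return AccessibilityVerdict(True, success)


def _windows_overlap(a0: int, a1: int, b0: int, b1: int) -> bool:
    """Inclusive day-of-year intervals sharing at least one day."""
    return min(a1, b1) - max(a0, b0) >= 0


def nectar_available(
    flower: FlowerMorphology,
    insect: InsectMorphology,
    mode: str = "window",
    survey_stage: int | None = None,
    survey_date: int | None = None,
    flowering_stages: tuple[int, int] = FLOWERING_STAGES,
) -> bool:
    """Is the species' nectar produced during the parasitoid's flight period?

    ``window`` mode intersects the species' production window with the insect
    activity window (floral nectar follows the flowering window; extrafloral
    producers use their production window instead).  ``survey`` mode judges
    availability from a phenology snapshot: the recorded stage (0-10 scale)
    must fall in the configured flowering range (extrafloral producers are
    exempt) and the survey date must fall within the activity window.
    """
    ntype = NectarType(flower.nectar_type)
    if ntype is NectarType.NONE:
        return False
    efn = ntype in (NectarType.EXTRAFLORAL, NectarType.BOTH)

    if mode == "window":
        if efn:
            return _windows_overlap(
                flower.efn_start, flower.efn_end, insect.activity_start, insect.activity_end
            )
        return _windows_overlap(
            flower.flower_start, flower.flower_end, insect.activity_start, insect.activity_end
        )
    if mode == "survey":
        if survey_stage is None or survey_date is None:
            raise ValueError("survey mode requires survey_stage and survey_date")
        if not 0 <= survey_stage <= 10:
            raise ValueError(f"survey_stage must be on the 0-10 scale, got {survey_stage}")
        if not _windows_overlap(survey_date, survey_date, insect.activity_start, insect.activity_end):
            return False
        if efn:
            return True
        lo, hi = flowering_stages
        return lo <= survey_stage <= hi
    raise ValueError(f"unknown availability mode {mode!r}")


def accessible_species(
    flora: Mapping[str, FlowerMorphology],
    insect: InsectMorphology,
    mode: str = "window",
    stages: Mapping[str, int] | None = None,
    survey_date: int | None = None,
    flowering_stages: tuple[int, int] = FLOWERING_STAGES,
) -> set[str]:
    """Species whose nectar is both available and accessible to ``insect``."""
    out: set[str] = set()
    for name, flower in flora.items():
        if mode == "survey":
            stage = None if stages is None else stages.get(name)
            if stage is None:
                continue
            avail = nectar_available(
                flower, insect, "survey", survey_stage=stage, survey_date=survey_date,
                flowering_stages=flowering_stages,
            )
        else:
            avail = nectar_available(flower, insect, "window")
        if avail and nectar_accessible(insect, flower).accessible:
            out.add(name)
    return out


def accessible_cover(
    covers: Mapping[str, float] | "pd.Series",
    flora: Mapping[str, FlowerMorphology],
    insect: InsectMorphology,
    mode: str = "window",
    stages: Mapping[str, int] | None = None,
    survey_date: int | None = None,
    flowering_stages: tuple[int, int] = FLOWERING_STAGES,
) -> float:
    """Percent plant cover providing available and accessible nectar.

    Sums the percent cover of surveyed species whose nectar is available
    (temporal match) and accessible (morphological match) to ``insect``.
    Species without a morphology record contribute 0 and trigger a warning;
    the result lies in ``[0, total cover]``.
    """
    if isinstance(covers, pd.Series):
        covers = covers.to_dict()
    total = 0.0
    missing: list[str] = []
    for species, cover in covers.items():
        if cover <= 0:
            continue
        flower = flora.get(species)
        if flower is None:
            missing.append(species)
            continue
        if mode == "survey":
            stage = None if stages is None else stages.get(species)
            if stage is None:
                missing.append(species)
                continue
            avail = nectar_available(
                flower, insect, "survey", survey_stage=stage, survey_date=survey_date,
                flowering_stages=flowering_stages,
            )
        else:
            avail = nectar_available(flower, insect, "window")
        if avail and nectar_accessible(insect, flower).accessible:
            total += float(cover)
    if missing:
        warnings.warn(
            f"{len(missing)} surveyed species lack morphology/phenology data and "
            f"contribute no accessible cover: {sorted(missing)[:5]}...",
            stacklevel=2,
        )
    return total


_MORPH_FIELDS = ("opening_width", "corolla_height", "nectar_depth", "tube_diameter")


def trait_coverage_report(flora: Mapping[str, FlowerMorphology]) -> dict:
    """Completeness summary of the flower-morphology matrix.

    Returns per-trait completeness fractions, the fraction of species with all
    four morphology fields recorded, and the list of incomplete species.
    ``tube_diameter=None`` counts as missing here even though the matching
    tree treats it as "no narrow tube".
    """
    n = len(flora)
    if n == 0:
        return {
            "n_species": 0,
            "per_trait": {t: float("nan") for t in _MORPH_FIELDS},
            "species_complete_fraction": float("nan"),
            "incomplete_species": [],
        }
    per_trait = {}
    for t in _MORPH_FIELDS:
        per_trait[t] = sum(getattr(f, t) is not None for f in flora.values()) / n
    incomplete = sorted(
        name
        for name, f in flora.items()
        if any(getattr(f, t) is None for t in _MORPH_FIELDS)
    )
    return {
        "n_species": n,
        "per_trait": per_trait,
        "species_complete_fraction": (n - len(incomplete)) / n,
        "incomplete_species": incomplete,
    }


def verdict_matrix(
    flora: Mapping[str, FlowerMorphology], insects: Iterable[InsectMorphology]
) -> pd.DataFrame:
    """Plant x parasitoid 0/1 accessibility matrix (morphology only)."""
    insects = list(insects)
    data = {
        ins.taxon: [int(nectar_accessible(ins, f).accessible) for f in flora.values()]
        for ins in insects
    }
    return pd.DataFrame(data, index=list(flora.keys()))
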