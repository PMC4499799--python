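"""European Pharmacopoeia Identification-C decision logic over TLC band patterns.

Lanes are abstract tabular records (controlled zone vocabulary, hue class,
relative front, intensity relative to the matching reference-lane zone), not
plate images.  Positive *E. arvense* identification needs the combination of
all four marker zones; the foreign-matter check compares the greenish-blue
kaempferol-glucoside zones just above the application line against the
*E. palustre* reference lane — those zones only ever *flag* possible
adulteration, they never identify *E. palustre*, because other horsetail
species show them too.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigError, InputError, SystemSuitabilityError

#: The four E. arvense marker zones whose combination identifies the species.
ARVENSE_ZONES = ("arv_marker_1", "arv_marker_2", "arv_marker_3", "arv_marker_4")

#: The two greenish-blue zones just above the application line (E. palustre flag).
PALUSTRE_ZONES = ("palustre_zone_1", "palustre_zone_2")

_KNOWN_ZONES = frozenset(ARVENSE_ZONES) | frozenset(PALUSTRE_ZONES) | {"other"}


class PalustreFlag(str, enum.Enum):
    ABSENT = "absent"
    WITHIN_LIMIT = "present_within_limit"
    ABOVE_LIMIT = "present_above_limit"


class LaneClass(str, enum.Enum):
    ARVENSE = "arvense"
    MIXTURE_SUSPECTED = "mixture_suspected"
    NON_EQUISETUM = "non_equisetum_pattern"
    NO_CHROMATOGRAM = "no_chromatogram"


@dataclass(frozen=True)
class Band:
    """One zone in a lane; intensity is relative to the reference zone (1.0 = equal)."""

    zone_id: str
    hue_class: str = "other"
    relative_front: float = 0.0
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.relative_front <= 1.0:
            raise InputError(
                f"relative_front {self.relative_front} outside [0, 1] "
                f"(zone {self.zone_id!r})"
            )
        if self.intensity < 0:
            raise InputError(f"negative intensity for zone {self.zone_id!r}")
        if self.zone_id not in _KNOWN_ZONES and not self.zone_id.startswith("other"):
            raise InputError(f"unknown zone id {self.zone_id!r}")


@dataclass(frozen=True)
class BandPattern:
    """All bands observed in one lane."""

    lane_id: str
    bands: tuple[Band, ...] = ()
    reference_lane: bool = False

    def __post_init__(self) -> None:
        ids = [b.zone_id for b in self.bands]
        if len(set(ids)) != len(ids):
            dupes = sorted({z for z in ids if ids.count(z) > 1})
            raise InputError(f"lane {self.lane_id!r} has duplicate zones: {dupes}")

    def band(self, zone_id: str) -> Band | None:
        for b in self.bands:
            if b.zone_id == zone_id:
                return b
        return None


@dataclass(frozen=True)
class TLCParams:
    """Decision thresholds.

    presence_threshold
        minimum relative intensity for a zone to count as present (the
        monograph's visual criterion has no printed number; 0.1 is this
        package's operational default).
    flag_on_any_zone
        if True (default) a single greenish-blue zone exceeding its reference
        counterpart already fails the foreign-matter limit; if False both
        zones must exceed it.
    """

    presence_threshold: float = 0.1
    flag_on_any_zone: bool = True

    def __post_init__(self) -> None:
        if self.presence_threshold < 0:
            raise ConfigError("presence_threshold must be >= 0")


@dataclass(frozen=True)
class TLCResult:
    lane_id: str
    arvense_identified: bool
    palustre_flag: PalustreFlag
    classification: LaneClass

    def to_dict(self) -> dict:
        return {
            "lane_id": self.lane_id,
            "arvense_identified": self.arvense_identified,
            "palustre_flag": self.palustre_flag.value,
            "classification": self.classification.value,
        }


def check_arvense_markers(
    pattern: BandPattern, params: TLCParams | None = None
) -> bool:
    """True iff all four arvense marker zones are present above threshold."""
    params = params or TLCParams()
    return all(
        (band := pattern.band(zone)) is not None
        and band.intensity > params.presence_threshold
        for zone in ARVENSE_ZONES
    )


def _check_system_suitability(
    reference: BandPattern, params: TLCParams
) -> None:
    missing = [
        zone
        for zone in PALUSTRE_ZONES
        if (band := reference.band(zone)) is None
        or band.intensity <= params.presence_threshold
    ]
    if missing:
        raise SystemSuitabilityError(
            f"reference lane {reference.lane_id!r} lacks greenish-blue zones "
            f"{missing}; test invalid"
        )


def check_foreign_matter(
    pattern: BandPattern,
    reference: BandPattern,
    params: TLCParams | None = None,
) -> PalustreFlag:
    """Compare the test lane's greenish-blue zones against the reference lane.

    Raises :class:`SystemSuitabilityError` when the reference lane does not
    show both zones.
    """
    params = params or TLCParams()
    _check_system_suitability(reference, params)
    present = [
        (band, reference.band(zone))
        for zone in PALUSTRE_ZONES
        if (band := pattern.band(zone)) is not None
        and band.intensity > params.presence_threshold
    ]
    if not present:
        return PalustreFlag.ABSENT
    exceed = [band.intensity > ref.intensity for band, ref in present]
    over = any(exceed) if params.flag_on_any_zone else (
        len(exceed) == len(PALUSTRE_ZONES) and all(exceed)
    )
    return PalustreFlag.ABOVE_LIMIT if over else PalustreFlag.WITHIN_LIMIT


def classify_lane(
    pattern: BandPattern,
    reference: BandPattern,
    params: TLCParams | None = None,
) -> TLCResult:
    """Classify one test lane; total over all syntactically valid patterns."""
    params = params or TLCParams()
    _check_system_suitability(reference, params)
    if not pattern.bands:
        return TLCResult(
            lane_id=pattern.lane_id,
            arvense_identified=False,
            palustre_flag=PalustreFlag.ABSENT,
            classification=LaneClass.NO_CHROMATOGRAM,
        )
    arvense = check_arvense_markers(pattern, params)
    flag = check_foreign_matter(pattern, reference, params)
    if arvense:
        classification = (
            LaneClass.ARVENSE if flag is PalustreFlag.ABSENT else LaneClass.MIXTURE_SUSPECTED
        )
    else:
        classification = LaneClass.NON_EQUISETUM
    return TLCResult(
        lane_id=pattern.lane_id,
        arvense_identified=arvense,
        palustre_flag=flag,
        classification=classification,
    )


def classify_panel(
    lanes: Sequence[BandPattern],
    reference: BandPattern,
    params: TLCParams | None = None,
) -> list[TLCResult]:
    return [classify_lane(lane, reference, params) for lane in lanes]


_CSV_COLUMNS = ["lane_id", "zone_id", "hue_class", "relative_front", "intensity", "reference"]


def read_lanes_csv(path: str | Path) -> list[BandPattern]:
    """Read lanes from CSV (lane_id, zone_id, hue_class, relative_front,
    intensity, reference).  A lane with an empty zone_id row and no other rows
    is an empty lane (no chromatogram)."""
    frame = pd.read_csv(path, dtype={"lane_id": str, "zone_id": str, "hue_class": str})
    missing = [c for c in _CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise InputError(f"lane CSV lacks columns {missing}")
    patterns = []
    for lane_id, group in frame.groupby("lane_id", sort=False):
        bands = tuple(
            Band(
                zone_id=row.zone_id,
                hue_class=row.hue_class if isinstance(row.hue_class, str) else "other",
                relative_front=float(row.relative_front),
                intensity=float(row.intensity),
            )
            for row in group.itertuples()
            if isinstance(row.zone_id, str) and row.zone_id
        )
        reference = bool(group["reference"].astype(bool).any())
        patterns.append(BandPattern(lane_id=str(lane_id), bands=bands, reference_lane=reference))
    return patterns


def write_lanes_csv(lanes: Iterable[BandPattern], path: str | Path) -> None:
    rows = []
    for lane in lanes:
        if not lane.bands:
            rows.append(
                {
                    "lane_id": lane.lane_id,
                    "zone_id": "",
                    "hue_class": "",
                    "relative_front": 0.0,
                    "intensity": 0.0,
                    "reference": lane.reference_lane,
                }
            )
        for band in lane.bands:
            rows.append(
                {
                    "lane_id": lane.lane_id,
                    "zone_id": band.zone_id,
                    "hue_class": band.hue_class,
                    "relative_front": band.relative_front,
                    "intensity": band.intensity,
                    "reference": lane.reference_lane,
                }
            )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
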