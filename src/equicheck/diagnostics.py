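"""Discovery of pair-distinguishing diagnostic sites in a genus-wide alignment.

A site "distinguishes" two focal species when it is a fixed difference: every
non-missing observation of species A shows one state, every observation of
species B shows a different state.  Each focal state is then classified as
*unique* (no other sampled species carries it at that column) or *shared*
with a named set of non-focal species.  Because sharing sets are computed
against the sampled roster, profiles record the roster they were computed on.

Gaps, ``N`` and IUPAC ambiguity letters in reference records are treated as
missing data and never count as diagnostic states; indel differences are not
reported.  Positions are 1-based per marker.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import pandas as pd

from .errors import InputError
from .io_markers import MarkerAlignment

#: Characters that carry a usable nucleotide observation in reference rows.
DNA_STATES = frozenset("ACGT")


@dataclass(frozen=True)
class FocalPair:
    """The two species whose fixed differences are sought."""

    species_a: str
    species_b: str

    def __post_init__(self) -> None:
        if self.species_a == self.species_b:
            raise InputError("focal pair must name two distinct species")

    def swapped(self) -> "FocalPair":
        return FocalPair(self.species_b, self.species_a)


@dataclass(frozen=True)
class DiagnosticSite:
    """One fixed-difference column with per-focal-species uniqueness.

    ``shared_with_a``/``shared_with_b`` list the non-focal species that also
    carry the respective focal state at this column; an empty set means the
    state is unique to that focal species among the sampled roster.
    """

    marker: str
    position: int
    state_a: str
    state_b: str
    shared_with_a: frozenset[str]
    shared_with_b: frozenset[str]

    def __post_init__(self) -> None:
        if self.state_a == self.state_b:
            raise InputError("a diagnostic site needs two different focal states")
        if self.position < 1:
            raise InputError("positions are 1-based")

    @property
    def unique_a(self) -> bool:
        return not self.shared_with_a

    @property
    def unique_b(self) -> bool:
        return not self.shared_with_b


class FixedDifference(NamedTuple):
    """Outcome of the fixed-difference test at one column."""

    is_diagnostic: bool
    state_a: str | None
    state_b: str | None
    note: str  # "", "polymorphic", "no data (<species>)", "shared state"


def column_states(aln: MarkerAlignment, position: int) -> dict[str, Counter]:
    """Observed nucleotide multiset per species at a 1-based column.

    Gaps, ``N`` and ambiguity letters are excluded; a species with only
    missing data maps to an empty multiset.
    """
    counts: dict[str, Counter] = {sp: Counter() for sp in aln.species}
    for species, _accession, char in aln.column(position):
        if char in DNA_STATES:
            counts[species][char] += 1
    return counts


def is_fixed_difference(
    aln: MarkerAlignment, position: int, pair: FocalPair
) -> FixedDifference:
    """Test whether a column is a fixed difference between the focal pair."""
    states = column_states(aln, position)
    missing = [
        sp for sp in (pair.species_a, pair.species_b) if not states.get(sp)
    ]
    if missing:
        return FixedDifference(False, None, None, f"no data ({', '.join(missing)})")
    set_a = set(states[pair.species_a])
    set_b = set(states[pair.species_b])
    if len(set_a) > 1 or len(set_b) > 1:
        return FixedDifference(False, None, None, "polymorphic")
    (a,) = set_a
    (b,) = set_b
    if a == b:
        return FixedDifference(False, None, None, "shared state")
    return FixedDifference(True, a, b, "")


def classify_uniqueness(
    aln: MarkerAlignment, position: int, focal: str, state: str
) -> frozenset[str]:
    """Non-focal species also carrying ``state`` at the column (empty = unique)."""
    states = column_states(aln, position)
    return frozenset(
        sp for sp, observed in states.items() if sp != focal and state in observed
    )


@dataclass(frozen=True)
class DiagnosticProfile:
    """All diagnostic sites for a focal pair across one or more markers."""

    pair: FocalPair
    sites: tuple[DiagnosticSite, ...]
    rosters: Mapping[str, tuple[str, ...]]
    marker_lengths: Mapping[str, int]

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(sorted(self.marker_lengths))

    def sites_for(self, marker: str) -> tuple[DiagnosticSite, ...]:
        return tuple(s for s in self.sites if s.marker == marker)

    @property
    def total(self) -> int:
        return len(self.sites)

    def marker_counts(self) -> pd.DataFrame:
        """Per-marker totals and unique/shared splits for both focal species."""
        rows = []
        for marker in self.markers:
            sites = self.sites_for(marker)
            rows.append(
                {
                    "marker": marker,
                    "total": len(sites),
                    "unique_a": sum(s.unique_a for s in sites),
                    "shared_a": sum(not s.unique_a for s in sites),
                    "unique_b": sum(s.unique_b for s in sites),
                    "shared_b": sum(not s.unique_b for s in sites),
                }
            )
        return pd.DataFrame(
            rows, columns=["marker", "total", "unique_a", "shared_a", "unique_b", "shared_b"]
        )

    def unique_positions(self, marker: str, side: str) -> tuple[int, ...]:
        """Positions whose state is unique to focal side 'a' or 'b' in a marker."""
        flag = {"a": "unique_a", "b": "unique_b"}[side]
        return tuple(s.position for s in self.sites_for(marker) if getattr(s, flag))

    def to_dict(self) -> dict:
        return {
            "pair": {"species_a": self.pair.species_a, "species_b": self.pair.species_b},
            "rosters": {m: list(r) for m, r in self.rosters.items()},
            "marker_lengths": dict(self.marker_lengths),
            "sites": [
                {
                    "marker": s.marker,
                    "position": s.position,
                    "state_a": s.state_a,
                    "state_b": s.state_b,
                    "shared_with_a": sorted(s.shared_with_a),
                    "shared_with_b": sorted(s.shared_with_b),
                }
                for s in self.sites
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    @classmethod
    def from_dict(cls, data: Mapping) -> "DiagnosticProfile":
        sites = tuple(
            DiagnosticSite(
                marker=s["marker"],
                position=int(s["position"]),
                state_a=s["state_a"],
                state_b=s["state_b"],
                shared_with_a=frozenset(s["shared_with_a"]),
                shared_with_b=frozenset(s["shared_with_b"]),
            )
            for s in data["sites"]
        )
        return cls(
            pair=FocalPair(data["pair"]["species_a"], data["pair"]["species_b"]),
            sites=sites,
            rosters={m: tuple(r) for m, r in data["rosters"].items()},
            marker_lengths={m: int(v) for m, v in data["marker_lengths"].items()},
        )

    @classmethod
    def from_json(cls, text: str) -> "DiagnosticProfile":
        return cls.from_dict(json.loads(text))

    def to_frame(self) -> pd.DataFrame:
        """One row per site, suitable for TSV export."""
        return pd.DataFrame(
            [
                {
                    "marker": s.marker,
                    "position": s.position,
                    "state_a": s.state_a,
                    "state_b": s.state_b,
                    "uniqueness_a": "unique" if s.unique_a else "shared",
                    "shared_set_a": ";".join(sorted(s.shared_with_a)),
                    "uniqueness_b": "unique" if s.unique_b else "shared",
                    "shared_set_b": ";".join(sorted(s.shared_with_b)),
                }
                for s in self.sites
            ],
            columns=[
                "marker",
                "position",
                "state_a",
                "state_b",
                "uniqueness_a",
                "shared_set_a",
                "uniqueness_b",
                "shared_set_b",
            ],
        )


def build_profile(
    alignments: Sequence[MarkerAlignment], pair: FocalPair
) -> DiagnosticProfile:
    """Scan every column of every marker for fixed differences of the pair.

    A marker missing one or both focal species contributes zero sites (with a
    warning); if the pair is absent from all markers this is an input error.
    Sites are reported in ascending (marker, position) order.
    """
    import logging

    logger = logging.getLogger(__name__)
    if not alignments:
        raise InputError("no alignments supplied")
    names = [a.marker_name for a in alignments]
    if len(set(names)) != len(names):
        raise InputError(f"duplicate marker names in input: {names}")

    any_pair = False
    sites: list[DiagnosticSite] = []
    rosters: dict[str, tuple[str, ...]] = {}
    lengths: dict[str, int] = {}
    for aln in alignments:
        rosters[aln.marker_name] = aln.species
        lengths[aln.marker_name] = aln.length
        present = set(aln.species)
        if pair.species_a not in present or pair.species_b not in present:
            logger.warning(
                "marker %s lacks one of the focal species; contributing zero sites",
                aln.marker_name,
            )
            continue
        any_pair = True
        by_species = aln.sequences_by_species()
        seqs_a = by_species[pair.species_a]
        seqs_b = by_species[pair.species_b]
        others = [(sp, by_species[sp]) for sp in aln.species if sp not in (pair.species_a, pair.species_b)]
        for i in range(aln.length):
            set_a = {s[i] for s in seqs_a} & DNA_STATES
            if len(set_a) != 1:
                continue
            set_b = {s[i] for s in seqs_b} & DNA_STATES
            if len(set_b) != 1 or set_a == set_b:
                continue
            (state_a,) = set_a
            (state_b,) = set_b
            shared_a = frozenset(
                sp for sp, seqs in others if any(s[i] == state_a for s in seqs)
            )
            shared_b = frozenset(
                sp for sp, seqs in others if any(s[i] == state_b for s in seqs)
            )
            sites.append(
                DiagnosticSite(
                    marker=aln.marker_name,
                    position=i + 1,
                    state_a=state_a,
                    state_b=state_b,
                    shared_with_a=shared_a,
                    shared_with_b=shared_b,
                )
            )
    if not any_pair:
        raise InputError(
            f"focal pair ({pair.species_a!r}, {pair.species_b!r}) absent from all markers"
        )
    sites.sort(key=lambda s: (s.marker, s.position))
    return DiagnosticProfile(
        pair=pair, sites=tuple(sites), rosters=rosters, marker_lengths=lengths
    )


def summarize_profile(profile: DiagnosticProfile) -> pd.DataFrame:
    """Tabulate the profile in the layout of a distinguishing-characters table.

    One row per (marker, focal species, sharing group): the unique sites of
    each focal species, then its shared sites grouped by identical sharing
    set.  ``sites`` prints "position state" pairs, comma-separated.
    """
    rows = []
    for marker in profile.markers:
        marker_sites = profile.sites_for(marker)
        for side, species in (("a", profile.pair.species_a), ("b", profile.pair.species_b)):
            state_of = {"a": lambda s: s.state_a, "b": lambda s: s.state_b}[side]
            shared_of = {"a": lambda s: s.shared_with_a, "b": lambda s: s.shared_with_b}[side]
            groups: dict[frozenset[str], list[DiagnosticSite]] = {}
            for s in marker_sites:
                groups.setdefault(shared_of(s), []).append(s)
            ordered = sorted(groups, key=lambda g: (len(g), sorted(g)))
            for shared in ordered:
                group_sites = sorted(groups[shared], key=lambda s: s.position)
                rows.append(
                    {
                        "marker": marker,
                        "species": species,
                        "category": "unique" if not shared else "shared",
                        "shared_with": ";".join(sorted(shared)),
                        "n_sites": len(group_sites),
                        "sites": ", ".join(
                            f"{s.position} {state_of(s)}" for s in group_sites
                        ),
                    }
                )
    return pd.DataFrame(
        rows, columns=["marker", "species", "category", "shared_with", "n_sites", "sites"]
    )
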