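"""Generators for every input the pipeline consumes, with ground truth.

Alignments use a deliberately minimal background model: every column carries
a single invariant ancestral state, and diagnostic structure is *planted*
explicitly (focal states, sharing sets), after which intraspecific
polymorphism and missing data can be injected at stated per-character rates.
This isolates the diagnostic-site logic under test; neutral variation is
never implicit.  Defaults are noise-free, matching clean Sanger consensus
reference panels in which fixed differences are fixed by construction.

``table1_fixture`` rebuilds the full two-marker diagnostic structure
separating *E. arvense* from *E. palustre* — 36 planted fixed differences
(25 in matK, 11 in trnH-psbA) with their published positions, states and
sharing sets; at each planted column the non-listed focal species carries
the ancestral state, which every species outside the sharing set also
carries, so uniqueness classes come out exactly as specified.

Tree and TLC generators plant non-monophyly (by regrafting one accession of
a species next to a host clade in the other subgenus) and lane classes in
closed loop with the monophyly and tlc_rules modules.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .diagnostics import FocalPair
from .errors import ConfigError
from .identify import IUPAC_EXPANSION, QuerySequence
from .io_markers import (
    DEFAULT_OUTGROUPS,
    EQUISETUM_ROSTER,
    SUBGENUS_EQUISETUM,
    SUBGENUS_HIPPOCHAETE,
    AlignmentRecord,
    MarkerAlignment,
    TaxonMap,
)
from .tlc_rules import (
    ARVENSE_ZONES,
    PALUSTRE_ZONES,
    Band,
    BandPattern,
    LaneClass,
)

ARVENSE = "Equisetum arvense"
PALUSTRE = "Equisetum palustre"

_BASES = "ACGT"

# two-nucleotide set -> IUPAC double-peak code
_IUPAC_CODE = {
    frozenset(values): letter
    for letter, values in IUPAC_EXPANSION.items()
    if len(values) == 2
}


@dataclass(frozen=True)
class PlantedSite:
    """Specification of one diagnostic column to embed in an alignment."""

    marker: str
    position: int
    state_a: str
    state_b: str
    shared_with_a: frozenset[str] = frozenset()
    shared_with_b: frozenset[str] = frozenset()
    ancestral: str | None = None  # default: a third state != both focal states

    def __post_init__(self) -> None:
        if self.state_a == self.state_b:
            raise ConfigError("planted focal states must differ")
        if self.state_a not in _BASES or self.state_b not in _BASES:
            raise ConfigError("planted states must be concrete DNA letters")
        if self.position < 1:
            raise ConfigError("positions are 1-based")
        if self.shared_with_a & self.shared_with_b:
            raise ConfigError("a species cannot share both focal states at one column")

    def ancestral_state(self) -> str:
        if self.ancestral is not None:
            return self.ancestral
        return next(b for b in _BASES if b not in (self.state_a, self.state_b))


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for alignment simulation.

    ``markers`` maps marker name to length; a ``None`` length means "just
    long enough for the largest planted position".  Rates are per
    (accession, column) probabilities applied after planting.
    """

    roster: tuple[str, ...] = EQUISETUM_ROSTER
    accessions: int | Mapping[str, int] = 2
    markers: tuple[tuple[str, int | None], ...] = (("matK", 670), ("trnH-psbA", 200))
    planted_sites: tuple[PlantedSite, ...] = ()
    pair: FocalPair = field(default_factory=lambda: FocalPair(ARVENSE, PALUSTRE))
    background_state: str = "A"
    polymorphism_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.polymorphism_rate <= 1.0:
            raise ConfigError("polymorphism_rate must be in [0, 1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigError("missing_rate must be in [0, 1]")
        if self.background_state not in _BASES:
            raise ConfigError("background_state must be a DNA letter")
        marker_names = [m for m, _ in self.markers]
        if len(set(marker_names)) != len(marker_names):
            raise ConfigError("duplicate marker names")
        focal = {self.pair.species_a, self.pair.species_b}
        if not focal <= set(self.roster):
            raise ConfigError("focal pair must be part of the roster")
        seen: set[tuple[str, int]] = set()
        for site in self.planted_sites:
            key = (site.marker, site.position)
            if key in seen:
                raise ConfigError(
                    f"two planting specs for column {site.position} of {site.marker!r}"
                )
            seen.add(key)
            if site.marker not in marker_names:
                raise ConfigError(f"planted site references unknown marker {site.marker!r}")
            sharers = site.shared_with_a | site.shared_with_b
            if sharers & focal:
                raise ConfigError("sharing sets may not contain the focal pair")
            if not sharers <= set(self.roster):
                raise ConfigError(
                    f"sharing set names species outside the roster: "
                    f"{sorted(sharers - set(self.roster))}"
                )

    def n_accessions(self, species: str) -> int:
        if isinstance(self.accessions, Mapping):
            return int(self.accessions.get(species, 1))
        return int(self.accessions)

    def marker_length(self, marker: str) -> int:
        declared = dict(self.markers)[marker]
        planted_max = max(
            (s.position for s in self.planted_sites if s.marker == marker), default=0
        )
        if declared is None:
            if planted_max == 0:
                raise ConfigError(f"marker {marker!r} needs a length or planted sites")
            return planted_max
        if planted_max > declared:
            raise ConfigError(
                f"planted position {planted_max} exceeds length {declared} of {marker!r}"
            )
        return declared


@dataclass(frozen=True)
class SimTruth:
    """Ground truth attached to generated artifacts."""

    planted_sites: tuple[PlantedSite, ...] = ()
    clean_sequences: Mapping[str, Mapping[str, str]] = field(default_factory=dict)
    marker_lengths: Mapping[str, int] = field(default_factory=dict)
    pair: FocalPair | None = None
    roster: tuple[str, ...] = ()
    nonmono_species: frozenset[str] = frozenset()
    taxon_map: TaxonMap | None = None
    lane_classes: Mapping[str, str] = field(default_factory=dict)

    def planted_positions(self, marker: str) -> frozenset[int]:
        return frozenset(s.position for s in self.planted_sites if s.marker == marker)


def accession_id(species: str, index: int) -> str:
    """Deterministic accession id, e.g. 'ARVE1' for Equisetum arvense."""
    epithet = species.split()[-1]
    return f"{epithet[:4].upper()}{index}"


def simulate_alignment(config: SimConfig) -> tuple[list[MarkerAlignment], SimTruth]:
    """Generate one alignment per marker with the configured planted structure.

    Clean per-species sequences are built first (ancestral background, then
    planted overrides), copied to accessions, then polymorphism and missing
    data are applied character-wise.  Fully reproducible from ``config.seed``.
    """
    alignments = []
    clean: dict[str, dict[str, str]] = {}
    lengths: dict[str, int] = {}
    for marker, _ in config.markers:
        length = config.marker_length(marker)
        lengths[marker] = length
        columns_default = [config.background_state] * length
        per_species = {
            sp: list(columns_default) for sp in config.roster
        }
        for site in config.planted_sites:
            if site.marker != marker:
                continue
            i = site.position - 1
            anc = site.ancestral_state()
            for sp in config.roster:
                if sp == config.pair.species_a or sp in site.shared_with_a:
                    per_species[sp][i] = site.state_a
                elif sp == config.pair.species_b or sp in site.shared_with_b:
                    per_species[sp][i] = site.state_b
                else:
                    per_species[sp][i] = anc
        clean[marker] = {sp: "".join(chars) for sp, chars in per_species.items()}

        rng = random.Random(f"{config.seed}:{marker}")
        records = []
        for sp in config.roster:
            for k in range(1, config.n_accessions(sp) + 1):
                chars = list(clean[marker][sp])
                if config.polymorphism_rate > 0:
                    for i, c in enumerate(chars):
                        if rng.random() < config.polymorphism_rate:
                            chars[i] = rng.choice([b for b in _BASES if b != c])
                if config.missing_rate > 0:
                    for i in range(len(chars)):
                        if rng.random() < config.missing_rate:
                            chars[i] = "N"
                records.append(
                    AlignmentRecord(accession_id(sp, k), sp, "".join(chars))
                )
        alignments.append(MarkerAlignment(marker_name=marker, records=tuple(records)))

    truth = SimTruth(
        planted_sites=config.planted_sites,
        clean_sequences=clean,
        marker_lengths=lengths,
        pair=config.pair,
        roster=config.roster,
    )
    return alignments, truth


# ---------------------------------------------------------------------------
# Published diagnostic structure: 36 fixed differences (25 matK, 11 trnH-psbA)
# between E. arvense (side a) and E. palustre (side b).
# ---------------------------------------------------------------------------

_E = "Equisetum "

_MATK_ARVENSE_SHARED: tuple[tuple[tuple[str, ...], tuple[tuple[int, str], ...]], ...] = (
    ((_E + "fluviatile",), ((265, "C"), (511, "G"))),
    (
        (_E + "diffusum", _E + "fluviatile"),
        (
            (294, "A"), (344, "C"), (351, "C"), (374, "C"), (397, "G"), (502, "T"),
            (512, "C"), (567, "G"), (572, "A"), (619, "T"), (636, "A"), (670, "G"),
        ),
    ),
    ((_E + "diffusum", _E + "fluviatile", _E + "sylvaticum"), ((212, "T"), (462, "T"))),
    (
        (_E + "diffusum", _E + "fluviatile", _E + "hyemale", _E + "sylvaticum"),
        ((372, "G"),),
    ),
)
_MATK_PALUSTRE_UNIQUE: tuple[tuple[int, str], ...] = (
    (273, "C"), (311, "A"), (391, "C"), (575, "C"), (594, "C"),
)
_MATK_PALUSTRE_SHARED: tuple[tuple[tuple[str, ...], tuple[tuple[int, str], ...]], ...] = (
    ((_E + "laevigatum", _E + "myriochaetum"), ((600, "G"),)),
    ((_E + "sylvaticum", _E + "telmateia"), ((534, "C"),)),
    ((_E + "hyemale", _E + "ramosissimum"), ((421, "A"),)),
)
_TRNH_ARVENSE_UNIQUE: tuple[tuple[int, str], ...] = ((193, "A"),)
_TRNH_ARVENSE_SHARED: tuple[tuple[tuple[str, ...], tuple[tuple[int, str], ...]], ...] = (
    ((_E + "diffusum", _E + "fluviatile"), ((87, "A"), (141, "A"))),
)
_TRNH_PALUSTRE_UNIQUE: tuple[tuple[int, str], ...] = ((124, "A"), (200, "A"))
_TRNH_PALUSTRE_SHARED: tuple[tuple[tuple[str, ...], tuple[tuple[int, str], ...]], ...] = (
    (
        (_E + "bogotense", _E + "diffusum", _E + "sylvaticum"),
        ((121, "G"), (122, "T"), (123, "A"), (125, "T"), (126, "A")),
    ),
    ((_E + "pratense", _E + "sylvaticum", _E + "telmateia"), ((151, "C"),)),
)


def _alt_state(state: str) -> str:
    """A fixed alternative (ancestral) state for the non-listed focal species."""
    return "T" if state != "T" else "G"


def _published_sites() -> tuple[PlantedSite, ...]:
    sites: list[PlantedSite] = []

    def add(marker, entries_unique, entries_shared, side):
        for pos, state in entries_unique:
            alt = _alt_state(state)
            if side == "a":
                sites.append(
                    PlantedSite(marker, pos, state, alt, frozenset(), frozenset(), ancestral=alt)
                )
            else:
                sites.append(
                    PlantedSite(marker, pos, alt, state, frozenset(), frozenset(), ancestral=alt)
                )
        for sharers, positions in entries_shared:
            for pos, state in positions:
                alt = _alt_state(state)
                if side == "a":
                    sites.append(
                        PlantedSite(
                            marker, pos, state, alt, frozenset(sharers), frozenset(), ancestral=alt
                        )
                    )
                else:
                    sites.append(
                        PlantedSite(
                            marker, pos, alt, state, frozenset(), frozenset(sharers), ancestral=alt
                        )
                    )

    add("matK", (), _MATK_ARVENSE_SHARED, "a")
    add("matK", _MATK_PALUSTRE_UNIQUE, _MATK_PALUSTRE_SHARED, "b")
    add("trnH-psbA", _TRNH_ARVENSE_UNIQUE, _TRNH_ARVENSE_SHARED, "a")
    add("trnH-psbA", _TRNH_PALUSTRE_UNIQUE, _TRNH_PALUSTRE_SHARED, "b")
    sites.sort(key=lambda s: (s.marker, s.position))
    return tuple(sites)


def table1_fixture(
    accessions: int = 2, seed: int = 0
) -> tuple[list[MarkerAlignment], SimTruth]:
    """Two-marker genus alignment embedding the 36 published diagnostic sites.

    matK is 670 columns, trnH-psbA 200; all non-planted columns invariant;
    every species carries ``accessions`` (>= 2) clean copies.
    """
    if accessions < 2:
        raise ConfigError("focal species need at least 2 accessions")
    config = SimConfig(
        roster=EQUISETUM_ROSTER,
        accessions=accessions,
        markers=(("matK", 670), ("trnH-psbA", 200)),
        planted_sites=_published_sites(),
        pair=FocalPair(ARVENSE, PALUSTRE),
        seed=seed,
    )
    return simulate_alignment(config)


# ---------------------------------------------------------------------------
# Queries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuerySpec:
    """What kind of query to synthesize.

    kind "pure" copies one species' clean sequences; "chimera" combines two
    parents either by splitting the diagnostic sites between them
    (``mode="site_split"``: conflicting fixed characters across sites, the
    across-marker chimera signature) or by writing the two-state IUPAC code
    at every conflicting site (``mode="double_peak"``: within-site double
    peaks).  ``missing_fraction`` then replaces that fraction of characters
    with N (degraded template).
    """

    kind: str = "pure"
    species: str | None = None
    parents: tuple[str, str] | None = None
    mode: str = "site_split"
    missing_fraction: float = 0.0
    markers: tuple[str, ...] | None = None
    sample_id: str = "query"

    def __post_init__(self) -> None:
        if self.kind not in ("pure", "chimera"):
            raise ConfigError(f"unknown query kind {self.kind!r}")
        if self.kind == "pure" and not self.species:
            raise ConfigError("pure query needs a species")
        if self.kind == "chimera":
            if not self.parents or len(self.parents) != 2:
                raise ConfigError("chimera needs two parents")
            if self.parents[0] == self.parents[1]:
                raise ConfigError("chimera parents must be distinct species")
            if self.mode not in ("site_split", "double_peak"):
                raise ConfigError(f"unknown chimera mode {self.mode!r}")
        if not 0.0 <= self.missing_fraction <= 1.0:
            raise ConfigError("missing_fraction must be in [0, 1]")


def simulate_query(
    truth: SimTruth, spec: QuerySpec, seed: int = 0
) -> tuple[list[QuerySequence], str]:
    """Synthesize one sample's queries plus its ground-truth label."""
    markers = spec.markers or tuple(truth.clean_sequences)
    unknown = [m for m in markers if m not in truth.clean_sequences]
    if unknown:
        raise ConfigError(f"markers {unknown} not in truth")

    def _species_seq(marker: str, species: str) -> str:
        try:
            return truth.clean_sequences[marker][species]
        except KeyError:
            raise ConfigError(f"species {species!r} not in truth for {marker!r}") from None

    sequences: dict[str, list[str]] = {}
    if spec.kind == "pure":
        label = spec.species  # type: ignore[assignment]
        for m in markers:
            sequences[m] = list(_species_seq(m, spec.species))  # type: ignore[arg-type]
    else:
        label = "mixture"
        p1, p2 = spec.parents  # type: ignore[misc]
        conflicts: list[tuple[str, int]] = []
        for m in markers:
            s1, s2 = _species_seq(m, p1), _species_seq(m, p2)
            sequences[m] = list(s1)
            conflicts.extend((m, i) for i in range(len(s1)) if s1[i] != s2[i])
        conflicts.sort()
        for rank, (m, i) in enumerate(conflicts):
            c1 = _species_seq(m, p1)[i]
            c2 = _species_seq(m, p2)[i]
            if spec.mode == "double_peak":
                sequences[m][i] = _IUPAC_CODE[frozenset((c1, c2))]
            elif rank % 2 == 1:  # alternate sites between the two parents
                sequences[m][i] = c2

    if spec.missing_fraction > 0:
        rng = random.Random(seed)
        for m in markers:
            n = len(sequences[m])
            k = round(spec.missing_fraction * n)
            for i in rng.sample(range(n), k):
                sequences[m][i] = "N"

    queries = [
        QuerySequence(sample_id=spec.sample_id, marker=m, sequence="".join(sequences[m]))
        for m in markers
    ]
    return queries, label  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def _random_join(items: list[str], rng: random.Random) -> str:
    """Random binary (Newick substring) combination of subtree strings."""
    items = list(items)
    rng.shuffle(items)
    while len(items) > 1:
        a = items.pop()
        b = items.pop()
        items.insert(rng.randrange(len(items) + 1), f"({a},{b})")
    return items[0]


def simulate_tree(
    roster: Sequence[str] = EQUISETUM_ROSTER,
    accessions: int | Mapping[str, int] = 2,
    nonmono: frozenset[str] | set[str] = frozenset(),
    seed: int = 0,
    include_outgroup: bool = True,
):
    """Species tree with accession clades; optionally planted paraphyly.

    Species falling in the two known subgenera are grouped accordingly (with
    the basal species sister to both clades, and fern outgroups outside);
    any other roster species are arranged with the basal group.  Paraphyly
    is planted by pruning one accession of each ``nonmono`` species and
    regrafting it as sister to a host species' clade in the *other*
    subgenus, which breaks the donor's monophyly without touching the host's.

    Returns ``(PhyloTree, SimTruth)``; the truth carries the taxon map
    (outgroup tips included) and the planted non-monophyletic species.
    """
    from .monophyly import PhyloTree  # local import to avoid a cycle

    nonmono = frozenset(nonmono)
    roster = tuple(roster)
    if not nonmono <= set(roster):
        raise ConfigError("nonmono species must be in the roster")
    rng = random.Random(seed)

    def n_acc(sp: str) -> int:
        if isinstance(accessions, Mapping):
            return int(accessions.get(sp, 1))
        return int(accessions)

    tips: dict[str, list[str]] = {
        sp: [accession_id(sp, k) for k in range(1, n_acc(sp) + 1)] for sp in roster
    }
    for sp in nonmono:
        if len(tips[sp]) < 2:
            raise ConfigError(f"cannot plant paraphyly for singleton species {sp!r}")

    strays: dict[str, str] = {sp: tips[sp].pop() for sp in sorted(nonmono)}
    clade_str = {sp: _random_join(list(t), rng) for sp, t in tips.items()}

    group_e = [sp for sp in roster if sp in SUBGENUS_EQUISETUM]
    group_h = [sp for sp in roster if sp in SUBGENUS_HIPPOCHAETE]
    rest = [
        sp for sp in roster
        if sp not in SUBGENUS_EQUISETUM and sp not in SUBGENUS_HIPPOCHAETE
    ]

    for sp, stray in strays.items():
        if sp in group_e and group_h:
            candidates = [h for h in group_h if h not in nonmono] or group_h
        elif sp in group_h and group_e:
            candidates = [e for e in group_e if e not in nonmono] or group_e
        else:
            candidates = [o for o in roster if o != sp]
        host = rng.choice(sorted(candidates))
        clade_str[host] = f"({clade_str[host]},{stray})"

    blocks = []
    if group_e:
        blocks.append(_random_join([clade_str[sp] for sp in group_e], rng))
    if group_h:
        blocks.append(_random_join([clade_str[sp] for sp in group_h], rng))
    ingroup = f"({blocks[0]},{blocks[1]})" if len(blocks) == 2 else (
        blocks[0] if blocks else None
    )
    basal = [clade_str[sp] for sp in rest]
    parts = basal + ([ingroup] if ingroup else [])
    if not parts:
        raise ConfigError("empty roster")
    genus = parts[0] if len(parts) == 1 else _random_join(parts, rng)

    taxon_pairs = [(tip, sp) for sp in roster for tip in tips[sp]]
    taxon_pairs += [(stray, sp) for sp, stray in strays.items()]
    if include_outgroup:
        og_tips = [accession_id(sp, 1) for sp in DEFAULT_OUTGROUPS]
        taxon_pairs += list(zip(og_tips, DEFAULT_OUTGROUPS))
        newick = f"(({og_tips[0]},{og_tips[1]}),{genus});"
    else:
        newick = f"{genus};"

    tree = PhyloTree.from_newick(newick)
    truth = SimTruth(
        roster=roster,
        nonmono_species=nonmono,
        taxon_map=TaxonMap.from_pairs(taxon_pairs),
    )
    return tree, truth


def fig1_tree_fixture(seed: int = 0):
    """Genus tree in the published shape: basal species sister to two
    seven-species subgeneric clades, two accessions per species, with
    *E. diffusum* and *E. sylvaticum* planted non-monophyletic."""
    return simulate_tree(
        roster=EQUISETUM_ROSTER,
        accessions=2,
        nonmono={_E + "diffusum", _E + "sylvaticum"},
        seed=seed,
        include_outgroup=True,
    )


# ---------------------------------------------------------------------------
# TLC lanes
# ---------------------------------------------------------------------------

_ARV_FRONTS = (0.38, 0.52, 0.66, 0.85)
_PAL_FRONTS = (0.08, 0.12)


def reference_lane(lane_id: str = "REF") -> BandPattern:
    """A suitability-passing E. palustre reference lane (both zones, unit intensity)."""
    bands = tuple(
        Band(zone_id=z, hue_class="greenish-blue", relative_front=f, intensity=1.0)
        for z, f in zip(PALUSTRE_ZONES, _PAL_FRONTS)
    )
    return BandPattern(lane_id=lane_id, bands=bands, reference_lane=True)


def simulate_band_patterns(
    classes: Sequence[str | LaneClass],
    seed: int = 0,
    lane_ids: Sequence[str] | None = None,
) -> tuple[list[BandPattern], BandPattern, SimTruth]:
    """Generate test lanes whose planted class matches the rule-based call.

    Returns (test lanes, reference lane, truth with per-lane classes).
    """
    rng = random.Random(seed)
    wanted = [LaneClass(c) for c in classes]
    ids = list(lane_ids) if lane_ids is not None else [
        f"L{i + 1}" for i in range(len(wanted))
    ]
    if len(ids) != len(wanted):
        raise ConfigError("lane_ids and classes must have equal length")

    lanes = []
    for lane_id, cls in zip(ids, wanted):
        bands: list[Band] = []
        if cls in (LaneClass.ARVENSE, LaneClass.MIXTURE_SUSPECTED):
            bands += [
                Band(zone_id=z, hue_class="orange", relative_front=f,
                     intensity=round(rng.uniform(0.6, 1.4), 3))
                for z, f in zip(ARVENSE_ZONES, _ARV_FRONTS)
            ]
        if cls is LaneClass.MIXTURE_SUSPECTED:
            bands += [
                Band(zone_id=z, hue_class="greenish-blue", relative_front=f,
                     intensity=round(rng.uniform(1.1, 1.6), 3))
                for z, f in zip(PALUSTRE_ZONES, _PAL_FRONTS)
            ]
        if cls is LaneClass.NON_EQUISETUM:
            for k in range(rng.randint(2, 4)):
                bands.append(
                    Band(zone_id=f"other_{k + 1}", hue_class="other",
                         relative_front=round(rng.uniform(0.2, 0.95), 3),
                         intensity=round(rng.uniform(0.3, 1.2), 3))
                )
        lanes.append(BandPattern(lane_id=lane_id, bands=tuple(bands)))

    truth = SimTruth(lane_classes={l.lane_id: c.value for l, c in zip(lanes, wanted)})
    return lanes, reference_lane(), truth


def product_panel(seed: int = 0) -> tuple[list[BandPattern], BandPattern, SimTruth]:
    """Eight-lane commercial-product analog: five clean arvense lanes, one
    suspected mixture, one non-horsetail pattern, one empty lane."""
    classes = (
        [LaneClass.ARVENSE] * 5
        + [LaneClass.MIXTURE_SUSPECTED, LaneClass.NON_EQUISETUM, LaneClass.NO_CHROMATOGRAM]
    )
    ids = ["P1", "P2", "P3", "P4", "P5", "B", "I", "HB"]
    return simulate_band_patterns(classes, seed=seed, lane_ids=ids)
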