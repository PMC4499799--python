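"""Reading, validating and writing species-labelled marker alignments and trees.

Alignments are fixed-width character matrices over DNA letters, IUPAC
ambiguity codes, ``N`` and ``-``; every record carries an accession id and a
canonical species name parsed from its FASTA header. Alignment columns are
numbered 1-based throughout the package. On ingest sequences are upper-cased
and ``U`` is mapped to ``T`` (the markers are plastid DNA).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentFormatError,
    EmptyInputError,
    InputError,
    LabelRuleError,
    TreeFormatError,
)

logger = logging.getLogger(__name__)

#: The seven species of subgenus Equisetum sampled in a genus-wide panel.
SUBGENUS_EQUISETUM = (
    "Equisetum arvense",
    "Equisetum palustre",
    "Equisetum pratense",
    "Equisetum sylvaticum",
    "Equisetum telmateia",
    "Equisetum fluviatile",
    "Equisetum diffusum",
)

#: The seven species of subgenus Hippochaete.
SUBGENUS_HIPPOCHAETE = (
    "Equisetum hyemale",
    "Equisetum ramosissimum",
    "Equisetum variegatum",
    "Equisetum scirpoides",
    "Equisetum laevigatum",
    "Equisetum myriochaetum",
    "Equisetum giganteum",
)

#: Basal species, sister to the rest of the genus.
BASAL_SPECIES = "Equisetum bogotense"

#: Default 15-species genus roster.
EQUISETUM_ROSTER = (BASAL_SPECIES,) + SUBGENUS_EQUISETUM + SUBGENUS_HIPPOCHAETE

#: Fern outgroups used for genus-level trees.
DEFAULT_OUTGROUPS = ("Angiopteris angustifolia", "Ophioglossum reticulatum")

# Characters accepted in aligned sequences: DNA + IUPAC ambiguity + missing.
_ALLOWED_CHARS = frozenset("ACGTRYSWKMBDHVN-?.")

# Known spelling variants -> canonical species name.  "fluvatile" is a common
# typo for "fluviatile" seen in printed tables.
_SPELLING_VARIANTS = {
    "E. fluvatile": "Equisetum fluviatile",
    "Equisetum fluvatile": "Equisetum fluviatile",
}


def _default_normalization() -> dict[str, str]:
    table = dict(_SPELLING_VARIANTS)
    for sp in EQUISETUM_ROSTER:
        epithet = sp.split(" ", 1)[1]
        table[f"E. {epithet}"] = sp
        table[sp] = sp
    for sp in DEFAULT_OUTGROUPS:
        table[sp] = sp
    return table


DEFAULT_NORMALIZATION: Mapping[str, str] = _default_normalization()


@dataclass(frozen=True)
class LabelRule:
    """How to split a FASTA header into (accession_id, species).

    The default matches headers of the form ``EA01|Equisetum_arvense``;
    underscores in the species field become spaces.
    """

    delimiter: str = "|"
    accession_field: int = 0
    species_field: int = 1
    underscore_to_space: bool = True

    def parse(self, header: str) -> tuple[str, str]:
        parts = header.strip().split(self.delimiter)
        try:
            accession = parts[self.accession_field].strip()
            species = parts[self.species_field].strip()
        except IndexError:
            raise LabelRuleError(
                f"header {header!r} does not match the "
                f"'accession{self.delimiter}species' labelling rule"
            ) from None
        if self.underscore_to_space:
            species = species.replace("_", " ")
        if not accession or not species:
            raise LabelRuleError(f"header {header!r} yields an empty accession or species")
        return accession, species

    def format(self, accession: str, species: str) -> str:
        if self.underscore_to_space:
            species = species.replace(" ", "_")
        fields = [""] * (max(self.accession_field, self.species_field) + 1)
        fields[self.accession_field] = accession
        fields[self.species_field] = species
        return self.delimiter.join(fields)


DEFAULT_LABEL_RULE = LabelRule()


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned sequence with its accession id and species label."""

    accession_id: str
    species: str
    sequence: str


@dataclass(frozen=True)
class MarkerAlignment:
    """A species-labelled, fixed-width alignment for one barcode marker."""

    marker_name: str
    records: tuple[AlignmentRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise EmptyInputError(f"alignment {self.marker_name!r} has no records")
        width = len(self.records[0].sequence)
        seen: set[str] = set()
        for rec in self.records:
            if len(rec.sequence) != width:
                raise AlignmentFormatError(
                    f"record {rec.accession_id!r} has length {len(rec.sequence)}, "
                    f"expected {width} (marker {self.marker_name!r})"
                )
            if rec.accession_id in seen:
                raise AlignmentFormatError(
                    f"duplicate accession id {rec.accession_id!r} in marker "
                    f"{self.marker_name!r}"
                )
            seen.add(rec.accession_id)
            if not rec.species:
                raise AlignmentFormatError(
                    f"record {rec.accession_id!r} has an empty species label"
                )
            bad = set(rec.sequence) - _ALLOWED_CHARS
            if bad:
                raise AlignmentFormatError(
                    f"record {rec.accession_id!r} contains illegal characters "
                    f"{sorted(bad)}"
                )

    @property
    def length(self) -> int:
        return len(self.records[0].sequence)

    @property
    def species(self) -> tuple[str, ...]:
        out: list[str] = []
        for rec in self.records:
            if rec.species not in out:
                out.append(rec.species)
        return tuple(out)

    def sequences_by_species(self) -> dict[str, tuple[str, ...]]:
        table: dict[str, list[str]] = {}
        for rec in self.records:
            table.setdefault(rec.species, []).append(rec.sequence)
        return {sp: tuple(seqs) for sp, seqs in table.items()}

    def column(self, position: int) -> list[tuple[str, str, str]]:
        """All (species, accession, character) at a 1-based column."""
        if not 1 <= position <= self.length:
            raise InputError(
                f"position {position} out of range 1..{self.length} "
                f"for marker {self.marker_name!r}"
            )
        i = position - 1
        return [(r.species, r.accession_id, r.sequence[i]) for r in self.records]


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def _clean_sequence(raw: str) -> str:
    return raw.upper().replace("U", "T")


def read_alignment(
    path: str | Path,
    marker_name: str,
    label_rule: LabelRule = DEFAULT_LABEL_RULE,
) -> MarkerAlignment:
    """Read and validate a FASTA alignment for one marker.

    Raises :class:`EmptyInputError` for an empty file,
    :class:`LabelRuleError` for an unparseable header and
    :class:`AlignmentFormatError` for ragged rows or illegal characters.
    """
    with _open_text(path) as handle:
        seq_records = list(SeqIO.parse(handle, "fasta"))
    if not seq_records:
        raise EmptyInputError(f"no FASTA records in {path}")
    records = []
    for sr in seq_records:
        accession, species = label_rule.parse(sr.description)
        records.append(AlignmentRecord(accession, species, _clean_sequence(str(sr.seq))))
    return MarkerAlignment(marker_name=marker_name, records=tuple(records))


def write_alignment(
    aln: MarkerAlignment,
    path: str | Path,
    label_rule: LabelRule = DEFAULT_LABEL_RULE,
) -> None:
    """Write an alignment back to FASTA (gzip if the path ends in .gz)."""
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=label_rule.format(rec.accession_id, rec.species), description="")
        for rec in aln.records
    ]
    with _open_text(path, "wt") as handle:
        SeqIO.write(seq_records, handle, "fasta")


def read_queries(
    path: str | Path,
    label_rule: LabelRule = DEFAULT_LABEL_RULE,
) -> list[tuple[str, str, str]]:
    """Read query FASTA as (sample_id, marker, sequence) triples.

    Headers follow the same delimiter rule as alignments, with the marker name
    in place of the species field, e.g. ``productF|matK``.
    """
    with _open_text(path) as handle:
        seq_records = list(SeqIO.parse(handle, "fasta"))
    if not seq_records:
        raise EmptyInputError(f"no FASTA records in {path}")
    rule = LabelRule(
        delimiter=label_rule.delimiter,
        accession_field=label_rule.accession_field,
        species_field=label_rule.species_field,
        underscore_to_space=False,
    )
    out = []
    for sr in seq_records:
        sample_id, marker = rule.parse(sr.description)
        out.append((sample_id, marker, _clean_sequence(str(sr.seq))))
    return out


def read_tree(path: str | Path):
    """Read a Newick tree with labelled tips into a :class:`PhyloTree`.

    Raises :class:`TreeFormatError` for malformed Newick or duplicate tips.
    """
    from .monophyly import PhyloTree

    with _open_text(path) as handle:
        newick = handle.read()
    return PhyloTree.from_newick(newick)


@dataclass(frozen=True)
class TaxonMap:
    """Mapping species -> accession ids, with a spelling-normalization table.

    Every accession maps to exactly one species; normalization is idempotent
    (canonical names map to themselves).
    """

    species_to_accessions: Mapping[str, frozenset[str]]
    normalization: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for sp, accs in self.species_to_accessions.items():
            for acc in accs:
                if acc in seen and seen[acc] != sp:
                    raise InputError(
                        f"accession {acc!r} mapped to both {seen[acc]!r} and {sp!r}"
                    )
                seen[acc] = sp

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.species_to_accessions)

    def accession_to_species(self) -> dict[str, str]:
        return {
            acc: sp
            for sp, accs in self.species_to_accessions.items()
            for acc in accs
        }

    def species_of(self, accession: str) -> str | None:
        return self.accession_to_species().get(accession)

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        normalization: Mapping[str, str] | None = None,
    ) -> "TaxonMap":
        """Build from (accession, species) pairs."""
        table: dict[str, set[str]] = {}
        for acc, sp in pairs:
            table.setdefault(sp, set()).add(acc)
        return cls(
            {sp: frozenset(accs) for sp, accs in table.items()},
            dict(normalization or {}),
        )

    @classmethod
    def from_alignment(cls, aln: MarkerAlignment) -> "TaxonMap":
        return cls.from_pairs((r.accession_id, r.species) for r in aln.records)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonMap":
        """Read a two-column (accession TAB species) table, '#' comments allowed."""
        pairs = []
        with _open_text(path) as handle:
            for line in handle:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise InputError(f"taxon table line {line!r} lacks a species column")
                pairs.append((fields[0], fields[1]))
        if not pairs:
            raise EmptyInputError(f"no taxon assignments in {path}")
        return cls.from_pairs(pairs)

    def to_tsv(self, path: str | Path) -> None:
        with _open_text(path, "wt") as handle:
            for sp in self.species_to_accessions:
                for acc in sorted(self.species_to_accessions[sp]):
                    handle.write(f"{acc}\t{sp}\n")


def normalize_species(name: str, taxon_map: TaxonMap | None = None) -> str:
    """Return the canonical spelling of a species name.

    The map's own normalization table takes precedence over the built-in one
    (which expands ``E. <epithet>`` abbreviations and fixes known variants).
    Unknown names pass through unchanged with a logged warning.
    """
    name = name.strip()
    if taxon_map is not None:
        if name in taxon_map.normalization:
            return taxon_map.normalization[name]
        if name in taxon_map.species_to_accessions:
            return name
    if name in DEFAULT_NORMALIZATION:
        return DEFAULT_NORMALIZATION[name]
    logger.warning("species name %r not recognized; passing through unchanged", name)
    return name
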