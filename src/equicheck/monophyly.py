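"""Species-monophyly assessment on input trees.

Trees are consumed, never inferred.  With a declared outgroup (or on an
unrooted tree) a tip set is monophyletic iff it is one side of some edge
bipartition — equivalent to forming a clade after rooting on the outgroup,
and invariant to how the input Newick happens to be rooted.  On an
explicitly rooted tree without an outgroup, the descendant tip set of a
single node must equal the query set; polytomies are treated as hard (no
soft-polytomy resolution).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Iterable

import dendropy
import pandas as pd

from .errors import InputError, TreeFormatError
from .io_markers import TaxonMap


class PhyloTree:
    """Immutable wrapper around a DendroPy tree with cached bipartitions."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [
            leaf.taxon.label if leaf.taxon is not None else None
            for leaf in tree.leaf_node_iter()
        ]
        if any(label is None for label in labels):
            raise TreeFormatError("tree has unlabelled tips")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeFormatError(f"duplicate tip labels: {dupes}")
        self._labels = frozenset(labels)

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeFormatError(f"could not parse Newick: {exc}") from exc
        return cls(tree)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> frozenset[str]:
        return self._labels

    @property
    def n_tips(self) -> int:
        return len(self._labels)

    @property
    def is_rooted(self) -> bool:
        return bool(self._tree.is_rooted)

    def newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    @cached_property
    def clades(self) -> frozenset[frozenset[str]]:
        """Descendant tip sets of every node (as drawn from the input root)."""
        sets: list[frozenset[str]] = []
        leafset: dict[int, frozenset[str]] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                leafset[id(node)] = frozenset([node.taxon.label])
            else:
                merged: frozenset[str] = frozenset()
                for child in node.child_nodes():
                    merged |= leafset[id(child)]
                leafset[id(node)] = merged
            sets.append(leafset[id(node)])
        return frozenset(sets)

    @cached_property
    def bipartition_sides(self) -> frozenset[frozenset[str]]:
        """Every edge side and its complement (monophyly up to rooting)."""
        sides: set[frozenset[str]] = set()
        for clade in self.clades:
            sides.add(clade)
            sides.add(self._labels - clade)
        sides.discard(frozenset())
        return frozenset(sides)


def is_monophyletic(
    tree: PhyloTree,
    tips: Iterable[str],
    outgroup: Iterable[str] | None = None,
) -> bool:
    """Whether ``tips`` form a clade (rooting on ``outgroup`` when given)."""
    tip_set = frozenset(tips)
    if not tip_set:
        raise InputError("empty tip set")
    unknown = tip_set - tree.tip_labels
    if unknown:
        raise InputError(f"unknown tip labels: {sorted(unknown)}")
    out_set = frozenset(outgroup) if outgroup else frozenset()
    if out_set:
        unknown_out = out_set - tree.tip_labels
        if unknown_out:
            raise InputError(f"unknown outgroup tips: {sorted(unknown_out)}")
        if out_set & tip_set:
            raise InputError("outgroup overlaps the queried tip set")
        return tip_set in tree.bipartition_sides
    if tree.is_rooted:
        return tip_set in tree.clades
    return tip_set in tree.bipartition_sides


@dataclass(frozen=True)
class SpeciesStatus:
    species: str
    n_tips: int
    monophyletic: bool
    trivial: bool  # single-tip species: untestable, reported True
    intruders: frozenset[str]


@dataclass(frozen=True)
class SpeciesMonophylyReport:
    statuses: tuple[SpeciesStatus, ...]
    outgroup: frozenset[str]

    @property
    def non_monophyletic(self) -> tuple[str, ...]:
        return tuple(s.species for s in self.statuses if not s.monophyletic)

    @property
    def n_monophyletic(self) -> int:
        return sum(s.monophyletic for s in self.statuses)

    def status_of(self, species: str) -> SpeciesStatus:
        for s in self.statuses:
            if s.species == species:
                return s
        raise InputError(f"species {species!r} not in report")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "species": s.species,
                    "n_tips": s.n_tips,
                    "monophyletic": s.monophyletic,
                    "untestable_singleton": s.trivial,
                    "intruders": ";".join(sorted(s.intruders)),
                }
                for s in self.statuses
            ],
            columns=["species", "n_tips", "monophyletic", "untestable_singleton", "intruders"],
        )

    def to_dict(self) -> dict:
        return {
            "outgroup": sorted(self.outgroup),
            "species": [
                {
                    "species": s.species,
                    "n_tips": s.n_tips,
                    "monophyletic": s.monophyletic,
                    "untestable_singleton": s.trivial,
                    "intruders": sorted(s.intruders),
                }
                for s in self.statuses
            ],
        }


def _minimal_containing_side(
    tree: PhyloTree, tips: frozenset[str], out_set: frozenset[str]
) -> frozenset[str]:
    """Smallest bipartition side containing ``tips`` and excluding the outgroup."""
    candidates = [
        side
        for side in tree.bipartition_sides
        if tips <= side and not side & out_set
    ]
    if not candidates:
        return tree.tip_labels - out_set
    return min(candidates, key=lambda side: (len(side), tuple(sorted(side))))


def assess_species(
    tree: PhyloTree,
    taxa: TaxonMap,
    outgroup: Iterable[str] | None = None,
) -> SpeciesMonophylyReport:
    """Per-species monophyly report for every species in the taxon map.

    ``outgroup`` names outgroup *tips*; these are excluded from species
    entries.  Singleton species are trivially monophyletic and flagged
    untestable.  For a non-monophyletic species the intruders are the foreign
    tips inside the smallest clade (bipartition side) containing its tips.
    """
    out_set = frozenset(outgroup) if outgroup else frozenset()
    tip_to_species = taxa.accession_to_species()
    unmapped = sorted(tree.tip_labels - set(tip_to_species) - out_set)
    if unmapped:
        raise InputError(f"tree tips not mapped to a species: {unmapped}")

    by_species: dict[str, set[str]] = {}
    for tip in sorted(tree.tip_labels - out_set):
        by_species.setdefault(tip_to_species[tip], set()).add(tip)

    statuses = []
    for species in sorted(by_species):
        tips = frozenset(by_species[species])
        if len(tips) < 2:
            statuses.append(
                SpeciesStatus(species, len(tips), True, True, frozenset())
            )
            continue
        mono = is_monophyletic(tree, tips, outgroup=out_set or None)
        intruders: frozenset[str] = frozenset()
        if not mono:
            side = _minimal_containing_side(tree, tips, out_set)
            intruders = frozenset(side - tips)
        statuses.append(SpeciesStatus(species, len(tips), mono, False, intruders))
    return SpeciesMonophylyReport(statuses=tuple(statuses), outgroup=out_set)
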