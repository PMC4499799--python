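"""Independent oracles and generators shared across the test suite.

Everything here is deliberately naive (nested loops, exhaustive
enumeration); these functions define expected behaviour and must never call
the implementation paths they are used to check.
"""

from __future__ import annotations

import random
from itertools import combinations

import dendropy

from equicheck.io_markers import AlignmentRecord, MarkerAlignment
from equicheck.monophyly import PhyloTree

DNA = "ACGT"


def naive_sites(aln: MarkerAlignment, species_a: str, species_b: str):
    """Brute-force fixed-difference discovery: three nested loops, per column.

    Returns a list of (position, state_a, state_b, shared_a, shared_b).
    """
    sites = []
    for pos in range(1, aln.length + 1):
        observed: dict[str, set[str]] = {}
        for rec in aln.records:
            char = rec.sequence[pos - 1]
            if char in DNA:
                observed.setdefault(rec.species, set()).add(char)
        states_a = observed.get(species_a, set())
        states_b = observed.get(species_b, set())
        if len(states_a) == 1 and len(states_b) == 1 and states_a != states_b:
            (sa,) = states_a
            (sb,) = states_b
            shared_a = set()
            shared_b = set()
            for sp, states in observed.items():
                if sp in (species_a, species_b):
                    continue
                if sa in states:
                    shared_a.add(sp)
                if sb in states:
                    shared_b.add(sp)
            sites.append((pos, sa, sb, frozenset(shared_a), frozenset(shared_b)))
    return sites


def random_alignment(rng: random.Random, max_species=10, max_accessions=6, max_columns=200):
    """Random species-labelled alignment with a mix of invariant, fixed-different
    and noisy columns (gaps/N/polymorphism included)."""
    n_species = rng.randint(2, max_species)
    n_cols = rng.randint(5, max_columns)
    species = [f"species_{i}" for i in range(n_species)]
    per_species_states = []
    for _ in range(n_cols):
        kind = rng.random()
        if kind < 0.5:  # invariant column
            state = rng.choice(DNA)
            per_species_states.append({sp: state for sp in species})
        else:  # per-species states from a small alphabet
            alphabet = rng.sample(DNA, rng.randint(1, 3))
            per_species_states.append({sp: rng.choice(alphabet) for sp in species})
    records = []
    for sp in species:
        for k in range(rng.randint(1, max_accessions)):
            chars = []
            for col in per_species_states:
                r = rng.random()
                if r < 0.05:
                    chars.append(rng.choice("N-"))
                elif r < 0.10:
                    chars.append(rng.choice(DNA))  # intraspecific noise
                else:
                    chars.append(col[sp])
            records.append(AlignmentRecord(f"{sp}_acc{k}", sp, "".join(chars)))
    return MarkerAlignment(marker_name="sim", records=tuple(records))


# --- exhaustive unrooted tree enumeration ---------------------------------


def _attach(node, leaf):
    """Yield copies of ``node`` (nested tuple) with ``leaf`` on each edge."""
    for i, child in enumerate(node):
        yield node[:i] + ((child, leaf),) + node[i + 1:]
        if isinstance(child, tuple):
            for sub in _attach(child, leaf):
                yield node[:i] + (sub,) + node[i + 1:]


def all_unrooted_trees(labels):
    """All unrooted topologies on the labels, as root-trifurcation tuples."""
    if len(labels) < 3:
        raise ValueError("need at least 3 tips")
    trees = [tuple(labels[:3])]
    for leaf in labels[3:]:
        trees = [t2 for t in trees for t2 in _attach(t, leaf)]
    return trees


def _leafset(node):
    if isinstance(node, str):
        return frozenset([node])
    out = frozenset()
    for child in node:
        out |= _leafset(child)
    return out


def oracle_bipartition_sides(nested):
    """All tip sets that are one side of some edge: the clade-enumeration oracle."""
    everything = _leafset(nested)
    sides = set()

    def walk(node):
        s = _leafset(node)
        sides.add(s)
        sides.add(everything - s)
        if isinstance(node, tuple):
            for child in node:
                walk(child)
        return s

    for child in nested:
        walk(child)
    sides.discard(frozenset())
    sides.add(everything)  # the complete tip set is trivially monophyletic
    return sides


def nested_to_phylo(nested) -> PhyloTree:
    """Build a PhyloTree directly from a nested-tuple topology (no parsing)."""
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)

    def build(spec):
        node = dendropy.Node()
        if isinstance(spec, str):
            node.taxon = tns.require_taxon(label=spec)
        else:
            for child in spec:
                node.add_child(build(child))
        return node

    tree.seed_node = build(nested)
    return PhyloTree(tree)


def all_subsets(labels, min_size=1):
    labels = sorted(labels)
    for size in range(min_size, len(labels) + 1):
        for combo in combinations(labels, size):
            yield frozenset(combo)
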