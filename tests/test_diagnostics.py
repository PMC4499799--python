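"""Fixed-difference discovery and uniqueness classification."""

import random
from collections import Counter

import pytest

from equicheck import (
    FocalPair,
    build_profile,
    classify_uniqueness,
    column_states,
    is_fixed_difference,
    summarize_profile,
)
from equicheck.errors import InputError
from equicheck.io_markers import AlignmentRecord, MarkerAlignment
from equicheck.synthetic_data import ARVENSE, PALUSTRE, PlantedSite, SimConfig, simulate_alignment

from helpers import naive_sites, random_alignment


def _aln(rows, marker="m"):
    """rows: list of (accession, species, sequence)."""
    return MarkerAlignment(marker, tuple(AlignmentRecord(*r) for r in rows))


class TestColumnStates:
    def test_invariant_column(self):
        aln = _aln([("a1", "sp1", "C"), ("b1", "sp2", "C"), ("c1", "sp3", "C")])
        assert column_states(aln, 1) == {
            "sp1": Counter("C"), "sp2": Counter("C"), "sp3": Counter("C"),
        }

    def test_gaps_and_missing_excluded(self):
        aln = _aln([("a1", "sp1", "C"), ("a2", "sp1", "-"), ("a3", "sp1", "T")])
        assert column_states(aln, 1) == {"sp1": Counter("CT")}

    def test_ambiguity_letters_excluded_in_references(self):
        aln = _aln([("a1", "sp1", "Y"), ("a2", "sp1", "N"), ("b1", "sp2", "G")])
        states = column_states(aln, 1)
        assert states["sp1"] == Counter()
        assert states["sp2"] == Counter("G")

    def test_union_equals_naive_scan(self):
        rng = random.Random(42)
        for _ in range(20):
            aln = random_alignment(rng, max_species=6, max_accessions=4, max_columns=40)
            pos = rng.randint(1, aln.length)
            states = column_states(aln, pos)
            expected = Counter(
                char for _, _, char in aln.column(pos) if char in "ACGT"
            )
            union = Counter()
            for multiset in states.values():
                union += multiset
            assert union == expected


class TestIsFixedDifference:
    def test_clean_fixed_difference(self):
        aln = _aln([("a1", "A", "C"), ("a2", "A", "C"), ("b1", "B", "T")])
        assert is_fixed_difference(aln, 1, FocalPair("A", "B"))[:3] == (True, "C", "T")

    def test_intraspecific_polymorphism_disqualifies(self):
        aln = _aln([("a1", "A", "C"), ("a2", "A", "T"), ("b1", "B", "G")])
        result = is_fixed_difference(aln, 1, FocalPair("A", "B"))
        assert not result.is_diagnostic
        assert result.note == "polymorphic"

    def test_missing_focal_species_is_no_data_not_error(self):
        aln = _aln([("a1", "A", "N"), ("b1", "B", "T")])
        result = is_fixed_difference(aln, 1, FocalPair("A", "B"))
        assert not result.is_diagnostic
        assert "no data" in result.note and "A" in result.note

    def test_published_palustre_state_at_matk_273(self, table1):
        alignments, truth = table1
        matk = next(a for a in alignments if a.marker_name == "matK")
        result = is_fixed_difference(matk, 273, truth.pair)
        assert result.is_diagnostic
        assert result.state_b == "C"  # palustre is fixed C at matK 273


class TestClassifyUniqueness:
    def test_published_unique_site(self, table1):
        alignments, _ = table1
        trnh = next(a for a in alignments if a.marker_name == "trnH-psbA")
        assert classify_uniqueness(trnh, 193, ARVENSE, "A") == frozenset()

    def test_published_shared_site(self, table1):
        alignments, _ = table1
        matk = next(a for a in alignments if a.marker_name == "matK")
        assert classify_uniqueness(matk, 265, ARVENSE, "C") == frozenset(
            {"Equisetum fluviatile"}
        )

    def test_agrees_with_bruteforce_on_random_alignments(self):
        rng = random.Random(99)
        for _ in range(30):
            aln = random_alignment(rng, max_species=6, max_accessions=4, max_columns=50)
            pair = FocalPair("species_0", "species_1")
            for pos, sa, sb, shared_a, shared_b in naive_sites(
                aln, pair.species_a, pair.species_b
            ):
                assert classify_uniqueness(aln, pos, pair.species_a, sa) == shared_a
                assert classify_uniqueness(aln, pos, pair.species_b, sb) == shared_b


class TestBuildProfile:
    def test_zero_variable_columns(self):
        aln = _aln([("a1", "A", "CCCC"), ("b1", "B", "CCCC")])
        profile = build_profile([aln], FocalPair("A", "B"))
        assert profile.total == 0
        assert summarize_profile(profile).empty

    def test_pair_absent_everywhere_is_error(self):
        aln = _aln([("a1", "A", "C"), ("b1", "B", "T")])
        with pytest.raises(InputError):
            build_profile([aln], FocalPair("X", "Y"))

    def test_pair_symmetry(self, table1, table1_profile):
        """Swapping the focal pair swaps states/uniqueness, keeps positions."""
        alignments, truth = table1
        swapped = build_profile(alignments, truth.pair.swapped())
        forward = {(s.marker, s.position): s for s in table1_profile.sites}
        assert len(swapped.sites) == len(forward)
        for s in swapped.sites:
            f = forward[(s.marker, s.position)]
            assert (s.state_a, s.state_b) == (f.state_b, f.state_a)
            assert (s.shared_with_a, s.shared_with_b) == (f.shared_with_b, f.shared_with_a)

    def test_count_conservation(self, table1_profile):
        counts = table1_profile.marker_counts()
        assert counts["total"].sum() == table1_profile.total
        assert (counts["unique_a"] + counts["shared_a"] == counts["total"]).all()
        assert (counts["unique_b"] + counts["shared_b"] == counts["total"]).all()

    def test_matches_bruteforce_reference(self):
        rng = random.Random(2024)
        for _ in range(60):
            aln = random_alignment(rng)
            pair = FocalPair("species_0", "species_1")
            profile = build_profile([aln], pair)
            expected = naive_sites(aln, pair.species_a, pair.species_b)
            got = [
                (s.position, s.state_a, s.state_b, s.shared_with_a, s.shared_with_b)
                for s in profile.sites
            ]
            assert got == expected


class TestPlantedSiteRecovery:
    def _config(self, rate=0.0, seed=5):
        planted = tuple(
            PlantedSite("m1", pos, "C", "T", frozenset(), frozenset())
            for pos in (10, 25, 40, 55, 70)
        )
        return SimConfig(
            markers=(("m1", 80),),
            planted_sites=planted,
            polymorphism_rate=rate,
            seed=seed,
        )

    def test_noiseless_recovery_is_exact(self):
        alignments, truth = simulate_alignment(self._config())
        profile = build_profile(alignments, truth.pair)
        assert {s.position for s in profile.sites} == truth.planted_positions("m1")
        assert all(s.unique_a and s.unique_b for s in profile.sites)
        assert all((s.state_a, s.state_b) == ("C", "T") for s in profile.sites)

    def test_polymorphism_at_planted_column_removes_it(self):
        """Corrupting one focal accession at a planted column drops exactly
        that column; noise never creates new sites."""
        alignments, truth = simulate_alignment(self._config())
        aln = alignments[0]
        planted = sorted(truth.planted_positions("m1"))
        previous_recall = 1.0
        for n_corrupt in range(1, len(planted) + 1):
            records = list(aln.records)
            for pos in planted[:n_corrupt]:
                idx = next(
                    i for i, r in enumerate(records) if r.species == truth.pair.species_a
                )
                rec = records[idx]
                seq = list(rec.sequence)
                seq[pos - 1] = "G" if seq[pos - 1] != "G" else "A"
                records[idx] = AlignmentRecord(rec.accession_id, rec.species, "".join(seq))
            noisy = MarkerAlignment(aln.marker_name, tuple(records))
            profile = build_profile([noisy], truth.pair)
            found = {s.position for s in profile.sites}
            assert found == set(planted[n_corrupt:])
            recall = len(found) / len(planted)
            assert recall <= previous_recall
            previous_recall = recall


class TestSummarizeProfile:
    def test_published_group_rows(self, table1_profile):
        summary = summarize_profile(table1_profile)
        unique_pal_matk = summary[
            (summary.marker == "matK")
            & (summary.species == PALUSTRE)
            & (summary.category == "unique")
        ]
        assert unique_pal_matk["sites"].tolist() == ["273 C, 311 A, 391 C, 575 C, 594 C"]
        unique_pal_trnh = summary[
            (summary.marker == "trnH-psbA")
            & (summary.species == PALUSTRE)
            & (summary.category == "unique")
        ]
        assert unique_pal_trnh["sites"].tolist() == ["124 A, 200 A"]

    def test_serialization_round_trip(self, table1_profile):
        from equicheck.diagnostics import DiagnosticProfile

        again = DiagnosticProfile.from_json(table1_profile.to_json())
        assert again == table1_profile
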