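"""Query identification, chimera detection and the positive-ID rules."""

import random

import pytest

from equicheck import (
    IdentifyParams,
    QuerySequence,
    evaluate_site,
    identify_query,
    simulate_decision_performance,
)
from equicheck.diagnostics import DiagnosticSite
from equicheck.errors import ConfigError, InputError
from equicheck.identify import Call, Support
from equicheck.synthetic_data import ARVENSE, PALUSTRE, QuerySpec, simulate_query

SITE = DiagnosticSite(
    marker="matK", position=3, state_a="T", state_b="C",
    shared_with_a=frozenset(), shared_with_b=frozenset(),
)


def _query(seq, marker="matK", sample="s"):
    return QuerySequence(sample_id=sample, marker=marker, sequence=seq)


class TestEvaluateSite:
    @pytest.mark.parametrize(
        ("observed", "support"),
        [
            ("T", Support.A),
            ("C", Support.B),
            ("Y", Support.BOTH),   # Y = {C, T}: the double-peak signature
            ("W", Support.A),      # W = {A, T}: only the arvense state
            ("G", Support.NEITHER),
            ("R", Support.NEITHER),  # R = {A, G}: neither focal state
            ("-", Support.MISSING),
            ("N", Support.MISSING),
        ],
    )
    def test_iupac_expansion(self, observed, support):
        evidence = evaluate_site(_query("AA" + observed), SITE)
        assert evidence.support is support
        assert evidence.observed == observed

    def test_marker_mismatch_rejected(self):
        with pytest.raises(InputError):
            evaluate_site(_query("AAT", marker="trnH-psbA"), SITE)


def _pure(truth, species, markers=None, sample="q", missing=0.0, seed=0):
    queries, label = simulate_query(
        truth,
        QuerySpec(kind="pure", species=species, markers=markers,
                  sample_id=sample, missing_fraction=missing),
        seed=seed,
    )
    return queries, label


class TestIdentifyQuery:
    def test_pure_arvense_both_markers_positive(self, table1, table1_profile):
        _, truth = table1
        queries, _ = _pure(truth, ARVENSE)
        result = identify_query(queries, table1_profile)
        assert result.call is Call.SPECIES_A
        assert result.called_species == ARVENSE
        assert result.positive_identification
        assert result.counts["n_supports_a"] == 36

    def test_pure_arvense_matk_only_positive_via_combination(self, table1, table1_profile):
        """matK has no arvense-unique site; the combination rule carries the ID."""
        _, truth = table1
        queries, _ = _pure(truth, ARVENSE, markers=("matK",))
        result = identify_query(queries, table1_profile)
        assert result.call is Call.SPECIES_A
        assert result.positive_identification
        assert result.positive_basis == "combination"

    def test_pure_palustre_positive_via_unique_sites(self, table1, table1_profile):
        _, truth = table1
        queries, _ = _pure(truth, PALUSTRE)
        result = identify_query(queries, table1_profile)
        assert result.call is Call.SPECIES_B
        assert result.positive_identification
        assert result.positive_basis == "unique_site"

    @pytest.mark.parametrize("mode", ["site_split", "double_peak"])
    def test_chimera_called_mixture(self, table1, table1_profile, mode):
        _, truth = table1
        queries, label = simulate_query(
            truth,
            QuerySpec(kind="chimera", parents=(ARVENSE, PALUSTRE), mode=mode),
        )
        assert label == "mixture"
        result = identify_query(queries, table1_profile)
        assert result.call is Call.MIXTURE
        if mode == "site_split":
            assert result.mixture_conflicting_sites
        else:
            assert result.mixture_double_peaks
            assert result.counts["n_both"] == 36

    def test_all_missing_is_inconclusive(self, table1, table1_profile):
        _, truth = table1
        queries, _ = _pure(truth, ARVENSE, missing=1.0)
        result = identify_query(queries, table1_profile)
        assert result.call is Call.INCONCLUSIVE
        assert result.counts["n_missing"] == 36

    def test_no_marker_overlap_is_error(self, table1_profile):
        with pytest.raises(InputError):
            identify_query([_query("ACGT", marker="rbcL")], table1_profile)

    def test_wrong_length_is_error(self, table1_profile):
        with pytest.raises(InputError, match="length"):
            identify_query([_query("ACGT", marker="matK")], table1_profile)

    def test_thresholds_below_one_rejected(self):
        with pytest.raises(ConfigError):
            IdentifyParams(t_call=0)

    def test_determinism(self, table1, table1_profile):
        _, truth = table1
        queries, _ = _pure(truth, PALUSTRE, missing=0.2, seed=9)
        first = identify_query(queries, table1_profile)
        second = identify_query(queries, table1_profile)
        assert first == second

    def test_masking_pure_query_never_creates_a_call(self, table1, table1_profile):
        """For a query with no contrary evidence, masking sites can only move
        a species call towards inconclusive, never the reverse."""
        _, truth = table1
        rng = random.Random(4)
        base = truth.clean_sequences["matK"][PALUSTRE]
        positions = sorted(truth.planted_positions("matK"))
        rng.shuffle(positions)
        previous_call = None
        masked = list(base)
        calls = []
        for pos in positions:
            masked[pos - 1] = "N"
            trnh = truth.clean_sequences["trnH-psbA"][PALUSTRE]
            result = identify_query(
                [
                    _query("".join(masked), marker="matK"),
                    _query("N" * len(trnh), marker="trnH-psbA"),
                ],
                table1_profile,
            )
            calls.append(result.call)
        # once inconclusive, further masking keeps it inconclusive
        seen_inconclusive = False
        for call in calls:
            if seen_inconclusive:
                assert call is Call.INCONCLUSIVE
            seen_inconclusive = seen_inconclusive or call is Call.INCONCLUSIVE

    def test_pair_relabel_preserves_mixture_and_inconclusive(self, table1):
        from equicheck import build_profile

        alignments, truth = table1
        forward = build_profile(alignments, truth.pair)
        backward = build_profile(alignments, truth.pair.swapped())
        specs = [
            QuerySpec(kind="chimera", parents=(ARVENSE, PALUSTRE), mode="site_split"),
            QuerySpec(kind="chimera", parents=(ARVENSE, PALUSTRE), mode="double_peak"),
            QuerySpec(kind="pure", species=ARVENSE, missing_fraction=1.0),
            QuerySpec(kind="pure", species=ARVENSE),
            QuerySpec(kind="pure", species=PALUSTRE),
        ]
        for spec in specs:
            queries, _ = simulate_query(truth, spec, seed=3)
            f = identify_query(queries, forward)
            b = identify_query(queries, backward)
            if f.call in (Call.MIXTURE, Call.INCONCLUSIVE):
                assert b.call is f.call
            else:
                assert b.called_species == f.called_species


class TestDecisionPerformance:
    def test_noiseless_pure_queries_all_correct(self, table1, table1_profile):
        _, truth = table1
        labeled = []
        for i in range(50):
            species = ARVENSE if i % 2 else PALUSTRE
            queries, label = _pure(truth, species, sample=f"q{i}")
            labeled.append((queries, label))
        summary = simulate_decision_performance(labeled, table1_profile)
        assert summary.n_correct == 50
        assert summary.recall(ARVENSE) == 1.0
        assert summary.recall(PALUSTRE) == 1.0
        assert summary.false_positives(ARVENSE) == 0

    def test_reported_counts_match_stored_evidence(self, table1, table1_profile):
        """Accuracy bookkeeping agrees with a recount from per-site evidence."""
        _, truth = table1
        labeled = []
        for i in range(30):
            queries, label = _pure(
                truth, PALUSTRE if i % 3 else ARVENSE,
                sample=f"q{i}", missing=0.3, seed=i,
            )
            labeled.append((queries, label))
        summary = simulate_decision_performance(labeled, table1_profile)
        recount = 0
        for true_label, result in summary.results:
            n_missing = sum(e.support is Support.MISSING for e in result.evidence)
            assert n_missing == result.counts["n_missing"]
            called = result.called_species or result.call.value
            recount += called == true_label
        assert recount == summary.n_correct
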