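"""Rule-based species assignment of query sequences against a diagnostic profile.

Each query (pre-aligned to reference coordinates) is read at every diagnostic
site of the markers it covers.  The observed character is expanded through the
IUPAC ambiguity alphabet: a character whose expansion contains only one focal
state supports that species; one containing both (e.g. ``Y`` over a C/T
difference — the double peak of a mixed-template Sanger chromatogram)
supports both; gaps and ``N`` are missing.

The call is then made from the support counts: conflicting fixed characters
across sites or repeated double peaks yield a *mixture* call (the chimeric
signature of adulterated material); a one-sided preponderance with no
contrary evidence yields a species call; anything else is inconclusive.  A
species call is *positive* when backed by at least one species-unique site,
or — for species A only, which may lack unique sites in a marker — when every
covered site supports it and enough sites are covered (the
combination-of-characters rule).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values

from .diagnostics import DiagnosticProfile, DiagnosticSite
from .errors import ConfigError, InputError

logger = logging.getLogger(__name__)

# IUPAC letter -> set of concrete nucleotides.  N/gaps are missing, not
# four-way ambiguity: a missing base is no evidence at all.
IUPAC_EXPANSION: Mapping[str, frozenset[str]] = {
    letter: frozenset(values)
    for letter, values in ambiguous_dna_values.items()
    if letter not in ("N", "X")
}
MISSING_CHARS = frozenset("N-?.X")


class Support(str, enum.Enum):
    A = "supports_a"
    B = "supports_b"
    BOTH = "supports_both"
    NEITHER = "supports_neither"
    MISSING = "missing"


class Call(str, enum.Enum):
    SPECIES_A = "species_a"
    SPECIES_B = "species_b"
    MIXTURE = "mixture"
    INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class QuerySequence:
    """A query in reference-alignment coordinates for one marker."""

    sample_id: str
    marker: str
    sequence: str


@dataclass(frozen=True)
class SiteEvidence:
    """What a query shows at one diagnostic site."""

    marker: str
    position: int
    expected_state_a: str
    expected_state_b: str
    observed: str
    support: Support
    unique_a: bool
    unique_b: bool


@dataclass(frozen=True)
class IdentifyParams:
    """Decision thresholds for :func:`identify_query`.

    t_call
        minimum one-sided supporting sites for a species call (with zero
        contrary sites).
    t_mix
        minimum supporting sites *per side* for a conflicting-characters
        mixture call.
    t_both
        minimum double-peak (supports-both) sites for a mixture call.
    c_min
        minimum covered sites for the species-A combination rule.

    These thresholds are operational choices of this implementation; they are
    echoed into every result for provenance.
    """

    t_call: int = 3
    t_mix: int = 2
    t_both: int = 2
    c_min: int = 4

    def __post_init__(self) -> None:
        for name in ("t_call", "t_mix", "t_both", "c_min"):
            if getattr(self, name) < 1:
                raise ConfigError(f"threshold {name} must be >= 1")


@dataclass(frozen=True)
class IdentificationResult:
    sample_id: str
    call: Call
    called_species: str | None
    positive_identification: bool
    positive_basis: str  # "unique_site", "combination", or ""
    mixture_conflicting_sites: bool
    mixture_double_peaks: bool
    evidence: tuple[SiteEvidence, ...]
    counts: Mapping[str, int]
    params: IdentifyParams

    def evidence_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "marker": e.marker,
                    "position": e.position,
                    "expected_state_a": e.expected_state_a,
                    "expected_state_b": e.expected_state_b,
                    "observed": e.observed,
                    "support": e.support.value,
                    "unique_a": e.unique_a,
                    "unique_b": e.unique_b,
                }
                for e in self.evidence
            ],
            columns=[
                "marker",
                "position",
                "expected_state_a",
                "expected_state_b",
                "observed",
                "support",
                "unique_a",
                "unique_b",
            ],
        )

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "call": self.call.value,
            "called_species": self.called_species,
            "positive_identification": self.positive_identification,
            "positive_basis": self.positive_basis,
            "mixture_conflicting_sites": self.mixture_conflicting_sites,
            "mixture_double_peaks": self.mixture_double_peaks,
            "counts": dict(self.counts),
            "params": {
                "t_call": self.params.t_call,
                "t_mix": self.params.t_mix,
                "t_both": self.params.t_both,
                "c_min": self.params.c_min,
            },
        }


def evaluate_site(query: QuerySequence, site: DiagnosticSite) -> SiteEvidence:
    """Read one diagnostic site in a query and classify its support."""
    if site.marker != query.marker:
        raise InputError(
            f"site marker {site.marker!r} does not match query marker {query.marker!r}"
        )
    observed = query.sequence[site.position - 1].upper()
    if observed in MISSING_CHARS or observed not in IUPAC_EXPANSION:
        support = Support.MISSING
    else:
        expansion = IUPAC_EXPANSION[observed]
        has_a = site.state_a in expansion
        has_b = site.state_b in expansion
        if has_a and has_b:
            support = Support.BOTH
        elif has_a:
            support = Support.A
        elif has_b:
            support = Support.B
        else:
            support = Support.NEITHER
    return SiteEvidence(
        marker=site.marker,
        position=site.position,
        expected_state_a=site.state_a,
        expected_state_b=site.state_b,
        observed=observed,
        support=support,
        unique_a=site.unique_a,
        unique_b=site.unique_b,
    )


def identify_query(
    queries: Sequence[QuerySequence],
    profile: DiagnosticProfile,
    params: IdentifyParams | None = None,
) -> IdentificationResult:
    """Assign one sample's queries (one per marker) to a species or mixture."""
    params = params or IdentifyParams()
    if not queries:
        raise InputError("no query sequences supplied")
    sample_ids = {q.sample_id for q in queries}
    if len(sample_ids) > 1:
        raise InputError(f"queries belong to several samples: {sorted(sample_ids)}")
    (sample_id,) = sample_ids

    by_marker: dict[str, QuerySequence] = {}
    for q in queries:
        if q.marker in by_marker:
            raise InputError(f"two queries for marker {q.marker!r}")
        by_marker[q.marker] = q

    overlap = [m for m in by_marker if m in profile.marker_lengths]
    if not overlap:
        raise InputError(
            f"no query marker overlaps the profile (query: {sorted(by_marker)}, "
            f"profile: {sorted(profile.marker_lengths)})"
        )
    for m in overlap:
        expected = profile.marker_lengths[m]
        if len(by_marker[m].sequence) != expected:
            raise InputError(
                f"query for marker {m!r} has length {len(by_marker[m].sequence)}, "
                f"expected the reference alignment length {expected}"
            )
    skipped = sorted(set(by_marker) - set(overlap))
    if skipped:
        logger.warning("query markers %s not in profile; ignored", skipped)

    evidence = tuple(
        evaluate_site(by_marker[site.marker], site)
        for site in profile.sites
        if site.marker in by_marker
    )
    counts = {
        "n_supports_a": sum(e.support is Support.A for e in evidence),
        "n_supports_b": sum(e.support is Support.B for e in evidence),
        "n_both": sum(e.support is Support.BOTH for e in evidence),
        "n_neither": sum(e.support is Support.NEITHER for e in evidence),
        "n_missing": sum(e.support is Support.MISSING for e in evidence),
    }
    m_a, m_b, m_both = counts["n_supports_a"], counts["n_supports_b"], counts["n_both"]

    conflicting = m_a >= params.t_mix and m_b >= params.t_mix
    double_peaks = m_both >= params.t_both
    if conflicting or double_peaks:
        call = Call.MIXTURE
    elif m_a >= params.t_call and m_b == 0:
        call = Call.SPECIES_A
    elif m_b >= params.t_call and m_a == 0:
        call = Call.SPECIES_B
    else:
        call = Call.INCONCLUSIVE

    positive = False
    basis = ""
    if call is Call.SPECIES_A:
        if any(e.support is Support.A and e.unique_a for e in evidence):
            positive, basis = True, "unique_site"
        else:
            covered = len(evidence) - counts["n_missing"]
            if covered >= params.c_min and m_a == covered:
                positive, basis = True, "combination"
    elif call is Call.SPECIES_B:
        if any(e.support is Support.B and e.unique_b for e in evidence):
            positive, basis = True, "unique_site"

    called_species = {
        Call.SPECIES_A: profile.pair.species_a,
        Call.SPECIES_B: profile.pair.species_b,
    }.get(call)

    return IdentificationResult(
        sample_id=sample_id,
        call=call,
        called_species=called_species,
        positive_identification=positive,
        positive_basis=basis,
        mixture_conflicting_sites=conflicting and call is Call.MIXTURE,
        mixture_double_peaks=double_peaks and call is Call.MIXTURE,
        evidence=evidence,
        counts=counts,
        params=params,
    )


@dataclass(frozen=True)
class PerformanceSummary:
    """Confusion summary of identification calls against ground truth."""

    results: tuple[tuple[str, IdentificationResult], ...]  # (true_label, result)

    @property
    def n(self) -> int:
        return len(self.results)

    def _called_label(self, result: IdentificationResult) -> str:
        if result.call in (Call.SPECIES_A, Call.SPECIES_B):
            return result.called_species or result.call.value
        return result.call.value

    def confusion(self) -> pd.DataFrame:
        """Cross-tabulation of true label vs call (species names for calls)."""
        rows = [
            {"true_label": truth, "call": self._called_label(res)}
            for truth, res in self.results
        ]
        frame = pd.DataFrame(rows, columns=["true_label", "call"])
        if frame.empty:
            return frame
        return pd.crosstab(frame["true_label"], frame["call"])

    @property
    def n_correct(self) -> int:
        return sum(truth == self._called_label(res) for truth, res in self.results)

    def recall(self, label: str) -> float:
        relevant = [res for truth, res in self.results if truth == label]
        if not relevant:
            raise InputError(f"no queries with true label {label!r}")
        return sum(self._called_label(r) == label for r in relevant) / len(relevant)

    def false_positives(self, label: str) -> int:
        return sum(
            self._called_label(res) == label and truth != label
            for truth, res in self.results
        )


def simulate_decision_performance(
    labeled_queries: Iterable[tuple[Sequence[QuerySequence], str]],
    profile: DiagnosticProfile,
    params: IdentifyParams | None = None,
) -> PerformanceSummary:
    """Run :func:`identify_query` over truth-labelled queries and summarize.

    ``labeled_queries`` yields (queries-for-one-sample, true label) pairs;
    labels use species names, or ``"mixture"`` for chimeric material.
    """
    results = tuple(
        (truth, identify_query(queries, profile, params))
        for queries, truth in labeled_queries
    )
    return PerformanceSummary(results=results)
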