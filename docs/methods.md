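# Methods

## Diagnostic-site discovery

The discovery model is deliberately strict: a column distinguishes the focal
pair only as a **fixed difference** — every non-missing observation of each
focal species shows a single state, and the two states differ. Published
distinguishing-character tables report one state per species per position,
which presupposes fixation across the sampled accessions; a single
intraspecifically polymorphic accession therefore disqualifies a column
(conservative by design, and the monotone-degradation property tests rely on
it). Gaps (`-`), `N` and IUPAC ambiguity letters in *reference* rows are
missing data: reference panels are assumed to be clean Sanger consensus, so
an ambiguity code there signals a problem, not a character. Indel
differences are never reported as diagnostic sites.

Uniqueness is relative to the sampled roster: a focal state is *unique* iff
no non-focal species shows it at that column, otherwise *shared* with the
exact set that does. Because this depends on taxon sampling, every profile
records the per-marker species roster it was computed on. Sites are emitted
in ascending (marker, position) order, positions 1-based per marker.

A focal species with zero usable observations at a column yields no site
there ("no data", logged), never an error: partial reference coverage is
normal in herbarium-derived panels.

## Query identification

A query must already be in reference-alignment coordinates (same length as
the marker's alignment); alignment of raw reads is out of scope and keeps
the decision layer deterministic. Support at each diagnostic site comes
from IUPAC expansion of the observed character: only state A → supports A;
only B → supports B; both (e.g. `Y` over C/T) → supports both — the
within-site double-peak signature of mixed templates; neither → supports
neither; gap/`N` → missing (no evidence, *not* four-way ambiguity).

Decision rule, with counts m_A, m_B (one-sided supports) and m_both:

- **mixture** if (m_A ≥ t_mix and m_B ≥ t_mix) — conflicting fixed
  characters across sites — or m_both ≥ t_both — repeated double peaks.
  Both chimera signatures yield the same call; the result distinguishes
  them in `mixture_conflicting_sites` / `mixture_double_peaks`.
- else **species A** if m_A ≥ t_call and m_B = 0 (symmetrically for B);
- else **inconclusive**.

Defaults t_call = 3, t_mix = 2, t_both = 2, c_min = 4. No published numeric
rule exists for "how many characters suffice"; these are this package's
operational choices, exposed in `IdentifyParams`, echoed into every result,
and chosen so that a handful of concordant sites make a call while any two
conflicting sites already block one.

A species call is **positive** when at least one supporting site is unique
to the called species. Species A additionally qualifies through the
combination rule — every covered site supports A and at least c_min sites
are covered — because *E. arvense* has no unique *matK* site and its
identification rests on a combination of shared characters; *E. palustre*,
with unique sites in both markers, never needs this fallback.

Limitation: the "masking never promotes a call" intuition holds only for
queries without contrary evidence. Because a species call requires *zero*
opposing sites, masking the single opposing site of an otherwise one-sided
query can turn `inconclusive` into a call; with default thresholds this
requires the contrary evidence to be exactly one site. The property tests
therefore assert the monotone behaviour on conflict-free queries.

Mixture proportions are not estimated (quantification is what the TLC side
offers and the barcoding side lacks).

## Monophyly

With a declared outgroup, a tip set is monophyletic iff it is one side of
some edge bipartition — equivalent to forming a clade after rooting on the
outgroup and therefore invariant to how the input Newick is rooted. On an
explicitly rooted tree (`[&R]`) without an outgroup the descendant set of a
single node must equal the query set. Polytomies are hard: no soft-polytomy
resolution is attempted, so a set resolvable only by splitting a polytomy
is non-monophyletic (deterministic and conservative). Singleton species are
untestable and reported trivially monophyletic with an explicit flag.
Intruders of a non-monophyletic species are the foreign tips in the
smallest bipartition side containing its tips (excluding outgroup tips).
Bootstrap values on input trees are carried through but never interpreted;
tree inference itself is out of scope.

## TLC decision rules

Lanes are abstract tabular records, not plate images (published plates are
not machine-readable; the decision logic is the implementable content). A
zone is present when its relative intensity exceeds `presence_threshold`
(default 0.1; the monograph's criterion is visual and prints no number).
Positive *E. arvense* identification requires all four marker zones —
three of four fail. The foreign-matter comparison flags `above_limit` when
a greenish-blue zone exceeds the corresponding reference-lane zone; by
default a single exceeding zone suffices (`flag_on_any_zone`), since the
relevant zones co-occur across species in subgenus *Hippochaete* and
requiring both would be the laxer reading. The two greenish-blue zones only
ever *flag* possible adulteration — they never identify *E. palustre*,
whose TLC trait is shared with other horsetails. A reference lane missing
either zone invalidates the whole test (system suitability), surfaced as a
dedicated error and CLI exit code 3.

Lane classification is total: empty lane → `no_chromatogram`; four markers
plus no greenish-blue zones → `arvense`; four markers plus any greenish-blue
zone → `mixture_suspected`; anything else with bands →
`non_equisetum_pattern`.

## Synthetic data

The generator emulates the *study design*, not molecular evolution: each
column carries one invariant ancestral state and all diagnostic structure is
planted explicitly (focal states, sharing sets), after which intraspecific
polymorphism and missing data are injected at per-character rates.
Background columns are `A`; at a planted column species in a sharing set
receive the focal state and all remaining species the column's ancestral
state, chosen distinct from both focal states unless the site spec pins it.
Defaults: 15-species genus roster, 2 accessions per species, markers
*matK* (670 columns) and *trnH-psbA* (200 columns), polymorphism and
missing rates 0 — clean Sanger consensus panels, in which fixed differences
are fixed by construction. There is no substitution model, rate
heterogeneity or indel process; passing tests therefore demonstrate the
correctness of the decision logic under planted truth, not robustness to
realistic sequence evolution, alignment error or lineage sorting.

`table1_fixture` plants the published 36-site diagnostic structure (25
*matK*, 11 *trnH-psbA*) with its printed positions, states and sharing
sets. The printed table lists only one focal state per site; the other
focal species receives a fixed alternative state equal to the column's
ancestral state, so that the unlisted side is shared with the rest of the
roster and the unique/shared counts come out exactly as printed. One known
source inconsistency is resolved in favour of the tabulated values: the
prose summary elsewhere counts one *trnH-psbA* site unique to
*E. palustre*, while the table itself lists two (124, 200); the fixture
follows the table. A spelling variant of *E. fluviatile* ("fluvatile") in
the same table is normalized to the canonical name.

Tree simulation arranges each species' accessions as a clade inside a
randomized species tree shaped like the genus phylogeny (basal species
sister to the two seven-species subgeneric clades, fern outgroups outside).
Paraphyly is planted by pruning one accession and regrafting it as sister
to a host species' clade in the other subgenus — this breaks exactly the
donor's monophyly and provably leaves the host's clade intact. TLC lane
simulation draws intensities from ranges that realize the requested class
(e.g. greenish-blue zones at 1.1–1.6 relative intensity for
`mixture_suspected`), closing the loop with the classifier.

All generators are reproducible from a seed (per-marker RNG streams keyed
by seed and marker name, so adding a marker does not shift others).

## Numerical and design choices

- Positions are 1-based per marker everywhere (types, TSV/JSON, CLI).
- `U` → `T` and upper-casing on ingest; plastid markers are reported as DNA.
- Equality comparisons are exact throughout; there is no floating-point
  tolerance anywhere in the decision logic (TLC intensities compare with
  strict `>`, so a test zone exactly as intense as the reference is within
  limit, matching the "may not be more intense" phrasing).
- Bipartition sides are cached per tree object; trees are treated as
  immutable after construction.
- Problem sizes used by the test suite (brute-force equivalence on 1000
  random panels of ≤10 species × ≤6 accessions × ≤200 columns; exhaustive
  tree sweep to 8 tips, 11,464 topologies) were chosen as the largest sizes
  at which the naive oracles remain exhaustive and the whole suite stays
  interactive (well under a minute).

## Known limitations

- Reference ambiguity codes are discarded rather than partially counted; a
  panel with genuinely polymorphic consensus letters would lose those
  columns.
- Identification thresholds are heuristics, not calibrated error rates; no
  statistical support (e.g. bootstrap over accessions) is attached to
  diagnostic sites.
- Sharing sets — and hence uniqueness — are only as good as the roster:
  an unsampled congener could carry a "unique" state.
- TLC hue and position semantics live in the controlled zone vocabulary;
  densitometry from images is out of scope (`relative_front` is carried for
  future use).
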