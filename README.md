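# equicheck

Molecular authentication of common horsetail (*Equisetum arvense* L.) herbal
material. *E. arvense* products are prone to adulteration with the closely
related *E. palustre* L., which produces the toxic pyridine alkaloid
palustrine; processed material cannot be told apart morphologically. This
package implements the two laboratory decision procedures used for that
quality-control problem, for analysts and bioinformaticians working on herbal
product authentication:

1. **Character-based DNA barcoding.** Given a genus-wide multiple sequence
   alignment for the plastid barcode markers *matK* and *trnH-psbA*, find
   every *fixed difference* between the two focal species — columns where
   all sampled accessions of species A show one nucleotide, all accessions
   of species B another. Each focal state is classified as **unique**
   (no other sampled *Equisetum* species carries it) or **shared** with a
   named set of non-focal species. Query sequences (e.g. amplified from a
   commercial tea) are then read at these diagnostic positions through the
   IUPAC ambiguity alphabet, so that a `Y` over a C/T difference — the
   double peak of a mixed-template Sanger chromatogram — counts as evidence
   for *both* species, and chimeric/mixed material is flagged.
2. **The European Pharmacopoeia TLC test (Identification C).** Rule-based
   classification of thin-layer-chromatography lane records: positive
   *E. arvense* identification requires the combination of all four marker
   zones, and any greenish-blue kaempferol-glucoside zone just above the
   application line may not be more intense than the corresponding zone of
   the *E. palustre* reference lane (foreign-matter flag).

Supporting machinery: species-monophyly assessment on Newick trees (the
species-delimitation check behind barcoding reference panels), and a
synthetic-data generator that plants diagnostic sites, chimeric queries,
paraphyletic species and TLC lane classes with ground truth — including an
exact reconstruction of the published two-marker diagnostic table.

## The statistic at the core

For focal pair (A, B), alignment column *j* is diagnostic iff

    |states_A(j)| = 1,  |states_B(j)| = 1,  states_A(j) ≠ states_B(j)

where `states_S(j)` is the set of non-missing nucleotides observed across
all accessions of species S (gaps, `N` and ambiguity codes are missing
data). The focal state `a_j` is *unique* iff no non-focal species' observed
state set at *j* contains `a_j`; otherwise it is *shared* with exactly the
set of species that do. Query support at a diagnostic site is computed by
IUPAC expansion of the observed character; calls are made from the support
counts (m_A, m_B, m_both) with declared thresholds (see `docs/methods.md`).

## Worked example

```sh
equicheck simulate --preset table1 -o sim
equicheck profile --pair "Equisetum arvense,E. palustre" \
    --aln sim/matK.fasta --aln sim/trnH-psbA.fasta -o prof
```

prints

```
total diagnostic sites: 36
  matK: 25 sites (unique Equisetum arvense: 0, unique Equisetum palustre: 5)
  trnH-psbA: 11 sites (unique Equisetum arvense: 1, unique Equisetum palustre: 2)
```

i.e. 36 substitutions distinguish the two species across the two markers;
*E. palustre* has five unique *matK* sites (positions 273, 311, 391, 575,
594) and two unique *trnH-psbA* sites (124, 200), allowing confident
positive identification, while *E. arvense* has a single unique site
(*trnH-psbA* 193) and is otherwise identified by its *combination* of
shared characters. (`E. palustre` in `--pair` is expanded and spelling
variants such as `E. fluvatile` are normalized automatically.)

Identifying a query (here a pure *E. palustre* sequence extracted from the
simulated alignment, header `productX|matK`):

```sh
equicheck identify --profile prof/profile.json --query query.fasta -o ident
# productX: species_b (Equisetum palustre) [positive]
```

A chimeric query — conflicting fixed characters across sites, or IUPAC
double-peak codes within sites — is called `mixture`, reproducing the
signature of an adulterated product. The same library API is available in
Python (`equicheck.build_profile`, `equicheck.identify_query`, ...), and
`equicheck monophyly` / `equicheck tlc` cover the tree and chromatography
sides.

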