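# Methods

This note records the models, parameter choices and numerical conventions
behind each analysis stage, what the synthetic-data generator does and does
not emulate, and the design decisions taken where the procedure was
genuinely open.

## Ortholog clustering

Protein pairs are aligned with exact affine-gap local dynamic programming
(BLOSUM62; a gap of length *k* costs 11 + *k*, the blastp default
convention). Per pair we record:

* **identity** — identical matches divided by aligned columns *including*
  gap columns (the blastp report convention);
* **coverage** — the aligned span on the *longer* of the two sequences
  divided by that sequence's length, evaluated on the single best-scoring
  local alignment;
* **e-value** — the Karlin–Altschul approximation
  *E = K·m·n·e^(−λS)* with the gapped BLOSUM62 constants λ = 0.267,
  K = 0.041 and *n* the total residue count of the run. Exact parity with a
  heuristic seeded search is not attempted: at the thresholds used the
  e-value filter is loose and the identity/coverage thresholds dominate.

An edge requires every threshold to pass as a strict inequality
(*E* < 10⁻³, identity > 0.78, coverage > 0.76) in either direction of the
pair — single linkage needs any qualifying hit, not a reciprocal best hit.
Groups are connected components with deterministic naming (lexicographic
smallest member). A shared-5-mer prefilter (≥ 8 common 5-mers) prunes the
quadratic alignment stage; at qualifying identity levels homologous pairs
share conserved 5-mers in abundance, and an `exhaustive=True` mode disables
the filter (the test suite verifies filter-on equals brute force on mixed
related/unrelated sets).

In the A/B/C/D partition, "absent" means *no intact member*: pseudogene
fragments never count as presence, and are instead surfaced by the
fragment-rescue cross-reference (a specific group is *rescued* when at
least one opposite-subspecies strain carries a detected fragment whose
best-hit protein belongs to the group).

## Pseudogene-fragment detection

The detection procedure takes annotated CDS at face value and asks whether
each one is the remnant of a longer ancestral gene:

1. six-frame translated search of the CDS against a protein database; ties
   break by score then lexicographic protein id. For a self-contained
   multi-strain run the database is the union of the *other* strains'
   intact proteins, which preserves the procedure without any external
   database dependency.
2. length-anomaly trigger: |hit − CDS| / CDS > `length_tol` (default 0.10,
   strict; the denominator is the CDS-encoded protein because the CDS is
   the query). Only anomalous CDS proceed — a deliberate, literal reading:
   a frameshift that splits a gene into two normal-looking CDS does not
   trip the trigger and is not called.
3. back-alignment of the hit protein against the CDS ± `context_window`
   (default 3000 bp, sized to span multi-fragment pseudogenes while
   bounding cost) in all six frames of the region, by exact local DP
   (deterministic; no seeded heuristics). Segments must score
   ≥ `min_segment_bits` (30 bits, comfortably above the random expectation
   for a few-kb region). Nested hits are discarded unless they add
   ≥ `min_novel_aa` (20) residues of novel protein coverage — plain overlap
   is not grounds for discarding, because the two local alignments
   bracketing a lesion overrun it by a fuzzy margin on both sides.
4. chaining: segments collinear on the protein chain when their genomic
   gap is ≤ `chain_max_gap` (60 bp), with negative gaps allowed up to
   3 nt per overlapping residue. A frame change between adjacent chained
   segments is recorded as a frameshift at the midpoint of the junction;
   stop codons inside aligned segments are internal stops. The CDS's own
   terminal stop counts as internal only when the alignment extends past
   the CDS 3' end (i.e. the stop sits inside the reconstructed gene, which
   is exactly the premature-stop situation).
5. verdict: *pseudogene_fragment* iff length anomaly ∧ chained genomic
   extent exceeds the CDS interval ∧ (≥ 1 frameshift ∨ internal stop).

Translation uses the bacterial code (table 11). 3'-truncated remnants leave
neither a frameshift nor an internal stop in the genome; the procedure
cannot see them and the package does not claim recall over that class.

## Genome statistics

GC excludes N from the denominator; IUPAC codes other than N are rejected
outright rather than silently skipped, because the reports are quoted to
one decimal. Report values round half-up to one decimal; raw fractions are
kept internally. Coding density is the union of non-pseudogene CDS
intervals. The largest IS-free interval is measured between element
boundaries (end of one to start of the next); a midpoint mode exists. On
circular genomes the wrap-around gap is considered, so the circular maximum
can never be smaller than the linear one.

## Phylogenetics

Multiple alignment delegates to MAFFT (FFT-NS-2, single thread) with input
canonicalized to sorted label order, making results order-invariant and
deterministic. Distances use pairwise deletion of gap columns; p-distance
is the default (the simplest adequate model for the low divergences
involved), Kimura-2P by flag, with undefined K2P entries flagged as missing
rather than fabricated. Neighbor joining is implemented directly: ties in
the Q-matrix break on the lexicographically smallest pair of cluster
labels; a negative branch length is clamped to zero with the deficit moved
to the sister edge. NJ reconstructs additive matrices exactly (topology and
branch lengths), which the tests exercise over random trees. Bootstrap
resamples alignment columns with replacement; support is the percentage of
replicate trees containing each internal bipartition of the full-data tree.

MLST concatenates seven housekeeping loci in scheme order; strains missing
a locus are excluded with a warning. Locus boundaries are data (the scheme
maps locus names to annotation gene ids); the synthetic dataset ships its
own scheme. Diagnostic-site coordinates are reported on the alignment
(1-based); no projection to an external numbering is attempted. The
Robinson–Foulds incongruence flag considers only bipartitions supported at
≥ 70 (unlabeled edges count as supported), so weak conflicts do not raise a
horizontal-transfer signal.

## Pathway phenotypes

Pathway definitions are data, not code: an editable YAML maps each
substrate to required gene groups (each an OR of alternatives, transporters
flagged). The shipped definitions for the 14-substrate panel are
literature-style but explicitly non-authoritative. A fragmented gene
("pseudo") never satisfies a group. Discrimination requires uniform "+" in
every tested strain of one subspecies and uniform "−" in the other;
untested cells are excluded, never imputed. Concordance between predicted
and observed matrices is reported, not asserted.

## Synthetic-data generator

The generator emulates the study design the analyses target: a shared
ancestral pangenome (default 160 genes of 312–960 nt at GC 0.50, fixed
150 bp intergenic spacers); two clades of five strains; clade-specific
(12/8) and partially lost (10/10) gene sets; per-strain pseudogenization of
four core genes; some clade-specific genes pseudogenized rather than lost
in the opposite clade (5/3, the planted fragment-rescue truth); a
four-gene HGT island at GC 0.34 in three strains of one clade; three IS
families inserted only into intergenic spacers at different per-clade loads
(12 vs 4); substitution divergence of 2% root→clade and 1% clade→strain.
Seven core genes double as the MLST loci and are spared pseudogenization.

Choices that make the planted truth authoritative rather than approximate:

* **Single-event lesions.** One frameshift (±1 nt), one in-frame stop
  substitution, or one 3'-truncation per pseudogenized gene, drawn in the
  central 30–70% of the coding region — remnant fragments substantially
  shorter than the ancestral protein, as the length trigger presumes.
* **Hidden off-frame stops.** Ancestral genes carry stop codons in both
  shifted reading frames at least every ~15 codons (real coding sequences
  are similarly enriched — the "ambush" effect), so a frameshifted ORF
  terminates close to the lesion instead of free-running; combined with
  central lesion placement this keeps every frameshift remnant inside the
  10% length slack. Composition is kept on target by inverting the
  stop-codon rejection bias analytically and choosing GC-poor or GC-rich
  stop cassettes against the running composition.
* **Frame-preserving substitutions.** Point substitutions never create or
  destroy an in-frame stop, never touch the start codon, and never destroy
  a hidden off-frame stop, so the planted intact/pseudogene status stays
  exact at any divergence setting.
* **Coordinates** are 0-based half-open internally and converted to GFF3's
  1-based inclusive convention only at emission.

What the generator does **not** emulate — hence what passing tests do not
show about real data: no recombination, no codon-usage or GC3 selection
(synthetic GC3 sits at the genomic GC, unlike the elevated GC3 of genomes
under directional pressure), no transposition dynamics or nested IS, no
assembly gaps or annotation error, uniform unweighted substitutions
(transition/transversion unweighted, so K2P ≈ p at these divergences), and
pseudogenes always annotated as a single remnant CDS. Recall claims for the
pseudogene caller are therefore claims about single-lesion, centrally
placed decay events with the ancestral protein present in the database;
real pseudogenes with multiple lesions, eroded termini or no surviving
homolog are harder, and real procedures also miss near-full-length
remnants (the length trigger is blind to them by construction).

## Problem sizes

The shipped study conditions (10 strains × ~125 kb, ~1 400 proteins,
~160 ortholog groups) are a desk-scale model of a ten-genome bacterial
comparison, chosen so the full pipeline — simulation, all-vs-all
clustering, per-strain pseudogene scans, MLST with bootstrap — completes in
about a minute while keeping every per-gene decision individually
checkable against the truth table. Oracle suites run at n ≤ 100 (graphs),
n ≤ 12 (trees) and ≤ 50 aa (alignment DP pairs).
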