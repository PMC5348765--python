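# Methods

`retromine` implements a mining-and-classification pipeline for
retrotransposons that carry an archaeal-type RNase H (aRNH) domain, the
hallmark of several convergently evolved element lineages in oomycete and
plant genomes, together with a synthetic-genome generator that makes every
stage of the pipeline testable at desk scale. This note records the models,
the parameters that matter, and the design choices made where the design
was genuinely open.

## Domain model and search

Protein domain families are modelled as position-specific profiles with
match, insert and delete states (a Plan7-style local architecture):

* **Match states** are alignment columns whose gap fraction is below
  `gap_fraction_cutoff` (default 0.5). Emission probabilities per state are
  `(counts + pseudocount × background) / (n + pseudocount)` with a single
  pseudocount weight (default 1.0), stored as log-odds in bits against the
  background.
* **Background** is the amino-acid distribution implied by the standard
  genetic code on compositionally uniform DNA (each of the 61 sense codons
  contributing equally). This is the correct null model for scoring
  six-frame translations of random nucleotide background, which is exactly
  what the genome scanner does.
* **Transitions** use uniform global parameters: insert/delete open 0.01,
  insert/delete extend 0.4 (configurable at profile construction). Inserts
  emit at background (0 bits). Entry is uniform over match states
  (−log₂ k bits); exit from any match state is free.
* **Stops and unknowns.** `*` and `X` emit at background, i.e. they are
  score-neutral inside a hit. Degenerate genomic copies accumulate in-frame
  stops, and the scan is deliberately stop-agnostic — open-reading-frame
  logic lives entirely in the annotation stage.

Decoding is local Viterbi over match/insert/delete states. The production
decoder is a numba-compiled dynamic program with O(k) rolling memory that
tracks the start coordinate of the best path per cell; reported hits are
re-decoded densely over their own span to obtain the full state path (used
by the catalytic-residue audit). Multiple hits per sequence are found
best-first: the best hit's span is excluded and the flanking segments are
searched recursively, which is exactly equivalent to masking because no
local path can cross an excluded residue. Ties are broken by score, then
smaller start, then shorter span, so hit lists are deterministic. A
brute-force path enumerator (exponential, used only on tiny instances)
serves as an independent oracle in the tests.

**Score threshold.** Per-profile thresholds are calibrated at build time to
`max(15, 0.25 × S_max)` bits, where `S_max` is the profile's maximum
attainable local score (Kadane over per-state best emissions chained with
match-match transitions). A fixed low threshold is unusable at genome
scale: with ~10⁶ translated positions per 500 kb genome and ~150 states,
random local excursions routinely exceed 15–20 bits
(Karlin–Altschul-style search-space growth). A quarter of the maximum
score sits far above the random-excursion regime yet far below the score
of heavily diverged true copies — even a copy split in half by a
frameshift retains ≈50% of `S_max` per fragment. The 15-bit floor only
binds for very small profiles. Thresholds are configurable and stored in
the profile's plain-text serialization.

## Mining algorithm

Per genome, in four steps:

1. **Anchor.** Scan all six reading frames with the aRNH profile;
   coordinate maps convert protein hits back to forward-strand nucleotide
   intervals. Hits overlapping >50% reciprocally across frames collapse to
   the best-scoring one, and anchors duplicated across frames are merged
   into a single locus (best anchor kept).
2. **Expand.** Each anchor is widened by up to 10,000 nt on both sides,
   clamped at contig edges.
3. **Screen.** Each window is scanned with the LTR-RT and non-LTR-RT
   reverse-transcriptase profiles. No RT hit ⇒ `INDIVIDUAL_RNH`; hits from
   one profile ⇒ that class; hits from both ⇒ the class of the best hit,
   with exact ties resolved to `LTR_RT` and logged.
4. **Group.** RT-positive windows are assigned to Chronos, Archon, L1 or
   Utopia by local protein alignment (BLOSUM62, gap open −11 / extend −1,
   via Biopython's pairwise aligner) of the window's six frame
   translations against per-group reference pol/ORF2 proteins. The best
   group wins when alignment identity ≥ 0.35 and the best/second-best
   score ratio ≥ 1.2. Chronos and Archon share most of their pol, so the
   ratio for that pair is measured against the best group outside the
   pair, and chromodomain presence in the window decides between the two
   (CHD ⇒ Chronos). Aligning frame translations rather than ORFs makes the
   assignment robust to frameshifts: a broken copy still carries a long
   alignable segment in one frame.

Fungi/Metazoa-type RNase H genes are mined identically with the fmRNH
profile and 1 kb flanks, fixed to `INDIVIDUAL_RNH`/`fmRNH`.

The count table reports per-genome counts with RT-associated groups
(Chronos, Archon, L1, Utopia) in one column block and individual-RNH
categories (aRNH clades, fmRNH) in another, zeros rendered as `-` in the
TSV. Each merged locus counts as one element; no cross-copy clustering of
distinct insertions into families is attempted (no criteria exist for it),
and nested or adjacent elements sharing one window stay a single locus —
both are known limitations.

## Structural annotation

* **ORFs**: ATG-initiated, to the first in-frame stop, both strands,
  minimum protein length 100 aa (configurable). ORFs truncated by the
  window edge (no stop) are kept, since mining windows clip elements.
* **LTR pairs**: local nucleotide self-alignment (match 2, mismatch −3,
  gap open −5, extend −2) of the upstream versus downstream flanks of the
  ORF region, flanks capped at 5 kb. A pair is reported at aligned length
  ≥ 100 nt and identity ≥ 0.8.
* **CCHC zinc knuckle**: the pattern C-x(2)-C-x(4)-H-x(4)-C, spacings
  configurable; overlapping matches all reported. A knuckle inside an
  already-annotated domain is not reported as a separate architecture unit.
* **Catalytic audit**: each RNase H profile declares the match states of
  the five active-site positions; the audit reads the target residues
  aligned to those states off the Viterbi trace (`-` for deletions) and
  compares them to the canonical D-E-D-R/H-D pattern — arginine at the
  semiconservative site in aRNH, histidine in fmRNH, unconstrained in the
  Ty3/Gypsy gRNH (whose conserved check is D-E-D-·-D).
* **Architecture strings** order domain hits by protein coordinate;
  "CHD next to the integrase" is operationalized as CHD starting within
  300 residues after the INT end.

## Phylogenetics

Maximum-likelihood/Bayesian inference is out of scope; the package makes
distance-based claims only, which is sufficient for clade membership of
simulated families:

* Poisson-corrected distances `d = −ln(1−p)` with pairwise deletion;
  saturated pairs capped at d = 10 (logged).
* Saitou–Nei neighbor joining, deterministic: equal-Q candidate pairs are
  resolved by the lexicographically smallest label pair (internal nodes
  inherit the smallest leaf label of their cluster); negative branch-length
  estimates clamp to zero.
* Column-resampling bootstrap; support = % of replicates containing each
  original bipartition.
* Multiple alignments are built by a deterministic center-star procedure
  (align everything globally to the highest-total-score sequence and merge
  gaps on center coordinates). This is adequate for the
  substitution-dominated families the simulator produces and was chosen
  over guide-tree progressive alignment for simplicity and reproducibility;
  it is not a general-purpose aligner.
* **Individual-aRNH clades.** Individuals are placed on an NJ tree with
  the per-group retrotransposon aRNH references. The smallest clade around
  an individual with bootstrap support ≥ 60 that contains references is
  decisive: references of a single group ⇒ the individual is called a
  remnant of that group; references of several groups ⇒ no significant
  clustering. Unclustered individuals found novel clades, pooled when two
  individuals are mutually closer than either is to any reference. The
  support cutoff of 60/100 mirrors the bootstrap-highlight convention used
  in this literature and is configurable.

## Synthetic data

The generator is the package's ground-truth instrument, not a fixture. All
protein templates are synthetic, generated once from a fixed internal seed
with the canonical motifs embedded (D-E-D-R-D for aRNH, D-E-D-H-D for
fmRNH, a CCHC knuckle, a YxDD-like RT motif), so the audit operations have
exact expectations and nothing derives from licensed repeat databases.

* **Element architectures** follow the group schemes: Chronos = LTR +
  PR–RT–gRH–aRH–IN–CHD; Archon = LTR + PR–RT–gRH–aRH–IN; L1 = ORF1 +
  ORF2(EN–RT–CCHC–aRH) with the aRNH C-terminal; Utopia = RT–aRH–RLE in a
  single ORF (the domain order within the Utopia ORF is an assumption of
  the generator; published schematics do not fix it). Cellular genes are
  a lone aRNH or fmRNH ORF.
* **Per-group variants.** Each group carries its own aRNH and RT variants,
  derived once from the base templates at ~25% amino-acid divergence with
  the active site protected. This gives the simulation the per-group clade
  structure (distinct aRNH clades per element group, a separate cellular
  aRNH lineage) that the phylogenetic stage is meant to recover; without
  it, remnant assignment would be undefined.
* **Copies** receive uniform substitutions at the stated nucleotide
  divergence and optional 1–3 nt indels at a per-site rate (default 0 in
  the standard study conditions; indel robustness is exercised separately
  because an indel inside the anchor domain can split one element into two
  reported loci — a known limitation of the anchor-overlap merge rule).
  Catalytic codons are protected by default so audits on recovered copies
  are interpretable; targeted active-site knockouts are available for
  building degenerate-gRNH cases.
* **Genomes** are i.i.d. background at a chosen GC content with elements
  inserted at uniform positions on random strands, never overlapping, with
  a 12 kb minimum spacing. The spacing exceeds the 10 kb mining half-width
  by design: it keeps every planted record's classification label
  well-defined (a cellular RNase H gene closer than 10 kb to a
  retrotransposon would legitimately have RT in its window, making the
  "truth" ambiguous). Same seed ⇒ byte-identical FASTA and GFF.
* **Seed alignments** for every profile are the family template plus nine
  substitution-only copies at 8% amino-acid divergence — trivially aligned,
  self-contained, and sufficient for the detection task. Real profiles can
  be substituted through the same aligned-FASTA reader.

What the generator does **not** emulate: realistic base composition and
codon usage, solo-LTR formation, nested/truncated insertions (switchable
but off by default), recombination, and sequence families with genuine
insertion histories. Passing recovery tests therefore demonstrates the
pipeline's correctness under controlled degeneracy, not its performance on
real assemblies, where repeat families are denser, older and interleaved.

## Evaluation

Predictions match planted truth by reciprocal interval overlap ≥ 50%,
greedy one-to-one by decreasing overlap. The pipeline feeds this rule
anchor-level intervals — the predicted aRNH/fmRNH hit against the planted
RNH-domain sub-feature — because a ±10 kb window against a ~5 kb element
can never satisfy a reciprocal-overlap criterion; the anchor is the
quantity the miner actually localizes. Precision with zero predictions is
reported as 1.0 with an explicit flag. Classification accuracy is the
fraction of matched pairs whose labels agree.

## Problem sizes

The standard study conditions used by the acceptance checks are five
500 kb genomes carrying 15 copies per element group (3 per genome) at 5%
nucleotide divergence plus one cellular aRNH and one fmRNH gene per
genome — 70 planted records in total; component checks use 200 random
Viterbi-oracle instances, 20 random additive matrices (6–12 leaves), and
100 bootstrap replicates. These sizes exercise every code path at full
fidelity while keeping a complete run in the minutes range on one CPU.
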