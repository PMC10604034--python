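# Methods

This note documents the models, conventions and numerical choices behind
each stage, what the synthetic generator does and does not emulate, and the
known limitations.

## Coordinates, vocabulary and gene order

All public coordinates are 1-based inclusive, matching published annotation
tables; 0-based slicing exists only inside the I/O layer.  Gene labels use
the MITOS-style controlled vocabulary (`nad1..6`, `nad4l`, `cox1..3`,
`atp6/8`, `cob`, `rrnS/rrnL`, `trnX`, `CR`), with isoacceptor tags for the
duplicated leucine and serine tRNAs: `trnL2` (UUR) precedes `trnL1` (CUN)
and `trnS2` (UCN) precedes `trnS1` (AGY) in the canonical arrangement.
Annotation tables often print codon-family triplets rather than literal
anticodons in their "anticodon" column; the loader stores the triplet
verbatim and resolves isoacceptors from it, falling back to genome order.
The built-in reference order is the canonical vertebrate/teleost
arrangement (37 genes + CR, nine features on the light strand).

## Architecture accounting

A junction's gap is `start(downstream) − end(upstream) − 1` in annotation
order.  The chain is linear by default — published tables attach intergenic
counts to the upstream row and do not count the final CR→trnF closure — with
the circular closing junction available opt-in (computed modulo genome
length).  Strand counts exclude the control region, which is not a gene.
Ties for longest spacer/overlap break to the first occurrence in annotation
order so reports are deterministic.  Gene-order comparison uses signed
circular adjacency sets (an adjacency matches its jointly-inverted mirror);
the breakpoint distance is the number of adjacencies of one order absent
from the other, which is symmetric and zero exactly on identical circular
orders.  Genes missing from one genome are reported in a `missing_genes`
field rather than raised.

## Composition and codons

Partition composition is computed on the deposited heavy (plus) strand for
all partitions — light-strand genes contribute their plus-strand substring —
because that is how whole-sequence partition statistics are conventionally
produced; codon classification alone uses sense strands.  N's are excluded
from percentage denominators.  Rounding is half-up, applied only at the
reporting boundary: two decimals for percentages, three for skews.  Skews
are scale-invariant (counts or percentages give the same value) and an
all-AT or all-GC partition yields an undefined-skew null, never 0.

Stop codons are classified purely from sense length mod 3: remainder 0
reports the final triplet, remainder 1 reports `X--`, remainder 2 `XY-`.
The vertebrate mitochondrial genetic code is the fixed context (stops TAA,
TAG, AGA, AGG); start codons are reported verbatim with no alternative-start
remapping.

### Documented discrepancies in the packaged published tables

The shipped *P. belcheri* tables are internally inconsistent in ways this
package deliberately does not "fix"; its own outputs are self-consistent
with the printed coordinates:

* genome length: 16,747 bp (annotation table, composition table) vs a
  16,739 bp mention elsewhere in the same publication — the loader keeps
  16,747;
* PCG total: coordinate sum 11,413 bp vs the printed summary cell 11,427;
* rRNA total: 961 + 1,702 = 2,663 bp vs the printed 2,689;
* control region: 15,725..16,747 = 1,023 bp vs the printed 1,015;
* three PCGs (atp6, cox3, nad3) print incomplete stops although their
  printed lengths are divisible by 3; classification from length mod 3
  reports their final triplet instead.

None of these cells is used as a numeric target; tests assert the
coordinate-derived values.

## tRNA folding

Folding is a deterministic search over a constrained cloverleaf template,
not free-energy minimization: the claims made of mitogenome tRNAs are
arm-level (canonical cloverleaf vs a missing DHU arm; Watson-Crick vs G:T
wobble pairing), and a template search is exactly checkable by exhaustive
enumeration.  The grid: acceptor stem 6–7 bp pairing the termini inward;
then, 5′→3′, a D hairpin (stem 3–4, loop 3–9), an anticodon hairpin (stem
4–5, loop 5/7/9 with the anticodon centered) and a T hairpin (stem 4–5,
loop 3–9), separated by linkers of 0–3 nt (0–7 nt for the variable region
between the anticodon and T arms).  Pairs score WC = 2, wobble = 1,
mismatch = 0; the maximal-score structure wins, with ties broken toward a
longer acceptor stem, more WC pairs, then the 5′-most D arm.  An arm whose
best stem keeps fewer than two legal pairs is reported missing (D and/or
T); no acceptor stem of at least four pairs is a fold failure.  An
anticodon hint (from the annotation) constrains the anticodon-loop center
and always wins over scanning; if the hint never matches a loop window the
fold falls back to the unconstrained scan.

## Control region

The repeat scanner compares `seq[i]` with `seq[i+p]` for each candidate
period p, merges exact-match runs greedily while the merged identity stays
at or above the threshold, and emits maximal regions with at least the
requested (fractional) copy number.  The consensus is the column-majority
string; reported identity is the fraction of positions matching the
consensus, and every emitted record re-satisfies its own thresholds
(self-audit).  Overlapping records of one locus collapse to the
highest-identity, smallest-period representative.  Defaults: identity 0.9,
2.0 copies.  This is intentionally not a probabilistic aligner in the style
of Tandem Repeats Finder; at control-region scale (~1 kb) the deterministic
scan is exact and reproducible.

CSB detection is best ungapped local alignment of each library motif
(match +1 / mismatch −1), called present at score ≥ 0.5·len (75% identity).
No consensus CSB motifs were available for this genus, so the shipped
library is a synthetic, clearly-labelled, editable FASTA with block lengths
27/36/51/35 (CSB-D/I/II/III) built around canonical vertebrate cores (the
CSB-II poly-C tract etc.); calls on real data are explicitly
library-dependent.  Control-region boundaries come from the annotation,
never re-inference.

## Phylogenetics and dating

* **K2P** — d = −½·ln((1−2P−Q)·√(1−2Q)) with transition/transversion
  proportions P, Q over pairwise-deleted sites (gap/N columns dropped per
  pair, the common distance-tool default); saturation returns an invalid
  flag with P and Q still reported, and the delta-method standard error
  accompanies every valid estimate.
* **Concatenation** — genes must be present for every taxon (no
  auto-gapping); the partition map records 1-based column spans.
* **NJ** — Saitou–Nei agglomeration, exact on additive matrices; negative
  branch lengths are clamped to zero with a warning.  Implemented
  in-package (the clamping and small-n error semantics are part of the
  contract) and cross-checked against dendropy's NJ in the test suite.
* **Likelihood** — Felsenstein pruning over compressed site patterns with a
  reusable engine (alignment encoded once; transition matrices from the
  cached symmetric eigendecomposition of the reversible rate matrix, which
  is normalized to one expected substitution/site).  Discrete-gamma rate
  variation uses k = 4 mean-per-category rates by default and averages site
  likelihoods over categories.
* **Model ranking** — BIC = p·ln(n_sites) − 2·lnL over {JC, K2P, HKY, GTR}
  × {+G}; p counts free model parameters (0/1/4/8, +1 for α) plus branch
  lengths.  Frequencies are empirical for HKY/GTR; exchangeabilities and α
  are optimized by Nelder–Mead on a log scale interleaved with
  coordinate-ascent branch-length optimization (bounded golden-section per
  branch).  A non-converged optimizer flags the fit but the model is still
  ranked.  The proportion-of-invariant-sites term is deliberately excluded
  from the candidate set: its well-known identifiability interplay with +G
  makes the ranking unstable, and +G alone spans the use case.
* **Dating** — the outgroup tip roots the topology and is then removed;
  relative node heights are computed tips→root by recursive rate averaging
  (each child lineage proposes `height(child) + branch`; the node takes the
  mean, clamped to keep ages monotone).  A single point calibration fixes
  the time scale; several point calibrations combine by least squares and
  raise a conflict error when no positive scale fits each within 10%;
  interval calibrations constrain the feasible scale range.  This is a
  simplified relative-rate scheme in the spirit of RelTime, not a
  reimplementation of its variance machinery; uncertainty comes from a
  seeded nonparametric site bootstrap (100 replicates by default) of the
  K2P→NJ→dating pipeline.  Relative heights are invariant to uniform
  branch-length scaling up to the calibration rescale.

## Synthetic data generator

`GenomeSpec.from_table` clones the packaged published coordinates (16,747
bp, real overlaps and spacers); `GenomeSpec.compact` builds an overlap-free
genome in canonical order (default 5 bp spacers, 300/303 bp PCGs, 70 bp
tRNAs, 400 bp rRNAs, 700 bp CR, total 7,132 bp).  Defaults are the study
conditions of the packaged genome: per-partition base frequencies from the
published composition table, the published 15 wobble-containing / 7 pure-WC
tRNA split, a DHU-less trnS1, a 72-bp × 2.5-copy control-region repeat, and
verbatim CSB motifs (mismatch counts configurable).

Features are written in annotation order onto the circular buffer.  At
overlapping coordinates the earlier feature's bases are pinned; the later
feature's achieved codons are recorded in the ground truth together with
the conflict positions (the published table itself contains junctions, e.g.
nad4l/nad4, whose printed codons are mutually unsatisfiable).  PCG
interiors are codon-structured with no in-frame sense-strand stops.
Designed tRNAs use a 7/4/5/5 arm template with unpairable {A,C} loops and
linkers, planted wobble pairs in the T stem, and a design-and-verify loop:
each candidate is folded back and redrawn (deterministically) unless the
fold recovers the designed structure exactly, so ground truth and folder
output agree for every seed.  Randomness is one seed per spec with
stage-local sub-generators keyed by (seed, feature name), so adding or
removing a stage never perturbs the other features' draws; equal seeds give
byte-identical genomes.

What the generator does *not* emulate: sequencing error and read-level
artifacts, realistic rRNA secondary structure, codon usage bias and
selection, among-gene rate heterogeneity in the evolved alignments, indels
(all simulated homologs are gapless), and recombination (none in animal
mitochondria).  Passing tests therefore demonstrate correctness of the
measurement machinery on data matching these idealizations, not robustness
to annotation error or alignment artifacts in real mitogenomes.

Sequence evolution draws the root from the model's stationary frequencies
and evolves each branch by the model's transition probabilities; with +G a
site keeps one gamma category across the whole tree.  Clock-like trees are
generated by recursive random splitting (ultrametric by construction) and
rate noise multiplies each branch by an i.i.d. lognormal(0, σ) factor.

## Problem sizes and tolerances used in the checks

The statistical checks run at sizes chosen to make their expected behavior
sharp on one CPU: K2P at 10 kb (estimator within 3 SE of d = 0.15); NJ
recovery on 8 taxa × 5 kb; BIC designs at 10 kb with 4–5 taxa, 20 seeded
replicates each (majority-correct criterion; both designs select the
generating model in 20/20 replicates at the shipped seeds); dating accuracy
on 12-taxon trees under σ = 0.2 lognormal rate noise across 20 seeds
(minimum Pearson correlation of inferred vs true relative heights ≥ 0.95);
the repeat-scanner null on 100 i.i.d. 1-kb sequences (zero loci at period
≥ 20, ≥ 2 copies, ≥ 90% identity).  Likelihood correctness is exact-to-1e-9
against brute-force state enumeration on 4-taxon, 6-site instances, and the
α→∞ discrete-gamma limit matches the rate-homogeneous likelihood to 1e-3
log units.

## Known limitations

* Template folding cannot represent non-cloverleaf tRNA topologies beyond
  missing D/T arms, and ignores modified bases.
* The CSB library is synthetic; real-data CSB calls require a curated
  motif set for the taxon of interest.
* The dater produces point ages plus bootstrap quantiles; it does not model
  rate autocorrelation or calibration densities.
* Bayesian tree inference and multiple sequence alignment are out of scope;
  pre-aligned input (or gapless synthetic homologs) is assumed, and any
  externally supplied newick can serve as the baseline topology for dating.
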