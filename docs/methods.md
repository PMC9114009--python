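# Methods

## Problem framing

m6A deposition is modelled as per-nucleotide binary classification on
pre-mRNA. A transcript contributes its full gene body (TSS to TES,
unspliced) in sense orientation with a flank on each side; positives are
the experimentally known (or, on synthetic data, planted) m6A sites, and
every other gene-body nucleotide is a negative. Flank positions are
context only: they are masked out of the loss and of evaluation. Genomic
coordinates are 0-based half-open throughout; minus-strand genes are
reverse-complemented exactly once at window extraction, so all downstream
analyses see sense-strand sequence and "downstream" always means 3'.

When a gene has several annotated transcripts the one with the largest
mature (exonic) length is kept; ties break on the lexicographically
smallest transcript id so the choice is deterministic.

## Encoding, blocks, labels

Sequences are one-hot encoded with channel order A, C, G, T; N (and any
non-ACGTN character, coerced with a warning) is the all-zero row, so
`decode(encode(s)) == s` up to that coercion. A gene body of length L is
split into ceil(L/B) label blocks of B positions; block i's input is its
span widened by C context nucleotides per side, drawn from the window
(flanks included) and N-padded beyond it. The final block's labels are
zero-padded and masked past the gene end, so concatenating the masked
label blocks reconstructs the original track exactly. B and C default to
5000 nt; desk-scale experiments use B = C = 80, which is sound because the
model's receptive field is required to fit inside the context (below).

## Classifier

Architecture: width-1 Conv → four residual blocks → sum of width-1 skip
projections of every block output → width-1 Conv → softmax over
{background, m6A}; the C context positions are cropped before the loss.
Each block repeats r times the pre-activation unit
BatchNorm → ReLU → dilated Conv(w, ar) → BatchNorm → ReLU → Conv(w, ar)
plus identity skip. The receptive-field half-width is
Σ_blocks r·2·((w−1)/2)·ar; configurations where it exceeds C are rejected,
which also guarantees that scoring is invariant to how a sequence is
chunked into blocks (verified as a test invariant). The default
desk-scale blocks are k=32, w=5, r=1, ar ∈ {1,2,4,8} (half-width 60 nt,
covering the downstream-50-nt region that carries most of the signal);
(k, w, ar, r) are configuration, not code.

Training: Adam (β1=0.9, β2=0.999) on masked categorical cross-entropy,
10 epochs, batch size 30, learning rate 1e-3 for the first 6 epochs then
halved every subsequent epoch. No class rebalancing or negative
subsampling: all gene-body positions are trained on, flanks masked. No
gradient clipping or weight decay. An ensemble of five members with
distinct seeds is averaged at inference; single-member training is used
where runtime matters more than variance. The whole network (forward,
backward, BatchNorm, Adam) is implemented in numpy in float64; gradients
are checked against central finite differences in the test suite, and
training is bit-deterministic given seeds.

Evaluation reports AUROC/AUPRC over all gene-body positions of held-out
genes (a flag restricts negatives to consensus-matched positions instead;
both conventions are supported because published evaluations differ).

## Planted grammar and synthetic genome

The oracle scorer assigns probability only at consensus As:

    linear:    p = clip(b0 + Σ_m e_m · count_m(window), 0, 1)
    logistic:  p = sigmoid(b0 + Σ_m e_m · count_m(window))

where count_m counts occurrences of pentamer m whose start offset
(relative to the methylated A at 0) lies in the active window, default
[+1, +50]. Enhancer pentamers are sampled from the family containing
GAC/AAC cores, silencers from the CG/GT/CT-containing family (disjoint
from the enhancers); both imitate the motif classes the real analyses
recover. The linear link makes ΔProbability exactly linear in pentamer
count changes (the regression testbed); the logistic link is used for
classifier training where graded probabilities are more realistic.

The generator's defaults are the package's study conditions, chosen once:
50 genes over two contigs (≈30% of genes on the held-out contig), 2–4
exons, intergenic gaps 250–450 nt, a 50–70 codon CDS contained in the last
exon and ending in a stop codon (TGA with probability 0.5, the remainder
split between TAA/TAG; half of the genes additionally carry a TGA-then-C
stop context so a consensus A sits at stop-relative +2), two planted
high-probability sites per gene in the noncoding last exon with four
planted enhancer occurrences at distinct downstream offsets, and one
consensus site inside the CDS (codon pair GGA|CTG) for codon-swap
analyses. Truth labels are the oracle probability thresholded at 0.5
(Bernoulli sampling is available). A conservation track (Gaussian noise,
mean shifted +1.5 in the [+1,+50] window downstream of positives) and a
variant table with oracle-recomputed expected ΔProbability are emitted
alongside FASTA/GTF/BED/bedGraph/VCF, with a manifest of config, seed and
file hashes.

What the generator does **not** emulate: realistic base composition and
gene geometry, multi-exon CDS (the CDS sits in one exon so the pre-mRNA
frame equals the CDS frame), splicing, expression-dependent detection
noise, or correlated methylation between neighbouring sites beyond what
window overlap induces. Passing tests therefore demonstrate that the
algorithms are correct and that the pipeline recovers a sequence-driven
deposition code when one exists; they do not measure performance on real
transcriptomes.

## Perturbation analyses

All perturbation operations take any scorer satisfying the scorer
contract (`score(seq)`, optional `score_at(seq, pos)`, `margin` =
receptive half-width) and rescore a subwindow wide enough to contain the
perturbation span plus the margin — by locality this equals full-sequence
rescoring, and it makes saturation scans cheap.

- Saturation mutagenesis substitutes each position of the span (default
  −250..+250, offset 0 = the methylated A, included because variants at
  the site itself are informative) with the three other bases. An
  `exclude_consensus` flag drops events touching the RAC triplet
  (offsets −1..+1) to isolate flanking-element signal from consensus
  destruction.
- Synonymous codon swaps anchor codon 0 at the codon containing the site's
  A, scan codons −15..+15, require the site ≥60 nt inside the CDS, never
  change the encoded peptide (checked against the standard genetic code),
  and flag swaps that break the consensus (possible for codons 0 and +1,
  which contain the A and the C respectively).
- Stop-codon swaps replace the annotated stop and report ΔProbability at
  the three stop-adjacent consensus geometries NRACTRR (A at stop-relative
  −2), TRACN (+2) and TRRACN (+3), where the stop's T is 0. The +2 offset
  is the only one at which TRACN's A coincides with a stop nucleotide,
  which resolves an ambiguity between alternative published numberings of
  these positions.
- Variant effects: for one SNV, ΔProbability at every reference consensus
  site within a search radius (default 500 nt), with the variant
  classified upstream / at-site / downstream of the most affected site.
  ΔEffectiveValue is the sum of effect values of the ≤5 pentamers created
  minus the ≤5 broken; incomplete pentamers at sequence edges are skipped
  and flagged.

## Motif-effect regression and its identifiability

Each substitution event contributes one design row with predictor
count_created(m) − count_broken(m) per motif. The default fit is a single
joint multiple regression on all 1024 pentamers (64 codons) plus an
intercept; a marginal per-motif mode is kept for sensitivity analysis.
p-values are two-sided coefficient t-tests (a Benjamini–Hochberg column is
emitted for convenience; ranking uses raw effects). Motifs never observed
with a nonzero predictor are non-identifiable and reported as NaN, not 0.

Two exact degeneracies of this design matter and are handled explicitly:

1. **4-mer gauge.** For interior substitutions, the five created (broken)
   pentamers overlap in a chain, so any effect vector of the form
   e(m) = u(m[0:4]) − u(m[1:5]) for a potential u on 4-mers telescopes to
   zero in every row: a 256-dimensional nullspace. It disappears when the
   counted pentamer starts are truncated asymmetrically in diverse
   contexts, which is why the recovery experiment places the grammar's
   causal window strictly inside the mutated span (window [+3,+42] inside
   offsets [+3,+46]) and aligns the design's counted starts with it
   (`motif_window` parameter); the right-edge truncations then occur in
   random sequence contexts and pin the potentials down.
2. **Uniform shift.** Every event creates and breaks equally many motifs,
   so predictors sum to zero per row and effects are identified only up to
   a common additive constant. The fit therefore uses the pseudoinverse,
   which returns the centred (minimum-norm) representative, and the
   recovery grammar plants zero-sum symmetric effects so that centred
   representative *is* the planted truth. With both choices exact recovery
   is a theorem, and the measured maximum absolute error is at float
   precision (~1e-14). Sites whose linear score clips at 0 or 1 are
   excluded from recovery experiments because clipping breaks linearity.

With Gaussian response noise (σ = 0.02) the recovered effects correlate
with the planted effects at r > 0.98; the correlation is computed over the
planted (nonzero-effect) motifs, since over the full universe it would be
dominated by estimation noise on true zeros and measure nothing about
recovery.

The localization experiment follows the mutagenesis site-selection
protocol (per gene, the single highest-probability site with probability
≥ 0.4), excludes clipped sites for the same linearity reason, and excludes
consensus-triplet events via the filter flag above; the statistic is the
fraction of events with |ΔProbability| > 0.1 whose offsets lie in the
planted window, ≈0.97 under the default conditions. Without the consensus
filter the fraction is ≈0.86–0.89, because each site carries five
structural consensus-destroying events at offsets −1/0 that have nothing
to do with flanking elements.

## Statistics

Binomial direction-concordance tests use the exact upper tail
P(X ≥ k | n, p) with the expectation n·p reported; Fisher tests are
two-sided exact with odds ratio ad/bc; the two-sample KS test uses the
asymptotic two-sided p-value (exact small-sample KS is out of scope);
genotype–methylation association is a simple linear regression of level on
genotype codes {0, 0.5, 1}. Binomial and Fisher p-values are cross-checked
against brute-force pmf/hypergeometric enumeration in the tests. Profiles
(motif frequency or conservation by offset) report mean ± SEM with
SEM = SD/√n; site groups use probability ≥ 0.7 for positives and
consensus-matched controls below a low cutoff (0.1 by default, 0.01 in the
coding-region analyses), with in-between sites discarded.

## Problem sizes and numerical choices

Reference experiments use 200 sites (26,400 design rows) for recovery,
50 genes for localization and training, and 60 CDS windows for the codon
direction check; these sizes make every experiment a theorem-scale or
minutes-scale computation on one CPU while leaving the estimators
well-conditioned. The joint fit solves the normal equations with a
pseudoinverse (rcond 1e-10); degrees of freedom use the design rank.
BatchNorm uses ε=1e-5 and momentum 0.9; inference uses running statistics,
which is what makes chunked scoring exactly position-wise deterministic.

## Known limitations

- Desk-scale training (tens of genes, context 80 nt) demonstrates
  correctness, not transcriptome-scale performance; the architecture and
  recipe scale, but no claim is made about real-genome accuracy.
- The joint regression reports gauge-centred effects; only effect
  *differences* (and hence rankings, enhancer/silencer calls) are
  estimable from interior-substitution data alone.
- Indels, multi-nucleotide variants and haplotype-aware scoring are
  unsupported; variant deltas are anchored at reference consensus sites.
- The RNA alphabet is not used; all analyses run on DNA-alphabet sense
  sequence (U ↔ T).
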