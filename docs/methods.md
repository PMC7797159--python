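# Methods

This note documents the models, defaults and numerical choices behind
`lncnet`, and what the synthetic benchmark does and does not establish.

## Identification cascade

The screen is a sequence of pure predicates applied in a fixed order;
each transcript is attributed to the first step that removes it, so the
report partitions the input exactly. Step semantics worth spelling out:

- Length is strict (> 200 bp, a 200-bp transcript is removed); the
  expression rule is inclusive (max FPKM ≥ 0.5 retained). Both mirror the
  protocol's wording.
- Step 3 is decided by the assembler's class code rather than by
  re-computing interval overlap: codes {=, c, j, e, o} denote exonic
  overlap with reference annotation, which is the authority the protocol
  delegates this decision to. Transcripts whose ids appear in the
  annotated-lncRNA list are routed to the output at this step and bypass
  the expression and coding-potential screens.
- The expression aggregate is the **maximum** across the 12 samples. The
  protocol does not state whether the FPKM ≥ 0.5 rule is per-sample,
  per-stage-mean or max; max is the most permissive stage-aware choice (a
  transcript expressed in only one stage still passes) and is exposed as
  a parameter (`min_fpkm`, and the aggregate is trivially changed by
  pre-aggregating the matrix).
- Step 5 consumes externally produced verdicts from four coding-potential
  predictors; only the consensus rule is implemented here (all-noncoding
  ⇒ lncRNA, any-coding ⇒ TUCP). A transcript that survives steps 1–4
  without a verdicts row is an input error, reported by id.
- The lincRNA/antisense classification applies to novel lncRNAs (codes
  "u"/"x"). Any other surviving code raises an error listing the ids
  rather than guessing — in a correctly screened set only these two codes
  can remain, so anything else indicates an upstream problem.

ORF counting for the characterization tables: an ORF is an ATG whose
nearest in-frame stop lies ≥ 30 codons downstream (stop excluded),
counted over the three forward frames of the spliced sequence; every
qualifying ATG counts, including nested starts. The 30-codon minimum is a
convention (no value is stated in the protocol) and is a parameter.

## Differential expression

Fold change is computed on FPKM stage means with pseudocount 0.01 added
to both numerator and denominator; FC = 1 exactly when both means are
zero. The two thresholds are kept as two flags: `is_de` (|FC| ≥ 1.7
inclusive, direction-symmetric — FC = 1/1.7 flags identically to 1.7 —
and q < 0.05 strict) and `is_cerna_grade` (|log₂FC| ≥ 1, q < 0.05). miRNA
DE calls use the q rule only.

The significance test is a deliberate, clearly labelled stand-in for an
NB-model DE caller; it reproduces the thresholding logic, not any
specific tool's numbers. Per feature, counts in the two 3-replicate
groups give means m₁, m₂ and a method-of-moments dispersion pooled across
the two groups, d = ((s₁²−m₁)+(s₂²−m₂))/(m₁²+m₂²), floored at 1e-8. The
Wald statistic is

    z = (ln(m₁+½) − ln(m₂+½)) / √( (1/m₁ + d)/n + (1/m₂ + d)/n )

referred to the standard normal, two-sided. With three replicates the raw
per-feature dispersion estimate is noisy enough to make this test
anti-conservative (measured type-I ≈ 0.11 at α = 0.05), so the estimator
shares information across features in the manner of NB DE callers: each
feature's dispersion is floored at the across-feature median. Measured
null type-I at α = 0.05 is then 0.036–0.053 (2,000 features, several
seeds), and strong effects retain the normal tail (group means 5 vs 500
at dispersion 0.1 give z > 10, p < 1e-6). The ½ pseudocount guards the
log and the 1/m term at zero counts; identical count vectors give p = 1
exactly.

q-values are Benjamini–Hochberg per comparison group (the de facto
meaning of "q-value" in NB-pipeline practice; the procedure is not
otherwise specified). BH is delegated to statsmodels; the test suite
checks it against an independent hand-written step-up.

## Target prediction

Cis distance is the unsigned span-to-span gap (first exon start to last
exon end), not TSS-based — the protocol says only "within ~100 kb up- and
downstream", and spans make the rule orientation-symmetric. The "~100 kb"
is implemented as a hard inclusive cutoff at exactly 100,000 bp
(reproducibility requires a definite boundary); the window is a
parameter. Trans correlation is signed (r > 0.95 strictly, per the
literal "r > 0.95"); an absolute-value mode exists behind a flag, and the
0.98 variant used for pathway views is the same parameter. Zero-variance
profiles are skipped with a warning rather than producing NaN.

## miRNA interactions

The upstream tool for miRNA target prediction is not specified in the
protocol, so the package implements the canonical, fully transparent
7-mer seed match (reverse complement of mature positions 2–8, ≥ 1 site;
seed window and minimum site count are parameters). Precursor homology is
exact forward-strand substring matching — the claim being modelled is a
lncRNA literally containing the hairpin — with 1-based inclusive
coordinates (a 66-nt precursor at position 309 reports (309, 374)); a
reverse-complement search mode exists but is off by default. All
sequences are normalized U→T on load so RNA and DNA inputs compare
directly.

## ceRNA triads

A triad requires: miRNA DE in the group, lncRNA and mRNA ceRNA-grade DE
in the group, and both (miRNA→lncRNA) and (miRNA→mRNA) target pairs. The
output is exactly the relational join, deduplicated, in lexicographic
order — verified against a brute-force triple loop in the tests. No
expression-direction constraint between the miRNA and its targets is
imposed by default (the protocol does not impose one); an
anticorrelation filter is available behind a flag. The per-gene network
count is the number of distinct (lncRNA, miRNA) pairs among the gene's
triads, which is the counting unit consistent with reported arithmetic
such as "13 networks from 2 miRNAs and 12 lncRNAs".

## Enrichment and PPI

Enrichment replaces a web service with the plain hypergeometric upper
tail P(X ≥ k), BH-corrected per namespace, significant at q < 0.05; the
EASE-style conservative variant (testing k−1) is behind a flag. The
universe defaults to expressed genes (max FPKM ≥ 0.5) in the pipeline and
is always explicit in the API. PPI edges keep combined score > 700
(strict), deduplicate unordered orientations keeping the best score, and
carry weight = score/1000.

## Synthetic data: what it emulates

The generator reproduces the structural features the analysis depends
on, at the study's design scale (12 samples = 4 stages × 3 replicates;
2,000 transcripts by default: 1,400 mRNAs, 260 novel + 40 annotated
lncRNAs, 100 TUCPs, and 200 transcripts that fail the structural or
expression screens):

- mRNAs are longer (~2 kb median) and more exon-rich (~10) than lncRNAs
  (~700 bp, 2–3 exons), and more expressed (log-normal baselines with
  medians 15 vs 4 FPKM), matching the qualitative contrasts the
  characterization stage reports.
- FPKM noise is multiplicative log-normal with σ = 0.1 per sample
  (replicate CV ≈ 10 %, plausible for replicate tissue from an inbred
  line). Counts are drawn NB around mean = FPKM × 50 with dispersion 0.1;
  the depth factor reflects the deep sequencing of the emulated design
  (~90 M fragments per library puts a 1-kb transcript at FPKM 0.7 near
  60 expected fragments, not single digits).
- DE features get one stage shifted by a log₂ effect drawn from (2, 4)
  with random sign; the planted truth records the implied noiseless
  log₂ ratio for every comparison. Triad members are planted so the three
  legs are jointly DE in exactly one comparison group.
- Trans pairs share a per-sample log-normal latent factor (σ = 1.2
  ln-units): within a pair the noiseless profiles are exactly
  proportional (r = 1), across pairs the 12-dimensional latents are
  independent, so chance r > 0.95 is negligible. The latent also inflates
  replicate variance, which correctly keeps these features out of the DE
  lists. Note the arithmetic constraint here: under multiplicative noise
  σ the attainable within-pair Pearson r on the linear scale is capped
  near e^(−σ²), so strongly correlated pairs only exist when replicate
  noise is modest — one reason r > 0.95 pairs in real data mark strong
  co-regulation.
- Cis pairs are placed on a dedicated chromosome at exact configured
  span-to-span offsets (0, 500, 50 k, 100 k, 100,001 and 150 k by
  default — both sides of the window boundary), with 400 kb spacing
  between pair blocks so no unplanned pair falls inside the window.
- Seed sites are written into target sequences by substring replacement,
  never overlapping embedded precursors; precursors (50–120 nt) are
  copied verbatim into host lncRNAs at configured 1-based positions, and
  hosts are sized to fit (placements that cannot fit under the 5-kb
  lncRNA cap are rejected as configuration errors). One precursor id can
  be planted into several hosts.

What it does **not** emulate: real genome composition and repeat
structure (backgrounds are uniform ACGT, so homology search is easier
than against real transcripts), assembler artefacts beyond the class
code, library-size variation (counts are scaled from FPKM with one
factor), GC or length biases, and correlated biological confounding
between stages. Passing the recovery tests therefore shows the *logic*
is correct and calibrated under the stated noise model — not that the
thresholds would achieve the same sensitivity on real data.

## Determinism and problem sizes

Every random element derives from a single integer seed through one
generator; identical configurations produce byte-identical datasets, and
identical pipeline runs produce byte-identical outputs (timing is logged
to stderr, never written into output files). Default problem sizes —
2,000 transcripts, 12 miRNAs, 2,000-feature null calibration — keep the
full test suite and the acceptance script in the seconds-to-a-minute
range on one CPU while leaving every planted structure at the
multiplicity the recovery checks need.

## Known limitations

- The NB stand-in shares dispersion via a global median floor; it has no
  mean-dispersion trend, so features with genuinely low dispersion at
  high counts are tested conservatively.
- Seed matching is presence/absence with site positions; no
  thermodynamic or context scoring.
- Enrichment ignores the GO graph (no term propagation).
- The cascade trusts class codes; it never re-computes exonic overlap
  from coordinates.
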