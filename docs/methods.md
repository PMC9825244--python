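# Methods

This note documents the models and procedures implemented in `exarch`, the
synthetic data they are verified against, the numerical choices made where
the design was genuinely open, and what the passing tests do and do not
establish about real data.

## Gene models and coordinates

GFF3 input is parsed with `gffutils` (in-memory database). All genomic
coordinates are 1-based inclusive; protein residues are 1-based inclusive.
Exons and CDS features are normalized to transcription order on both
strands, so downstream code never branches on strand. A transcript whose CDS
length — after discarding the phase overhang of its first CDS feature — is
not divisible by three is skipped with a warning rather than aborting the
run, because production gene builds contain such records.

**Codon attribution.** A codon split across an exon junction is attributed
to the exon carrying at least two of its three nucleotides. This majority
rule is deterministic for two-way splits; the pathological case of a codon
spread over three exons (a one-coding-nucleotide exon) is resolved by the
exon holding the middle nucleotide. The stop codon is excluded from the
protein length and from all residue maps, since residue-level annotations
(disorder predictors, domain assignments) never cover it. Consequently each
coding exon maps to a contiguous residue interval and the intervals of a
transcript partition `[1, protein_length]` exactly — a property asserted for
every synthetic transcript in the test suite.

**Deduplication.** Internal exons are made nonredundant per gene by genomic
interval. An exon internal in at least one transcript variant counts as
internal (inclusive rule; the generator plants variants with an extra
5′ UTR exon precisely to exercise this). The only analysis run on the
variant-redundant exon set is the longest-exon search of the accretion
stage, where candidates are gathered per transcript and unioned per gene.

**Exon length.** Binning uses the full exon nucleotide length by default;
a `use_coding_length` switch selects the CDS-only length instead. Default
binning is nine 120-nt bins covering 1–1080 nt with the last bin absorbing
longer exons; this reconciles a majority of internal exons below 241 nt
with nine-point per-bin correlations and the 360/720/960-nt thresholds used
elsewhere. All bin edges are configurable.

## Interval annotations

Disorder (IDR) and domain intervals are stored per protein and per source.
Sources are never merged: every analysis runs separately per predictor so
robustness to the annotation method is visible. On input, overlapping or
touching intervals of one source are merged with a warning (predictor output
dialects differ on adjacency), out-of-range rows are rejected with their
line numbers, and a converter for DISOPRED-style per-residue `*` mark-up is
provided.

## Constrained exons

Observed classification uses interval containment: an internal exon is
constrained iff its encoded interval is a subset of a single domain
interval, boundaries included. The analytic expectation counts window
placements whose endpoints are *strictly interior* to a domain —
`(x − y − 1)` placements in a domain of length `x` — as stated in the
formula. These two conventions differ at domain boundaries; both are
implemented exactly as defined and the discrepancy is deliberately left in
place rather than "fixed". The expectation is computed per genome with all
internal exons pooled (`L` is the genome-wide total of encoded residues;
the domain pool contains every domain overlapping an internal exon, with
overlapping domain annotations merged first). The per-bin expected fraction
is the mean of per-exon probabilities, which is exact under the formula,
rather than the probability at the bin midpoint. The implementation keeps
an exact-rational mode (`exact=True`, `fractions.Fraction`) used by the
oracle tests, and a suffix-sum float path for genome-scale runs.

Domain subsampling (`subsample_domains`) keeps ⌊fraction·N⌋ of the pooled
domains uniformly at random under a fixed seed; it reproduces the
robustness check against unidentified ("latent") domain assignments.

## Insertion detection

A segment is called inserted on one ingroup lineage when the alignment has a
maximal run of columns with residues in that lineage and gaps in *both* the
outgroup and the other ingroup (strict two-outgroup support: a segment
present in only one ingroup is unlikely to have been deleted independently
twice). Runs separated by even one shared column stay separate. Segments
are mapped to exons via the residue maps; a segment is discarded when its
interval coincides exactly (tolerance 0 residues, configurable) with the
union of one or more consecutive entire exon spans, and when it overlaps no
internal exon. Host-exon constraint is evaluated on the present-day exon
against present-day domains — ancestral states are unavailable — and the
per-bin expectation is the constrained fraction of *all* internal exons in
that bin. Insertions spanning an exon junction count each overlapped
internal exon once.

## Domain accretion

Segments are extracted per gene from the representative transcript (most
domains, then longest protein): one group A segment per consecutive domain
pair and exactly one group B segment downstream of the last domain; genes
without domains are ignored. Candidate internal exons follow the literal
rules (group A: encodes the upstream domain's C-terminal residue, or first
encoded residue strictly between the domains; group B: last encoded residue
downstream of the last domain's end). Ties for the longest candidate break
toward the 5′-most exon. Segment length is measured in encoded residues ×3
so groups A and B share a nucleotide scale; distance bins are 600 nt wide by
default and a bin is only reported when both groups have at least 25
segments in it.

## GO enrichment

Pearson χ² (df = 1, no continuity correction, via `scipy`) on the 2×2 table
of long-exon-gene membership versus term annotation; a term is enriched when
its in-set count exceeds the expectation and p < 0.05. No multiple-testing
adjustment is applied by default, matching the per-term usage the thresholds
come from; a Benjamini–Hochberg option (via `statsmodels`) is available. The
universe is the annotated genes with at least one internal exon; GO-graph
propagation is out of scope (terms are used as annotated).

## The synthetic genome

The generator emulates the statistical structure the analyses are designed
to detect; all randomness flows from one seed and reruns are byte-identical.

* **Architecture.** 2,000 genes by default; internal exons per gene are
  2 + Poisson(3); lengths follow a lognormal mixture (short mode median
  120 nt, σ = 0.45; long mode median 700 nt, σ = 0.35; long weight 0.15),
  clipped to 30–2400 nt. Terminal exons are lognormal around 150 nt. Half
  the genes sit on the minus strand; 20% carry a second transcript variant
  with an extra 5′ UTR exon. Emitted sequences are random codons encoding
  random proteins; no biophysical realism is attempted (disorder and
  domains are labels, not sequence properties).
* **Disorder.** Each exon's residues get a stationary disorder probability
  `expit(logit(0.15) + β·nt/120 + ε)` with coupling β = 0.4 by default and
  an exon-level random effect ε ~ N(0, 0.4²). States are laid down as
  alternating blocks with geometric lengths whose mean scales with the exon
  (a quarter of its residue span): long disordered exons encode long IDRs,
  and — importantly for inference — the per-exon coverage noise is then
  roughly length-independent. Without that property (fixed block length),
  the sampling variance of the disorder fraction shrinks as 1/length while
  long exons dominate the correlation leverage, and the Pearson t-test on
  null genomes becomes severely conservative (empirical rejection near 0
  instead of 0.05). With the scaled blocks and the ε term, 500 null
  replicates reject at 0.04–0.06, and the β > 0 default is recovered with
  r > 0 at p < 0.001 in ≥ 95/100 seeds.
* **Domains.** Two domain classes are placed. *Anchored* domains make
  observed constrained exons: an anchored exon's residue span extended one
  residue into each neighbour, so both boundaries fall just outside the exon
  (the exon is constrained; its neighbours never are). *Intra-exon* domains
  are whole domains encoded inside single long exons (≥ 780 nt hosts),
  with near-constant SCOP-like length (truncated normal, 320 ± 30 residues);
  they constrain nothing but carry most of the domain-length pool of the
  analytic null. Anchoring probabilities are calibrated genome-wide by a
  small fixed-point iteration so that q(exon) ∝ E(y)·(1 − nt/1080)⁺, where
  E is the analytic expectation implied by the placed domains themselves:
  the planted observed/expected ratio then declines roughly linearly with
  exon length and vanishes by ~1080 nt, the depletion signature, while the
  observed fraction still arises from actually placed, coherent domain
  intervals. The residue count is approximated as nt/3 during calibration;
  the analyses recompute the exact expectation from the emitted domains.
* **Accretion structure.** Unanchored long exons (> 480 nt) are routed into
  inter-anchor gaps with probability 0.8, upstream of the first domain
  otherwise, and only rarely (0.05) downstream of the last domain; short
  exons assigned to inter-anchor gaps are stretched ×1.5. The region after
  the last domain receives extra short exons instead. This concentrates
  exonic mass into few long exons between domains and spreads it over many
  short exons after the terminal domain — the group A > group B ordering at
  matched segment length.
* **GO.** Twenty terms; each gene draws 1 + Poisson(1.5) background terms,
  and one designated term is planted on long-exon genes at odds ratio 6
  (base probability 0.1).
* **Trios.** 120 genes, codon-aligned exon lengths (so planted insertion
  intervals coincide exactly with residue spans), flat disorder background
  at 0.3. Fifty within-exon and twenty whole-exon insertions are planted
  (alternating target lineage, one per gene, lengths 3 + geometric),
  restricted to unconstrained host exons and to insertion points outside
  all domains; inserted residues are disordered with probability 0.9.
  Alignments are constructed exactly: gaps appear in the outgroup and the
  non-target lineage at precisely the planted columns.

**What the synthetic data does not emulate.** Alignment error (MAFFT
artifacts, ambiguous gap placement), deletions, annotation noise in IDR and
domain calls, codon-usage or cytidine-content biases, genes gained or lost
between lineages, and any sequence-level realism. Passing tests therefore
demonstrate that the pipeline's logic is correct and its statistics
calibrated under the stated generative model — not that real genomes will
show these effect sizes.

## Numerical and testing choices

* Statistical kernels (SEM, t-from-r, χ²) are asserted against textbook
  formulas to 1e-9 and cross-checked against `scipy.stats.pearsonr` /
  `chi2_contingency`.
* The window-placement expectation is verified against exhaustive
  enumeration in exact rational arithmetic on hundreds of random instances.
* Bin fractions with zero denominators are reported as NaN, never silently
  dropped; ratios with zero expectation are NaN.
* The constrained-depletion property test averages per-bin fractions over
  three replicate genomes before correlating against bin index: single
  2,000-gene genomes leave only a few hundred exons in the mid-length bins
  and the nine-point correlation is then dominated by their sampling noise.
* Problem sizes in the test suite (2,000-gene genomes, 100 recovery seeds,
  500 null replicates, 120-gene trio sets) were chosen to keep the full
  suite in the low minutes on one CPU while leaving the binomial error of
  every estimated rate well inside its asserted band.

## Known limitations

* Gene models with trans-splicing, ribosomal frameshifts, or CDS features
  not nested in exons are outside the parser's contract (the latter is
  tolerated with a warning).
* The accretion stage unions candidates across transcript variants only
  when variants share the representative's domain layout; variants with a
  different domain annotation are logged and skipped.
* `host_exon_constraint_by_bin` reports observed ≤ expected as data, not as
  an assertion — with few host exons per bin the comparison is noisy.
* The insertion detector requires exactly three sequences per alignment;
  generalization to more outgroups is not attempted.
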