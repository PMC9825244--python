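# exarch — exon architecture evolution toolkit

`exarch` analyses how the length of internal exons (exons that are neither
first nor last in a transcript) relates to the structure of the proteins they
encode. Across eukaryotes, longer internal exons preferentially encode
intrinsically disordered regions (IDRs), are rarely confined within a single
SCOP structural domain, and sit between domains more often than downstream of
the last one — signatures of an evolutionary scenario in which unconstrained
exons elongated by gaining IDR-encoding sequence and thereby facilitated
domain accretion. This package implements those four analyses as a tested,
reusable pipeline for anyone with gene models (GFF3), per-protein disorder
and domain interval annotations, and three-way ortholog protein alignments —
plus a synthetic-data generator so every stage can be verified end to end
without any external download.

## The statistics at the core

* **Length vs. disorder (per length bin).** Nonredundant internal exons are
  binned by nucleotide length (nine 120-nt bins by default); each bin reports
  its occurrence frequency and the mean fraction of encoded residues inside
  IDR intervals ± SEM. The length–disorder association is tested with a
  Pearson correlation and *t* = *r*·√(*n*−2)/√(1−*r*²) on *n*−2 degrees of
  freedom.
* **Constrained exons.** An internal exon encoding residues
  [*f*, *l*] is *constrained* when [*f*, *l*] ⊆ one SCOP domain. The null
  probability that an exon encoding *y* residues is constrained is

      P(y) = Σᵢ (xᵢ − y − 1) / (L − y + 1)   for every domain with xᵢ > y + 1,

  where *L* is the total number of residues encoded by internal exons and
  *xᵢ* the length of SCOP domain *i* (both boundaries of a random *y*-residue
  window strictly interior to the domain). Observed fraction, expected
  fraction and their ratio are reported per length bin.
* **Lineage-specific insertions.** In a three-way protein alignment
  (outgroup + two ingroup lineages), a maximal run of columns where one
  ingroup has residues and both other sequences have gaps is an insertion on
  that lineage. Segments that coincide exactly with one or more entire exons
  are removed; the rest are insertions *within* internal exons, whose IDR
  content and host-exon constraint are compared with the genomic background.
* **Domain accretion (groups A/B).** For every gene with SCOP domains, group
  A segments lie between consecutive domains and group B downstream of the
  last domain. In each segment the longest candidate internal exon is found
  (candidates: exons encoding the upstream domain's C-terminal residue or
  starting between the domains; for B, exons ending past the last domain).
  Mean longest-exon length ± SEM is reported per segment-length bin, only
  when both groups have ≥ 25 segments in the bin.
* **GO enrichment.** Genes whose longest internal exon exceeds 720 nt (or
  960 nt) are tested per GO term with a Pearson χ² on the 2×2 membership
  table (df = 1, no continuity correction).

## Worked example

Generate a 300-gene synthetic genome and run the length-vs-disorder stage:

```bash
$ exarch simulate genome --out demo --seed 7 --config cfg.yaml   # cfg.yaml: "n_genes: 300"
$ exarch idr-by-length --gff demo/genes.gff3 --idr-tsv demo/idr.tsv --out demo/idr_by_length.tsv
{
 "simdis": {
  "r": 0.5518081194423808,
  "n": 1821,
  "t": 28.219767661408817,
  "p": 1.2685451853214714e-145
 }
}
$ head -8 demo/idr_by_length.tsv
#exarch 0.1.0
#config_hash=5bed97d2cb25
source  bin_label  n    frequency  mean_idr  sem
simdis  1-120      786  0.431631   0.192498  0.00790643
simdis  121-240    712  0.390994   0.249884  0.00883136
simdis  241-360    116  0.0637013  0.329241  0.0234331
simdis  361-480    29   0.0159253  0.494138  0.0511584
simdis  481-600    47   0.02581    0.522132  0.0390649
```

Reading the output: 1,821 nonredundant internal exons were binned; short
exons (< 241 nt) make up ~82% of them, and the mean encoded-IDR fraction
rises from 0.19 in the shortest bin to 0.52 by 600 nt. The per-exon Pearson
correlation between exon length and IDR fraction is r = 0.55 (n = 1821,
t = 28.2, p ≈ 1e−145) — the generator plants a positive length–disorder
coupling and the pipeline recovers it. The other stages run the same way
(`exarch constrained`, `exarch insertions`, `exarch accretion`,
`exarch enrich`, or `exarch run-all --config run.yaml`); every output TSV
carries `#`-prefixed provenance headers.

As a library:

```python
from exarch import GeneratorConfig, sample_genome
from exarch.simulate import internal_exon_records, idr_annotations
from exarch.idr_analysis import idr_by_length

archs = sample_genome(GeneratorConfig(n_genes=300), seed=7)
result = idr_by_length(internal_exon_records(archs), idr_annotations(archs))
print(result["correlation"])
```

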