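"""Synthetic genomes, annotations, and ortholog trios with known ground truth.

The generator emulates the statistical structure the analyses look for, so
every stage of the pipeline can be exercised and verified without external
data:

* internal-exon lengths follow a two-component lognormal mixture (a short
  mode around 120 nt and a long tail around 700 nt);
* the per-residue probability of intrinsic disorder increases with host-exon
  length through a log-odds coupling ``beta`` per 120 nt, and disorder is
  laid down as alternating blocks (geometric lengths), the way predictors
  emit intervals;
* SCOP-like domains come in two classes: anchored domains that make their
  anchor exon constrained, with anchoring probabilities calibrated
  genome-wide so the observed/expected depletion ratio declines linearly
  with exon length, and whole domains encoded inside single long exons that
  feed the analytic null without constraining anything;
* in genes with two or more domains, long exons are planted preferentially
  in inter-domain regions (and the inter-domain short exons are stretched),
  while the region downstream of the last domain receives many short exons —
  the accretion signature;
* one GO term is planted to correlate with genes whose longest internal exon
  exceeds 720 nt;
* ortholog trios carry planted lineage-specific insertions, within-exon and
  whole-exon, with elevated disorder probability in the inserted residues.

All randomness flows from a single seed; identical configuration and seed
give byte-identical outputs.  Proteins are random sequences over the
20-letter alphabet: disorder and domains are labels, not sequence
properties, and no attempt is made at biophysical realism.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotations import IntervalAnnotation, merge_intervals
from .enrichment import GeneTermTable
from .gene_models import Exon, GeneModel, InternalExonRecord, Transcript
from .insertions import TrioAlignment

__all__ = [
    "GeneratorConfig",
    "GeneArchitecture",
    "TrioSet",
    "sample_genome",
    "internal_exon_records",
    "to_gene_models",
    "idr_annotations",
    "domain_annotations",
    "go_table",
    "generate_genome",
    "generate_ortholog_trios",
]

FLANK_NT = 400
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

CODONS_BY_AA = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "M": ["ATG"],
    "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}
STOP_CODONS = ["TAA", "TAG", "TGA"]


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic genome.

    Lengths are nucleotides unless stated otherwise.  ``idr_coupling_beta``
    is the log-odds increase of the per-residue disorder probability per
    120 nt of host-exon length; zero gives the null genome.
    """

    n_genes: int = 2000
    # exon architecture
    internal_pool_lambda: float = 3.0  # internal exons per gene = 2 + Poisson
    short_len_median: float = 120.0
    short_len_sigma: float = 0.45
    long_len_median: float = 700.0
    long_len_sigma: float = 0.35
    long_weight: float = 0.15
    min_exon_nt: int = 30
    max_exon_nt: int = 2400
    terminal_len_median: float = 150.0
    terminal_len_sigma: float = 0.5
    intron_min_nt: int = 60
    intron_max_nt: int = 400
    minus_strand_prob: float = 0.5
    utr_variant_prob: float = 0.2  # second transcript with an extra 5' UTR exon
    codon_aligned_exons: bool = False  # force exon lengths to multiples of 3
    # disorder model
    idr_base_fraction: float = 0.15
    idr_coupling_beta: float = 0.4
    idr_block_mean: float = 15.0  # residues (protein-level background blocks)
    idr_block_frac: float = 0.25  # disorder block length as fraction of exon span
    idr_exon_sd: float = 0.4  # exon-level random effect on the disorder logit
    # domain (constrained-exon) model
    constrained_base_prob: float = 0.4  # peak anchoring probability
    constrained_zero_nt: int = 1080  # observed/expected depletion reaches 0 here
    # domain length in residues (truncated normal): near-constant, SCOP-like
    domain_len_mean: float = 320.0
    domain_len_sd: float = 30.0
    # domains encoded entirely within one long exon (they constrain nothing:
    # the host exon is longer than the domain)
    latent_domain_prob: float = 1.0
    latent_host_min_nt: int = 780
    # accretion structure
    accretion_structure: float = 0.8  # P(long exon into an inter-domain gap)
    accretion_gap_scale: float = 1.5  # stretch of short exons in those gaps
    group_b_long_prob: float = 0.05  # P(long exon lands downstream of last domain)
    long_filler_nt: int = 480  # exons above this count as "long" when placed
    tail_extra_lambda: float = 1.0  # extra short exons after the last domain
    # GO annotation
    n_go_terms: int = 20
    planted_go_term: str = "GO:0005634"
    go_terms_lambda: float = 1.5
    planted_base_prob: float = 0.1
    planted_odds_ratio: float = 6.0
    long_exon_threshold_nt: int = 720
    # ortholog trios
    trio_n_genes: int = 120
    n_within_insertions: int = 50
    n_whole_insertions: int = 20
    insertion_len_mean: float = 12.0  # residues, 3 + geometric
    whole_exon_len_mean: float = 25.0  # residues of a planted whole exon
    idr_probability_inserted: float = 0.9
    idr_background: float = 0.3
    host_restriction: str = "unconstrained_only"  # or "any"

    def validate(self) -> None:
        for name in (
            "long_weight", "minus_strand_prob", "utr_variant_prob",
            "constrained_base_prob", "accretion_structure", "group_b_long_prob",
            "idr_base_fraction", "idr_probability_inserted", "idr_background",
            "planted_base_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.idr_coupling_beta < 0:
            raise ValueError("idr_coupling_beta must be >= 0")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.min_exon_nt < 9 or self.max_exon_nt <= self.min_exon_nt:
            raise ValueError("bad exon length limits")
        if self.host_restriction not in ("unconstrained_only", "any"):
            raise ValueError(f"unknown host_restriction {self.host_restriction!r}")

    @classmethod
    def trio_defaults(cls, **overrides) -> "GeneratorConfig":
        """Conditions for ortholog-trio generation: codon-aligned exons,
        flat disorder background, single transcript per gene."""
        base = dict(
            n_genes=120,
            codon_aligned_exons=True,
            utr_variant_prob=0.0,
            idr_base_fraction=0.3,
            idr_coupling_beta=0.0,
            idr_block_mean=10.0,
            constrained_base_prob=0.3,
            minus_strand_prob=0.5,
        )
        base.update(overrides)
        return cls(**base)


# ---------------------------------------------------------------------------
# Architecture
# ---------------------------------------------------------------------------


@dataclass
class GeneArchitecture:
    """In-memory description of one synthetic gene (transcription order)."""

    gene_id: str
    protein_id: str
    strand: str
    contig: str
    exon_nt: list[int]  # all exons fully coding; last includes the stop codon
    intron_nt: list[int]
    protein_len: int
    spans: list[tuple[int, int] | None]  # residue interval per exon
    anchor_idx: list[int]  # exon indices carrying a domain
    domains: list[tuple[int, int]]
    idr_intervals: list[tuple[int, int]]
    true_exon_idr: list[float]
    go_terms: list[str]
    utr_variant: bool = False
    utr_exon_nt: int = 0
    exon_coords: list[tuple[int, int]] = field(default_factory=list)
    utr_exon_coords: tuple[int, int] | None = None
    contig_len: int = 0


def _residue_spans(exon_nt: Sequence[int], protein_len: int) -> list[tuple[int, int] | None]:
    """Residue interval encoded by each exon under the majority-codon rule."""
    spans: list[tuple[int, int] | None] = []
    pos = 0
    for length in exon_nt:
        a, b = pos + 1, pos + length
        pos = b
        c_a = (a - 1) // 3 + 1
        first = c_a if min(b, 3 * c_a) - a + 1 >= 2 else c_a + 1
        c_b = (b - 1) // 3 + 1
        last = c_b if b - max(a, 3 * c_b - 2) + 1 >= 2 else c_b - 1
        last = min(last, protein_len)
        spans.append((first, last) if first <= last else None)
    return spans


def _lognormal_int(rng, median: float, sigma: float, size: int) -> np.ndarray:
    return np.rint(np.exp(rng.normal(math.log(median), sigma, size=size))).astype(int)


def _sample_idr_blocks(
    rng: np.random.Generator,
    y: np.ndarray,
    p: np.ndarray,
    block_mean,
) -> list[list[tuple[int, int]]]:
    """Alternating-block disorder states over intervals of lengths y with
    per-interval stationary disordered fraction p; returns local disordered
    intervals per element.  ``block_mean`` may be a scalar or per-interval
    array of mean disordered-block lengths."""
    n = y.size
    p = np.clip(p, 1e-6, 1 - 1e-6)
    m_d = np.broadcast_to(np.asarray(block_mean, dtype=float), (n,)).copy()
    m_o = m_d * (1.0 - p) / p
    state = rng.random(n) < p
    pos = np.zeros(n, dtype=int)
    out: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    active = pos < y
    while active.any():
        idx = np.flatnonzero(active)
        means = np.where(state[idx], m_d[idx], m_o[idx])
        lens = rng.geometric(np.minimum(1.0, 1.0 / means))
        for k, i in enumerate(idx):
            if state[i]:
                s = int(pos[i]) + 1
                e = min(int(pos[i] + lens[k]), int(y[i]))
                out[i].append((s, e))
        pos[idx] += lens
        state[idx] = ~state[idx]
        active = pos < y
    return out


def _layout_gene(arch: GeneArchitecture) -> None:
    """Assign genomic coordinates on the gene's own contig (mirrored for the
    minus strand)."""
    pos = FLANK_NT
    plus_coords = []
    for i, ln in enumerate(arch.exon_nt):
        plus_coords.append((pos + 1, pos + ln))
        pos += ln
        if i < len(arch.intron_nt):
            pos += arch.intron_nt[i]
    contig_len = pos + FLANK_NT
    utr_plus = None
    if arch.utr_variant:
        first_start = plus_coords[0][0]
        utr_plus = (first_start - 80 - arch.utr_exon_nt, first_start - 81)

    def mirror(iv: tuple[int, int]) -> tuple[int, int]:
        return (contig_len - iv[1] + 1, contig_len - iv[0] + 1)

    if arch.strand == "-":
        arch.exon_coords = [mirror(iv) for iv in plus_coords]
        arch.utr_exon_coords = mirror(utr_plus) if utr_plus else None
    else:
        arch.exon_coords = plus_coords
        arch.utr_exon_coords = utr_plus
    arch.contig_len = contig_len


def _suffix_weighted(sorted_vals: np.ndarray, weights: np.ndarray):
    """Suffix sums of weights and weight*value over ascending sorted_vals."""
    w0 = np.concatenate([np.cumsum(weights[::-1])[::-1], [0.0]])
    w1 = np.concatenate([np.cumsum((weights * sorted_vals)[::-1])[::-1], [0.0]])
    return w0, w1


def _calibrate_anchor_probs(
    cfg: GeneratorConfig, lens: np.ndarray, latent_x: np.ndarray
) -> np.ndarray:
    """Per-exon anchoring probabilities solving the depletion fixed point.

    The anchored-domain pool feeds back into the analytic expected fraction,
    so the anchor probability is chosen genome-wide such that
    q(exon) = c * E(y) * (1 - nt/zero)+ — making the observed/expected ratio
    decline linearly with exon length (zero at ``constrained_zero_nt``) while
    the observed fraction still tracks the placed domains.  Residue counts
    are approximated as nt/3 at this stage; the analyses recompute the exact
    expectation from the emitted domains.
    """
    yhat = lens // 3
    L = float(yhat.sum())
    lin = np.clip(1.0 - lens / cfg.constrained_zero_nt, 0.0, None)
    xs = np.sort(latent_x[latent_x > 0]).astype(float)
    xs_w0, xs_w1 = _suffix_weighted(xs, np.ones_like(xs))
    order = np.argsort(yhat)
    ys = yhat[order].astype(float)
    denom = L - yhat + 1.0

    q = np.zeros(lens.size)
    for _ in range(10):
        j_lat = np.searchsorted(xs, yhat + 1, side="right")
        e_lat = (xs_w1[j_lat] - (yhat + 1) * xs_w0[j_lat]) / denom
        w = q[order]
        w0, w1 = _suffix_weighted(ys, w)
        # anchored domain length is y+2: term (y_i + 2 - y' - 1)+ = (y_i - y' + 1)+
        j_anc = np.searchsorted(ys, yhat, side="left")
        e_anc = (w1[j_anc] - (yhat - 1) * w0[j_anc]) / denom
        e_tot = e_lat + e_anc
        target = e_tot * lin
        peak = target.max()
        if peak <= 0:
            break
        q_new = np.clip(cfg.constrained_base_prob * target / peak, 0.0, 0.9)
        q = 0.5 * q + 0.5 * q_new
    q[latent_x > 0] = 0.0
    return q


def _assemble_gene(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    gene_index: int,
    lens: np.ndarray,
    marked: np.ndarray,
    latent_x: np.ndarray,
) -> GeneArchitecture:
    gid = f"g{gene_index:05d}"
    anchors = list(np.flatnonzero(marked))
    fillers = list(np.flatnonzero(~marked))
    d = len(anchors)

    # distribute fillers over the d+1 gaps around the anchors; long exons go
    # preferentially into inter-domain gaps, rarely downstream of the last
    # domain, and short exons placed between domains are stretched
    gaps: list[list[int]] = [[] for _ in range(d + 1)]
    order = list(rng.permutation(len(fillers)))
    for oi in order:
        fi = fillers[oi]
        if lens[fi] > cfg.long_filler_nt and d >= 1:
            if d >= 2 and rng.random() < cfg.accretion_structure:
                gaps[int(rng.integers(1, d))].append(fi)
            elif rng.random() < cfg.group_b_long_prob:
                gaps[d].append(fi)
            else:
                gaps[0].append(fi)
        else:
            gaps[int(rng.integers(0, d + 1))].append(fi)
    tail_extra = rng.poisson(cfg.tail_extra_lambda)
    extra_lens = list(
        np.clip(
            _lognormal_int(rng, cfg.short_len_median, cfg.short_len_sigma, tail_extra),
            cfg.min_exon_nt,
            cfg.max_exon_nt,
        )
    )

    internal_order: list[tuple[int, bool, int]] = []  # (length, anchored, latent x)
    for g in range(d + 1):
        for fi in gaps[g]:
            ln = int(lens[fi])
            if 1 <= g <= d - 1 and ln <= cfg.long_filler_nt:
                ln = min(cfg.max_exon_nt, int(round(ln * cfg.accretion_gap_scale)))
            internal_order.append((ln, False, int(latent_x[fi])))
        if g < d:
            internal_order.append((int(lens[anchors[g]]), True, 0))
    for ln in extra_lens:
        internal_order.append((int(ln), False, 0))

    term5, term3 = _lognormal_int(rng, cfg.terminal_len_median, cfg.terminal_len_sigma, 2)
    term5 = int(np.clip(term5, cfg.min_exon_nt, cfg.max_exon_nt))
    term3 = int(np.clip(term3, cfg.min_exon_nt, cfg.max_exon_nt))
    exon_nt = [term5] + [ln for ln, _a, _x in internal_order] + [term3]
    if cfg.codon_aligned_exons:
        exon_nt = [max(cfg.min_exon_nt // 3 * 3, (ln // 3) * 3) for ln in exon_nt]
    total = sum(exon_nt)
    exon_nt[-1] += (3 - total % 3) % 3
    total = sum(exon_nt)
    protein_len = total // 3 - 1

    spans = _residue_spans(exon_nt, protein_len)

    # anchored domains: the anchor exon's residue span extended one residue
    # into each neighbouring exon, so both domain boundaries fall just
    # outside the exon (the exon is constrained, its neighbours are not)
    domains: list[tuple[int, int]] = []
    kept_anchor_idx = []
    prev_end = 0
    for i, (_ln, anchored, _x) in enumerate(internal_order):
        ei = 1 + i
        span = spans[ei]
        if span is None:
            continue
        f, l = span
        if anchored:
            ds = max(1, max(f - 1, prev_end + 1))
            de = min(protein_len, l + 1)
            if ds > f or de < l:
                continue  # crowded out; anchor dropped
            domains.append((ds, de))
            kept_anchor_idx.append(ei)
            prev_end = de

    # whole domains inside single long exons: the host exon is longer than
    # the domain, so these leave the constrained classification untouched
    # while carrying most of the domain-length pool of the null model
    for i, (_ln, _anchored, x) in enumerate(internal_order):
        ei = 1 + i
        span = spans[ei]
        if x <= 0 or span is None:
            continue
        f, l = span
        yy = l - f + 1
        x = min(x, yy - 6)
        if x < 50:
            continue
        if any(ds <= l and f <= de for ds, de in domains):
            continue  # host exon already touched by an anchored domain
        off = int(rng.integers(2, yy - x))
        domains.append((f + off, f + off + x - 1))
    domains.sort()

    # disorder blocks per exon, stationary fraction tied to exon length
    alpha = _logit(cfg.idr_base_fraction)
    valid = [i for i, s in enumerate(spans) if s is not None]
    y = np.array([spans[i][1] - spans[i][0] + 1 for i in valid])
    logits = (
        alpha
        + cfg.idr_coupling_beta * np.array([exon_nt[i] for i in valid]) / 120.0
        + rng.normal(0.0, cfg.idr_exon_sd, size=len(valid))
    )
    p = 1.0 / (1.0 + np.exp(-logits))
    # disordered blocks scale with the exon: long disordered exons encode
    # long IDRs, and the per-exon coverage noise stays length-independent
    block = np.maximum(3, (cfg.idr_block_frac * y).astype(int))
    local = _sample_idr_blocks(rng, y, p, block)
    idr_intervals: list[tuple[int, int]] = []
    true_exon_idr = [0.0] * len(exon_nt)
    for k, i in enumerate(valid):
        f = spans[i][0]
        cov = 0
        for s, e in local[k]:
            idr_intervals.append((f + s - 1, f + e - 1))
            cov += e - s + 1
        true_exon_idr[i] = cov / y[k]
    idr_intervals = merge_intervals(idr_intervals)

    utr_variant = rng.random() < cfg.utr_variant_prob
    utr_exon_nt = int(rng.integers(80, 300)) if utr_variant else 0

    arch = GeneArchitecture(
        gene_id=gid,
        protein_id=f"{gid}.p1",
        strand="-" if rng.random() < cfg.minus_strand_prob else "+",
        contig=f"ctg_{gid}",
        exon_nt=exon_nt,
        intron_nt=[int(v) for v in rng.integers(cfg.intron_min_nt, cfg.intron_max_nt + 1,
                                                size=len(exon_nt) - 1)],
        protein_len=protein_len,
        spans=spans,
        anchor_idx=kept_anchor_idx,
        domains=domains,
        idr_intervals=idr_intervals,
        true_exon_idr=true_exon_idr,
        go_terms=[],
        utr_variant=utr_variant,
        utr_exon_nt=utr_exon_nt,
    )
    _layout_gene(arch)
    return arch


def _assign_go_terms(rng, cfg: GeneratorConfig, archs: list[GeneArchitecture]) -> None:
    vocab = [f"GO:{1000000 + i:07d}" for i in range(cfg.n_go_terms - 1)]
    odds_short = cfg.planted_base_prob / (1.0 - cfg.planted_base_prob)
    odds_long = odds_short * cfg.planted_odds_ratio
    p_long = odds_long / (1.0 + odds_long)
    for arch in archs:
        internal = arch.exon_nt[1:-1]
        longest = max(internal) if internal else 0
        p_term = p_long if longest > cfg.long_exon_threshold_nt else cfg.planted_base_prob
        terms = set()
        if rng.random() < p_term:
            terms.add(cfg.planted_go_term)
        k = 1 + rng.poisson(cfg.go_terms_lambda)
        terms.update(rng.choice(vocab, size=min(k, len(vocab)), replace=False).tolist())
        arch.go_terms = sorted(terms)


def sample_genome(cfg: GeneratorConfig, seed: int | np.random.Generator) -> list[GeneArchitecture]:
    """Sample the full genome architecture (no nucleotide sequences).

    Internal-exon lengths are drawn first for the whole genome; anchoring
    probabilities are then calibrated genome-wide (see
    ``_calibrate_anchor_probs``) before genes are assembled one by one.
    """
    cfg.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    counts = 2 + rng.poisson(cfg.internal_pool_lambda, size=cfg.n_genes)
    total = int(counts.sum())
    is_long = rng.random(total) < cfg.long_weight
    lens = np.where(
        is_long,
        _lognormal_int(rng, cfg.long_len_median, cfg.long_len_sigma, total),
        _lognormal_int(rng, cfg.short_len_median, cfg.short_len_sigma, total),
    )
    lens = np.clip(lens, cfg.min_exon_nt, cfg.max_exon_nt)

    # hosts of whole intra-exon domains
    latent_x = np.zeros(total, dtype=int)
    host = (lens >= cfg.latent_host_min_nt) & (rng.random(total) < cfg.latent_domain_prob)
    n_host = int(host.sum())
    if n_host:
        draw = np.rint(rng.normal(cfg.domain_len_mean, cfg.domain_len_sd, n_host)).astype(int)
        latent_x[host] = np.minimum(draw, lens[host] // 3 - 8)

    q = _calibrate_anchor_probs(cfg, lens, latent_x)
    marked = rng.random(total) < q

    archs = []
    offsets = np.concatenate([[0], np.cumsum(counts)])
    for i in range(cfg.n_genes):
        sl = slice(offsets[i], offsets[i + 1])
        archs.append(
            _assemble_gene(rng, cfg, i, lens[sl], marked[sl], latent_x[sl])
        )
    _assign_go_terms(rng, cfg, archs)
    return archs


# ---------------------------------------------------------------------------
# Views onto the analysis interfaces
# ---------------------------------------------------------------------------


def _exon_objects(arch: GeneArchitecture) -> list[Exon]:
    n = len(arch.exon_nt)
    classes = ["first_terminal"] + ["internal"] * (n - 2) + ["last_terminal"]
    return [
        Exon(s, e, cls, ln)
        for (s, e), cls, ln in zip(arch.exon_coords, classes, arch.exon_nt)
    ]


def internal_exon_records(archs: Iterable[GeneArchitecture]) -> list[InternalExonRecord]:
    """Nonredundant internal-exon records straight from the architecture.

    Equivalent to running the gene-model reader and deduplicator on the
    emitted files (asserted by tests); used where building full gene models
    is unnecessary.  In genes with a UTR-bearing second variant the first
    coding exon is internal in that variant and is therefore included.
    """
    records = []
    for arch in archs:
        n = len(arch.exon_nt)
        lo = 0 if arch.utr_variant else 1
        for i in range(lo, n - 1):
            if i == 0:
                exon = Exon(*arch.exon_coords[0], "internal", arch.exon_nt[0])
            else:
                exon = Exon(*arch.exon_coords[i], "internal", arch.exon_nt[i])
            span = arch.spans[i]
            records.append(
                InternalExonRecord(
                    gene_id=arch.gene_id,
                    transcript_id=f"{arch.gene_id}.t1",
                    protein_id=arch.protein_id,
                    exon=exon,
                    first_residue=span[0] if span else None,
                    last_residue=span[1] if span else None,
                )
            )
    return records


def to_gene_models(archs: Iterable[GeneArchitecture]) -> list[GeneModel]:
    """Materialize architectures as GeneModel objects (all variants)."""
    genes = []
    for arch in archs:
        exons = _exon_objects(arch)
        tx_order = exons  # already transcription order
        cds = []
        cum = 0
        for (gs, ge), ln in zip(arch.exon_coords, arch.exon_nt):
            phase = (3 - cum % 3) % 3
            cds.append((gs, ge, phase))
            cum += ln
        t1 = Transcript(
            transcript_id=f"{arch.gene_id}.t1",
            protein_id=arch.protein_id,
            strand=arch.strand,
            exons=list(tx_order),
            cds_intervals=cds,
            seqid=arch.contig,
        )
        transcripts = [t1]
        if arch.utr_variant:
            coords2 = [arch.utr_exon_coords] + list(arch.exon_coords)
            lens2 = [0] + list(arch.exon_nt)
            exons2 = []
            for i, c in enumerate(coords2):
                if i == 0:
                    cls = "first_terminal"
                elif i == len(coords2) - 1:
                    cls = "last_terminal"
                else:
                    cls = "internal"
                exons2.append(Exon(c[0], c[1], cls, lens2[i]))
            transcripts.append(
                Transcript(
                    transcript_id=f"{arch.gene_id}.t2",
                    protein_id=arch.protein_id,
                    strand=arch.strand,
                    exons=exons2,
                    cds_intervals=cds,
                    seqid=arch.contig,
                )
            )
        genes.append(
            GeneModel(
                gene_id=arch.gene_id,
                strand=arch.strand,
                transcripts=transcripts,
                seqid=arch.contig,
            )
        )
    return genes


def idr_annotations(
    archs: Iterable[GeneArchitecture], source: str = "simdis"
) -> dict[str, IntervalAnnotation]:
    return {
        a.protein_id: IntervalAnnotation(a.protein_id, source, "IDR", tuple(a.idr_intervals))
        for a in archs
        if a.idr_intervals
    }


def domain_annotations(
    archs: Iterable[GeneArchitecture], source: str = "SCOP"
) -> dict[str, IntervalAnnotation]:
    return {
        a.protein_id: IntervalAnnotation(a.protein_id, source, "DOMAIN", tuple(a.domains))
        for a in archs
        if a.domains
    }


def go_table(archs: Iterable[GeneArchitecture]) -> GeneTermTable:
    return GeneTermTable({a.gene_id: set(a.go_terms) for a in archs if a.go_terms})


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------


def _random_nt(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _protein_and_cds(rng, protein_len: int) -> tuple[str, str]:
    aa_idx = rng.integers(0, len(AMINO_ACIDS), size=protein_len)
    protein = "".join(AMINO_ACIDS[i] for i in aa_idx)
    codons = []
    for i in aa_idx:
        options = CODONS_BY_AA[AMINO_ACIDS[i]]
        codons.append(options[rng.integers(0, len(options))])
    codons.append(STOP_CODONS[rng.integers(0, 3)])
    return protein, "".join(codons)


def _contig_sequence(arch: GeneArchitecture, cds: str, rng) -> str:
    """Plus-strand contig sequence with the CDS laid into the exon slots."""
    parts = []
    pos = 0  # consumed CDS nt
    cursor = 0  # plus-strand coordinate already built (0-based)
    if arch.strand == "-":
        # genomic order is the reverse of transcription order
        plus_coords = list(arch.exon_coords)[::-1]
        exon_nt = list(arch.exon_nt)[::-1]
    else:
        plus_coords = list(arch.exon_coords)
        exon_nt = list(arch.exon_nt)
    # in plus coordinates the exon order is ascending; for minus-strand genes
    # the CDS runs right-to-left, so fill exons with the reverse-complemented
    # CDS laid left-to-right
    from .gene_models import reverse_complement

    seq_cds = reverse_complement(cds) if arch.strand == "-" else cds
    for (s, e), ln in zip(plus_coords, exon_nt):
        if s - 1 > cursor:
            parts.append(_random_nt(rng, s - 1 - cursor))
        parts.append(seq_cds[pos : pos + ln])
        pos += ln
        cursor = e
    if cursor < arch.contig_len:
        parts.append(_random_nt(rng, arch.contig_len - cursor))
    return "".join(parts)


def _write_fasta(path: str, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _gff_lines(arch: GeneArchitecture) -> list[str]:
    lines = []
    coords = list(arch.exon_coords)
    all_starts = [c[0] for c in coords] + ([arch.utr_exon_coords[0]] if arch.utr_exon_coords else [])
    all_ends = [c[1] for c in coords] + ([arch.utr_exon_coords[1]] if arch.utr_exon_coords else [])
    gs, ge = min(all_starts), max(all_ends)
    st = arch.strand
    gid = arch.gene_id
    lines.append(f"{arch.contig}\tsim\tgene\t{gs}\t{ge}\t.\t{st}\t.\tID={gid}")

    def tx(tid: str, exon_coords: list[tuple[int, int]]) -> None:
        ts = min(c[0] for c in exon_coords)
        te = max(c[1] for c in exon_coords)
        lines.append(
            f"{arch.contig}\tsim\tmRNA\t{ts}\t{te}\t.\t{st}\t.\t"
            f"ID={tid};Parent={gid};protein_id={arch.protein_id}"
        )
        for i, (s, e) in enumerate(exon_coords, start=1):
            lines.append(
                f"{arch.contig}\tsim\texon\t{s}\t{e}\t.\t{st}\t.\t"
                f"ID={tid}.e{i};Parent={tid}"
            )
        cum = 0
        cds_tx_order = sorted(coords, key=lambda c: c[0], reverse=(st == "-"))
        for s, e in cds_tx_order:
            phase = (3 - cum % 3) % 3
            lines.append(
                f"{arch.contig}\tsim\tCDS\t{s}\t{e}\t.\t{st}\t{phase}\t"
                f"ID=cds_{tid};Parent={tid};protein_id={arch.protein_id}"
            )
            cum += e - s + 1

    tx(f"{gid}.t1", sorted(coords))
    if arch.utr_variant and arch.utr_exon_coords:
        tx(f"{gid}.t2", sorted(coords + [arch.utr_exon_coords]))
    return lines


def generate_genome(cfg: GeneratorConfig, outdir: str, seed: int) -> dict[str, str]:
    """Sample a genome and emit GFF3, genome/protein FASTA, IDR/domain/GO
    TSVs and the ground truth; returns the emitted paths."""
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(seed)
    archs = sample_genome(cfg, rng)

    paths = {
        "gff3": os.path.join(outdir, "genes.gff3"),
        "genome": os.path.join(outdir, "genome.fa"),
        "proteins": os.path.join(outdir, "proteins.fa"),
        "idr": os.path.join(outdir, "idr.tsv"),
        "domains": os.path.join(outdir, "domains.tsv"),
        "go": os.path.join(outdir, "go.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }

    contigs = []
    proteins = []
    for arch in archs:
        protein, cds = _protein_and_cds(rng, arch.protein_len)
        contigs.append((arch.contig, _contig_sequence(arch, cds, rng)))
        proteins.append((arch.protein_id, protein))
    _write_fasta(paths["genome"], contigs)
    _write_fasta(paths["proteins"], proteins)

    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for arch in archs:
            fh.write("\n".join(_gff_lines(arch)) + "\n")

    with open(paths["idr"], "w") as fh:
        fh.write("protein_id\tsource\tstart\tend\n")
        for arch in archs:
            for s, e in arch.idr_intervals:
                fh.write(f"{arch.protein_id}\tsimdis\t{s}\t{e}\n")
    with open(paths["domains"], "w") as fh:
        fh.write("protein_id\tsource\tstart\tend\n")
        for arch in archs:
            for s, e in arch.domains:
                fh.write(f"{arch.protein_id}\tSCOP\t{s}\t{e}\n")
    with open(paths["go"], "w") as fh:
        fh.write("gene_id\tterms\n")
        for arch in archs:
            if arch.go_terms:
                fh.write(f"{arch.gene_id}\t{','.join(arch.go_terms)}\n")

    truth = {
        "config": dataclasses.asdict(cfg),
        "seed": seed,
        "genes": [
            {
                "gene_id": a.gene_id,
                "protein_id": a.protein_id,
                "strand": a.strand,
                "exon_nt": a.exon_nt,
                "anchor_idx": a.anchor_idx,
                "true_exon_idr": a.true_exon_idr,
                "utr_variant": a.utr_variant,
            }
            for a in archs
        ],
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    return paths


# ---------------------------------------------------------------------------
# Ortholog trios with planted insertions
# ---------------------------------------------------------------------------


@dataclass
class PlantedInsertion:
    target_lineage: str  # "lineage1" | "lineage2"
    gene_id: str
    protein_id: str
    start: int  # target-protein residue coordinates
    end: int
    whole_exon: bool
    host_exon_index: int  # exon index in the (modified) target transcript


@dataclass
class TrioSet:
    """Everything the insertion analysis consumes, plus the ground truth."""

    alignments: list[TrioAlignment]
    lineage1_genes: list[GeneModel]
    lineage2_genes: list[GeneModel]
    idr_by_protein: dict[str, IntervalAnnotation]
    domains_by_protein: dict[str, IntervalAnnotation]
    truth: list[PlantedInsertion]
    protein_seqs: dict[str, str]

    def transcript_of(self, protein_id: str) -> Transcript:
        for g in self.lineage1_genes + self.lineage2_genes:
            for t in g.transcripts:
                if t.protein_id == protein_id:
                    return t
        raise KeyError(protein_id)


def _insert_into_arch(
    arch: GeneArchitecture,
    rng: np.random.Generator,
    k_res: int,
    whole: bool,
    restriction: str,
) -> tuple[GeneArchitecture, int, int, int] | None:
    """Plant one 3*k_res-nt insertion; returns (new arch, start, end,
    host exon index in the modified transcript) or None if no site fits."""
    n = len(arch.exon_nt)

    def span_free_of_domains(f: int, l: int) -> bool:
        return all(de < f or ds > l for ds, de in arch.domains)

    if not whole:
        hosts = []
        for i in range(1, n - 1):
            span = arch.spans[i]
            if span is None or span[1] - span[0] + 1 < 4:
                continue
            if restriction == "unconstrained_only" and not span_free_of_domains(*span):
                continue
            hosts.append(i)
        if not hosts:
            return None
        i = int(hosts[rng.integers(0, len(hosts))])
        f, l = arch.spans[i]
        p = int(rng.integers(f + 1, l + 1))  # insert before residue p
        exon_nt = list(arch.exon_nt)
        exon_nt[i] += 3 * k_res
        new = replace(
            arch,
            exon_nt=exon_nt,
            intron_nt=list(arch.intron_nt),
            protein_len=arch.protein_len + k_res,
            domains=[
                (ds + k_res, de + k_res) if ds >= p else (ds, de)
                for ds, de in arch.domains
            ],
        )
        new.spans = _residue_spans(new.exon_nt, new.protein_len)
        _layout_gene(new)
        return new, p, p + k_res - 1, i
    # whole-exon: new exon between exons j and j+1
    sites = []
    for j in range(0, n - 1):
        span_next = arch.spans[j + 1]
        if span_next is None:
            continue
        p = span_next[0]
        if all(not (ds <= p - 1 and p <= de) for ds, de in arch.domains):
            sites.append((j, p))
    if not sites:
        return None
    j, p = sites[int(rng.integers(0, len(sites)))]
    exon_nt = list(arch.exon_nt)
    exon_nt.insert(j + 1, 3 * k_res)
    intron_nt = list(arch.intron_nt)
    old = intron_nt[j]
    intron_nt[j] = max(30, old // 2)
    intron_nt.insert(j + 1, max(30, old - old // 2))
    new = replace(
        arch,
        exon_nt=exon_nt,
        intron_nt=intron_nt,
        protein_len=arch.protein_len + k_res,
        domains=[
            (ds + k_res, de + k_res) if ds >= p else (ds, de) for ds, de in arch.domains
        ],
    )
    new.spans = _residue_spans(new.exon_nt, new.protein_len)
    _layout_gene(new)
    return new, p, p + k_res - 1, j + 1


def _idr_for_protein(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    length: int,
    inserted: tuple[int, int] | None,
) -> list[tuple[int, int]]:
    """Background disorder blocks over the protein, overridden inside the
    inserted interval by per-residue calls at the elevated probability."""
    blocks = _sample_idr_blocks(
        rng,
        np.array([length]),
        np.array([cfg.idr_background]),
        cfg.idr_block_mean,
    )[0]
    if inserted is None:
        return merge_intervals(blocks)
    s0, e0 = inserted
    kept = []
    for s, e in blocks:
        for piece_s, piece_e in ((s, min(e, s0 - 1)), (max(s, e0 + 1), e)):
            if piece_s <= piece_e:
                kept.append((piece_s, piece_e))
    calls = rng.random(e0 - s0 + 1) < cfg.idr_probability_inserted
    run = None
    for off, c in enumerate(calls):
        if c and run is None:
            run = s0 + off
        elif not c and run is not None:
            kept.append((run, s0 + off - 1))
            run = None
    if run is not None:
        kept.append((run, e0))
    return merge_intervals(kept)


def generate_ortholog_trios(cfg: GeneratorConfig, seed: int | np.random.Generator) -> TrioSet:
    """Generate aligned ortholog trios with planted lineage-specific
    insertions and the matching lineage gene models and annotations."""
    cfg.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base_cfg = replace(cfg, n_genes=cfg.trio_n_genes, codon_aligned_exons=True,
                       utr_variant_prob=0.0)
    archs = sample_genome(base_cfg, rng)

    n_plant = cfg.n_within_insertions + cfg.n_whole_insertions
    if n_plant > len(archs):
        raise ValueError("trio_n_genes too small for the insertion plan")
    queue = list(rng.permutation(len(archs)))

    # plant the requested number of each insertion type up front, skipping
    # genes without an eligible site, so the plan counts are met exactly
    planted_by_arch: dict[int, tuple[tuple, bool, str]] = {}
    n_assigned = 0
    for count, whole in ((cfg.n_within_insertions, False), (cfg.n_whole_insertions, True)):
        placed = 0
        while placed < count:
            if not queue:
                raise ValueError("not enough genes to host the planned insertions")
            ai = int(queue.pop(0))
            mean = cfg.whole_exon_len_mean if whole else cfg.insertion_len_mean
            k = int(3 + rng.geometric(1.0 / mean))
            result = _insert_into_arch(archs[ai], rng, k, whole, cfg.host_restriction)
            if result is None:
                continue  # gene has no eligible site; stays clean
            lineage = "lineage1" if n_assigned % 2 == 0 else "lineage2"
            n_assigned += 1
            planted_by_arch[ai] = (result, whole, lineage)
            placed += 1

    alignments = []
    l1_genes: list[GeneArchitecture] = []
    l2_genes: list[GeneArchitecture] = []
    idr: dict[str, IntervalAnnotation] = {}
    domains: dict[str, IntervalAnnotation] = {}
    truth: list[PlantedInsertion] = []
    protein_seqs: dict[str, str] = {}
    for ai, arch in enumerate(archs):
        gid = arch.gene_id
        base_protein = "".join(
            AMINO_ACIDS[i] for i in rng.integers(0, 20, size=arch.protein_len)
        )
        per_lineage: dict[str, tuple[GeneArchitecture, tuple[int, int] | None]] = {
            "lineage1": (arch, None),
            "lineage2": (arch, None),
        }
        if ai in planted_by_arch:
            (new_arch, s, e, host_idx), whole, lineage = planted_by_arch[ai]
            per_lineage[lineage] = (new_arch, (s, e))
            truth.append(
                PlantedInsertion(lineage, gid, f"{gid}.{lineage}", s, e, whole, host_idx)
            )

        seqs = {"outgroup": base_protein}
        for lineage in ("lineage1", "lineage2"):
            la, ins = per_lineage[lineage]
            pid = f"{gid}.{lineage}"
            la = replace(la, protein_id=pid, exon_nt=list(la.exon_nt))
            la.spans = list(la.spans)
            per_lineage[lineage] = (la, ins)
            if ins is None:
                seqs[lineage] = base_protein
            else:
                s, e = ins
                inserted_aa = "".join(
                    AMINO_ACIDS[i] for i in rng.integers(0, 20, size=e - s + 1)
                )
                seqs[lineage] = base_protein[: s - 1] + inserted_aa + base_protein[s - 1 :]
            ivs = _idr_for_protein(rng, cfg, la.protein_len, ins)
            if ivs:
                idr[pid] = IntervalAnnotation(pid, "simdis", "IDR", tuple(ivs))
            if la.domains:
                domains[pid] = IntervalAnnotation(pid, "SCOP", "DOMAIN", tuple(la.domains))
            protein_seqs[pid] = seqs[lineage]
        protein_seqs[f"{gid}.outgroup"] = base_protein

        # build alignment rows: gap columns in the two sequences lacking the
        # inserted segment
        def rows() -> tuple[str, str, str]:
            ins1 = per_lineage["lineage1"][1]
            ins2 = per_lineage["lineage2"][1]
            og, r1, r2 = base_protein, seqs["lineage1"], seqs["lineage2"]
            if ins1 is not None:
                s, e = ins1
                gap = "-" * (e - s + 1)
                og = og[: s - 1] + gap + og[s - 1 :]
                r2 = r2[: s - 1] + gap + r2[s - 1 :]
            elif ins2 is not None:
                s, e = ins2
                gap = "-" * (e - s + 1)
                og = og[: s - 1] + gap + og[s - 1 :]
                r1 = r1[: s - 1] + gap + r1[s - 1 :]
            return og, r1, r2

        og_row, l1_row, l2_row = rows()
        alignments.append(
            TrioAlignment(
                outgroup_id=f"{gid}.outgroup",
                lineage1_id=f"{gid}.lineage1",
                lineage2_id=f"{gid}.lineage2",
                outgroup=og_row,
                lineage1=l1_row,
                lineage2=l2_row,
            )
        )
        l1_genes.append(per_lineage["lineage1"][0])
        l2_genes.append(per_lineage["lineage2"][0])

    return TrioSet(
        alignments=alignments,
        lineage1_genes=to_gene_models(l1_genes),
        lineage2_genes=to_gene_models(l2_genes),
        idr_by_protein=idr,
        domains_by_protein=domains,
        truth=truth,
        protein_seqs=protein_seqs,
    )


def _write_gene_models_gff(genes: Sequence[GeneModel], path: str) -> None:
    """Emit gene models as GFF3 (structure only, no genomic sequence)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            coords = [
                (e.genomic_start, e.genomic_end)
                for t in gene.transcripts
                for e in t.exons
            ]
            gs, ge = min(c[0] for c in coords), max(c[1] for c in coords)
            fh.write(
                f"{gene.seqid}\tsim\tgene\t{gs}\t{ge}\t.\t{gene.strand}\t.\tID={gene.gene_id}\n"
            )
            for t in gene.transcripts:
                ts = min(e.genomic_start for e in t.exons)
                te = max(e.genomic_end for e in t.exons)
                fh.write(
                    f"{gene.seqid}\tsim\tmRNA\t{ts}\t{te}\t.\t{t.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={gene.gene_id};protein_id={t.protein_id}\n"
                )
                for i, e in enumerate(t.exons, start=1):
                    fh.write(
                        f"{gene.seqid}\tsim\texon\t{e.genomic_start}\t{e.genomic_end}\t.\t"
                        f"{t.strand}\t.\tID={t.transcript_id}.e{i};Parent={t.transcript_id}\n"
                    )
                for s, e, phase in t.cds_intervals:
                    fh.write(
                        f"{gene.seqid}\tsim\tCDS\t{s}\t{e}\t.\t{t.strand}\t{phase}\t"
                        f"ID=cds_{t.transcript_id};Parent={t.transcript_id};"
                        f"protein_id={t.protein_id}\n"
                    )


def write_trios(trio_set: TrioSet, outdir: str) -> dict[str, str]:
    """Emit aligned FASTA files, the manifest, lineage gene models (GFF3),
    annotations and the truth."""
    os.makedirs(outdir, exist_ok=True)
    aln_dir = os.path.join(outdir, "alignments")
    os.makedirs(aln_dir, exist_ok=True)
    manifest = os.path.join(outdir, "manifest.tsv")
    with open(manifest, "w") as mf:
        mf.write("alignment_file\toutgroup_id\tlineage1_id\tlineage2_id\n")
        for aln in trio_set.alignments:
            gid = aln.outgroup_id.rsplit(".", 1)[0]
            rel = os.path.join("alignments", f"{gid}.afa")
            _write_fasta(
                os.path.join(outdir, rel),
                [
                    (aln.outgroup_id, aln.outgroup),
                    (aln.lineage1_id, aln.lineage1),
                    (aln.lineage2_id, aln.lineage2),
                ],
            )
            mf.write(f"{rel}\t{aln.outgroup_id}\t{aln.lineage1_id}\t{aln.lineage2_id}\n")
    idr_path = os.path.join(outdir, "idr.tsv")
    with open(idr_path, "w") as fh:
        fh.write("protein_id\tsource\tstart\tend\n")
        for pid in sorted(trio_set.idr_by_protein):
            ann = trio_set.idr_by_protein[pid]
            for s, e in ann.intervals:
                fh.write(f"{pid}\t{ann.source}\t{s}\t{e}\n")
    dom_path = os.path.join(outdir, "domains.tsv")
    with open(dom_path, "w") as fh:
        fh.write("protein_id\tsource\tstart\tend\n")
        for pid in sorted(trio_set.domains_by_protein):
            ann = trio_set.domains_by_protein[pid]
            for s, e in ann.intervals:
                fh.write(f"{pid}\t{ann.source}\t{s}\t{e}\n")
    gff1 = os.path.join(outdir, "lineage1.gff3")
    gff2 = os.path.join(outdir, "lineage2.gff3")
    _write_gene_models_gff(trio_set.lineage1_genes, gff1)
    _write_gene_models_gff(trio_set.lineage2_genes, gff2)
    truth_path = os.path.join(outdir, "truth.json")
    with open(truth_path, "w") as fh:
        json.dump([dataclasses.asdict(p) for p in trio_set.truth], fh, indent=1)
    return {
        "manifest": manifest,
        "gff_lineage1": gff1,
        "gff_lineage2": gff2,
        "idr": idr_path,
        "domains": dom_path,
        "truth": truth_path,
    }
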