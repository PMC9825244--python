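"""GO-term over-representation in genes with long internal exons.

Genes whose longest nonredundant internal exon exceeds a length threshold
(720 nt, or 960 nt for extremely long exons) are tested per GO term with a
Pearson chi-square on the 2x2 table of set membership versus term
annotation (df=1, no continuity correction).  A term is enriched when its
in-set count exceeds the expectation and p falls below alpha.  No GO-graph
propagation is performed; terms are used as annotated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .gene_models import GeneModel, nonredundant_internal_exons
from .stats import benjamini_hochberg, pearson_chi2

logger = logging.getLogger("exarch")

__all__ = [
    "GeneTermTable",
    "read_gene_term_table",
    "long_exon_gene_set",
    "term_enrichment",
]

LONG_EXON_NT = 720
EXTREME_EXON_NT = 960


@dataclass
class GeneTermTable:
    """gene_id -> set of GO terms; the universe is every annotated gene
    (restricted downstream to genes with internal exons)."""

    terms_by_gene: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.terms_by_gene = {g: set(t) for g, t in self.terms_by_gene.items() if t}

    @property
    def universe(self) -> set[str]:
        return set(self.terms_by_gene)

    @property
    def terms(self) -> set[str]:
        out: set[str] = set()
        for t in self.terms_by_gene.values():
            out |= t
        return out


def read_gene_term_table(tsv_path: str) -> GeneTermTable:
    """Read a TSV of gene_id<TAB>comma-or-tab-separated GO terms."""
    table: dict[str, set[str]] = {}
    with open(tsv_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_id"):
                continue
            fields = line.split("\t")
            gene = fields[0]
            terms = set()
            for f in fields[1:]:
                terms.update(t for t in f.split(",") if t)
            if terms:
                table.setdefault(gene, set()).update(terms)
    return GeneTermTable(table)


def long_exon_gene_set(
    genes: Iterable[GeneModel], threshold_nt: int = LONG_EXON_NT
) -> set[str]:
    """Genes with at least one nonredundant internal exon longer than the
    threshold."""
    if threshold_nt < 0:
        raise ValueError("threshold must be non-negative")
    selected = set()
    for rec in nonredundant_internal_exons(genes):
        if rec.nt_length > threshold_nt:
            selected.add(rec.gene_id)
    return selected


def term_enrichment(
    selected: set[str],
    table: GeneTermTable,
    universe: set[str] | None = None,
    alpha: float = 0.05,
    adjust: bool = False,
) -> list[dict]:
    """Per-term 2x2 chi-square enrichment of the selected gene set.

    The universe defaults to all annotated genes; the selected set must be a
    subset of it.  Terms with a zero margin (annotating every gene or none in
    the universe) are skipped.  ``adjust`` adds Benjamini-Hochberg adjusted
    p-values (the enriched flag then uses them).
    """
    universe = universe if universe is not None else table.universe
    selected = selected & universe
    n_sel = len(selected)
    n_out = len(universe) - n_sel
    if n_sel == 0 or n_out == 0:
        raise ValueError("selected set must be a non-empty strict subset of the universe")

    rows = []
    for term in sorted(table.terms):
        with_term = {g for g in universe if term in table.terms_by_gene.get(g, ())}
        a = len(with_term & selected)
        b = n_sel - a
        c = len(with_term) - a
        d = n_out - c
        if len(with_term) == 0 or len(with_term) == len(universe):
            logger.info("term %s has a zero margin; skipped", term)
            continue
        chi2, p = pearson_chi2([[a, b], [c, d]])
        expected_a = n_sel * len(with_term) / len(universe)
        rows.append(
            {
                "term": term,
                "selected_with_term": a,
                "selected_without_term": b,
                "other_with_term": c,
                "other_without_term": d,
                "expected_selected_with_term": expected_a,
                "chi2": chi2,
                "p": p,
                "enriched": bool(a > expected_a and p < alpha),
            }
        )
    if adjust and rows:
        adj = benjamini_hochberg([r["p"] for r in rows])
        for r, q in zip(rows, adj):
            r["p_adjusted"] = float(q)
            r["enriched"] = bool(
                r["selected_with_term"] > r["expected_selected_with_term"] and q < alpha
            )
    return rows
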