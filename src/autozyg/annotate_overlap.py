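"""ROH–gene overlap and keyword triage of enrichment tables.

``overlap_genes`` intersects ROH segments (1-based inclusive) with gene
annotations (BED, 0-based half-open); any overlap of at least one base
pair assigns the gene to the segment, the permissive rule standard for
ROH gene reporting (switchable to full containment).

``keyword_triage`` reproduces the manual step of scanning an exported
enrichment-portal table for phenotype keywords: a row is retained when
its term contains any keyword case-insensitively as a substring. The
default keyword list targets sex-development phenotypes; the two printed
variants "hermaphroditism"/"hermaphroditic" are covered by the single
stem "hermaphrodit".
"""

from __future__ import annotations

import fnmatch
import os
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from .vcf_io import FormatError, GeneInterval

DEFAULT_KEYWORDS = ("Development", "Sex", "hermaphrodit")

#: Name patterns for genes an enrichment portal typically fails to map:
#: microRNAs and olfactory receptors.
DEFAULT_EXCLUDE_PATTERNS = ("MIR*", "OR*")

CATEGORIES = ("Biological Process", "Mouse Phenotype", "Disease", "PubMed")


@dataclass(frozen=True)
class EnrichmentRow:
    category: str
    term: str
    genes: tuple
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.term:
            raise ValueError("term must be non-empty")


def overlap_genes(segments: Sequence, genes: Sequence[GeneInterval],
                  *, containment: bool = False) -> Tuple[dict, list]:
    """Assign genes to ROH segments by interval intersection.

    Returns ``(per_segment, union)`` where ``per_segment`` maps each
    segment to the sorted list of overlapping gene names and ``union`` is
    the sorted, deduplicated union across segments. With
    ``containment=True`` a gene must lie entirely inside the segment.
    """
    trees: dict = {}
    for g in genes:
        # BED half-open [start, end) -> 1-based inclusive [start+1, end]
        trees.setdefault(g.chromosome, IntervalTree()).addi(
            g.start + 1, g.end + 1, g.gene_name)
    per_segment: dict = {}
    union: set = set()
    for seg in segments:
        hits = []
        tree = trees.get(seg.chromosome)
        if tree is not None:
            for iv in tree.overlap(seg.start_bp, seg.end_bp + 1):
                if containment and not (seg.start_bp <= iv.begin
                                        and iv.end - 1 <= seg.end_bp):
                    continue
                hits.append(iv.data)
        names = sorted(set(hits))
        per_segment[seg] = names
        union.update(names)
    return per_segment, sorted(union)


def keyword_triage(rows: Sequence[EnrichmentRow],
                   keywords: Sequence[str] = DEFAULT_KEYWORDS
                   ) -> Tuple[list, dict, list]:
    """Filter enrichment rows by term keywords.

    Returns ``(retained, counts, genes)``: the retained rows in input
    order, per-category retained counts, and the sorted deduplicated
    union of genes across retained rows.
    """
    if not keywords or any(not k for k in keywords):
        raise ValueError("keywords must be a non-empty list of non-empty strings")
    lowered = [k.lower() for k in keywords]
    retained = [r for r in rows
                if any(k in r.term.lower() for k in lowered)]
    counts = dict(Counter(r.category for r in retained))
    genes: set = set()
    for r in retained:
        genes.update(r.genes)
    return retained, counts, sorted(genes)


def exclude_gene_patterns(gene_names: Iterable[str],
                          patterns: Sequence[str] = DEFAULT_EXCLUDE_PATTERNS
                          ) -> list:
    """Drop gene names matching any shell-style pattern (case-insensitive).

    Emulates the portal-side loss of unmapped identifiers (predominantly
    miRNA and olfactory-receptor names). Note the default ``OR*`` pattern
    is deliberately broad, as such portals drop most OR-prefixed symbols.
    """
    upper_patterns = [p.upper() for p in patterns]
    return [g for g in gene_names
            if not any(fnmatch.fnmatchcase(g.upper(), p) for p in upper_patterns)]


def read_enrichment_table(path: str | os.PathLike) -> list:
    """Read a tab-separated enrichment export (category, term, score, genes).

    The score column may be empty; genes are comma-joined.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if lineno == 1 and line.lower().startswith("category\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 tab-separated "
                                  f"columns, got {len(fields)}")
            category, term, score_s, genes_s = fields[:4]
            rows.append(EnrichmentRow(
                category=category, term=term,
                genes=tuple(g for g in genes_s.split(",") if g),
                score=float(score_s) if score_s else None))
    return rows


def write_enrichment_table(rows: Sequence[EnrichmentRow],
                           path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("category\tterm\tscore\tgenes\n")
        for r in rows:
            score = "" if r.score is None else repr(r.score)
            fh.write(f"{r.category}\t{r.term}\t{score}\t{','.join(r.genes)}\n")
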