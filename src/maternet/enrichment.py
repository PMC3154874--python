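"""Term over-representation of a gene list against a reference universe,
with rollup of enriched terms into expert-defined macro categories."""

from __future__ import annotations

import fnmatch
import json
from dataclasses import dataclass

from .annotation import NAMESPACES, AnnotationCorpus
from .errors import FormatError, ValidationError
from .expression import DIRECTION_DOWN, DIRECTION_UP, ContrastCall, normalize_gene
from .stats import hypergeom_upper_tail

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class EnrichmentRecord:
    term: str
    namespace: str
    annotated_in_list: int
    annotated_in_universe: int
    p_value: float
    list_genes: frozenset[str]
    macro_category: str = UNASSIGNED


@dataclass(frozen=True)
class MacroCategoryMap:
    """term id (or fnmatch glob on term ids) -> category label; first match wins."""

    mapping: tuple[tuple[str, str], ...] = ()

    @classmethod
    def from_dict(cls, mapping: dict[str, str]) -> "MacroCategoryMap":
        return cls(mapping=tuple(sorted(mapping.items())))

    def category(self, term: str) -> str:
        for pattern, cat in self.mapping:
            if term == pattern or fnmatch.fnmatchcase(term, pattern):
                return cat
        return UNASSIGNED


def load_macro_map(path) -> MacroCategoryMap:
    pairs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected term_or_glob<TAB>category")
            pairs.append((parts[0], parts[1]))
    return MacroCategoryMap(mapping=tuple(pairs))


def enrich_terms(gene_list: set[str], corpus: AnnotationCorpus, universe: set[str],
                 p_threshold: float = 0.01,
                 macro_map: MacroCategoryMap | None = None) -> list[EnrichmentRecord]:
    """One upper-tail hypergeometric test per term hit by the gene list.

    No term propagation: a gene counts for exactly the terms assigned in the
    corpus. Records with p <= p_threshold are kept, sorted by (p, term id).
    """
    gene_list = {normalize_gene(g) for g in gene_list}
    universe = {normalize_gene(g) for g in universe}
    if not gene_list:
        raise ValidationError("empty gene list")
    if not universe:
        raise ValidationError("empty universe")
    if not gene_list <= universe:
        raise ValidationError(
            f"gene list not contained in universe: {sorted(gene_list - universe)}")
    if not universe <= corpus.genes:
        raise ValidationError(
            f"universe genes missing from corpus: {sorted(universe - corpus.genes)}")

    records = []
    N, n = len(universe), len(gene_list)
    for ns in NAMESPACES:
        term_to_universe: dict[str, set[str]] = {}
        for g in universe:
            for t in corpus.terms(g, ns):
                term_to_universe.setdefault(t, set()).add(g)
        for term, annotated in term_to_universe.items():
            hits = annotated & gene_list
            if not hits:
                continue
            p = hypergeom_upper_tail(N, len(annotated), n, len(hits))
            if p <= p_threshold:
                cat = macro_map.category(term) if macro_map else UNASSIGNED
                records.append(EnrichmentRecord(
                    term=term, namespace=ns, annotated_in_list=len(hits),
                    annotated_in_universe=len(annotated), p_value=p,
                    list_genes=frozenset(hits), macro_category=cat))
    return sorted(records, key=lambda r: (r.p_value, r.term))


def rollup_macro(records: list[EnrichmentRecord], macro_map: MacroCategoryMap,
                 stage1_calls: list[ContrastCall]) -> dict[str, tuple[int, int]]:
    """Per-category distinct-gene (n_up, n_down) tallies from enriched terms.

    A gene annotated to terms of two categories is counted in both; category
    tallies are therefore not a partition of the gene list.
    """
    if not records:
        raise ValidationError("no enrichment records to roll up")
    direction = {c.gene: c.direction for c in stage1_calls}
    per_category: dict[str, set[str]] = {}
    for rec in records:
        cat = macro_map.category(rec.term)
        per_category.setdefault(cat, set()).update(rec.list_genes)
    out: dict[str, tuple[int, int]] = {}
    for cat, genes in sorted(per_category.items()):
        n_up = sum(1 for g in genes if direction.get(g) == DIRECTION_UP)
        n_down = sum(1 for g in genes if direction.get(g) == DIRECTION_DOWN)
        out[cat] = (n_up, n_down)
    return out


def write_enrichment_report(records: list[EnrichmentRecord], path,
                            rollup: dict[str, tuple[int, int]] | None = None) -> None:
    """JSON report: every record with its full hypergeometric context."""
    payload = {
        "records": [
            {
                "term": r.term,
                "namespace": r.namespace,
                "annotated_in_list": r.annotated_in_list,
                "annotated_in_universe": r.annotated_in_universe,
                "p_value": r.p_value,
                "macro_category": r.macro_category,
                "list_genes": sorted(r.list_genes),
            }
            for r in records
        ],
    }
    if rollup is not None:
        payload["macro_rollup"] = {cat: {"n_up": u, "n_down": d}
                                   for cat, (u, d) in rollup.items()}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_enrichment_tsv(records: list[EnrichmentRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term\tnamespace\tannotated_in_list\tannotated_in_universe\t"
                 "p_value\tmacro_category\n")
        for r in records:
            fh.write(f"{r.term}\t{r.namespace}\t{r.annotated_in_list}\t"
                     f"{r.annotated_in_universe}\t{r.p_value:.6g}\t{r.macro_category}\n")
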