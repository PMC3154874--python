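"""Gene-gene annotation-similarity networks over GO and MeSH term vectors.

Per namespace, similarity is the cosine of term-incidence vectors (binary by
default, optionally idf-weighted); an edge exists iff at least one namespace
similarity strictly exceeds the cutoff. Edge support records which namespaces
cleared the cutoff on their own (GO, MESH, or BOTH).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

from .errors import FormatError, ValidationError
from .expression import normalize_gene

NAMESPACES = ("GO", "MESH")

SUPPORT_GO = "GO"
SUPPORT_MESH = "MESH"
SUPPORT_BOTH = "BOTH"


@dataclass
class AnnotationCorpus:
    """gene -> namespace -> set of term ids, plus per-namespace term universes."""

    assignments: dict[str, dict[str, frozenset[str]]] = field(default_factory=dict)
    term_universe: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ns in NAMESPACES:
            self.term_universe.setdefault(ns, set())
        for gene, per_ns in self.assignments.items():
            for ns, terms in per_ns.items():
                if ns not in NAMESPACES:
                    raise ValidationError(f"{gene}: unknown namespace {ns!r}")
                missing = set(terms) - self.term_universe[ns]
                if missing:
                    self.term_universe[ns] |= missing

    @property
    def genes(self) -> set[str]:
        return set(self.assignments)

    def terms(self, gene: str, namespace: str) -> frozenset[str]:
        if gene not in self.assignments:
            raise ValidationError(f"unknown gene {gene!r}")
        if namespace not in NAMESPACES:
            raise ValidationError(f"unknown namespace {namespace!r}")
        return self.assignments[gene].get(namespace, frozenset())

    def document_frequency(self, namespace: str) -> dict[str, int]:
        df: dict[str, int] = {}
        for per_ns in self.assignments.values():
            for t in per_ns.get(namespace, ()):
                df[t] = df.get(t, 0) + 1
        return df


@dataclass(frozen=True)
class SimilarityEdge:
    """Undirected similarity edge; gene_a < gene_b lexicographically."""

    gene_a: str
    gene_b: str
    sim_go: float | None
    sim_mesh: float | None
    support: str
    weight: float

    def __post_init__(self) -> None:
        if not self.gene_a < self.gene_b:
            raise ValidationError(f"edge endpoints unordered: {self.gene_a}, {self.gene_b}")


@dataclass
class AnnotationNetwork:
    """Undirected annotation-similarity graph with a similarity cutoff."""

    graph: nx.Graph
    cutoff: float

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> list[SimilarityEdge]:
        out = []
        for a, b, data in self.graph.edges(data=True):
            a, b = sorted((a, b))
            out.append(SimilarityEdge(gene_a=a, gene_b=b,
                                      sim_go=data.get("sim_go"),
                                      sim_mesh=data.get("sim_mesh"),
                                      support=data["support"],
                                      weight=data["weight"]))
        return sorted(out, key=lambda e: (-e.weight, e.gene_a, e.gene_b))


def load_annotations(path) -> AnnotationCorpus:
    """Read a 3-column annotation TSV: gene, namespace (GO/MESH), term."""
    assignments: dict[str, dict[str, set[str]]] = {}
    n_rows = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 tab-separated fields")
            gene, ns, term = parts
            if ns not in NAMESPACES:
                raise FormatError(f"{path}:{lineno}: unknown namespace {ns!r}")
            if not term:
                raise FormatError(f"{path}:{lineno}: empty term")
            g = normalize_gene(gene)
            assignments.setdefault(g, {}).setdefault(ns, set()).add(term)
            n_rows += 1
    if n_rows == 0:
        raise ValidationError(f"{path}: no annotation rows")
    frozen = {g: {ns: frozenset(ts) for ns, ts in per.items()}
              for g, per in assignments.items()}
    return AnnotationCorpus(assignments=frozen)


def write_annotations(corpus: AnnotationCorpus, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene in sorted(corpus.assignments):
            for ns in NAMESPACES:
                for term in sorted(corpus.assignments[gene].get(ns, ())):
                    fh.write(f"{gene}\t{ns}\t{term}\n")


def annotation_similarity(corpus: AnnotationCorpus, a: str, b: str, namespace: str,
                          weighting: str = "binary") -> float | None:
    """Cosine similarity of two genes' term vectors in one namespace.

    Binary weighting reduces to |A∩B| / sqrt(|A|·|B|). Returns None (not 0)
    when either gene has no terms in the namespace: unannotated is not the
    same as dissimilar.
    """
    terms_a = corpus.terms(a, namespace)
    terms_b = corpus.terms(b, namespace)
    if not terms_a or not terms_b:
        return None
    if weighting == "binary":
        num = len(terms_a & terms_b)
        return num / math.sqrt(len(terms_a) * len(terms_b))
    if weighting == "idf":
        df = corpus.document_frequency(namespace)
        n_genes = max(1, len(corpus.assignments))
        # smoothed idf keeps weights positive even for universally shared terms
        w = {t: math.log(1 + n_genes / df.get(t, 1)) for t in terms_a | terms_b}
        num = sum(w[t] ** 2 for t in terms_a & terms_b)
        na = math.sqrt(sum(w[t] ** 2 for t in terms_a))
        nb = math.sqrt(sum(w[t] ** 2 for t in terms_b))
        return num / (na * nb)
    raise ValidationError(f"unknown weighting {weighting!r}")


def _edge_attrs(sim_go: float | None, sim_mesh: float | None,
                cutoff: float) -> dict | None:
    go_ok = sim_go is not None and sim_go > cutoff
    mesh_ok = sim_mesh is not None and sim_mesh > cutoff
    if not (go_ok or mesh_ok):
        return None
    support = SUPPORT_BOTH if (go_ok and mesh_ok) else (SUPPORT_GO if go_ok else SUPPORT_MESH)
    weight = max(s for s in (sim_go, sim_mesh) if s is not None)
    attrs = {"support": support, "weight": float(weight)}
    if sim_go is not None:
        attrs["sim_go"] = float(sim_go)
    if sim_mesh is not None:
        attrs["sim_mesh"] = float(sim_mesh)
    return attrs


def build_network(corpus: AnnotationCorpus, genes: set[str], cutoff: float = 0.7,
                  weighting: str = "binary") -> AnnotationNetwork:
    """All-pairs thresholded similarity network over the given genes.

    An edge is created iff at least one namespace similarity STRICTLY exceeds
    the cutoff; a similarity exactly at the cutoff is not an edge.
    """
    genes = {normalize_gene(g) for g in genes}
    unknown = genes - corpus.genes
    if unknown:
        raise ValidationError(f"genes not in corpus: {sorted(unknown)}")
    if len(genes) < 2:
        raise ValidationError("need at least 2 genes to build a network")
    if not 0 < cutoff < 1:
        raise ValidationError("cutoff must be in (0, 1)")

    graph = nx.Graph(cutoff=float(cutoff))
    ordered = sorted(genes)
    graph.add_nodes_from(ordered)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            sim_go = annotation_similarity(corpus, a, b, "GO", weighting)
            sim_mesh = annotation_similarity(corpus, a, b, "MESH", weighting)
            attrs = _edge_attrs(sim_go, sim_mesh, cutoff)
            if attrs is not None:
                graph.add_edge(a, b, **attrs)
    return AnnotationNetwork(graph=graph, cutoff=float(cutoff))


def export_network(network: AnnotationNetwork, path, format: str = "graphml") -> None:
    """Write GraphML (full edge attributes) or SIF (support as interaction type)."""
    if network.graph.number_of_nodes() == 0:
        raise ValidationError("refusing to export an empty network")
    if format == "graphml":
        nx.write_graphml(network.graph, path)
    elif format == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            isolated = sorted(n for n in network.graph.nodes
                              if network.graph.degree(n) == 0)
            for e in network.edges:
                fh.write(f"{e.gene_a}\t{e.support}\t{e.gene_b}\n")
            for n in isolated:
                fh.write(f"{n}\n")
    else:
        raise ValidationError(f"unknown format {format!r}")


def import_network(path) -> AnnotationNetwork:
    """Read a GraphML file written by :func:`export_network`."""
    graph = nx.read_graphml(path)
    graph = nx.relabel_nodes(graph, str)
    cutoff = float(graph.graph.get("cutoff", 0.7))
    return AnnotationNetwork(graph=graph, cutoff=cutoff)
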