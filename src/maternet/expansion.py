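"""Bait-seeded, hop-limited network expansion with expression overlay.

Expansion is a multi-source BFS from the bait set, keeping genes within a hop
budget (a "< 3 sequential connections" phrasing maps to max_hops = 2).
Expression calls from the two stages partition expanded genes into a Venn
labelling, and connected components of the kept subgraph become clusters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx

from .annotation import AnnotationCorpus, AnnotationNetwork, build_network
from .errors import ValidationError
from .expression import DIRECTION_NOT_EXPRESSED, ContrastCall, normalize_gene

logger = logging.getLogger(__name__)

VENN_STAGE1_ONLY = "stage1_only"
VENN_STAGE2_ONLY = "stage2_only"
VENN_BOTH = "both"
VENN_UNEXPRESSED = "bait_unexpressed"
VENN_LABELS = (VENN_STAGE1_ONLY, VENN_STAGE2_ONLY, VENN_BOTH, VENN_UNEXPRESSED)


@dataclass(frozen=True)
class BaitSet:
    genes: frozenset[str]
    label: str = "baits"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError("bait set is empty")
        object.__setattr__(self, "genes",
                           frozenset(normalize_gene(g) for g in self.genes))


@dataclass(frozen=True)
class GeneCluster:
    cluster_id: int
    members: frozenset[str]
    core_members: frozenset[str]
    bait_members: frozenset[str]

    @property
    def has_core(self) -> bool:
        return bool(self.core_members)


@dataclass
class ExpandedNetwork:
    network: AnnotationNetwork
    bait_distance: dict[str, int]
    venn_label: dict[str, str]
    clusters: list[GeneCluster] = field(default_factory=list)

    def venn_counts(self) -> dict[str, int]:
        counts = {label: 0 for label in VENN_LABELS}
        for label in self.venn_label.values():
            counts[label] += 1
        return counts

    def expressed_gene_count(self) -> int:
        """Count of expanded genes expressed at >= 1 stage (the network components)."""
        return sum(1 for v in self.venn_label.values() if v != VENN_UNEXPRESSED)

    def summary(self) -> dict:
        return {
            "n_genes": len(self.venn_label),
            "n_expressed": self.expressed_gene_count(),
            "venn_counts": self.venn_counts(),
            "n_clusters": len(self.clusters),
            "clusters": [
                {
                    "cluster_id": c.cluster_id,
                    "size": len(c.members),
                    "members": sorted(c.members),
                    "core_members": sorted(c.core_members),
                    "bait_members": sorted(c.bait_members),
                    "has_core": c.has_core,
                }
                for c in self.clusters
            ],
        }

    def to_json(self, path) -> None:
        report = self.summary()
        report["bait_distance"] = {g: self.bait_distance[g]
                                   for g in sorted(self.bait_distance)}
        report["venn_label"] = {g: self.venn_label[g] for g in sorted(self.venn_label)}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")


def load_baits(path, label: str = "baits") -> BaitSet:
    """One symbol per line; '#' comments and blank lines skipped."""
    genes = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(normalize_gene(line))
    return BaitSet(genes=frozenset(genes), label=label)


def hop_expand(network: AnnotationNetwork, baits: BaitSet,
               max_hops: int = 2) -> dict[str, int]:
    """Multi-source BFS hop distances from the bait set, truncated at max_hops.

    Baits absent from the network are skipped with a warning; if none remain,
    an error listing the missing baits is raised.
    """
    if max_hops < 0:
        raise ValidationError("max_hops must be >= 0")
    present = baits.genes & set(network.graph.nodes)
    missing = baits.genes - present
    if not present:
        raise ValidationError(f"no bait present in the network; missing: {sorted(missing)}")
    if missing:
        logger.warning("baits absent from network (skipped): %s", sorted(missing))
    dist = nx.multi_source_dijkstra_path_length(
        network.graph, present, cutoff=max_hops, weight=None)
    return {g: int(d) for g, d in dist.items()}


def overlay_expression(genes: set[str], stage1_calls: list[ContrastCall],
                       stage2_calls: list[ContrastCall]) -> dict[str, str]:
    """Label each gene by the stages at which it is expressed.

    A gene is expressed at a stage iff its call there is not not_expressed;
    a gene missing from a stage's call list is treated as not_expressed
    (with a warning when missing from both).
    """
    by_gene1 = {c.gene: c for c in stage1_calls}
    by_gene2 = {c.gene: c for c in stage2_calls}
    labels: dict[str, str] = {}
    for gene in genes:
        c1, c2 = by_gene1.get(gene), by_gene2.get(gene)
        if c1 is None and c2 is None:
            logger.warning("gene %s missing from both call lists; treated as not expressed",
                           gene)
        e1 = c1 is not None and c1.direction != DIRECTION_NOT_EXPRESSED
        e2 = c2 is not None and c2.direction != DIRECTION_NOT_EXPRESSED
        if e1 and e2:
            labels[gene] = VENN_BOTH
        elif e1:
            labels[gene] = VENN_STAGE1_ONLY
        elif e2:
            labels[gene] = VENN_STAGE2_ONLY
        else:
            labels[gene] = VENN_UNEXPRESSED
    return labels


def extract_clusters(network: AnnotationNetwork, kept_genes: set[str],
                     venn_label: dict[str, str] | None = None,
                     baits: BaitSet | None = None) -> list[GeneCluster]:
    """Connected components of the induced subgraph, numbered by decreasing size.

    Ties broken by the lexicographically smallest member. Whether every
    cluster holds a core ("both"-labelled) gene is reported, not enforced.
    """
    unknown = kept_genes - set(network.graph.nodes)
    if unknown:
        raise ValidationError(f"kept genes not in network: {sorted(unknown)}")
    if not kept_genes:
        return []
    venn_label = venn_label or {}
    bait_genes = baits.genes if baits else frozenset()
    sub = network.graph.subgraph(kept_genes)
    components = sorted(nx.connected_components(sub),
                        key=lambda c: (-len(c), min(c)))
    clusters = []
    for i, comp in enumerate(components, start=1):
        members = frozenset(comp)
        clusters.append(GeneCluster(
            cluster_id=i,
            members=members,
            core_members=frozenset(g for g in members
                                   if venn_label.get(g) == VENN_BOTH),
            bait_members=members & bait_genes,
        ))
    return clusters


def expand_pipeline(corpus: AnnotationCorpus, baits: BaitSet,
                    stage1_calls: list[ContrastCall],
                    stage2_calls: list[ContrastCall],
                    cutoff: float = 0.7, max_hops: int = 2,
                    weighting: str = "binary",
                    network: AnnotationNetwork | None = None) -> ExpandedNetwork:
    """build_network -> hop_expand -> overlay_expression -> extract_clusters.

    The network is built over all corpus genes first and intersected with
    expression afterwards (annotated-then-expressed order); pass a prebuilt
    ``network`` to skip the all-pairs step.
    """
    if network is None:
        network = build_network(corpus, corpus.genes, cutoff=cutoff, weighting=weighting)
    distances = hop_expand(network, baits, max_hops=max_hops)
    expanded_genes = set(distances)
    sub = AnnotationNetwork(graph=network.graph.subgraph(expanded_genes).copy(),
                            cutoff=network.cutoff)
    venn = overlay_expression(expanded_genes, stage1_calls, stage2_calls)
    clusters = extract_clusters(sub, expanded_genes, venn_label=venn, baits=baits)
    return ExpandedNetwork(network=sub, bait_distance=distances,
                           venn_label=venn, clusters=clusters)
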