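"""Seeded synthetic fixtures with machine-readable truth tables.

The generator plants three kinds of structure so every pipeline stage has a
known answer: annotation modules whose members share a term core (recoverable
by thresholded similarity), a minority of genes with an (up, down) reversal
expression pattern across the two stages, and per-gene expression
compartments (stage-1 only / stage-2 only / both / unexpressed). Planting is
by deterministic assignment of seeded-shuffled gene indices, so truth counts
are exact, and identical configs produce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .annotation import AnnotationCorpus, write_annotations
from .errors import ValidationError
from .expansion import (
    VENN_BOTH,
    VENN_STAGE1_ONLY,
    VENN_STAGE2_ONLY,
    VENN_UNEXPRESSED,
    BaitSet,
)
from .expression import (
    DIRECTION_NOT_EXPRESSED,
    DIRECTION_UNCHANGED,
    DIRECTION_UP,
    DIRECTION_DOWN,
    ExpressionTable,
    write_expression_table,
)
from .stats import GeneSet, write_gmt

logger = logging.getLogger(__name__)

BUNDLE_VERSION = "1"


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 500
    n_modules: int = 3
    module_size: int = 8
    within_module_term_overlap: float = 0.9
    background_term_rate: float = 2.0
    n_terms_per_namespace: int = 400
    n_baits: int = 5
    reversal_fraction: float = 0.1
    effect_ratio: float = 3.0
    noise_cv: float = 0.2
    detection_noise: float = 0.0
    seed: int = 7
    # plumbing knobs beyond the planted-structure core
    module_term_count: int = 10  # terms per module gene per namespace (core + private)
    n_samples: int = 2
    frac_stage1_only: float = 0.10
    frac_stage2_only: float = 0.05
    frac_unexpressed: float = 0.05
    external_fraction: float = 0.30
    base_signal: float = 100.0

    def __post_init__(self) -> None:
        if self.n_modules * self.module_size > self.n_genes:
            raise ValidationError("n_modules * module_size must be <= n_genes")
        if not self.effect_ratio > 1:
            raise ValidationError("effect_ratio must be > 1")
        for name in ("within_module_term_overlap", "reversal_fraction",
                     "frac_stage1_only", "frac_stage2_only", "frac_unexpressed",
                     "external_fraction", "detection_noise"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.noise_cv < 0 or self.background_term_rate < 0:
            raise ValidationError("noise_cv and background_term_rate must be >= 0")
        if self.n_samples < 1 or self.n_baits < 1:
            raise ValidationError("n_samples and n_baits must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass(frozen=True)
class TruthRecord:
    module_id: int | None
    true_pattern: tuple[str, str]
    true_venn: str
    in_external_set: bool


@dataclass
class TruthTable:
    records: dict[str, TruthRecord] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return sorted(self.records)

    def module_partition(self) -> dict[str, int]:
        return {g: r.module_id for g, r in self.records.items()
                if r.module_id is not None}

    def reversal_genes(self) -> set[str]:
        return {g for g, r in self.records.items()
                if r.true_pattern == (DIRECTION_UP, DIRECTION_DOWN)}

    def venn_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records.values():
            counts[r.true_venn] = counts.get(r.true_venn, 0) + 1
        return counts

    def external_genes(self) -> set[str]:
        return {g for g, r in self.records.items() if r.in_external_set}

    def to_json(self, path, config: SimulationConfig | None = None) -> None:
        payload = {
            "version": BUNDLE_VERSION,
            "genes": {
                g: {
                    "module_id": r.module_id,
                    "true_pattern": list(r.true_pattern),
                    "true_venn": r.true_venn,
                    "in_external_set": r.in_external_set,
                }
                for g, r in sorted(self.records.items())
            },
        }
        if config is not None:
            payload["config"] = dataclasses.asdict(config)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        records = {
            g: TruthRecord(module_id=rec["module_id"],
                           true_pattern=tuple(rec["true_pattern"]),
                           true_venn=rec["true_venn"],
                           in_external_set=rec["in_external_set"])
            for g, rec in payload["genes"].items()
        }
        return cls(records=records)


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _plant_assignments(
    config: SimulationConfig,
) -> tuple[list[str], dict[str, int | None], dict[str, str], set[str]]:
    """Seeded assignment of module ids and Venn compartments. Counts are exact."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    genes = _gene_names(config.n_genes)
    n = config.n_genes

    module_of: dict[str, int | None] = {g: None for g in genes}
    module_perm = rng.permutation(n)
    idx = 0
    for m in range(config.n_modules):
        for _ in range(config.module_size):
            module_of[genes[module_perm[idx]]] = m
            idx += 1

    n_rev = round(config.reversal_fraction * n)
    if config.reversal_fraction > 0 and n_rev == 0:
        logger.warning("reversal_fraction * n_genes < 1; zero genes planted")
    n_s1 = round(config.frac_stage1_only * n)
    n_s2 = round(config.frac_stage2_only * n)
    n_un = round(config.frac_unexpressed * n)
    if n_rev + n_s1 + n_s2 + n_un > n:
        raise ValidationError("planted fractions exceed the gene count")

    venn_perm = [genes[i] for i in rng.permutation(n)]
    venn_of: dict[str, str] = {}
    cursor = 0
    for g in venn_perm[cursor:cursor + n_rev]:
        venn_of[g] = VENN_BOTH  # reversal genes must be expressed at both stages
    cursor += n_rev
    for g in venn_perm[cursor:cursor + n_s1]:
        venn_of[g] = VENN_STAGE1_ONLY
    cursor += n_s1
    for g in venn_perm[cursor:cursor + n_s2]:
        venn_of[g] = VENN_STAGE2_ONLY
    cursor += n_s2
    for g in venn_perm[cursor:cursor + n_un]:
        venn_of[g] = VENN_UNEXPRESSED
    cursor += n_un
    for g in venn_perm[cursor:]:
        venn_of[g] = VENN_BOTH
    reversal = set(venn_perm[:n_rev])
    return genes, module_of, venn_of, reversal


def _build_truth(config: SimulationConfig) -> tuple[list[str], TruthTable]:
    genes, module_of, venn_of, reversal = _plant_assignments(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_ext = round(config.external_fraction * config.n_genes)
    external = {genes[i] for i in rng.permutation(config.n_genes)[:n_ext]}

    records = {}
    for g in genes:
        venn = venn_of[g]
        if g in reversal:
            pattern = (DIRECTION_UP, DIRECTION_DOWN)
        elif venn == VENN_BOTH:
            pattern = (DIRECTION_UNCHANGED, DIRECTION_UNCHANGED)
        elif venn == VENN_STAGE1_ONLY:
            pattern = (DIRECTION_UNCHANGED, DIRECTION_NOT_EXPRESSED)
        elif venn == VENN_STAGE2_ONLY:
            pattern = (DIRECTION_NOT_EXPRESSED, DIRECTION_UNCHANGED)
        else:
            pattern = (DIRECTION_NOT_EXPRESSED, DIRECTION_NOT_EXPRESSED)
        records[g] = TruthRecord(module_id=module_of[g], true_pattern=pattern,
                                 true_venn=venn, in_external_set=g in external)
    return genes, TruthTable(records=records)


def _zipf_weights(n: int, exponent: float = 1.5) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** exponent
    return w / w.sum()


def simulate_corpus(config: SimulationConfig) -> tuple[AnnotationCorpus, TruthTable]:
    """Annotation corpus with planted modules sharing term cores per namespace.

    Each module gene carries ``round(overlap * module_term_count)`` shared core
    terms plus private terms up to ``module_term_count``, then background terms
    (Poisson with a Zipf-skewed frequency distribution) drawn from a term
    region disjoint from all cores, in both namespaces.
    """
    genes, truth = _build_truth(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    core_size = round(config.within_module_term_overlap * config.module_term_count)
    private_size = config.module_term_count - core_size
    reserved = config.n_modules * (core_size + config.module_size * private_size)
    n_terms = config.n_terms_per_namespace
    if reserved >= n_terms:
        raise ValidationError(
            f"term universe too small: need > {reserved} terms per namespace, "
            f"have {n_terms}")

    module_members: dict[int, list[str]] = {m: [] for m in range(config.n_modules)}
    for g in genes:
        m = truth.records[g].module_id
        if m is not None:
            module_members[m].append(g)

    assignments: dict[str, dict[str, frozenset[str]]] = {g: {} for g in genes}
    universes: dict[str, set[str]] = {}
    for ns, prefix in (("GO", "GO:"), ("MESH", "D")):
        terms = [f"{prefix}{i:06d}" for i in range(1, n_terms + 1)]
        universes[ns] = set(terms)
        cursor = 0
        core_terms: dict[int, list[str]] = {}
        private_terms: dict[str, list[str]] = {}
        for m in range(config.n_modules):
            core_terms[m] = terms[cursor:cursor + core_size]
            cursor += core_size
            for g in module_members[m]:
                private_terms[g] = terms[cursor:cursor + private_size]
                cursor += private_size
        background_region = terms[cursor:]
        weights = _zipf_weights(len(background_region))

        for g in genes:
            m = truth.records[g].module_id
            term_set: set[str] = set()
            if m is not None:
                term_set.update(core_terms[m])
                term_set.update(private_terms[g])
            n_bg = int(rng.poisson(config.background_term_rate))
            n_bg = min(n_bg, len(background_region))
            if n_bg > 0:
                picks = rng.choice(len(background_region), size=n_bg,
                                   replace=False, p=weights)
                term_set.update(background_region[i] for i in picks)
            if term_set:
                assignments[g][ns] = frozenset(term_set)

    corpus = AnnotationCorpus(assignments=assignments, term_universe=universes)
    return corpus, truth


def _signal_matrix(rng: np.random.Generator, means: np.ndarray, n_samples: int,
                   cv: float) -> np.ndarray:
    """Log-normal samples around per-gene means with the given CV (exact at cv=0)."""
    if cv == 0:
        return np.tile(means[:, None], (1, n_samples))
    sigma = math.sqrt(math.log(1 + cv * cv))
    noise = rng.lognormal(mean=-sigma * sigma / 2, sigma=sigma,
                          size=(len(means), n_samples))
    return means[:, None] * noise


def simulate_expression(config: SimulationConfig,
                        truth: TruthTable | None = None
                        ) -> tuple[dict[tuple[str, str], ExpressionTable], TruthTable]:
    """Four expression tables ({stage1, stage2} x {ctrl, NSN}) plus the truth.

    Planted reversal genes have an NSN/ctrl mean ratio of ``effect_ratio`` at
    stage 1 and ctrl/NSN of ``effect_ratio`` at stage 2; unexpressed stages
    get floor-level signals and detection p = 0.5; expressed genes pass the
    detection threshold except with probability ``detection_noise`` per sample.
    """
    if truth is None:
        genes, truth = _build_truth(config)
    else:
        genes = truth.genes
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    n = len(genes)
    base = config.base_signal * rng.lognormal(mean=0.0, sigma=0.5, size=n)

    expressed_at = {
        "stage1": np.array([truth.records[g].true_venn in (VENN_BOTH, VENN_STAGE1_ONLY)
                            for g in genes]),
        "stage2": np.array([truth.records[g].true_venn in (VENN_BOTH, VENN_STAGE2_ONLY)
                            for g in genes]),
    }
    reversal = np.array([g in truth.reversal_genes() for g in genes])

    tables: dict[tuple[str, str], ExpressionTable] = {}
    sample_ids = [f"s{i + 1}" for i in range(config.n_samples)]
    for stage in ("stage1", "stage2"):
        for condition in ("ctrl", "NSN"):
            means = base.copy()
            if condition == "NSN":
                if stage == "stage1":
                    means = np.where(reversal, base * config.effect_ratio, base)
                else:
                    means = np.where(reversal, base / config.effect_ratio, base)
            means = np.where(expressed_at[stage], means, 1.0)
            signal = _signal_matrix(rng, means, config.n_samples, config.noise_cv)
            signal = np.where(expressed_at[stage][:, None], signal, 1.0)

            detp = np.full((n, config.n_samples), 0.5)
            detp[expressed_at[stage]] = 0.001
            if config.detection_noise > 0:
                flips = rng.random((n, config.n_samples)) < config.detection_noise
                detp = np.where(expressed_at[stage][:, None] & flips, 0.5, detp)

            tables[(stage, condition)] = ExpressionTable(
                stage=stage, condition=condition,
                signal=pd.DataFrame(signal, index=genes, columns=sample_ids),
                detp=pd.DataFrame(detp, index=genes, columns=sample_ids),
                sample_ids=list(sample_ids))
    return tables, truth


def simulate_baits(config: SimulationConfig, truth: TruthTable) -> BaitSet:
    """Baits drawn round-robin across planted modules (deterministic)."""
    members: dict[int, list[str]] = {}
    for g in truth.genes:
        m = truth.records[g].module_id
        if m is not None:
            members.setdefault(m, []).append(g)
    for m in members:
        members[m].sort()
    picked: list[str] = []
    rank = 0
    while len(picked) < config.n_baits:
        advanced = False
        for m in sorted(members):
            if rank < len(members[m]) and len(picked) < config.n_baits:
                picked.append(members[m][rank])
                advanced = True
        if not advanced:
            raise ValidationError("n_baits exceeds the number of module genes")
        rank += 1
    return BaitSet(genes=frozenset(picked), label="planted-baits")


def simulate_external_set(truth: TruthTable) -> GeneSet:
    return GeneSet(name="external", genes=frozenset(truth.external_genes()),
                   source="simulated external catalogue")


def write_fixture_bundle(config: SimulationConfig, out_dir) -> list[str]:
    """Emit the 8-file fixture bundle; same config (incl. seed) is byte-identical.

    Files: 4 expression TSVs, annotations.tsv, baits.txt, external.gmt, and
    truth.json (which embeds the config echo and bundle version).
    """
    os.makedirs(out_dir, exist_ok=True)
    corpus, truth = simulate_corpus(config)
    tables, _ = simulate_expression(config, truth=truth)
    baits = simulate_baits(config, truth)
    external = simulate_external_set(truth)

    written = []

    def path(name: str) -> str:
        written.append(name)
        return os.path.join(out_dir, name)

    for (stage, condition), table in sorted(tables.items()):
        write_expression_table(table, path(f"{stage}_{condition.lower()}.tsv"))
    write_annotations(corpus, path("annotations.tsv"))
    with open(path("baits.txt"), "w", encoding="utf-8") as fh:
        fh.write("# planted baits\n")
        for g in sorted(baits.genes):
            fh.write(g + "\n")
    write_gmt([external], path("external.gmt"))
    truth.to_json(path("truth.json"), config=config)
    return written
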