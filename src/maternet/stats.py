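"""Joint two-stage pattern classification and hypergeometric tests.

The focal pattern of interest is the reversal (up at stage 1, down at
stage 2). All over-representation tests share one exact upper-tail
hypergeometric statistic computed in log space.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from scipy.special import logsumexp

from .errors import FormatError, ValidationError
from .expression import (
    DIRECTION_DOWN,
    DIRECTION_NOT_EXPRESSED,
    DIRECTION_UNCHANGED,
    DIRECTION_UP,
    ContrastCall,
    normalize_gene,
)

DIRECTIONS = (DIRECTION_UP, DIRECTION_DOWN, DIRECTION_UNCHANGED, DIRECTION_NOT_EXPRESSED)

PatternLabel = tuple[str, str]

REVERSAL: PatternLabel = (DIRECTION_UP, DIRECTION_DOWN)

ALL_PATTERNS: tuple[PatternLabel, ...] = tuple(itertools.product(DIRECTIONS, DIRECTIONS))


@dataclass(frozen=True)
class HypergeomResult:
    """Parameters and upper-tail p of one hypergeometric test, for auditability."""

    population_N: int
    successes_K: int
    draws_n: int
    observed_k: int
    p_upper: float

    def as_dict(self) -> dict:
        return {"N": self.population_N, "K": self.successes_K,
                "n": self.draws_n, "k": self.observed_k, "p_upper": self.p_upper}


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")


def read_gmt(path) -> list[GeneSet]:
    """Read GMT: name<TAB>source<TAB>gene..."""
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT rows need name, source, >=1 gene")
            name, source, *genes = parts
            sets.append(GeneSet(name=name,
                                genes=frozenset(normalize_gene(g) for g in genes if g),
                                source=source))
    if not sets:
        raise ValidationError(f"{path}: no gene sets")
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.source, *sorted(s.genes)]) + "\n")


def joint_pattern(stage1_calls: list[ContrastCall], stage2_calls: list[ContrastCall],
                  gene: str) -> PatternLabel:
    """Pair a gene's stage-1 and stage-2 directions; a missing stage is not_expressed."""
    gene = normalize_gene(gene)
    c1 = next((c for c in stage1_calls if c.gene == gene), None)
    c2 = next((c for c in stage2_calls if c.gene == gene), None)
    if c1 is None and c2 is None:
        raise ValidationError(f"gene {gene!r} absent from both stages' call lists")
    d1 = c1.direction if c1 is not None else DIRECTION_NOT_EXPRESSED
    d2 = c2.direction if c2 is not None else DIRECTION_NOT_EXPRESSED
    return (d1, d2)


def pattern_partition(genes: set[str], stage1_calls: list[ContrastCall],
                      stage2_calls: list[ContrastCall]) -> dict[PatternLabel, int]:
    """Exhaustive counts over all 16 joint labels; counts sum to |genes|."""
    if not genes:
        raise ValidationError("empty gene set")
    by1 = {c.gene: c.direction for c in stage1_calls}
    by2 = {c.gene: c.direction for c in stage2_calls}
    counts: dict[PatternLabel, int] = {p: 0 for p in ALL_PATTERNS}
    for gene in genes:
        g = normalize_gene(gene)
        if g not in by1 and g not in by2:
            raise ValidationError(f"gene {g!r} absent from both stages' call lists")
        label = (by1.get(g, DIRECTION_NOT_EXPRESSED), by2.get(g, DIRECTION_NOT_EXPRESSED))
        counts[label] += 1
    return counts


def _log_comb(n: int, r: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(r + 1) - math.lgamma(n - r + 1)


def hypergeom_logpmf(i: int, N: int, K: int, n: int) -> float:
    return _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)


# below this population size, exact integer binomials are cheap and give the
# tail correctly rounded; beyond it, log-factorials keep the tail stable
_EXACT_N = 10_000


def hypergeom_pmf(i: int, N: int, K: int, n: int) -> float:
    """P[X = i]; exact big-integer ratio for moderate N, log-factorials above."""
    if i < max(0, n + K - N) or i > min(n, K):
        return 0.0
    if N <= _EXACT_N:
        return math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
    return math.exp(hypergeom_logpmf(i, N, K, n))


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact P[X >= k] for X ~ Hypergeometric(N, K, n).

    Moderate populations use exact integer binomials (correctly rounded);
    larger ones use log-factorials with log-sum-exp for stability.
    """
    if not (0 <= K <= N):
        raise ValidationError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValidationError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not (0 <= k <= min(n, K)):
        raise ValidationError(f"need 0 <= k <= min(n, K), got k={k}, n={n}, K={K}")
    lo = max(0, n + K - N)
    if k <= lo:
        return 1.0
    hi = min(n, K)
    if N <= _EXACT_N:
        numer = sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, hi + 1))
        return numer / math.comb(N, n)
    logs = [hypergeom_logpmf(i, N, K, n) for i in range(k, hi + 1)]
    return float(min(1.0, math.exp(logsumexp(logs))))


def pattern_enrichment(bait_genes: set[str], focal: PatternLabel,
                       stage1_calls: list[ContrastCall],
                       stage2_calls: list[ContrastCall]) -> HypergeomResult:
    """Upper-tail test for over-representation of a joint pattern in a bait set.

    Population: all genes with a defined pattern (present in at least one
    stage's call list). Successes: population genes with the focal pattern.
    """
    universe = ({c.gene for c in stage1_calls} | {c.gene for c in stage2_calls})
    if not universe:
        raise ValidationError("empty universe: no contrast calls given")
    baits = {normalize_gene(g) for g in bait_genes}
    outside = baits - universe
    if outside:
        raise ValidationError(f"bait genes outside the call universe: {sorted(outside)}")
    by1 = {c.gene: c.direction for c in stage1_calls}
    by2 = {c.gene: c.direction for c in stage2_calls}

    def pat(g: str) -> PatternLabel:
        return (by1.get(g, DIRECTION_NOT_EXPRESSED), by2.get(g, DIRECTION_NOT_EXPRESSED))

    focal_genes = {g for g in universe if pat(g) == tuple(focal)}
    N, K, n = len(universe), len(focal_genes), len(baits)
    k = len(baits & focal_genes)
    return HypergeomResult(population_N=N, successes_K=K, draws_n=n, observed_k=k,
                           p_upper=hypergeom_upper_tail(N, K, n, k))


def geneset_overlap_test(network_genes: set[str], external: GeneSet,
                         universe: set[str]) -> tuple[int, float, HypergeomResult]:
    """Overlap of a network gene list with an external set, plus upper-tail p.

    N = |universe|, K = |external ∩ universe|, n = |network genes|, k = overlap.
    """
    if not universe:
        raise ValidationError("empty universe")
    universe = {normalize_gene(g) for g in universe}
    network_genes = {normalize_gene(g) for g in network_genes}
    if not network_genes <= universe:
        raise ValidationError(
            f"network genes outside universe: {sorted(network_genes - universe)}")
    ext_in_universe = external.genes & universe
    if not ext_in_universe:
        raise ValidationError(f"gene set {external.name!r} has no genes in the universe")
    overlap = network_genes & ext_in_universe
    k = len(overlap)
    n = len(network_genes)
    result = HypergeomResult(
        population_N=len(universe), successes_K=len(ext_in_universe),
        draws_n=n, observed_k=k,
        p_upper=hypergeom_upper_tail(len(universe), len(ext_in_universe), n, k))
    return k, k / n if n else 0.0, result


def benjamini_hochberg(pvalues: list[float]) -> list[float]:
    """BH adjusted p-values, order-preserving. Optional for batched runs."""
    m = len(pvalues)
    if m == 0:
        return []
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, pvalues[idx] * m / rank)
        adjusted[idx] = running
    return adjusted
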