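import numpy as np
import pandas as pd
import pytest

from maternet import (
    AnnotationCorpus,
    ContrastCall,
    ExpressionTable,
    SimulationConfig,
    simulate_corpus,
    simulate_expression,
)


@pytest.fixture(scope="session")
def default_config():
    """The default synthetic scenario (500 genes, 3 modules of 8, seed 7)."""
    return SimulationConfig()


@pytest.fixture(scope="session")
def default_corpus_truth(default_config):
    return simulate_corpus(default_config)


@pytest.fixture(scope="session")
def default_expression(default_config, default_corpus_truth):
    _, truth = default_corpus_truth
    tables, _ = simulate_expression(default_config, truth=truth)
    return tables, truth


@pytest.fixture
def small_config():
    return SimulationConfig(n_genes=40, n_modules=2, module_size=5, n_baits=2,
                            n_terms_per_namespace=120, seed=11)


def make_table(stage, condition, rows, n_samples=1):
    """rows: {gene: (mean_signal, detp)} replicated across samples."""
    genes = list(rows)
    signal = pd.DataFrame(
        {f"s{i+1}": [rows[g][0] for g in genes] for i in range(n_samples)}, index=genes)
    detp = pd.DataFrame(
        {f"s{i+1}": [rows[g][1] for g in genes] for i in range(n_samples)}, index=genes)
    return ExpressionTable(stage=stage, condition=condition, signal=signal, detp=detp)


def make_calls(directions):
    """directions: {gene: direction}; fold change fixed at a neutral value."""
    calls = []
    for gene, d in directions.items():
        expressed = frozenset() if d == "not_expressed" else frozenset({"ctrl", "NSN"})
        fc = 2.0 if d in ("up", "down") else 1.0
        calls.append(ContrastCall(gene=gene, fold_change=fc, direction=d,
                                  expressed_in=expressed))
    return calls


def random_corpus(rng, n_genes=12, n_terms=30, terms_per_gene=(1, 6)):
    """Random two-namespace corpus for property tests."""
    assignments = {}
    for i in range(n_genes):
        gene = f"R{i:03d}"
        per_ns = {}
        for ns, prefix in (("GO", "GO:"), ("MESH", "D")):
            k = int(rng.integers(*terms_per_gene))
            if k > 0:
                picks = rng.choice(n_terms, size=k, replace=False)
                per_ns[ns] = frozenset(f"{prefix}{p:04d}" for p in picks)
        assignments[gene] = per_ns
    return AnnotationCorpus(assignments=assignments)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
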