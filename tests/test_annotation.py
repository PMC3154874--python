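import math

import numpy as np
import pytest

from maternet import (
    AnnotationCorpus,
    FormatError,
    SimulationConfig,
    ValidationError,
    annotation_similarity,
    build_network,
    export_network,
    import_network,
    load_annotations,
    simulate_corpus,
)
from maternet.annotation import write_annotations

from .conftest import random_corpus


def cosine_oracle(terms_a, terms_b, universe):
    """Explicit 0/1 vector dot product; independent of the set-based path."""
    universe = sorted(universe)
    va = np.array([1.0 if t in terms_a else 0.0 for t in universe])
    vb = np.array([1.0 if t in terms_b else 0.0 for t in universe])
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        return None
    return float(va @ vb / (na * nb))


def corpus_from(d):
    return AnnotationCorpus(assignments={
        g: {ns: frozenset(ts) for ns, ts in per.items()} for g, per in d.items()})


class TestLoadAnnotations:
    def test_two_namespace_row_parse(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("geneA\tGO\tGO:0001\ngeneA\tMESH\tD001\n")
        corpus = load_annotations(p)
        assert corpus.genes == {"GENEA"}
        assert corpus.terms("GENEA", "GO") == {"GO:0001"}
        assert corpus.terms("GENEA", "MESH") == {"D001"}

    def test_unknown_namespace(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("geneA\tKEGG\tK00001\n")
        with pytest.raises(FormatError, match="KEGG"):
            load_annotations(p)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("# only comments\n")
        with pytest.raises(ValidationError):
            load_annotations(p)

    def test_generator_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_genes=30, n_modules=2, module_size=4,
                               n_terms_per_namespace=80, seed=3)
        corpus, _ = simulate_corpus(cfg)
        p = tmp_path / "ann.tsv"
        write_annotations(corpus, p)
        loaded = load_annotations(p)
        assert loaded.genes == {g for g in corpus.genes
                                if corpus.assignments[g]}  # termless genes drop out
        for g in loaded.genes:
            for ns in ("GO", "MESH"):
                assert loaded.terms(g, ns) == corpus.terms(g, ns)


class TestAnnotationSimilarity:
    def test_hand_computed_half(self):
        corpus = corpus_from({"A": {"GO": {"t1", "t2"}}, "B": {"GO": {"t2", "t3"}}})
        assert annotation_similarity(corpus, "A", "B", "GO") == pytest.approx(0.5)

    def test_identical_sets(self):
        corpus = corpus_from({"A": {"GO": {"t1", "t2"}}, "B": {"GO": {"t1", "t2"}}})
        assert annotation_similarity(corpus, "A", "B", "GO") == 1.0

    def test_empty_set_undefined(self):
        corpus = corpus_from({"A": {"GO": {"t1"}}, "B": {"MESH": {"d1"}}})
        assert annotation_similarity(corpus, "A", "B", "GO") is None
        assert annotation_similarity(corpus, "A", "B", "MESH") is None

    def test_unknown_gene_or_namespace(self):
        corpus = corpus_from({"A": {"GO": {"t1"}}, "B": {"GO": {"t1"}}})
        with pytest.raises(ValidationError):
            annotation_similarity(corpus, "A", "ZZZ", "GO")
        with pytest.raises(ValidationError):
            annotation_similarity(corpus, "A", "B", "KEGG")

    def test_brute_force_oracle_200_pairs(self, rng):
        corpus = random_corpus(rng, n_genes=20, n_terms=25)
        genes = sorted(corpus.genes)
        for _ in range(200):
            a, b = rng.choice(genes, size=2, replace=False)
            ns = ["GO", "MESH"][int(rng.integers(2))]
            expected = cosine_oracle(corpus.terms(a, ns), corpus.terms(b, ns),
                                     corpus.term_universe[ns])
            got = annotation_similarity(corpus, a, b, ns)
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    def test_symmetry_and_bounds(self, rng):
        corpus = random_corpus(rng, n_genes=15)
        genes = sorted(corpus.genes)
        for _ in range(100):
            a, b = rng.choice(genes, size=2, replace=False)
            for ns in ("GO", "MESH"):
                s_ab = annotation_similarity(corpus, a, b, ns)
                s_ba = annotation_similarity(corpus, b, a, ns)
                assert s_ab == s_ba
                if s_ab is not None:
                    assert 0.0 <= s_ab <= 1.0

    def test_one_iff_identical(self, rng):
        corpus = random_corpus(rng, n_genes=15)
        genes = sorted(corpus.genes)
        for _ in range(100):
            a, b = rng.choice(genes, size=2, replace=False)
            s = annotation_similarity(corpus, a, b, "GO")
            if s is not None:
                identical = corpus.terms(a, "GO") == corpus.terms(b, "GO")
                assert math.isclose(s, 1.0, abs_tol=1e-12) == identical

    def test_shared_term_addition_never_decreases(self, rng):
        # equal-size sets; adding one shared term to both raises binary cosine
        for _ in range(50):
            k = int(rng.integers(1, 6))
            shared = {f"s{i}" for i in range(int(rng.integers(0, k + 1)))}
            a = shared | {f"a{i}" for i in range(k - len(shared))}
            b = shared | {f"b{i}" for i in range(k - len(shared))}
            c0 = corpus_from({"A": {"GO": a}, "B": {"GO": b}})
            c1 = corpus_from({"A": {"GO": a | {"NEW"}}, "B": {"GO": b | {"NEW"}}})
            assert (annotation_similarity(c1, "A", "B", "GO")
                    >= annotation_similarity(c0, "A", "B", "GO") - 1e-12)

    def test_idf_weighting_defined_and_bounded(self, rng):
        corpus = random_corpus(rng, n_genes=12)
        genes = sorted(corpus.genes)
        for _ in range(50):
            a, b = rng.choice(genes, size=2, replace=False)
            s = annotation_similarity(corpus, a, b, "GO", weighting="idf")
            if s is not None:
                assert 0.0 <= s <= 1.0 + 1e-12
        with pytest.raises(ValidationError):
            annotation_similarity(corpus, genes[0], genes[1], "GO", weighting="bogus")


class TestBuildNetwork:
    def test_go_only_support(self):
        corpus = corpus_from({"A": {"GO": {"t1", "t2"}}, "B": {"GO": {"t1", "t2"}}})
        net = build_network(corpus, {"A", "B"}, cutoff=0.7)
        (edge,) = net.edges
        assert edge.support == "GO"
        assert edge.sim_mesh is None
        assert edge.weight == 1.0

    def test_both_support(self):
        corpus = corpus_from({"A": {"GO": {"t1"}, "MESH": {"d1"}},
                              "B": {"GO": {"t1"}, "MESH": {"d1"}}})
        net = build_network(corpus, {"A", "B"}, cutoff=0.7)
        (edge,) = net.edges
        assert edge.support == "BOTH"

    def test_exact_cutoff_is_not_an_edge(self):
        # |A|=|B|=10, intersection 7 -> cosine exactly 0.7
        a = {f"t{i}" for i in range(10)}
        b = {f"t{i}" for i in range(7)} | {f"u{i}" for i in range(3)}
        corpus = corpus_from({"A": {"GO": a}, "B": {"GO": b}})
        assert annotation_similarity(corpus, "A", "B", "GO") == 0.7
        net = build_network(corpus, {"A", "B"}, cutoff=0.7)
        assert net.graph.number_of_edges() == 0

    def test_planted_modules_vs_brute_force(self):
        cfg = SimulationConfig(n_genes=24, n_modules=3, module_size=8,
                               within_module_term_overlap=0.9,
                               background_term_rate=0.5,
                               n_terms_per_namespace=120, seed=5)
        corpus, _ = simulate_corpus(cfg)
        net = build_network(corpus, corpus.genes, cutoff=0.7)
        genes = sorted(corpus.genes)
        expected_edges = set()
        for i, a in enumerate(genes):
            for b in genes[i + 1:]:
                sims = [annotation_similarity(corpus, a, b, ns) for ns in ("GO", "MESH")]
                if any(s is not None and s > 0.7 for s in sims):
                    expected_edges.add((a, b))
        got = {(e.gene_a, e.gene_b) for e in net.edges}
        assert got == expected_edges

    def test_cutoff_monotonicity(self, rng):
        corpus = random_corpus(rng, n_genes=14)
        lo = build_network(corpus, corpus.genes, cutoff=0.5)
        hi = build_network(corpus, corpus.genes, cutoff=0.8)
        lo_edges = {(e.gene_a, e.gene_b) for e in lo.edges}
        hi_edges = {(e.gene_a, e.gene_b) for e in hi.edges}
        assert hi_edges <= lo_edges

    def test_too_few_genes(self):
        corpus = corpus_from({"A": {"GO": {"t1"}}})
        with pytest.raises(ValidationError):
            build_network(corpus, {"A"})

    def test_unknown_gene(self):
        corpus = corpus_from({"A": {"GO": {"t1"}}, "B": {"GO": {"t1"}}})
        with pytest.raises(ValidationError):
            build_network(corpus, {"A", "B", "ZZZ"})


class TestExportImport:
    def test_sif_line(self, tmp_path):
        corpus = corpus_from({"GENEA": {"GO": {"t1"}}, "GENEB": {"GO": {"t1"}}})
        net = build_network(corpus, {"GENEA", "GENEB"}, cutoff=0.7)
        path = tmp_path / "net.sif"
        export_network(net, path, format="sif")
        assert path.read_text() == "GENEA\tGO\tGENEB\n"

    def test_graphml_round_trip(self, rng):
        corpus = random_corpus(rng, n_genes=24, terms_per_gene=(2, 8))
        net = build_network(corpus, corpus.genes, cutoff=0.3)
        assert net.graph.number_of_edges() > 0
        import tempfile, os

        with tempfile.TemporaryDirectory() as d:
            path = os.path.join(d, "net.graphml")
            export_network(net, path, format="graphml")
            back = import_network(path)
        assert set(back.graph.nodes) == set(net.graph.nodes)
        assert back.cutoff == net.cutoff
        orig = {(e.gene_a, e.gene_b): e for e in net.edges}
        loaded = {(e.gene_a, e.gene_b): e for e in back.edges}
        assert orig.keys() == loaded.keys()
        for key in orig:
            a, b = orig[key], loaded[key]
            assert a.support == b.support
            assert a.weight == pytest.approx(b.weight, abs=1e-12)
            for attr in ("sim_go", "sim_mesh"):
                x, y = getattr(a, attr), getattr(b, attr)
                assert (x is None) == (y is None)
                if x is not None:
                    assert x == pytest.approx(y, abs=1e-12)

    def test_empty_network_error(self):
        import networkx as nx

        from maternet import AnnotationNetwork

        net = AnnotationNetwork(graph=nx.Graph(), cutoff=0.7)
        with pytest.raises(ValidationError):
            export_network(net, "/tmp/never.graphml")

    def test_unknown_format(self, tmp_path):
        corpus = corpus_from({"A": {"GO": {"t1"}}, "B": {"GO": {"t1"}}})
        net = build_network(corpus, {"A", "B"}, cutoff=0.7)
        with pytest.raises(ValidationError):
            export_network(net, tmp_path / "x", format="gexf")
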