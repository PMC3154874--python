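# maternet

Bait-seeded gene-network inference across two developmental stages:

1. **expression** — read per-gene signal / detection-p tables (BeadStudio-style
   TSV), call expressed genes (detection p ≤ 0.01, inclusive) and differential
   genes (fold change ≥ 1.5 between a control and an NSN condition, direction
   relative to control).
2. **annotation** — build a gene–gene similarity network from GO and MeSH term
   assignments: per-namespace binary (or idf-weighted) cosine over term
   vectors, edge iff a similarity *strictly exceeds* the cutoff (default 0.7),
   with GO / MESH / BOTH support labels. GraphML and SIF export.
3. **expansion** — multi-source BFS from a bait gene set with a hop limit
   (default 2), expression overlay into a Venn partition
   (stage1_only / stage2_only / both / unexpressed), and connected-component
   clusters ordered by size.
4. **stats** — joint two-stage pattern classification (focal pattern: up at
   stage 1, down at stage 2), exact upper-tail hypergeometric tests for
   pattern enrichment in a bait set and for external gene-set (GMT) overlap;
   every reported p carries its (N, K, n, k) for auditability.
5. **enrichment** — per-term hypergeometric over-representation of a gene list
   against a universe (p ≤ 0.01 retained) with rollup of enriched terms into
   expert-defined macro categories and per-category up/down gene tallies.
6. **simulate** — seeded synthetic fixtures with machine-readable truth:
   annotation corpora with planted modules (shared term cores), expression
   tables with planted reversal genes and Venn compartments, bait lists and
   external gene sets. Same config ⇒ byte-identical bundles.

## CLI

```sh
maternet simulate --seed 7 -o fixtures/              # synthetic bundle + truth.json
maternet de --ctrl fixtures/stage1_ctrl.tsv --nsn fixtures/stage1_nsn.tsv \
    --stage 1 --fc 1.5 --detp 0.01 -o s1.tsv
maternet net-build --annotations fixtures/annotations.tsv --cutoff 0.7 -o net.graphml
maternet expand --net net.graphml --baits fixtures/baits.txt \
    --stage1 s1.tsv --stage2 s2.tsv --max-hops 2 -o expanded.json
maternet patterns --stage1 s1.tsv --stage2 s2.tsv --baits fixtures/baits.txt \
    --focal up,down -o patterns.json
maternet overlap --genes list.txt --geneset fixtures/external.gmt --universe universe.txt
maternet enrich --list genes.txt --annotations ann.tsv --universe universe.txt \
    --p 0.01 --macro-map map.tsv -o enrich.json
```

File dialects: expression TSV (`gene<TAB>{sample}.signal<TAB>{sample}.detp…`),
annotation TSV (`gene<TAB>GO|MESH<TAB>term`), bait lists (one symbol per line),
GMT gene sets, GraphML/SIF networks, JSON reports. Gene symbols are uppercased
everywhere; `#` lines are comments.

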