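# ecnet

Gene co-expression network inference with the **extended core network**
(ECN) method, plus a differential analysis of sense vs sense+anti-sense
networks: AS-impacted genes, change motifs, AS-impacted sub-graphs,
Steiner-tree rewiring, and GO / GO-slim over-representation tests.

## What it does

1. **Preprocess** — quantile-normalize two condition matrices
   (transcripts × samples, log2 intensities) and keep transcripts that are
   differentially expressed (paired t-test p < 0.01, |log2FC| ≥ 1).
2. **MI estimation** — copula-transform each profile (normalized ranks),
   estimate pairwise mutual information with the Gaussian estimator
   `½·log(σ²_I σ²_J / |C|)`, and zero entries that do not beat a pooled
   permutation null.
3. **Network inference** — for each gene accept every significant partner
   whose MI is within an accepting rate `r` of the gene's best MI
   (`r = 0` → argmax set, `r = 1` → all significant partners). The result
   is an asymmetric adjacency; a single-best-edge baseline (undirected)
   is included for comparison.
4. **Differential analysis** — compare the sense-only (S) and
   sense+anti-sense (SAS) networks: a sense gene with S-neighbors whose
   SAS out-neighborhood is non-empty but contains only anti-sense
   transcripts is *AS-impacted*; its two neighborhoods form a *change
   motif* (optionally enlarged by the SAS neighborhoods of its anti-sense
   actors). Connected AS-impacted genes in the S network form
   *AS-impacted sub-graphs*.
5. **Steiner trees** — reconnect each sub-graph's members inside the SAS
   network with the shortest-path (Takahashi–Matsuyama) approximation;
   an exact Dreyfus–Wagner solver validates it on small instances.
6. **Enrichment** — upper-tail hypergeometric tests on GO or GO-slim
   vocabularies with Bonferroni or Benjamini–Hochberg correction,
   true-path annotation propagation, and the *revealed-by-AS* comparison
   (terms significant only when anti-sense transcripts are included).
7. **Synthetic benchmark** — connected regulatory-network generator,
   Hill-kinetics expression simulator, anti-sense injection, and a
   precision/recall/F1 simulation study over random sample subsets.

## CLI

```sh
ecnet normalize expr.tsv -o norm.tsv
ecnet de h.tsv d60.tsv --alpha 0.01 --min-lfc 1 -o de.tsv
ecnet mi norm.tsv --perm 30 --alpha 0.05 --seed 1 -o mi.tsv
ecnet infer mi.tsv --rate 0.05 -o net.sif          # --c3net for baseline
ecnet diff --s-net s.sif --sas-net sas.sif --enlarge -o outdir/
ecnet steiner --graph sas.sif --terminals terms.txt -o tree.sif
ecnet enrich --genes g.txt --universe u.txt --annotations ann.tsv -o enr.tsv
ecnet revealed --s-genes s.txt --sas-genes sas.txt --universe u.txt \
    --annotations ann.tsv -o revealed.tsv
ecnet simulate --n 200 --p 100 --seed 7 -o X.tsv --truth net.sif
ecnet benchmark --n 50 --p 60 --s 50 --rates 0,0.05,1 --seed 7 -o f1.tsv
ecnet run --expr-h h.tsv --expr-60 d60.tsv --rate 0.05 -o results/
```

Expression matrices are tab-delimited with transcript IDs in the first
column and sample labels in the header; an anti-sense transcript of gene
`g` is written `g_AS`. Networks are exported as SIF / GraphML
(Cytoscape-readable).

## Layout

- `src/ecnet/datatypes.py` — transcript IDs, expression matrices
- `src/ecnet/preprocess.py` — quantile normalization, DE filter
- `src/ecnet/mi.py` — copula transform, Gaussian MI, permutation mask
- `src/ecnet/core_network.py` — ECN inference, baseline, symmetrize
- `src/ecnet/differential.py` — AS-impacted genes, motifs, sub-graphs
- `src/ecnet/steiner.py` — approximate + exact Steiner trees
- `src/ecnet/enrichment.py` — hypergeometric tests, revealed-by-AS
- `src/ecnet/synthetic.py` — benchmark generator and F1 study
- `src/ecnet/io.py`, `pipeline.py`, `cli.py` — formats, workflow, CLI
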