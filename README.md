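# coexnet

Gene co-expression network analysis and guilt-by-association annotation for
RNA-Seq, with long non-coding RNAs (lncRNAs) as the motivating use case.
lncRNAs are poorly conserved at the sequence level, so homology-based
annotation fails for them; what often works instead is inferring function
from the company a transcript keeps — the protein-coding genes it is
co-expressed with across many samples.

`coexnet` covers that whole path as a small Python library plus a
one-command-per-stage CLI:

1. **Pretreatment** — five normalization methods (median, quantile,
   median-of-ratios, TMM, housekeeping-gene) and low-expression filtering
   by mean or variance (by default the weakest quarter of genes is dropped).
2. **Network construction** — all-pairs Spearman or Pearson correlation,
   used directly (no soft thresholding):
   `rho = Σᵢ(xᵢ−x̄)(yᵢ−ȳ) / √(Σᵢ(xᵢ−x̄)² Σᵢ(yᵢ−ȳ)²)`,
   with exact t-based p-values and a joint Benjamini–Hochberg FDR; edges
   must pass both `|rho|` and FDR cutoffs (optionally positive only).
   Networks from independent datasets can be merged with a minimum-support
   rule.
3. **Module identification** — agglomerative clustering on the
   shared-neighbour similarity
   `s_ij = (h_ij + a_ij) / (c_i + c_j − h_ij − a_ij)`
   (h = shared neighbours, a = adjacency, c = degree).
4. **Function annotation** — for an unknown gene with n annotated
   neighbours (or module co-members), of which k carry a term present in M
   of N background genes, the enrichment p-value is the hypergeometric
   upper tail `p = 1 − Σ_{i<k} C(M,i)C(N−M,n−i)/C(N,n)`; alternatively,
   random walk with restart `p_k = α p₀ + (1−α) W p_{k−1}` on the
   column-stochastic adjacency ranks every gene's proximity to annotated
   seed genes. A leave-one-out evaluator measures annotation accuracy
   against a degree-preserving shuffled network control.

A synthetic-data generator with planted co-expression blocks makes every
stage testable without downloads.

## Worked example

```sh
python examples/annotate_unknown_genes.py
```

builds a 30-gene / 20-sample matrix with three planted co-expression
blocks, hides the labels of 20 % of each block, and transfers them back
from network neighbours:

```
6 network genes lack annotation: ['b01_g005', 'b01_g007', 'b02_g004', 'b02_g006', 'b03_g007', 'b03_g008']
  b01_g007 <- T1  (k=5/5 neighbours, p=6.24e-04, FDR=7.49e-04, correct)
  b02_g004 <- T2  (k=7/7 neighbours, p=3.26e-05, FDR=1.96e-04, correct)
  ...
leave-one-out accuracy 0.91 vs shuffled control 0.04 over 23 genes
```

Each line reads: all k of the target's n annotated neighbours carry the
term, giving the printed hypergeometric p-value and FDR; `correct` means
the transferred term matches the planted block. The final line is the
honesty check: hiding each annotated gene in turn, 91 % of genes get a
true term back on the real network versus 4 % on a degree-preserving
shuffle — the transfer rides on co-expression structure, not on degree.
`examples/build_network.py` and `examples/detect_modules.py` walk the
earlier stages the same way.

The identical pipeline is available from the shell:

```sh
coexnet make_fixtures --seed 1 -o demo/
coexnet network_build -i demo/expr.tsv -o demo/net.tsv --method spearman --rho 0.8 --fdr 0.05
coexnet module_identify -i demo/net.tsv -o demo/modules.tsv
coexnet annotate -i demo/net.tsv -a demo/ann.tsv -o demo/enrich.tsv
coexnet calculate_accuracy -i demo/net.tsv -a demo/ann.tsv --control-seed 42
```

Every stage is deterministic: identical inputs, seeds and flags give
byte-identical outputs, independent of `--threads`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full pipeline from scratch on seeded synthetic data —
generation, filtering, normalization, network construction, module
detection, neighbour annotation, random-walk scoring and the
shuffled-control accuracy evaluation — printing a run summary to stderr
and writing the target-value JSON to `--out`.

See `docs/methods.md` for the models, parameter defaults and numerical
choices, and their limitations.
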