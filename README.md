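# straincgh

Array-CGH strain comparison toolkit. Given a gene-level log2-ratio matrix
(genes × strains), a genome annotation, functional gene sets (GMT) and
optionally electrophoretic band patterns, it runs:

1. **Cohort-average re-normalization** — each gene is re-referenced to the
   mean over all strains, cancelling any per-gene bias shared with a common
   reference sample.
2. **Divergence profiling** — per-gene cross-strain population SD plus a
   centered moving-average trend computed per chromosome (windows shrink at
   chromosome ends and never cross boundaries).
3. **Piecewise-constant segmentation** — exact penalized least-squares
   change-point fit by dynamic programming, with a robust automatic penalty.
4. **Region gain/loss calls** — mean log2 per named region per strain,
   thresholded symmetrically.
5. **Divergent-gene selection** — genes whose |log2| strictly exceeds
   k (default 4) pooled global SDs in at least one strain.
6. **Overrepresentation** — exact hypergeometric upper-tail test per gene
   set with Benjamini–Hochberg FDR (significance at q < 0.05).
7. **Strain clustering** — complete linkage on Euclidean distances
   (pairwise-complete over missing values), Newick export, deterministic
   leaf order for heatmap columns.
8. **Karyotype similarity** — band binning by relative size tolerance,
   Jaccard similarity, UPGMA tree.

A synthetic-cohort simulator (`straincgh.simulate`) generates matched
matrices, annotations, term sets and band patterns with planted group
structure and subtelomeric copy-number events, so the whole pipeline is
testable end-to-end with known ground truth.

## CLI

```sh
# generate a synthetic cohort (deterministic given the seed)
straincgh simulate --out-dir cohort/ --seed 1

# full pipeline
straincgh run-all \
    --matrix cohort/matrix.tsv --annotation cohort/annotation.tsv \
    --gmt cohort/terms.gmt --bands cohort/bands.tsv --out-dir results/

# individual stages
straincgh normalize --matrix cohort/matrix.tsv --out normalized.tsv
straincgh divergence --matrix normalized.tsv --annotation cohort/annotation.tsv \
    --window 21 --out divergence.tsv
straincgh segment --matrix normalized.tsv --annotation cohort/annotation.tsv \
    --penalty auto --out segments.tsv
straincgh call-regions --matrix normalized.tsv --annotation cohort/annotation.tsv \
    --threshold 0.2 --out calls.tsv
straincgh select --matrix normalized.tsv --k 4 --out-tsv sel.tsv --out-json sel.json
straincgh enrich --selection sel.tsv --gmt cohort/terms.gmt --alpha 0.05 --out enr.tsv
straincgh cluster --input normalized.tsv --out-tree tree.nwk --out-order order.tsv
straincgh karyotype --bands cohort/bands.tsv --tolerance 0.05 \
    --out-tree ktree.nwk --out-sim ksim.tsv
```

`run-all` also accepts `--config pipeline.yaml` mirroring all flags
(explicit flags win). Every defaulted parameter is logged, and all outputs
are bitwise-reproducible given the same inputs.

## File formats

- **Matrix TSV** — header `gene_id` + strain ids; missing values as `NA`.
- **Annotation TSV** — `chromosome  start  end  gene_id  subtelomeric`,
  1-based closed coordinates (declared in a header comment); pass
  `--bed-strict` for 0-based half-open starts.
- **GMT** — `term_id <TAB> description <TAB> gene …` per line.
- **Bands TSV** — `strain_id <TAB> comma-separated kb sizes`.
- **Trees** — Newick with branch lengths.

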