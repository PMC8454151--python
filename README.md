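# pathfin

Drug–target–pathway heterogeneous-network toolkit for investigating drug
mechanism of action. It integrates multi-source drug–target evidence into a
combined confidence score, builds a tripartite drug/target/pathway network,
compares drugs by target-profile Jaccard similarity and by PathSim metapath
(pathway-fingerprint) similarity, clusters drugs hierarchically, extracts the
shared metapath subgraph between a query drug and a reference to predict the
query's pathway associations, and scores pathway regulation direction from
differential-expression tables.

## Method summary

- **Evidence integration** — per-source probabilities (e.g. stitch / pubchem /
  batman channels; bioassay outcomes map as active→1, inactive→0,
  inconclusive→0.5) are fused per drug–target pair with a noisy-OR:
  `CS = 1 − Π_s (1 − P_s)`. Multi-composition drugs merge by taking the
  maximum score per target. Interactions with `CS > 0.4` (strict) are kept.
- **Pathway fingerprints & PathSim** — `F_x[p] = |targets(x) ∩ genes(p)|`;
  the number of metapath instances drug→target→pathway←target←drug between
  drugs x, y is `F_x · F_y`, and
  `pathsim(x, y) = 2 F_x·F_y / (F_x·F_x + F_y·F_y) ∈ [0, 1]`.
- **Clustering** — agglomerative (complete/average/single linkage, in-house
  implementation with deterministic tie-breaking) on `d = 1 − similarity`,
  with exact-k cuts and Newick export.
- **MoA inference** — shared pathways between query and reference ranked by
  path-instance contribution, with mediating targets partitioned into
  common / query-only / reference-only; DE genes called with inclusive
  thresholds FDR ≤ 0.1 and FC ≥ 1.5 (down: FC ≤ 1/1.5), and per-pathway
  up-regulated ratios with a configurable denominator policy.
- **Synthetic data** — planted-structure generators, including a confounder
  drug that clusters with one group by target similarity but with another by
  PathSim, plus evidence tables and DE tables with planted direction.

## CLI

The `pathfin` entry point exposes the workflow stage by stage:

```sh
pathfin simulate --seed 5 -o demo            # synthetic fixture bundle
pathfin score demo/evidence.tsv -o demo/interactions.tsv
pathfin build demo/interactions.tsv --gmt demo/pathways.gmt -o demo/net
pathfin sim-target demo/net -o demo/sim_target.tsv
pathfin sim-path demo/net -o demo/sim_path.tsv
pathfin cluster demo/sim_path.tsv -k 2 --newick demo/tree.nwk --clusters demo/clusters.tsv
pathfin predict demo/net --query DX --reference D1_0 -o demo/predicted.tsv
pathfin regulate demo/de_table.tsv demo/pathways.gmt -o demo/regulation.tsv
```

`pathfin run --config config.yaml` executes the whole pipeline from a YAML
config (see `pathfin.config.RunConfig` for keys and defaults); all outputs
are deterministic text files.

### Formats

Evidence TSV (`drug_id, target_id, source, probability`; the probability
column also accepts bioassay outcome labels), composition map TSV
(`composition_id, drug_id`), standard GMT gene sets, DE table TSV
(`gene, fc|log2fc, fdr, contrast` — scale declared by column name), network
directories (edge-list TSVs + GMT + JSON header), similarity matrices (TSV
with a JSON sidecar), Newick dendrograms.

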