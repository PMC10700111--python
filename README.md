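# orthotrim

Inference, refinement, and curation of orthologous protein groups for
dense sets of closely related annotated genomes.

The package covers the full post-search pipeline:

1. **Hit processing** (`orthotrim.hit_processing`) — parse BLAST+ tabular
   output, de-duplicate protein sequences per (sequence, gene) pair,
   extract HSPs of the best-scoring target gene, merge HSPs into hits with
   disjoint/compatible subsets, and apply coverage (≥ 50%) and
   reciprocity filters to produce an undirected best-hit edge list.
   Within-genome self-searches yield paralog pairs whose score exceeds
   every inter-genome hit of the query.
2. **Clustering** (`orthotrim.ortho_clustering`) — k-clique percolation
   (default k = 4) over each connected component of the hit graph, with a
   progressive community-merging implementation and a k-core fallback on
   timeout; paralog augmentation; gene-level grouping of orthogroups
   (≥ 50% parent-gene overlap); single-copy selection under configurable
   phylogenetic diversity criteria.
3. **Profile weighting** (`orthotrim.profile_weighting`) — alignments
   coded into gap/non-gap symbols, tree-derived minimum-variance species
   weights, weighted binary profiles (pseudocount 0.005), and
   maximum-likelihood representative selection per gene.
4. **Refinement** (`orthotrim.alignment_refinement`) — conserved regions
   from a closed binary mask (threshold > 0.5, structuring element 3,
   minimum length 10); diverged regions realigned through an adapter with
   a weaker over-alignment correction and stitched back. The production
   adapter shells out to MAFFT (`--unalignlevel`); the test suite uses a
   deterministic built-in progressive aligner.
5. **Phylo-HMM** (`orthotrim.phylo_hmm`) — a generic scaled
   forward/backward engine decoupled from emissions, plus the
   phylogenetic emission architecture: per-state 2-state CTMC on the
   species tree (Felsenstein pruning, vectorized across columns), a tip
   observation-error mixture, and a beta-binomial gap-stickiness
   component; posterior-of-observed-symbol emissions for the missing-data
   model; simulation; discriminative (cross-entropy) training.
6. **Curation** (`orthotrim.alignment_curation`) — seed-and-expand region
   calls with derivative × gap-profile-change boundary selection,
   per-sequence state-3 segment trims via the geometric cutoff
   k = log(α)/log(1−p) − 1 with p = 1/(μ+1), state-2 column trims on the
   combined posterior, and per-sequence missing-segment calls serialized
   as slice lists.
7. **Tree support** (`orthotrim.tree_support`) — meta-alignment column
   sampling under invariant/gap-fraction strategies, validated reverse
   translation of protein alignments, and majority / loose consensus
   trees with bipartition supports.
8. **Fixtures** (`orthotrim.synthetic_fixtures`) — planted-truth scenario
   generation (proteomes, search tables, alignments with planted
   insertions and missing segments, labels, species tree) used by the
   end-to-end tests.

## CLI

Generate a planted scenario and run pipeline stages over it:

```sh
orthotrim fixtures --seed 1 --out data/
orthotrim run --stage hits    --data data/ --out out/
orthotrim run --stage cluster --data data/ --out out/
orthotrim run --stage represent --data data/ --out out/
orthotrim run --stage refine  --data data/ --out out/
orthotrim run --stage curate  --data data/ --out out/
```

Fixture parameters can be overridden with a TOML config
(`--config cfg.toml`, section `[fixtures]`); stage options live in
sections named after the stage (e.g. `[cluster] k = 4`). Each stage
writes a `manifest.json` next to its outputs and logs to stderr.

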