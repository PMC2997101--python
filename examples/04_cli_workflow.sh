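#!/usr/bin/env bash
# Shell workflow: simulate expression data, cluster it, inspect the outputs.
set -euo pipefail

workdir=$(mktemp -d)
trap 'rm -rf "$workdir"' EXIT

# 1. three-group synthetic expression data (30/15/15 samples x 500 genes)
ahcut simulate --seed 1 -o "$workdir/sim"

# 2. divisive dendrogram from centred correlation distances
ahcut cluster "$workdir/sim/expression.tsv" --kind expression --seed 1 \
    -o "$workdir/clust"

# 3. outputs: Newick tree, per-level flat partitions, per-split run log
head -c 200 "$workdir/clust/tree.nwk"; echo
echo "--- level 2 clusters (first rows) vs planted truth ---"
paste <(head -5 "$workdir/clust/level_2.tsv") <(head -5 "$workdir/sim/truth.tsv")

# 4. a single bipartition with its objective breakdown
ahcut bipartition "$workdir/sim/expression.tsv" --kind expression --seed 1 \
    -o "$workdir/split"
cat "$workdir/split/objective.json"
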