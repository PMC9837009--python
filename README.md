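# exoscreen

In-silico screening of single-nucleotide EXO-motif variants of a miRNA.

Some miRNAs are actively sorted into exosomes and transferred between cells,
guided by short sequence elements — EXO-motifs such as GGAG and GCAG — that
are recognized by RNA-binding proteins (RBPs, e.g. hnRNPA2B1).  The mature
miR-1246 mimic (5'-AAUGGAUUUUUGGAGCAGG-3', 19 nt) carries both motifs,
overlapping in the 5'-GGAGCAG-3' stretch at positions 12–18.  `exoscreen`
implements the computational side of a mutational screen of such a motif:
it enumerates every single-base substitution inside the motif window and
characterizes each variant at three levels before a shortlist goes to the
bench.

For each variant *v* of the native sequence *s*:

1. **1D / protein interactions** — scan *v* against a consensus-motif
   database over the degenerate IUPAC RNA alphabet, count all (overlapping)
   hits, collapse hit genes to homolog groups, and rank sequences by
   binding-site content.
2. **2D** — predict or ingest dot-bracket secondary structures, extract
   hairpin geometry (stem length, terminal-loop length, motif placement),
   compute pairwise Levenshtein distances `LD(db_i, db_j)` and cluster with
   DBSCAN(eps, min_samples) on the precomputed matrix.
3. **3D** — read multi-model PDB ensembles, superimpose model pairs with
   the Kabsch algorithm (RMSD = min over rotations R of
   √(Σ‖x_i − R y_i‖²/n), reflections excluded), summarize each ensemble
   (avg/sd/min/max RMSD, medoid centroid), then cluster the ensemble
   centroids by single linkage.
4. **Selection** — flag variants that fall outside the native's cluster in
   every available clustering, plus configurable extremes of the
   distinct-RBP count, plus user-pinned ids.

A synthetic-data module generates offline stand-ins (with planted ground
truth) for every external resource: ATtRACT-dialect motif tables, homolog
annotation tables, Vienna dot-bracket sets, and coarse-grained multi-model
PDB ensembles.  See `docs/methods.md` for models, parameters, and
limitations.

## Worked example

Run the whole workflow on a freshly generated synthetic bundle:

```sh
exoscreen run-all --outdir demo --seed 0
```

This writes one TSV per stage (variants, hits, summary, structures,
2D/3D distance matrices and clusters, ensemble statistics) plus
`report.json`, every file headed by the seed and configuration hash, and
prints the selection:

```json
{
 "selected": ["6", "7"],
 "rationale": {
  "6": ["structure-divergent"],
  "7": ["structure-divergent"]
 },
 "support": {
  "6": {"folded": true, "cluster_2d": 2, "cluster_3d": 2,
        "n_motif_hits": 4, "n_distinct_rbps": 3},
  "7": {"folded": true, "cluster_2d": 2, "cluster_3d": 2,
        "n_motif_hits": 4, "n_distinct_rbps": 3}
 }
}
```

Reading this: variants 6 and 7 are the only ones that fold into hairpins,
and in both the secondary-structure clustering and the tertiary-centroid
clustering they form a two-member cluster (id 2) apart from the native and
the other ten variants — so they are selected as structure-divergent.  The
per-stage files carry the numbers behind that call, e.g. the majority 3D
cluster:

```
cluster_id  n_members  members                    avg_rmsd  sd      min_rmsd  max_rmsd  centroid_id  avg_to_centroid
1           11         0,1,2,3,4,5,8,9,10,11,12   0.2362    0.0115  0.2133    0.2633    0            0.2270
```

and the ranking table (native sequence 0 first, with the most binding
sites):

```
sequence_id  n_motif_hits  n_distinct_rbps
0            12            6
1            5             3
2            5             3
```

The same stages are available individually (`exoscreen variants`, `scan`,
`fold`, `cluster2d`, `stats3d`, `cluster3d`, `simulate`) and as library
functions (`exoscreen.pipeline.run_insilico` over a `PipelineConfig`).

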