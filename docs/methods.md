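# Methods

## Scope and model

`exoscreen` implements an in-silico screen for the effect of single-nucleotide
substitutions inside an exosome-sorting motif (EXO-motif) of a mature miRNA.
The canonical subject is the 19-nt miR-1246 mimic
(5'-AAUGGAUUUUUGGAGCAGG-3'), which carries two overlapping EXO-motifs, GGAG
(positions 12–15) and GCAG (15–18), sharing the G at position 15.  The screen
asks, for every possible substitution inside the GGAG window, how the variant
changes (i) its repertoire of RNA-binding-protein (RBP) consensus binding
sites, (ii) its secondary structure, and (iii) its tertiary fold — and then
selects a small set of variants worth validating in the wet lab.

The pipeline is a composition of independently testable stages; there is no
hidden state, and each stage's artifact can be regenerated by calling the
stage function on the previous stage's files.

## Variant enumeration and numbering

All `3 × window-length` single-base substitutions inside the motif window are
enumerated.  The numbering scheme is deterministic: window positions 5'→3',
alternative bases in the fixed order A < C < G < U, ids from 1.  The
historical numbering of the original probe set is only partially recoverable
(three variants are pinned: A14C, G15C, G15U, called 5, 6 and 7); those
aliases ship as `data/paper_aliases.tsv` and the constant
`seqvariants.PAPER_VARIANT_ALIASES`.  Coordinates in every public interface
are 1-based inclusive; only the sense strand is ever scanned, because a
mature miRNA is single-stranded.

Control probes are produced by rejection sampling: uniform random bases, the
kept EXO-motif overlaid at its native coordinates, candidates rejected until
an IUPAC scan against the excluded-motif list returns zero hits (default
attempt budget 10,000 — generous for 19-nt sequences and small exclusion
lists).

## RBP motif scanning

Motif tables use the ATtRACT column dialect (Gene_name, Gene_id, Organism,
Motif, Len, Matrix_id, Score), so a real ATtRACT download is usable
unmodified; DNA-alphabet patterns are normalized T→U, and rows with invalid
IUPAC codes are skipped and logged rather than aborting a 1,583-row parse.
Matching is position-by-position IUPAC set membership; degenerate positions
carry no weight and N matches anything.  Every match of every (motif, gene)
row counts separately, including overlapping and self-overlapping matches.

Two counts summarize a sequence, mirroring the two-column convention of the
source study's ranking table: the **total hit count** and the number of
**distinct RBPs**, obtained by collapsing hit genes to homolog groups via an
offline annotation table (stand-in for live homology retrieval; unannotated
genes degrade to singleton groups).  Ranking is by descending total hits,
ties by descending distinct-RBP count, then ascending id — the tie-break is
this package's rule, since no published key exists for the tied rows.

## Secondary structure

Short mature miRNAs either stay essentially unfolded or form one hairpin.
The 2D stage is pluggable:

* **Vienna ingestion** (default in the pipeline): dot-bracket files from any
  external predictor, with optional trailing `(energy)` values parsed as ΔG
  in kcal/mol.
* **`fold_maxpair`**: Nussinov-style base-pair maximization over canonical +
  wobble pairs, minimum loop 3 nt, deterministic traceback (the 5'-most base
  prefers pairing, smallest partner first).
* **`fold_mfe_hairpin`**: exhaustive enumeration of single-hairpin
  candidates (one contiguous helix + terminal loop) scored by a simplified
  nearest-neighbor-style table.  The packaged `EnergyParams` is an explicit
  stand-in with Turner-like magnitudes — stack energy
  `-(s_outer + s_inner)` with strengths GC 1.5, AU 0.9, GU 0.5 kcal/mol;
  tabulated terminal-loop penalties (5.4–6.3 kcal/mol for 3–9 nt, log-
  extrapolated beyond); 0.5 kcal/mol penalty for a weak closing pair.  It
  supports sign and ordering comparisons between hairpins; it does not
  reproduce trained predictors' printed ΔG values, which depend on their
  internal parameter sets and are out of scope.  A sequence with no
  negative-ΔG hairpin is reported unfolded at exactly 0.0 kcal/mol,
  mirroring the observed dichotomy "unfolded vs hairpin".

Hairpin features: the loop-closing (innermost) pair defines the terminal
loop; the stem is the maximal contiguous helix around it; among several
hairpins the longest helix wins (ties by GC-pair count, then 5'-most).  The
motif location is `loop` only when every window position is unpaired and
inside the selected terminal loop, `stem` only when every window position is
paired, `mixed` otherwise, `unpaired` for a pair-free structure.  This strict
rule means a window overlapping the loop-closing pair is `mixed`, not
`loop`; the one-position shift relative to a center-placed hairpin is why
the default synthetic hairpin for id 6 starts its helix at position 4.

## Clustering

Both comparison arms share one substrate: a labeled, exactly symmetric,
zero-diagonal distance matrix.

* **2D**: Levenshtein distance between dot-bracket strings (unit-cost
  insertions/deletions/substitutions, computed with edlib), clustered by
  DBSCAN on the precomputed matrix.  Defaults `min_samples = 2` (the
  published minority cluster has two members) and `eps = 4` edits for 19-nt
  structures: in the emulated study configuration the two hairpins are 2
  edits apart while any hairpin is ≥ 6 edits from an unfolded record, and
  DBSCAN neighborhoods are inclusive (d ≤ eps), so eps must lie strictly
  between those scales.  Noise points are reported separately and excluded
  from the cluster count; `noise_as_singletons()` converts them to
  singleton clusters when the other convention is wanted.
* **3D**: Kabsch RMSD between ensemble centroids, single-linkage
  agglomeration.  An explicit threshold t yields exactly the connected
  components of the strictly-sub-threshold graph (the defining property of
  single linkage).  The automatic `largest-gap` cut sorts the dendrogram
  merge heights and cuts in the middle of the widest gap, **provided** the
  height above the gap is at least twice the height below it; without that
  scale-separation criterion the cut fragments pure within-scale noise
  (e.g., 13 jitter-only ensembles) into arbitrary clusters.  Gap ties
  resolve toward fewer clusters.

Cluster centroids are medoids: the member minimizing mean distance to the
rest, ties toward the earliest label.  Centroid statistics (average and
population SD of distance to the centroid) run over the non-centroid
members only — forced by the reporting convention for two-model ensembles,
whose average-to-centroid equals the single pairwise RMSD, not half of it.

## Tertiary structures

Multi-model PDB files are read with Bio.PDB (HETATM and non-'A' altLocs
skipped; a file without MODEL records is a single-model ensemble).  Atoms
are paired across structures by residue index and atom name — never by
sequence alignment, since variants differ by substitution only — restricted
to the default atom set {P, C4', C1'} so that structures of different
sequences remain fully comparable (base atoms cannot be paired across a
substitution).  Superposition is plain Kabsch: both sets centered, optimal
rotation from the SVD of the covariance matrix with a determinant correction
that excludes reflections.  The RMSD is computed from the explicitly rotated
residuals rather than the closed-form trace expression, which cancels
catastrophically near zero and cannot meet the 1e-9 rigid-motion-invariance
contract in double precision.  No iterative outlier rejection is performed;
interactive viewers' default `align` commands do reject outliers, so RMSD
magnitudes from such tools are comparable in structure but not bit-identical.

## Synthetic data

The generators stand in for the external services the real study used and
carry explicit planted truth:

* **Motif tables**: a configurable fraction of motifs embeds a GGAG/GCAG
  core *with the target sequence's own flanking context* (random flanks
  would almost never hit the target), the rest are random patterns with
  occasional degenerate codes; the manifest lists every hit found by an
  independent naive scanner at generation time.
* **Dot-bracket sets**: 11 all-dot records plus two hairpins — id 6 with
  the reported geometry (3-bp stem, 9-nt loop) and id 7 with a 4-bp stem /
  7-nt loop at the same offset.  The study reports a 4-nt loop for its
  second hairpin, but any 4-nt-loop geometry on a 19-mer is ≥ ~6 edits from
  the id-6 hairpin and would destroy the planted "two mutually close
  hairpins" truth that the published partition encodes; the stand-in
  therefore preserves the partition, not the second loop size.  Stem arms
  are Watson-Crick complementary so every record passes structural
  validation.
* **3D ensembles**: an ideal helical backbone trace (rise 2.81 Å, twist
  32.7°, three atoms per residue named P/C4'/C1' to match the comparison
  atom set; the 5'-terminal residue lacks P, as in real RNA).  Each model
  adds iid Gaussian jitter σ (default 0.1 Å); every ensemble in a planted
  divergent group additionally shifts its motif-window residues by one
  shared random direction of magnitude δ (default 3 Å).  Model counts
  follow the study condition: 10 models for the two divergent variants,
  2 for the rest.  A shared rigid sub-window shift is controlled ground
  truth for "a local difference confined to the motif region" — it is not
  RNA physics, and passing tests on these ensembles says nothing about the
  realism of any 3D predictor.

Generation is a pure function of (spec, seed); reruns are byte-identical.

## Selection rules

The published probe choice mixes a structural criterion with judgment; the
pipeline encodes it as three explicit rules (structure-divergent in every
available clustering; configurable low/high extremes of the distinct-RBP
count; user pins).  The extreme key is the distinct-RBP count, not the raw
hit count — that is what makes the published high-extreme choice (variant
9, 13 RBPs) reproducible even though another variant has more raw hits
(16 hits, 12 RBPs).  The published outcome {5, 6, 7, 8, 9} corresponds to
pins {5, 8} with one high extreme; the pins are documented as pins, not
disguised as an algorithm.

## Problem sizes and determinism

Default test and acceptance runs use the study-scale conditions throughout:
19-nt sequences, 13 structures/ensembles, ≤ 10 models per ensemble, ~30-row
motif tables; exhaustive oracles run at n ≤ 12 (structure enumeration) and
n ≤ 25 (hairpin candidates).  The stochastic planted-partition check uses 50
replicate seeds with δ/σ = 30 and requires ≥ 95% recovery.  All randomness
flows from explicit integer seeds; every pipeline artifact embeds the seed
and a configuration hash, and rerunning a configuration reproduces every
artifact byte for byte.

## Known limitations

* No pseudoknots, multibranch loops, interior loops/bulges, or partition-
  function quantities; the MFE engine considers single contiguous-helix
  hairpins only.
* The energy table is a stand-in; printed free energies from trained
  predictors are out of reach by design.
* PDB only (no mmCIF); pairing by residue index assumes no indels between
  compared structures.
* DBSCAN/single-linkage defaults are tuned to 19-nt dot-brackets and
  Ångström-scale RMSD matrices respectively; other scales need explicit
  `ClusterParams`.
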