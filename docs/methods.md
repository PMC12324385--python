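# Methods

This note documents the models and procedures phylomark implements, the
parameters that matter, the numerical choices behind them, and what the
synthetic data generator does and does not emulate.

## Profiles and search

A marker profile is a position-specific score matrix over the match
columns of a seed alignment. Match columns are those with gap fraction
strictly below 0.5; gap characters, `.`-gaps, and ambiguity codes (`X`
for amino acids, `N` for nucleotides) all count as gaps. Emission
probabilities use background-weighted pseudocounts,

    e_i(s) = (c_i(s) + α·q(s)) / (n_i + α),

with pseudocount α = 1 and a uniform background q (1/20 or 1/4) by
default. All probabilities are therefore strictly positive, every column
sums to one, and the log-odds `log2(e_i(s)/q(s))` satisfy
`Σ_s 2^logodds · q(s) = 1`. The consensus is the per-column argmax state
(ties broken by alphabet order). Insert states are not modeled; an
external profile-HMM engine could be slotted in behind the same
`MarkerSet` interface if insert-state emissions ever matter.

Search is Smith–Waterman local alignment of each sequence against each
profile's log-odds columns with affine gap penalties, defaults
gap-open = 4 bits and gap-extend = 0.5 bits in both gap directions.
The forward pass is vectorized per sequence row; the in-row gap state is
computed with a prefix-maximum transformation, which is exact whenever
gap-open ≥ gap-extend (re-opening a running gap can then never beat
extending it) — the profile constructor enforces this inequality. Tests
verify exact agreement with a cell-by-cell three-state Gotoh oracle.
Hit spans are recovered by a second pass on the reversed prefix, the
standard trick for locating a local alignment's start without a
traceback matrix.

**Hit threshold.** The default is 50 bits. Measured on simulated data,
local scores of *unrelated* random peptides against a 300-column profile
reach the low twenties (the score of the best chance alignment grows
with the product of sequence and profile length), while genuine family
members at the divergences the generator produces score roughly 650–880
bits. Fifty bits sits well above the chance regime and far below the
signal regime across the profile lengths the pipeline encounters
(tens to a few hundred columns); it is overridable per run
(`--min-bitscore`), and the threshold is part of the checkpoint's
parameter fingerprint, so changing it forces a clean re-search.

CDS inputs are translated with the standard genetic code before scoring;
a single terminal stop codon is stripped, an internal stop is an error.

## Single-copy resolution

For each marker, a sample contributing two or more distinct
above-threshold sequences is excluded from that marker — regardless of
the score gap between them, since a large gap is not evidence of
orthology for the better hit. A sample with exactly one hit sequence
contributes it (multiple local hits within the same sequence are one
hit). Markers retained by fewer than four samples are dropped: four taxa
is the minimum for any informative unrooted topology. The same
four-sample minimum applies to the whole analysis.

## Checkpointing

Samples are identified by the SHA-256 of their file bytes, so renames and
moves are invisible and checkpoint files are portable. The checkpoint is
a versioned JSON file holding, under a single parameter fingerprint
(marker-set name, marker count, threshold, gap penalties), the complete
hit list per sample digest. On rerun, digests already present are served
from the file; a fingerprint mismatch discards everything. Digests no
longer among the inputs are deliberately kept, so a checkpoint built on a
large collection can serve as a prebuilt backbone when placing new
samples. Creation/update timestamps only move when content changes,
which makes repeated updates with identical inputs byte-stable.

## Alignment, threading, trimming

Assigned orthologs are aligned to their marker profile by global dynamic
programming over the profile's match columns (same scores and gap
penalties as the search); sequence residues that align as insertions are
projected out, so every row has exactly one symbol per match column.
The traceback is bitwise-exact: every comparison re-executes the same
floating-point operation the forward pass used.

For CDS runs, the codons of each (stop-stripped) CDS are threaded onto
the peptide alignment — each residue becomes its codon, each gap becomes
`---` — after validating that the CDS translates exactly to the ungapped
peptide row.

Trimming keeps exactly the parsimony-informative columns: at least two
distinct states, each present in at least two rows, with gaps and
ambiguity codes counting as no state. Trimming is idempotent, and the
0-based indices of kept columns plus the source alignment length are
recorded (in-memory on `TrimmedMsa`, on disk in `alignments/trim.tsv`).

## Distances, gene trees, ranking

Pairwise distances are p-distances over columns where both rows have a
proper state, corrected under the uniform-exchange model:
`d = −((k−1)/k)·ln(1 − k·p/(k−1))` with k = 4 (JC69) or k = 20. A pair
at or beyond the correction's domain boundary is capped at d = 10
substitutions/site rather than erroring; a pair with no shared scored
column is an error naming the pair.

**Constant-site restoration.** Applying these corrections directly to an
alignment trimmed to parsimony-informative sites overstates every
distance, and the logarithmic correction amplifies the distortion
non-uniformly enough to mislead neighbor joining (in simulations this
misplaced one taxon in both inference modes on several seeds). When a
trimmed alignment knows its source length, the trimmed-away columns are
therefore restored to the denominator as shared invariant sites — an
approximation (a removed column can carry a singleton difference for a
particular pair) that in practice recovers distances on the scale of the
untrimmed alignment and, in simulations, restores exact topology
recovery. Plain alignments without trimming metadata are scored exactly
as stated above.

Gene trees are built by canonical neighbor joining on the Q-criterion.
Ties are broken by the lexicographically smallest label pair, so the
topology is invariant to taxon input order; negative branch-length
estimates are clamped to zero; additive matrices are recovered exactly
(topology and branch lengths). NJ was chosen over approximate ML for the
gene-tree role because it is deterministic and cheap, and the filter
stage only needs trees good enough to rank markers.

Markers are ranked by treeness/RCV. Treeness is the fraction of total
branch length on internal branches (a bifurcating root's two edges count
as one branch). RCV is `Σ_i Σ_s |c_is − c̄_s| / (n·t)` over the trimmed
alignment, gaps and ambiguities excluded. A marker with RCV exactly 0
gets a +∞ score and ranks first (tie-broken by id) — degenerate, but the
ranking must be total and deterministic. The default keeps all markers;
`--top-n` restricts to the best n.

## Species-tree inference

**Consensus.** The objective is the quartet score: the number of 4-taxon
subsets (of each gene tree's taxa) whose induced unrooted topology
matches the candidate. Quartets not fully present in a gene tree are
skipped. For up to `taxa_limit_exact` taxa (default 8, i.e. 10,395
topologies) the search is exhaustive, with per-quartet pairing counts
precomputed once over the gene trees; ties are broken by the
lexicographically smallest canonical newick, so the result is unique.
Above the limit, the best of a candidate set is returned: every distinct
full-coverage gene-tree topology, a greedy majority-rule consensus of
gene-tree splits, and an NJ tree on mean gene-tree path distances.
The consensus tree is topology-only; no branch lengths are estimated
on it.

**Concatenation.** Marker alignments are concatenated in ascending
marker-id order, taxa missing from a marker gap-filled, and each
marker's 1-based inclusive span recorded. The tree is distances + NJ on
the supermatrix (with constant-site restoration summed over markers).
For external ML tools the supermatrix is also written as relaxed PHYLIP
with a RAxML-style partition file (`LG, m1 = 1-3` / `GTR, ...`), one
substitution model per marker; partitioned likelihood fitting itself is
out of scope here.

**Support.** Branch support is a standard Felsenstein bootstrap
(default 100 replicates): sites resampled with replacement across the
whole supermatrix, tree rebuilt per replicate by the same
distance+NJ route, each internal branch annotated with the percentage of
replicates containing its bipartition; fully reproducible from the seed.
Gene concordance (gCF) is the percentage of decisive gene trees (≥ 2
taxa on each side of the branch) whose induced split set contains the
branch. Site concordance (sCF) samples, per internal branch, 100
quartets with one taxon from each of the four subtrees around the
branch; a site is decisive for a quartet when its four states form two
pairs of two distinct states, and supports the branch when the pairs
match the species-tree pairing; the branch's sCF is the mean percentage
of supporting decisive sites (branches with no decisive site in any
sampled quartet carry no sCF). Annotated trees serialize as newick with
`bootstrap/gCF/sCF` internal labels and round-trip losslessly.

## Tree comparison

Robinson–Foulds distance is the size of the symmetric difference of the
nontrivial bipartition sets, normalized by 2(n−3) (the maximum for
binary trees). This is the standard RF metric; matching-based
generalized variants are not implemented. Monophyly assessment requires
an explicit outgroup: the tree is rooted on the outgroup's attachment
edge and a group is monophyletic iff some clade equals it exactly;
single-member groups are reported as singletons.

## Synthetic data

The generator emulates the pipeline's study inputs: a pure-birth (Yule)
species tree (birth rate 1.0), per marker a random root sequence evolved
along the tree under a uniform-exchange substitution model at
`mutation_scale` (default 0.1) expected substitutions per site per unit
branch length, no rate heterogeneity, no indels, and gene trees equal to
the species tree (no coalescent discordance). Defaults: 8 taxa, 20
markers, 300 residues — a small, low-divergence clade where both
inference modes should recover the generating topology exactly. Each
marker also gets an independently evolved replicate of the same family
whose leaf sequences serve as the profile seed alignment, so profiles
are built from data disjoint from the analyzed sequences. With
probability `duplication_prob` a sample receives a second copy of a
marker, mutated a further 0.15 expected substitutions/site, to exercise
the multi-hit exclusion rule. CDS files are uniform synonymous-codon
back-translations of the peptides plus a stop codon. All randomness
derives from one seed via spawned seed sequences; regeneration is
byte-identical.

What passing tests on these data do **not** show: robustness to
alignment error from indels, to rate heterogeneity or compositional
bias, to incomplete lineage sorting or other gene-tree discordance, to
annotation errors, or to genuinely missing markers. The generator's
role is to verify the machinery (search, exclusion, checkpoint,
trimming, both inference routes) against a known truth, not to certify
accuracy on real genomes.

Scaled-down worlds inside the test-suite and acceptance script use
4–11 taxa and 2–3 markers of 120–150 residues; markers much shorter
than that would push legitimate hits toward the 50-bit threshold and
test the threshold rather than the property at hand.

## Known limitations

- Profiles have no insert states; highly indel-rich families will score
  worse than under a full profile HMM.
- The in-repo tree builders are distance-based; for publication-grade
  branch lengths and model-based inference, feed the emitted
  supermatrix/partition files to an external ML tool.
- The consensus heuristic above the exact-search limit is a candidate-set
  argmax, not a global quartet optimization.
- Bootstrap resampling draws from the trimmed supermatrix only; the
  restored constant sites are held fixed across replicates.
- One global bit-score threshold; no per-marker calibrated cutoffs.
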