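# Methods

This note records the models, parameter choices and numerical
conventions behind `madascan`, and what the synthetic benchmark does and
does not establish.

## The analysis in brief

Plant CC-NLR immune receptors are filtered from proteomes by the
presence of a Walker-A p-loop and a usable N-terminal domain, their
N-terminal domains are clustered into families ("tribes") by Markov
clustering of a local-alignment similarity graph, a conserved N-terminal
motif is discovered in the helper-containing tribe by ZOOPS EM, a
profile HMM built from the motif sites scans the database, and each
protein is classified **MADA** (bit score ≥ 10.0), **MADA-like**
(positive score below 10.0) or negative, with positional and clade-level
summaries on top.

## Database compilation (`nlrome`)

* **p-loop**: first match of `G-x(4)-G-K-[S/T]` (configurable). The
  pattern is a design choice — upstream NLR annotation tools do not
  publish a single canonical regex — and only the *first* match is used,
  deterministically.
* **NB-ARC anchor**: `nbarc_start = ploop_start − offset`, floored at 1.
  The offset is configurable (default 0) because no universal NB-ARC
  boundary rule exists; for simulated data the exact template offset
  (10 residues) is known and used, which the tests exploit to check the
  annotation recovers ground truth exactly.
* **Filters**: no p-loop → drop; N-terminal domain not *strictly* longer
  than 30 residues → drop; membership in a caller-supplied TIR clade
  (from `phylo.flag_clade`) → drop. Every dropped record carries a
  reason code, and kept ∪ dropped partitions the input.
* Coordinates are 1-based inclusive throughout.

## Alignment (`align`)

Affine-gap dynamic programming over BLOSUM62 with gap open 11 and
extend 1; a gap of length k costs `open + (k−1)·extend`. Global mode
penalizes terminal gaps (full Needleman–Wunsch); local mode floors at
the empty alignment with score 0. Traceback ties break
diagonal > up > left, making outputs deterministic. The progressive
multiple aligner builds an NJ guide tree on pairwise identity distances
(1 − identities / aligned non-gap columns) and merges profiles with the
same scoring scheme (expected substitution score between column
frequency vectors). Bulk pairwise scoring inside the tribe graph and
guide-tree stages runs on Biopython's C pairwise aligner, configured to
the identical scheme; the in-package DP is the reference implementation
and the two are asserted score-equal in the tests. Gap-heavy columns
are stripped with a configurable per-column gap-fraction threshold
(default 0: remove any column containing a gap).

## Phylogeny (`phylo`)

Distances are p-distances over mutually non-gap columns (optional
Poisson correction `−ln(1−p)`); a pair with no comparable columns is an
error rather than a guess. Full rate-matrix (JTT-style) corrections
are deliberately out of scope: the analysis consumes topology and clade
support, not absolute branch lengths, and p-distance NJ recovers
additive topologies exactly. Neighbour joining follows Saitou–Nei with
two declared conventions: Q-matrix ties break to the lowest (i, j)
index pair, and negative branch lengths are clamped to zero with the
deficit moved to the sibling branch. Bootstrap support is the fraction
of column-resampled replicates containing each bipartition of the point
tree (default 100 replicates, seeded). `flag_clade` returns the
smallest clade containing all anchors whose stem support is ≥ 0.7
(single leaves qualify trivially; the whole leaf set is the fallback).

## Tribes (`tribes`)

Edges of the similarity graph require Karlin–Altschul
`E = K·m·n·exp(−λS) < 1e-8` with the published gapped-BLOSUM62
constants λ = 0.267, K = 0.041 and effective lengths equal to raw
lengths; edge weight is −log10 E capped at 200. Exact agreement with
BLASTP's composition-adjusted E-values is not claimed (and a 200-mer
perfect self-match scores ≈ 110, well under the cap — the cap only
binds for long, highly similar pairs). MCL adds per-node self-loops
(max incident weight), column-normalizes, and iterates expansion
(matrix square) and inflation (entrywise power 2.0 — the canonical
Tribe-MCL default, exposed as a parameter) with pruning at 1e-6 until
the matrix change falls below 1e-8; clusters are connected components
of the limit matrix's support. Non-convergence returns the current
clustering with a warning rather than failing. Tribe ids are dense
from 1, ordered by descending size then lexicographically smallest
member, so runs are reproducible and order-invariant.

## Motif discovery (`motif`)

The ZOOPS likelihood mixes "no site" (probability 1−γ) with one site at
a uniform start, PWM columns versus a 0-order background. EM
re-estimates the PWM (pseudocount 0.01 per cell), the background (from
expected non-site residues) and γ; the data log-likelihood is monotone
and asserted so. Starting points matter more than iteration count:
following MEME's practice, a large pool of substring-derived seeds
(default 300) is screened with a single EM step and only the best
(default 10) are refined to convergence (tolerance 1e-6, ≤ 100 steps),
which reliably finds the planted optimum rather than a shifted one.
Sites are reported at posterior ≥ 0.5 — the natural ZOOPS decision
boundary, declared because site-reporting thresholds vary between
implementations. Additional motifs are found by masking reported sites
with `X`; masked windows are excluded outright, so later motifs can
never overlap earlier ones. The consensus string prints the majority
residue where its site frequency is ≥ 0.45, else `x`. Information
content is relative entropy versus the background, in bits per column.

## Profile HMM (`hmm`)

Topology: flanking N/C states that emit background residues on their
self-loops (so the motif may occur anywhere in the sequence), match
states M1..MM, and insert/delete states between them — unused by models
built from ungapped site alignments but fully supported when reading
external HMMER2 files. The per-sequence flank self-loop probability is
set to L/(L+1), matching the geometric null, so flank emissions cancel
and the bit score reduces to the motif log-odds plus an explicit length
correction (≈ −log2(L+1)). Forward sums all paths and is provably ≥
Viterbi; both are verified against exhaustive path enumeration on toy
models. Only the best-scoring domain per sequence is reported, with
1-based Viterbi start/end coordinates.

Construction uses Laplace (+1) emission pseudocounts against a uniform
default background; Dirichlet-mixture priors are out of scope, so
absolute bit scores will differ from HMMER's for the same sites —
score *ordering* agreement with HMMER (via pyhmmer) is what the tests
assert. Classification: score ≥ 10.0 → MADA (boundary inclusive);
reported (score > 0) and below the cutoff → MADA-like. The 0-bit
MADAL floor operationalizes "positive hit" and is configurable.

Calibration scores n (default 5000) background sequences of length 350
and fits a Gumbel by maximum likelihood (scipy), exposing
`E(S) = n_db · exp(−λ(S−μ))`.

The HMMER2 ASCII save format is read and written with integer
1/1000-bit scores; probabilities decode as `2^(score/1000) · null`
(null = the NULE residue frequency for emissions, 1 for transitions,
`*` = probability zero). Round-trips are lossless at the format's
integer precision; parse errors name the offending line.

## Reporting (`report`, `pipeline`)

A hit is *very N-terminal* when at most 15 residues precede the motif
(the complement of "extension over 15 residues"); N-terminal regions of
≥ 450 residues before the predicted CC start are reported as
NTD-bearing — a declared heuristic for the ~600-residue sensor
extension domains. Percentages are always `round(100·a/b, 1)` and
recompute exactly from the emitted counts. The score histogram uses
5-bit bins (configurable; bin edges are a presentation choice, not a
result). The pipeline writes every stage artifact plus a timestamp-free
log, so a rerun with the same configuration and seed is bit-identical;
skipping the tree stage changes only the clade tables.

## Synthetic study conditions (`simulate`)

The generator's defaults are the package's reference conditions,
chosen once:

| parameter | default | rationale |
| --- | --- | --- |
| families × members | 3 × 40 (+30 decoys) | a 150-protein repertoire, small enough for minutes-scale runs, large enough for stable percentages |
| motif width / consensus | 21, `MADAEVSFAVGKLTKLLENEL` | a concrete instantiation of the 21-residue MADA-type consensus |
| motif_conservation | 0.9 | per-column consensus probability typical of a strong family motif; the recovery benchmarks are defined at this level |
| helper_motif_fraction | 0.9 | ~9 in 10 helpers carry an intact motif, mirroring the observed 20-of-22 helper-clade rate |
| sensor_decay_rate | 0.4 | extra per-site substitution on sensor motifs; an a-priori bit-score budget (expected window log-odds ≈ 21·(7.5p−3.3), p = 0.9·(1−d), minus the ≈8-bit length correction) places decayed sensors straddling the 10.0 cutoff, producing the intended MADA/MADAL/negative gradient |
| ntd_fraction / ntd_length_mean | 0.55 / 600 | just over half of sensors carry a ~600-residue N-terminal extension domain, as in the helper/sensor clade counts (65/117) |
| extension_jitter | 6 | small N-terminal extensions before intact motifs (the Pik-2-style six extra residues), all within the 15-residue "very N-terminal" band |
| linker vs core divergence | 0.3 / 0.03 | within-family N-terminal linkers diverge faster than the motif (so the motif, not the linker, is the most conserved window — as in real tribes) while NB-ARC cores stay family-monophyletic |

Non-motif positions are uniform over the 20 residues; sensor decay is
per-column Bernoulli substitution to a random non-consensus residue;
NTDs are unstructured background sequence (only their length matters to
the positional rule). Each record is checked so its *first* Walker-A
match is the planted one, and decoys are rejection-sampled to be
p-loop-free.

**What the benchmark shows — and does not.** Passing on this generator
demonstrates that every stage is implemented correctly against
independent oracles and that the pipeline recovers planted structure
under realistic conservation levels. It does not demonstrate
performance on real proteomes: real NLRomes have non-uniform residue
composition, indels inside domains, paralog-specific duplication
structure, mis-annotated gene models, and LRR repeat grammar, none of
which are simulated (no codon-level evolution, no indels in the NB-ARC
core). Counts published for real NLRomes can be re-derived with
`madascan.supplementary` when the corresponding tables are available
locally; they are not shipped with the package.

## Problem sizes

The default test-and-acceptance workload uses the 150-record reference
repertoire, 100 bootstrap replicates on 120 taxa, 300-seed motif
screening, and 5000-sequence calibration — about one minute end-to-end
on one CPU, a size chosen so the full battery runs routinely rather
than occasionally.

## Known limitations

* Bit scores are not HMMER-calibrated absolute values (pseudocount and
  null-model differences of a few tenths of a bit per column); when
  reproducing published scores, load the published HMM file rather than
  rebuilding from sites, and expect ±0.2-bit agreement at best.
* The NB-ARC boundary is an offset from the p-loop, not a domain-model
  fit; on real data an HMM-based NB-ARC annotation would be preferable.
* MCL is dense-matrix; repertoires beyond ~5000 members would need a
  sparse implementation.
* The EDVID-type secondary motifs can be re-detected via the masking
  rounds (`n_motifs > 1`) but are a pipeline demonstration, not a
  validated output.
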