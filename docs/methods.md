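# Methods

## The problem and the shortcut

The exhaustive all-against-all aligns every unordered pair of proteins in a
multi-genome set and keeps the significant homologous pairs. Its cost is
n(n−1)/2 Smith–Waterman alignments, and on realistic proteome sets about
half of that effort is spent on unrelated pairs. `homclust` avoids most of
those: if A is homologous to B over a set of residues and A shows no
homology to C, then B and C need not be compared — A *represents* B. The
pipeline therefore (i) assigns sequences to homologous clusters by aligning
each incoming sequence only against cluster representatives, then (ii) runs
the full all-against-all within each cluster under exactly the baseline
criteria. Within-cluster output is a subset of the exhaustive output by
construction; the quantity traded is recall of pairs split across clusters,
and the quantity gained is the alignment count, which the package reports
as a hardware-independent speedup proxy.

Transitivity only holds when homology covers a *consistent* residue
stretch. Insertions and, above all, domain fusions produce proteins whose
different parts are homologous to different families. Two mechanisms deal
with this: a sequence may join any number of clusters, and (in the
subsequence-aware variant) the union of the sequence's residues covered by
its significant representative alignments is tracked as an interval set —
a sequence whose uncovered residue count exceeds a tolerance (20 residues)
founds an additional cluster as representative, *in addition to* its
memberships, so its unmatched region can recruit homologs later.

## Clustering procedure

Genomes are processed in descending order of sequence count (stable ties),
sequences within a genome in file order. For each sequence:

1. align it against every representative of every existing cluster
   (creation order, exhaustive scan);
2. for each cluster with at least one representative alignment scoring
   ≥ `min_score` (135.75), add the sequence as member; if the cluster has
   fewer than `max_representatives` representatives the sequence also
   becomes one (representatives are thus the first k members in join
   order);
3. accumulate the sequence-side interval of every significant
   representative alignment (across all clusters) into the sequence's
   coverage;
4. if the sequence joined no cluster, or its uncovered residues exceed the
   tolerance, found a new cluster with it as sole member and
   representative.

Only the score criterion is applied during clustering. The aligned-length
criterion (shorter-sequence aligned length ≥ 61% of the longer sequence)
applies only in the within-cluster all-against-all: applying it during
clustering would prevent fusion proteins from joining any cluster and
defeat the coverage mechanism, since a fusion's alignment to one family
covers only part of it.

Scores computed during clustering are cached by unordered id pair and
reused by the within-cluster stage; each unordered pair is aligned at most
once overall, and the alignment-count accounting reports clustering-phase
and within-cluster-phase computations separately.

## Scoring model

Scores are log-odds in 10·log10 units, the convention under which the
classic significance threshold 135.75 is calibrated. The substitution
model is a reversible Markov chain over the 20 canonical amino acids
parameterised by PAM distance (1 PAM = 1 accepted substitution per 100
residues). The default one-step model is Dayhoff-style, recovered at run
time from the classic PAM250 integer log-odds table shipped with
Biopython, anchored on the Dayhoff equilibrium frequencies: the symmetric
flux J[a,b] ∝ f_a f_b 10^(S250[a,b]/10) is normalized, its conditional
matrix is taken to the 250th root by eigendecomposition, tiny negative
entries are clipped with reversibility restored, and the off-diagonal is
rescaled so exactly 1% of residues mutate per step. (Solving for fully
self-consistent frequencies is ill-posed — the rounded integer log-odds
admit no positive frequency vector — hence the frequency anchor.) The
working matrix is M[a,b] = 10·log10(P_d(b|a)/f_b) at d = 224 by default;
any user matrix can be supplied through a labelled 20×20 text table. The
model gives ~33% expected identity at 146 PAM and a negative expected
background score, both in line with the PAM family.

Defaults and their meaning:

| parameter            | default | units            | role |
|----------------------|---------|------------------|------|
| `pam_distance`       | 224     | PAM              | matrix evolutionary distance |
| `gap_open`           | 20.0    | matrix units     | cost of a gap's first residue |
| `gap_extend`         | 1.0     | matrix units     | cost per further gapped residue |
| `min_score`          | 135.75  | matrix units     | significance threshold (inclusive) |
| `length_fraction`    | 0.61    | —                | aligned-length criterion (inclusive) |
| `coverage_tolerance` | 20      | residues         | max uncovered residues |
| `min_seq_length`     | 50      | residues         | input filter: keep length > 50 |
| `ambiguous_score`    | −5.0    | matrix units     | any pair involving B/Z/X/U/O/J |

Gap penalties are not fixed by the baseline criteria; the defaults are in
the conventional range for PAM/Gonnet-family matrices. Every evaluation in
this package compares the clustered pipeline against *its own* exhaustive
baseline under one shared scheme, so conclusions about recall and
alignment economy do not hinge on the gap defaults.

## Alignment kernel

Affine-gap local alignment in the standard three-state formulation
(H/E/F), gap of length k costing open + (k−1)·extend. The production
kernel is numba-compiled: a rolling-row score-only pass for the bulk of
pair screening, and a full-traceback pass (run only for significant pairs
and for coverage intervals) that reports the residue interval each
sequence contributes. Tie-breaking is fixed — first maximum in row-major
order; diagonal preferred over gap-in-subject over gap-in-query; gap
closure preferred over extension — and a pure-Python textbook DP with the
identical conventions serves as an independent oracle; the two agree
exactly (floating-point equality) on thousands of random pairs. Intervals
are 0-based half-open internally, 1-based inclusive in output tables. Only
the single optimal alignment per pair is used; sub-optimal alignments do
not contribute coverage.

## Synthetic data

The simulator emulates multi-genome proteome sets with the pathologies the
clustering must survive: deep divergence, indels, domain fusions, and
unrelated singletons. Families evolve on a star phylogeny — each member
descends independently from an i.i.d.-random ancestor at half the family's
target pairwise PAM distance — so pairwise divergence is controlled
directly and interval ground truth stays exact. Substitutions follow the
package's own PAM model; indels arrive as a Poisson process (default 0.01
events per residue per 100 PAM, geometric lengths of mean 3, deletions
clamped so sequences stay detectable). Fusion proteins concatenate two
independently evolved windows (≥100 residues) of two distinct family
ancestors, so each half can clear the score threshold on its own.

The desk-scale preset — 6 genomes × 60 proteins, 40 families of 2–12
members, ancestral lengths 150–500, pairwise distances uniform in 30–150
PAM, 5% fusions, 15% singletons — was chosen to reach the divergence
regime where homology detection begins to fail (empirical proteome sets
have median pair distances near 146–149 PAM) while every experiment runs
in minutes on one CPU. What the star phylogeny does *not* emulate:
tree-shaped family structure (so within-family divergence is more uniform
than in real data), site-rate heterogeneity, compositional bias, and
genome-level gene order; recall measured here therefore shows the
mechanism works under controlled divergence, not that the exact empirical
recall numbers transfer to any particular proteome set.

A `TruthSet` records which ancestral family windows each emitted sequence
carries; two sequences are a truth pair iff they share a family. The
operational reference for recall, however, is the exhaustive
all-against-all under the same scheme — matching how the method is
evaluated — while the truth set validates the simulator itself (at zero
divergence the exhaustive search recovers the truth set exactly, and
recall against truth decays as divergence grows).

## Evaluation

Recall is |predicted ∩ reference| / |reference| over unordered id pairs;
extra pairs (impossible by construction, since the clustered engine uses
the same aligner and criteria) are counted separately and treated as a
precision violation. Missing pairs carry their reference scores; their
distribution is summarized in 25-unit bins from `min_score` upward (last
bin open) and by the median-score ratio of missing vs all reference pairs.
In the five-replicate desk-scale experiment the subsequence-aware
1-representative variant loses no pairs at all, so the skew of missed-pair
scores is assessed on the pooled misses of both variants; the misses come
from cluster fragmentation and sit at the bottom of the score
distribution. An empty reference set makes recall undefined; it is
reported as 1 with an explicit flag and a warning.

## Numerical and design choices

* "Longer than 50 residues" is read strictly: the input filter keeps
  length ≥ 51, configurable.
* For equal-length sequences the aligned-length criterion uses the smaller
  of the two aligned lengths (conservative).
* Coverage accumulates from every significant representative alignment,
  not only the best per cluster: the information is already paid for, and
  more coverage can only suppress spurious extra clusters.
* A sequence founding a cluster for incomplete coverage keeps all
  memberships already granted.
* Genome-size ties and all scans are resolved in stable input/creation
  order; with a fixed scheme and input the entire pipeline is
  deterministic down to output bytes.
* Pair scores are rounded to 2 decimals at table precision when stored;
  significance is decided before rounding.
* The second-matrix filter used in some production settings (score ≥ 181
  under a separately optimised matrix) is intentionally not applied; the
  configuration leaves room to add such a filter.
* Input order sensitivity: shuffling the input changes cluster composition
  (the greedy procedure is order-dependent) but never violates totality or
  the coverage guarantee; this is property-tested over shuffles.

## Known limitations

* Recall depends on representative quality; the first-member choice is
  deliberate (it matches the incremental procedure) but suboptimal —
  centroid or profile representatives would likely recover the residual
  fragmentation losses.
* Cluster count grows roughly linearly in genome count at small scale, so
  the asymptotic advantage of the O(n·k) clustering phase emerges only for
  larger genome collections than the desk-scale preset.
* The aligner is serial and unbanded; throughput (~10⁸ DP cells/s) is
  adequate for the package's scale, not for production proteome volumes.
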