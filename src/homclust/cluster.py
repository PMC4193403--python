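"""Incremental construction of homologous clusters with representatives,
multi-cluster membership, and subsequence-level coverage.

The procedure exploits the transitivity of homology: one member of a
cluster can stand in for the whole cluster when deciding whether a new
sequence is homologous to it, so each sequence is aligned only against
cluster representatives, O(n*k) instead of O(n^2). Because homology is a
property of residue stretches rather than whole proteins (insertions,
domain fusions), a sequence may join several clusters, and in the
subsequence-aware variant the residues of each sequence covered by
representative alignments are tracked: a sequence whose residues are not
covered up to a tolerance founds an additional cluster as representative,
so its unmatched region can recruit homologs later.

Membership is decided on the alignment score alone; the aligned-length
criterion belongs to the within-cluster all-against-all stage (applying it
here would stop fusion proteins from ever joining a cluster).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from sklearn.base import BaseEstimator

from .align import smith_waterman, sw_score
from .io_formats import GenomeSet, ProteinSequence
from .scoring import ScoringScheme


@dataclass
class IntervalSet:
    """Union of disjoint, sorted, 0-based half-open intervals on one sequence."""

    seq_length: int
    intervals: list[tuple[int, int]] = field(default_factory=list)

    def add(self, start: int, end: int) -> None:
        """Add [start, end) and restore the canonical disjoint sorted form.

        Idempotent; touching intervals are merged.
        """
        if start < 0 or end > self.seq_length or start > end:
            raise ValueError(
                f"interval [{start}, {end}) out of bounds for length {self.seq_length}"
            )
        if start == end:
            return
        merged: list[tuple[int, int]] = []
        placed = False
        for s, e in self.intervals:
            if e < start or s > end:
                merged.append((s, e))
            else:
                start, end = min(s, start), max(e, end)
        for k, (s, e) in enumerate(merged):
            if s > start:
                merged.insert(k, (start, end))
                placed = True
                break
        if not placed:
            merged.append((start, end))
        self.intervals = merged

    @property
    def covered_length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def uncovered(self) -> int:
        return self.seq_length - self.covered_length


def add_interval(cov: IntervalSet, interval: tuple[int, int]) -> IntervalSet:
    """Functional wrapper around IntervalSet.add (returns its input)."""
    cov.add(*interval)
    return cov


def is_fully_covered(cov: IntervalSet, seq_length: int, tolerance: int) -> bool:
    """True iff at most ``tolerance`` residues are uncovered."""
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    return (seq_length - cov.covered_length) <= tolerance


@dataclass
class ClusteringConfig:
    max_representatives: int = 1
    use_subsequence_homology: bool = True
    coverage_tolerance: int | None = None  # None: take it from the scheme

    def __post_init__(self) -> None:
        if self.max_representatives < 1:
            raise ValueError("max_representatives must be >= 1")


@dataclass
class Cluster:
    cluster_id: int
    representatives: list[str]
    members: list[str]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterSet:
    clusters: list[Cluster] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def membership(self) -> dict[str, list[int]]:
        """seq_id -> cluster ids, in cluster creation order."""
        out: dict[str, list[int]] = {}
        for c in self.clusters:
            for sid in c.members:
                out.setdefault(sid, []).append(c.cluster_id)
        return out

    def __eq__(self, other) -> bool:
        return isinstance(other, ClusterSet) and self.clusters == other.clusters


def order_sequences(genomes: GenomeSet) -> list[ProteinSequence]:
    """Processing order: genomes by sequence count descending (stable ties),
    file order within each genome."""
    ranked = sorted(genomes.genomes, key=lambda g: -len(g[1]))
    return [s for _gid, seqs in ranked for s in seqs]


class HomologyClusterer(BaseEstimator):
    """Greedy incremental homology clustering over cluster representatives.

    Parameters
    ----------
    max_representatives : int
        Cap on representatives per cluster; the first ``max_representatives``
        members in join order serve as representatives.
    use_subsequence_homology : bool
        Track per-sequence coverage by representative alignments and found a
        new cluster for any sequence not covered up to the tolerance.
    scheme : ScoringScheme or None
        Scoring scheme; default PAM-224 scheme if None.
    coverage_tolerance : int or None
        Maximum uncovered residues; defaults to the scheme's value (20).

    Attributes
    ----------
    clusters_ : ClusterSet
    n_alignments_ : int
        Number of distinct Smith-Waterman computations performed.
    score_cache_ : dict[tuple[str, str], float]
        Scores of all alignments computed, keyed by sorted id pair; reused
        by the within-cluster all-against-all.
    coverage_ : dict[str, IntervalSet]
        Per-sequence coverage (subsequence variant only).
    """

    def __init__(
        self,
        max_representatives: int = 1,
        use_subsequence_homology: bool = True,
        scheme: ScoringScheme | None = None,
        coverage_tolerance: int | None = None,
    ):
        self.max_representatives = max_representatives
        self.use_subsequence_homology = use_subsequence_homology
        self.scheme = scheme
        self.coverage_tolerance = coverage_tolerance

    def fit(self, X: GenomeSet, y=None) -> "HomologyClusterer":
        """Build homologous clusters from a GenomeSet."""
        if not isinstance(X, GenomeSet):
            raise TypeError("X must be a GenomeSet")
        if self.max_representatives < 1:
            raise ValueError("max_representatives must be >= 1")
        scheme = self.scheme if self.scheme is not None else ScoringScheme.default()
        tol = (
            self.coverage_tolerance
            if self.coverage_tolerance is not None
            else scheme.coverage_tolerance
        )
        seqs = order_sequences(X)
        clusters: list[Cluster] = []
        rep_seqs: list[list[ProteinSequence]] = []  # parallel to clusters
        cache: dict[tuple[str, str], float] = {}
        n_alignments = 0
        coverage: dict[str, IntervalSet] = {}

        for seq in seqs:
            joined_any = False
            cov = IntervalSet(seq.length) if self.use_subsequence_homology else None
            for c, reps in zip(clusters, rep_seqs):
                significant = False
                for rep in reps:
                    key = (seq.seq_id, rep.seq_id) if seq.seq_id < rep.seq_id else (rep.seq_id, seq.seq_id)
                    score = cache.get(key)
                    if score is None:
                        score = sw_score(seq, rep, scheme)
                        cache[key] = score
                        n_alignments += 1
                    if score >= scheme.min_score:
                        significant = True
                        if cov is not None:
                            aln = smith_waterman(seq, rep, scheme)
                            cov.add(*aln.query_interval)
                if significant:
                    joined_any = True
                    c.members.append(seq.seq_id)
                    if len(c.representatives) < self.max_representatives:
                        c.representatives.append(seq.seq_id)
                        reps.append(seq)
            needs_own = not joined_any or (
                cov is not None and not is_fully_covered(cov, seq.length, tol)
            )
            if needs_own:
                cid = len(clusters)
                clusters.append(Cluster(cid, [seq.seq_id], [seq.seq_id]))
                rep_seqs.append([seq])
            if cov is not None:
                coverage[seq.seq_id] = cov

        self.clusters_ = ClusterSet(clusters)
        self.n_alignments_ = n_alignments
        self.score_cache_ = cache
        self.coverage_ = coverage
        self.scheme_ = scheme
        self.tolerance_ = tol
        return self

    def fit_predict(self, X: GenomeSet, y=None) -> dict[str, list[int]]:
        """Fit and return the seq_id -> cluster ids membership map."""
        return self.fit(X).clusters_.membership()


def build_clusters(
    genomes: GenomeSet, scheme: ScoringScheme, config: ClusteringConfig
) -> tuple[ClusterSet, int]:
    """Functional wrapper over HomologyClusterer; returns (clusters, n_alignments)."""
    est = HomologyClusterer(
        max_representatives=config.max_representatives,
        use_subsequence_homology=config.use_subsequence_homology,
        scheme=scheme,
        coverage_tolerance=config.coverage_tolerance,
    ).fit(genomes)
    return est.clusters_, est.n_alignments_


def cluster_statistics(clusters: ClusterSet) -> dict:
    """Summary: cluster count, size histogram, multi-membership counts."""
    sizes = Counter(c.size for c in clusters.clusters)
    per_seq = Counter()
    for c in clusters.clusters:
        for sid in c.members:
            per_seq[sid] += 1
    clusters_per_sequence = Counter(per_seq.values())
    return {
        "n_clusters": clusters.n_clusters,
        "size_histogram": dict(sorted(sizes.items())),
        "n_multi_membership": sum(1 for v in per_seq.values() if v >= 2),
        "clusters_per_sequence": dict(sorted(clusters_per_sequence.items())),
    }
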