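"""Significant-pair engines.

``full_all_against_all`` is the exhaustive baseline: every unordered pair
of distinct sequences (within and across genomes) is aligned and retained
if both the score threshold and the aligned-length criterion hold. It is
the reference ("oracle") against which the accelerated pipeline is
evaluated.

``within_cluster_all_against_all`` aligns only pairs co-occurring in at
least one homologous cluster, under identical criteria, so its output is a
subset of the baseline's by construction (perfect precision); the saving is
in the number of alignments computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from .align import is_significant, passes_length_criterion, smith_waterman, sw_score
from .cluster import ClusterSet
from .io_formats import GenomeSet
from .scoring import ScoringScheme


@dataclass(frozen=True)
class HomologPair:
    """A significant homologous pair in canonical (lexicographic) id order.

    Intervals are 0-based half-open; query_interval is on id1."""

    id1: str
    id2: str
    score: float
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]

    def __post_init__(self) -> None:
        if self.id1 == self.id2:
            raise ValueError("self-pairs are not allowed")
        if self.id1 > self.id2:
            raise ValueError("pair ids must be in canonical (sorted) order")

    @property
    def key(self) -> tuple[str, str]:
        return (self.id1, self.id2)


@dataclass
class PairSet:
    """Set of homologous pairs plus the alignment-count accounting."""

    _pairs: dict[tuple[str, str], HomologPair] = field(default_factory=dict)
    total_alignments_computed: int = 0

    def add(self, pair: HomologPair) -> None:
        if pair.key in self._pairs:
            raise ValueError(f"duplicate pair {pair.key}")
        self._pairs[pair.key] = pair

    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self) -> Iterator[HomologPair]:
        return iter(self._pairs.values())

    def __contains__(self, key) -> bool:
        if isinstance(key, HomologPair):
            key = key.key
        a, b = key
        return ((a, b) if a < b else (b, a)) in self._pairs

    def get(self, id_a: str, id_b: str) -> HomologPair | None:
        key = (id_a, id_b) if id_a < id_b else (id_b, id_a)
        return self._pairs.get(key)

    def keys(self) -> set[tuple[str, str]]:
        return set(self._pairs)

    def __eq__(self, other) -> bool:
        return isinstance(other, PairSet) and self._pairs == other._pairs


def _make_pair(seq_a, seq_b, scheme: ScoringScheme) -> HomologPair | None:
    """Traceback alignment in canonical orientation, apply both criteria."""
    a, b = (seq_a, seq_b) if seq_a.seq_id < seq_b.seq_id else (seq_b, seq_a)
    aln = smith_waterman(a, b, scheme)
    if not is_significant(aln, scheme):
        return None
    if not passes_length_criterion(aln, a.length, b.length, scheme):
        return None
    return HomologPair(
        a.seq_id,
        b.seq_id,
        round(aln.score, 2),
        aln.query_interval,
        aln.subject_interval,
    )


def full_all_against_all(genomes: GenomeSet, scheme: ScoringScheme) -> PairSet:
    """Exhaustive baseline: align all n(n-1)/2 unordered pairs."""
    seqs = list(genomes.sequences())
    out = PairSet()
    n_aln = 0
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            n_aln += 1
            score = sw_score(seqs[i], seqs[j], scheme)
            if score >= scheme.min_score:
                pair = _make_pair(seqs[i], seqs[j], scheme)
                if pair is not None:
                    out.add(pair)
    out.total_alignments_computed = n_aln
    return out


def within_cluster_all_against_all(
    clusters: ClusterSet,
    genomes: GenomeSet,
    scheme: ScoringScheme,
    score_cache: dict[tuple[str, str], float] | None = None,
) -> PairSet:
    """All-against-all restricted to pairs sharing at least one cluster.

    Each unordered pair is aligned once regardless of how many clusters it
    co-occurs in; scores already computed during clustering (passed via
    ``score_cache``) are reused and not counted again, so
    ``total_alignments_computed`` is the number of new alignments.
    """
    by_id = genomes.by_id()
    cache = score_cache or {}
    candidate: set[tuple[str, str]] = set()
    for c in clusters.clusters:
        for sid in c.members:
            if sid not in by_id:
                raise ValueError(f"cluster member {sid!r} not found in genomes")
        ms = c.members
        for i in range(len(ms)):
            for j in range(i + 1, len(ms)):
                a, b = ms[i], ms[j]
                candidate.add((a, b) if a < b else (b, a))
    out = PairSet()
    n_new = 0
    for key in sorted(candidate):
        score = cache.get(key)
        if score is None:
            score = sw_score(by_id[key[0]], by_id[key[1]], scheme)
            n_new += 1
        if score >= scheme.min_score:
            pair = _make_pair(by_id[key[0]], by_id[key[1]], scheme)
            if pair is not None:
                out.add(pair)
    out.total_alignments_computed = n_new
    return out
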