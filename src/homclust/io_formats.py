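"""Input/output: multi-genome FASTA reading with the global length filter,
and the tab-separated cluster / homologous-pair tables.

One FASTA file corresponds to one genome; within-genome sequence order is
the file order, which the clustering stage relies on. Coordinates are
0-based half-open internally and converted to 1-based inclusive only in
the written tables.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import SeqIO

from ._alphabet import encode, sanitize

logger = logging.getLogger(__name__)

PAIRS_COLUMNS = ["id1", "id2", "score", "qstart", "qend", "sstart", "send"]
CLUSTERS_COLUMNS = ["cluster_id", "seq_id", "is_representative"]


@dataclass
class ProteinSequence:
    """A single protein with a globally unique id and sanitized residues."""

    seq_id: str
    genome_id: str
    residues: str
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.residues) == 0:
            raise ValueError(f"sequence {self.seq_id!r} is empty")

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def codes(self) -> np.ndarray:
        """int8 matrix indices, computed once and cached."""
        if self._codes is None:
            self._codes = encode(self.residues)
        return self._codes


@dataclass
class GenomeSet:
    """Ordered collection of genomes, each an ordered list of proteins."""

    genomes: list[tuple[str, list[ProteinSequence]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for _gid, seqs in self.genomes:
            for s in seqs:
                if s.seq_id in seen:
                    raise ValueError(f"duplicate seq_id {s.seq_id!r}")
                seen.add(s.seq_id)

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)

    @property
    def n_sequences(self) -> int:
        return sum(len(seqs) for _g, seqs in self.genomes)

    def sequences(self) -> Iterator[ProteinSequence]:
        for _gid, seqs in self.genomes:
            yield from seqs

    def by_id(self) -> dict[str, ProteinSequence]:
        return {s.seq_id: s for s in self.sequences()}


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_genomes(
    paths: list[str | Path],
    min_length: int = 50,
    genome_ids: list[str] | None = None,
) -> GenomeSet:
    """Read one genome per FASTA file, dropping sequences of length <= min_length.

    The seq_id is the first whitespace-delimited header token; the genome id
    defaults to the file stem. Sequences are uppercased, '*' and '-' are
    stripped, and a residue outside the accepted alphabet raises ValueError.
    """
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    if genome_ids is not None and len(genome_ids) != len(paths):
        raise ValueError("genome_ids must match paths in length")
    genomes: list[tuple[str, list[ProteinSequence]]] = []
    n_dropped = 0
    for k, p in enumerate(paths):
        path = Path(p)
        if not path.is_file():
            raise OSError(f"cannot read FASTA file: {path}")
        gid = genome_ids[k] if genome_ids else path.name.removesuffix(".gz").rsplit(".", 1)[0]
        seqs: list[ProteinSequence] = []
        with _open_text(path) as handle:
            for rec in SeqIO.parse(handle, "fasta"):
                residues = sanitize(str(rec.seq))
                if not residues:
                    raise ValueError(f"empty record {rec.id!r} in {path}")
                if len(residues) <= min_length:
                    n_dropped += 1
                    continue
                seqs.append(ProteinSequence(rec.id, gid, residues))
        genomes.append((gid, seqs))
    if n_dropped:
        logger.info("read_genomes: dropped %d sequence(s) of length <= %d", n_dropped, min_length)
    return GenomeSet(genomes)


def write_genomes(genomes: GenomeSet, out_dir: str | Path, width: int = 60) -> list[Path]:
    """Write one plain FASTA file per genome into out_dir; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for gid, seqs in genomes.genomes:
        path = out_dir / f"{gid}.fasta"
        with open(path, "w") as fh:
            for s in seqs:
                fh.write(f">{s.seq_id}\n")
                for i in range(0, len(s.residues), width):
                    fh.write(s.residues[i : i + width] + "\n")
        paths.append(path)
    return paths


def write_pairs(pairs, path: str | Path) -> None:
    """Write a PairSet as a TSV table, sorted for byte-identical output."""
    rows = sorted(pairs, key=lambda p: (p.id1, p.id2))
    with open(path, "w") as fh:
        fh.write("\t".join(PAIRS_COLUMNS) + "\n")
        for p in rows:
            qs, qe = p.query_interval
            ss, se = p.subject_interval
            # 1-based inclusive in the table
            fh.write(f"{p.id1}\t{p.id2}\t{p.score:.2f}\t{qs + 1}\t{qe}\t{ss + 1}\t{se}\n")


def read_pairs(path: str | Path):
    from .allvsall import HomologPair, PairSet

    pairs = PairSet()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != PAIRS_COLUMNS:
            raise ValueError(f"unexpected pairs table header in {path}")
        for line in fh:
            id1, id2, score, qs, qe, ss, se = line.rstrip("\n").split("\t")
            pairs.add(
                HomologPair(
                    id1,
                    id2,
                    float(score),
                    (int(qs) - 1, int(qe)),
                    (int(ss) - 1, int(se)),
                )
            )
    return pairs


def write_clusters(clusters, path: str | Path) -> None:
    """Write a ClusterSet as a TSV table; representatives flagged with 1."""
    with open(path, "w") as fh:
        fh.write("\t".join(CLUSTERS_COLUMNS) + "\n")
        for c in clusters.clusters:
            reps = set(c.representatives)
            for sid in c.members:
                fh.write(f"{c.cluster_id}\t{sid}\t{1 if sid in reps else 0}\n")


def read_clusters(path: str | Path):
    from .cluster import Cluster, ClusterSet

    by_cluster: dict[int, Cluster] = {}
    order: list[int] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != CLUSTERS_COLUMNS:
            raise ValueError(f"unexpected clusters table header in {path}")
        for line in fh:
            cid_s, sid, rep_s = line.rstrip("\n").split("\t")
            cid = int(cid_s)
            if cid not in by_cluster:
                by_cluster[cid] = Cluster(cid, [], [])
                order.append(cid)
            c = by_cluster[cid]
            c.members.append(sid)
            if rep_s == "1":
                c.representatives.append(sid)
    return ClusterSet([by_cluster[cid] for cid in order])
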