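"""Synthetic multi-genome proteomes with known homology ground truth.

Families are simulated on a star phylogeny: an ancestral protein is drawn
i.i.d. from the model's equilibrium frequencies and each member evolves
independently from it at half the family's target pairwise PAM distance,
so two members are separated by approximately the target distance.
Substitutions follow the package's reversible PAM model; insertions and
deletions arrive as a Poisson process along each branch with geometric
lengths. Domain-fusion proteins — the structures that break whole-protein
transitivity — are built by concatenating independently evolved windows
(>= 100 residues) of two distinct family ancestors, so each half can carry
a significant alignment on its own. Singletons are unrelated random
sequences.

The ground truth records, for every emitted sequence, which ancestral
family windows it carries; two sequences are a truth pair iff they share
at least one ancestral family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from ._alphabet import CANONICAL_AA
from .io_formats import GenomeSet, ProteinSequence
from .scoring import OnePamModel, dayhoff_one_pam_model

MIN_FUSION_SEGMENT = 100  # residues; keeps each half independently detectable
MIN_SURVIVING_LENGTH = 60  # deletions never shrink a sequence below this


@dataclass
class EvolutionParams:
    """Simulation conditions.

    The defaults are the desk-scale preset: 6 genomes x 60 proteins built
    from 40 families (2-12 members each), ancestral lengths 150-500,
    pairwise divergence uniform in 30-150 PAM (median ~90, reaching the
    ~150 PAM regime where homology detection starts to fail), 5% fusion
    proteins and 15% singletons. Indels arrive at 0.01 events per residue
    per 100 PAM with geometric lengths of mean 3.
    """

    n_genomes: int = 6
    proteins_per_genome: int = 60
    n_families: int = 40
    family_size_min: int = 2
    family_size_max: int = 12
    pam_min: float = 30.0
    pam_max: float = 150.0
    indel_rate: float = 0.01
    indel_mean_length: float = 3.0
    fusion_probability: float = 0.05
    singleton_fraction: float = 0.15
    length_min: int = 150
    length_max: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.fusion_probability <= 1 and 0 <= self.singleton_fraction <= 1):
            raise ValueError("probabilities must be in [0, 1]")
        if self.fusion_probability + self.singleton_fraction > 1:
            raise ValueError("fusion_probability + singleton_fraction must be <= 1")
        if self.pam_min < 0 or self.pam_max < self.pam_min:
            raise ValueError("need 0 <= pam_min <= pam_max")
        if self.indel_rate < 0 or self.indel_mean_length < 1:
            raise ValueError("indel_rate >= 0 and indel_mean_length >= 1 required")
        if not (1 <= self.family_size_min <= self.family_size_max):
            raise ValueError("invalid family size range")
        if self.length_min < MIN_FUSION_SEGMENT or self.length_max < self.length_min:
            raise ValueError(f"ancestral lengths must be >= {MIN_FUSION_SEGMENT}")
        if self.n_genomes < 1 or self.proteins_per_genome < 1 or self.n_families < 1:
            raise ValueError("counts must be positive")

    @classmethod
    def desk(cls, seed: int = 0) -> "EvolutionParams":
        """The default desk-scale preset."""
        return cls(seed=seed)

    @classmethod
    def perfect(cls, seed: int = 0) -> "EvolutionParams":
        """Zero divergence, no indels, no fusions, no singletons: every
        family member is an identical copy of its ancestor."""
        return cls(
            seed=seed,
            pam_min=0.0,
            pam_max=0.0,
            indel_rate=0.0,
            fusion_probability=0.0,
            singleton_fraction=0.0,
        )


class Domain(NamedTuple):
    """An ancestral family window carried by an emitted sequence."""

    family: int
    anc_start: int
    anc_end: int
    seq_start: int
    seq_end: int


@dataclass
class TruthSet:
    """Ground-truth homology: unordered id pairs sharing >= 1 family."""

    pairs: set[tuple[str, str]] = field(default_factory=set)
    domains: dict[str, list[Domain]] = field(default_factory=dict)

    def shared_intervals(
        self, id1: str, id2: str
    ) -> list[tuple[tuple[int, int], tuple[int, int]]]:
        """Sequence intervals of every family the two sequences share."""
        out = []
        for d1 in self.domains.get(id1, []):
            for d2 in self.domains.get(id2, []):
                if d1.family == d2.family:
                    out.append(((d1.seq_start, d1.seq_end), (d2.seq_start, d2.seq_end)))
        return out


def _sample_codes(freqs: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(freqs)
    return np.searchsorted(cum, rng.random(n)).astype(np.int8)


def _evolve_codes(
    codes: np.ndarray,
    distance: float,
    params: EvolutionParams,
    rng: np.random.Generator,
    model: OnePamModel,
) -> np.ndarray:
    """One branch: per-site substitution under P_distance, then indels."""
    if distance > 0:
        cum = np.cumsum(model.compose(distance), axis=1)
        u = rng.random(len(codes))
        child = (cum[codes.astype(int)] < u[:, None]).sum(axis=1).astype(np.int8)
    else:
        child = codes.copy()
    n_events = rng.poisson(params.indel_rate * len(codes) * distance / 100.0)
    out = list(child)
    for _ in range(n_events):
        length = int(rng.geometric(1.0 / params.indel_mean_length))
        if rng.random() < 0.5:  # deletion
            if len(out) - length < MIN_SURVIVING_LENGTH:
                continue
            pos = int(rng.integers(0, len(out) - length + 1))
            del out[pos : pos + length]
        else:  # insertion of background residues
            pos = int(rng.integers(0, len(out) + 1))
            out[pos:pos] = list(_sample_codes(model.freqs, length, rng))
    return np.array(out, dtype=np.int8)


def _to_residues(codes: np.ndarray) -> str:
    return "".join(CANONICAL_AA[c] for c in codes)


def evolve_sequence(
    parent: ProteinSequence,
    distance: float,
    params: EvolutionParams,
    rng: np.random.Generator,
    model: OnePamModel | None = None,
    seq_id: str | None = None,
) -> ProteinSequence:
    """Evolve a descendant of ``parent`` at ``distance`` PAM units."""
    if distance < 0:
        raise ValueError("distance must be >= 0")
    model = model or dayhoff_one_pam_model()
    child = _evolve_codes(parent.codes, distance, params, rng, model)
    return ProteinSequence(
        seq_id or f"{parent.seq_id}_child", parent.genome_id, _to_residues(child)
    )


def _family_sizes(params: EvolutionParams, n_members: int, rng) -> np.ndarray:
    lo, hi, k = params.family_size_min, params.family_size_max, params.n_families
    if n_members == 0:
        return np.zeros(k, dtype=int)
    if not (k * lo <= n_members <= k * hi):
        raise ValueError(
            f"cannot split {n_members} family members into {k} families of size {lo}-{hi}"
        )
    sizes = rng.integers(lo, hi + 1, k)
    while sizes.sum() > n_members:
        idx = rng.integers(0, k)
        if sizes[idx] > lo:
            sizes[idx] -= 1
    while sizes.sum() < n_members:
        idx = rng.integers(0, k)
        if sizes[idx] < hi:
            sizes[idx] += 1
    return sizes


def generate_dataset(params: EvolutionParams) -> tuple[GenomeSet, TruthSet]:
    """Simulate a multi-genome proteome set with its homology ground truth."""
    rng = np.random.default_rng(params.seed)
    model = dayhoff_one_pam_model()
    total = params.n_genomes * params.proteins_per_genome
    n_singletons = round(params.singleton_fraction * total)
    n_fusions = round(params.fusion_probability * total)
    if n_fusions > 0 and params.n_families < 2:
        raise ValueError("fusions require at least two families")
    n_members = total - n_singletons - n_fusions
    sizes = _family_sizes(params, n_members, rng)

    anc_codes: list[np.ndarray] = []
    anc_dist: list[float] = []
    for _f in range(params.n_families):
        length = int(rng.integers(params.length_min, params.length_max + 1))
        anc_codes.append(_sample_codes(model.freqs, length, rng))
        anc_dist.append(float(rng.uniform(params.pam_min, params.pam_max)))

    proteins: list[tuple[str, str, list[Domain]]] = []  # (id, residues, domains)
    for f in range(params.n_families):
        for m in range(int(sizes[f])):
            child = _evolve_codes(anc_codes[f], anc_dist[f] / 2.0, params, rng, model)
            sid = f"F{f:03d}_{m:02d}"
            proteins.append(
                (sid, _to_residues(child), [Domain(f, 0, len(anc_codes[f]), 0, len(child))])
            )
    for k in range(n_fusions):
        f1, f2 = rng.choice(params.n_families, size=2, replace=False)
        segs: list[np.ndarray] = []
        doms: list[Domain] = []
        offset = 0
        for f in (int(f1), int(f2)):
            anc = anc_codes[f]
            wlen = int(rng.integers(MIN_FUSION_SEGMENT, len(anc) + 1))
            start = int(rng.integers(0, len(anc) - wlen + 1))
            seg = _evolve_codes(anc[start : start + wlen], anc_dist[f] / 2.0, params, rng, model)
            segs.append(seg)
            doms.append(Domain(f, start, start + wlen, offset, offset + len(seg)))
            offset += len(seg)
        proteins.append((f"X{k:03d}", _to_residues(np.concatenate(segs)), doms))
    for k in range(n_singletons):
        length = int(rng.integers(params.length_min, params.length_max + 1))
        proteins.append((f"S{k:03d}", _to_residues(_sample_codes(model.freqs, length, rng)), []))

    order = rng.permutation(total)
    genomes: list[tuple[str, list[ProteinSequence]]] = []
    domains: dict[str, list[Domain]] = {}
    for g in range(params.n_genomes):
        gid = f"g{g + 1}"
        seqs = []
        for idx in order[g * params.proteins_per_genome : (g + 1) * params.proteins_per_genome]:
            sid, residues, doms = proteins[idx]
            seqs.append(ProteinSequence(sid, gid, residues))
            domains[sid] = doms
        genomes.append((gid, seqs))

    by_family: dict[int, list[str]] = {}
    for sid, _res, doms in proteins:
        for d in doms:
            by_family.setdefault(d.family, []).append(sid)
    pairs: set[tuple[str, str]] = set()
    for ids in by_family.values():
        uniq = sorted(set(ids))
        for i in range(len(uniq)):
            for j in range(i + 1, len(uniq)):
                pairs.add((uniq[i], uniq[j]))
    return GenomeSet(genomes), TruthSet(pairs, domains)
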