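"""PAM-family substitution matrices and the scoring scheme.

The substitution model is a time-reversible Markov chain over the 20
canonical amino acids, parameterised by PAM distance: one PAM is the amount
of divergence at which 1% of residues have undergone an accepted point
substitution. The default one-step model is a Dayhoff-style 1-PAM mutation
matrix recovered from the classic PAM250 log-odds table (shipped with
Biopython) anchored on the Dayhoff equilibrium frequencies: the symmetric
substitution flux J[a,b] = f_a f_b 10^(S250[a,b]/10) is normalized, its
conditional matrix is taken to the 250th root by eigendecomposition, and
the result is rescaled so that exactly 1% of residues mutate per step.

Log-odds scores at distance d are M[a,b] = 10*log10(P_d(b|a) / f_b),
i.e. the 10*log10 unit convention under which the classic significance
threshold of 135.75 applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np

from ._alphabet import AMBIGUOUS_INDEX, CANONICAL_AA
from .io_formats import ProteinSequence

# Dayhoff (1978) amino-acid equilibrium frequencies.
_DAYHOFF_FREQS = {
    "A": 0.087, "R": 0.041, "N": 0.040, "D": 0.047, "C": 0.033,
    "Q": 0.038, "E": 0.050, "G": 0.089, "H": 0.034, "I": 0.037,
    "L": 0.085, "K": 0.081, "M": 0.015, "F": 0.040, "P": 0.051,
    "S": 0.070, "T": 0.058, "W": 0.010, "Y": 0.030, "V": 0.065,
}


@dataclass
class OnePamModel:
    """Single-step (1 PAM) mutation probability model with its frequencies.

    probs[a, b] is the probability that residue a is observed as b after
    one PAM of divergence; rows sum to 1 and detailed balance holds with
    respect to ``freqs``.
    """

    probs: np.ndarray
    freqs: np.ndarray
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.probs.shape != (20, 20):
            raise ValueError("one-PAM model must be a 20x20 table")
        if np.any(self.probs < 0) or np.max(np.abs(self.probs.sum(axis=1) - 1.0)) > 1e-8:
            raise ValueError("one-PAM model rows must be probability distributions")
        if abs(self.freqs.sum() - 1.0) > 1e-8 or np.any(self.freqs <= 0):
            raise ValueError("frequencies must be positive and sum to 1")
        flux = self.freqs[:, None] * self.probs
        if np.max(np.abs(flux - flux.T)) > 1e-8:
            raise ValueError("one-PAM model violates detailed balance")

    def _eigendecomposition(self):
        if self._eig is None:
            d = np.sqrt(self.freqs)
            B = (d[:, None] * self.probs) / d[None, :]
            B = 0.5 * (B + B.T)
            w, V = np.linalg.eigh(B)
            self._eig = (np.clip(w, 1e-300, None), V, d)
        return self._eig

    def compose(self, distance: float) -> np.ndarray:
        """Transition probabilities after ``distance`` PAM units (d >= 0)."""
        if distance < 0:
            raise ValueError("PAM distance must be >= 0")
        if distance == 0:
            return np.eye(20)
        w, V, d = self._eigendecomposition()
        P = (V * w**distance) @ V.T
        P = P / d[:, None] * d[None, :]
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=1, keepdims=True)

    def expected_identity(self, distance: float) -> float:
        """Probability that a site is identical in two sequences separated
        by ``distance`` PAM (analytic; used as simulation oracle)."""
        return float(np.sum(self.freqs * np.diag(self.compose(distance))))


@lru_cache(maxsize=1)
def dayhoff_one_pam_model() -> OnePamModel:
    """Dayhoff-style 1-PAM model derived from the PAM250 log-odds table."""
    from Bio.Align import substitution_matrices

    pam250 = substitution_matrices.load("PAM250")
    idx = [pam250.alphabet.index(c) for c in CANONICAL_AA]
    S = np.array(pam250)[np.ix_(idx, idx)]
    f0 = np.array([_DAYHOFF_FREQS[c] for c in CANONICAL_AA])
    f0 = f0 / f0.sum()
    J = np.outer(f0, f0) * 10.0 ** (S / 10.0)
    J = 0.5 * (J + J.T)
    J /= J.sum()
    f = J.sum(axis=1)
    P250 = J / f[:, None]
    d = np.sqrt(f)
    B = (d[:, None] * P250) / d[None, :]
    B = 0.5 * (B + B.T)
    w, V = np.linalg.eigh(B)
    P1 = (V * np.clip(w, 1e-12, None) ** (1.0 / 250.0)) @ V.T
    P1 = P1 / d[:, None] * d[None, :]
    P1 = np.clip(P1, 0.0, None)
    # restore reversibility and row-stochasticity after clipping
    for _ in range(60):
        flux = f[:, None] * P1
        flux = 0.5 * (flux + flux.T)
        P1 = flux / f[:, None]
        P1 /= P1.sum(axis=1, keepdims=True)
    mutability = 1.0 - float(np.sum(f * np.diag(P1)))
    P1 = np.eye(20) + (0.01 / mutability) * (P1 - np.eye(20))
    return OnePamModel(P1, f)


@dataclass
class SubstitutionMatrix:
    """20x20 symmetric log-odds scores (10*log10 units) at a PAM distance."""

    pam_distance: float
    scores: np.ndarray
    background_freqs: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.background_freqs = np.asarray(self.background_freqs, dtype=float)
        if self.scores.shape != (20, 20):
            raise ValueError("scores must be 20x20")
        if np.max(np.abs(self.scores - self.scores.T)) > 1e-9:
            raise ValueError("substitution matrix must be symmetric")
        if not np.any(np.diag(self.scores) > 0):
            raise ValueError("matrix must have at least one positive diagonal entry")
        if self.expected_background_score() >= 0:
            raise ValueError("expected background score must be negative")

    def expected_background_score(self) -> float:
        f = self.background_freqs
        return float(np.sum(np.outer(f, f) * self.scores))

    def score(self, a: str, b: str) -> float:
        return float(self.scores[CANONICAL_AA.index(a), CANONICAL_AA.index(b)])


def build_pam_matrix(
    pam_distance: float, one_pam_model: OnePamModel | None = None
) -> SubstitutionMatrix:
    """Compose the one-step model to ``pam_distance`` and take log-odds.

    M[a,b] = 10*log10(P_d(b|a) / f_b), symmetrized by averaging (the model
    is reversible so the asymmetry is numerical only).
    """
    if pam_distance <= 0:
        raise ValueError("pam_distance must be > 0")
    model = one_pam_model or dayhoff_one_pam_model()
    Pd = model.compose(float(pam_distance))
    M = 10.0 * np.log10(np.maximum(Pd / model.freqs[None, :], 1e-300))
    M = 0.5 * (M + M.T)
    return SubstitutionMatrix(float(pam_distance), M, model.freqs.copy())


def self_score(seq: ProteinSequence, matrix: SubstitutionMatrix) -> float:
    """Sum of diagonal scores over the sequence's residues.

    Only defined for fully canonical sequences (ambiguous residues carry no
    diagonal entry in the 20x20 matrix).
    """
    codes = seq.codes
    if np.any(codes == AMBIGUOUS_INDEX):
        raise ValueError("self_score is undefined for ambiguous residues")
    return float(np.diag(matrix.scores)[codes.astype(int)].sum())


@dataclass
class ScoringScheme:
    """Substitution matrix, affine gap model and all pipeline thresholds.

    Scores are in matrix (10*log10) units. A gap of length k costs
    gap_open + (k - 1) * gap_extend. The defaults are the classic
    all-against-all criteria: score >= 135.75 with the PAM-224 matrix and
    shorter-sequence aligned length >= 61% of the longer sequence; the
    coverage tolerance of 20 residues and the >50-residue length filter
    belong to the clustering stage and input reading respectively.
    """

    matrix: SubstitutionMatrix
    gap_open: float = 20.0
    gap_extend: float = 1.0
    min_score: float = 135.75
    length_fraction: float = 0.61
    coverage_tolerance: int = 20
    min_seq_length: int = 50
    ambiguous_score: float = -5.0
    _kernel_matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.min_score <= 0:
            raise ValueError("min_score must be > 0")
        if not (0 < self.length_fraction <= 1):
            raise ValueError("length_fraction must be in (0, 1]")
        if self.coverage_tolerance < 0:
            raise ValueError("coverage_tolerance must be >= 0")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")

    @classmethod
    def default(cls, pam_distance: float = 224.0, **kwargs) -> "ScoringScheme":
        return cls(matrix=build_pam_matrix(pam_distance), **kwargs)

    @property
    def kernel_matrix(self) -> np.ndarray:
        """21x21 score table: canonical indices 0-19 plus the ambiguous
        index, whose row/column carry the flat ambiguous score."""
        if self._kernel_matrix is None:
            K = np.full((21, 21), self.ambiguous_score, dtype=np.float64)
            K[:20, :20] = self.matrix.scores
            self._kernel_matrix = K
        return self._kernel_matrix


def write_matrix_file(matrix: SubstitutionMatrix, path: str | Path) -> None:
    """Write the 20x20 score table with one-letter row/column labels."""
    with open(path, "w") as fh:
        fh.write("   " + " ".join(f"{c:>8s}" for c in CANONICAL_AA) + "\n")
        for i, c in enumerate(CANONICAL_AA):
            fh.write(c + "  " + " ".join(f"{v:8.3f}" for v in matrix.scores[i]) + "\n")


def read_matrix_file(
    path: str | Path,
    pam_distance: float = 224.0,
    background_freqs: np.ndarray | None = None,
) -> SubstitutionMatrix:
    """Read a labelled whitespace-delimited 20x20 score table.

    Frequencies are not part of the file format; the Dayhoff-anchored
    frequencies are assumed unless given.
    """
    with open(path) as fh:
        header = fh.readline().split()
        rows = {}
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            rows[parts[0]] = [float(x) for x in parts[1:]]
    if sorted(header) != sorted(CANONICAL_AA) or sorted(rows) != sorted(CANONICAL_AA):
        raise ValueError("matrix file must be labelled with the 20 canonical residues")
    order = [header.index(c) for c in CANONICAL_AA]
    M = np.array([[rows[c][j] for j in order] for c in CANONICAL_AA])
    freqs = (
        background_freqs
        if background_freqs is not None
        else dayhoff_one_pam_model().freqs.copy()
    )
    return SubstitutionMatrix(pam_distance, M, freqs)
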