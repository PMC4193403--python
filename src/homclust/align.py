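"""Smith-Waterman local alignment with affine gaps, plus the pair criteria.

``smith_waterman`` is the production path (numba kernels); ``sw_score`` is
its score-only fast path used by the pair engines. ``naive_smith_waterman``
is a deliberately simple pure-Python dynamic program with the same
recurrence and tie-breaking, kept as an independent correctness oracle.

Intervals are 0-based half-open and count the residues each sequence
contributes to the alignment (gaps consume residues of one sequence only),
so interval length equals aligned length on each side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernel import sw_score_kernel, sw_traceback_kernel
from .io_formats import ProteinSequence
from .scoring import ScoringScheme

_NEG = -1e30


@dataclass(frozen=True)
class LocalAlignment:
    score: float
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("local alignment score cannot be negative")
        if self.score == 0 and (
            self.query_interval != (0, 0) or self.subject_interval != (0, 0)
        ):
            raise ValueError("zero-score alignment must have empty intervals")

    @property
    def query_aligned_length(self) -> int:
        return self.query_interval[1] - self.query_interval[0]

    @property
    def subject_aligned_length(self) -> int:
        return self.subject_interval[1] - self.subject_interval[0]


def _codes(seq) -> np.ndarray:
    if isinstance(seq, ProteinSequence):
        return seq.codes
    if isinstance(seq, str):
        from ._alphabet import encode, sanitize

        return encode(sanitize(seq))
    return np.asarray(seq, dtype=np.int8)


def sw_score(a, b, scheme: ScoringScheme) -> float:
    """Best local alignment score only (fast path)."""
    return float(
        sw_score_kernel(
            _codes(a), _codes(b), scheme.kernel_matrix, scheme.gap_open, scheme.gap_extend
        )
    )


def smith_waterman(a, b, scheme: ScoringScheme) -> LocalAlignment:
    """Maximal-scoring local alignment of a (query) and b (subject)."""
    ca, cb = _codes(a), _codes(b)
    if ca.shape[0] == 0 or cb.shape[0] == 0:
        raise ValueError("cannot align empty sequences")
    score, qs, qe, ss, se = sw_traceback_kernel(
        ca, cb, scheme.kernel_matrix, scheme.gap_open, scheme.gap_extend
    )
    return LocalAlignment(float(score), (int(qs), int(qe)), (int(ss), int(se)))


def naive_smith_waterman(a, b, scheme: ScoringScheme) -> LocalAlignment:
    """Textbook three-table affine-gap local alignment with full traceback.

    Independent of the numba kernels; no performance requirements.
    """
    ca, cb = _codes(a), _codes(b)
    m, n = len(ca), len(cb)
    if m == 0 or n == 0:
        raise ValueError("cannot align empty sequences")
    S = scheme.kernel_matrix
    go, ge = scheme.gap_open, scheme.gap_extend
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[_NEG] * (n + 1) for _ in range(m + 1)]
    F = [[_NEG] * (n + 1) for _ in range(m + 1)]
    PH = [[0] * (n + 1) for _ in range(m + 1)]
    PE = [[0] * (n + 1) for _ in range(m + 1)]
    PF = [[0] * (n + 1) for _ in range(m + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            eo, ee = H[i][j - 1] - go, E[i][j - 1] - ge
            E[i][j], PE[i][j] = (eo, 1) if eo >= ee else (ee, 0)
            fo, fe = H[i - 1][j] - go, F[i - 1][j] - ge
            F[i][j], PF[i][j] = (fo, 1) if fo >= fe else (fe, 0)
            h = H[i - 1][j - 1] + S[ca[i - 1], cb[j - 1]]
            p = 1
            if F[i][j] > h:
                h, p = F[i][j], 2
            if E[i][j] > h:
                h, p = E[i][j], 3
            if h <= 0.0:
                h, p = 0.0, 0
            H[i][j], PH[i][j] = h, p
            if h > best:
                best, bi, bj = h, i, j
    if best == 0.0:
        return LocalAlignment(0.0, (0, 0), (0, 0))
    i, j, state = bi, bj, 0
    while True:
        if state == 0:
            p = PH[i][j]
            if p == 0:
                break
            if p == 1:
                i, j = i - 1, j - 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:
            p = PF[i][j]
            i -= 1
            state = 0 if p == 1 else 2
        else:
            p = PE[i][j]
            j -= 1
            state = 0 if p == 1 else 3
    return LocalAlignment(float(best), (i, bi), (j, bj))


def is_significant(aln, scheme: ScoringScheme) -> bool:
    """Score criterion: alignment score >= min_score (inclusive)."""
    score = aln.score if isinstance(aln, LocalAlignment) else float(aln)
    return score >= scheme.min_score


def passes_length_criterion(
    aln: LocalAlignment, len_a: int, len_b: int, scheme: ScoringScheme
) -> bool:
    """Length criterion: the aligned length of the shorter sequence must be
    at least length_fraction of the longer sequence's length (inclusive).

    For equal-length sequences the smaller of the two aligned lengths is
    used (conservative reading).
    """
    longer = max(len_a, len_b)
    if len_a < len_b:
        shorter_aligned = aln.query_aligned_length
    elif len_b < len_a:
        shorter_aligned = aln.subject_aligned_length
    else:
        shorter_aligned = min(aln.query_aligned_length, aln.subject_aligned_length)
    return shorter_aligned >= scheme.length_fraction * longer
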