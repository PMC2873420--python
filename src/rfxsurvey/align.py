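"""Pairwise protein alignment with affine gaps, corrected PID, and shuffle-null significance.

The engine implements Smith-Waterman local and Needleman-Wunsch global
alignment over integer substitution scores with affine gap penalties
(a gap of length ``g`` costs ``gap_open + g * gap_extend``).  Scores are
exact integers; tie-breaking is deterministic so repeated runs are
byte-identical.

The survey statistic built on top of the aligner is the *corrected percent
identity*: identical aligned positions divided by the full ungapped query
length, times 100.  Gapped or unaligned query positions therefore count
against the score, which is what makes the PID "corrected".

Statistical significance of a local score is estimated by a
composition-preserving shuffle test of the target sequence, replacing
analytic e-value statistics with a distribution-free, seedable null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .exceptions import InputError, ParameterError

#: 20 standard residues followed by the ambiguity symbol 'X'.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"
_X_INDEX = 20

# Robinson-Robinson background frequencies, the standard protein-search null.
BACKGROUND_FREQS = np.array(
    [
        0.07805, 0.01925, 0.05364, 0.06295, 0.03856,
        0.07377, 0.02199, 0.05142, 0.05744, 0.09019,
        0.02243, 0.04487, 0.05203, 0.04264, 0.05129,
        0.07120, 0.05841, 0.06441, 0.01330, 0.03216,
    ]
)
BACKGROUND_FREQS = BACKGROUND_FREQS / BACKGROUND_FREQS.sum()

_ENCODE_LUT = np.full(256, -1, dtype=np.int8)
for _i, _aa in enumerate(ALPHABET):
    _ENCODE_LUT[ord(_aa)] = _i


def encode(sequence: str) -> np.ndarray:
    """Encode a peptide as residue indices; 'X' is allowed, anything else is an error."""
    if not sequence:
        raise InputError("empty sequence")
    raw = np.frombuffer(sequence.encode("ascii", errors="replace"), dtype=np.uint8)
    idx = _ENCODE_LUT[raw]
    if (idx < 0).any():
        bad = sequence[int(np.argmax(idx < 0))]
        raise InputError(f"unknown residue {bad!r} in sequence")
    return idx.astype(np.int8)


@dataclass(frozen=True)
class SubstitutionScheme:
    """Integer substitution scores plus affine gap penalties and a background.

    ``matrix`` is indexed by :data:`ALPHABET` order (21x21; the final row and
    column are the 'X' symbol, which scores 0 against everything).  A gap of
    length ``g`` costs ``gap_open + g * gap_extend``.
    """

    matrix: np.ndarray
    gap_open: int
    gap_extend: int
    background: np.ndarray = field(default_factory=lambda: BACKGROUND_FREQS.copy())

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.int32)
        if m.shape != (21, 21):
            raise ParameterError("substitution matrix must be 21x21 (20 residues + X)")
        if not np.array_equal(m, m.T):
            raise ParameterError("substitution matrix must be symmetric")
        if not (self.gap_open >= self.gap_extend >= 1):
            raise ParameterError("require gap_open >= gap_extend >= 1")
        object.__setattr__(self, "matrix", m)
        b = np.asarray(self.background, dtype=float)
        if b.shape != (20,) or (b <= 0).any():
            raise ParameterError("background must be 20 positive frequencies")
        object.__setattr__(self, "background", b / b.sum())


def default_scheme(gap_open: int = 11, gap_extend: int = 1) -> SubstitutionScheme:
    """BLOSUM62 with the classic protein-search gap penalties 11/1."""
    blosum = substitution_matrices.load("BLOSUM62")
    m = np.zeros((21, 21), dtype=np.int32)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            m[i, j] = int(blosum[a, b])
    # 'X' scores 0 against everything (conservative; never counts as identical).
    return SubstitutionScheme(matrix=m, gap_open=gap_open, gap_extend=gap_extend)


def read_ncbi_matrix(path, gap_open: int = 11, gap_extend: int = 1) -> SubstitutionScheme:
    """Load a scheme from a matrix file in NCBI text format."""
    mat = substitution_matrices.read(str(path))
    m = np.zeros((21, 21), dtype=np.int32)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            m[i, j] = int(mat[a, b])
    return SubstitutionScheme(matrix=m, gap_open=gap_open, gap_extend=gap_extend)


@dataclass(frozen=True)
class LocalAlignment:
    """One pairwise alignment: gapped strings, 0-based half-open intervals, score."""

    query_interval: tuple[int, int]
    target_interval: tuple[int, int]
    aligned_query: str
    aligned_target: str
    score: int
    identities: int

    def __post_init__(self):
        dq = self.aligned_query.replace("-", "")
        dt = self.aligned_target.replace("-", "")
        if len(dq) != self.query_interval[1] - self.query_interval[0]:
            raise ParameterError("aligned_query inconsistent with query_interval")
        if len(dt) != self.target_interval[1] - self.target_interval[0]:
            raise ParameterError("aligned_target inconsistent with target_interval")


@dataclass(frozen=True)
class SignificanceEstimate:
    """Empirical p-value from a composition-preserving shuffle null."""

    p_value: float
    n_shuffles: int


_NEG_INF = np.int32(-(2**30))


@njit(nogil=True)
def _local_dp_score(q, t, sub, gap_first, gap_ext):  # pragma: no cover - jitted
    n = q.shape[0]
    m = t.shape[0]
    h_prev = np.zeros(m + 1, dtype=np.int32)
    e_prev = np.full(m + 1, _NEG_INF, dtype=np.int32)
    best = np.int32(0)
    for i in range(1, n + 1):
        h_cur = np.zeros(m + 1, dtype=np.int32)
        e_cur = np.empty(m + 1, dtype=np.int32)
        e_cur[0] = _NEG_INF
        f = _NEG_INF
        qi = q[i - 1]
        for j in range(1, m + 1):
            e = max(h_prev[j] - gap_first, e_prev[j] - gap_ext)
            f = max(h_cur[j - 1] - gap_first, f - gap_ext)
            h = h_prev[j - 1] + sub[qi, t[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            h_cur[j] = h
            e_cur[j] = e
            if h > best:
                best = h
        h_prev = h_cur
        e_prev = e_cur
    return best


@njit(nogil=True)
def _local_dp_matrices(q, t, sub, gap_first, gap_ext):  # pragma: no cover - jitted
    n = q.shape[0]
    m = t.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), _NEG_INF, dtype=np.int32)
    F = np.full((n + 1, m + 1), _NEG_INF, dtype=np.int32)
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e = max(H[i - 1, j] - gap_first, E[i - 1, j] - gap_ext)
            f = max(H[i, j - 1] - gap_first, F[i, j - 1] - gap_ext)
            h = H[i - 1, j - 1] + sub[qi, t[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
    return H, E, F


@njit(nogil=True)
def _global_dp_matrices(q, t, sub, gap_first, gap_ext):  # pragma: no cover - jitted
    n = q.shape[0]
    m = t.shape[0]
    H = np.full((n + 1, m + 1), _NEG_INF, dtype=np.int32)
    E = np.full((n + 1, m + 1), _NEG_INF, dtype=np.int32)
    F = np.full((n + 1, m + 1), _NEG_INF, dtype=np.int32)
    H[0, 0] = 0
    for i in range(1, n + 1):
        E[i, 0] = -(gap_first + (i - 1) * gap_ext)
        H[i, 0] = E[i, 0]
    for j in range(1, m + 1):
        F[0, j] = -(gap_first + (j - 1) * gap_ext)
        H[0, j] = F[0, j]
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e = max(H[i - 1, j] - gap_first, E[i - 1, j] - gap_ext)
            f = max(H[i, j - 1] - gap_first, F[i, j - 1] - gap_ext)
            h = H[i - 1, j - 1] + sub[qi, t[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
    return H, E, F


def _traceback(q: str, t: str, H, E, F, i: int, j: int, gap_first: int,
               gap_ext: int, sub: np.ndarray, qidx, tidx, *, local: bool):
    """Deterministic traceback from cell (i, j).

    Move preference at equal score: diagonal first (fewest gaps), then gap in
    the target (consume query), then gap in the query.
    """
    aq, at = [], []
    state = "H"
    while i > 0 or j > 0:
        if local and state == "H" and H[i, j] == 0:
            break
        if state == "H":
            if not local and (i == 0 or j == 0):
                state = "E" if j == 0 else "F"
                continue
            s = sub[qidx[i - 1], tidx[j - 1]]
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + s:
                aq.append(q[i - 1])
                at.append(t[j - 1])
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            elif H[i, j] == F[i, j]:
                state = "F"
            else:  # pragma: no cover - DP recurrence guarantees a predecessor
                raise AssertionError("traceback: no predecessor")
        elif state == "E":
            aq.append(q[i - 1])
            at.append("-")
            if E[i, j] == H[i - 1, j] - gap_first:
                state = "H"
            i -= 1
        else:  # state == "F"
            aq.append("-")
            at.append(t[j - 1])
            if F[i, j] == H[i, j - 1] - gap_first:
                state = "H"
            j -= 1
        if local and state == "H" and H[i, j] == 0:
            break
    return i, j, "".join(reversed(aq)), "".join(reversed(at))


def _count_identities(aq: str, at: str) -> int:
    # 'X' never counts as identical even against itself.
    return sum(1 for a, b in zip(aq, at) if a == b and a != "-" and a != "X")


def local_align(query: str, target: str, scheme: SubstitutionScheme) -> LocalAlignment:
    """Maximum-scoring Smith-Waterman local alignment under affine gaps.

    Ties are broken deterministically: the end cell is the maximum-scoring
    cell with the smallest query coordinate, then target coordinate; the
    traceback prefers diagonal moves, then gaps in the target.  Returns a
    score-0 empty alignment when no positive-scoring alignment exists.
    """
    qidx = encode(query)
    tidx = encode(target)
    gap_first = scheme.gap_open + scheme.gap_extend
    H, E, F = _local_dp_matrices(qidx, tidx, scheme.matrix, np.int32(gap_first),
                                 np.int32(scheme.gap_extend))
    best = int(H.max())
    if best == 0:
        return LocalAlignment((0, 0), (0, 0), "", "", 0, 0)
    i, j = np.unravel_index(int(np.argmax(H)), H.shape)  # row-major: smallest (i, j)
    qs, ts, aq, at = _traceback(query, target, H, E, F, int(i), int(j), gap_first,
                                scheme.gap_extend, scheme.matrix, qidx, tidx, local=True)
    return LocalAlignment((qs, int(i)), (ts, int(j)), aq, at, best,
                          _count_identities(aq, at))


def global_align(a: str, b: str, scheme: SubstitutionScheme) -> LocalAlignment:
    """End-to-end Needleman-Wunsch alignment with affine gaps.

    The result spans both sequences entirely; the score may be negative.
    """
    qidx = encode(a)
    tidx = encode(b)
    gap_first = scheme.gap_open + scheme.gap_extend
    H, E, F = _global_dp_matrices(qidx, tidx, scheme.matrix, np.int32(gap_first),
                                  np.int32(scheme.gap_extend))
    n, m = len(a), len(b)
    qs, ts, aq, at = _traceback(a, b, H, E, F, n, m, gap_first,
                                scheme.gap_extend, scheme.matrix, qidx, tidx, local=False)
    assert qs == 0 and ts == 0
    return LocalAlignment((0, n), (0, m), aq, at, int(H[n, m]),
                          _count_identities(aq, at))


def local_score(query: str, target: str, scheme: SubstitutionScheme) -> int:
    """Score-only Smith-Waterman (linear memory); used for bulk scans."""
    return int(
        _local_dp_score(encode(query), encode(target), scheme.matrix,
                        np.int32(scheme.gap_open + scheme.gap_extend),
                        np.int32(scheme.gap_extend))
    )


def corrected_pid(aln: LocalAlignment, query_length: int) -> float:
    """Corrected percent identity: 100 x identities / full query length.

    Dividing by the whole query length (not the aligned length) penalises
    partial-domain matches, which is the acceptance statistic of the survey.
    """
    if query_length <= 0:
        raise ParameterError("query_length must be positive")
    span = aln.query_interval[1] - aln.query_interval[0]
    if query_length < span:
        raise ParameterError("query_length smaller than the aligned query span")
    return 100.0 * aln.identities / query_length


def empirical_significance(score: int, query: str, target: str,
                           scheme: SubstitutionScheme, n_shuffles: int = 199,
                           rng_seed: int = 0) -> SignificanceEstimate:
    """Shuffle-null p-value for a local alignment score.

    The target is permuted (composition preserved) ``n_shuffles`` times and
    the best local score recomputed each time; the plus-one estimator
    ``p = (1 + #{null >= score}) / (n_shuffles + 1)`` keeps p in
    ``[1/(n+1), 1]``.
    """
    if n_shuffles < 99:
        raise ParameterError("n_shuffles must be at least 99")
    qidx = encode(query)
    tidx = encode(target)
    gap_first = np.int32(scheme.gap_open + scheme.gap_extend)
    gap_ext = np.int32(scheme.gap_extend)
    rng = np.random.default_rng(rng_seed)
    exceed = 0
    for _ in range(n_shuffles):
        perm = rng.permutation(tidx)
        null = _local_dp_score(qidx, perm, scheme.matrix, gap_first, gap_ext)
        if null >= score:
            exceed += 1
    return SignificanceEstimate(p_value=(1 + exceed) / (n_shuffles + 1),
                                n_shuffles=n_shuffles)
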