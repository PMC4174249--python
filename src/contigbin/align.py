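"""Global pairwise alignment percent identity.

Needleman–Wunsch with linear gap penalties and a fixed traceback
tie-break (prefer diagonal, then up, then left), so a given sequence
pair and scoring always yield the same alignment and hence the same
identity figure.  Percent identity is 100 x identical columns /
alignment columns of the optimal global alignment.

Nucleotide scoring defaults to match +1 / mismatch -1 / gap -2; protein
mode scores with a named substitution matrix (BLOSUM62 by default) and
a linear gap penalty.
"""

from __future__ import annotations

from typing import Mapping

from Bio.Align import substitution_matrices

__all__ = [
    "global_percent_identity",
    "global_alignment_score",
    "NT_SCORING",
    "AlphabetError",
]

NT_SCORING: dict[str, float] = {"match": 1.0, "mismatch": -1.0, "gap": -2.0}

_NT_CHARS = set("ACGTUN")


class AlphabetError(ValueError):
    """The two sequences are not drawn from the same alphabet."""


def _looks_nucleotide(seq: str) -> bool:
    return set(seq.upper()) <= _NT_CHARS


def _check_alphabets(seq_a: str, seq_b: str) -> bool:
    """Return True for a nucleotide pair; raise on a mixed pair."""
    a_nt, b_nt = _looks_nucleotide(seq_a), _looks_nucleotide(seq_b)
    if a_nt != b_nt:
        raise AlphabetError(
            "sequences use different alphabets (one nucleotide, one protein)"
        )
    return a_nt


def _substitution(scoring: Mapping[str, float] | None, matrix):
    if matrix is not None:
        def score(x: str, y: str) -> float:
            return float(matrix[x, y])

        return score
    s = dict(NT_SCORING)
    if scoring:
        s.update(scoring)

    def score(x: str, y: str) -> float:
        return s["match"] if x == y else s["mismatch"]

    return score


def _resolve_scoring(seq_a, seq_b, scoring, matrix_name):
    """Shared setup: alphabet check, substitution function, gap penalty."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    is_nt = _check_alphabets(seq_a, seq_b)
    matrix = None
    if matrix_name is not None:
        matrix = substitution_matrices.load(matrix_name)
        gap = float(scoring["gap"]) if scoring and "gap" in scoring else -8.0
    else:
        s = dict(NT_SCORING)
        if scoring:
            s.update(scoring)
        gap = s["gap"]
    if matrix is None and not is_nt and scoring is None:
        # Protein pair without explicit parameters: use BLOSUM62.
        matrix = substitution_matrices.load("BLOSUM62")
        gap = -8.0
    return _substitution(scoring, matrix), gap


def _dp_matrix(a: str, b: str, sub, gap: float) -> list[list[float]]:
    """F[i][j] = best score aligning a[:i] with b[:j]."""
    n, m = len(a), len(b)
    F = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        F[i][0] = i * gap
    for j in range(1, m + 1):
        F[0][j] = j * gap
    for i in range(1, n + 1):
        row, prev = F[i], F[i - 1]
        ai = a[i - 1]
        for j in range(1, m + 1):
            row[j] = max(
                prev[j - 1] + sub(ai, b[j - 1]),
                prev[j] + gap,
                row[j - 1] + gap,
            )
    return F


def global_alignment_score(
    seq_a: str,
    seq_b: str,
    scoring: Mapping[str, float] | None = None,
    matrix_name: str | None = None,
) -> float:
    """Optimal global alignment score under the same scoring scheme."""
    sub, gap = _resolve_scoring(seq_a, seq_b, scoring, matrix_name)
    a, b = seq_a.upper(), seq_b.upper()
    return _dp_matrix(a, b, sub, gap)[len(a)][len(b)]


def global_percent_identity(
    seq_a: str,
    seq_b: str,
    scoring: Mapping[str, float] | None = None,
    matrix_name: str | None = None,
) -> float:
    """Percent identity of the optimal global alignment of two sequences.

    ``scoring`` overrides any of ``match``, ``mismatch``, ``gap`` for
    nucleotide (or generic) scoring; ``matrix_name`` selects a Biopython
    substitution matrix (e.g. ``"BLOSUM62"``) for protein mode, with the
    ``gap`` penalty still taken from ``scoring`` (default -8 in matrix
    mode).  Case-insensitive; deterministic via diagonal > up > left
    traceback preference.
    """
    sub, gap = _resolve_scoring(seq_a, seq_b, scoring, matrix_name)
    a, b = seq_a.upper(), seq_b.upper()
    n, m = len(a), len(b)
    F = _dp_matrix(a, b, sub, gap)

    # Traceback with fixed preference: diagonal, then up (gap in b),
    # then left (gap in a).
    i, j = n, m
    ident = 0
    columns = 0
    while i > 0 or j > 0:
        here = F[i][j]
        if i > 0 and j > 0 and here == F[i - 1][j - 1] + sub(a[i - 1], b[j - 1]):
            if a[i - 1] == b[j - 1]:
                ident += 1
            i, j = i - 1, j - 1
        elif i > 0 and here == F[i - 1][j] + gap:
            i -= 1
        else:
            j -= 1
        columns += 1
    return 100.0 * ident / columns
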