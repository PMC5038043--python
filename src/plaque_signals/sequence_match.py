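"""Percent-identity phylotype selection.

Representative sequences are compared to a reference set by global
(Needleman-Wunsch) alignment with match +1, mismatch -1, linear gap -2;
identity is matches / alignment columns (gap columns in the
denominator, configurable to matched-columns-only).  A query is
selected when its best identity against any reference strictly exceeds
the threshold (default 98.5%, the species-level cutoff used to define
oral taxa in the reference database).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .io_core import SequenceSet, ValidationError

__all__ = ["IdentityHit", "global_identity", "select_by_identity"]

MATCH = 1
MISMATCH = -1
GAP = -2

_VALID = set("ACGTN")


@dataclass
class IdentityHit:
    query_id: str
    reference_id: str
    identity: float  # percent
    aligned_columns: int
    score: int


def _check(seq: str, name: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValidationError(f"{name} is empty")
    bad = set(seq) - _VALID
    if bad:
        raise ValidationError(f"{name} contains invalid characters {sorted(bad)}")
    return seq


@njit(cache=True)
def _nw_kernel(a_arr: np.ndarray, b_arr: np.ndarray) -> tuple[int, int, int]:  # pragma: no cover
    n, m = a_arr.size, b_arr.size
    n_code = 78  # ord('N'); N matches nothing, even against N
    neg = -(1 << 30)
    score = np.empty((n + 1, m + 1), dtype=np.int32)
    matches = np.empty((n + 1, m + 1), dtype=np.int32)
    columns = np.empty((n + 1, m + 1), dtype=np.int32)
    for j in range(m + 1):
        score[0, j] = GAP * j
        matches[0, j] = 0
        columns[0, j] = j
    for i in range(1, n + 1):
        score[i, 0] = GAP * i
        matches[i, 0] = 0
        columns[i, 0] = i
        ai = a_arr[i - 1]
        for j in range(1, m + 1):
            bj = b_arr[j - 1]
            is_match = 1 if (ai == bj and ai != n_code and bj != n_code) else 0
            sub = MATCH if is_match else MISMATCH
            s_diag = score[i - 1, j - 1] + sub
            s_up = score[i - 1, j] + GAP
            s_left = score[i, j - 1] + GAP
            best = max(s_diag, s_up, s_left)
            score[i, j] = best
            # among optimal moves: maximize matches, then minimize columns
            best_m = neg
            best_c = 1 << 30
            if s_diag == best:
                cand_m = matches[i - 1, j - 1] + is_match
                cand_c = columns[i - 1, j - 1] + 1
                if cand_m > best_m or (cand_m == best_m and cand_c < best_c):
                    best_m, best_c = cand_m, cand_c
            if s_up == best:
                cand_m = matches[i - 1, j]
                cand_c = columns[i - 1, j] + 1
                if cand_m > best_m or (cand_m == best_m and cand_c < best_c):
                    best_m, best_c = cand_m, cand_c
            if s_left == best:
                cand_m = matches[i, j - 1]
                cand_c = columns[i, j - 1] + 1
                if cand_m > best_m or (cand_m == best_m and cand_c < best_c):
                    best_m, best_c = cand_m, cand_c
            matches[i, j] = best_m
            columns[i, j] = best_c
    return score[n, m], matches[n, m], columns[n, m]


def _nw_align(a: str, b: str) -> tuple[int, int, int]:
    """Global alignment; returns (score, matches, alignment columns).

    Among all optimal-score alignments the one maximizing matches and
    then minimizing columns is summarized, which makes the reported
    identity well defined and symmetric in (a, b).  N matches nothing
    (scored as a mismatch even against N).
    """
    a_arr = np.frombuffer(a.encode(), dtype=np.uint8)
    b_arr = np.frombuffer(b.encode(), dtype=np.uint8)
    score, matches, columns = _nw_kernel(a_arr, b_arr)
    return int(score), int(matches), int(columns)


def global_identity(
    a: str, b: str, query_id: str = "query", reference_id: str = "reference",
    denominator: str = "alignment",
) -> IdentityHit:
    """Global percent identity between two DNA sequences.

    ``denominator`` is "alignment" (gap columns counted, the default)
    or "matched" (columns where both sequences have a residue).
    """
    a = _check(a, "sequence a")
    b = _check(b, "sequence b")
    score, matches, columns = _nw_align(a, b)
    if denominator == "alignment":
        denom = columns
    elif denominator == "matched":
        gaps = 2 * columns - len(a) - len(b)  # each gap column skips one residue
        denom = columns - gaps
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    identity = 100.0 * matches / denom if denom else 0.0
    return IdentityHit(query_id, reference_id, identity, columns, score)


def select_by_identity(
    queries: SequenceSet,
    references: SequenceSet,
    threshold: float = 98.5,
    denominator: str = "alignment",
) -> tuple[list[str], dict[str, IdentityHit]]:
    """Select queries whose best reference identity strictly exceeds the
    threshold; the best hit per query is reported (ties broken by
    reference id)."""
    if len(queries) == 0 or len(references) == 0:
        raise ValidationError("both sequence sets must be non-empty")
    selected: list[str] = []
    best_hits: dict[str, IdentityHit] = {}
    for qid, qseq in queries:
        best: IdentityHit | None = None
        for rid, rseq in sorted(zip(references.record_ids, references.sequences)):
            hit = global_identity(qseq, rseq, qid, rid, denominator=denominator)
            if best is None or hit.identity > best.identity:
                best = hit
        assert best is not None
        best_hits[qid] = best
        if best.identity > threshold:
            selected.append(qid)
    return selected, best_hits
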