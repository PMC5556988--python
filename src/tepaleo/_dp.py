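"""Affine-gap pairwise alignment engine (three-state dynamic programming).

A gap of length L costs ``gap_open + gap_extend * L`` (blastn convention:
with the defaults 5/2 a single-base gap costs 7).  Rows are filled with
vectorised numpy operations; the within-row dependency of the horizontal
gap state is resolved exactly with a max-plus prefix scan, so the recurrence
is identical to the textbook three-matrix (Gotoh) formulation.

Modes
-----
global      Needleman–Wunsch with affine gaps; terminal gaps are penalised.
semiglobal  Terminal gaps in either sequence are free (overlap alignment).
local       Smith–Waterman; used by the homology-search extension stage,
            optionally with drop-off (X-drop style) row termination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NEG = -(2**29)  # effectively -infinity; safe against int32 overflow

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 codes (A,C,G,T -> 0..3; anything else 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class Alignment:
    """A gapped pairwise alignment: two equal-length rows plus the score."""

    aligned_a: str
    aligned_b: str
    score: int

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)

    @property
    def n_identical(self) -> int:
        return sum(
            x == y and x != "-" for x, y in zip(self.aligned_a, self.aligned_b)
        )


def _fill(
    a: np.ndarray,
    b: np.ndarray,
    match: int,
    mismatch: int,
    gap_open: int,
    gap_extend: int,
    mode: str,
    x_drop: int | None = None,
):
    """Fill H, E, F matrices.  E = gap in a (consumes b), F = gap in b.

    Returns (H, E, F, last_row_filled).  In local mode with ``x_drop`` set,
    filling stops once a row's maximum falls more than ``x_drop`` below the
    best score seen; remaining rows stay at NEG.
    """
    n, m = len(a), len(b)
    H = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    js = np.arange(m + 1, dtype=np.int32)

    if mode == "global":
        H[0] = -(gap_open + gap_extend * js)
        H[0, 0] = 0
        E[0, 1:] = H[0, 1:]
    else:
        H[0] = 0

    local = mode == "local"
    best = 0
    last_row = n
    bvalid = b < 4
    for i in range(1, n + 1):
        if mode == "global":
            h0 = -(gap_open + gap_extend * i)
        else:
            h0 = 0
        srow = np.where((b == a[i - 1]) & bvalid, match, mismatch).astype(np.int32)

        F[i] = np.maximum(F[i - 1] - gap_extend, H[i - 1] - gap_open - gap_extend)
        cand = np.maximum(H[i - 1, :-1] + srow, F[i, 1:])
        if local:
            cand = np.maximum(cand, 0)

        # Horizontal-gap scan: E[j] = max_{k<j} (c[k] - open - ext*(j-k))
        t = np.empty(m + 1, dtype=np.int64)
        t[0] = h0 - gap_open
        t[1:] = cand.astype(np.int64) - gap_open
        t += np.asarray(gap_extend, dtype=np.int64) * js
        run = np.maximum.accumulate(t)
        E[i, 1:] = (run[:-1] - np.asarray(gap_extend, dtype=np.int64) * js[1:]).astype(
            np.int32
        )

        H[i, 0] = h0
        if mode == "global":
            F[i, 0] = h0 if i > 0 else NEG
        H[i, 1:] = np.maximum(cand, E[i, 1:])
        if local:
            np.maximum(H[i, 1:], 0, out=H[i, 1:])
        if x_drop is not None:
            row_best = int(H[i].max())
            if row_best > best:
                best = row_best
            elif row_best < best - x_drop:
                last_row = i
                break
    return H, E, F, last_row


def _traceback(H, E, F, a, b, match, mismatch, gap_open, gap_extend, start, stop_mode):
    """Walk back from ``start`` (i, j).  stop_mode: 'corner', 'edge' or 'zero'."""
    i, j = start
    cols_a: list[str] = []
    cols_b: list[str] = []
    state = "H"
    bvalid = b < 4
    while True:
        if state == "H":
            if stop_mode == "zero" and H[i, j] == 0:
                break
            if i == 0 and j == 0:
                break
            if stop_mode == "edge" and (i == 0 or j == 0):
                break
            if i > 0 and j > 0:
                s = match if (a[i - 1] == b[j - 1] and bvalid[j - 1]) else mismatch
                if H[i, j] == H[i - 1, j - 1] + s:
                    cols_a.append("M")
                    cols_b.append("M")
                    i -= 1
                    j -= 1
                    continue
            if j > 0 and H[i, j] == E[i, j]:
                state = "E"
                continue
            if i > 0 and H[i, j] == F[i, j]:
                state = "F"
                continue
            # global boundary rows/columns
            if i == 0:
                cols_a.append("-")
                cols_b.append("M")
                j -= 1
                continue
            cols_a.append("M")
            cols_b.append("-")
            i -= 1
            continue
        if state == "E":
            cols_a.append("-")
            cols_b.append("M")
            if j > 1 and E[i, j] == E[i, j - 1] - gap_extend:
                j -= 1
                continue
            j -= 1
            state = "H"
            continue
        # state == "F"
        cols_a.append("M")
        cols_b.append("-")
        if i > 1 and F[i, j] == F[i - 1, j] - gap_extend:
            i -= 1
            continue
        i -= 1
        state = "H"
    return i, j, cols_a[::-1], cols_b[::-1]


def _render(a_str, b_str, ia, ja, ops_a, ops_b):
    out_a, out_b = [], []
    i, j = ia, ja
    for oa, ob in zip(ops_a, ops_b):
        if oa == "M":
            out_a.append(a_str[i])
            i += 1
        else:
            out_a.append("-")
        if ob == "M":
            out_b.append(b_str[j])
            j += 1
        else:
            out_b.append("-")
    return "".join(out_a), "".join(out_b), i, j


def align(
    a: str,
    b: str,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = 5,
    gap_extend: int = 2,
    mode: str = "global",
) -> Alignment:
    """Optimal affine-gap alignment of two DNA strings.

    ``semiglobal`` leaves terminal gaps unpenalised but renders them
    explicitly, so ungapping either row recovers the full input sequence.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    if mode not in ("global", "semiglobal"):
        raise ValueError(f"unknown mode {mode!r}")
    ca, cb = encode(a), encode(b)
    H, E, F, _ = _fill(ca, cb, match, mismatch, gap_open, gap_extend, mode)
    n, m = len(ca), len(cb)
    if mode == "global":
        start = (n, m)
        score = int(H[n, m])
        stop = "corner"
    else:
        last_col = H[:, m]
        last_row = H[n, :]
        bi = int(np.argmax(last_col))
        bj = int(np.argmax(last_row))
        if last_col[bi] >= last_row[bj]:
            start, score = (bi, m), int(last_col[bi])
        else:
            start, score = (n, bj), int(last_row[bj])
        stop = "edge"
    ia, ja, ops_a, ops_b = _traceback(
        H, E, F, ca, cb, match, mismatch, gap_open, gap_extend, start, stop
    )
    row_a, row_b, ea, eb = _render(a, b, ia, ja, ops_a, ops_b)
    if mode == "semiglobal":
        # render free terminal gaps explicitly
        head_a, head_b = a[:ia], b[:ja]
        tail_a, tail_b = a[ea:], b[eb:]
        row_a = head_a + "-" * len(head_b) + row_a + tail_a + "-" * len(tail_b)
        row_b = "-" * len(head_a) + head_b + row_b + "-" * len(tail_a) + tail_b
    return Alignment(row_a, row_b, score)


@dataclass(frozen=True)
class LocalHit:
    """Best local alignment of a query against a subject window."""

    score: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    n_identical: int
    n_columns: int

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.n_identical / self.n_columns if self.n_columns else 0.0


def _extend_half(
    a: np.ndarray,
    b: np.ndarray,
    match: int,
    mismatch: int,
    gap_open: int,
    gap_extend: int,
    x_drop: int,
):
    """One-directional gapped X-drop extension anchored at (0, 0).

    Fills a global-style DP (boundaries pay gap costs) but scores the best
    cell anywhere; rows stop once their maximum falls ``x_drop`` below the
    best.  Returns (score, a_used, b_used, n_identical, n_columns).
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return 0, 0, 0, 0, 0
    H, E, F, last = _fill(a, b, match, mismatch, gap_open, gap_extend, "global",
                          x_drop=x_drop)
    sub = H[: last + 1]
    flat = int(np.argmax(sub))
    bi, bj = divmod(flat, H.shape[1])
    score = int(H[bi, bj])
    if score <= 0:
        return 0, 0, 0, 0, 0
    ia, ja, ops_a, ops_b = _traceback(
        H, E, F, a, b, match, mismatch, gap_open, gap_extend, (bi, bj), "corner"
    )
    n_ident = 0
    i = j = 0
    for oa, ob in zip(ops_a, ops_b):
        if oa == "M" and ob == "M":
            if a[i] == b[j] and b[j] < 4:
                n_ident += 1
        if oa == "M":
            i += 1
        if ob == "M":
            j += 1
    return score, bi, bj, n_ident, len(ops_a)


def extend_seed(
    qc: np.ndarray,
    sc: np.ndarray,
    qpos: int,
    spos: int,
    word: int,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = 5,
    gap_extend: int = 2,
    x_drop: int = 100,
    band_slack: int = 500,
) -> "LocalHit":
    """Gapped X-drop extension of an exact ``word`` match in both directions.

    The subject side of each half is capped at the remaining query length
    plus ``band_slack`` (a longer gap could never survive the drop-off).
    Coordinates in the returned hit are on the full query/subject arrays.
    """
    seed_score = word * match
    ra = qc[qpos + word :]
    rb = sc[spos + word : spos + word + len(ra) + band_slack]
    rs, ra_used, rb_used, rid, rcols = _extend_half(
        ra, rb, match, mismatch, gap_open, gap_extend, x_drop
    )
    la = qc[:qpos][::-1]
    lb = sc[max(0, spos - len(la) - band_slack) : spos][::-1]
    ls, la_used, lb_used, lid, lcols = _extend_half(
        la, lb, match, mismatch, gap_open, gap_extend, x_drop
    )
    return LocalHit(
        score=seed_score + rs + ls,
        a_start=qpos - la_used,
        a_end=qpos + word + ra_used,
        b_start=spos - lb_used,
        b_end=spos + word + rb_used,
        n_identical=word + rid + lid,
        n_columns=word + rcols + lcols,
    )


def local_align(
    a: str,
    b: str,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = 5,
    gap_extend: int = 2,
    x_drop: int | None = None,
) -> LocalHit | None:
    """Smith–Waterman local alignment with optional drop-off termination."""
    if not a or not b:
        return None
    ca, cb = encode(a), encode(b)
    H, E, F, last_row = _fill(
        ca, cb, match, mismatch, gap_open, gap_extend, "local", x_drop=x_drop
    )
    sub = H[: last_row + 1]
    flat = int(np.argmax(sub))
    bi, bj = divmod(flat, H.shape[1])
    score = int(H[bi, bj])
    if score <= 0:
        return None
    ia, ja, ops_a, ops_b = _traceback(
        H, E, F, ca, cb, match, mismatch, gap_open, gap_extend, (bi, bj), "zero"
    )
    n_ident = 0
    i, j = ia, ja
    for oa, ob in zip(ops_a, ops_b):
        if oa == "M" and ob == "M":
            if ca[i] == cb[j] and cb[j] < 4:
                n_ident += 1
        if oa == "M":
            i += 1
        if ob == "M":
            j += 1
    return LocalHit(score, ia, bi, ja, bj, n_ident, len(ops_a))
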