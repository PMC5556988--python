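"""Consensus reconstruction and Kimura two-parameter divergence.

Per-species family consensus is built by star alignment: every copy is
semiglobally aligned to a reference (the search query consensus by default),
columns are the reference positions plus insertion columns supported by a
majority of copies, and each emitted column takes its majority base.

Divergence uses the K2P estimator
``d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q))`` with transition fraction P and
transversion fraction Q over pairwise-deleted sites (gap or ambiguous sites
excluded).  A saturated comparison (log argument <= 0) raises
``SaturationError`` rather than returning a silent NaN.

A deterministic neighbor-joining utility turns a distance matrix into a
Newick tree (negative branch lengths clamped to zero, ties broken by label
order).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._dp import Alignment, align, encode

__all__ = [
    "Alignment",
    "ConsensusProfile",
    "DistanceMatrix",
    "DivergenceRecord",
    "SaturationError",
    "global_affine_align",
    "build_majority_consensus",
    "k2p_distance",
    "p_distance",
    "divergence_table",
    "consensus_matrix",
    "nj_tree",
]


class SaturationError(ValueError):
    """K2P distance undefined: substitutions are saturated."""


def global_affine_align(
    a: str,
    b: str,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = 5,
    gap_extend: int = 2,
    mode: str = "global",
) -> Alignment:
    """Optimal affine-gap alignment; ``mode='semiglobal'`` frees end gaps."""
    return align(a, b, match, mismatch, gap_open, gap_extend, mode)


@dataclass
class ConsensusProfile:
    """Per-species majority consensus with per-column A/C/G/T/gap counts."""

    species_id: str
    sequence: str
    n_copies: int
    column_counts: np.ndarray = field(repr=False)  # (L, 5): A C G T gap

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.column_counts):
            raise ValueError("counts do not match consensus length")


def build_majority_consensus(
    copies,
    reference: str,
    species_id: str = "species",
    min_coverage: float = 0.2,
    **align_kw,
) -> ConsensusProfile:
    """Star-align copies to ``reference`` and majority-vote each column.

    ``copies`` is a list of sequences or objects with a ``sequence``
    attribute.  Reference columns are emitted when their non-gap coverage is
    at least ``min_coverage`` of the copies; insertion columns relative to
    the reference are emitted only when more than half of the copies support
    an insertion at that junction.  Majority ties go to the alphabetically
    first base; a gap wins a column only by strict majority over every base
    (and a gap-majority column is simply not emitted).
    """
    seqs = [getattr(c, "sequence", c) for c in copies]
    if len(seqs) < 1:
        raise ValueError("need at least one copy")
    L = len(reference)
    counts = np.zeros((L, 5), dtype=int)  # A C G T gap
    insertions: list[dict[str, list[str]]] = [dict() for _ in range(L + 1)]
    ins_support = np.zeros(L + 1, dtype=int)

    for ci, seq in enumerate(seqs):
        aln = align(reference, seq, mode="semiglobal", **align_kw)
        ref_pos = 0
        pending_ins: list[str] = []
        started = False
        seen_end = False
        for ra, rb in zip(aln.aligned_a, aln.aligned_b):
            if ra == "-":
                pending_ins.append(rb)
                continue
            if pending_ins:
                if started and not seen_end:
                    key = "".join(pending_ins)
                    insertions[ref_pos].setdefault(key, []).append(str(ci))
                    ins_support[ref_pos] += 1
                pending_ins = []
            if rb == "-":
                counts[ref_pos, 4] += 1
            else:
                code = encode(rb)[0]
                if code < 4:
                    counts[ref_pos, code] += 1
                else:
                    counts[ref_pos, 4] += 1
                started = True
            ref_pos += 1
        # terminal insertions (pending at the end) are unaligned overhang
    n = len(seqs)
    bases = "ACGT"
    out: list[str] = []
    out_counts: list[np.ndarray] = []
    for j in range(L):
        # a majority-supported insertion before reference position j
        if ins_support[j] * 2 > n:
            best_key = min(
                insertions[j], key=lambda k: (-len(insertions[j][k]), k)
            )
            for t, ch in enumerate(best_key):
                col = np.zeros(5, dtype=int)
                for key2, members in insertions[j].items():
                    if t < len(key2):
                        c2 = encode(key2[t])[0]
                        if c2 < 4:
                            col[c2] += len(members)
                code = int(np.argmax(col[:4]))
                out.append(bases[code])
                out_counts.append(col)
        col = counts[j]
        coverage = int(col[:4].sum())
        if coverage < math.ceil(min_coverage * n) or coverage == 0:
            continue
        if col[4] > col[:4].max():
            continue  # strict gap majority: deletion in the consensus
        code = int(np.argmax(col[:4]))  # argmax tie -> lowest index -> alphabetical
        out.append(bases[code])
        out_counts.append(col.copy())
    return ConsensusProfile(
        species_id, "".join(out), n, np.array(out_counts, dtype=int).reshape(-1, 5)
    )


_PURINES = frozenset("AG")


def _pq(aligned_a: str, aligned_b: str) -> tuple[float, float, int]:
    ca, cb = encode(aligned_a.upper()), encode(aligned_b.upper())
    if len(ca) != len(cb):
        raise ValueError("aligned sequences differ in length")
    usable = (ca < 4) & (cb < 4)
    n = int(usable.sum())
    if n == 0:
        raise ValueError("no usable (gap-free, unambiguous) sites")
    x, y = ca[usable], cb[usable]
    diff = x != y
    # transitions: A<->G (codes 0,2), C<->T (codes 1,3): same parity
    ts = diff & ((x % 2) == (y % 2))
    p = float(ts.sum()) / n
    q = float(diff.sum() - ts.sum()) / n
    return p, q, n


def p_distance(aligned_a: str, aligned_b: str) -> float:
    """Raw proportion of differing sites over pairwise-deleted sites."""
    p, q, _ = _pq(aligned_a, aligned_b)
    return p + q


def k2p_distance(aligned_a: str, aligned_b: str) -> float:
    """Kimura 2-parameter distance with pairwise deletion of gaps/ambiguity."""
    p, q, _ = _pq(aligned_a, aligned_b)
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P undefined at P={p:.3f}, Q={q:.3f} (saturated)"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


@dataclass(frozen=True)
class DivergenceRecord:
    copy_id: str
    k2p: float | None
    n_sites: int
    saturated: bool = False


def divergence_table(copies, profile: ConsensusProfile, **align_kw) -> list[DivergenceRecord]:
    """K2P of every copy against its species consensus (one row per copy).

    Saturated copies are flagged (``saturated=True``, ``k2p=None``) rather
    than silently dropped.
    """
    records: list[DivergenceRecord] = []
    for i, c in enumerate(copies):
        seq = getattr(c, "sequence", c)
        cid = getattr(c, "copy_id", f"copy_{i:05d}")
        aln = align(profile.sequence, seq, mode="semiglobal", **align_kw)
        try:
            p, q, n = _pq(aln.aligned_a, aln.aligned_b)
            records.append(DivergenceRecord(cid, k2p_distance(aln.aligned_a, aln.aligned_b), n))
        except SaturationError:
            records.append(DivergenceRecord(cid, None, n, saturated=True))
    return records


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be >= 0")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for i, lab in enumerate(self.labels):
                row = "\t".join(f"{x:.4f}" for x in self.values[i])
                fh.write(f"{lab}\t{row}\n")


def consensus_matrix(profiles: list[ConsensusProfile], **align_kw) -> DistanceMatrix:
    """Pairwise K2P between species consensus sequences (Table-1 shape)."""
    labels = [p.species_id for p in profiles]
    n = len(profiles)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = align(profiles[i].sequence, profiles[j].sequence, mode="semiglobal", **align_kw)
            m[i, j] = m[j, i] = k2p_distance(aln.aligned_a, aln.aligned_b)
    return DistanceMatrix(labels, m)


def nj_tree(matrix: DistanceMatrix) -> str:
    """Neighbor joining with the standard Q criterion; returns Newick.

    Negative branch lengths are clamped to zero; equal Q values are resolved
    by label order, so the output is deterministic.
    """
    labels = list(matrix.labels)
    if len(labels) < 3:
        raise ValueError("need at least three taxa")
    d = {a: {b: matrix.get(a, b) for b in labels} for a in labels}
    nodes = {lab: lab for lab in labels}  # label -> newick subtree
    active = sorted(labels)
    while len(active) > 2:
        r = len(active)
        sums = {a: sum(d[a][b] for b in active if b != a) for a in active}
        best = None
        for ai in range(r):
            for bi in range(ai + 1, r):
                a, b = active[ai], active[bi]
                q = (r - 2) * d[a][b] - sums[a] - sums[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        la = 0.5 * d[a][b] + (sums[a] - sums[b]) / (2 * (r - 2))
        lb = d[a][b] - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        new = f"u{len(nodes)}"
        nodes[new] = f"({nodes[a]}:{la:.6f},{nodes[b]}:{lb:.6f})"
        d[new] = {}
        for c in active:
            if c in (a, b):
                continue
            dc = 0.5 * (d[a][c] + d[b][c] - d[a][b])
            d[new][c] = d[c][new] = max(dc, 0.0)
        d[new][new] = 0.0
        active = sorted([c for c in active if c not in (a, b)] + [new])
    a, b = active
    half = max(d[a][b], 0.0) / 2
    return f"({nodes[a]}:{half:.6f},{nodes[b]}:{half:.6f});"


def write_divergence_tsv(records: list[DivergenceRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("copy_id\tk2p\tn_sites\tsaturated\n")
        for r in records:
            k = "NA" if r.k2p is None else f"{r.k2p:.6f}"
            fh.write(f"{r.copy_id}\t{k}\t{r.n_sites}\t{int(r.saturated)}\n")
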