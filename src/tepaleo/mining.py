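"""Homology search for TE copies: seed-and-extend with E-value statistics.

Re-implements the blastn-style screen used to census a TE family in genome
assemblies: exact word seeds on both strands, ungapped X-drop extension to
triage, then gapped affine extension over the seed cluster; hits are kept
at ``E <= 1e-10`` (the published cutoff), merged into loci, and extracted
with up to 200 bp of flanking sequence.

Defaults mirror blastn: word size 11, match +2 / mismatch -3, gap open 5 /
extend 2.  lambda is solved numerically from the scoring scheme and the
genome's base composition; the Karlin–Altschul K prefactor defaults to the
conventional 0.1 (it enters E only linearly and the decision margins here
are tens of orders of magnitude).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from ._dp import encode, extend_seed
from .simulate import revcomp


@dataclass(frozen=True)
class SearchParams:
    word_size: int = 11
    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    evalue_max: float = 1e-10
    x_drop_ungapped: int = 20
    x_drop_gapped: int = 100
    gapped_trigger: int = 40  # raw ungapped score needed to attempt gapped DP
    cluster_gap: int = 500  # max seed spacing within one diagonal cluster
    diag_band: int = 20
    karlin_k: float = 0.1
    dust: bool = False  # optional low-complexity masking, off by default


@dataclass(frozen=True)
class Hsp:
    """One high-scoring segment pair, genome coordinates 0-based half-open."""

    contig_id: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    strand: str
    score: int
    percent_identity: float
    evalue: float

    def __post_init__(self) -> None:
        if self.query_start >= self.query_end or self.subject_start >= self.subject_end:
            raise ValueError("empty HSP interval")
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError("identity outside [0, 100]")
        if self.evalue < 0:
            raise ValueError("negative E-value")


@dataclass(frozen=True)
class Locus:
    """A merged copy locus (same contig/strand HSPs within ``max_gap``)."""

    contig_id: str
    start: int
    end: int
    strand: str
    score: int
    evalue: float
    n_hsps: int = 1


@dataclass(frozen=True)
class TECopy:
    """One mined element occurrence with strand-corrected flanks."""

    copy_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    sequence: str
    flank5: str
    flank3: str
    flank5_truncated: bool = False
    flank3_truncated: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start:
            raise ValueError("sequence length disagrees with interval")
        if len(self.flank5) > 200 or len(self.flank3) > 200:
            raise ValueError("flanks longer than 200 bp")


def karlin_lambda(
    match: int, mismatch: int, composition: np.ndarray | None = None
) -> float:
    """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 for lambda > 0."""
    p = np.full(4, 0.25) if composition is None else np.asarray(composition, float)
    p = p / p.sum()
    pp = np.outer(p, p)
    s = np.full((4, 4), mismatch, dtype=float)
    np.fill_diagonal(s, match)
    if float((pp * s).sum()) >= 0:
        raise ValueError("expected score must be negative for local statistics")

    def f(lam):
        return float((pp * np.exp(lam * s)).sum()) - 1.0

    return float(brentq(f, 1e-6, 10.0, xtol=1e-12))


def evalue(score: int, m: int, n: int, lam: float, k: float = 0.1) -> float:
    """Karlin–Altschul expectation E = K m n exp(-lambda S)."""
    return k * m * n * math.exp(-lam * score)


def _words(codes: np.ndarray, k: int) -> np.ndarray:
    """Packed k-mer codes per position; -1 where the window holds non-ACGT."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    v = np.zeros(n, dtype=np.int64)
    for t in range(k):
        v = v * 4 + codes[t : t + n]
    bad = np.convolve((codes >= 4).astype(np.int32), np.ones(k, np.int32))[
        k - 1 : k - 1 + n
    ]
    v[bad > 0] = -1
    return v


def _ungapped_extend(q, s, qpos, spos, k, match, mismatch, x_drop):
    """Grow an exact word match on its diagonal; return the best raw score."""
    score = k * match
    best = score
    i, j = qpos + k, spos + k
    while i < len(q) and j < len(s):
        score += match if (q[i] == s[j] and s[j] < 4) else mismatch
        if score > best:
            best = score
        elif score < best - x_drop:
            break
        i += 1
        j += 1
    score = best
    i, j = qpos - 1, spos - 1
    while i >= 0 and j >= 0:
        score += match if (q[i] == s[j] and s[j] < 4) else mismatch
        if score > best:
            best = score
        elif score < best - x_drop:
            break
        i -= 1
        j -= 1
    return best


def _cluster_seeds(matches: list[tuple[int, int]], params: SearchParams):
    """Group (qpos, spos) seeds into diagonal clusters."""
    matches.sort(key=lambda t: (t[1] - t[0], t[1]))
    clusters: list[list[tuple[int, int]]] = []
    for qpos, spos in matches:
        diag = spos - qpos
        if clusters:
            lq, ls = clusters[-1][-1]
            if abs(diag - (ls - lq)) <= params.diag_band and (
                spos - ls
            ) <= params.cluster_gap:
                clusters[-1].append((qpos, spos))
                continue
        clusters.append([(qpos, spos)])
    return clusters


def seed_and_extend_search(
    query: str,
    genome: dict[str, str] | list[tuple[str, str]],
    params: SearchParams = SearchParams(),
) -> list[Hsp]:
    """Find all HSPs of ``query`` in ``genome`` on both strands.

    ``genome`` maps contig ids to sequences.  HSPs with
    ``E <= params.evalue_max`` are returned sorted by contig and position.
    """
    if isinstance(genome, list):
        genome = dict(genome)
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("empty genome")
    if len(query) < params.word_size:
        raise ValueError("query shorter than the seed word size")

    total_n = sum(len(s) for s in genome.values())
    counts = np.zeros(4, dtype=float)
    for s in genome.values():
        c = encode(s)
        counts += np.bincount(c[c < 4], minlength=4)
    comp = counts / counts.sum() if counts.sum() else None
    lam = karlin_lambda(params.match, params.mismatch, comp)
    # both strands are searched: double the effective search space
    search_space_n = 2 * total_n

    hsps: list[Hsp] = []
    qlen = len(query)
    for strand, qseq in (("+", query), ("-", revcomp(query))):
        qc = encode(qseq)
        qwords = _words(qc, params.word_size)
        word_index: dict[int, list[int]] = {}
        for pos, w in enumerate(qwords):
            if w >= 0:
                word_index.setdefault(int(w), []).append(pos)
        qword_arr = np.fromiter(word_index.keys(), dtype=np.int64, count=len(word_index))
        for contig_id, cseq in genome.items():
            sc = encode(cseq)
            gwords = _words(sc, params.word_size)
            if len(gwords) == 0:
                continue
            hit_mask = np.isin(gwords, qword_arr)
            matches = [
                (qpos, int(spos))
                for spos in np.nonzero(hit_mask)[0]
                for qpos in word_index[int(gwords[spos])]
            ]
            seen: list[tuple[int, int]] = []  # accepted (sstart, send) windows
            for cluster in _cluster_seeds(matches, params):
                qpos, spos = cluster[len(cluster) // 2]
                if any(a <= spos < b for a, b in seen):
                    continue
                raw = _ungapped_extend(
                    qc, sc, qpos, spos, params.word_size,
                    params.match, params.mismatch, params.x_drop_ungapped,
                )
                if raw < params.gapped_trigger:
                    continue
                hit = extend_seed(
                    qc,
                    sc,
                    qpos,
                    spos,
                    params.word_size,
                    params.match,
                    params.mismatch,
                    params.gap_open,
                    params.gap_extend,
                    x_drop=params.x_drop_gapped,
                )
                e = evalue(hit.score, qlen, search_space_n, lam, params.karlin_k)
                if e > params.evalue_max:
                    continue
                sstart, send = hit.b_start, hit.b_end
                # duplicate if it substantially overlaps an accepted HSP
                if any(
                    min(send, b) - max(sstart, a) > 0.5 * (send - sstart)
                    for a, b in seen
                ):
                    continue
                seen.append((sstart, send))
                if strand == "+":
                    q_start, q_end = hit.a_start, hit.a_end
                else:
                    q_start, q_end = qlen - hit.a_end, qlen - hit.a_start
                hsps.append(
                    Hsp(
                        contig_id,
                        q_start,
                        q_end,
                        sstart,
                        send,
                        strand,
                        hit.score,
                        hit.percent_identity,
                        e,
                    )
                )
    hsps.sort(key=lambda h: (h.contig_id, h.subject_start, h.subject_end, h.strand))
    return hsps


def merge_hits(hsps: list[Hsp], max_gap: int = 100) -> list[Locus]:
    """Merge same-contig, same-strand HSPs within ``max_gap`` into loci.

    One element copy can yield several HSPs (e.g. the two retained termini
    of a MITE against a full-length query); merging recovers one locus per
    copy.  Loci inherit the best (lowest) E-value and best score.
    """
    groups: dict[tuple[str, str], list[Hsp]] = {}
    for h in hsps:
        groups.setdefault((h.contig_id, h.strand), []).append(h)
    loci: list[Locus] = []
    for (contig, strand), hs in groups.items():
        hs.sort(key=lambda h: (h.subject_start, h.subject_end))
        cur: list[Hsp] = []
        for h in hs:
            if cur and h.subject_start <= cur[-1].subject_end + max_gap:
                cur.append(h)
            else:
                if cur:
                    loci.append(_locus_from(cur, contig, strand))
                cur = [h]
        if cur:
            loci.append(_locus_from(cur, contig, strand))
    loci.sort(key=lambda l: (l.contig_id, l.start, l.end))
    return loci


def _locus_from(hs: list[Hsp], contig: str, strand: str) -> Locus:
    return Locus(
        contig,
        min(h.subject_start for h in hs),
        max(h.subject_end for h in hs),
        strand,
        max(h.score for h in hs),
        min(h.evalue for h in hs),
        len(hs),
    )


def extract_copies(
    genome: dict[str, str] | list[tuple[str, str]],
    loci: list[Locus],
    flank: int = 200,
) -> list[TECopy]:
    """Extract copy sequences plus up to ``flank`` bp of context.

    Minus-strand copies keep genomic coordinates but their sequence and
    flanks are reverse-complemented to element orientation (flank5 precedes
    the element 5' end).  Flanks hitting a contig edge are truncated and
    flagged.
    """
    if isinstance(genome, list):
        genome = dict(genome)
    copies: list[TECopy] = []
    for i, loc in enumerate(loci):
        contig = genome.get(loc.contig_id)
        if contig is None:
            raise KeyError(f"locus on unknown contig {loc.contig_id!r}")
        if loc.start < 0 or loc.end > len(contig):
            raise ValueError("locus outside contig bounds")
        seq = contig[loc.start : loc.end]
        left = contig[max(0, loc.start - flank) : loc.start]
        right = contig[loc.end : loc.end + flank]
        left_trunc = loc.start - flank < 0
        right_trunc = loc.end + flank > len(contig)
        if loc.strand == "+":
            f5, f3 = left, right
            t5, t3 = left_trunc, right_trunc
        else:
            seq = revcomp(seq)
            f5, f3 = revcomp(right), revcomp(left)
            t5, t3 = right_trunc, left_trunc
        copies.append(
            TECopy(
                f"copy_{i:05d}", loc.contig_id, loc.start, loc.end,
                loc.strand, seq, f5, f3, t5, t3,
            )
        )
    return copies


def write_bed(loci: list[Locus], path) -> None:
    """BED6: contig, start, end, name, score, strand."""
    with open(path, "w") as fh:
        for i, l in enumerate(loci):
            fh.write(
                f"{l.contig_id}\t{l.start}\t{l.end}\tcopy_{i:05d}\t{l.score}\t{l.strand}\n"
            )


def write_hits_tsv(hsps: list[Hsp], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "contig\tquery_start\tquery_end\tsubject_start\tsubject_end\t"
            "strand\tscore\tpercent_identity\tevalue\n"
        )
        for h in hsps:
            fh.write(
                f"{h.contig_id}\t{h.query_start}\t{h.query_end}\t"
                f"{h.subject_start}\t{h.subject_end}\t{h.strand}\t{h.score}\t"
                f"{h.percent_identity:.2f}\t{h.evalue:.3e}\n"
            )


def write_copies_fasta(copies: list[TECopy], path, with_flanks: bool = False) -> None:
    """Copies as FASTA with structured headers copy_id|contig|start-end|strand."""
    with open(path, "w") as fh:
        for c in copies:
            header = f">{c.copy_id}|{c.contig_id}|{c.start}-{c.end}|{c.strand}"
            seq = (c.flank5 + c.sequence + c.flank3) if with_flanks else c.sequence
            fh.write(header + "\n")
            for k in range(0, len(seq), 80):
                fh.write(seq[k : k + 80] + "\n")
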