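"""Structural annotation of mined TE copies: TIRs, TSDs, ORFs, classes.

Copies are binned into the four functional classes used for mariner-family
censuses — potential autonomous (conserved TIRs + a transposase-sized ORF),
potential non-autonomous (TIRs, no such ORF; MITEs fall here), potential
coding (ORF but a missing TIR) and partial — plus length-band size classes
(full-length ~1.2–1.4 kb, MITE ~450–650 bp, otherwise partial).

"Conserved TIRs" is operationalised as a detected terminal inverted repeat
of >= 20 bp at >= 80% identity (both configurable); real TIRs are imperfect,
so detection aligns the two termini allowing mismatches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._dp import encode
from .simulate import revcomp

FUNCTIONAL_CLASSES = (
    "potential_autonomous",
    "potential_non_autonomous",
    "potential_coding",
    "partial",
)
SIZE_CLASSES = ("full_length", "mite", "partial_size")


@dataclass(frozen=True)
class TirAnnotation:
    """Best terminal inverted repeat: (start, length) at each terminus."""

    five_prime: tuple[int, int]
    three_prime: tuple[int, int]
    mismatches: int
    identity: float


@dataclass(frozen=True)
class Orf:
    frame: int  # +1..+3 / -1..-3
    start: int  # nucleotide interval on the input, 0-based half-open,
    end: int    # including the terminating stop codon when present
    aa_length: int
    starts_with_methionine: bool
    has_stop: bool = True


@dataclass(frozen=True)
class CopyAnnotation:
    copy_id: str
    length: int
    tir: TirAnnotation | None
    tsd: str | None
    orfs: tuple[Orf, ...]
    functional_class: str
    size_class: str


def detect_tirs(
    copy_seq: str,
    min_len: int = 20,
    max_len: int = 40,
    min_identity: float = 0.8,
    window: int = 60,
) -> TirAnnotation | None:
    """Find the best terminal inverted repeat of a copy, if any.

    The first ``window`` bases are compared against the reverse complement
    of the last ``window`` bases over all ungapped offsets; among segments
    with length in [min_len, max_len] and identity >= ``min_identity`` the
    highest-scoring one (matches - mismatches, i.e. a +1/-1 local alignment)
    wins, so a full imperfect TIR beats a shorter perfect core (ties: longer,
    then closer to the termini).
    """
    if len(copy_seq) < 2 * min_len:
        raise ValueError("sequence shorter than twice the minimum TIR length")
    w = min(window, len(copy_seq) // 2)
    a = encode(copy_seq[:w])
    b = encode(revcomp(copy_seq[-w:]))
    best = None  # (identity, length, -(i+j), i, j, mism)
    for offset in range(-(w - min_len), w - min_len + 1):
        # compare a[i] with b[i + offset]
        lo = max(0, -offset)
        hi = min(w, w - offset)
        if hi - lo < min_len:
            continue
        eq = (a[lo:hi] == b[lo + offset : hi + offset]) & (a[lo:hi] < 4)
        cs = np.concatenate(([0], np.cumsum(eq)))
        span = hi - lo
        for length in range(min_len, min(max_len, span) + 1):
            wins = cs[length:] - cs[:-length]
            kbest = int(np.argmax(wins))
            # prefer segments starting nearest the termini on equal identity
            matches = int(wins[kbest])
            ident = matches / length
            if ident < min_identity:
                continue
            i = lo + kbest
            j = i + offset  # position in the reversed 3' window
            key = (2 * matches - length, length, -(i + j))
            if best is None or key > best[0]:
                best = (key, i, j, length, length - matches)
    if best is None:
        return None
    _, i, j, length, mism = best
    # map j back to coordinates on the forward copy: segment occupies
    # positions [L - w + (w - j - length), ...) = [L - j - length, L - j)
    L = len(copy_seq)
    return TirAnnotation(
        five_prime=(i, length),
        three_prime=(L - w + (w - j - length), length),
        mismatches=mism,
        identity=1.0 - mism / length,
    )


def detect_tsd(flank5: str, flank3: str, tsd: str = "TA") -> str | None:
    """Target-site duplication: ``tsd`` must end flank5 and start flank3."""
    if not flank5 or not flank3:
        return None
    if flank5.upper().endswith(tsd.upper()) and flank3.upper().startswith(tsd.upper()):
        return tsd.upper()
    return None


_STOPS = {"TAA", "TAG", "TGA"}


def _scan_frame(seq: str, frame_off: int, min_aa: int, require_met: bool):
    """ATG->stop spans in one forward frame of ``seq`` (uppercase)."""
    out = []
    n = len(seq)
    start = None
    for pos in range(frame_off, n - 2, 3):
        codon = seq[pos : pos + 3]
        if start is None:
            if (not require_met and codon not in _STOPS) or codon == "ATG":
                start = pos
                continue
        else:
            if codon in _STOPS:
                aa = (pos - start) // 3
                if aa >= min_aa:
                    out.append((start, pos + 3, aa, seq[start : start + 3] == "ATG", True))
                start = None
    if start is not None:
        end = start + 3 * ((n - start) // 3)
        aa = (end - start) // 3
        if aa >= min_aa:
            out.append((start, end, aa, seq[start : start + 3] == "ATG", False))
    return out


def find_orfs(
    seq: str, min_aa: int = 300, require_methionine: bool = True
) -> list[Orf]:
    """Six-frame ORF scan (getorf-like: -find 1 semantics).

    Reports ATG-to-stop spans translating to >= ``min_aa`` residues (the
    stop codon is inside the interval but not counted).  Degenerate bases
    never form a start or stop and translate as X.  Reverse-frame intervals
    are reported on the input coordinates.
    """
    s = seq.upper()
    n = len(s)
    orfs: list[Orf] = []
    for off in range(3):
        for start, end, aa, met, stopped in _scan_frame(s, off, min_aa, require_methionine):
            orfs.append(Orf(off + 1, start, end, aa, met, stopped))
    rc = revcomp(s)
    for off in range(3):
        for start, end, aa, met, stopped in _scan_frame(rc, off, min_aa, require_methionine):
            orfs.append(Orf(-(off + 1), n - end, n - start, aa, met, stopped))
    orfs.sort(key=lambda o: (-o.aa_length, o.start, o.frame))
    return orfs


def classify_copy(
    tir: TirAnnotation | None,
    orfs: list[Orf] | tuple[Orf, ...],
    length: int,
    min_aa: int = 300,
    full_length_band: tuple[int, int] = (1200, 1400),
    mite_band: tuple[int, int] = (450, 650),
) -> tuple[str, str]:
    """Assign the functional class and the length-band size class.

    TIR present + ORF >= min_aa -> potential_autonomous; TIR only ->
    potential_non_autonomous; ORF only -> potential_coding; neither ->
    partial.  Ties at exactly ``min_aa`` count as coding-capable.
    """
    if length < 0:
        raise ValueError("negative length")
    max_aa = max((o.aa_length for o in orfs), default=0)
    has_orf = max_aa >= min_aa
    if tir is not None:
        functional = "potential_autonomous" if has_orf else "potential_non_autonomous"
    else:
        functional = "potential_coding" if has_orf else "partial"
    if full_length_band[0] <= length <= full_length_band[1]:
        size = "full_length"
    elif mite_band[0] <= length <= mite_band[1]:
        size = "mite"
    else:
        size = "partial_size"
    return functional, size


def annotate_copy(copy, tsd: str = "TA", min_aa: int = 300, **tir_kw) -> CopyAnnotation:
    """Full annotation of one mined TECopy."""
    try:
        tir = detect_tirs(copy.sequence, **tir_kw)
    except ValueError:
        tir = None
    found_tsd = detect_tsd(copy.flank5, copy.flank3, tsd)
    orfs = tuple(find_orfs(copy.sequence, min_aa=min_aa))
    functional, size = classify_copy(tir, orfs, len(copy.sequence), min_aa=min_aa)
    return CopyAnnotation(
        copy.copy_id, len(copy.sequence), tir, found_tsd, orfs, functional, size
    )


def conservation_matrix(aligned_segments: list[str]):
    """Per-column base frequencies and information content (bits).

    The numeric stand-in for a sequence-logo figure: for each column the
    A/C/G/T counts (gaps and Ns excluded from the column total) and
    IC = 2 + sum f log2 f.  Returns (counts[L,4], freqs[L,4], ic[L]).
    """
    if len(aligned_segments) < 2:
        raise ValueError("need at least two segments")
    L = len(aligned_segments[0])
    if any(len(s) != L for s in aligned_segments):
        raise ValueError("segments must have equal length")
    counts = np.zeros((L, 4), dtype=int)
    for s in aligned_segments:
        c = encode(s)
        ok = c < 4
        counts[np.nonzero(ok)[0], c[ok]] += 1
    totals = counts.sum(axis=1)
    freqs = np.zeros_like(counts, dtype=float)
    ic = np.zeros(L)
    for i in range(L):
        if totals[i] == 0:
            continue
        f = counts[i] / totals[i]
        freqs[i] = f
        ic[i] = 2.0 + sum(x * math.log2(x) for x in f if x > 0)
    return counts, freqs, np.clip(ic, 0.0, 2.0)


def write_annotations_tsv(annotations: list[CopyAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "copy_id\tlength\ttir_identity\ttsd\tmax_orf_aa\t"
            "functional_class\tsize_class\n"
        )
        for a in annotations:
            tir_id = f"{a.tir.identity:.3f}" if a.tir else "NA"
            max_aa = max((o.aa_length for o in a.orfs), default=0)
            fh.write(
                f"{a.copy_id}\t{a.length}\t{tir_id}\t{a.tsd or 'NA'}\t"
                f"{max_aa}\t{a.functional_class}\t{a.size_class}\n"
            )


def write_conservation_tsv(counts, freqs, ic, path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tA\tC\tG\tT\tfA\tfC\tfG\tfT\tIC_bits\n")
        for i in range(len(ic)):
            cs = "\t".join(str(int(x)) for x in counts[i])
            fs = "\t".join(f"{x:.4f}" for x in freqs[i])
            fh.write(f"{i + 1}\t{cs}\t{fs}\t{ic[i]:.4f}\n")
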