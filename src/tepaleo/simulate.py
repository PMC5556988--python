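"""Synthetic genomes, TE families and invasion scenarios with known truth.

The generator is the inverse of the downstream estimators: copies diverge
from their family ancestor under a Kimura two-parameter (K2P) substitution
process, with expected divergence ``2 * rate * age`` per copy so that the
dating relation ``T = k / (2 r)`` inverts exactly.  Insertions carry the
duplicated TA target site that mariner transposases leave behind.

All randomness flows through a single ``numpy.random.Generator``; the same
seed yields byte-identical genomes, truth tables and ortholog sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._dp import encode

BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class ElementModel:
    """A transposable-element sequence model.

    ``tir_length`` terminal bases form an inverted repeat (before mutation);
    MITE derivatives record the internal deletion that produced them.
    """

    element_id: str
    sequence: str
    tir_length: int
    internal_deletion: tuple[int, int] | None = None
    is_mite: bool = False

    def __post_init__(self) -> None:
        t = self.tir_length
        if len(self.sequence) < 2 * t:
            raise ValueError("element too short for its TIRs")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TruthRow:
    copy_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    true_age_my: float
    class_truth: str  # full_length | mite
    element_id: str


@dataclass
class SimTruth:
    """Ground-truth table for planted copies (0-based half-open intervals)."""

    rows: list[TruthRow] = field(default_factory=list)

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("copy_id\tcontig\tstart\tend\tstrand\tage_My\tclass\n")
            for r in self.rows:
                fh.write(
                    f"{r.copy_id}\t{r.contig_id}\t{r.start}\t{r.end}\t"
                    f"{r.strand}\t{r.true_age_my:g}\t{r.class_truth}\n"
                )


@dataclass(frozen=True)
class ScenarioConfig:
    """Two-lineage invasion scenario.

    Times in My; ``rate`` in substitutions/site/My.  ``th_a``/``th_b`` are
    the element invasion (burst) ages in each lineage; the lineages split
    ``td`` My ago.  A transfer happened iff ``min(th_a, th_b) < td``.
    """

    td: float = 90.0
    th_a: float = 90.0
    th_b: float = 25.0
    rate: float = 1.9e-3
    kappa: float = 2.0
    n_copies: int = 15
    n_ortholog_pairs: int = 50
    genome_length: int = 120_000
    gc: float = 0.42
    gene_length: int = 900
    rate_sigma: float = 0.25
    element_length: int = 1300
    tir_length: int = 28
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.td, self.th_a, self.th_b) < 0:
            raise ValueError("times must be >= 0")
        if self.rate <= 0 or self.kappa <= 0:
            raise ValueError("rate and kappa must be > 0")
        if self.n_ortholog_pairs < 2:
            raise ValueError("need at least 2 ortholog pairs")


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=length, p=p)])


def make_ancestral_element(
    length: int, tir_length: int = 28, seed: int | np.random.Generator = 0
) -> ElementModel:
    """Random-composition element whose termini form a perfect inverted repeat.

    Mariner-family elements are ~1.3 kb with ~28-bp TIRs; those are the
    natural arguments here.
    """
    if length < 2 * tir_length + 1:
        raise ValueError(
            f"length {length} cannot hold two {tir_length}-bp TIRs"
        )
    rng = _as_rng(seed)
    core = random_sequence(length - tir_length, 0.5, rng)
    tir5 = core[:tir_length]
    seq = core + revcomp(tir5)
    return ElementModel("element", seq, tir_length)


def derive_mite(element: ElementModel, keep5: int, keep3: int) -> ElementModel:
    """Internally-deleted derivative keeping both termini (a MITE).

    The sequence is the first ``keep5`` plus the last ``keep3`` bases of the
    parent, so both TIRs stay intact.
    """
    t = element.tir_length
    if keep5 < t or keep3 < t:
        raise ValueError("kept termini must contain the TIRs")
    if keep5 + keep3 >= element.length:
        raise ValueError("kept termini overlap: no internal deletion left")
    seq = element.sequence[:keep5] + element.sequence[element.length - keep3 :]
    return replace(
        element,
        element_id=element.element_id + "_mite",
        sequence=seq,
        internal_deletion=(keep5, element.length - keep3),
        is_mite=True,
    )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# K2P transition-probability helpers.  Rates are scaled so that the total
# expected number of substitutions per site per unit branch length is 1:
# alpha (transitions) = kappa/(kappa+2), beta (each transversion) = 1/(kappa+2).
def _k2p_probs(d: float, kappa: float) -> tuple[float, float]:
    """(P(transition), P(each transversion)) after branch length d."""
    alpha = kappa / (kappa + 2.0)
    beta = 1.0 / (kappa + 2.0)
    p_ts = 0.25 + 0.25 * np.exp(-4 * beta * d) - 0.5 * np.exp(-2 * (alpha + beta) * d)
    p_tv = 0.25 - 0.25 * np.exp(-4 * beta * d)  # each of the two transversions
    return float(p_ts), float(p_tv)


# index = base code; value = code of its transition partner (A<->G, C<->T)
_TS_PARTNER = np.array([2, 3, 0, 1])
# the two transversion partners per base
_TV_PARTNERS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])


def evolve_sequence(
    seq: str,
    expected_divergence: float,
    kappa: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> str:
    """Mutate ``seq`` under a K2P process to a given expected divergence.

    ``expected_divergence`` is the expected number of substitutions per site
    (branch length); sites change state with the exact continuous-time K2P
    transition probabilities, so the K2P distance estimator applied to
    input/output pairs is asymptotically unbiased for this value.  Length is
    preserved (substitution-only process); non-ACGT symbols are left as-is.
    """
    if expected_divergence < 0:
        raise ValueError("divergence must be >= 0")
    if expected_divergence == 0:
        return seq
    rng = _as_rng(seed)
    codes = encode(seq).copy()
    valid = codes < 4
    p_ts, p_tv = _k2p_probs(expected_divergence, kappa)
    u = rng.random(len(codes))
    ts = valid & (u < p_ts)
    tv1 = valid & (u >= p_ts) & (u < p_ts + p_tv)
    tv2 = valid & (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    out = codes.copy()
    out[ts] = _TS_PARTNER[codes[ts]]
    out[tv1] = _TV_PARTNERS[codes[tv1], 0]
    out[tv2] = _TV_PARTNERS[codes[tv2], 1]
    chars = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    chars[valid] = lut[out[valid]]
    return chars.tobytes().decode("ascii")


def plant_copies(
    genome_length: int,
    gc: float,
    element: ElementModel | list[ElementModel],
    ages: list[float],
    rate: float,
    kappa: float = 2.0,
    seed: int | np.random.Generator = 0,
    tsd: str = "TA",
    contig_id: str = "contig_1",
    class_truth: str | None = None,
    strands: str = "both",
    min_spacing: int = 300,
    max_retries: int = 200,
) -> tuple[tuple[str, str], SimTruth]:
    """Plant evolved element copies into a random genome background.

    Each copy is evolved from the element with expected divergence
    ``2 * rate * age`` and inserted at a random position flanked by a
    duplicated target site (default TA).  Returns a ``(contig_id, sequence)``
    record and the truth table; truth intervals slice the final genome to
    exactly the planted (mutated) copy sequence.

    A list of element models (e.g. the full-length element plus its MITE
    derivative) is cycled over the copies, so mixed families can be planted
    into one genome.
    """
    rng = _as_rng(seed)
    elements = element if isinstance(element, list) else [element]
    total = sum(
        len(elements[i % len(elements)].sequence) + 2 * len(tsd)
        for i in range(len(ages))
    )
    if total >= genome_length / 2:
        raise ValueError("planted copies would exceed half the genome")
    background = random_sequence(genome_length, gc, rng)

    # Insertion points are spliced between background bases, so copies can
    # never overlap; the spacing floor keeps distinct copies from being
    # merged into one locus downstream.
    points: list[int] = []
    margin = max(min_spacing, 10)
    for _ in ages:
        for _try in range(max_retries):
            p = int(rng.integers(margin, genome_length - margin))
            if all(abs(p - q) > margin for q in points):
                points.append(p)
                break
        else:
            raise RuntimeError("could not place copies without overlap")
    order = np.argsort(points)

    pieces: list[str] = []
    truth = SimTruth()
    prev = 0
    offset = 0
    for idx in order:
        p = points[idx]
        age = ages[idx]
        elem = elements[idx % len(elements)]
        cls = class_truth or ("mite" if elem.is_mite else "full_length")
        copy = evolve_sequence(elem.sequence, 2.0 * rate * age, kappa, rng)
        strand = "+"
        if strands == "both" and rng.random() < 0.5:
            strand = "-"
        ins = copy if strand == "+" else revcomp(copy)
        pieces.append(background[prev:p])
        offset += p - prev
        pieces.append(tsd)
        offset += len(tsd)
        start = offset
        pieces.append(ins)
        offset += len(ins)
        truth.rows.append(
            TruthRow(
                f"copy_{idx:04d}", contig_id, start, offset, strand,
                float(age), cls, elem.element_id,
            )
        )
        pieces.append(tsd)
        offset += len(tsd)
        prev = p
    pieces.append(background[prev:])
    genome = "".join(pieces)
    truth.rows.sort(key=lambda r: r.start)
    return (contig_id, genome), truth


@dataclass
class HtScenario:
    """Everything a two-lineage transfer experiment needs, with truth."""

    config: ScenarioConfig
    genomes: dict[str, tuple[str, str]]  # lineage -> (contig_id, sequence)
    truth: dict[str, SimTruth]
    element_ancestor: ElementModel
    lineage_elements: dict[str, ElementModel]
    ortholog_pairs: list[tuple[str, str, str]]  # (gene_id, seq_A, seq_B)
    is_ht: bool


def simulate_ht_scenario(config: ScenarioConfig) -> HtScenario:
    """Simulate a vertical-vs-horizontal element invasion of two lineages.

    Orthologous genes diverge by ``2 * rate * td`` scaled by a per-gene
    lognormal rate multiplier.  The element lineages diverge by
    ``2 * rate * min(th_a, th_b)``: for a transfer that is the transfer age,
    for the vertical control (th = td) it equals the gene expectation.  Each
    lineage's copies then diverge from its own element master by
    ``2 * rate * th`` — so consensus reconstruction and T = k/2r dating
    recover the invasion ages, and the consensus-vs-consensus distance
    carries the transfer signal.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    ancestor = make_ancestral_element(cfg.element_length, cfg.tir_length, rng)
    t_elem = min(cfg.th_a, cfg.th_b)
    is_ht = t_elem < cfg.td

    genomes: dict[str, tuple[str, str]] = {}
    truth: dict[str, SimTruth] = {}
    masters: dict[str, ElementModel] = {}
    for lineage, th in (("A", cfg.th_a), ("B", cfg.th_b)):
        master_seq = evolve_sequence(
            ancestor.sequence, cfg.rate * t_elem, cfg.kappa, rng
        )
        master = replace(ancestor, element_id=f"element_{lineage}", sequence=master_seq)
        masters[lineage] = master
        rec, tr = plant_copies(
            cfg.genome_length,
            cfg.gc,
            master,
            [th] * cfg.n_copies,
            cfg.rate,
            cfg.kappa,
            rng,
            contig_id=f"contig_{lineage}",
        )
        genomes[lineage] = rec
        truth[lineage] = tr

    pairs: list[tuple[str, str, str]] = []
    for g in range(cfg.n_ortholog_pairs):
        gene = random_sequence(cfg.gene_length, cfg.gc, rng)
        mult = float(rng.lognormal(0.0, cfg.rate_sigma))
        d_half = cfg.rate * cfg.td * mult
        a = evolve_sequence(gene, d_half, cfg.kappa, rng)
        b = evolve_sequence(gene, d_half, cfg.kappa, rng)
        pairs.append((f"gene_{g:03d}", a, b))

    return HtScenario(cfg, genomes, truth, ancestor, masters, pairs, is_ht)


def read_scenario_config(path) -> ScenarioConfig:
    """Read a flat key=value scenario config file."""
    kw = {}
    casts = {f.name: f.type for f in ScenarioConfig.__dataclass_fields__.values()}
    ints = {"n_copies", "n_ortholog_pairs", "genome_length", "gene_length",
            "element_length", "tir_length", "seed"}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            if key not in casts:
                raise ValueError(f"unknown scenario key {key!r}")
            kw[key] = int(val) if key in ints else float(val)
    return ScenarioConfig(**kw)
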