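"""End-to-end orchestration: mine -> annotate -> consensus -> date -> HT test.

Given per-species genome FASTAs and a query TE consensus, each genome is
screened for copies, copies are structurally annotated and classified,
a per-species majority consensus is reconstructed, copy ages are estimated
with T = k/2r, and (when ortholog pairs are supplied) the cross-species
horizontal-transfer quantile test is run on the consensus distances.

The JSON report is the machine-readable surface; TSV/FASTA/BED artifacts
are written alongside for inspection.  The run is fully deterministic for a
given config: rerunning into a fresh directory reproduces every file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .io import ensure_dir, read_fasta, read_flat_config, write_fasta
from .mining import (
    SearchParams,
    extract_copies,
    merge_hits,
    seed_and_extend_search,
    write_bed,
    write_copies_fasta,
    write_hits_tsv,
)
from .annotate import annotate_copy, write_annotations_tsv
from .consensus import (
    build_majority_consensus,
    consensus_matrix,
    divergence_table,
    global_affine_align,
    k2p_distance,
    nj_tree,
    write_divergence_tsv,
)
from .dating import (
    RateTable,
    age_from_divergence,
    age_histogram_peaks,
    ht_quantile_test,
    write_ages_tsv,
)

log = logging.getLogger("tepaleo")

#: Size-class -> census-table column (partial / non_autonomous / full_length)
_SIZE_TO_COLUMN = {
    "partial_size": "partial",
    "mite": "non_autonomous",
    "full_length": "full_length",
}


@dataclass
class PipelineConfig:
    genomes: dict[str, str]  # species_id -> FASTA path
    query_path: str
    out_dir: str
    ortholog_pairs: dict[str, tuple[str, str]] = field(default_factory=dict)
    # key "A,B" -> (fasta for species A genes, fasta for species B genes)
    rates: RateTable = field(default_factory=RateTable)
    default_rate: float = 1.9e-3
    search: SearchParams = field(default_factory=SearchParams)
    merge_max_gap: int = 100
    flank: int = 200
    min_orf_aa: int = 300
    bin_width: float = 6.25
    ht_threshold: float = 0.90
    ht_lower: float = 0.25
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Flat key=value config; genome.<species>=path, orthologs.<A,B>=pA;pB."""
        raw = read_flat_config(path)
        genomes: dict[str, str] = {}
        orthologs: dict[str, tuple[str, str]] = {}
        kw: dict = {}
        for key, val in raw.items():
            if key.startswith("genome."):
                genomes[key.split(".", 1)[1]] = val
            elif key.startswith("orthologs."):
                a, _, b = val.partition(";")
                orthologs[key.split(".", 1)[1]] = (a.strip(), b.strip())
            elif key == "query":
                kw["query_path"] = val
            elif key == "out_dir":
                kw["out_dir"] = val
            elif key in ("merge_max_gap", "flank", "min_orf_aa", "seed"):
                kw[key] = int(val)
            elif key in ("bin_width", "ht_threshold", "ht_lower", "default_rate"):
                kw[key] = float(val)
            elif key == "evalue_max":
                kw.setdefault("_search", {})["evalue_max"] = float(val)
            elif key == "word_size":
                kw.setdefault("_search", {})["word_size"] = int(val)
            else:
                raise ValueError(f"unknown config key {key!r}")
        search = SearchParams(**kw.pop("_search", {}))
        if not genomes:
            raise ValueError("config lists no genomes")
        return cls(genomes=genomes, ortholog_pairs=orthologs, search=search, **kw)


@dataclass
class SpeciesReport:
    """Per-species census in the shape of the published summary table."""

    species_id: str
    n_copies: int
    table_counts: dict[str, int]  # partial / non_autonomous / full_length
    functional_counts: dict[str, int]
    mite_fraction: float  # non_autonomous / total, in [0, 1]
    consensus_length: int | None = None
    mean_k2p: float | None = None
    n_saturated: int = 0
    age_peaks_my: list[float] = field(default_factory=list)
    rate: float | None = None

    def __post_init__(self) -> None:
        if sum(self.table_counts.values()) != self.n_copies:
            raise ValueError("class counts do not sum to the copy total")

    @classmethod
    def from_counts(
        cls, species_id: str, partial: int, non_autonomous: int, full_length: int
    ) -> "SpeciesReport":
        total = partial + non_autonomous + full_length
        frac = non_autonomous / total if total else 0.0
        return cls(
            species_id,
            total,
            {
                "partial": partial,
                "non_autonomous": non_autonomous,
                "full_length": full_length,
            },
            {},
            frac,
        )

    @property
    def mite_percent(self) -> float:
        """Human-readable MITE share, rounded to 0.1%."""
        return round(100.0 * self.mite_fraction, 1)


def summarize_species(
    annotations, divergences=None, ages=None, species_id: str = "species",
    consensus_length: int | None = None, rate: float | None = None,
    bin_width: float = 6.25,
) -> SpeciesReport:
    """Collapse per-copy annotations into the census-table row."""
    table = {"partial": 0, "non_autonomous": 0, "full_length": 0}
    functional: dict[str, int] = {}
    for a in annotations:
        table[_SIZE_TO_COLUMN[a.size_class]] += 1
        functional[a.functional_class] = functional.get(a.functional_class, 0) + 1
    total = len(annotations)
    mean_k = None
    n_sat = 0
    if divergences:
        ks = [d.k2p for d in divergences if not d.saturated]
        n_sat = sum(d.saturated for d in divergences)
        mean_k = float(np.mean(ks)) if ks else None
    peaks: list[float] = []
    if ages:
        peaks = age_histogram_peaks(ages, bin_width, species_id).peak_ages
    return SpeciesReport(
        species_id,
        total,
        table,
        functional,
        (table["non_autonomous"] / total) if total else 0.0,
        consensus_length,
        mean_k,
        n_sat,
        peaks,
        rate,
    )


def _report_to_json(obj) -> dict:
    d = asdict(obj)
    return d


def run_species(
    species_id: str,
    genome: dict[str, str],
    query: str,
    config: PipelineConfig,
    out: Path,
):
    """All within-genome stages for one species.  Returns
    (report, copies, profile, divergences, ages)."""
    hsps = seed_and_extend_search(query, genome, config.search)
    log.info("%s: %d HSPs at E<=%g", species_id, len(hsps), config.search.evalue_max)
    loci = merge_hits(hsps, config.merge_max_gap)
    copies = extract_copies(genome, loci, config.flank)
    log.info("%s: %d loci after merging", species_id, len(copies))
    write_hits_tsv(hsps, out / f"{species_id}.hits.tsv")
    write_bed(loci, out / f"{species_id}.loci.bed")
    write_copies_fasta(copies, out / f"{species_id}.copies.fasta")

    annotations = [annotate_copy(c, min_aa=config.min_orf_aa) for c in copies]
    write_annotations_tsv(annotations, out / f"{species_id}.annotations.tsv")

    profile = None
    divergences = []
    ages: list[float] = []
    rate = config.rates.rates.get(species_id, config.default_rate)
    if copies:
        profile = build_majority_consensus(copies, query, species_id)
        write_fasta({f"{species_id}_consensus": profile.sequence},
                    out / f"{species_id}.consensus.fasta")
        divergences = divergence_table(copies, profile)
        write_divergence_tsv(divergences, out / f"{species_id}.divergence.tsv")
        dated = [(d.copy_id, age_from_divergence(d.k2p, rate))
                 for d in divergences if not d.saturated]
        ages = [a for _, a in dated]
        write_ages_tsv([c for c, _ in dated], ages, out / f"{species_id}.ages.tsv")

    report = summarize_species(
        annotations, divergences, ages, species_id,
        consensus_length=len(profile.sequence) if profile else None,
        rate=rate, bin_width=config.bin_width,
    )
    return report, copies, profile, divergences, ages


def _gene_distances(fasta_a, fasta_b) -> list[float]:
    genes_a = read_fasta(fasta_a)
    genes_b = read_fasta(fasta_b)
    shared = sorted(set(genes_a) & set(genes_b))
    if len(shared) < 2:
        raise ValueError("fewer than two shared ortholog ids")
    out = []
    for g in shared:
        a, b = genes_a[g], genes_b[g]
        if len(a) == len(b):
            out.append(k2p_distance(a, b))
        else:
            aln = global_affine_align(a, b, mode="global")
            out.append(k2p_distance(aln.aligned_a, aln.aligned_b))
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage for every genome; returns the machine report dict.

    A genome with zero hits yields an empty-but-valid species entry.  The
    report, all artifacts, and the run log land under ``config.out_dir``.
    """
    out = ensure_dir(config.out_dir)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("tepaleo %s seed=%d", __version__, config.seed)
        log.info("params: %s", config.search)
        query_records = read_fasta(config.query_path)
        query = next(iter(query_records.values()))

        species_reports: dict[str, dict] = {}
        profiles = []
        for species_id in sorted(config.genomes):
            genome = read_fasta(config.genomes[species_id])
            report, _copies, profile, _div, _ages = run_species(
                species_id, genome, query, config, out
            )
            if profile is not None:
                profiles.append(profile)
            species_reports[species_id] = _report_to_json(report)

        cross: dict = {}
        if len(profiles) >= 2:
            dm = consensus_matrix(profiles)
            dm.to_tsv(out / "consensus_k2p.tsv")
            cross["consensus_k2p"] = {
                "labels": dm.labels,
                "values": dm.values.tolist(),
            }
            if len(profiles) >= 3:
                newick = nj_tree(dm)
                (out / "consensus_nj.nwk").write_text(newick + "\n")
                cross["nj_tree"] = newick
            ht_results = {}
            for pair_key, (fa, fb) in sorted(config.ortholog_pairs.items()):
                a, b = [s.strip() for s in pair_key.split(",")]
                te_d = dm.get(a, b)
                gene_d = _gene_distances(fa, fb)
                res = ht_quantile_test(te_d, gene_d, config.ht_threshold, config.ht_lower)
                res.to_json(out / f"httest.{a}-{b}.json")
                ht_results[pair_key] = asdict(res)
                log.info("HT test %s: fraction_greater=%.3f call=%s",
                         pair_key, res.fraction_greater, res.call)
            if ht_results:
                cross["ht_tests"] = ht_results

        report = {
            "version": __version__,
            "seed": config.seed,
            "species": species_reports,
            "cross_species": cross,
        }
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        return report
    finally:
        log.removeHandler(handler)
        handler.close()
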