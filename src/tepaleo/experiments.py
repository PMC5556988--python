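"""Ground-truth validation experiments on simulated genomes.

Each experiment wires the simulator to the full analysis chain and measures
how well a known quantity is recovered: mining recall against planted
truth, burst-age recovery through consensus + K2P dating, transfer-vs-
vertical discrimination of the HT quantile test, and MITE classification.
These drive both the acceptance checks and the reproduction script.

Problem sizes are desk-scale by design: a 5-Mb genome with 200 copies for
recall, 50-copy bursts for dating, 120-kb two-lineage scenarios for the
transfer replicates.
"""

from __future__ import annotations

import numpy as np

from .annotate import annotate_copy
from .consensus import build_majority_consensus, divergence_table, k2p_distance
from .dating import age_from_divergence, age_histogram_peaks, ht_quantile_test
from .mining import extract_copies, merge_hits, seed_and_extend_search
from .simulate import (
    ScenarioConfig,
    derive_mite,
    make_ancestral_element,
    plant_copies,
    random_sequence,
    simulate_ht_scenario,
)


def _overlap(a0, a1, b0, b1) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def mine_genome(query: str, genome: dict[str, str], max_gap: int = 100):
    hsps = seed_and_extend_search(query, genome)
    loci = merge_hits(hsps, max_gap)
    return extract_copies(genome, loci)


def mining_recall_experiment(
    seed: int,
    genome_length: int = 5_000_000,
    n_copies: int = 200,
    max_divergence: float = 0.25,
    rate: float = 1.9e-3,
    min_overlap: float = 0.8,
) -> dict:
    """Recall of planted copies (3:1 full-length:MITE, divergences up to
    ``max_divergence``) as loci overlapping truth by >= ``min_overlap``."""
    rng = np.random.default_rng(seed)
    element = make_ancestral_element(1300, 28, rng)
    mite = derive_mite(element, 275, 275)
    max_age = max_divergence / (2 * rate)
    ages = list(np.linspace(0.0, max_age, n_copies))
    (cid, g), truth = plant_copies(
        genome_length, 0.42, [element, element, element, mite], ages, rate, seed=rng
    )
    hsps = seed_and_extend_search(element.sequence, {cid: g})
    loci = merge_hits(hsps)
    recovered = 0
    for r in truth:
        span = r.end - r.start
        if any(
            l.contig_id == r.contig_id
            and _overlap(l.start, l.end, r.start, r.end) >= min_overlap * span
            for l in loci
        ):
            recovered += 1
    return {
        "n_planted": len(truth),
        "n_loci": len(loci),
        "n_recovered": recovered,
        "recall": recovered / len(truth),
    }


def null_search_experiment(
    seed: int, n_genomes: int = 20, genome_length: int = 1_000_000
) -> dict:
    """Total HSPs at E<=1e-10 across unplanted random genomes."""
    rng = np.random.default_rng(seed)
    element = make_ancestral_element(1300, 28, rng)
    total = 0
    for _ in range(n_genomes):
        g = random_sequence(genome_length, 0.42, rng)
        total += len(seed_and_extend_search(element.sequence, {"c": g}))
    return {"n_genomes": n_genomes, "n_hits": total}


def burst_recovery_experiment(
    seed: int,
    true_age: float = 30.0,
    n_copies: int = 50,
    rate: float = 1.9e-3,
    genome_length: int = 300_000,
    bin_width: float = 6.25,
) -> dict:
    """Recover a single amplification burst's age through the full chain:
    plant -> mine -> consensus -> K2P -> T = k/2r -> histogram peaks."""
    rng = np.random.default_rng(seed)
    element = make_ancestral_element(1300, 28, rng)
    (cid, g), truth = plant_copies(
        genome_length, 0.42, element, [true_age] * n_copies, rate, seed=rng
    )
    copies = mine_genome(element.sequence, {cid: g})
    profile = build_majority_consensus(copies, element.sequence)
    records = divergence_table(copies, profile)
    ages = [
        age_from_divergence(r.k2p, rate) for r in records if not r.saturated
    ]
    dist = age_histogram_peaks(ages, bin_width)
    sem = float(np.std(ages, ddof=1) / np.sqrt(len(ages)))
    return {
        "true_age": true_age,
        "n_copies_mined": len(copies),
        "mean_age": float(np.mean(ages)),
        "sem": sem,
        "peak_bins": dist.peak_bins,
        "peak_contains_truth": any(
            dist.bin_edges[i] <= true_age < dist.bin_edges[i + 1]
            for i in dist.peak_bins
        ),
        "n_peaks": len(dist.peak_bins),
    }


def ht_replicates_experiment(
    seed: int,
    n_replicates: int = 20,
    td: float = 90.0,
    th: float = 25.0,
    vertical: bool = False,
    rate: float = 1.9e-3,
) -> dict:
    """Fraction of replicates called HT by the quantile test.

    Each replicate simulates a two-lineage scenario (invasion age ``th`` in
    lineage B, or ``td`` for the vertical control), mines both genomes,
    rebuilds both consensus elements, and compares their K2P distance with
    the 50 ortholog-pair distances.
    """
    th_b = td if vertical else th
    calls = []
    fractions = []
    for rep in range(n_replicates):
        cfg = ScenarioConfig(
            td=td, th_a=td, th_b=th_b, rate=rate, seed=seed + rep
        )
        sc = simulate_ht_scenario(cfg)
        profiles = {}
        for lineage, (cid, g) in sc.genomes.items():
            copies = mine_genome(sc.element_ancestor.sequence, {cid: g})
            profiles[lineage] = build_majority_consensus(
                copies, sc.element_ancestor.sequence, lineage
            )
        from .consensus import global_affine_align

        aln = global_affine_align(
            profiles["A"].sequence, profiles["B"].sequence, mode="semiglobal"
        )
        te_d = k2p_distance(aln.aligned_a, aln.aligned_b)
        gene_d = [k2p_distance(a, b) for _, a, b in sc.ortholog_pairs]
        res = ht_quantile_test(te_d, gene_d)
        calls.append(res.call)
        fractions.append(res.fraction_greater)
    return {
        "n_replicates": n_replicates,
        "n_ht_calls": sum(c == "HT" for c in calls),
        "ht_call_rate": sum(c == "HT" for c in calls) / n_replicates,
        "mean_fraction_greater": float(np.mean(fractions)),
        "calls": calls,
    }


def mite_classification_experiment(
    seed: int,
    n_copies: int = 40,
    max_divergence: float = 0.15,
    rate: float = 1.9e-3,
    genome_length: int = 400_000,
) -> dict:
    """Mine and classify a planted MITE family with divergences up to
    ``max_divergence``.

    Reports the unconditional rate at which planted MITEs come back as
    potential_non_autonomous, and the rate conditional on the copy's TIRs
    remaining detectable (TIR decay, not classification, is the binding
    factor at high divergence: the detector compares two independently
    diverged termini).
    """
    rng = np.random.default_rng(seed)
    element = make_ancestral_element(1300, 28, rng)
    mite = derive_mite(element, 275, 275)
    max_age = max_divergence / (2 * rate)
    ages = list(np.linspace(0.0, max_age, n_copies))
    (cid, g), truth = plant_copies(
        genome_length, 0.42, mite, ages, rate, seed=rng
    )
    copies = mine_genome(element.sequence, {cid: g})
    annotations = [annotate_copy(c) for c in copies]
    n_with_tir = sum(a.tir is not None for a in annotations)
    n_correct = sum(
        a.functional_class == "potential_non_autonomous" for a in annotations
    )
    n_correct_given_tir = sum(
        a.functional_class == "potential_non_autonomous"
        for a in annotations
        if a.tir is not None
    )
    return {
        "n_planted": len(truth),
        "n_mined": len(copies),
        "n_with_tir": n_with_tir,
        "functional_classes": sorted({a.functional_class for a in annotations}),
        "accuracy_unconditional": n_correct / len(copies) if copies else 0.0,
        "accuracy_given_intact_tirs": (
            n_correct_given_tir / n_with_tir if n_with_tir else 0.0
        ),
    }
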