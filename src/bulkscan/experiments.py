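"""Replicate validation experiments at the study's design conditions.

These functions re-run the full simulate → scan pipeline under the
experimental design the package models (188 F2:11 RILs, extreme bulks of
25, pooled sequencing near 40x) and measure the properties that make the
genome scan trustworthy: false-positive calibration of the null band,
power to recover a major QTL, and fidelity of the inbreeding process
itself.  They are used by both the test suite and the acceptance script.

Genome sizes are scaled to a few chromosomes of tens of Mbp so a full
replicate set runs in minutes on one core; the statistics being checked
(per-window calibration, per-replicate recovery, per-locus heterozygosity)
do not depend on total genome length.
"""

from __future__ import annotations

import numpy as np

from bulkscan import qtlseq_core, simbulk


def null_genome_exceedance(
    seed: int,
    sites_per_chrom: int = 1000,
    n_replicates: int = 10_000,
    depth: float = 40.0,
    bulk_size: int = 25,
    n_lines: int = 188,
) -> float:
    """Fraction of emitted windows whose |mean Δ| exceeds the 99% band on one
    fully null genome (two 30-Mbp / 90-cM chromosomes, no QTL)."""
    gmap = simbulk.evenly_spaced_map(
        [("A01", 30_000_000, 90.0), ("A02", 30_000_000, 90.0)], sites_per_chrom
    )
    cfg = simbulk.SimConfig(
        seed=seed,
        n_lines=n_lines,
        bulk_size=bulk_size,
        depth_mean_high=depth,
        depth_mean_low=depth,
        artifact_fraction=0.0,
    )
    res = simbulk.simulate_dataset(gmap, cfg, qtls=None, env_sd=1.0)
    points = qtlseq_core.snp_index_from_sim_sites(res.sites)
    windows = qtlseq_core.sliding_window_profile(
        points, chrom_lengths={c.name: c.length_bp for c in gmap.chromosomes}
    )
    windows = qtlseq_core.simulate_null_band(
        windows,
        points,
        bulk_size=bulk_size,
        n_replicates=n_replicates,
        seed=int(np.random.SeedSequence([seed, 7]).generate_state(1)[0] % (2**31)),
    )
    return float((windows["mean_delta"].abs() > windows["cutoff_99"]).mean())


def null_calibration(
    n_genomes: int = 20, seed: int = 0, n_replicates: int = 10_000
) -> dict:
    """Mean 99%-band exceedance over replicate null genomes, with its
    between-genome standard error (windows within a genome are correlated,
    so the genome is the Monte-Carlo unit)."""
    child = np.random.SeedSequence(seed).generate_state(n_genomes) % (2**31)
    rates = [
        null_genome_exceedance(int(s), n_replicates=n_replicates) for s in child
    ]
    rates = np.asarray(rates)
    return {
        "rates": rates,
        "mean": float(rates.mean()),
        "se": float(rates.std(ddof=1) / np.sqrt(n_genomes)),
        "n_genomes": n_genomes,
    }


def qtl_recovery(
    n_reps: int = 40,
    seed: int = 0,
    variance_explained: float = 0.45,
    depth: float = 40.0,
    bulk_size: int = 25,
    n_lines: int = 188,
    n_replicates: int = 10_000,
) -> dict:
    """Fraction of replicate pipelines whose top-ranked candidate region
    contains the causal position (one major QTL on a 50-Mbp chromosome plus
    one null 30-Mbp chromosome)."""
    causal_chrom, causal_pos = "A09", 35_000_000
    child = np.random.SeedSequence([seed, 1]).generate_state(n_reps) % (2**31)
    hits, peaks = [], []
    for s in child:
        s = int(s)
        gmap = simbulk.evenly_spaced_map(
            [("A09", 50_000_000, 100.0), ("A03", 30_000_000, 90.0)], 1200
        )
        cfg = simbulk.SimConfig(
            seed=s,
            n_lines=n_lines,
            bulk_size=bulk_size,
            depth_mean_high=depth,
            depth_mean_low=depth,
            artifact_fraction=0.0,
        )
        qtl = simbulk.QTLEffect(
            causal_chrom, causal_pos, variance_explained_target=variance_explained
        )
        res = simbulk.simulate_dataset(gmap, cfg, [qtl], env_sd=1.0)
        points = qtlseq_core.snp_index_from_sim_sites(res.sites)
        windows = qtlseq_core.sliding_window_profile(
            points, chrom_lengths={c.name: c.length_bp for c in gmap.chromosomes}
        )
        windows = qtlseq_core.simulate_null_band(
            windows,
            points,
            bulk_size=bulk_size,
            n_replicates=n_replicates,
            seed=int(np.random.SeedSequence([s, 11]).generate_state(1)[0] % (2**31)),
        )
        regions = qtlseq_core.call_candidate_regions(windows)
        if len(regions) == 0:
            hits.append(False)
            continue
        top = regions.sort_values("peak_delta", ascending=False).iloc[0]
        peaks.append(float(top["peak_delta"]))
        hits.append(
            bool(
                top["chrom"] == causal_chrom
                and top["start"] <= causal_pos <= top["end"]
                and top["peak_delta"] > 0
            )
        )
    return {
        "hits": int(np.sum(hits)),
        "n_reps": n_reps,
        "rate": float(np.mean(hits)),
        "peak_deltas": peaks,
    }


def selfing_fidelity(n_lines: int = 50_000, seed: int = 7) -> dict:
    """Residual heterozygosity and two-locus recombinant fraction at F2:11.

    Closed-form expectations: per-locus heterozygosity (1/2)^g after g
    selfing generations, and RIL recombinant fraction R = 2r/(1+2r) with
    r = (1 - exp(-2d))/2 for loci d Morgans apart (Haldane).
    """
    gmap = simbulk.GeneticMap(
        [simbulk.Chromosome("c1", 1_000_000, 10.0)],
        {"c1": np.array([1, 250_000, 500_000, 750_000, 1_000_000])},
    )
    cfg = simbulk.SimConfig(n_lines=n_lines, bulk_size=10, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    pop = simbulk.simulate_ril_population(gmap, cfg, rng)
    dos = pop.dosage("c1", gmap.marker_sites["c1"])
    het = float(np.mean(dos == 1))
    g = cfg.n_selfing_generations
    # recombinants between the terminal loci, 10 cM apart
    hom = dos != 1
    both = hom[:, 0] & hom[:, -1]
    rec = float(np.mean(dos[both, 0] != dos[both, -1]))
    r = 0.5 * (1 - np.exp(-2 * 0.10))
    return {
        "heterozygosity": het,
        "heterozygosity_expected": 0.5**g,
        "recombinant_fraction": rec,
        "recombinant_fraction_expected": float(2 * r / (1 + 2 * r)),
        "n_lines": n_lines,
    }
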