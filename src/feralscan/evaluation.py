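"""Benchmark suites on synthetic ground-truth worlds.

Each function builds the study-shaped synthetic inputs, runs the relevant
pipeline stage, and measures recovery against the generator's truth set.
They are used by the test suite and the reproduction script; sizes are
desk-scale versions of the study design (two groups of ~50, thousands of
sites, 100-permutation nulls).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from feralscan import anchor as anchor_mod
from feralscan import depth as depth_mod
from feralscan import gwas as gwas_mod
from feralscan import scan as scan_mod
from feralscan import synthetic as synth_mod
from feralscan import te as te_mod
from feralscan.variants import build_windows

__all__ = [
    "scan_power_null",
    "pav_cnv_recovery",
    "te_confusion",
    "mlm_null_calibration",
    "variance_explained_recovery",
    "anchor_recovery",
]


def _scan_config(delta: float, seed: int) -> synth_mod.CohortConfig:
    return synth_mod.CohortConfig(
        n_per_group={"DE": 50, "DO": 50},
        chromosomes=[("chr1A", 2_500_000), ("chr1D", 2_500_000)],
        n_sites=5_000,
        divergent_windows=(
            [("chr1A", 1_000_000, 1_100_000, delta)] if delta > 0 else []
        ),
        seed=seed,
    )


def scan_power_null(n_seeds: int = 20, delta: float = 0.8, n_perm: int = 100,
                    base_seed: int = 0) -> dict:
    """Power and null calibration of the windowed F_ST scan.

    Power: over ``n_seeds`` cohorts with one divergent 100 kb window
    (frequency shift ``delta``), count how often that window reaches the
    top-5% threshold of its subgenome partition.  Null: over ``n_seeds``
    cohorts with no divergence, count how often the observed genome-wide
    maximum falls inside the range of ``n_perm`` label-shuffling maxima.
    """
    grid = build_windows({"chr1A": 2_500_000, "chr1D": 2_500_000}, 100_000)
    power_hits = 0
    for seed in range(n_seeds):
        table, frame, _ = synth_mod.generate_cohort(_scan_config(delta, base_seed + seed))
        g1 = frame.loc[frame["group"] == "DE", "sample"].tolist()
        g2 = frame.loc[frame["group"] == "DO", "sample"].tolist()
        track = scan_mod.windowed_fst(table, g1, g2, grid)
        _, thresholds = scan_mod.candidate_regions(track, "fst")
        target = track[
            (track["chrom"] == "chr1A") & (track["start"] == 1_000_000)
        ]["fst"].iloc[0]
        if target >= thresholds["AB"]:
            power_hits += 1

    null_within = 0
    for seed in range(n_seeds):
        table, frame, _ = synth_mod.generate_cohort(_scan_config(0.0, base_seed + 1_000 + seed))
        g1 = frame.loc[frame["group"] == "DE", "sample"].tolist()
        g2 = frame.loc[frame["group"] == "DO", "sample"].tolist()
        track = scan_mod.windowed_fst(table, g1, g2, grid)
        obs_max = float(np.nanmax(track["fst"]))
        perm = scan_mod.permutation_max_fst(
            table, g1, g2, grid, n_perm=n_perm, seed=base_seed + seed
        )
        null_max = perm[[c for c in perm.columns if c.startswith("max_fst")]].max(axis=1)
        if null_max.min() <= obs_max <= null_max.max():
            null_within += 1

    return {"power_hits": power_hits, "null_within": null_within, "n_seeds": n_seeds}


def pav_cnv_recovery(mean_cov: float = 10.0, seed: int = 0) -> dict:
    """PAV window recovery (noise-free and Poisson) and CNV-index signs.

    The world carries grid-aligned deletions separated by well over the
    10 kb merge gap, so noise-free region calls must match the truth
    intervals exactly; with Poisson depth noise at ``mean_cov`` the
    window-level F1 is reported.  CNV-index sign is checked on every truth
    window of a DE-carrier cohort.
    """
    deletions = [
        synth_mod.DeletionTruth("chr1A", 100_000, 150_000, "SELF", 1.0),
        synth_mod.DeletionTruth("chr1A", 300_000, 320_000, "SELF", 1.0),
        synth_mod.DeletionTruth("chr1A", 700_000, 780_000, "SELF", 1.0),
    ]
    cfg = synth_mod.CohortConfig(
        n_per_group={"SELF": 1, "OTHER": 1},
        chromosomes=[("chr1A", 1_000_000)],
        n_sites=10,
        deletions=deletions,
        seed=seed,
    )
    table, frame, truth = synth_mod.generate_cohort(cfg)
    grid = build_windows({"chr1A": 1_000_000}, 5_000)
    carrier = sorted(truth.deletions[0][1])[0]

    truth_windows = np.zeros(grid.n_windows, dtype=bool)
    for deletion, _ in truth.deletions:
        on = (
            (grid.windows["chrom"] == deletion.chrom)
            & (grid.windows["start"] >= deletion.start)
            & (grid.windows["end"] <= deletion.end)
        ).to_numpy()
        truth_windows |= on

    def region_calls(noise, sd):
        dm = synth_mod.generate_depth_matrix(
            [carrier], truth, grid, mean_cov, noise=noise, seed=sd
        )
        ncn_other = dm.depth[0] / mean_cov
        return depth_mod.call_pav_regions(np.ones(grid.n_windows), ncn_other, grid)

    calls_nf = region_calls("none", seed)
    truth_intervals = {(d.start, d.end) for d, _ in truth.deletions}
    called_intervals = {(c.start, c.end) for c in calls_nf}
    tp = len(truth_intervals & called_intervals)
    precision_nf = tp / len(called_intervals) if called_intervals else 0.0
    recall_nf = tp / len(truth_intervals)

    dm = synth_mod.generate_depth_matrix(
        [carrier], truth, grid, mean_cov, noise="poisson", seed=seed + 1
    )
    ncn_other = dm.depth[0] / mean_cov
    selected = (np.ones(grid.n_windows) > 0.8) & (ncn_other < 0.2)
    tp = int((selected & truth_windows).sum())
    fp = int((selected & ~truth_windows).sum())
    fn = int((~selected & truth_windows).sum())
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0

    # CNV-index sign on a DE-carrier cohort
    cfg2 = synth_mod.CohortConfig(
        n_per_group={"DE": 25, "DO": 25},
        chromosomes=[("chr1A", 1_000_000)],
        n_sites=10,
        deletions=[synth_mod.DeletionTruth("chr1A", 300_000, 400_000, "DE", 1.0)],
        seed=seed + 2,
    )
    t2, frame2, truth2 = synth_mod.generate_cohort(cfg2)
    grid100 = build_windows({"chr1A": 1_000_000}, 100_000)
    dm2 = synth_mod.generate_depth_matrix(
        t2.samples, truth2, grid100, mean_cov, seed=seed + 3
    )
    ncn2, kept = depth_mod.normalize_depth(dm2)
    de = frame2.loc[frame2["group"] == "DE", "sample"].tolist()
    do = frame2.loc[frame2["group"] == "DO", "sample"].tolist()
    cnv = depth_mod.cnv_index(ncn2, kept, de, do, grid100)
    on_truth = (
        (cnv["start"] >= 300_000) & (cnv["end"] <= 400_000)
    ).to_numpy()
    sign_ok = bool((cnv.loc[on_truth, "cnv_index"] > 0).all())

    return {
        "precision_noise_free": precision_nf,
        "recall_noise_free": recall_nf,
        "f1_noisy": f1,
        "cnv_sign_ok": sign_ok,
        "n_truth_windows": int(truth_windows.sum()),
    }


def te_confusion(seed: int = 0) -> dict:
    """Confusion-matrix accuracy of the TE genotyper on noise-free
    evidence, plus the two strict boundary behaviours."""
    cfg = synth_mod.CohortConfig(
        n_per_group={"DE": 20, "DO": 20},
        chromosomes=[("chr5A", 700_000_000)],
        n_sites=10,
        te=synth_mod.TeTruth("chr5A", 650_129_563, carrier_group="DE",
                             carrier_fraction=0.6),
        seed=seed,
    )
    table, frame, truth = synth_mod.generate_cohort(cfg)
    rng = np.random.default_rng(seed + 1)
    ref = synth_mod.random_dna(rng, 1200)
    offset = 650_129_563 - 600
    recs = synth_mod.generate_te_alignments(table.samples, truth, ref, offset,
                                            seed=seed + 2)
    no_evidence = table.samples[-1]
    recs[no_evidence] = []
    calls, _ = te_mod.genotype_cohort(
        recs, 650_129_563, truth.te_seq, ref, offset, rname="chr5A"
    )
    correct = 0
    for c in calls:
        if c.sample == no_evidence:
            expected = "unknown"
        elif c.sample in truth.te_carriers:
            expected = "insertion"
        else:
            expected = "non_insertion"
        correct += c.call == expected
    accuracy = correct / len(calls)

    # boundary cases: exactly two perfect reads; exactly 10 bp clip match
    site = 650_129_563
    span = te_mod.AlignmentRecord(
        "chr5A", site - 20, "40M", ref[site - 20 - offset : site + 20 - offset]
    )
    two_perfect = te_mod.classify_sample([span, span], site, truth.te_seq, ref, offset)
    m = 40
    clip10 = te_mod.AlignmentRecord(
        "chr5A", site - m, f"{m}M10S",
        ref[site - m - offset : site - offset] + truth.te_seq[:10],
    )
    ten_bp = te_mod.classify_sample([clip10, span], site, truth.te_seq, ref, offset)
    eleven = te_mod.AlignmentRecord(
        "chr5A", site - m, f"{m}M11S",
        ref[site - m - offset : site - offset] + truth.te_seq[:11],
    )
    eleven_bp = te_mod.classify_sample([eleven], site, truth.te_seq, ref, offset)

    return {
        "accuracy": accuracy,
        "n_samples": len(calls),
        "two_perfect_is_non_insertion": two_perfect.call == "non_insertion",
        "ten_bp_clip_is_unknown": ten_bp.call == "unknown",
        "eleven_bp_clip_is_insertion": eleven_bp.call == "insertion",
    }


def mlm_null_calibration(n_markers: int = 200, n_samples: int = 80, seed: int = 0) -> dict:
    """Type-I error of the mixed model at alpha = 0.05 on null markers."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, size=n_markers)
    dosage = 2 * (rng.random((n_samples, n_markers)) < p).astype(np.int8)
    variants = pd.DataFrame(
        {
            "chrom": ["chr1A"] * n_markers,
            "pos": np.arange(1, n_markers + 1) * 100,
            "ref": ["A"] * n_markers,
            "alt": ["T"] * n_markers,
        }
    )
    from feralscan.variants import GenotypeTable

    table = GenotypeTable(variants=variants, dosage=dosage,
                          samples=[f"s{i}" for i in range(n_samples)])
    y = rng.normal(size=n_samples)
    K = gwas_mod.kinship_matrix(table)
    assoc = gwas_mod.mlm_association(table, y, None, K)
    rate = float((assoc["p"] < 0.05).mean())
    return {"type1_rate": rate, "n_markers": n_markers}


def variance_explained_recovery(planted: float = 0.75, n_seeds: int = 50,
                                n_samples: int = 102, base_seed: int = 0) -> dict:
    """Mean recovered marker partial R^2 against the planted fraction."""
    estimates = []
    for seed in range(n_seeds):
        rng = np.random.default_rng(base_seed + seed)
        x = np.repeat([0.0, 2.0], n_samples // 2)
        rng.shuffle(x)
        signal = (x - x.mean()) / x.std()
        noise = rng.normal(size=n_samples)
        noise = (noise - noise.mean()) / noise.std()
        y = np.sqrt(planted) * signal + np.sqrt(1.0 - planted) * noise
        estimates.append(
            gwas_mod.variance_explained(x, y, None, np.eye(n_samples))
        )
    return {
        "ve_mean": float(np.mean(estimates)),
        "ve_planted": planted,
        "n_seeds": n_seeds,
    }


def anchor_recovery(seed: int = 17) -> dict:
    """Placement recovery on a 20-scaffold 3-chromosome world, the
    21-vs-22 read chrUn boundary, and the pseudomolecule length identity."""
    ref, scaffolds, truth = synth_mod.generate_scaffold_world(seed=seed)
    placements = anchor_mod.anchor_scaffolds(scaffolds, ref)
    recovered = 0
    order_ok = True
    for _, row in placements.iterrows():
        chrom, off, strand = truth.placements[row["scaffold"]]
        ok = row["chrom"] == chrom and (chrom == "chrUn" or row["orientation"] == strand)
        recovered += ok
    for chrom in {c for c, _, _ in truth.placements.values() if c != "chrUn"}:
        sub = placements[placements["chrom"] == chrom].sort_values("position")
        true_order = [s for _, s in sorted((truth.placements[s][1], s) for s in sub["scaffold"])]
        order_ok &= list(sub["scaffold"]) == true_order

    def fake_hits(n):
        return pd.DataFrame(
            {
                "chrom": ["chr1A"] * n,
                "ordinal": range(n),
                "mate": 0,
                "offset": np.arange(n) * 500,
                "pos": np.arange(n) * 500,
                "strand": ["+"] * n,
            }
        )

    boundary_21 = anchor_mod.assign_chromosome(fake_hits(21))[0] == "chrUn"
    boundary_22 = anchor_mod.assign_chromosome(fake_hits(22))[0] == "chr1A"

    seqs, _ = anchor_mod.build_pseudomolecules(placements, scaffolds, gap=300)
    placed = placements[placements["chrom"] != "chrUn"]
    expected_len = placed["scaffold"].map(lambda s: len(scaffolds[s])).sum() + 300 * (
        len(placed) - placed["chrom"].nunique()
    )
    length_ok = sum(len(s) for c, s in seqs.items() if c != "chrUn") == expected_len

    return {
        "recovered": int(recovered),
        "n_scaffolds": len(placements),
        "order_ok": bool(order_ok),
        "boundary_21_chrun": bool(boundary_21),
        "boundary_22_assigned": bool(boundary_22),
        "length_identity": bool(length_ok),
    }
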