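"""End-to-end orchestration: simulate -> scan -> depth -> TE -> haplotypes
-> GWAS -> anchor, with a manifest of output checksums.

Analysis thresholds default to the published settings (100 kb scan
windows, 5 kb PAV windows with 0.8/0.2 NCN cut-offs and <10 kb merging,
top-5% candidate quantile per subgenome set, 100 permutations,
alpha = 0.01, 5 PCs, 22-read anchoring minimum, 300 bp gaps).  The
bundled toy cohort keeps the same thresholds on a desk-scale world.

A single global seed fans out to per-stage child seeds through
numpy's SeedSequence, so identical seeds give identical manifests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from feralscan import anchor as anchor_mod
from feralscan import depth as depth_mod
from feralscan import gwas as gwas_mod
from feralscan import haplotypes as hap_mod
from feralscan import scan as scan_mod
from feralscan import synthetic as synth_mod
from feralscan import te as te_mod
from feralscan.variants import (
    GenotypeTable,
    VariantFilterConfig,
    apply_variant_filters,
    build_windows,
    write_vcf,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "toy_config"]

_STAGES = ("simulate", "scan", "cnv", "te", "haplotypes", "gwas", "anchor")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    outdir: str = "feralscan_out"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})
    # cohort shape
    n_per_group: dict = field(default_factory=lambda: {"DE": 50, "DO": 52})
    chromosomes: list = field(
        default_factory=lambda: [["chr1A", 2_000_000], ["chr1D", 2_000_000]]
    )
    n_sites: int = 2_000
    divergent_windows: list = field(
        default_factory=lambda: [["chr1A", 500_000, 600_000, 0.8]]
    )
    deletion: list = field(default_factory=lambda: ["chr1D", 300_000, 400_000])
    te_site: list = field(default_factory=lambda: ["chr1A", 1_000_000])
    misclassification_rate: float = 0.05
    # analysis thresholds (published defaults)
    window_size: int = 100_000
    window_step: int = 100_000
    pav_window: int = 5_000
    maf_min: float = 0.05
    missing_max: float = 0.30
    quantile: float = 0.05
    n_perm: int = 100
    pav_hi: float = 0.8
    pav_lo: float = 0.2
    merge_gap: int = 10_000
    alpha: float = 0.01
    n_pcs: int = 5
    mean_cov: float = 10.0
    min_reads: int = 22
    gap: int = 300

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def toy_config(outdir: str, seed: int = 0) -> PipelineConfig:
    """Desk-scale cohort with the published analysis thresholds."""
    return PipelineConfig(
        outdir=outdir,
        seed=seed,
        n_per_group={"DE": 12, "DO": 12},
        chromosomes=[["chr1A", 1_000_000], ["chr1D", 1_000_000]],
        n_sites=600,
        divergent_windows=[["chr1A", 300_000, 400_000, 0.8]],
        deletion=["chr1D", 200_000, 300_000],
        te_site=["chr1A", 800_000],
        n_perm=100,
        n_pcs=3,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(path: Path, stage: str):
    if not path.exists():
        raise PipelineError(
            f"stage '{stage}' needs {path.name}, produced by a disabled upstream stage"
        )
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages and return the output manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage_seeds = {
        s: int(v % (2**31))
        for s, v in zip(_STAGES, np.random.SeedSequence(config.seed).generate_state(len(_STAGES)))
    }
    lengths = dict((c, int(n)) for c, n in config.chromosomes)
    written: list[Path] = []

    cohort_cfg = synth_mod.CohortConfig(
        n_per_group=dict(config.n_per_group),
        chromosomes=[(c, int(n)) for c, n in config.chromosomes],
        n_sites=config.n_sites,
        divergent_windows=[tuple(w) for w in config.divergent_windows],
        deletions=[
            synth_mod.DeletionTruth(
                config.deletion[0], int(config.deletion[1]), int(config.deletion[2]),
                carrier_group=list(config.n_per_group)[0],
            )
        ],
        te=synth_mod.TeTruth(config.te_site[0], int(config.te_site[1])),
        phenotype=synth_mod.PhenotypeModel(
            causal=("deletion0", "te"),
            misclassification_rate=config.misclassification_rate,
        ),
        seed=stage_seeds["simulate"],
    )
    groups = list(config.n_per_group)
    table = frame = truth = None

    if config.stages.get("simulate", True):
        table, frame, truth = synth_mod.generate_cohort(cohort_cfg)
        write_vcf(table, out / "cohort.vcf")
        frame.to_csv(out / "samples.tsv", sep="\t", index=False)
        written += [out / "cohort.vcf", out / "samples.tsv"]

    def need_cohort(stage):
        if table is None:
            raise PipelineError(
                f"stage '{stage}' needs the simulated cohort; enable 'simulate'"
            )

    if config.stages.get("scan", True):
        need_cohort("scan")
        filt = apply_variant_filters(
            table, VariantFilterConfig(config.maf_min, config.missing_max)
        )
        grid = build_windows(lengths, config.window_size, config.window_step)
        g1 = frame.loc[frame["group"] == groups[0], "sample"].tolist()
        g2 = frame.loc[frame["group"] == groups[1], "sample"].tolist()
        track = scan_mod.windowed_fst(filt, g1, g2, grid)
        track["pi_de"] = scan_mod.windowed_pi(filt, g1, grid)["pi"]
        track["pi_do"] = scan_mod.windowed_pi(filt, g2, grid)["pi"]
        track["pi_ratio"] = scan_mod.pi_ratio(track["pi_do"], track["pi_de"])
        track.to_csv(out / "scan_windows.tsv", sep="\t", index=False)
        cands, thresholds = scan_mod.candidate_regions(track, "fst", config.quantile)
        cands.to_csv(out / "candidate_regions.tsv", sep="\t", index=False)
        perm = scan_mod.permutation_max_fst(
            filt, g1, g2, grid, config.n_perm, stage_seeds["scan"]
        )
        perm.to_csv(out / "permutation_max_fst.tsv", sep="\t", index=False)
        (out / "scan_thresholds.json").write_text(json.dumps(thresholds))
        written += [
            out / "scan_windows.tsv",
            out / "candidate_regions.tsv",
            out / "permutation_max_fst.tsv",
            out / "scan_thresholds.json",
        ]

    if config.stages.get("cnv", True):
        need_cohort("cnv")
        grid100 = build_windows(lengths, config.window_size, config.window_step)
        dm = synth_mod.generate_depth_matrix(
            list(frame["sample"]), truth, grid100,
            mean_cov=config.mean_cov, seed=stage_seeds["cnv"],
        )
        ncn, kept = depth_mod.normalize_depth(dm)
        g1 = frame.loc[frame["group"] == groups[0], "sample"].tolist()
        g2 = frame.loc[frame["group"] == groups[1], "sample"].tolist()
        cnv = depth_mod.cnv_index(ncn, kept, g1, g2, grid100)
        cnv.to_csv(out / "cnv_index.tsv", sep="\t", index=False)
        deletion = cohort_cfg.deletions[0]
        geno = depth_mod.genotype_deletion(
            ncn, kept, grid100, deletion.chrom, deletion.start, deletion.end,
            config.pav_hi, config.pav_lo,
        )
        geno.to_csv(out / "deletion_genotypes.tsv", sep="\t", index=False)
        # PAV between the reference genome (flat NCN 1) and a deletion carrier
        grid5 = build_windows(lengths, config.pav_window, config.pav_window)
        carrier = sorted(truth.deletions[0][1])[0]
        dm5 = synth_mod.generate_depth_matrix(
            [carrier], truth, grid5, mean_cov=config.mean_cov,
            noise="none", seed=stage_seeds["cnv"],
        )
        ncn5, _ = depth_mod.normalize_depth(dm5)
        # renormalize the carrier so intact windows sit at 1
        ncn_other = ncn5[0] / max(np.median(ncn5[0]), 1e-9)
        ncn_self = np.ones(grid5.n_windows)
        pav = depth_mod.call_pav_regions(
            ncn_self, ncn_other, grid5, config.pav_hi, config.pav_lo, config.merge_gap
        )
        pd.DataFrame([vars(p) for p in pav]).to_csv(
            out / "pav_regions.bed", sep="\t", index=False, header=False
        )
        written += [
            out / "cnv_index.tsv",
            out / "deletion_genotypes.tsv",
            out / "pav_regions.bed",
        ]

    if config.stages.get("te", True):
        need_cohort("te")
        rng = np.random.default_rng(stage_seeds["te"])
        chrom, site = truth.te_site
        ctx_start = site - 500
        ref_ctx = synth_mod.random_dna(rng, 1000)
        records = synth_mod.generate_te_alignments(
            list(frame["sample"]), truth, ref_ctx, ctx_start,
            seed=stage_seeds["te"],
        )
        calls, summary = te_mod.genotype_cohort(
            records, site, truth.te_seq, ref_ctx, ctx_start, rname=chrom
        )
        pd.DataFrame([vars(c) for c in calls]).to_csv(
            out / "te_calls.tsv", sep="\t", index=False
        )
        written.append(out / "te_calls.tsv")

    if config.stages.get("haplotypes", True):
        need_cohort("haplotypes")
        chrom, start, end, _ = cohort_cfg.divergent_windows[0]
        haps = hap_mod.call_gene_haplotypes(table, "divergent_gene", chrom, start, end)
        if haps is not None:
            alt_groups = {
                s: ("HA" if g == groups[0] else "LA")
                for s, g in zip(frame["sample"], frame["group"])
            }
            classes = hap_mod.classify_ha_la(haps, list(haps.positions), alt_groups)
            freqs = hap_mod.haplotype_frequencies(haps, classes, alt_groups)
            freqs.to_csv(out / "haplotype_frequencies.tsv", sep="\t")
            written.append(out / "haplotype_frequencies.tsv")

    if config.stages.get("gwas", True):
        need_cohort("gwas")
        filt = apply_variant_filters(
            table, VariantFilterConfig(config.maf_min, config.missing_max)
        )
        y = frame["brittle"].to_numpy(dtype=float)
        K = gwas_mod.kinship_matrix(filt)
        pcs = gwas_mod.genotype_pca(filt, config.n_pcs)
        deletion = cohort_cfg.deletions[0]
        sv_rows = {"id": ["del0", "te0"],
                   "chrom": [deletion.chrom, truth.te_site[0]],
                   "pos": [deletion.start + 1, truth.te_site[1]]}
        del_carriers = truth.deletions[0][1]
        for s in frame["sample"]:
            sv_rows.setdefault(s, [])
            sv_rows[s] = [
                "present" if s in del_carriers else "absent",
                "present" if s in truth.te_carriers else "absent",
            ]
        sv_table = gwas_mod.encode_sv_pseudo_variants(
            pd.DataFrame(sv_rows), list(frame["sample"])
        )
        assoc = gwas_mod.mlm_association(sv_table, y, pcs, K, config.alpha)
        assoc["variance_explained"] = [
            gwas_mod.variance_explained(sv_table.dosage[:, j].astype(float), y, pcs, K)
            for j in range(sv_table.n_sites)
        ]
        assoc.to_csv(out / "gwas_sv.tsv", sep="\t", index=False)
        written.append(out / "gwas_sv.tsv")

    if config.stages.get("anchor", True):
        reference, scaffolds, sc_truth = synth_mod.generate_scaffold_world(
            seed=stage_seeds["anchor"]
        )
        placements = anchor_mod.anchor_scaffolds(
            scaffolds, reference, min_reads=config.min_reads
        )
        placements.to_csv(out / "placements.tsv", sep="\t", index=False)
        seqs, agp = anchor_mod.build_pseudomolecules(placements, scaffolds, config.gap)
        with open(out / "pseudomolecules.fa", "w") as fh:
            for name, seq in seqs.items():
                fh.write(f">{name}\n{seq}\n")
        agp.to_csv(out / "pseudomolecules.agp", sep="\t", index=False)
        written += [
            out / "placements.tsv",
            out / "pseudomolecules.fa",
            out / "pseudomolecules.agp",
        ]

    manifest = {
        "seed": config.seed,
        "outputs": {p.name: _sha256(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
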