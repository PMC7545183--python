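"""Synthetic cohorts with known ground truth.

Generates the study-shaped inputs every downstream stage needs: a
two-group inbred cohort with divergent windows (allele-frequency shift
delta), per-sample depth tracks containing true deletions, soft-clipped
read evidence at a TE insertion site, structural-variant-driven
phenotypes, and a scaffold world with known placements.

Defaults mirror the study conditions: a DE (de-domesticated, brittle)
group of 50 versus a DO (domesticated) group of 52, near-homozygous
genotypes (2% heterozygosity — wheat is selfing), a 161 bp TE, and
Poisson-count depth noise.

Group frequencies inside a divergent window are p1 = p(1-delta) and
p2 = p1 + delta, which keeps both in [0, 1] and makes the between-group
difference exactly delta (delta=1 gives fixed differences).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from feralscan.te import AlignmentRecord
from feralscan.variants import MISSING, GenotypeTable, WindowGrid, build_windows

__all__ = [
    "CohortConfig",
    "DeletionTruth",
    "TeTruth",
    "PhenotypeModel",
    "TruthSet",
    "generate_cohort",
    "generate_depth_matrix",
    "generate_te_alignments",
    "generate_scaffold_world",
    "random_dna",
]

_BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


@dataclass
class DeletionTruth:
    chrom: str
    start: int  # 0-based half-open
    end: int
    carrier_group: str
    carrier_fraction: float = 1.0


@dataclass
class TeTruth:
    chrom: str
    site: int  # 1-based insertion breakpoint
    te_seq: str | None = None  # None -> random 161 bp at generation time
    carrier_group: str = "DE"
    carrier_fraction: float = 1.0


@dataclass
class PhenotypeModel:
    """Phenotype = carrier of any causal SV, flipped at the
    misclassification rate."""

    causal: tuple = ("deletion0",)  # ids: deletion<i> or "te"
    misclassification_rate: float = 0.0


@dataclass
class CohortConfig:
    n_per_group: dict = field(default_factory=lambda: {"DE": 50, "DO": 52})
    chromosomes: list = field(
        default_factory=lambda: [("chr1A", 2_000_000), ("chr1D", 2_000_000)]
    )
    n_sites: int = 2_000
    freq_range: tuple = (0.05, 0.95)  # uniform allele-frequency prior
    divergent_windows: list = field(default_factory=list)  # (chrom, start, end, delta)
    deletions: list = field(default_factory=list)  # DeletionTruth
    te: TeTruth | None = None
    phenotype: PhenotypeModel | None = None
    het_rate: float = 0.02
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        lengths = dict(self.chromosomes)
        for chrom, start, end, delta in self.divergent_windows:
            if chrom not in lengths or not (0 <= start < end <= lengths[chrom]):
                raise ValueError(f"divergent window {chrom}:{start}-{end} out of bounds")
            if not 0.0 <= delta <= 1.0:
                raise ValueError("delta must be in [0, 1]")
        if any(n <= 0 for n in self.n_per_group.values()):
            raise ValueError("every group needs at least one sample")


@dataclass
class TruthSet:
    """Ground truth written alongside every generated artifact."""

    divergent_windows: list = field(default_factory=list)
    deletions: list = field(default_factory=list)  # (DeletionTruth, carrier set)
    te_site: tuple | None = None  # (chrom, 1-based site)
    te_seq: str | None = None
    te_carriers: set = field(default_factory=set)
    phenotype: dict = field(default_factory=dict)  # sample -> 0/1 brittle
    placements: dict = field(default_factory=dict)  # scaffold -> (chrom, offset, strand)


def _sample_ids(n_per_group: dict) -> dict:
    return {
        grp: [f"{grp}{i:03d}" for i in range(n)] for grp, n in n_per_group.items()
    }


def generate_cohort(config: CohortConfig):
    """Generate (GenotypeTable, SampleFrame, TruthSet).

    Genotypes are inbred-style: dosage 1 with probability ``het_rate``,
    else 2x a Bernoulli draw from the group allele frequency; missing
    calls at ``missing_rate``.  Divergent windows shift the first two
    groups' frequencies apart by exactly delta.
    """
    rng = np.random.default_rng(config.seed)
    ids = _sample_ids(config.n_per_group)
    groups = list(config.n_per_group)
    samples = [s for grp in groups for s in ids[grp]]
    group_of = {s: grp for grp in groups for s in ids[grp]}

    # site positions: allocated to chromosomes proportionally to length
    lengths = dict(config.chromosomes)
    total = sum(lengths.values())
    chroms_col, pos_col = [], []
    remaining = config.n_sites
    for k, (chrom, length) in enumerate(config.chromosomes):
        n_here = (
            remaining
            if k == len(config.chromosomes) - 1
            else int(round(config.n_sites * length / total))
        )
        n_here = min(n_here, remaining)
        remaining -= n_here
        pos = np.sort(rng.choice(length, size=n_here, replace=False)) + 1
        chroms_col.extend([chrom] * n_here)
        pos_col.extend(pos.tolist())
    chrom_arr = np.array(chroms_col)
    pos_arr = np.array(pos_col)

    ref = rng.choice(_BASES, size=len(pos_arr))
    alt = np.array(
        [rng.choice([b for b in "ACGT" if b != r]) for r in ref]
    )

    lo, hi = config.freq_range
    base_p = rng.uniform(lo, hi, size=len(pos_arr))
    delta_site = np.zeros(len(pos_arr))
    for chrom, start, end, delta in config.divergent_windows:
        on = (chrom_arr == chrom) & (pos_arr - 1 >= start) & (pos_arr - 1 < end)
        delta_site[on] = np.maximum(delta_site[on], delta)
    p_low = base_p * (1.0 - delta_site)
    p_high = p_low + delta_site

    # first group gets the low frequency, second the high one; any further
    # groups share the baseline
    freq_by_group = {}
    for k, grp in enumerate(groups):
        if k == 0:
            freq_by_group[grp] = p_low
        elif k == 1:
            freq_by_group[grp] = p_high
        else:
            freq_by_group[grp] = base_p

    dosage = np.empty((len(samples), len(pos_arr)), dtype=np.int8)
    for i, s in enumerate(samples):
        p = freq_by_group[group_of[s]]
        hom = 2 * (rng.random(len(p)) < p).astype(np.int8)
        het = rng.random(len(p)) < config.het_rate
        row = np.where(het, np.int8(1), hom)
        miss = rng.random(len(p)) < config.missing_rate
        dosage[i] = np.where(miss, np.int8(MISSING), row)

    variants = pd.DataFrame(
        {"chrom": chrom_arr, "pos": pos_arr, "ref": ref, "alt": alt}
    )
    table = GenotypeTable(variants=variants, dosage=dosage, samples=samples)

    truth = TruthSet(divergent_windows=list(config.divergent_windows))

    # deletions: carriers drawn from the carrier group
    for deletion in config.deletions:
        pool = ids[deletion.carrier_group]
        n_carriers = int(round(deletion.carrier_fraction * len(pool)))
        carriers = set(rng.choice(pool, size=n_carriers, replace=False))
        truth.deletions.append((deletion, carriers))

    if config.te is not None:
        te = config.te
        te_seq = te.te_seq if te.te_seq is not None else random_dna(rng, 161)
        pool = ids[te.carrier_group]
        n_carriers = int(round(te.carrier_fraction * len(pool)))
        truth.te_site = (te.chrom, te.site)
        truth.te_seq = te_seq
        truth.te_carriers = set(rng.choice(pool, size=n_carriers, replace=False))

    # phenotype: brittle = carries any causal SV, then misclassified
    phenotype = {}
    if config.phenotype is not None:
        carrier_sets = []
        for sv_id in config.phenotype.causal:
            if sv_id == "te":
                carrier_sets.append(truth.te_carriers)
            elif sv_id.startswith("deletion"):
                carrier_sets.append(truth.deletions[int(sv_id[len("deletion") :])][1])
            else:
                raise ValueError(f"unknown causal SV id {sv_id!r}")
        for s in samples:
            brittle = any(s in cs for cs in carrier_sets)
            if rng.random() < config.phenotype.misclassification_rate:
                brittle = not brittle
            phenotype[s] = int(brittle)
    truth.phenotype = phenotype

    frame = pd.DataFrame(
        {
            "sample": samples,
            "group": [group_of[s] for s in samples],
            "altitude": ["HA" if group_of[s] in ("DE", "DO") else "LA" for s in samples],
            "brittle": [phenotype.get(s, 0) for s in samples],
        }
    )
    return table, frame, truth


def _copy_state(
    samples: list, truth: TruthSet, grid: WindowGrid
) -> np.ndarray:
    """Fraction of each window retained per sample (0 inside a carried
    deletion, 1 elsewhere, partial on boundary windows)."""
    copy = np.ones((len(samples), grid.n_windows))
    win = grid.windows
    for deletion, carriers in truth.deletions:
        rows = [i for i, s in enumerate(samples) if s in carriers]
        if not rows:
            continue
        on = (
            (win["chrom"] == deletion.chrom)
            & (win["start"] < deletion.end)
            & (win["end"] > deletion.start)
        ).to_numpy()
        idx = np.flatnonzero(on)
        ov = np.minimum(win["end"].to_numpy()[idx], deletion.end) - np.maximum(
            win["start"].to_numpy()[idx], deletion.start
        )
        frac = ov / (win["end"].to_numpy()[idx] - win["start"].to_numpy()[idx])
        for i in rows:
            copy[i, idx] = np.minimum(copy[i, idx], 1.0 - frac)
    return copy


def generate_depth_matrix(
    samples: list,
    truth: TruthSet,
    grid: WindowGrid,
    mean_cov: float = 10.0,
    read_len: int = 150,
    noise: str = "poisson",
    seed: int = 0,
):
    """Per-sample per-window mean depth around mean_cov x copy state.

    ``poisson`` draws the read count per window from a Poisson with mean
    mean_cov * window_len / read_len * copy and converts back to depth;
    ``none`` returns the exact expectation (deleted windows get depth 0).
    """
    from feralscan.depth import DepthMatrix

    if mean_cov <= 0:
        raise ValueError("mean_cov must be positive")
    rng = np.random.default_rng(seed)
    copy = _copy_state(samples, truth, grid)
    wlen = grid.lengths().astype(float)
    if noise == "none":
        depth = mean_cov * copy
    elif noise == "poisson":
        lam = mean_cov * wlen[None, :] / read_len * copy
        reads = rng.poisson(lam)
        depth = reads * read_len / wlen[None, :]
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    return DepthMatrix(depth=depth, samples=list(samples), grid=grid)


def generate_te_alignments(
    samples: list,
    truth: TruthSet,
    ref_seq: str,
    ref_offset: int = 1,
    n_reads: int = 4,
    read_len: int = 100,
    seed: int = 0,
) -> dict:
    """Per-sample alignment records at the TE insertion site.

    Carriers emit reads soft-clipped at the site whose clipped tails are
    TE prefixes/suffixes (>10 bp); non-carriers emit reads matching the
    reference across the site.  ``ref_seq`` starts at 1-based position
    ``ref_offset`` on the TE chromosome.  n_reads=0 yields empty evidence.
    """
    if truth.te_site is None:
        raise ValueError("truth set has no TE insertion")
    chrom, site = truth.te_site
    te_seq = truth.te_seq
    rng = np.random.default_rng(seed)
    if read_len < 30 or site - ref_offset < read_len or (
        ref_offset + len(ref_seq) - site
    ) < read_len:
        raise ValueError("read_len too short or site too close to context edge")

    def ref_sub(pos1, n):
        i = pos1 - ref_offset
        return ref_seq[i : i + n]

    out = {}
    for s in samples:
        records = []
        carrier = s in truth.te_carriers
        for k in range(n_reads):
            if carrier:
                if k % 2 == 0:
                    # right soft clip: aligned ref up to the site, then TE 5'
                    m = int(rng.integers(read_len // 2, read_len - 15))
                    clip = read_len - m
                    start = site - m
                    seq = ref_sub(start, m) + te_seq[:clip]
                    records.append(
                        AlignmentRecord(chrom, start, f"{m}M{clip}S", seq, f"{s}.r{k}")
                    )
                else:
                    # left soft clip: TE 3' tail, then aligned ref from site
                    m = int(rng.integers(read_len // 2, read_len - 15))
                    clip = read_len - m
                    seq = te_seq[-clip:] + ref_sub(site, m)
                    records.append(
                        AlignmentRecord(chrom, site, f"{clip}S{m}M", seq, f"{s}.r{k}")
                    )
            else:
                jitter = int(rng.integers(-read_len // 4, read_len // 4))
                start = site - read_len // 2 + jitter
                seq = ref_sub(start, read_len)
                records.append(
                    AlignmentRecord(chrom, start, f"{read_len}M", seq, f"{s}.r{k}")
                )
        out[s] = records
    return out


def generate_scaffold_world(
    chromosomes: dict | None = None,
    n_scaffolds: int = 20,
    scaffold_len: int = 30_000,
    n_unplaceable: int = 2,
    revcomp_fraction: float = 0.4,
    seed: int = 0,
):
    """Random reference chromosomes plus scaffolds cut from them.

    Scaffolds are non-overlapping substrings of the reference, a fraction
    reverse-complemented; ``n_unplaceable`` extra scaffolds are random
    sequence (truth chrUn).  Returns (reference dict, scaffolds dict,
    TruthSet with placements scaffold -> (chrom, 0-based offset, strand)).
    """
    from feralscan.te import revcomp

    rng = np.random.default_rng(seed)
    if chromosomes is None:
        chromosomes = {"chr1A": 300_000, "chr2B": 300_000, "chr3D": 300_000}
    reference = {c: random_dna(rng, n) for c, n in chromosomes.items()}

    truth = TruthSet()
    scaffolds = {}
    chrom_names = list(chromosomes)
    # slotted placement: partition each chromosome into equal slots and
    # jitter inside the slot, guaranteeing non-overlap at any density
    per_chrom = {
        c: [k for k in range(n_scaffolds) if chrom_names[k % len(chrom_names)] == c]
        for c in chrom_names
    }
    for chrom, members in per_chrom.items():
        if not members:
            continue
        length = chromosomes[chrom]
        slot = length // len(members)
        if slot < scaffold_len:
            raise ValueError(
                f"{chrom} too short for {len(members)} scaffolds of {scaffold_len} bp"
            )
        for j, k in enumerate(members):
            off = j * slot + int(rng.integers(0, slot - scaffold_len + 1))
            name = f"scaffold{k:03d}"
            seq = reference[chrom][off : off + scaffold_len]
            strand = "-" if rng.random() < revcomp_fraction else "+"
            scaffolds[name] = revcomp(seq) if strand == "-" else seq
            truth.placements[name] = (chrom, off, strand)
    scaffolds = {k: scaffolds[k] for k in sorted(scaffolds)}

    for k in range(n_unplaceable):
        name = f"random{k:03d}"
        scaffolds[name] = random_dna(rng, scaffold_len)
        truth.placements[name] = ("chrUn", -1, ".")

    return reference, scaffolds, truth
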