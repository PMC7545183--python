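"""Genotype containers, VCF I/O, variant filters, LD pruning, window grids.

The central container is :class:`GenotypeTable`, a dense samples × variants
matrix of alt-allele dosages for biallelic sites.  Dosages are coded
0 / 1 / 2 with ``-1`` for a missing call, the convention of inbred-line
resequencing panels where nearly all calls are homozygous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeTable",
    "VariantFilterConfig",
    "WindowGrid",
    "read_vcf",
    "write_vcf",
    "apply_variant_filters",
    "ld_prune",
    "assign_subgenome",
    "build_windows",
]


@dataclass
class GenotypeTable:
    """Samples × biallelic variants with alt-allele dosages.

    Attributes
    ----------
    variants : pandas.DataFrame
        One row per site with columns ``chrom``, ``pos`` (1-based),
        ``ref``, ``alt``.  Positions are strictly increasing within each
        chromosome.
    dosage : numpy.ndarray
        ``(n_samples, n_sites)`` int8 array of alt-allele dosages
        {0, 1, 2}; missing calls are ``-1``.
    samples : list of str
    """

    variants: pd.DataFrame
    dosage: np.ndarray
    samples: list = field(default_factory=list)

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x sites)")
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} sites"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be in {0,1,2,-1}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.variants)

    def called_mask(self) -> np.ndarray:
        return self.dosage != MISSING

    def alt_freq(self) -> np.ndarray:
        """Per-site alt allele frequency among called alleles (NaN if none)."""
        called = self.called_mask()
        n_alleles = 2.0 * called.sum(axis=0)
        alt = np.where(called, self.dosage, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / n_alleles, np.nan)

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> np.ndarray:
        return (self.dosage == MISSING).mean(axis=0)

    def subset_sites(self, mask_or_idx) -> "GenotypeTable":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeTable(
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[:, idx],
            samples=list(self.samples),
        )

    def subset_samples(self, names) -> "GenotypeTable":
        pos = [self.samples.index(s) for s in names]
        return GenotypeTable(
            variants=self.variants.copy(),
            dosage=self.dosage[pos, :],
            samples=list(names),
        )

    def sample_indices(self, names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[s] for s in names], dtype=int)


@dataclass
class VariantFilterConfig:
    """Site-level filters.

    ``maf_min`` keeps sites with MAF >= threshold; ``missing_max`` keeps
    sites with missing fraction strictly below the threshold when
    ``missing_strict`` (the association-panel rule, "<30%") or at-or-below
    otherwise (the discovery rule, "<=40%").
    """

    maf_min: float = 0.05
    missing_max: float = 0.30
    missing_strict: bool = True
    biallelic_only: bool = True

    def __post_init__(self):
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if not 0.0 <= self.missing_max <= 1.0:
            raise ValueError("missing_max must be in [0, 1]")


@dataclass
class WindowGrid:
    """Fixed windows tiling a set of chromosomes (0-based half-open)."""

    windows: pd.DataFrame  # columns chrom, start, end
    size: int
    step: int

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def lengths(self) -> np.ndarray:
        return (self.windows["end"] - self.windows["start"]).to_numpy()

    def site_to_window(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Window index per site (-1 when a site falls in no window).

        Positions are 1-based.  Requires a non-overlapping grid
        (step >= size); sites in step-gaps map to -1.
        """
        if self.step < self.size:
            raise ValueError("site_to_window requires a non-overlapping grid")
        pos0 = np.asarray(pos) - 1
        chrom = np.asarray(chrom)
        out = np.full(len(pos0), -1, dtype=int)
        wchrom = self.windows["chrom"].to_numpy()
        wstart = self.windows["start"].to_numpy()
        wend = self.windows["end"].to_numpy()
        for c in pd.unique(wchrom):
            widx = np.flatnonzero(wchrom == c)
            son = np.flatnonzero(chrom == c)
            if len(son) == 0:
                continue
            k = np.searchsorted(wstart[widx], pos0[son], side="right") - 1
            ok = (k >= 0) & (pos0[son] < wend[widx[np.clip(k, 0, len(widx) - 1)]])
            out[son[ok]] = widx[k[ok]]
        return out

    def site_window_indices(self, chrom: np.ndarray, pos: np.ndarray) -> list:
        """Per-window arrays of site indices (positions are 1-based)."""
        pos0 = np.asarray(pos) - 1
        chrom = np.asarray(chrom)
        if self.step >= self.size:
            assign = self.site_to_window(chrom, pos)
            return [np.flatnonzero(assign == w) for w in range(self.n_windows)]
        out = []
        for _, w in self.windows.iterrows():
            on = (chrom == w["chrom"]) & (pos0 >= w["start"]) & (pos0 < w["end"])
            out.append(np.flatnonzero(on))
        return out


def read_vcf(path) -> GenotypeTable:
    """Read a GT-only VCF into a :class:`GenotypeTable` (biallelic sites).

    Raises ``ValueError`` on multi-allelic records.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chroms, poss, refs, alts, rows = [], [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(f"multi-allelic record at {rec.CHROM}:{rec.POS}")
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        gt = rec.gt_types.astype(np.int8)  # 0,1,2 dosage; 3 unknown
        gt[gt == 3] = MISSING
        rows.append(gt)
    variants = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    dosage = (
        np.stack(rows, axis=1) if rows else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeTable(variants=variants, dosage=dosage, samples=samples)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(table: GenotypeTable, path) -> None:
    """Write a GT-only VCF v4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=feralscan\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(table.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        for j, row in table.variants.iterrows():
            gts = "\t".join(_GT_STR[int(d)] for d in table.dosage[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def apply_variant_filters(table: GenotypeTable, cfg: VariantFilterConfig) -> GenotypeTable:
    """Drop sites failing the MAF and missingness thresholds."""
    if table.n_sites == 0:
        raise ValueError("empty genotype table")
    maf = table.maf()
    miss = table.missing_fraction()
    keep = ~np.isnan(maf) & (maf >= cfg.maf_min)
    if cfg.missing_strict:
        keep &= miss < cfg.missing_max
    else:
        keep &= miss <= cfg.missing_max
    if not keep.any():
        warnings.warn("all sites removed by variant filters", stacklevel=2)
    return table.subset_sites(keep)


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors on pairwise-complete
    observations; 0.0 when either is constant or <2 complete pairs."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    sx = xv.std()
    sy = yv.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = np.mean((xv - xv.mean()) * (yv - yv.mean())) / (sx * sy)
    return float(r * r)


def ld_prune(table: GenotypeTable, r2_max: float = 0.4, window_sites: int = 50) -> GenotypeTable:
    """Greedy intra-chromosomal LD pruning.

    Scans sites left to right within each chromosome; a site is dropped when
    its r^2 with any already-kept site fewer than ``window_sites`` positions
    upstream reaches ``r2_max``.  The earlier site is always the one kept,
    which makes the output deterministic for a fixed input order.
    """
    if not 0.0 < r2_max <= 1.0:
        raise ValueError("r2_max must be in (0, 1]")
    keep = []
    for chrom in pd.unique(table.variants["chrom"]):
        site_idx = np.flatnonzero((table.variants["chrom"] == chrom).to_numpy())
        kept_local: list[int] = []
        for rank, j in enumerate(site_idx):
            ok = True
            for krank, k in kept_local:
                if rank - krank >= window_sites:
                    continue
                if _pairwise_r2(table.dosage[:, k], table.dosage[:, j]) >= r2_max:
                    ok = False
                    break
            if ok:
                kept_local.append((rank, j))
        keep.extend(k for _, k in kept_local)
    return table.subset_sites(np.array(sorted(keep), dtype=int))


def assign_subgenome(chrom_name: str) -> str:
    """Map a wheat chromosome name to its subgenome letter (A/B/D) or Un."""
    if chrom_name and chrom_name[-1] in ("A", "B", "D"):
        return chrom_name[-1]
    return "Un"


def build_windows(chrom_lengths, size: int, step: int | None = None) -> WindowGrid:
    """Tile chromosomes with fixed windows.

    ``chrom_lengths`` is a mapping or list of (name, length-bp).  The last
    window of each chromosome is truncated at the chromosome end.  A step
    larger than the size leaves gaps and is flagged with a warning.
    """
    if step is None:
        step = size
    if size <= 0 or step <= 0:
        raise ValueError("size and step must be positive")
    if step > size:
        warnings.warn("step > size: windows will not cover the genome", stacklevel=2)
    items = chrom_lengths.items() if hasattr(chrom_lengths, "items") else chrom_lengths
    rows = []
    for chrom, length in items:
        start = 0
        while start < length:
            rows.append((chrom, start, min(start + size, length)))
            start += step
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return WindowGrid(windows=df, size=size, step=step)
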