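"""Gene haplotype construction and high-/low-altitude classification.

Haplotypes are built per gene from the homozygous SNP genotypes inside the
gene interval (inbred panels: heterozygous calls become missing symbols).
A haplotype that carries an amino-acid-changing allele and is more
frequent in the high-altitude (HA) group than in the low-altitude (LA)
group is labelled the HA-adapted haplotype; the others are LA; ties and
haplotypes absent from both groups stay unclassified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from feralscan.variants import MISSING, GenotypeTable

__all__ = [
    "GeneHaplotypes",
    "HaploClass",
    "intersect_datasets",
    "call_gene_haplotypes",
    "classify_ha_la",
    "haplotype_frequencies",
]

MISSING_SYMBOL = "N"


def intersect_datasets(table_a: GenotypeTable, table_b: GenotypeTable):
    """Restrict two genotype tables to sites polymorphic in both.

    Sites are matched on (chrom, pos, ref, alt).  A site is polymorphic in
    a table when its called alt frequency is strictly between 0 and 1.
    """

    def poly_keys(t: GenotypeTable):
        p = t.alt_freq()
        ok = ~np.isnan(p) & (p > 0.0) & (p < 1.0)
        keys = list(
            zip(t.variants["chrom"], t.variants["pos"], t.variants["ref"], t.variants["alt"])
        )
        return {k for k, good in zip(keys, ok) if good}, keys

    keys_a, all_a = poly_keys(table_a)
    keys_b, all_b = poly_keys(table_b)
    shared = keys_a & keys_b
    if not shared:
        warnings.warn("no shared polymorphic sites between data sets", stacklevel=2)
    mask_a = np.array([k in shared for k in all_a])
    mask_b = np.array([k in shared for k in all_b])
    return table_a.subset_sites(mask_a), table_b.subset_sites(mask_b)


@dataclass
class GeneHaplotypes:
    """Per-gene haplotype strings and their ids.

    ``haplo_by_sample`` maps sample -> string over {ref base, alt base, N};
    identical strings share one id (H1, H2, ... in decreasing count order).
    """

    gene: str
    chrom: str
    start: int
    end: int
    positions: list  # 1-based site positions inside the gene
    ref_alleles: list
    alt_alleles: list
    haplo_by_sample: dict
    hap_id: dict = field(default_factory=dict)  # string -> id
    counts: dict = field(default_factory=dict)  # id -> count

    def id_of(self, sample: str) -> str | None:
        s = self.haplo_by_sample.get(sample)
        return None if s is None else self.hap_id[s]


def call_gene_haplotypes(
    table: GenotypeTable,
    gene: str,
    chrom: str,
    start: int,
    end: int,
    min_sites: int = 2,
    max_missing: float = 0.5,
) -> GeneHaplotypes | None:
    """Build haplotypes from SNPs in a gene interval (0-based half-open).

    Homozygous ref/alt dosages map to the ref/alt base; heterozygous and
    missing calls map to ``N``.  Samples whose string has a missing
    fraction above ``max_missing`` are dropped; genes with fewer than
    ``min_sites`` usable sites return None (discarded).
    """
    on = (
        (table.variants["chrom"] == chrom)
        & (table.variants["pos"] - 1 >= start)
        & (table.variants["pos"] - 1 < end)
    ).to_numpy()
    idx = np.flatnonzero(on)
    if len(idx) == 0:
        raise ValueError(f"no sites in gene interval {chrom}:{start}-{end}")
    if len(idx) < min_sites:
        warnings.warn(f"gene {gene}: only {len(idx)} site(s), discarded", stacklevel=2)
        return None

    refs = table.variants["ref"].to_numpy()[idx]
    alts = table.variants["alt"].to_numpy()[idx]
    haplo = {}
    for i, sample in enumerate(table.samples):
        chars = []
        for j, site in enumerate(idx):
            d = table.dosage[i, site]
            if d == 0:
                chars.append(refs[j])
            elif d == 2:
                chars.append(alts[j])
            else:  # het or missing
                chars.append(MISSING_SYMBOL)
        s = "".join(chars)
        if s.count(MISSING_SYMBOL) / len(s) <= max_missing:
            haplo[sample] = s

    strings = sorted(haplo.values())
    counts_by_string = pd.Series(strings).value_counts()
    hap_id = {
        s: f"H{k + 1}"
        for k, s in enumerate(
            sorted(counts_by_string.index, key=lambda s: (-counts_by_string[s], s))
        )
    }
    counts = {hap_id[s]: int(c) for s, c in counts_by_string.items()}
    return GeneHaplotypes(
        gene=gene,
        chrom=chrom,
        start=start,
        end=end,
        positions=list(table.variants["pos"].to_numpy()[idx]),
        ref_alleles=list(refs),
        alt_alleles=list(alts),
        haplo_by_sample=haplo,
        hap_id=hap_id,
        counts=counts,
    )


@dataclass
class HaploClass:
    hap: str  # haplotype id
    label: str  # HA | LA | unclassified
    carries_missense: bool
    freq_ha: float
    freq_la: float


def classify_ha_la(
    haps: GeneHaplotypes, missense_positions, groups: dict
) -> list[HaploClass]:
    """Label haplotypes HA / LA / unclassified.

    ``missense_positions`` lists 1-based positions (within the gene's site
    list) whose alt allele changes the protein; ``groups`` maps sample ->
    "HA" or "LA".  A haplotype is HA when it carries a missense alt allele
    and its frequency in the HA group strictly exceeds its LA-group
    frequency; equal frequencies or absence from both groups leave it
    unclassified; everything else is LA.
    """
    missense = set(missense_positions)
    if not missense:
        warnings.warn("empty missense site list: all haplotypes unclassified", stacklevel=2)

    ha_samples = [s for s in haps.haplo_by_sample if groups.get(s) == "HA"]
    la_samples = [s for s in haps.haplo_by_sample if groups.get(s) == "LA"]

    def group_freq(hid, members):
        if not members:
            return 0.0
        return sum(1 for s in members if haps.id_of(s) == hid) / len(members)

    out = []
    for string, hid in sorted(haps.hap_id.items(), key=lambda kv: kv[1]):
        carries = any(
            pos in missense and ch == alt
            for pos, alt, ch in zip(haps.positions, haps.alt_alleles, string)
        )
        f_ha = group_freq(hid, ha_samples)
        f_la = group_freq(hid, la_samples)
        if not missense or (f_ha == 0.0 and f_la == 0.0) or f_ha == f_la:
            label = "unclassified"
        elif carries and f_ha > f_la:
            label = "HA"
        else:
            label = "LA"
        out.append(HaploClass(hid, label, carries, f_ha, f_la))
    return out


def haplotype_frequencies(
    haps: GeneHaplotypes, classes: list[HaploClass], regions: dict
) -> pd.DataFrame:
    """Per-region proportions of HA / LA / unclassified haplotype carriers.

    ``regions`` maps sample -> region name.  Rows sum to 1 over labels.
    """
    label_of = {c.hap: c.label for c in classes}
    rows = {}
    for sample, region in regions.items():
        hid = haps.id_of(sample)
        if hid is None:
            continue
        rows.setdefault(region, {"HA": 0, "LA": 0, "unclassified": 0})
        rows[region][label_of[hid]] += 1
    if not rows:
        raise ValueError("no classified samples in any region")
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0)
    totals = df.sum(axis=1)
    return (df.T / totals).T
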