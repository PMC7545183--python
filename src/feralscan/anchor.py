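"""Scaffold ordering and orientation into pseudomolecules.

From each scaffold, paired probe reads (500 bp mates, 500 bp spacing,
1000 bp step) are simulated and located on the reference by unique exact
matching.  A scaffold is assigned to the chromosome collecting most of
its probe reads; fewer than 22 reads on the best chromosome sends it to
chrUn.  The first and last runs of five continuously aligned reads give
the scaffold's relative position and direction, and the per-chromosome
ordered scaffolds are concatenated with 300 bp N gaps into
pseudomolecules (FASTA + AGP).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from feralscan.te import revcomp

__all__ = [
    "ProbeRead",
    "simulate_probe_reads",
    "map_probe_reads",
    "assign_chromosome",
    "place_and_orient",
    "anchor_scaffolds",
    "build_pseudomolecules",
    "assembly_stats",
]

DEFAULT_MIN_READS = 22
DEFAULT_GAP = 300


@dataclass
class ProbeRead:
    """One simulated probe mate cut from a scaffold."""

    scaffold: str
    ordinal: int  # pair index along the scaffold
    mate: int  # 0 or 1
    offset: int  # 0-based start on the scaffold
    seq: str


def pair_span(read_len: int, insert: int, mode: str = "abutting") -> int:
    """Total reference span of one read pair.

    ``abutting`` reads the stated insert as the mate-to-mate fragment
    spacing, i.e. two 500 bp mates covering 1000 bp in total; ``outer``
    reads it as an inner gap between the mates (span 2*read_len+insert).
    """
    if mode == "abutting":
        return read_len + insert
    if mode == "outer":
        return 2 * read_len + insert
    raise ValueError(f"unknown span mode {mode!r}")


def simulate_probe_reads(
    scaffolds: dict,
    read_len: int = 500,
    insert: int = 500,
    step: int = 1000,
    span_mode: str = "abutting",
) -> list[ProbeRead]:
    """Deterministic paired probe reads from every scaffold.

    Pairs start at multiples of ``step``; a scaffold of length L yields
    floor((L - span)/step) + 1 pairs, zero (flagged) when shorter than the
    span.
    """
    span = pair_span(read_len, insert, span_mode)
    reads = []
    for name, seq in scaffolds.items():
        L = len(seq)
        if L < span:
            warnings.warn(f"scaffold {name} shorter than pair span; no reads", stacklevel=2)
            continue
        n_pairs = (L - span) // step + 1
        for i in range(n_pairs):
            t = i * step
            reads.append(ProbeRead(name, i, 0, t, seq[t : t + read_len]))
            reads.append(
                ProbeRead(name, i, 1, t + span - read_len, seq[t + span - read_len : t + span])
            )
    return reads


def _find_all(hay: str, needle: str):
    start = 0
    while True:
        i = hay.find(needle, start)
        if i < 0:
            return
        yield i
        start = i + 1


def map_probe_reads(reads: list[ProbeRead], reference: dict) -> pd.DataFrame:
    """Locate each read by unique exact matching on either strand.

    A read maps only when its sequence (or reverse complement) occurs
    exactly once across all chromosomes; otherwise it is unmapped.
    Returns a frame with scaffold, ordinal, mate, offset, chrom, pos,
    strand (chrom is None for unmapped reads).
    """
    rows = []
    for r in reads:
        hits = []
        rc = revcomp(r.seq)
        for chrom, seq in reference.items():
            for i in _find_all(seq, r.seq):
                hits.append((chrom, i, "+"))
            if rc != r.seq:
                for i in _find_all(seq, rc):
                    hits.append((chrom, i, "-"))
        if len(hits) == 1:
            chrom, pos, strand = hits[0]
        else:
            chrom, pos, strand = None, -1, "."
        rows.append(
            {
                "scaffold": r.scaffold,
                "ordinal": r.ordinal,
                "mate": r.mate,
                "offset": r.offset,
                "chrom": chrom,
                "pos": pos,
                "strand": strand,
            }
        )
    return pd.DataFrame(rows)


def assign_chromosome(hits: pd.DataFrame, min_reads: int = DEFAULT_MIN_READS):
    """Best chromosome for one scaffold's hits, or chrUn.

    The chromosome with the most mapped reads wins; a maximum below
    ``min_reads`` (the <22-read rule) sends the scaffold to chrUn.  Ties
    break lexicographically (logged via warning).
    """
    mapped = hits[hits["chrom"].notna()]
    if mapped.empty:
        return "chrUn", 0
    counts = mapped.groupby("chrom").size().sort_index()
    best_n = int(counts.max())
    winners = counts[counts == best_n].index.tolist()
    if len(winners) > 1:
        warnings.warn(f"chromosome tie {winners}; keeping {winners[0]}", stacklevel=2)
    if best_n < min_reads:
        return "chrUn", best_n
    return winners[0], best_n


def _runs(sub: pd.DataFrame, step: int, min_run: int = 5):
    """Maximal runs of continuously aligned reads along the scaffold.

    Continuity: consecutive scaffold offsets (gap <= step), same strand,
    reference positions advancing monotonically in the strand direction
    within a 2*step tolerance.
    """
    sub = sub.sort_values(["offset"]).reset_index(drop=True)
    runs = []
    cur = [0]
    for i in range(1, len(sub)):
        prev, here = sub.iloc[i - 1], sub.iloc[i]
        d_off = here["offset"] - prev["offset"]
        d_ref = here["pos"] - prev["pos"]
        same_strand = here["strand"] == prev["strand"]
        direction = 1 if here["strand"] == "+" else -1
        cont = (
            same_strand
            and 0 < d_off <= step
            and np.sign(d_ref) == direction
            and abs(d_ref) <= 2 * step
        )
        if cont:
            cur.append(i)
        else:
            runs.append(cur)
            cur = [i]
    runs.append(cur)
    return [sub.iloc[r] for r in runs if len(r) >= min_run]


def place_and_orient(hits: pd.DataFrame, step: int = 1000):
    """Relative position and direction for one assigned scaffold.

    Uses the first and last runs of >=5 continuously aligned reads: the
    position key is the mean reference position of the two runs, and the
    direction comes from the run strand.  Returns (position, orientation)
    or None when no run exists (scaffold demoted to chrUn, logged).
    """
    mapped = hits[hits["chrom"].notna()]
    runs = _runs(mapped, step)
    if not runs:
        warnings.warn("no 5-read continuous run; scaffold demoted to chrUn", stacklevel=2)
        return None
    first = runs[0].head(5)
    last = runs[-1].tail(5)
    position = float((first["pos"].mean() + last["pos"].mean()) / 2.0)
    strand = first["strand"].iloc[0]
    orientation = "+" if strand == "+" else "-"
    return position, orientation


def anchor_scaffolds(
    scaffolds: dict,
    reference: dict,
    read_len: int = 500,
    insert: int = 500,
    step: int = 1000,
    min_reads: int = DEFAULT_MIN_READS,
    span_mode: str = "abutting",
) -> pd.DataFrame:
    """Full anchoring: probe reads -> mapping -> assignment -> placement.

    Returns a PlacementTable frame: scaffold, chrom (or chrUn), position,
    orientation, n_supporting.
    """
    reads = simulate_probe_reads(scaffolds, read_len, insert, step, span_mode)
    hits = map_probe_reads(reads, reference)
    rows = []
    for name in scaffolds:
        sub = hits[hits["scaffold"] == name]
        chrom, n_sup = assign_chromosome(sub, min_reads)
        position, orientation = np.nan, "."
        if chrom != "chrUn":
            placed = place_and_orient(sub[sub["chrom"] == chrom], step)
            if placed is None:
                chrom = "chrUn"
            else:
                position, orientation = placed
        rows.append(
            {
                "scaffold": name,
                "chrom": chrom,
                "position": position,
                "orientation": orientation,
                "n_supporting": n_sup,
            }
        )
    return pd.DataFrame(rows)


def build_pseudomolecules(
    placements: pd.DataFrame, scaffolds: dict, gap: int = DEFAULT_GAP
):
    """Concatenate ordered, oriented scaffolds with N gaps.

    Returns (sequences dict chrom -> str, AGP DataFrame).  Scaffolds with
    orientation "-" are reverse-complemented; equal position keys keep a
    stable order by scaffold id.  chrUn members are concatenated in id
    order with the same gap.
    """
    seqs = {}
    agp_rows = []
    chroms = sorted(c for c in placements["chrom"].unique() if c != "chrUn")
    if (placements["chrom"] == "chrUn").any():
        chroms.append("chrUn")
    for chrom in chroms:
        sub = placements[placements["chrom"] == chrom]
        if chrom == "chrUn":
            sub = sub.sort_values("scaffold", kind="stable")
        else:
            sub = sub.sort_values(["position", "scaffold"], kind="stable")
        parts = []
        cursor = 0
        part_no = 0
        for _, row in sub.iterrows():
            if parts:
                part_no += 1
                agp_rows.append(
                    {
                        "object": chrom,
                        "object_beg": cursor + 1,
                        "object_end": cursor + gap,
                        "part_number": part_no,
                        "component_type": "N",
                        "component_id": str(gap),
                        "orientation": "na",
                    }
                )
                parts.append("N" * gap)
                cursor += gap
            seq = scaffolds[row["scaffold"]]
            if row["orientation"] == "-":
                seq = revcomp(seq)
            part_no += 1
            agp_rows.append(
                {
                    "object": chrom,
                    "object_beg": cursor + 1,
                    "object_end": cursor + len(seq),
                    "part_number": part_no,
                    "component_type": "W",
                    "component_id": row["scaffold"],
                    "orientation": row["orientation"] if row["orientation"] in "+-" else "+",
                }
            )
            parts.append(seq)
            cursor += len(seq)
        seqs[chrom] = "".join(parts)
    return seqs, pd.DataFrame(agp_rows)


def assembly_stats(lengths, gap_bases: int = 0) -> dict:
    """N50/N90, max, total and gap fraction for a set of sequence lengths.

    Nx is the length at which the cumulative sorted-descending total first
    reaches x% of the assembly; gap_fraction = gap_bases / total.
    """
    lengths = np.asarray(sorted(lengths, reverse=True), dtype=float)
    if lengths.size == 0:
        raise ValueError("empty length set")
    total = float(lengths.sum())
    cum = np.cumsum(lengths)

    def nx(x):
        return float(lengths[np.searchsorted(cum, x / 100.0 * total)])

    return {
        "n50": nx(50),
        "n90": nx(90),
        "max": float(lengths[0]),
        "total": total,
        "gap_fraction": gap_bases / total if total else 0.0,
    }
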