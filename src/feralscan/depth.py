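"""Read-depth normalization, PAV calling, CNV-index, deletion genotyping.

All statistics work on the Normalized Coverage Number (NCN): a sample's
per-window mean depth divided by its genome-wide mean depth, which cancels
library-size differences between samples.  A window covered normally has
NCN near 1; a hemizygous-absent or deleted window has NCN near 0.

PAV (presence/absence variation) between two genomes is called on a 5 kb
grid: a window normally covered by the carrier genome's own reads
(NCN > 0.8) but nearly uncovered by the other genome's reads (NCN < 0.2)
is retained-specific; selected windows closer than 10 kb are merged.

The CNV-index contrasts two sample groups per 100 kb window as
mean NCN(DO) - mean NCN(DE): positive values mean more deletion carriers
in the de-domesticated (DE) group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from feralscan.variants import WindowGrid

__all__ = [
    "DepthMatrix",
    "PavCall",
    "normalize_depth",
    "call_pav_regions",
    "call_pav_genes",
    "cnv_index",
    "genotype_deletion",
]


@dataclass
class DepthMatrix:
    """Per-sample per-window mean read depth on a fixed grid."""

    depth: np.ndarray  # (n_samples, n_windows), mean depth per window
    samples: list
    grid: WindowGrid

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.shape != (len(self.samples), self.grid.n_windows):
            raise ValueError("depth shape does not match samples x windows")
        if (self.depth < 0).any():
            raise ValueError("depths must be non-negative")

    def genome_mean(self) -> np.ndarray:
        """Per-sample genome-wide mean depth (window-length weighted)."""
        w = self.grid.lengths().astype(float)
        return (self.depth * w).sum(axis=1) / w.sum()


@dataclass
class PavCall:
    """A merged run of retained-specific windows."""

    chrom: str
    start: int
    end: int
    n_windows: int


def normalize_depth(matrix: DepthMatrix):
    """NCN[s, w] = depth[s, w] / genome-wide mean depth of sample s.

    Samples whose genome-wide mean is zero are dropped with a warning.
    Returns (ncn array, retained sample names).
    """
    gmean = matrix.genome_mean()
    ok = gmean > 0
    if not ok.all():
        dropped = [s for s, keep in zip(matrix.samples, ok) if not keep]
        warnings.warn(f"dropping zero-coverage samples: {dropped}", stacklevel=2)
    ncn = matrix.depth[ok] / gmean[ok, None]
    samples = [s for s, keep in zip(matrix.samples, ok) if keep]
    return ncn, samples


def _select_and_merge(grid: WindowGrid, selected: np.ndarray, merge_gap: int):
    """Merge selected windows whose inter-window gap is < merge_gap."""
    win = grid.windows
    calls: list[PavCall] = []
    cur = None
    order = np.lexsort((win["start"].to_numpy(), win["chrom"].to_numpy()))
    for i in order:
        if not selected[i]:
            continue
        chrom = win["chrom"].iloc[i]
        start = int(win["start"].iloc[i])
        end = int(win["end"].iloc[i])
        if cur is not None and cur.chrom == chrom and start - cur.end < merge_gap:
            cur = PavCall(cur.chrom, cur.start, end, cur.n_windows + 1)
        else:
            if cur is not None:
                calls.append(cur)
            cur = PavCall(chrom, start, end, 1)
    if cur is not None:
        calls.append(cur)
    return calls


def call_pav_regions(
    ncn_self: np.ndarray,
    ncn_other: np.ndarray,
    grid: WindowGrid,
    hi: float = 0.8,
    lo: float = 0.2,
    merge_gap: int = 10_000,
) -> list[PavCall]:
    """Retained-specific regions from two NCN tracks on the same grid.

    A window is selected when NCN_self > hi (normally covered by the
    genome's own reads) and NCN_other < lo (nearly absent from the other
    genome's reads); both thresholds are strict.  Selected windows whose
    gap is strictly less than ``merge_gap`` (so a gap of exactly 10 kb is
    NOT merged) are merged into one call.
    """
    ncn_self = np.asarray(ncn_self, dtype=float)
    ncn_other = np.asarray(ncn_other, dtype=float)
    if ncn_self.shape != (grid.n_windows,) or ncn_other.shape != (grid.n_windows,):
        raise ValueError("NCN tracks must be 1-D and match the grid")
    selected = (ncn_self > hi) & (ncn_other < lo)
    return _select_and_merge(grid, selected, merge_gap)


def _interval_mean_ncn(
    ncn: np.ndarray, grid: WindowGrid, chrom: str, start: int, end: int
) -> float:
    """Overlap-length-weighted mean NCN over an interval; NaN if no overlap.

    ``ncn`` is 1-D (one track) or 2-D (samples x windows); returns a float
    or a per-sample vector accordingly.
    """
    win = grid.windows
    on = (win["chrom"] == chrom) & (win["start"] < end) & (win["end"] > start)
    idx = np.flatnonzero(on.to_numpy())
    if len(idx) == 0:
        return np.nan if np.ndim(ncn) == 1 else np.full(ncn.shape[0], np.nan)
    ov = np.minimum(win["end"].to_numpy()[idx], end) - np.maximum(
        win["start"].to_numpy()[idx], start
    )
    ov = ov.astype(float)
    if np.ndim(ncn) == 1:
        return float((np.asarray(ncn)[idx] * ov).sum() / ov.sum())
    return (np.asarray(ncn)[:, idx] * ov).sum(axis=1) / ov.sum()


def call_pav_genes(
    genes: pd.DataFrame,
    ncn_self: np.ndarray,
    ncn_other: np.ndarray,
    grid: WindowGrid,
    hi: float = 0.8,
    lo: float = 0.2,
) -> pd.DataFrame:
    """Per-gene PAV calls with the same hi/lo rule as region calls.

    ``genes`` has columns chrom, start, end (0-based half-open), name.
    Gene NCN is the mean over bases, computed from overlapping grid windows
    weighted by overlap length.  Returns the genes frame with ``ncn_self``,
    ``ncn_other`` and boolean ``pav`` columns.
    """
    if (genes["end"] <= genes["start"]).any():
        raise ValueError("zero- or negative-length gene interval")
    out = genes.copy()
    self_vals, other_vals = [], []
    for _, g in genes.iterrows():
        self_vals.append(
            _interval_mean_ncn(ncn_self, grid, g["chrom"], g["start"], g["end"])
        )
        other_vals.append(
            _interval_mean_ncn(ncn_other, grid, g["chrom"], g["start"], g["end"])
        )
    out["ncn_self"] = self_vals
    out["ncn_other"] = other_vals
    out["pav"] = (out["ncn_self"] > hi) & (out["ncn_other"] < lo)
    return out


def cnv_index(
    ncn: np.ndarray, samples: list, group_de, group_do, grid: WindowGrid
) -> pd.DataFrame:
    """CNV-index per window: mean NCN(DO) - mean NCN(DE).

    Positive values indicate more deletion carriers in the DE
    (de-domesticated) group; the sign convention is fixed by construction.
    """
    if not group_de or not group_do:
        raise ValueError("both groups must be nonempty")
    lookup = {s: i for i, s in enumerate(samples)}
    de_idx = [lookup[s] for s in group_de]
    do_idx = [lookup[s] for s in group_do]
    out = grid.windows.copy()
    out["ncn_de"] = ncn[de_idx].mean(axis=0)
    out["ncn_do"] = ncn[do_idx].mean(axis=0)
    out["cnv_index"] = out["ncn_do"] - out["ncn_de"]
    return out


def genotype_deletion(
    ncn: np.ndarray,
    samples: list,
    grid: WindowGrid,
    chrom: str,
    start: int,
    end: int,
    hi: float = 0.8,
    lo: float = 0.2,
) -> pd.DataFrame:
    """Per-sample deletion genotype over a region from regional mean NCN.

    Mean NCN < lo -> ``deleted``; > hi -> ``present``; the band in between
    is left ``unknown`` rather than forced into a binary call.
    """
    regional = _interval_mean_ncn(np.atleast_2d(ncn), grid, chrom, start, end)
    if np.isnan(regional).all():
        raise ValueError(f"region {chrom}:{start}-{end} overlaps no grid window")
    call = np.where(regional < lo, "deleted", np.where(regional > hi, "present", "unknown"))
    return pd.DataFrame({"sample": samples, "ncn": regional, "call": call})
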