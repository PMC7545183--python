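"""Windowed differentiation and diversity scans.

F_ST follows the Weir & Cockerham (1984) two-population estimator: per site
the among-population (a), among-individual (b) and within-individual (c)
variance components are computed from per-group sample sizes, allele
frequencies and observed heterozygosity; a window's F_ST is the
ratio-of-sums Sum(a) / Sum(a+b+c) over usable sites — the "weighted"
windowed form reported by the standard VCF scan tools.  Nucleotide
diversity per window is the sum over variant sites of x(n-x)/C(n,2)
divided by the window length in bp.

The permutation null shuffles group labels jointly over the whole cohort
(samples, not windows, are exchangeable), recomputes the genome-wide
windowed scan, and records the per-subgenome-partition maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from feralscan.variants import MISSING, GenotypeTable, WindowGrid, assign_subgenome

__all__ = [
    "SiteFstComponents",
    "wc_fst_components",
    "site_fst_components",
    "windowed_fst",
    "windowed_pi",
    "pi_ratio",
    "candidate_regions",
    "permutation_max_fst",
    "estimate_ne",
]


@dataclass
class SiteFstComponents:
    """Weir–Cockerham variance components at one site.

    ``a``: among-population, ``b``: among-individual-within-population,
    ``c``: within-individual.  ``usable`` is False when the site is
    monomorphic across both groups or either group has no called genotype.
    """

    a: float
    b: float
    c: float
    usable: bool


def _group_site_stats(dosage: np.ndarray):
    """Per-site (n individuals, alt freq, het fraction) for one group."""
    called = dosage != MISSING
    n = called.sum(axis=0).astype(float)
    alt = np.where(called, dosage, 0).sum(axis=0).astype(float)
    het = np.where(called, dosage == 1, False).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
        h = np.where(n > 0, het / n, np.nan)
    return n, p, h


def wc_fst_components(dosage1: np.ndarray, dosage2: np.ndarray):
    """Vectorized Weir–Cockerham (1984) components for two populations.

    Parameters
    ----------
    dosage1, dosage2 : (n_individuals, n_sites) int arrays, missing = -1.

    Returns
    -------
    a, b, c : float arrays, zero where unusable
    usable : bool array — both groups called, pooled sample > 1 individual,
        and the site polymorphic in the pooled sample.
    """
    dosage1 = np.atleast_2d(dosage1)
    dosage2 = np.atleast_2d(dosage2)
    n1, p1, h1 = _group_site_stats(dosage1)
    n2, p2, h2 = _group_site_stats(dosage2)

    r = 2.0
    nbar = (n1 + n2) / r
    usable = (n1 >= 1) & (n2 >= 1) & (nbar > 1.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)

        a = (nbar / nc) * (
            s2 - (pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0

    polymorphic = usable & ((pbar > 0.0) & (pbar < 1.0) | (np.nan_to_num(hbar) > 0.0))
    usable &= polymorphic & (np.nan_to_num(nc) > 0.0)
    a = np.where(usable, a, 0.0)
    b = np.where(usable, b, 0.0)
    c = np.where(usable, c, 0.0)
    return a, b, c, usable


def site_fst_components(dosages_group1, dosages_group2) -> SiteFstComponents:
    """Single-site wrapper around :func:`wc_fst_components`."""
    d1 = np.asarray(dosages_group1).reshape(-1, 1)
    d2 = np.asarray(dosages_group2).reshape(-1, 1)
    a, b, c, usable = wc_fst_components(d1, d2)
    return SiteFstComponents(
        a=float(a[0]), b=float(b[0]), c=float(c[0]), usable=bool(usable[0])
    )


def _site_assignment(table: GenotypeTable, grid: WindowGrid) -> np.ndarray:
    if grid.step >= grid.size:
        return grid.site_to_window(
            table.variants["chrom"].to_numpy(), table.variants["pos"].to_numpy()
        )
    raise ValueError("windowed scans require a non-overlapping grid")


def _window_sums(values: np.ndarray, assign: np.ndarray, n_windows: int) -> np.ndarray:
    on = assign >= 0
    return np.bincount(assign[on], weights=values[on], minlength=n_windows)


def windowed_fst(
    table: GenotypeTable,
    group1,
    group2,
    grid: WindowGrid,
    _assign: np.ndarray | None = None,
) -> pd.DataFrame:
    """Windowed weighted F_ST = Sum(a)/Sum(a+b+c) over usable sites.

    ``group1``/``group2`` are sample-name lists (disjoint).  Windows with no
    usable site get NaN.  Negative window values are reported, not clamped.
    """
    if set(group1) & set(group2):
        raise ValueError("groups must be disjoint")
    if not group1 or not group2:
        raise ValueError("both groups must be nonempty")
    d1 = table.dosage[table.sample_indices(group1), :]
    d2 = table.dosage[table.sample_indices(group2), :]
    a, b, c, usable = wc_fst_components(d1, d2)
    denom_site = a + b + c

    assign = _site_assignment(table, grid) if _assign is None else _assign
    nw = grid.n_windows
    num = _window_sums(a, assign, nw)
    den = _window_sums(denom_site, assign, nw)
    n_sites = _window_sums(usable.astype(float), assign, nw).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where((n_sites > 0) & (den != 0.0), num / den, np.nan)

    out = grid.windows.copy()
    out["n_sites"] = n_sites
    out["fst"] = fst
    return out


def windowed_pi(table: GenotypeTable, group, grid: WindowGrid) -> pd.DataFrame:
    """Per-window nucleotide diversity for one sample group.

    Per site the expected pairwise difference is x(n-x)/C(n,2) with x the
    alt allele count among n called alleles; a window's pi is the sum over
    its variant sites divided by the window length in bp.  Sites with fewer
    than 2 called alleles are skipped; monomorphic sites contribute 0.
    """
    if not group:
        raise ValueError("group must be nonempty")
    d = table.dosage[table.sample_indices(group), :]
    called = d != MISSING
    n = 2.0 * called.sum(axis=0)
    x = np.where(called, d, 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_site = np.where(n >= 2, x * (n - x) / (n * (n - 1.0) / 2.0), 0.0)

    assign = _site_assignment(table, grid)
    sums = _window_sums(per_site, assign, grid.n_windows)
    out = grid.windows.copy()
    out["pi"] = sums / grid.lengths()
    return out


def pi_ratio(pi_do: np.ndarray, pi_de: np.ndarray) -> np.ndarray:
    """Element-wise pi_DO / pi_DE; NaN where the denominator is 0."""
    pi_do = np.asarray(pi_do, dtype=float)
    pi_de = np.asarray(pi_de, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(pi_de > 0.0, pi_do / pi_de, np.nan)


def _partition_of(chrom: str) -> str:
    sub = assign_subgenome(chrom)
    return "AB" if sub in ("A", "B") else ("D" if sub == "D" else "Un")


def candidate_regions(
    track: pd.DataFrame, value_col: str = "fst", quantile: float = 0.05
):
    """Top-quantile windows, thresholded separately for the A&B and D
    subgenome partitions (tetraploid introgression makes their
    differentiation distributions incomparable).

    Returns (candidates DataFrame with a ``threshold`` column, thresholds
    dict keyed by partition).
    """
    track = track.copy()
    track["partition"] = [_partition_of(c) for c in track["chrom"]]
    thresholds = {}
    keep_rows = []
    for part, sub in track.groupby("partition"):
        vals = sub[value_col].dropna()
        if vals.empty:
            raise ValueError(f"partition {part} has no non-missing windows")
        thr = float(np.quantile(vals.to_numpy(), 1.0 - quantile))
        thresholds[part] = thr
        hit = sub[sub[value_col] >= thr].copy()
        hit["threshold"] = thr
        keep_rows.append(hit)
    out = pd.concat(keep_rows).sort_index()
    return out, thresholds


def permutation_max_fst(
    table: GenotypeTable,
    group1,
    group2,
    grid: WindowGrid,
    n_perm: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Label-shuffling permutation null for the windowed F_ST scan.

    Group labels are shuffled jointly over the union of the two groups
    (preserving group sizes), the genome-wide windowed scan is recomputed,
    and the per-partition maximum recorded.  Returns one row per replicate
    with columns ``rep`` and one max-F_ST column per partition present.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    union_idx = table.sample_indices(list(group1) + list(group2))
    n1 = len(group1)
    assign = _site_assignment(table, grid)
    nw = grid.n_windows
    window_part = np.array([_partition_of(c) for c in grid.windows["chrom"]])
    partitions = sorted(set(window_part))
    rows = []
    for rep in range(n_perm):
        perm = rng.permutation(union_idx)
        a, b, c, usable = wc_fst_components(
            table.dosage[perm[:n1], :], table.dosage[perm[n1:], :]
        )
        num = _window_sums(a, assign, nw)
        den = _window_sums(a + b + c, assign, nw)
        n_sites = _window_sums(usable.astype(float), assign, nw)
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = np.where((n_sites > 0) & (den != 0.0), num / den, np.nan)
        row = {"rep": rep}
        for part in partitions:
            vals = fst[window_part == part]
            vals = vals[~np.isnan(vals)]
            row[f"max_fst_{part}"] = float(vals.max()) if len(vals) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def estimate_ne(theta: float, mu: float = 6.5e-9, generation_years: float = 1.0) -> float:
    """Effective population size from scaled diversity, Ne = theta/(4*mu*L).

    Defaults: neutral mutation rate mu = 6.5e-9 per site per generation and
    a generation time L of one year, the standard settings for wheat.
    """
    if theta <= 0 or mu <= 0 or generation_years <= 0:
        raise ValueError("theta, mu and generation time must be positive")
    return theta / (4.0 * mu * generation_years)
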