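"""Windowed F_ST genome scan: Hudson-type estimator, Z-transformation,
outlier detection, taxon-specific assignment, and low-differentiation
region calling.

The estimator is the Bhatia/Hudson form: per site, a numerator
``(p1-p2)^2 - p1(1-p1)/(m1-1) - p2(1-p2)/(m2-1)`` (the two correction terms
remove within-population sampling variance) and a denominator
``p1(1-p2) + p2(1-p1)``.  Windows combine sites as a *ratio of sums*
(sum num / sum den), the weighted convention recommended for window
averaging; window values may be slightly negative and are kept unclamped so
that the Z-transform is unbiased.

ZF_ST standardizes each pair's window F_ST by the genome-wide mean and SD
over *eligible* windows (enough SNPs, nonzero denominator).  A window with
ZF_ST >= 6 (default) is an outlier; an outlier window is assigned to a taxon
when it is an outlier in BOTH pairwise comparisons involving that taxon.
Runs of windows jointly low in all three comparisons are merged into
candidate uniform-selection regions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .popdata import SampleTable, SiteMatrix
from .sfs import JointSFS2D
from .windows import WindowGrid

__all__ = [
    "WindowGrid",
    "hudson_site_components",
    "site_components",
    "window_fst",
    "fst_from_joint_sfs",
    "zfst_transform",
    "detect_outliers",
    "taxon_specific_outliers",
    "low_fst_regions",
    "pair_key",
]


def pair_key(pop_a: str, pop_b: str) -> str:
    """Canonical, order-free label for a population pair."""
    return "-".join(sorted((pop_a, pop_b)))


# ---------------------------------------------------------------------------
# Hudson estimator


def hudson_site_components(
    p1,
    p2,
    m1: int | np.ndarray = 0,
    m2: int | np.ndarray = 0,
    sample_corrected: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site numerator and denominator of Hudson's F_ST.

    ``p1, p2`` are sample derived-allele frequencies, ``m1, m2`` the numbers
    of sampled chromosomes.  With ``sample_corrected`` (default) the
    numerator subtracts the finite-sample variance terms and requires
    ``m1, m2 >= 2``.
    """
    p1 = np.asarray(p1, dtype=np.float64)
    p2 = np.asarray(p2, dtype=np.float64)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    num = (p1 - p2) ** 2
    if sample_corrected:
        m1 = np.asarray(m1)
        m2 = np.asarray(m2)
        if (m1 <= 1).any() if np.ndim(m1) else m1 <= 1:
            raise ValueError("sample-corrected mode needs m1 >= 2 chromosomes")
        if (m2 <= 1).any() if np.ndim(m2) else m2 <= 1:
            raise ValueError("sample-corrected mode needs m2 >= 2 chromosomes")
        num = num - p1 * (1 - p1) / (m1 - 1) - p2 * (1 - p2) / (m2 - 1)
    return num, den


def site_components(
    sm: SiteMatrix,
    sample_table: SampleTable,
    pop_a: str,
    pop_b: str,
    sample_corrected: bool = True,
) -> pd.DataFrame:
    """Hudson components for every site retained in both populations.

    Returns a frame with chrom, pos, num, den restricted to the joint mask.
    """
    joint = sm.mask_for(pop_a) & sm.mask_for(pop_b)
    pa = sm.derived_freq(sample_table, pop_a)[joint]
    pb = sm.derived_freq(sample_table, pop_b)[joint]
    m1 = 2 * sample_table.n_individuals(pop_a)
    m2 = 2 * sample_table.n_individuals(pop_b)
    num, den = hudson_site_components(pa, pb, m1, m2, sample_corrected)
    return pd.DataFrame(
        {"chrom": sm.chrom[joint], "pos": sm.pos[joint], "num": num, "den": den}
    )


def window_fst(
    components: pd.DataFrame,
    grid: WindowGrid,
    min_snps: int = 10,
) -> pd.DataFrame:
    """Ratio-of-sums window F_ST on the grid.

    One row per grid window (including empty windows): num_sum, den_sum,
    n_snps, fst (NaN when den_sum == 0), fst_clamped (display column, floored
    at 0) and an ``eligible`` flag (n_snps >= min_snps and den_sum > 0).
    Ineligible windows are excluded from Z-standardization and outlier
    calling downstream.
    """
    table = grid.to_frame()
    num_sum = np.zeros(grid.total_windows)
    den_sum = np.zeros(grid.total_windows)
    n_snps = np.zeros(grid.total_windows, dtype=np.int64)
    if len(components):
        gidx = grid.global_index(
            components["chrom"].to_numpy(), components["pos"].to_numpy()
        )
        np.add.at(num_sum, gidx, components["num"].to_numpy())
        np.add.at(den_sum, gidx, components["den"].to_numpy())
        np.add.at(n_snps, gidx, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(den_sum > 0, num_sum / np.where(den_sum > 0, den_sum, 1), np.nan)
    table = table.assign(
        num_sum=num_sum,
        den_sum=den_sum,
        n_snps=n_snps,
        fst=fst,
        fst_clamped=np.fmax(fst, 0.0),
        eligible=(n_snps >= min_snps) & (den_sum > 0),
    )
    return table


def fst_from_joint_sfs(
    jsfs: JointSFS2D, sample_corrected: bool = True
) -> tuple[float, float]:
    """Aggregate Hudson components from a 2D SFS.

    Cell (i, j) contributes ``counts[i, j]`` sites with frequencies
    ``i/m1, j/m2``; on complete data this equals the per-site path exactly.
    """
    if jsfs.m1 < 2 or jsfs.m2 < 2:
        raise ValueError("need m1, m2 >= 2 chromosomes")
    i = np.arange(jsfs.m1 + 1)[:, None] / jsfs.m1
    j = np.arange(jsfs.m2 + 1)[None, :] / jsfs.m2
    num, den = hudson_site_components(i, j, jsfs.m1, jsfs.m2, sample_corrected)
    return float((num * jsfs.counts).sum()), float((den * jsfs.counts).sum())


# ---------------------------------------------------------------------------
# Z-scan


def zfst_transform(fst_table: pd.DataFrame) -> pd.DataFrame:
    """Standardize window F_ST to ZF_ST over the pair's eligible windows.

    Mean and SD are pooled over all chromosomes of the scan (the study design
    pools autosomes and Z together).  Degenerate scans (fewer than two
    eligible windows, or zero SD) are a hard error.
    """
    eligible = fst_table["eligible"].to_numpy()
    if eligible.sum() < 2:
        raise ValueError("degenerate scan: fewer than 2 eligible windows")
    vals = fst_table.loc[eligible, "fst"].to_numpy()
    mean, sd = float(vals.mean()), float(vals.std())
    if sd <= 1e-12 * max(1.0, abs(mean)):  # constant up to float rounding
        raise ValueError("degenerate scan: constant F_ST across eligible windows")
    out = fst_table.copy()
    z = (out["fst"].to_numpy() - mean) / sd
    out["zfst"] = np.where(eligible, z, np.nan)
    out.attrs["fst_mean"] = mean
    out.attrs["fst_sd"] = sd
    return out


def detect_outliers(zscan: pd.DataFrame, threshold: float = 6.0) -> pd.DataFrame:
    """Eligible windows with ZF_ST at or above the threshold."""
    z = zscan["zfst"].to_numpy()
    hit = zscan["eligible"].to_numpy() & (z >= threshold)
    return zscan.loc[hit].copy()


def taxon_specific_outliers(
    outliers_by_pair: dict[str, pd.DataFrame],
    taxa: list[str],
) -> pd.DataFrame:
    """Assign outlier windows to taxa by the both-comparisons rule.

    A window is taxon-specific for T when it is an outlier in *both* pairwise
    comparisons involving T.  With three taxa each taxon appears in exactly
    two of the three pairs; a window can be assigned to several taxa only by
    satisfying the rule for each independently.
    """
    if len(taxa) != 3:
        raise ValueError("taxon-specific assignment is defined for exactly 3 taxa")
    pairs = {pair_key(a, b) for a, b in itertools.combinations(taxa, 2)}
    if set(outliers_by_pair) != pairs:
        raise ValueError(
            f"need outlier sets for all pairs {sorted(pairs)}, got {sorted(outliers_by_pair)}"
        )
    rows = []
    for taxon in taxa:
        involving = [k for k in outliers_by_pair if taxon in k.split("-")]
        sets = [
            set(map(tuple, outliers_by_pair[k][["chrom", "window"]].to_numpy()))
            for k in involving
        ]
        for chrom, window in sorted(sets[0] & sets[1]):
            ref = outliers_by_pair[involving[0]]
            row = ref[(ref["chrom"] == chrom) & (ref["window"] == window)].iloc[0]
            rows.append(
                {
                    "taxon": taxon,
                    "chrom": chrom,
                    "window": int(window),
                    "start": int(row["start"]),
                    "end": int(row["end"]),
                    "pairs": ",".join(sorted(involving)),
                }
            )
    return pd.DataFrame(
        rows, columns=["taxon", "chrom", "window", "start", "end", "pairs"]
    )


# ---------------------------------------------------------------------------
# low-differentiation regions


def low_fst_regions(
    zscans: dict[str, pd.DataFrame],
    z_low: float = -1.0,
    min_windows: int = 20,
    max_gap: int = 2,
) -> pd.DataFrame:
    """Merged runs of windows jointly low in every pairwise comparison.

    A window is flagged when it is eligible in all pairs and has
    ``zfst < z_low`` in all of them.  Flagged windows on a chromosome are
    merged into one region while consecutive flagged windows are separated by
    at most ``max_gap`` unflagged windows; merged runs spanning fewer than
    ``min_windows`` windows are dropped.  Reported intervals run from the
    first to the last flagged window (0-based half-open bases).
    """
    keys = sorted(zscans)
    base = zscans[keys[0]][["chrom", "start", "end", "window", "gindex"]].copy()
    flagged = np.ones(len(base), dtype=bool)
    zcols = {}
    for k in keys:
        t = zscans[k]
        if not (t["gindex"].to_numpy() == base["gindex"].to_numpy()).all():
            raise ValueError("Z-scans are not on a common window grid")
        z = t["zfst"].to_numpy()
        flagged &= t["eligible"].to_numpy() & (z < z_low)
        zcols[k] = z

    rows = []
    for chrom, sub in base.assign(flagged=flagged).groupby("chrom", sort=False):
        idx = sub.loc[sub["flagged"], "window"].to_numpy()
        if len(idx) == 0:
            continue
        run_start = idx[0]
        prev = idx[0]
        runs = []
        for w in idx[1:]:
            if w - prev - 1 > max_gap:
                runs.append((run_start, prev))
                run_start = w
            prev = w
        runs.append((run_start, prev))
        for w0, w1 in runs:
            span = w1 - w0 + 1
            if span < min_windows:
                continue
            in_run = (sub["window"] >= w0) & (sub["window"] <= w1)
            gsel = sub.loc[in_run, "gindex"].to_numpy()
            row = {
                "chrom": chrom,
                "start": int(sub.loc[sub["window"] == w0, "start"].iloc[0]),
                "end": int(sub.loc[sub["window"] == w1, "end"].iloc[0]),
                "first_window": int(w0),
                "last_window": int(w1),
                "n_windows": int(span),
            }
            for k in keys:
                row[f"mean_zfst_{k}"] = float(np.nanmean(zcols[k][gsel]))
            rows.append(row)
    cols = ["chrom", "start", "end", "first_window", "last_window", "n_windows"] + [
        f"mean_zfst_{k}" for k in keys
    ]
    return pd.DataFrame(rows, columns=cols)
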