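"""End-to-end orchestration: filter -> SFS -> statistics -> scan -> report.

:func:`scan_site_matrix` is the in-memory core used by tests and the
acceptance machinery; :func:`run_pipeline` wraps it with VCF/popmap input,
file output and logging.  All stages are pure functions of
(inputs, config, seed), so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import neutrality, scan, sfs
from .popdata import (
    FilterConfig,
    SampleTable,
    SiteMatrix,
    filter_sites,
    polarize_sites,
    read_popmap,
    read_variant_table,
    write_outputs,
)
from .windows import WindowGrid

logger = logging.getLogger("grousescan")

__all__ = ["RunConfig", "ScanResult", "scan_site_matrix", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything one scan run depends on; serializable and echoed verbatim
    into the JSON summary."""

    vcf: str | None = None
    popmap: str | None = None
    out_dir: str = "scan_out"
    window_size: int = 15_000
    zfst_threshold: float = 6.0
    min_snps: int = 10
    z_low: float = -1.0
    min_region_windows: int = 20
    max_gap: int = 2
    maf_min: float = 0.05
    min_call_rate: float = 1.0
    apply_depth: bool = True
    coverage: dict[str, float] | None = None  # falls back to popmap column
    polarization: str = "reference-is-ancestral"
    sample_corrected: bool = True
    seed: int = 0

    def filter_config(self, sample_table: SampleTable) -> FilterConfig:
        cov = self.coverage
        if cov is None and self.apply_depth:
            cov = {
                p: sample_table.mean_coverage(p) for p in sample_table.populations
            }
            if any(v is None for v in cov.values()):
                cov = None
        return FilterConfig(
            maf_min=self.maf_min,
            mean_taxon_coverage=cov,
            min_call_rate=self.min_call_rate,
            apply_depth=self.apply_depth,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ScanResult:
    """Products of one scan over a site matrix."""

    grid: WindowGrid
    window_table: pd.DataFrame               # long: pair rows + taxon rows
    zscans: dict[str, pd.DataFrame]          # per pair
    stats: dict[str, pd.DataFrame]           # per taxon window statistics
    outliers_by_pair: dict[str, pd.DataFrame]
    taxon_outliers: pd.DataFrame
    regions: pd.DataFrame
    summary: dict


def _grid_for(sm: SiteMatrix, window_size: int) -> WindowGrid:
    if sm.chrom_lengths:
        lengths = dict(sorted(sm.chrom_lengths.items()))
    else:  # fall back to the span actually covered by sites
        lengths = {
            str(c): int(sm.pos[sm.chrom == c].max())
            for c in sorted(np.unique(sm.chrom).tolist())
        }
    return WindowGrid(lengths, window_size)


def scan_site_matrix(
    sm: SiteMatrix, sample_table: SampleTable, config: RunConfig
) -> ScanResult:
    """Filter a polarized site matrix and run the full windowed analysis."""
    taxa = sample_table.populations
    fc = config.filter_config(sample_table)
    for pop in taxa:
        filter_sites(sm, pop, fc, sample_table)
    grid = _grid_for(sm, config.window_size)

    # per-taxon windowed SFS statistics
    stats: dict[str, pd.DataFrame] = {}
    for pop in taxa:
        xiw = sfs.windowed_marginal_sfs(sm, sample_table, pop, grid)
        frame = grid.to_frame().assign(**neutrality.window_stats(xiw))
        stats[pop] = frame

    # per-pair windowed F_ST and Z-scan
    zscans: dict[str, pd.DataFrame] = {}
    outliers: dict[str, pd.DataFrame] = {}
    for a, b in itertools.combinations(taxa, 2):
        key = scan.pair_key(a, b)
        comp = scan.site_components(sm, sample_table, a, b, config.sample_corrected)
        ftab = scan.window_fst(comp, grid, min_snps=config.min_snps)
        ztab = scan.zfst_transform(ftab)
        zscans[key] = ztab
        outliers[key] = scan.detect_outliers(ztab, config.zfst_threshold)

    taxon_outliers = (
        scan.taxon_specific_outliers(outliers, taxa)
        if len(taxa) == 3
        else pd.DataFrame(columns=["taxon", "chrom", "window", "start", "end", "pairs"])
    )
    regions = (
        scan.low_fst_regions(
            zscans,
            z_low=config.z_low,
            min_windows=config.min_region_windows,
            max_gap=config.max_gap,
        )
        if len(taxa) == 3
        else pd.DataFrame()
    )

    window_table = _long_window_table(zscans, stats)
    summary = _summarize(sm, zscans, stats, taxon_outliers, regions, config)
    return ScanResult(
        grid, window_table, zscans, stats, outliers, taxon_outliers, regions, summary
    )


def _long_window_table(
    zscans: dict[str, pd.DataFrame], stats: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    parts = []
    for key in sorted(zscans):
        t = zscans[key]
        parts.append(
            t[["chrom", "start", "end", "window", "fst", "zfst", "n_snps", "eligible"]]
            .assign(unit=f"pair:{key}")
        )
    for pop in stats:
        t = stats[pop]
        parts.append(
            t[
                ["chrom", "start", "end", "window", "S", "theta_pi", "theta_w",
                 "theta_h", "tajima_d", "fay_wu_h"]
            ].assign(unit=f"taxon:{pop}")
        )
    out = pd.concat(parts, ignore_index=True)
    front = ["unit", "chrom", "start", "end", "window"]
    return out[front + [c for c in out.columns if c not in front]]


def _summarize(sm, zscans, stats, taxon_outliers, regions, config) -> dict:
    fst_summary = {}
    for key, t in zscans.items():
        el = t["eligible"]
        fst_summary[key] = {
            "mean_fst": float(t.loc[el, "fst"].mean()),
            "sd_fst": float(t.loc[el, "fst"].std(ddof=0)),
            "n_eligible_windows": int(el.sum()),
            "n_outlier_windows": int((t.loc[el, "zfst"] >= config.zfst_threshold).sum()),
        }
    stat_summary = {}
    for pop, t in stats.items():
        defined = t["S"] > 0
        stat_summary[pop] = {
            "mean_tajima_d": float(t.loc[defined, "tajima_d"].mean()),
            "sd_tajima_d": float(t.loc[defined, "tajima_d"].std(ddof=0)),
            "mean_fay_wu_h": float(t.loc[defined, "fay_wu_h"].mean()),
            "sd_fay_wu_h": float(t.loc[defined, "fay_wu_h"].std(ddof=0)),
            "mean_theta_pi": float(t.loc[defined, "theta_pi"].mean()),
            "n_windows_with_snps": int(defined.sum()),
        }
    return {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_sites": int(sm.n_sites),
        "filter_counts": sm.filter_counts,
        "skipped_records": sm.skipped,
        "fst": fst_summary,
        "neutrality": stat_summary,
        "n_taxon_outliers": int(len(taxon_outliers)),
        "n_low_fst_regions": int(len(regions)),
    }


def run_pipeline(config: RunConfig) -> ScanResult:
    """File-to-file run: read VCF + popmap, scan, write all outputs.

    Writes windows.tsv, outliers.bed, low_fst_regions.bed, summary.json and
    run.log into ``config.out_dir``.  Any stage failure raises with the stage
    name; nothing is written until the scan has completed.
    """
    if config.vcf is None or config.popmap is None:
        raise ValueError("run_pipeline needs both a VCF and a popmap path")
    stage = "read_popmap"
    try:
        table = read_popmap(config.popmap)
        stage = "read_variant_table"
        sm = read_variant_table(config.vcf, table)
        stage = "polarize"
        sm = polarize_sites(sm, config.polarization)
        stage = "scan"
        result = scan_site_matrix(sm, table, config)
        stage = "write"
        paths = write_outputs(
            result.window_table,
            result.taxon_outliers,
            result.regions,
            config.out_dir,
            result.summary,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    with open(os.path.join(config.out_dir, "run.log"), "w") as fh:
        fh.write(f"stages completed through {stage}\n")
        fh.write(f"skipped records: {sm.skipped}\n")
        for pop, counts in sm.filter_counts.items():
            fh.write(f"filters[{pop}]: {counts}\n")
    logger.info("pipeline complete: %s", paths)
    return result
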