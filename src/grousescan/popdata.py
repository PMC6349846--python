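"""Input handling for genotype matrices and population maps.

This module turns a multi-sample VCF plus a two-column population map into a
:class:`SiteMatrix` of derived-allele dosages, polarizes alleles against an
ancestral convention, and applies the per-population site filters used
throughout the scan: minor-allele frequency, summed read depth relative to
expected coverage, and genotype call rate.  Sites are *masked* per population,
never deleted, so each population's retained set is independent of the others.
"""

from __future__ import annotations

import json
import logging
import math
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger("grousescan")

MISSING = -1  # dosage sentinel for an uncalled genotype

__all__ = [
    "SampleTable",
    "SiteMatrix",
    "FilterConfig",
    "read_popmap",
    "read_variant_table",
    "write_vcf",
    "polarize_sites",
    "filter_sites",
    "write_outputs",
]


# ---------------------------------------------------------------------------
# sample table


@dataclass
class SampleTable:
    """Sample -> population assignment, with optional expected coverage.

    ``frame`` has columns ``sample_id``, ``population`` and optionally
    ``mean_coverage`` (x-fold per-sample depth).  Sample order is preserved
    from the input file and defines dosage-matrix column order.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        ids = self.frame["sample_id"]
        dup = ids[ids.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate sample id: {dup.iloc[0]!r}")
        if len(self.frame) == 0:
            raise ValueError("sample table is empty")

    @property
    def samples(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        return self.frame["population"].drop_duplicates().tolist()

    def members(self, population: str) -> list[str]:
        sel = self.frame["population"] == population
        if not sel.any():
            raise KeyError(f"unknown population {population!r}")
        return self.frame.loc[sel, "sample_id"].tolist()

    def n_individuals(self, population: str) -> int:
        return len(self.members(population))

    def mean_coverage(self, population: str) -> float | None:
        if "mean_coverage" not in self.frame.columns:
            return None
        vals = self.frame.loc[self.frame["population"] == population, "mean_coverage"]
        if vals.isna().all():
            return None
        return float(vals.mean())


def read_popmap(path: str | os.PathLike) -> SampleTable:
    """Read a whitespace-delimited sample -> population map.

    Columns: sample id, population label, optional per-sample mean coverage.
    A header line is accepted if its first field is ``sample`` or
    ``sample_id`` (case-insensitive).  Lines starting with ``#`` are ignored.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append(line.split())
    if not rows:
        raise ValueError(f"popmap {path} is empty")
    if rows[0][0].lower() in {"sample", "sample_id"}:
        rows = rows[1:]
        if not rows:
            raise ValueError(f"popmap {path} has a header but no samples")
    ids = [r[0] for r in rows]
    pops = [r[1] for r in rows]
    frame = pd.DataFrame({"sample_id": ids, "population": pops})
    if any(len(r) > 2 for r in rows):
        frame["mean_coverage"] = [float(r[2]) if len(r) > 2 else np.nan for r in rows]
    table = SampleTable(frame)
    for pop in table.populations:
        n = table.n_individuals(pop)
        if n < 3:
            warnings.warn(
                f"population {pop!r} has only {n} sample(s); "
                "frequency estimates and F_ST corrections will be noisy",
                stacklevel=2,
            )
    return table


# ---------------------------------------------------------------------------
# site matrix


@dataclass
class SiteMatrix:
    """Polarized biallelic sites x samples.

    ``dosage[s, j]`` counts copies of the derived allele carried by diploid
    sample ``j`` at site ``s`` (0, 1, 2, or -1 for missing).  ``ancestral`` /
    ``derived`` hold the two observed alleles under the active polarization.
    Per-population boolean retention masks live in ``masks`` and are attached
    by :func:`filter_sites`; a site absent from a population's mask simply
    does not contribute to that population's statistics.
    """

    chrom: np.ndarray          # str per site
    pos: np.ndarray            # int64, 1-based
    ancestral: np.ndarray      # allele strings
    derived: np.ndarray
    dosage: np.ndarray         # int8 (n_sites, n_samples)
    samples: list[str]
    depth: np.ndarray | None = None      # int32 (n_sites, n_samples)
    chrom_lengths: dict[str, int] | None = None
    aa: np.ndarray | None = None         # INFO/AA ancestral tag, "" if absent
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    filter_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    skipped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n, k = self.dosage.shape
        if not (len(self.chrom) == len(self.pos) == n):
            raise ValueError("site arrays and dosage rows disagree")
        if len(self.samples) != k:
            raise ValueError("sample list and dosage columns disagree")
        for name in np.unique(self.chrom):
            p = self.pos[self.chrom == name]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {name}")

    @property
    def n_sites(self) -> int:
        return self.dosage.shape[0]

    def sample_cols(self, sample_ids: list[str]) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([index[s] for s in sample_ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not present in variant data") from None

    def pop_cols(self, sample_table: SampleTable, population: str) -> np.ndarray:
        return self.sample_cols(sample_table.members(population))

    def pop_depth(self, sample_table: SampleTable, population: str) -> np.ndarray:
        """Per-site summed read depth over the population's samples."""
        if self.depth is None:
            raise ValueError("no per-sample depth available")
        cols = self.pop_cols(sample_table, population)
        return self.depth[:, cols].sum(axis=1)

    def mask_for(self, population: str) -> np.ndarray:
        """Retention mask for a population (all-true when never filtered)."""
        if population in self.masks:
            return self.masks[population]
        return np.ones(self.n_sites, dtype=bool)

    def derived_freq(self, sample_table: SampleTable, population: str) -> np.ndarray:
        """Per-site derived-allele sample frequency from non-missing genotypes
        (NaN where no genotype is called)."""
        cols = self.pop_cols(sample_table, population)
        d = self.dosage[:, cols]
        called = d != MISSING
        n_chr = 2 * called.sum(axis=1)
        tot = np.where(called, d, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_chr > 0, tot / np.maximum(n_chr, 1), np.nan)


# ---------------------------------------------------------------------------
# VCF reading / writing


def read_variant_table(path: str | os.PathLike, sample_table: SampleTable) -> SiteMatrix:
    """Read biallelic SNPs from a VCF into a :class:`SiteMatrix`.

    Multi-allelic records and indels are skipped and counted.  Genotypes come
    from GT (``./.`` -> missing), per-sample depth from FORMAT/DP when
    present.  VCF samples must be a superset of the sample table; dosage
    columns follow sample-table order.
    """
    vcf = VCF(str(path), gts012=True)
    missing = [s for s in sample_table.samples if s not in vcf.samples]
    if missing:
        raise ValueError(f"sample(s) in popmap absent from VCF: {missing}")
    col_of = {s: i for i, s in enumerate(vcf.samples)}
    take = np.array([col_of[s] for s in sample_table.samples], dtype=np.intp)

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    aas: list[str] = []
    dosages: list[np.ndarray] = []
    depths: list[np.ndarray] = []
    have_dp = True
    skipped = {"indel": 0, "multiallelic": 0, "malformed": 0}

    for var in vcf:
        try:
            if len(var.ALT) != 1:
                skipped["multiallelic"] += 1
                continue
            if var.is_indel or len(var.REF) != 1 or len(var.ALT[0]) != 1:
                skipped["indel"] += 1
                continue
            # gts012: 0=hom ref, 1=het, 2=hom alt, 3=unknown
            gt = var.gt_types.astype(np.int8)
            gt[gt == 3] = MISSING
            dosages.append(gt[take])
            if have_dp:
                dp = var.format("DP")
                if dp is None:
                    have_dp = False
                else:
                    dp = dp.astype(np.int64).reshape(-1)
                    dp[dp < 0] = 0
                    depths.append(dp[take].astype(np.int32))
            chroms.append(var.CHROM)
            poss.append(var.POS)
            refs.append(var.REF)
            alts.append(var.ALT[0])
            aa = var.INFO.get("AA")
            aas.append(aa if isinstance(aa, str) else "")
        except Exception:  # malformed record: count and move on
            skipped["malformed"] += 1

    lengths = None
    if vcf.seqnames and vcf.seqlens:
        lengths = {n: l for n, l in zip(vcf.seqnames, vcf.seqlens) if l > 0}
    vcf.close()

    n = len(chroms)
    if sum(skipped.values()):
        logger.info(
            "read_variant_table: kept %d sites, skipped %s", n, skipped
        )
    dosage = (
        np.vstack(dosages) if n else np.empty((0, len(sample_table.samples)), dtype=np.int8)
    )
    depth = np.vstack(depths) if (have_dp and depths) else None
    return SiteMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ancestral=np.array(refs, dtype=object),
        derived=np.array(alts, dtype=object),
        dosage=dosage,
        samples=list(sample_table.samples),
        depth=depth,
        chrom_lengths=lengths,
        aa=np.array(aas, dtype=object),
        skipped=skipped,
    )


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(sm: SiteMatrix, path: str | os.PathLike) -> None:
    """Write a SiteMatrix as a plain-text VCF (REF = ancestral allele).

    The ancestral allele is also echoed in INFO/AA so the file round-trips
    under either polarization mode.  Output is deterministic for a given
    matrix.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=grousescan\n")
        if sm.chrom_lengths:
            for name, length in sm.chrom_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if sm.depth is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sm.samples)
            + "\n"
        )
        fmt = "GT:DP" if sm.depth is not None else "GT"
        for s in range(sm.n_sites):
            if sm.depth is not None:
                cells = [
                    f"{_GT_STR[int(g)]}:{int(dp)}"
                    for g, dp in zip(sm.dosage[s], sm.depth[s])
                ]
            else:
                cells = [_GT_STR[int(g)] for g in sm.dosage[s]]
            fh.write(
                f"{sm.chrom[s]}\t{sm.pos[s]}\t.\t{sm.ancestral[s]}\t{sm.derived[s]}"
                f"\t.\tPASS\tAA={sm.ancestral[s]}\t{fmt}\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# polarization


def polarize_sites(sm: SiteMatrix, mode: str = "reference-is-ancestral") -> SiteMatrix:
    """Orient dosages so they count the *derived* allele.

    ``reference-is-ancestral`` (default) treats REF as ancestral — the
    convention when reads are mapped to an outgroup-matched reference genome,
    so ALT dosages are already derived counts.  ``aa-tag`` reads the INFO/AA
    annotation: sites where AA equals the ALT allele are flipped
    (dosage -> 2 - dosage) and sites lacking a usable AA call are dropped and
    counted in ``skipped['unpolarized']``.
    """
    if mode == "reference-is-ancestral":
        return sm
    if mode != "aa-tag":
        raise ValueError(f"unknown polarization mode {mode!r}")
    if sm.aa is None:
        raise ValueError("aa-tag polarization requires INFO/AA annotations")
    aa = np.asarray(sm.aa, dtype=object)
    is_anc = aa == sm.ancestral
    is_der = aa == sm.derived
    keep = is_anc | is_der
    dropped = int((~keep).sum())

    dosage = sm.dosage[keep].copy()
    anc = sm.ancestral[keep].copy()
    der = sm.derived[keep].copy()
    flip = is_der[keep]
    sub = dosage[flip]
    sub[sub != MISSING] = 2 - sub[sub != MISSING]
    dosage[flip] = sub
    anc[flip], der[flip] = sm.derived[keep][flip], sm.ancestral[keep][flip]

    skipped = dict(sm.skipped)
    skipped["unpolarized"] = skipped.get("unpolarized", 0) + dropped
    return SiteMatrix(
        chrom=sm.chrom[keep],
        pos=sm.pos[keep],
        ancestral=anc,
        derived=der,
        dosage=dosage,
        samples=list(sm.samples),
        depth=None if sm.depth is None else sm.depth[keep],
        chrom_lengths=sm.chrom_lengths,
        aa=aa[keep],
        skipped=skipped,
    )


# ---------------------------------------------------------------------------
# site filters


@dataclass
class FilterConfig:
    """Per-population site filters.

    maf_min
        Minimum minor-allele frequency; sites are retained when
        ``min(p, 1-p) > maf_min`` strictly (default 0.05).
    depth_min_factor / depth_max_factor
        Bounds on summed population depth as multiples of
        ``mean_taxon_coverage * n_individuals``; the lower bound is floored to
        an integer, both bounds are inclusive.
    mean_taxon_coverage
        x-fold coverage, either one value for all populations or a mapping
        population -> coverage.  Required when ``apply_depth``.
    min_call_rate
        Minimum fraction of non-missing genotypes per population (default 1.0:
        complete cases only, keeping the SFS sample size fixed).
    """

    maf_min: float = 0.05
    depth_min_factor: float = 1.0 / 3.0
    depth_max_factor: float = 2.0
    mean_taxon_coverage: float | dict[str, float] | None = None
    min_call_rate: float = 1.0
    apply_depth: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must lie in [0, 0.5)")
        if self.depth_min_factor >= self.depth_max_factor:
            raise ValueError("depth_min_factor must be below depth_max_factor")
        if not 0 <= self.min_call_rate <= 1:
            raise ValueError("min_call_rate must lie in [0, 1]")

    def coverage_for(self, population: str) -> float:
        cov = self.mean_taxon_coverage
        if isinstance(cov, dict):
            cov = cov.get(population)
        if cov is None:
            raise ValueError(
                f"depth filter enabled but mean coverage unset for {population!r}"
            )
        if cov <= 0:
            raise ValueError("coverage must be positive")
        return float(cov)

    def depth_bounds(self, population: str, n_individuals: int) -> tuple[int, float]:
        cov = self.coverage_for(population)
        # small epsilon so 1/3 * 28 * 6 floors to 56, not 55 via float error
        return (
            math.floor(self.depth_min_factor * cov * n_individuals + 1e-9),
            self.depth_max_factor * cov * n_individuals,
        )


def filter_sites(
    sm: SiteMatrix,
    population: str,
    config: FilterConfig,
    sample_table: SampleTable,
) -> SiteMatrix:
    """Attach the retention mask for one population.

    Filters, applied in order with each drop attributed to the first failing
    filter: call rate, summed depth within the coverage-derived bounds, minor
    allele frequency strictly above ``maf_min``.  The mask is recomputed from
    all sites each call, so filtering is idempotent and populations never
    interact.
    """
    cols = sm.pop_cols(sample_table, population)
    n_ind = len(cols)
    d = sm.dosage[:, cols]
    called = d != MISSING

    ok_call = called.mean(axis=1) >= config.min_call_rate

    if config.apply_depth:
        lo, hi = config.depth_bounds(population, n_ind)
        if sm.depth is None:
            raise ValueError("depth filter enabled but the VCF carried no DP field")
        pd_sum = sm.depth[:, cols].sum(axis=1)
        ok_depth = (pd_sum >= lo) & (pd_sum <= hi)
    else:
        ok_depth = np.ones(sm.n_sites, dtype=bool)

    n_chr = 2 * called.sum(axis=1)
    tot = np.where(called, d, 0).sum(axis=1)
    # integer allele counts keep the strict > boundary exact (0.05 of 20
    # chromosomes is exactly one copy, which must be masked, not kept)
    minor = np.minimum(tot, n_chr - tot)
    ok_maf = minor > config.maf_min * n_chr  # n_chr == 0 fails automatically

    mask = ok_call & ok_depth & ok_maf
    counts = {
        "total": sm.n_sites,
        "callrate": int((~ok_call).sum()),
        "depth": int((ok_call & ~ok_depth).sum()),
        "maf": int((ok_call & ok_depth & ~ok_maf).sum()),
        "retained": int(mask.sum()),
    }
    assert counts["total"] == sum(counts[k] for k in ("callrate", "depth", "maf", "retained"))
    sm.masks[population] = mask
    sm.filter_counts[population] = counts
    logger.info("filter_sites[%s]: %s", population, counts)
    return sm


# ---------------------------------------------------------------------------
# output writing


def _write_bed(path: str, rows: list[tuple], header: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"#{header}\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_outputs(
    window_table: pd.DataFrame,
    outlier_calls: pd.DataFrame,
    regions: pd.DataFrame,
    out_dir: str | os.PathLike,
    summary: dict,
) -> dict[str, str]:
    """Write the scan products: window TSV, outlier/region BEDs, JSON summary.

    All intervals are emitted 0-based half-open (BED convention).  The output
    directory is probed for writability before anything is written, so a bad
    destination never leaves partial output.
    """
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    probe = os.path.join(out_dir, ".write_probe")
    try:
        with open(probe, "w"):
            pass
        os.remove(probe)
    except OSError as exc:
        raise OSError(f"output directory {out_dir!r} is not writable") from exc

    paths = {
        "windows": os.path.join(out_dir, "windows.tsv"),
        "outliers": os.path.join(out_dir, "outliers.bed"),
        "regions": os.path.join(out_dir, "low_fst_regions.bed"),
        "summary": os.path.join(out_dir, "summary.json"),
    }
    window_table.to_csv(paths["windows"], sep="\t", index=False, float_format="%.6g")

    out_rows = [
        (r.chrom, r.start, r.end, f"{r.taxon}|{r.pairs}")
        for r in outlier_calls.itertuples()
    ]
    _write_bed(paths["outliers"], out_rows, "chrom\tstart\tend\ttaxon|pairs")

    reg_rows = [
        (r.chrom, r.start, r.end, f"n_windows={r.n_windows}")
        for r in regions.itertuples()
    ]
    _write_bed(paths["regions"], reg_rows, "chrom\tstart\tend\tname")

    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return paths
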