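"""Population map, VCF I/O, polarization and site-filter behaviour."""

import json

import numpy as np
import pandas as pd
import pytest

from conftest import build_site_matrix, sample_table
from grousescan.popdata import (
    MISSING,
    FilterConfig,
    filter_sites,
    polarize_sites,
    read_popmap,
    read_variant_table,
    write_outputs,
    write_vcf,
)
from grousescan.windows import WindowGrid


# ---------------------------------------------------------------------------
# popmap


def test_read_popmap_three_taxa(tmp_path):
    """The study layout: 34 samples in three populations of 19/9/6."""
    lines = (
        [f"w{i}\twillow" for i in range(19)]
        + [f"r{i}\tred" for i in range(9)]
        + [f"k{i}\trock" for i in range(6)]
    )
    p = tmp_path / "popmap.tsv"
    p.write_text("\n".join(lines) + "\n")
    table = read_popmap(p)
    assert table.populations == ["willow", "red", "rock"]
    assert [table.n_individuals(t) for t in table.populations] == [19, 9, 6]
    assert len(table.samples) == 34


def test_read_popmap_single_sample_warns(tmp_path):
    p = tmp_path / "popmap.tsv"
    p.write_text("s1 popA\n")
    with pytest.warns(UserWarning, match="popA"):
        table = read_popmap(p)
    assert table.populations == ["popA"]


def test_read_popmap_duplicate_and_empty(tmp_path):
    p = tmp_path / "dup.tsv"
    p.write_text("s1 popA\ns1 popA\n")
    with pytest.raises(ValueError, match="s1"):
        read_popmap(p)
    q = tmp_path / "empty.tsv"
    q.write_text("")
    with pytest.raises(ValueError):
        read_popmap(q)


def test_read_popmap_header_and_coverage(tmp_path):
    p = tmp_path / "popmap.tsv"
    p.write_text("sample_id\tpopulation\tmean_coverage\n" + "\n".join(
        f"s{i}\tpopA\t28.0" for i in range(4)) + "\n")
    table = read_popmap(p)
    assert table.mean_coverage("popA") == 28.0


# ---------------------------------------------------------------------------
# VCF reading

TOY_VCF = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1\ts2
chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT:DP\t0/0:10\t0/1:12\t1/1:9
chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT:DP\t0/1:8\t0/1:11\t0/0:10
chr1\t300\t.\tG\tGA\t.\tPASS\t.\tGT:DP\t0/0:10\t0/0:10\t0/0:10
chr1\t400\t.\tT\tC\t.\tPASS\t.\tGT:DP\t./.:0\t0/1:10\t1/1:12
chr1\t500\t.\tA\tC\t.\tPASS\t.\tGT:DP\t1/1:11\t1/1:9\t1/1:13
chr1\t600\t.\tAT\tA\t.\tPASS\t.\tGT:DP\t0/0:10\t0/1:10\t0/0:10
chr1\t700\t.\tC\tA\t.\tPASS\t.\tGT:DP\t0/0:9\t0/0:8\t0/1:10
chr1\t800\t.\tG\tT\t.\tPASS\t.\tGT:DP\t0/1:12\t0/0:11\t0/0:9
chr1\t900\t.\tT\tA\t.\tPASS\t.\tGT:DP\t0/0:10\t0/1:10\t0/1:11
chr1\t950\t.\tA\tT\t.\tPASS\t.\tGT:DP\t0/1:10\t0/0:12\t0/0:10
"""


def test_read_variant_table_skips_indels_and_counts(tmp_path):
    """10 records, 2 indels: 8 SNP rows kept and the skip log says why."""
    vcf = tmp_path / "toy.vcf"
    vcf.write_text(TOY_VCF)
    table = sample_table({"popA": 3})
    table.frame["sample_id"] = ["s0", "s1", "s2"]
    sm = read_variant_table(vcf, table)
    assert sm.n_sites == 8
    assert sm.skipped["indel"] == 2
    # missing genotype convention at chr1:400 sample s0
    row = np.where(sm.pos == 400)[0][0]
    assert sm.dosage[row, 0] == MISSING
    assert sm.dosage[row, 1] == 1 and sm.dosage[row, 2] == 2
    assert sm.chrom_lengths == {"chr1": 100000}
    # depth came through
    assert sm.depth[0].tolist() == [10, 12, 9]


def test_read_variant_table_missing_sample_errors(tmp_path):
    vcf = tmp_path / "toy.vcf"
    vcf.write_text(TOY_VCF)
    table = sample_table({"popA": 2})
    table.frame["sample_id"] = ["s0", "absent"]
    with pytest.raises(ValueError, match="absent"):
        read_variant_table(vcf, table)


def test_vcf_round_trip_exact(tmp_path, tiny_neutral):
    """Write-then-read on generated data reproduces dosage and depth exactly."""
    sm, table, _, _, _ = tiny_neutral
    path = tmp_path / "rt.vcf"
    write_vcf(sm, path)
    back = read_variant_table(path, table)
    np.testing.assert_array_equal(back.dosage, sm.dosage)
    np.testing.assert_array_equal(back.depth, sm.depth)
    np.testing.assert_array_equal(back.pos, sm.pos)
    assert back.chrom_lengths == sm.chrom_lengths
    assert (back.ancestral == sm.ancestral).all()


# ---------------------------------------------------------------------------
# polarization


def test_polarize_default_counts_alt_as_derived():
    sm = build_site_matrix([[0, 1, 2]])
    out = polarize_sites(sm)
    assert out.dosage[0].tolist() == [0, 1, 2]


def test_polarize_aa_tag_flips_and_drops():
    # site0: AA == REF (keep), site1: AA == ALT (flip), site2: AA missing (drop)
    sm = build_site_matrix(
        [[0, 1, 2], [0, 1, 2], [1, 1, 1]], aa=["A", "G", ""]
    )
    out = polarize_sites(sm, mode="aa-tag")
    assert out.n_sites == 2
    assert out.dosage[0].tolist() == [0, 1, 2]
    assert out.dosage[1].tolist() == [2, 1, 0]
    assert out.ancestral[1] == "G" and out.derived[1] == "A"
    assert out.skipped["unpolarized"] == 1


def test_polarize_aa_tag_preserves_missing():
    sm = build_site_matrix([[MISSING, 1, 2]], aa=["G"])
    out = polarize_sites(sm, mode="aa-tag")
    assert out.dosage[0].tolist() == [MISSING, 1, 0]


def test_polarize_unknown_mode():
    with pytest.raises(ValueError, match="mode"):
        polarize_sites(build_site_matrix([[0, 1, 0]]), mode="nonsense")


def test_fully_derived_site_retained():
    """Fixed-derived sites survive polarization (they fill SFS bin m)."""
    sm = build_site_matrix([[2, 2, 2]])
    out = polarize_sites(sm)
    assert out.n_sites == 1


# ---------------------------------------------------------------------------
# filters


def test_depth_bounds_printed_formula():
    """cov=28, n=6 diploids -> summed-depth bounds [56, 336]."""
    fc = FilterConfig(mean_taxon_coverage=28.0)
    assert fc.depth_bounds("rock", 6) == (56, 336.0)


def test_maf_strictly_greater():
    """Derived frequency 0.97 (MAF 0.03) is masked; MAF must exceed 0.05."""
    # 10 diploids: 19 derived copies of 20 -> p=0.95 -> MAF 0.05 -> masked (not >)
    # and 0.97-style case with 17 of 20 kept
    d_boundary = [[2] * 9 + [1]]
    d_kept = [[2] * 7 + [1] * 3]
    table = sample_table({"popA": 10})
    fc = FilterConfig(apply_depth=False)
    sm = build_site_matrix(np.vstack([d_boundary, d_kept]), samples=table.samples)
    filter_sites(sm, "popA", fc, table)
    assert sm.masks["popA"].tolist() == [False, True]
    assert sm.filter_counts["popA"]["maf"] == 1


def test_missing_genotype_masks_locally():
    """A missing call masks the site for that population only."""
    table = sample_table({"popA": 2, "popB": 2})
    dosage = [[MISSING, 1, 1, 1], [1, 1, 1, 1]]
    sm = build_site_matrix(dosage, samples=table.samples)
    fc = FilterConfig(maf_min=0.0, apply_depth=False)
    filter_sites(sm, "popA", fc, table)
    filter_sites(sm, "popB", fc, table)
    assert sm.masks["popA"].tolist() == [False, True]
    assert sm.masks["popB"].tolist() == [True, True]


def test_filter_idempotent_and_conserves_counts():
    rng = np.random.default_rng(0)
    table = sample_table({"popA": 5}, coverage=20.0)
    dosage = rng.integers(0, 3, size=(200, 5)).astype(np.int8)
    depth = rng.poisson(20, size=(200, 5))
    sm = build_site_matrix(dosage, samples=table.samples, depth=depth)
    fc = FilterConfig(mean_taxon_coverage=20.0)
    filter_sites(sm, "popA", fc, table)
    first = sm.masks["popA"].copy()
    counts = dict(sm.filter_counts["popA"])
    filter_sites(sm, "popA", fc, table)
    np.testing.assert_array_equal(first, sm.masks["popA"])
    assert counts == sm.filter_counts["popA"]
    assert counts["total"] == counts["retained"] + counts["callrate"] + counts[
        "depth"
    ] + counts["maf"]


def test_masks_are_independent_between_populations():
    table = sample_table({"popA": 3, "popB": 3})
    rng = np.random.default_rng(1)
    dosage = rng.integers(0, 3, size=(100, 6)).astype(np.int8)
    sm = build_site_matrix(dosage, samples=table.samples)
    fc = FilterConfig(apply_depth=False)
    filter_sites(sm, "popB", fc, table)
    before = sm.masks["popB"].copy()
    filter_sites(sm, "popA", FilterConfig(maf_min=0.4, apply_depth=False), table)
    np.testing.assert_array_equal(before, sm.masks["popB"])


def test_depth_filter_requires_coverage():
    table = sample_table({"popA": 2})
    sm = build_site_matrix([[0, 1]], samples=table.samples, depth=[[5, 5]])
    with pytest.raises(ValueError, match="coverage"):
        filter_sites(sm, "popA", FilterConfig(), table)


# ---------------------------------------------------------------------------
# window grid anchoring and outputs


def test_window_grid_matches_published_coordinates():
    """A 15-kb grid anchored at 0 puts 95.610-95.625 Mb at window 6374."""
    grid = WindowGrid({"chr2": 100_000_000})
    assert grid.global_index(np.array(["chr2"]), np.array([95_610_001]))[0] == 6374
    assert grid.bounds("chr2", 6374) == (95_610_000, 95_625_000)
    # a position on the boundary belongs to the window containing pos-1
    assert grid.local_index(95_610_000) == 6373


def test_partial_terminal_window_retained():
    grid = WindowGrid({"chr1": 40_000})
    assert grid.n_windows("chr1") == 3
    assert grid.bounds("chr1", 2) == (30_000, 40_000)
    assert grid.is_partial("chr1", 2)


def test_write_outputs(tmp_path):
    windows = pd.DataFrame(
        {"unit": ["pair:a-b"], "chrom": ["chr2"], "start": [0], "end": [15000],
         "window": [0], "fst": [0.1]}
    )
    outliers = pd.DataFrame(
        [{"taxon": "willow", "chrom": "chr2", "window": 6374,
          "start": 95_610_000, "end": 95_625_000, "pairs": "red-willow,rock-willow"}]
    )
    regions = pd.DataFrame(columns=["chrom", "start", "end", "n_windows"])
    paths = write_outputs(windows, outliers, regions, tmp_path / "out", {"seed": 42})
    bed = (tmp_path / "out" / "outliers.bed").read_text().splitlines()
    assert bed[1].startswith("chr2\t95610000\t95625000\twillow|")
    region_lines = (tmp_path / "out" / "low_fst_regions.bed").read_text().splitlines()
    assert len(region_lines) == 1 and region_lines[0].startswith("#")
    summary = json.loads((tmp_path / "out" / "summary.json").read_text())
    assert summary["seed"] == 42
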