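"""Three-population synthetic genotype generator with known truth.

The generator draws independent biallelic sites under a hierarchical
Balding–Nichols model on the species tree ``((willow, red), rock)``:

* an ancestral derived-allele frequency ``p0`` is drawn from a discrete
  spectrum over classes ``i / m_ref`` with class probabilities proportional
  to ``i**-alpha`` — ``alpha = 1`` is the constant-size neutral shape,
  ``alpha > 1`` skews mass toward rare derived alleles, mimicking the excess
  of low-frequency variants left by population expansion;
* each branch applies Balding–Nichols drift
  ``p' ~ Beta(p(1-F)/F, (1-p)(1-F)/F)``, which preserves the mean and has
  variance ``p(1-p)F``;
* inside a designated *sweep* window, the focal taxon's frequency is pushed
  toward fixation by ``p -> p**(1/kappa)`` (a lineage-specific sweep
  signature: high F_ST against both other taxa, excess high-frequency
  derived alleles);
* inside the *conserved* region every branch F is multiplied by
  ``delta`` in [0, 1], damping drift in all lineages at once — the uniform
  selection signature of a jointly low-F_ST block.

Diploid genotypes are binomial draws from the population frequency and
per-sample read depth is Poisson at the taxon's mean coverage.  Everything
is driven by one seed; the same config yields byte-identical VCF output.
No linkage is simulated: sites are exchangeable within and across windows.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .popdata import MISSING, SampleTable, SiteMatrix, write_vcf
from .windows import WindowGrid

import pandas as pd

__all__ = [
    "SweepSpec",
    "ConservedSpec",
    "SimConfig",
    "TruthTable",
    "balding_nichols",
    "simulate_dataset",
    "expected_pairwise_fst",
    "make_fixture",
    "FIXTURE_NAMES",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SweepSpec:
    """A lineage-specific sweep confined to one interval (0-based half-open)."""

    taxon: str
    chrom: str
    start: int
    end: int
    kappa: float = 50.0

    def __post_init__(self):
        if self.kappa < 1:
            raise ValueError("sweep intensity kappa must be >= 1")
        if self.end <= self.start:
            raise ValueError("empty sweep interval")


@dataclass(frozen=True)
class ConservedSpec:
    """A drift-damped (uniform-selection) region shared by all lineages."""

    chrom: str
    start: int
    end: int
    delta: float = 0.02

    def __post_init__(self):
        if not 0 <= self.delta <= 1:
            raise ValueError("delta must lie in [0, 1]")
        if self.end <= self.start:
            raise ValueError("empty conserved interval")


@dataclass
class SimConfig:
    """Generator parameters.

    Defaults mirror the study system: samples (willow 19, red 9, rock 6
    diploids), mean coverage (29x / 28x / 28x), an expansion-skewed ancestral
    spectrum (alpha = 1.6 over m_ref = 1000 frequency classes — a fine grid
    approximating the continuous frequency density, coarse grids truncate the
    rare-variant tail and bias Tajima's D upward) and branch
    drifts (F_node = 0.05 shared by the sister pair; F_willow = F_red = 0.06;
    F_rock = 0.20) chosen so the sister pair is the least differentiated and
    the comparisons involving rock ptarmigan diverge most.
    """

    seed: int = 0
    chromosomes: tuple[tuple[str, int], ...] = (("chr1", 3_000_000),)
    n_sites: int = 10_000
    samples_per_pop: dict[str, int] = field(
        default_factory=lambda: {"willow": 19, "red": 9, "rock": 6}
    )
    coverage: dict[str, float] = field(
        default_factory=lambda: {"willow": 29.0, "red": 28.0, "rock": 28.0}
    )
    alpha: float = 1.6
    m_ref: int = 1000
    f_node: float = 0.05
    f_willow: float = 0.06
    f_red: float = 0.06
    f_rock: float = 0.20
    sweeps: tuple[SweepSpec, ...] = ()
    conserved: ConservedSpec | None = None
    window_size: int = 15_000

    def __post_init__(self):
        for f in (self.f_node, self.f_willow, self.f_red, self.f_rock):
            if not 0 <= f < 1:
                raise ValueError("branch drift F must lie in [0, 1)")
        if self.conserved is not None:
            for sw in self.sweeps:
                if sw.chrom == self.conserved.chrom and not (
                    sw.end <= self.conserved.start or sw.start >= self.conserved.end
                ):
                    raise ValueError(
                        "sweep window overlaps the conserved region; "
                        "ground truth would be ambiguous"
                    )
        known = set(self.samples_per_pop)
        for sw in self.sweeps:
            if sw.taxon not in known:
                raise ValueError(f"sweep names unknown taxon {sw.taxon!r}")

    @property
    def taxa(self) -> list[str]:
        return list(self.samples_per_pop)

    def grid(self) -> WindowGrid:
        return WindowGrid(dict(self.chromosomes), self.window_size)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TruthTable:
    """Ground truth of one simulated dataset."""

    sweeps: tuple[SweepSpec, ...]
    conserved: ConservedSpec | None
    p0: np.ndarray                      # ancestral frequency per site
    pop_freq: dict[str, np.ndarray]     # realized branch-tip frequency per site

    def sweep_windows(self, grid: WindowGrid) -> pd.DataFrame:
        """Sweep intervals expressed as grid windows (one row per window)."""
        rows = []
        for sw in self.sweeps:
            w0 = sw.start // grid.window_size
            w1 = (sw.end - 1) // grid.window_size
            for w in range(w0, w1 + 1):
                start, end = grid.bounds(sw.chrom, w)
                rows.append(
                    {"taxon": sw.taxon, "chrom": sw.chrom, "window": w,
                     "start": start, "end": end}
                )
        return pd.DataFrame(rows, columns=["taxon", "chrom", "window", "start", "end"])

    def write_bed(self, path: str, grid: WindowGrid) -> None:
        with open(path, "w") as fh:
            fh.write("#chrom\tstart\tend\tname\n")
            for sw in self.sweeps:
                fh.write(f"{sw.chrom}\t{sw.start}\t{sw.end}\tsweep|{sw.taxon}\n")
            if self.conserved is not None:
                c = self.conserved
                fh.write(f"{c.chrom}\t{c.start}\t{c.end}\tconserved|delta={c.delta}\n")


# ---------------------------------------------------------------------------


def balding_nichols(rng: np.random.Generator, p: np.ndarray, f) -> np.ndarray:
    """One generation of Balding–Nichols drift: mean-preserving Beta draw.

    ``f`` may be a scalar or a per-site array; ``f = 0`` entries (and fixed
    frequencies 0/1) pass through unchanged.
    """
    p = np.asarray(p, dtype=np.float64)
    f = np.broadcast_to(np.asarray(f, dtype=np.float64), p.shape)
    out = p.copy()
    active = (f > 0) & (p > 0) & (p < 1)
    if active.any():
        ratio = (1 - f[active]) / f[active]
        out[active] = rng.beta(p[active] * ratio, (1 - p[active]) * ratio)
    return out


def _spectrum_probs(alpha: float, m_ref: int) -> np.ndarray:
    i = np.arange(1, m_ref)
    w = i.astype(np.float64) ** -alpha
    return w / w.sum()


def _site_positions(
    rng: np.random.Generator, chromosomes: tuple[tuple[str, int], ...], n_sites: int
) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.array([l for _, l in chromosomes], dtype=np.float64)
    counts = rng.multinomial(n_sites, lengths / lengths.sum())
    chroms, poss = [], []
    for (name, length), n_c in zip(chromosomes, counts):
        # rejection-free uniform draw without replacement: oversample, dedupe,
        # then thin uniformly so no region is favoured
        chosen = np.array([], dtype=np.int64)
        while len(chosen) < n_c:
            extra = rng.integers(1, length + 1, size=n_c + 4 * (n_c - len(chosen)))
            chosen = np.unique(np.concatenate([chosen, extra]))
        if len(chosen) > n_c:
            chosen = chosen[np.sort(rng.choice(len(chosen), size=n_c, replace=False))]
        chroms.append(np.full(n_c, name, dtype=object))
        poss.append(chosen)
    return np.concatenate(chroms), np.concatenate(poss)


def _interval_mask(chrom: np.ndarray, pos: np.ndarray, c: str, start: int, end: int):
    return (chrom == c) & (pos - 1 >= start) & (pos - 1 < end)


def simulate_dataset(config: SimConfig) -> tuple[SiteMatrix, SampleTable, TruthTable]:
    """Draw a full dataset: site matrix with depths, sample table, truth."""
    rng = np.random.default_rng(config.seed)
    chrom, pos = _site_positions(rng, config.chromosomes, config.n_sites)
    n = len(pos)

    probs = _spectrum_probs(config.alpha, config.m_ref)
    classes = rng.choice(np.arange(1, config.m_ref), size=n, p=probs)
    p0 = classes / config.m_ref

    damp = np.ones(n)
    if config.conserved is not None:
        c = config.conserved
        damp[_interval_mask(chrom, pos, c.chrom, c.start, c.end)] = c.delta

    p_node = balding_nichols(rng, p0, config.f_node * damp)
    freq = {
        "willow": balding_nichols(rng, p_node, config.f_willow * damp),
        "red": balding_nichols(rng, p_node, config.f_red * damp),
        "rock": balding_nichols(rng, p0, config.f_rock * damp),
    }
    freq = {t: freq[t] for t in config.taxa}  # respect configured taxon order

    for sw in config.sweeps:
        hit = _interval_mask(chrom, pos, sw.chrom, sw.start, sw.end)
        freq[sw.taxon][hit] = freq[sw.taxon][hit] ** (1.0 / sw.kappa)

    # genotypes and depths, sample-major within each taxon
    sample_ids, pops, dosage_cols, depth_cols = [], [], [], []
    for taxon in config.taxa:
        k = config.samples_per_pop[taxon]
        geno = rng.binomial(2, freq[taxon][:, None], size=(n, k)).astype(np.int8)
        depth = rng.poisson(config.coverage[taxon], size=(n, k)).astype(np.int32)
        geno[depth == 0] = MISSING  # no reads, no call
        dosage_cols.append(geno)
        depth_cols.append(depth)
        sample_ids += [f"{taxon}_{i + 1}" for i in range(k)]
        pops += [taxon] * k

    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    ancestral = _BASES[ref_idx].astype(object)
    derived = _BASES[alt_idx].astype(object)

    sm = SiteMatrix(
        chrom=chrom,
        pos=pos.astype(np.int64),
        ancestral=ancestral,
        derived=derived,
        dosage=np.hstack(dosage_cols),
        samples=sample_ids,
        depth=np.hstack(depth_cols),
        chrom_lengths=dict(config.chromosomes),
        aa=ancestral.copy(),
    )
    table = SampleTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "population": pops,
                "mean_coverage": [config.coverage[p] for p in pops],
            }
        )
    )
    truth = TruthTable(config.sweeps, config.conserved, p0, freq)
    return sm, table, truth


def expected_pairwise_fst(config: SimConfig, pair: tuple[str, str]) -> float:
    """Closed-form expected Hudson F_ST for a taxon pair, no sweeps.

    Branch drifts compound from the pair's most recent common ancestor as
    ``F' = 1 - prod(1 - F_branch)``; the expectation is ``(F'_A + F'_B) / 2``
    (drift shared below the ancestor cancels between numerator and
    denominator, so the sister pair depends only on its two terminal
    branches).
    """
    branches = {
        "willow": (config.f_node, config.f_willow),
        "red": (config.f_node, config.f_red),
        "rock": (config.f_rock,),
    }
    a, b = pair
    if a not in branches or b not in branches or a == b:
        raise ValueError(f"unknown pair {pair!r}")
    shared = 1 if {a, b} == {"willow", "red"} else 0  # drop shared node branch
    total = 0.0
    for t in (a, b):
        fs = branches[t][shared:] if t != "rock" else branches[t]
        compound = 1.0
        for f in fs:
            compound *= 1.0 - f
        total += 1.0 - compound
    return total / 2.0


def demo_scan_config(seed: int = 11, with_signals: bool = True) -> SimConfig:
    """The 30-Mb validation genome used for scan-recovery checks.

    Three chromosomes (12 + 12 + 6 Mb = 2000 windows), 600k sites (~100
    filter-passing SNPs per window per pair, the order of density the study
    system shows), default drifts, and — when ``with_signals`` — six
    single-window lineage-specific sweeps (two per taxon, kappa = 50) plus a
    233-window (~3.5 Mb) conserved region on chr20.  The ancestral spectrum
    uses the neutral shape (alpha = 1) so that filtered SNP density is
    uniform across drift regimes; the expansion-skewed shape is exercised by
    the sign-recovery analyses instead.
    """
    ws = 15_000
    sweeps: tuple[SweepSpec, ...] = ()
    conserved = None
    if with_signals:
        sweeps = tuple(
            SweepSpec(taxon, chrom, w * ws, (w + 1) * ws, kappa=50.0)
            for chrom, picks in (
                ("chr1", (("willow", 100), ("red", 400), ("rock", 700))),
                ("chr2", (("willow", 150), ("red", 450), ("rock", 750))),
            )
            for taxon, w in picks
        )
        conserved = ConservedSpec("chr20", 80 * ws, 313 * ws, delta=0.02)
    return SimConfig(
        seed=seed,
        chromosomes=(("chr1", 12_000_000), ("chr2", 12_000_000), ("chr20", 6_000_000)),
        n_sites=600_000,
        alpha=1.0,
        sweeps=sweeps,
        conserved=conserved,
    )


# ---------------------------------------------------------------------------
# bundled deterministic fixtures

FIXTURE_NAMES = ("tiny-neutral", "tiny-sweeps", "tiny-conserved")


def _fixture_config(name: str) -> tuple[SimConfig, dict]:
    """Fixture generator configs plus the scan settings sized for them."""
    scan = {"min_snps": 4, "zfst_threshold": 6.0, "z_low": -1.0,
            "min_region_windows": 20, "max_gap": 2}
    if name == "tiny-neutral":
        cfg = SimConfig(
            seed=101, chromosomes=(("chr1", 1_500_000),), n_sites=2000, alpha=1.0
        )
    elif name == "tiny-sweeps":
        ws = 15_000
        sweeps = tuple(
            SweepSpec(taxon, chrom, w * ws, (w + 1) * ws, kappa=50.0)
            for chrom, picks in (
                ("chr1", (("willow", 20), ("red", 90), ("rock", 140))),
                ("chr2", (("willow", 25), ("red", 85), ("rock", 150))),
            )
            for taxon, w in picks
        )
        cfg = SimConfig(
            seed=202,
            chromosomes=(("chr1", 2_500_000), ("chr2", 2_500_000)),
            n_sites=2000,
            alpha=1.0,
            sweeps=sweeps,
        )
    elif name == "tiny-conserved":
        ws = 15_000
        cfg = SimConfig(
            seed=303,
            chromosomes=(("chr20", 2_500_000),),
            n_sites=2000,
            alpha=1.0,
            conserved=ConservedSpec("chr20", 60 * ws, 94 * ws, delta=0.02),
        )
    else:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return cfg, scan


def make_fixture(
    name: str, out_dir: str | os.PathLike | None = None
) -> tuple[SiteMatrix, SampleTable, TruthTable, SimConfig, dict]:
    """Regenerate a named deterministic test dataset (~2000 sites, <= 5 Mb).

    With ``out_dir`` the bundle is also written to disk as VCF + popmap +
    truth BED + config JSON.  Fixed internal seeds make regeneration
    hash-identical across runs.
    """
    cfg, scan = _fixture_config(name)
    sm, table, truth = simulate_dataset(cfg)
    if out_dir is not None:
        out_dir = str(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        write_vcf(sm, os.path.join(out_dir, f"{name}.vcf"))
        with open(os.path.join(out_dir, f"{name}.popmap.tsv"), "w") as fh:
            for r in table.frame.itertuples():
                fh.write(f"{r.sample_id}\t{r.population}\t{r.mean_coverage}\n")
        truth.write_bed(os.path.join(out_dir, f"{name}.truth.bed"), cfg.grid())
        with open(os.path.join(out_dir, f"{name}.config.json"), "w") as fh:
            json.dump({"sim": cfg.to_dict(), "scan": scan}, fh, indent=2, default=str)
    return sm, table, truth, cfg, scan
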