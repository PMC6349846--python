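"""Unfolded site-frequency spectra, marginal and joint (2D).

Spectra are exact integer histograms of derived-allele counts taken from
called dosages — no posterior weighting.  A population's spectrum uses only
the sites retained by that population's filter mask; a joint spectrum uses
the intersection of the two masks.  Windowed spectra are restrictions of the
same site list to 0-based half-open windows, so spectra over a partition of
the genome add up to the genome-wide spectrum bin by bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .popdata import MISSING, SampleTable, SiteMatrix
from .windows import WindowGrid

__all__ = [
    "MarginalSFS",
    "JointSFS2D",
    "marginal_sfs",
    "joint_sfs",
    "windowed_marginal_sfs",
    "write_sfs_text",
]


@dataclass
class MarginalSFS:
    """Unfolded spectrum for one population.

    ``xi[i]`` is the number of sites carrying the derived allele on exactly
    ``i`` of the ``m`` sampled chromosomes; bins 0 and m are the monomorphic
    classes.
    """

    population: str
    m: int
    xi: np.ndarray
    span: str = "genome"

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi, dtype=np.int64)
        if len(self.xi) != self.m + 1:
            raise ValueError("xi must have length m+1")
        if (self.xi < 0).any():
            raise ValueError("negative SFS bin")

    @property
    def n_sites(self) -> int:
        return int(self.xi.sum())

    @property
    def segregating(self) -> int:
        return int(self.xi[1:-1].sum())


@dataclass
class JointSFS2D:
    """Unfolded joint spectrum for an ordered population pair."""

    pops: tuple[str, str]
    m1: int
    m2: int
    counts: np.ndarray
    span: str = "genome"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.m1 + 1, self.m2 + 1):
            raise ValueError("counts must be (m1+1) x (m2+1)")
        if (self.counts < 0).any():
            raise ValueError("negative SFS cell")

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())

    def transpose(self) -> "JointSFS2D":
        return JointSFS2D(
            pops=(self.pops[1], self.pops[0]),
            m1=self.m2,
            m2=self.m1,
            counts=self.counts.T.copy(),
            span=self.span,
        )

    def marginal(self, which: int) -> MarginalSFS:
        """Marginal spectrum of population 0 or 1 over the jointly retained sites."""
        if which not in (0, 1):
            raise ValueError("which must be 0 or 1")
        xi = self.counts.sum(axis=1 - which)
        return MarginalSFS(self.pops[which], (self.m1, self.m2)[which], xi, self.span)


# ---------------------------------------------------------------------------


def _site_selector(
    sm: SiteMatrix, mask: np.ndarray, span: tuple[str, int, int] | None
) -> np.ndarray:
    sel = mask.copy()
    if span is not None:
        chrom, start, end = span
        sel &= (sm.chrom == chrom) & (sm.pos - 1 >= start) & (sm.pos - 1 < end)
    return sel

def _derived_counts(sm: SiteMatrix, cols: np.ndarray, sel: np.ndarray) -> np.ndarray:
    d = sm.dosage[np.ix_(sel.nonzero()[0], cols)]
    if (d == MISSING).any():
        raise ValueError(
            "missing genotypes inside the retained site set; apply a "
            "complete-case filter (min_call_rate=1) before building spectra"
        )
    return d.sum(axis=1, dtype=np.int64)


def marginal_sfs(
    sm: SiteMatrix,
    sample_table: SampleTable,
    population: str,
    span: tuple[str, int, int] | None = None,
) -> MarginalSFS:
    """Unfolded marginal SFS over the population's retained sites.

    ``span`` optionally restricts to a 0-based half-open interval
    ``(chrom, start, end)``.
    """
    cols = sm.pop_cols(sample_table, population)
    if len(cols) == 0:
        raise ValueError(f"population {population!r} has no samples")
    m = 2 * len(cols)
    sel = _site_selector(sm, sm.mask_for(population), span)
    counts = _derived_counts(sm, cols, sel)
    xi = np.bincount(counts, minlength=m + 1)
    label = "genome" if span is None else f"{span[0]}:{span[1]}-{span[2]}"
    return MarginalSFS(population, m, xi, label)


def joint_sfs(
    sm: SiteMatrix,
    sample_table: SampleTable,
    pop_a: str,
    pop_b: str,
    span: tuple[str, int, int] | None = None,
) -> JointSFS2D:
    """Unfolded 2D SFS over sites retained in *both* populations."""
    if pop_a == pop_b:
        raise ValueError("joint SFS requires two distinct populations")
    cols_a = sm.pop_cols(sample_table, pop_a)
    cols_b = sm.pop_cols(sample_table, pop_b)
    if set(cols_a.tolist()) & set(cols_b.tolist()):
        raise ValueError(f"populations {pop_a!r} and {pop_b!r} share samples")
    m1, m2 = 2 * len(cols_a), 2 * len(cols_b)
    sel = _site_selector(sm, sm.mask_for(pop_a) & sm.mask_for(pop_b), span)
    i = _derived_counts(sm, cols_a, sel)
    j = _derived_counts(sm, cols_b, sel)
    flat = np.bincount(i * (m2 + 1) + j, minlength=(m1 + 1) * (m2 + 1))
    label = "genome" if span is None else f"{span[0]}:{span[1]}-{span[2]}"
    return JointSFS2D((pop_a, pop_b), m1, m2, flat.reshape(m1 + 1, m2 + 1), label)


def windowed_marginal_sfs(
    sm: SiteMatrix,
    sample_table: SampleTable,
    population: str,
    grid: WindowGrid,
) -> np.ndarray:
    """Per-window unfolded SFS, shape ``(grid.total_windows, m+1)``.

    Row ``g`` is the spectrum of the population's retained sites falling in
    global window ``g``; rows sum to the genome-wide spectrum.
    """
    cols = sm.pop_cols(sample_table, population)
    m = 2 * len(cols)
    sel = sm.mask_for(population)
    counts = _derived_counts(sm, cols, sel)
    gidx = grid.global_index(sm.chrom[sel], sm.pos[sel])
    out = np.zeros((grid.total_windows, m + 1), dtype=np.int64)
    np.add.at(out, (gidx, counts), 1)
    return out


def write_sfs_text(sfs: MarginalSFS | JointSFS2D, path: str) -> None:
    """Flat-text export: one line of m+1 integers, or an (m1+1)x(m2+1) block."""
    with open(path, "w") as fh:
        if isinstance(sfs, MarginalSFS):
            fh.write(f"# {sfs.population} m={sfs.m} span={sfs.span}\n")
            fh.write(" ".join(str(int(x)) for x in sfs.xi) + "\n")
        else:
            fh.write(
                f"# {sfs.pops[0]}x{sfs.pops[1]} m1={sfs.m1} m2={sfs.m2} span={sfs.span}\n"
            )
            for row in sfs.counts:
                fh.write(" ".join(str(int(x)) for x in row) + "\n")
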