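"""Non-overlapping genomic window grids anchored at coordinate zero.

Windows are 0-based half-open intervals ``[k*size, (k+1)*size)`` tiling each
chromosome from its first base.  Variant positions are 1-based (VCF
convention), so position ``pos`` falls in window ``(pos - 1) // size``.  The
terminal window of a chromosome may be shorter than ``size``; it is kept and
flagged as partial rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["WindowGrid"]


@dataclass
class WindowGrid:
    """Exact tiling of one or more chromosomes by fixed-size windows.

    Parameters
    ----------
    chrom_lengths
        Mapping chromosome name -> length in bases.  Iteration order of the
        mapping fixes the global window order (the pipeline sorts names).
    window_size
        Window span in bases (default 15 kb).
    """

    chrom_lengths: dict[str, int]
    window_size: int = 15_000
    _offsets: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        self._offsets = {}
        running = 0
        for name, length in self.chrom_lengths.items():
            self._offsets[name] = running
            running += self.n_windows(name)
        self._total = running

    # -- sizes -------------------------------------------------------------

    def n_windows(self, chrom: str) -> int:
        length = self.chrom_lengths[chrom]
        return -(-length // self.window_size)  # ceil division

    @property
    def total_windows(self) -> int:
        return self._total

    # -- coordinate mapping ------------------------------------------------

    def local_index(self, pos: np.ndarray | int) -> np.ndarray | int:
        """Window index within a chromosome for 1-based positions."""
        return (np.asarray(pos) - 1) // self.window_size

    def global_index(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Genome-wide window index for arrays of chromosome names / positions."""
        chrom = np.asarray(chrom)
        pos = np.asarray(pos)
        offs = np.empty(pos.shape, dtype=np.int64)
        for name, off in self._offsets.items():
            offs[chrom == name] = off
        unknown = ~np.isin(chrom, list(self._offsets))
        if unknown.any():
            bad = sorted(set(chrom[unknown].tolist()))
            raise KeyError(f"chromosome(s) not on grid: {bad}")
        return offs + (pos - 1) // self.window_size

    def bounds(self, chrom: str, index: int) -> tuple[int, int]:
        """0-based half-open interval of a window; the end is clipped to the
        chromosome length for the terminal partial window."""
        if not 0 <= index < self.n_windows(chrom):
            raise IndexError(f"window {index} out of range for {chrom!r}")
        start = index * self.window_size
        end = min(start + self.window_size, self.chrom_lengths[chrom])
        return start, end

    def is_partial(self, chrom: str, index: int) -> bool:
        start, end = self.bounds(chrom, index)
        return end - start < self.window_size

    # -- tabular view ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """One row per window: chrom, start, end, window (local), gindex, partial."""
        rows = []
        for name in self.chrom_lengths:
            nw = self.n_windows(name)
            starts = np.arange(nw, dtype=np.int64) * self.window_size
            ends = np.minimum(starts + self.window_size, self.chrom_lengths[name])
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": name,
                        "start": starts,
                        "end": ends,
                        "window": np.arange(nw),
                        "gindex": self._offsets[name] + np.arange(nw),
                        "partial": ends - starts < self.window_size,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)
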