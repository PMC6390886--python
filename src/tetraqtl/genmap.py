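"""Genetic maps on a centiMorgan grid.

Autotetraploid QTL analysis here works on a regular cM grid per chromosome
(default step 1 cM, coordinates rounded to 0.1 cM), the resolution at which
IBD probabilities are tabulated and scans are run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GeneticMap"]


@dataclass(frozen=True)
class GeneticMap:
    """A set of chromosomes with lengths in cM and a scan grid.

    Parameters
    ----------
    chromosomes
        Sequence of ``(name, length_cM)`` pairs. Lengths must be positive.
    grid_step
        Spacing of the evaluation grid in cM (default 1.0). Grid positions
        run from 0 to the chromosome length inclusive and are rounded to
        0.1 cM.
    """

    chromosomes: tuple
    grid_step: float = 1.0

    def __post_init__(self):
        chroms = tuple((str(n), float(l)) for n, l in self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in chroms:
            if not np.isfinite(length) or length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")

    @property
    def names(self) -> list:
        return [n for n, _ in self.chromosomes]

    def length(self, chromosome: str) -> float:
        for n, l in self.chromosomes:
            if n == str(chromosome):
                return l
        raise KeyError(f"unknown chromosome {chromosome!r}")

    def chrom_grid(self, chromosome: str) -> np.ndarray:
        """Grid positions (cM) for one chromosome, rounded to 0.1 cM."""
        length = self.length(chromosome)
        pos = np.arange(0.0, length + self.grid_step / 2, self.grid_step)
        pos = np.round(pos, 1)
        return pos[pos <= round(length, 1) + 1e-9]

    @property
    def positions(self) -> pd.DataFrame:
        """Long table of all grid positions: columns chromosome, position."""
        frames = [
            pd.DataFrame({"chromosome": n, "position": self.chrom_grid(n)})
            for n in self.names
        ]
        return pd.concat(frames, ignore_index=True)

    @property
    def n_positions(self) -> int:
        return sum(len(self.chrom_grid(n)) for n in self.names)

    def locate(self, chromosome: str, position: float) -> int:
        """Global grid index of the position nearest to ``position``."""
        offset = 0
        for n in self.names:
            grid = self.chrom_grid(n)
            if n == str(chromosome):
                return offset + int(np.argmin(np.abs(grid - position)))
            offset += len(grid)
        raise KeyError(f"unknown chromosome {chromosome!r}")
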