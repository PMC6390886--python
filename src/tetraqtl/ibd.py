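"""IBD probabilities and homologue dosages on the cM grid.

An autotetraploid F1 individual inherits two of the four homologues of each
parent per position.  Per parent there are 6 distinct unordered homologue
pairs from bivalent meiosis ({12,13,14,23,24,34}) plus 4 double-reduction
classes ({11,22,33,44}) in which the gamete carries two copies of the same
homologue.  Probabilistic haplotype reconstruction yields, per individual and
position, a distribution over these gamete classes for each parent; the
expected homologue dosages X1..X4 (parent 1) and X5..X8 (parent 2) derived
from them are the predictors of the QTL regression models.  By construction
X1+X2+X3+X4 = 2 and X5+X6+X7+X8 = 2 at every position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BIVALENT_CLASSES",
    "DR_CLASSES",
    "GAMETE_CLASSES",
    "CLASS_DOSAGE",
    "GameteClassProbabilities",
    "HomologueDosageGrid",
    "classes_to_dosage",
    "interpolate_to_grid",
    "gic",
]

#: unordered homologue pairs a bivalent-meiosis gamete can carry
BIVALENT_CLASSES = ("12", "13", "14", "23", "24", "34")
#: double-reduction classes (two chromatid copies of one homologue)
DR_CLASSES = ("11", "22", "33", "44")
GAMETE_CLASSES = BIVALENT_CLASSES + DR_CLASSES

# (10, 4): copies of homologue j contributed by class i
CLASS_DOSAGE = np.zeros((len(GAMETE_CLASSES), 4))
for _i, _cls in enumerate(GAMETE_CLASSES):
    for _ch in _cls:
        CLASS_DOSAGE[_i, int(_ch) - 1] += 1.0

_SUM_TOL = 1e-9


def _check_positions(positions: pd.DataFrame) -> pd.DataFrame:
    missing = {"chromosome", "position"} - set(positions.columns)
    if missing:
        raise ValueError(f"positions table lacks columns {sorted(missing)}")
    return positions.reset_index(drop=True)


@dataclass
class GameteClassProbabilities:
    """Per-individual, per-position gamete-class distributions.

    Attributes
    ----------
    probs
        Array of shape ``(n_individuals, n_positions, 2, 10)``: axis 2 is the
        parent (0 = parent 1, 1 = parent 2), axis 3 indexes
        :data:`GAMETE_CLASSES`.  Each per-parent vector sums to 1.
    positions
        DataFrame with columns ``chromosome`` and ``position`` (cM).
    individuals
        Individual identifiers, length ``n_individuals``.
    """

    probs: np.ndarray
    positions: pd.DataFrame
    individuals: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.positions = _check_positions(self.positions)
        self.individuals = np.asarray(self.individuals)
        if self.probs.ndim != 4 or self.probs.shape[2:] != (2, 10):
            raise ValueError("probs must have shape (n, n_pos, 2, 10)")
        if self.probs.shape[0] != len(self.individuals):
            raise ValueError("individuals length mismatch")
        if self.probs.shape[1] != len(self.positions):
            raise ValueError("positions length mismatch")
        self.validate()

    def validate(self, tol: float = 1e-6) -> None:
        if (self.probs < -tol).any():
            raise ValueError("negative class probability")
        sums = self.probs.sum(axis=3)
        if not np.allclose(sums, 1.0, atol=tol):
            bad = np.argwhere(~np.isclose(sums, 1.0, atol=tol))[0]
            raise ValueError(
                f"class probabilities do not sum to 1 at individual index "
                f"{bad[0]}, position index {bad[1]}, parent {bad[2] + 1}"
            )

    @property
    def n_individuals(self) -> int:
        return self.probs.shape[0]

    @property
    def n_positions(self) -> int:
        return self.probs.shape[1]

    def to_dosage(self) -> "HomologueDosageGrid":
        return classes_to_dosage(self)


@dataclass
class HomologueDosageGrid:
    """Expected parental-homologue dosages X1..X8 on the map grid.

    ``X`` has shape ``(n_individuals, n_positions, 8)``; columns 0..3 are the
    parent-1 homologues, 4..7 the parent-2 homologues.  Parent sums equal 2.
    """

    X: np.ndarray
    positions: pd.DataFrame
    individuals: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.positions = _check_positions(self.positions)
        self.individuals = np.asarray(self.individuals)
        if self.X.ndim != 3 or self.X.shape[2] != 8:
            raise ValueError("X must have shape (n, n_pos, 8)")
        if self.X.shape[0] != len(self.individuals):
            raise ValueError("individuals length mismatch")
        if self.X.shape[1] != len(self.positions):
            raise ValueError("positions length mismatch")

    def validate(self, tol: float = 1e-6) -> None:
        if (self.X < -tol).any() or (self.X > 2 + tol).any():
            raise ValueError("dosages outside [0, 2]")
        for sl in (slice(0, 4), slice(4, 8)):
            if not np.allclose(self.X[:, :, sl].sum(axis=2), 2.0, atol=tol):
                raise ValueError("parental dosage sums differ from 2")

    @property
    def n_individuals(self) -> int:
        return self.X.shape[0]

    @property
    def n_positions(self) -> int:
        return self.X.shape[1]

    @property
    def chromosomes(self) -> list:
        return list(pd.unique(self.positions["chromosome"]))

    def chrom_mask(self, chromosome: str) -> np.ndarray:
        return (self.positions["chromosome"] == str(chromosome)).to_numpy()

    def locate(self, chromosome: str, position: float) -> int:
        """Global index of the grid point nearest to (chromosome, position)."""
        mask = self.chrom_mask(chromosome)
        if not mask.any():
            raise KeyError(f"unknown chromosome {chromosome!r}")
        idx = np.flatnonzero(mask)
        pos = self.positions["position"].to_numpy()[idx]
        return int(idx[np.argmin(np.abs(pos - position))])


def classes_to_dosage(probabilities: GameteClassProbabilities) -> HomologueDosageGrid:
    """Expected homologue dosages under the gamete-class distributions.

    The map is linear: class ``12`` of parent 1 contributes one copy each to
    X1 and X2, double-reduction class ``11`` contributes two copies to X1,
    and so on; parent-2 classes fill X5..X8.  Normalised class vectors
    therefore give parent sums of exactly 2.
    """
    p = probabilities.probs
    X = np.empty((p.shape[0], p.shape[1], 8))
    X[:, :, :4] = p[:, :, 0, :] @ CLASS_DOSAGE
    X[:, :, 4:] = p[:, :, 1, :] @ CLASS_DOSAGE
    return HomologueDosageGrid(
        X=X,
        positions=probabilities.positions,
        individuals=probabilities.individuals,
    )


def interpolate_to_grid(
    dosages: HomologueDosageGrid,
    chromosome_lengths: dict | None = None,
    step: float = 1.0,
) -> HomologueDosageGrid:
    """Resample dosages from marker positions onto a regular cM grid.

    Linear interpolation is used per homologue.  Because every support row
    satisfies the parent-sum and range constraints and linear interpolation
    is a convex combination of rows, interpolated rows satisfy them too; a
    clamp-and-renormalise pass guards against floating-point drift only.

    Parameters
    ----------
    dosages
        Dosages at (possibly irregular) marker positions.
    chromosome_lengths
        Optional mapping chromosome -> length in cM; defaults to the last
        support position per chromosome.
    step
        Grid step in cM (default 1).
    """
    frames = []
    blocks = []
    for chrom in dosages.chromosomes:
        mask = dosages.chrom_mask(chrom)
        pos = dosages.positions["position"].to_numpy()[mask]
        if len(pos) < 2:
            raise ValueError(
                f"chromosome {chrom!r} has fewer than 2 support positions"
            )
        order = np.argsort(pos)
        pos = pos[order]
        Xc = dosages.X[:, mask, :][:, order, :]
        length = (
            chromosome_lengths[chrom]
            if chromosome_lengths is not None
            else pos[-1]
        )
        grid = np.round(np.arange(0.0, length + step / 2, step), 1)
        grid = grid[grid <= round(float(length), 1) + 1e-9]
        out = np.empty((Xc.shape[0], len(grid), 8))
        for h in range(8):
            # np.interp holds end values constant outside the support range
            out[:, :, h] = np.vstack(
                [np.interp(grid, pos, Xc[i, :, h]) for i in range(Xc.shape[0])]
            )
        out = np.clip(out, 0.0, 2.0)
        for sl in (slice(0, 4), slice(4, 8)):
            s = out[:, :, sl].sum(axis=2, keepdims=True)
            out[:, :, sl] *= 2.0 / s
        frames.append(pd.DataFrame({"chromosome": chrom, "position": grid}))
        blocks.append(out)
    return HomologueDosageGrid(
        X=np.concatenate(blocks, axis=1),
        positions=pd.concat(frames, ignore_index=True),
        individuals=dosages.individuals,
    )


def gic(dosages: HomologueDosageGrid) -> pd.DataFrame:
    """Genotypic information coefficient per position and homologue.

    With carrier probability ``p = min(X, 1)`` the coefficient is
    ``1 - 4 * mean(p * (1 - p))`` over individuals: 1 when every carrier
    probability is 0 or 1 (fully informative reconstruction), 0 when all are
    1/2 (no information).

    Returns a DataFrame with chromosome, position and columns GIC1..GIC8.
    """
    if dosages.n_individuals == 0:
        raise ValueError("empty population")
    p = np.minimum(dosages.X, 1.0)
    g = 1.0 - 4.0 * (p * (1.0 - p)).mean(axis=0)
    out = dosages.positions.copy()
    for h in range(8):
        out[f"GIC{h + 1}"] = g[:, h]
    return out
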