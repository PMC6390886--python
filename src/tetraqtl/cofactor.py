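"""Cofactor QTL analysis: residualize on known QTLs and rescan.

A naive single-locus scan can miss ("mask") a minor QTL whose signal is
drowned by a major one.  The cofactor analysis takes the significant peaks
of the naive scan, absorbs them by regressing the trait on the model-B
dosage columns of the cofactor positions jointly, and re-runs the genome
scan on the residuals with a fresh permutation threshold computed on those
residuals.  Peaks that emerge in a rescan but were absent from the naive
peak set are flagged as newly identified (masked) QTLs.  All non-empty
subsets of the naive peaks are analysed so masking by any combination can
be detected.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.linalg

from .ibd import HomologueDosageGrid
from .scan import (
    QTLScan,
    QTLScanResults,
    _align_phenotype,
    _subset_grid,
    model_b_columns,
)

__all__ = [
    "residualize",
    "CofactorScan",
    "CofactorScanResults",
    "cofactor_analysis",
]


def _cofactor_index(grid: HomologueDosageGrid, chromosome, position) -> int:
    mask = grid.chrom_mask(chromosome)
    if not mask.any():
        raise ValueError(f"cofactor chromosome {chromosome!r} not on grid")
    pos = grid.positions["position"].to_numpy()[mask]
    hit = np.flatnonzero(np.isclose(pos, float(position), atol=1e-6))
    if len(hit) == 0:
        raise ValueError(
            f"cofactor position {chromosome}:{position} is not a grid position"
        )
    return int(np.flatnonzero(mask)[hit[0]])


def residualize(y, grid: HomologueDosageGrid, cofactor_positions) -> np.ndarray:
    """Residuals of the trait after absorbing the cofactor QTLs.

    ``cofactor_positions`` is an iterable of ``(chromosome, position)``
    pairs that must lie exactly on the grid.  The trait is regressed by OLS
    on the model-B dosage columns of all cofactors jointly (plus an
    intercept); with no cofactors the residuals are the centred trait.
    Individual alignment is preserved.
    """
    yv, rows = _align_phenotype(y, grid)
    cols = [np.ones(len(yv))]
    for chromosome, position in cofactor_positions:
        j = _cofactor_index(grid, chromosome, position)
        cols.append(model_b_columns(grid.X[rows, j, :], check=False))
    design = np.column_stack(cols)
    coef, _, _, _ = scipy.linalg.lstsq(
        design, yv, cond=1e-10, lapack_driver="gelsd"
    )
    return yv - design @ coef


class CofactorScan:
    """Genome rescan after residualizing on cofactor QTL positions.

    Parameters
    ----------
    y
        Trait values aligned with ``grid.individuals`` (array or Series).
    grid
        Homologue dosages on the scan grid.
    cofactors
        Iterable of ``(chromosome, position)`` grid positions to absorb.
    """

    def __init__(self, y, grid: HomologueDosageGrid, cofactors):
        self.grid = grid
        self.cofactors = [(str(c), float(p)) for c, p in cofactors]
        yv, rows = _align_phenotype(y, grid)
        self.rows = rows
        self.residuals = residualize(yv, _subset_grid(grid, rows), self.cofactors) \
            if not rows.all() else residualize(y, grid, self.cofactors)

    def fit(
        self,
        n_perm: int | None = None,
        alpha: float = 0.05,
        seed: int = 0,
        threshold: float | None = None,
    ) -> "CofactorScanResults":
        """Scan the residuals; the permutation threshold (when requested)
        is computed on the residuals with the same permutation engine and
        seed discipline as the naive scan."""
        scan = QTLScan(self.residuals, _subset_grid(self.grid, self.rows))
        res = scan.fit(
            n_perm=n_perm, alpha=alpha, seed=seed, threshold=threshold
        )
        return CofactorScanResults(
            cofactors=self.cofactors, scan=res, residuals=self.residuals
        )


@dataclass
class CofactorScanResults:
    """Rescan results for one cofactor set."""

    cofactors: list
    scan: QTLScanResults
    residuals: np.ndarray

    @property
    def peaks(self) -> pd.DataFrame | None:
        return self.scan.peaks

    def new_peaks(
        self, naive_peaks: pd.DataFrame, match_window: float = 15.0
    ) -> pd.DataFrame:
        """Peaks absent from the naive peak set (masked QTLs).

        A rescan peak matches a naive peak when it lies on the same
        chromosome within ``match_window`` cM; everything else is new.
        """
        if self.peaks is None or self.peaks.empty:
            return self.peaks if self.peaks is not None else pd.DataFrame()
        new = []
        for _, p in self.peaks.iterrows():
            matched = (
                (naive_peaks["chromosome"].astype(str) == str(p["chromosome"]))
                & (np.abs(naive_peaks["position"] - p["position"]) <= match_window)
            ).any()
            if not matched:
                new.append(p)
        return pd.DataFrame(new, columns=self.peaks.columns)

    def summary(self) -> str:
        cof = " + ".join(f"{c} ({p:g})" for c, p in self.cofactors)
        head = f"Cofactor scan [cofactors: {cof or 'none'}]"
        return head + "\n" + self.scan.summary()


def cofactor_analysis(
    y,
    grid: HomologueDosageGrid,
    naive_peaks: pd.DataFrame,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    match_window: float = 15.0,
) -> pd.DataFrame:
    """Run the rescan for every non-empty subset of the naive peaks.

    Returns a tidy table with one row per (cofactor subset, rescan peak) —
    or a single no-peak row per subset — flagging newly significant peaks
    that are absent from the naive set.  ``seed`` controls the permutation
    thresholds (one derived seed per subset).
    """
    if naive_peaks is None or naive_peaks.empty:
        raise ValueError("naive peak list is empty")
    peaks = [
        (str(p["chromosome"]), float(p["position"]))
        for _, p in naive_peaks.iterrows()
    ]
    rows = []
    subset_id = 0
    for size in range(1, len(peaks) + 1):
        for subset in combinations(peaks, size):
            subset_id += 1
            res = CofactorScan(y, grid, subset).fit(
                n_perm=n_perm, alpha=alpha, seed=seed + subset_id
            )
            label = " + ".join(f"{c} ({p:g})" for c, p in subset)
            new = res.new_peaks(naive_peaks, match_window=match_window)
            if res.peaks is None or res.peaks.empty:
                rows.append(
                    {
                        "cofactors": label,
                        "chromosome": None,
                        "position": np.nan,
                        "lod": np.nan,
                        "r2": np.nan,
                        "threshold": res.scan.threshold,
                        "significant": False,
                        "new_qtl": False,
                    }
                )
                continue
            new_keys = {
                (str(p["chromosome"]), float(p["position"]))
                for _, p in new.iterrows()
            }
            for _, p in res.peaks.iterrows():
                rows.append(
                    {
                        "cofactors": label,
                        "chromosome": p["chromosome"],
                        "position": p["position"],
                        "lod": p["lod"],
                        "r2": p["r2"],
                        "threshold": res.scan.threshold,
                        "significant": True,
                        "new_qtl": (str(p["chromosome"]), float(p["position"]))
                        in new_keys,
                    }
                )
    return pd.DataFrame(rows)
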