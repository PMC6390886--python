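"""Naive single-locus QTL genome scan on homologue dosages.

At every grid position the trait is regressed on the expected parental
homologue dosages.  The full additive model is

    y = mu + a1*X1 + ... + a8*X8 + e          (model A)

but the constraints X1+X2+X3+X4 = 2 and X5+X6+X7+X8 = 2 make it
over-parameterised, so one dosage per parent (X1 and X5 here; any choice per
parent gives the same fit) is dropped:

    y = mu' + a2'*X2 + a3'*X3 + a4'*X4 + a6'*X6 + a7'*X7 + a8'*X8 + e
                                              (model B)

Evidence is summarised per position as

    LOD = n/2 * log10(RSS_0 / RSS_1),     R^2 = 1 - RSS_1/RSS_0

with RSS_0 the intercept-only residual sum of squares, which gives the exact
identity R^2 = 1 - 10^(-2*LOD/n).  Genome-wide significance thresholds are
the (1 - alpha) quantile of the maximum LOD over phenotype permutations
(Churchill–Doerge style), and QTL support is reported as LOD-2 intervals
truncated to above-threshold positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .ibd import HomologueDosageGrid

__all__ = [
    "QTLScan",
    "QTLScanResults",
    "design_matrix_model_b",
    "model_b_columns",
    "zero_variance_predictors",
    "fit_position",
    "lod",
    "permutation_threshold",
    "find_peaks",
]

#: retained dosage columns of model B (0-based homologue indices)
MODEL_B_COLUMNS = (1, 2, 3, 5, 6, 7)
_COEF_NAMES = ("mu", "a2", "a3", "a4", "a6", "a7", "a8")
_SUM_TOL = 1e-6


def model_b_columns(X_pos: np.ndarray, check: bool = True) -> np.ndarray:
    """The six model-B predictor columns (X2, X3, X4, X6, X7, X8)."""
    X_pos = np.asarray(X_pos, dtype=float)
    if X_pos.ndim != 2 or X_pos.shape[1] != 8:
        raise ValueError("expected an (n, 8) dosage block")
    if check:
        for sl in (slice(0, 4), slice(4, 8)):
            if not np.allclose(X_pos[:, sl].sum(axis=1), 2.0, atol=_SUM_TOL):
                raise ValueError("parental dosage sums differ from 2")
    return X_pos[:, MODEL_B_COLUMNS]


def design_matrix_model_b(X_pos: np.ndarray, check: bool = True) -> np.ndarray:
    """Model-B design matrix: intercept plus X2, X3, X4, X6, X7, X8."""
    cols = model_b_columns(X_pos, check=check)
    return np.column_stack([np.ones(len(cols)), cols])


def zero_variance_predictors(design: np.ndarray) -> np.ndarray:
    """Boolean mask over the non-intercept columns with (near-)zero variance."""
    return np.ptp(design[:, 1:], axis=0) < 1e-12


def fit_position(y: np.ndarray, design: np.ndarray):
    """OLS fit at one position.

    Returns ``(coefficients, RSS1, RSS0)`` where RSS0 is the intercept-only
    residual sum of squares.  Rank-deficient designs are resolved by the
    minimum-norm least-squares solution.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 8:
        raise ValueError("need at least 8 individuals to fit model B")
    coef, _, _, _ = scipy.linalg.lstsq(
        design, y, cond=1e-10, lapack_driver="gelsd"
    )
    resid = y - design @ coef
    rss1 = float(resid @ resid)
    dev = y - y.mean()
    rss0 = float(dev @ dev)
    return coef, rss1, rss0


def lod(n: int, rss0: float, rss1: float) -> float:
    """LOD score ``n/2 * log10(RSS0/RSS1)``.

    Zero when the model explains nothing (RSS0 == RSS1), including the
    degenerate constant-phenotype case RSS0 = RSS1 = 0.
    """
    if rss1 < 0:
        raise ValueError("RSS1 must be non-negative")
    if rss0 < rss1 - 1e-9 * max(rss1, 1.0):
        raise ValueError("RSS0 must be >= RSS1")
    if rss0 <= 0.0 or rss0 <= rss1:
        return 0.0
    if rss1 == 0.0:
        return float("inf")
    return 0.5 * n * np.log10(rss0 / rss1)


def _orthonormal_bases(grid: HomologueDosageGrid, rows: np.ndarray) -> list:
    """Orthonormal column bases of the model-B design at every position."""
    bases = []
    for j in range(grid.n_positions):
        design = design_matrix_model_b(grid.X[rows, j, :], check=False)
        # rcond truncation keeps numerically rank-deficient designs (e.g.
        # uninformative positions with all dosages equal) from leaking a
        # spurious basis direction
        bases.append(scipy.linalg.orth(design, rcond=1e-10))
    return bases


def _max_lods(bases: list, Y: np.ndarray) -> np.ndarray:
    """Genome-wide max LOD for each column of the phenotype matrix Y."""
    n = Y.shape[0]
    ss = (Y * Y).sum(axis=0)
    rss0 = ss - n * Y.mean(axis=0) ** 2
    best = np.full(Y.shape[1], -np.inf)
    for Q in bases:
        proj = Q.T @ Y
        rss1 = np.maximum(ss - (proj * proj).sum(axis=0), 1e-300)
        with np.errstate(divide="ignore"):
            lods = 0.5 * n * np.log10(np.maximum(rss0, 1e-300) / rss1)
        lods[rss0 <= rss1] = 0.0
        np.maximum(best, lods, out=best)
    return best


def permutation_threshold(
    y,
    grid: HomologueDosageGrid,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Genome-wide LOD threshold from phenotype permutations.

    Permutes trait values against intact genotype rows (preserving the
    dosage LD structure), records the genome-wide maximum LOD of each
    permuted scan, and returns the empirical (1 - alpha) quantile.
    Deterministic for a given seed.
    """
    if n_perm < 20:
        raise ValueError("need at least 20 permutations")
    yv, rows = _align_phenotype(y, grid)
    rng = np.random.default_rng(seed)
    Y = np.empty((len(yv), n_perm))
    for b in range(n_perm):
        Y[:, b] = rng.permutation(yv)
    bases = _orthonormal_bases(grid, rows)
    maxima = _max_lods(bases, Y)
    return float(np.quantile(maxima, 1.0 - alpha, method="higher"))


def find_peaks(
    profile: pd.DataFrame, threshold: float
) -> pd.DataFrame:
    """Per-chromosome QTL peaks with LOD-2 support intervals.

    A chromosome contributes a peak when its maximum LOD exceeds the
    threshold; the support interval is the contiguous run of positions
    around the peak with LOD within 2 of the maximum, truncated to
    above-threshold positions.  Ties in the maximum break toward the lower
    cM position.
    """
    peaks = []
    for chrom, sub in profile.groupby("chromosome", sort=False):
        sub = sub.sort_values("position")
        lods = sub["lod"].to_numpy()
        pos = sub["position"].to_numpy()
        k = int(np.argmax(lods))
        if not lods[k] > threshold:
            continue
        keep = (lods >= lods[k] - 2.0) & (lods > threshold)
        lo = k
        while lo > 0 and keep[lo - 1]:
            lo -= 1
        hi = k
        while hi < len(keep) - 1 and keep[hi + 1]:
            hi += 1
        peaks.append(
            {
                "chromosome": chrom,
                "position": pos[k],
                "lod": lods[k],
                "r2": sub["r2"].to_numpy()[k],
                "interval_lo": pos[lo],
                "interval_hi": pos[hi],
            }
        )
    return pd.DataFrame(
        peaks,
        columns=["chromosome", "position", "lod", "r2", "interval_lo", "interval_hi"],
    )


def _align_phenotype(y, grid: HomologueDosageGrid):
    """Align a phenotype vector/Series with the grid's individuals.

    Returns the finite phenotype values and the boolean row mask of
    individuals used (missing phenotypes are dropped).
    """
    if isinstance(y, pd.Series):
        missing = [i for i in grid.individuals if i not in y.index]
        if missing:
            raise ValueError(
                f"phenotype missing for {len(missing)} genotyped individuals "
                f"(e.g. {missing[0]!r})"
            )
        yv = y.reindex(grid.individuals).to_numpy(dtype=float)
    else:
        yv = np.asarray(y, dtype=float)
        if len(yv) != grid.n_individuals:
            raise ValueError(
                "phenotype length does not match the genotyped individuals"
            )
    rows = np.isfinite(yv)
    return yv[rows], rows


class QTLScan:
    """Naive single-locus QTL genome scan (model object).

    Parameters
    ----------
    y
        Trait values: an array aligned with ``grid.individuals`` or a
        pandas Series indexed by individual (e.g. BLUEs). Missing values
        are dropped, with the per-position sample size recorded.
    grid
        Homologue dosages on the scan grid.
    """

    def __init__(self, y, grid: HomologueDosageGrid):
        self.grid = grid
        self.y, self.rows = _align_phenotype(y, grid)
        self.nobs = int(self.rows.sum())

    def fit(
        self,
        n_perm: int | None = None,
        alpha: float = 0.05,
        seed: int = 0,
        threshold: float | None = None,
    ) -> "QTLScanResults":
        """Run the scan; optionally compute a permutation threshold.

        Provide either ``n_perm`` (to estimate the genome-wide threshold at
        level ``alpha`` by permutation) or an explicit ``threshold``.
        """
        grid = self.grid
        n = self.nobs
        records = []
        coefs = np.empty((grid.n_positions, 7))
        for j in range(grid.n_positions):
            design = design_matrix_model_b(
                grid.X[self.rows, j, :], check=False
            )
            coef, rss1, rss0 = fit_position(self.y, design)
            coefs[j] = coef
            score = lod(n, rss0, rss1)
            r2 = 1.0 - rss1 / rss0 if rss0 > 0 else 0.0
            records.append((score, r2, rss0, rss1))
        profile = grid.positions.copy()
        profile[["lod", "r2", "rss0", "rss1"]] = np.asarray(records)
        profile["n"] = n
        for k, name in enumerate(_COEF_NAMES):
            profile[name] = coefs[:, k]
        if threshold is None and n_perm is not None:
            threshold = permutation_threshold(
                self.y if not isinstance(self.y, pd.Series) else self.y,
                _subset_grid(grid, self.rows),
                n_perm=n_perm,
                alpha=alpha,
                seed=seed,
            )
        peaks = (
            find_peaks(profile, threshold) if threshold is not None else None
        )
        return QTLScanResults(
            model=self,
            profile=profile,
            threshold=threshold,
            alpha=alpha,
            n_perm=n_perm,
            peaks=peaks,
        )


def _subset_grid(grid: HomologueDosageGrid, rows: np.ndarray) -> HomologueDosageGrid:
    if rows.all():
        return grid
    return HomologueDosageGrid(
        X=grid.X[rows],
        positions=grid.positions,
        individuals=grid.individuals[rows],
    )


@dataclass
class QTLScanResults:
    """Results of a naive QTL scan.

    Attributes
    ----------
    profile
        Per-position table: chromosome, position, lod, r2, rss0, rss1, n and
        the model-B coefficients (mu, a2..a4, a6..a8).
    threshold
        Genome-wide LOD threshold (None when not requested).
    peaks
        Per-chromosome peaks with LOD-2 intervals (None without threshold).
    """

    model: QTLScan
    profile: pd.DataFrame
    threshold: float | None
    alpha: float
    n_perm: int | None
    peaks: pd.DataFrame | None

    def summary(self) -> str:
        lines = [
            f"QTL scan: {self.model.nobs} individuals, "
            f"{len(self.profile)} positions, "
            f"{self.profile['chromosome'].nunique()} chromosomes",
            f"max LOD = {self.profile['lod'].max():.2f} "
            f"(R^2 = {self.profile.loc[self.profile['lod'].idxmax(), 'r2']:.3f})",
        ]
        if self.threshold is not None:
            lines.append(
                f"genome-wide threshold = {self.threshold:.2f} "
                f"(alpha = {self.alpha}"
                + (f", {self.n_perm} permutations)" if self.n_perm else ")")
            )
            if self.peaks is None or self.peaks.empty:
                lines.append("no significant QTL")
            else:
                for _, p in self.peaks.iterrows():
                    lines.append(
                        f"QTL chr {p.chromosome} @ {p.position:g} cM: "
                        f"LOD {p.lod:.1f}, R^2 {p.r2:.3f}, "
                        f"LOD-2 interval {p.interval_lo:g}-{p.interval_hi:g} cM"
                    )
        return "\n".join(lines)

    def plot(self, ax=None):
        """LOD profile along the genome, one panel track per chromosome."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        offset = 0.0
        for chrom, sub in self.profile.groupby("chromosome", sort=False):
            pos = sub["position"].to_numpy()
            ax.plot(pos + offset, sub["lod"].to_numpy(), label=str(chrom))
            offset += pos.max() + 5.0
        if self.threshold is not None:
            ax.axhline(self.threshold, ls="--", color="grey")
        ax.set_xlabel("position (cM, chromosomes concatenated)")
        ax.set_ylabel("LOD")
        ax.legend(title="chromosome", fontsize="small")
        return ax
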