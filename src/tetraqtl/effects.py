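"""Homologue effects and bi-allelic QTL model search.

Once a QTL is located, two complementary summaries of its allelic
architecture are computed.

Per-homologue effects: with homologue weights ``pi_i = X_i / 2`` (the
probability scale of carrying homologue i), the weighted trait mean of the
carriers of homologue i is

    hbar_i = sum_n pi_in * y_n / sum_n pi_in

and its effect is ``hbar_i - ybar``.  Because the weights of the eight
homologues sum to a constant per individual, the weighted effects sum to
zero.

Bi-allelic model search: every assignment of a bi-allelic Q/q genotype to
the 8 parental homologues (for example QQQQ x QQQq) is fitted by regressing
the trait on the expected Q-allele dosage (additive coding), optionally plus
the probability of carrying at least one Q copy (dominance coding).  Models
are ranked by the Schwarz information criterion

    SIC = n * ln(RSS / n) + k * ln(n)

and reported as Delta-SIC against the best model; a runner-up within 2 SIC
units is weak evidence for distinguishing the models.  Under additive coding
an assignment and its within-parent complement give affinely identical
predictors (the parental dosages sum to 2) and therefore identical SIC;
such models are reported as one equivalence class.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
import scipy.linalg

from .ibd import GAMETE_CLASSES, GameteClassProbabilities, HomologueDosageGrid

__all__ = [
    "homologue_effects",
    "enumerate_biallelic_models",
    "fit_biallelic_model",
    "model_evidence",
    "additive_equivalence_key",
    "BiallelicModelSearch",
    "BiallelicSearchResults",
]


def homologue_effects(y, X_pos: np.ndarray) -> pd.DataFrame:
    """Weighted per-homologue trait means and effects at one position.

    Returns a DataFrame indexed by homologue 1..8 with columns ``h_bar``
    (weighted mean), ``effect`` (``h_bar - ybar``) and ``weight``
    (total homologue weight ``sum_n pi_in``).
    """
    y = np.asarray(y, dtype=float)
    X_pos = np.asarray(X_pos, dtype=float)
    if X_pos.shape != (len(y), 8):
        raise ValueError("dosage block must be (n, 8) and match y")
    pi = X_pos / 2.0
    weights = pi.sum(axis=0)
    if np.any(weights <= 0):
        bad = int(np.flatnonzero(weights <= 0)[0]) + 1
        raise ValueError(f"homologue {bad} has zero total weight")
    h_bar = (pi * y[:, None]).sum(axis=0) / weights
    return pd.DataFrame(
        {
            "h_bar": h_bar,
            "effect": h_bar - y.mean(),
            "weight": weights,
        },
        index=pd.RangeIndex(1, 9, name="homologue"),
    )


def _genotype_string(mask: tuple) -> str:
    p1 = "".join("Q" if q else "q" for q in mask[:4])
    p2 = "".join("Q" if q else "q" for q in mask[4:])
    return f"{p1} x {p2}"


def _is_segregating(mask: tuple) -> bool:
    p1, p2 = mask[:4], mask[4:]
    return not (len(set(p1)) == 1 and len(set(p2)) == 1)


def _canonical(mask: tuple) -> tuple:
    swapped = tuple(not q for q in mask)
    return min(mask, swapped)


def enumerate_biallelic_models() -> list:
    """All canonical segregating Q/q assignments to the 8 homologues.

    The 2^8 assignments are de-duplicated under the global Q <-> q swap and
    assignments in which both parents are homozygous (non-segregating QTL)
    are removed, leaving 126 canonical assignments.
    """
    seen = set()
    models = []
    for bits in product((False, True), repeat=8):
        canon = _canonical(bits)
        if canon in seen:
            continue
        seen.add(canon)
        if _is_segregating(canon):
            models.append(canon)
    return models


def additive_equivalence_key(mask: tuple) -> tuple:
    """Canonical key of the additive-coding equivalence class of a model.

    Complementing the Q-set within one parent maps the Q-dosage predictor x
    to 2 - x per parent, an affine change that leaves the additive
    regression fit (RSS, SIC) unchanged.  The key is the minimum over the
    four per-parent complementations and the global swap.
    """
    variants = []
    for flip1, flip2 in product((False, True), repeat=2):
        v = tuple(
            (not q) if (flip1 and i < 4) or (flip2 and i >= 4) else q
            for i, q in enumerate(mask)
        )
        variants.append(_canonical(v))
    return min(variants)


def _q_dosage(mask: tuple, X_pos: np.ndarray) -> np.ndarray:
    idx = [i for i, q in enumerate(mask) if q]
    return X_pos[:, idx].sum(axis=1) if idx else np.zeros(len(X_pos))


def _carrier_probability(
    mask: tuple,
    X_pos: np.ndarray,
    class_probs: np.ndarray | None,
) -> tuple:
    """P(at least one Q copy) per individual.

    Computed exactly from the per-parent gamete-class distributions when
    available; otherwise a product-of-marginals approximation from the
    dosages is used and flagged.
    """
    if class_probs is not None:
        p_noq = np.ones((X_pos.shape[0], 2))
        for parent in (0, 1):
            q_set = {
                i - 4 * parent for i, q in enumerate(mask) if q and i // 4 == parent
            }
            free = np.array(
                [
                    not ({int(c[0]) - 1, int(c[1]) - 1} & q_set)
                    for c in GAMETE_CLASSES
                ],
                dtype=float,
            )
            p_noq[:, parent] = class_probs[:, parent, :] @ free
        return 1.0 - p_noq.prod(axis=1), False
    p_no = np.ones(X_pos.shape[0])
    for i, q in enumerate(mask):
        if q:
            p_no = p_no * np.clip(1.0 - X_pos[:, i] / 2.0, 0.0, 1.0)
    return 1.0 - p_no, True


def fit_biallelic_model(
    y,
    X_pos: np.ndarray,
    mask: tuple,
    coding: str = "additive",
    class_probs: np.ndarray | None = None,
) -> dict:
    """Fit one bi-allelic assignment at a position.

    Parameters
    ----------
    y, X_pos
        Trait values and the (n, 8) dosage block at the position.
    mask
        Tuple of 8 booleans, True where the homologue carries Q.
    coding
        ``'additive'`` (expected Q dosage) or ``'additive+dominance'``
        (plus the probability of carrying at least one Q copy).
    class_probs
        Optional (n, 2, 10) gamete-class probabilities at the position for
        an exact dominance predictor.

    Returns a dict with the genotype string, coefficients, RSS, k, SIC,
    fitted means per (rounded) Q-dosage class, and an ``approx_dominance``
    flag.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    add = _q_dosage(mask, X_pos)
    if np.ptp(add) < 1e-12:
        raise ValueError("degenerate (zero-variance) Q-dosage predictor")
    cols = [np.ones(n), add]
    approx = False
    if coding == "additive+dominance":
        dom, approx = _carrier_probability(mask, X_pos, class_probs)
        cols.append(dom)
    elif coding != "additive":
        raise ValueError("coding must be 'additive' or 'additive+dominance'")
    design = np.column_stack(cols)
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    rss = float(resid @ resid)
    k = design.shape[1]
    sic = n * np.log(max(rss, 1e-300) / n) + k * np.log(n)
    classes = np.round(add).astype(int)
    class_means = {
        int(c): float(y[classes == c].mean()) for c in np.unique(classes)
    }
    return {
        "genotype": _genotype_string(mask),
        "mask": mask,
        "coding": coding,
        "coef": coef,
        "rss": rss,
        "k": k,
        "sic": float(sic),
        "class_means": class_means,
        "approx_dominance": approx,
    }


def model_evidence(fits: list) -> pd.DataFrame:
    """Delta-SIC table over fitted models with evidence labels.

    ``delta_sic = SIC - min SIC``; the evidence column grades the
    separation of each model from the best one (below 2: weak — the models
    are effectively indistinguishable; 2-6 positive; 6-10 strong; above 10
    very strong).
    """
    if not fits:
        raise ValueError("no fitted models")
    table = pd.DataFrame(
        {
            "genotype": [f["genotype"] for f in fits],
            "coding": [f["coding"] for f in fits],
            "k": [f["k"] for f in fits],
            "rss": [f["rss"] for f in fits],
            "sic": [f["sic"] for f in fits],
            "mask": [f["mask"] for f in fits],
        }
    )
    table["delta_sic"] = table["sic"] - table["sic"].min()
    bins = [-np.inf, 2.0, 6.0, 10.0, np.inf]
    labels = ["weak", "positive", "strong", "very strong"]
    table["evidence"] = pd.cut(table["delta_sic"], bins=bins, labels=labels)
    return table.sort_values("sic", kind="stable").reset_index(drop=True)


class BiallelicModelSearch:
    """Exhaustive minimum-SIC search over bi-allelic QTL models.

    Parameters
    ----------
    y
        Trait values aligned with ``grid.individuals`` (array or Series).
    grid
        Homologue dosages.
    chromosome, position
        QTL position at which to run the search (nearest grid point).
    probabilities
        Optional gamete-class probabilities for exact dominance predictors.
    """

    def __init__(
        self,
        y,
        grid: HomologueDosageGrid,
        chromosome: str,
        position: float,
        probabilities: GameteClassProbabilities | None = None,
    ):
        from .scan import _align_phenotype

        self.grid = grid
        self.y, self.rows = _align_phenotype(y, grid)
        self.index = grid.locate(chromosome, position)
        self.chromosome = str(chromosome)
        self.position = float(
            grid.positions["position"].iloc[self.index]
        )
        self.class_probs = (
            probabilities.probs[self.rows, self.index, :, :]
            if probabilities is not None
            else None
        )

    def fit(self, include_dominance: bool = True) -> "BiallelicSearchResults":
        X_pos = self.grid.X[self.rows, self.index, :]
        fits = []
        for mask in enumerate_biallelic_models():
            codings = ["additive"]
            if include_dominance:
                codings.append("additive+dominance")
            for coding in codings:
                try:
                    fits.append(
                        fit_biallelic_model(
                            self.y, X_pos, mask, coding, self.class_probs
                        )
                    )
                except ValueError:
                    continue  # degenerate predictor at this position
        table = model_evidence(fits)
        table["equiv_class"] = [
            additive_equivalence_key(m) for m in table["mask"]
        ]
        best_row = table.iloc[0]
        best = next(
            f
            for f in fits
            if f["mask"] == best_row["mask"] and f["coding"] == best_row["coding"]
        )
        return BiallelicSearchResults(
            model=self, table=table, best=best
        )


@dataclass
class BiallelicSearchResults:
    """Ranked bi-allelic models at a QTL position."""

    model: BiallelicModelSearch
    table: pd.DataFrame
    best: dict

    @property
    def best_mask(self) -> tuple:
        return self.best["mask"]

    @property
    def runner_up_delta(self) -> float:
        """Delta-SIC of the best model outside the winner's additive
        equivalence class (the reported model separation)."""
        t = self.table
        other = t[t["equiv_class"] != t.iloc[0]["equiv_class"]]
        return float(other["delta_sic"].iloc[0]) if len(other) else float("inf")

    def summary(self) -> str:
        b = self.best
        means = ", ".join(
            f"Q-dosage {c}: {m:.3f}" for c, m in sorted(b["class_means"].items())
        )
        lines = [
            f"Bi-allelic model search at chr {self.model.chromosome} "
            f"@ {self.model.position:g} cM "
            f"({len(self.table)} fitted models)",
            f"best model: {b['genotype']} ({b['coding']}), "
            f"SIC = {b['sic']:.1f}",
            f"allele-class means: {means}",
            f"separation from next model class: Delta-SIC = "
            f"{self.runner_up_delta:.1f}",
        ]
        if b["approx_dominance"]:
            lines.append(
                "note: dominance predictor approximated from marginal dosages"
            )
        return "\n".join(lines)
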