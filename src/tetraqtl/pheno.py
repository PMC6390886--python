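"""Trait derivation, variance components, heritability and BLUEs.

The trait is tuber protein content, derived from soluble protein measured in
potato fruit juice (PFJ, % w/v) corrected by tuber moisture content:

    protein_content = PFJ_protein * (100 - dry_matter) / 100

Variance components come from the mean squares of a one-way (within-year,
clones + blocks) or two-way (between-years, clones + years + blocks-in-years
+ clone-by-year) ANOVA:

    sigma2_E = MS_E
    sigma2_G (one-way)  = (MS_G - MS_E) / r
    sigma2_G (two-way)  = (MS_G - MS_GxY) / (r * y)
    sigma2_GxY          = (MS_GxY - MS_E) / r

with r replicates (blocks) and y years, and broad-sense heritability

    H2 within  = sigma2_G / (sigma2_G + sigma2_E / r)
    H2 between = sigma2_G / (sigma2_G + sigma2_GxY / y + sigma2_E / (r * y))

BLUEs (per-clone adjusted means over years) come from a mixed model with the
genotype effect fixed and year effects random, fitted by REML.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "tuber_moisture",
    "protein_content",
    "derive_trait",
    "anova_mean_squares",
    "variance_components",
    "heritability",
    "compute_blues",
    "VarianceComponents",
    "TrialANOVA",
    "TrialANOVAResults",
]


def tuber_moisture(dry_matter):
    """Tuber moisture content (%) from tuber dry matter (%).

    ``moisture = 100 - dry_matter``; input must lie in [0, 100].
    """
    dm = np.asarray(dry_matter, dtype=float)
    if np.any((dm < 0) | (dm > 100)):
        raise ValueError("dry matter must be within [0, 100] %")
    out = 100.0 - dm
    return float(out) if np.isscalar(dry_matter) else out


def protein_content(pfj_protein, moisture):
    """Moisture-corrected protein content.

    ``pfj_protein * moisture / 100`` with PFJ protein in % w/v
    (1% = 10 mg/ml PFJ) and moisture in %.  Bilinear in both arguments.
    """
    p = np.asarray(pfj_protein, dtype=float)
    m = np.asarray(moisture, dtype=float)
    if np.any(p < 0) or np.any(m < 0):
        raise ValueError("inputs must be non-negative")
    out = p * m / 100.0
    if np.isscalar(pfj_protein) and np.isscalar(moisture):
        return float(out)
    return out


def derive_trait(table: pd.DataFrame) -> pd.DataFrame:
    """Add moisture and protein_content columns to a raw phenotype table."""
    out = table.copy()
    out["moisture"] = tuber_moisture(out["dry_matter"].to_numpy())
    out["protein_content"] = protein_content(
        out["pfj_protein"].to_numpy(), out["moisture"].to_numpy()
    )
    return out


@dataclass
class VarianceComponents:
    """ANOVA variance components for the clonal trial.

    Estimates are reported raw (they can be negative by sampling error) and
    floored at zero for heritability via :meth:`nonneg`.
    """

    sigma2_G: float
    sigma2_E: float
    sigma2_GxY: float | None = None
    r: int = 2
    y: int = 1
    MS_G: float | None = None
    MS_GxY: float | None = None
    MS_E: float | None = None

    def nonneg(self, name: str) -> float:
        value = getattr(self, name)
        if value is None:
            raise ValueError(f"{name} not available")
        return max(float(value), 0.0)


def _require_columns(table: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns {missing}")


def anova_mean_squares(table: pd.DataFrame, model: str = "within") -> dict:
    """Mean squares for the clone trial ANOVA.

    ``model='within'`` fits ``y ~ clone + block`` on a single year's data and
    returns ``MS_G`` (clones) and ``MS_E`` (residual).  ``model='between'``
    fits ``y ~ clone + year + block-in-year + clone:year`` and additionally
    returns ``MS_GxY``.  Sums of squares are type II, so mildly unbalanced
    data (clones missing the odd cell) are handled.

    Returns a dict with the mean squares, their degrees of freedom and the
    clone (and interaction) F-test p-values.
    """
    _require_columns(table, ["clone", "block", "protein_content"])
    df = table.copy()
    if model == "within":
        if df["year"].nunique() > 1 if "year" in df.columns else False:
            raise ValueError("within-year model expects a single year of data")
        if df["block"].nunique() < 2:
            raise ValueError("within-year ANOVA needs >= 2 blocks")
        fit = smf.ols("protein_content ~ C(clone) + C(block)", data=df).fit()
        tab = anova_lm(fit, typ=2)
        return {
            "MS_G": tab.loc["C(clone)", "sum_sq"] / tab.loc["C(clone)", "df"],
            "MS_E": tab.loc["Residual", "sum_sq"] / tab.loc["Residual", "df"],
            "df_G": tab.loc["C(clone)", "df"],
            "df_E": tab.loc["Residual", "df"],
            "p_clone": tab.loc["C(clone)", "PR(>F)"],
        }
    if model == "between":
        _require_columns(table, ["year"])
        if df["year"].nunique() < 2:
            raise ValueError("between-years ANOVA needs >= 2 years")
        fit = smf.ols(
            "protein_content ~ C(clone) + C(year) + C(year):C(block)"
            " + C(clone):C(year)",
            data=df,
        ).fit()
        tab = anova_lm(fit, typ=2)
        inter = "C(clone):C(year)"
        return {
            "MS_G": tab.loc["C(clone)", "sum_sq"] / tab.loc["C(clone)", "df"],
            "MS_GxY": tab.loc[inter, "sum_sq"] / tab.loc[inter, "df"],
            "MS_E": tab.loc["Residual", "sum_sq"] / tab.loc["Residual", "df"],
            "df_G": tab.loc["C(clone)", "df"],
            "df_GxY": tab.loc[inter, "df"],
            "df_E": tab.loc["Residual", "df"],
            "p_clone": tab.loc["C(clone)", "PR(>F)"],
            "p_interaction": tab.loc[inter, "PR(>F)"],
        }
    raise ValueError("model must be 'within' or 'between'")


def variance_components(
    ms: dict, r: int, y: int = 1, model: str = "within"
) -> VarianceComponents:
    """Variance components from ANOVA mean squares.

    One-way: ``sigma2_G = (MS_G - MS_E) / r``.  Two-way:
    ``sigma2_G = (MS_G - MS_GxY) / (r*y)`` and
    ``sigma2_GxY = (MS_GxY - MS_E) / r``.  ``sigma2_E = MS_E`` always.
    """
    if r < 1 or y < 1:
        raise ValueError("r and y must be >= 1")
    if model == "within":
        return VarianceComponents(
            sigma2_G=(ms["MS_G"] - ms["MS_E"]) / r,
            sigma2_E=ms["MS_E"],
            r=r,
            y=1,
            MS_G=ms["MS_G"],
            MS_E=ms["MS_E"],
        )
    if model == "between":
        return VarianceComponents(
            sigma2_G=(ms["MS_G"] - ms["MS_GxY"]) / (r * y),
            sigma2_GxY=(ms["MS_GxY"] - ms["MS_E"]) / r,
            sigma2_E=ms["MS_E"],
            r=r,
            y=y,
            MS_G=ms["MS_G"],
            MS_GxY=ms["MS_GxY"],
            MS_E=ms["MS_E"],
        )
    raise ValueError("model must be 'within' or 'between'")


def heritability(components: VarianceComponents, model: str = "within") -> float:
    """Broad-sense heritability H2 in [0, 1].

    Within year: ``H2 = sigma2_G / (sigma2_G + sigma2_E / r)``.
    Between years: ``H2 = sigma2_G / (sigma2_G + sigma2_GxY / y
    + sigma2_E / (r*y))``.  Negative component estimates are floored at 0.
    """
    sG = components.nonneg("sigma2_G")
    sE = components.nonneg("sigma2_E")
    r = components.r
    if model == "within":
        denom = sG + sE / r
    elif model == "between":
        sGY = components.nonneg("sigma2_GxY")
        y = components.y
        denom = sG + sGY / y + sE / (r * y)
    else:
        raise ValueError("model must be 'within' or 'between'")
    if denom == 0.0:
        raise ValueError("all variance components are zero")
    return sG / denom


def compute_blues(table: pd.DataFrame) -> pd.Series:
    """Per-clone adjusted means (BLUEs) over years.

    Fits ``protein_content ~ clone`` with clone fixed and year random by
    REML.  With a single year the model reduces to per-clone means.  Clones
    observed in no record raise; in fully balanced data the BLUEs equal raw
    clone means after centring on year means.
    """
    _require_columns(table, ["clone", "year", "protein_content"])
    df = table.dropna(subset=["protein_content"]).copy()
    if df.empty:
        raise ValueError("no phenotype records")
    if df["year"].nunique() == 1:
        return df.groupby("clone")["protein_content"].mean().rename("blue")
    df["clone"] = df["clone"].astype(str)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = smf.mixedlm(
            "protein_content ~ 0 + C(clone)", data=df, groups=df["year"]
        )
        fit = md.fit(reml=True)
    params = fit.fe_params
    names = {}
    for key, value in params.items():
        if key.startswith("C(clone)["):
            names[key[len("C(clone)[") : -1]] = value
    return pd.Series(names, name="blue").sort_index()


class TrialANOVA:
    """ANOVA model of a clonal field trial (statsmodels-style).

    Parameters
    ----------
    table
        Phenotype records with columns clone, year, block, protein_content
        (use :func:`derive_trait` to compute the trait from raw columns).
    design
        ``'within'`` for a one-way (single-year) analysis or ``'between'``
        for the two-way multi-year analysis.
    """

    def __init__(self, table: pd.DataFrame, design: str = "within"):
        if design not in ("within", "between"):
            raise ValueError("design must be 'within' or 'between'")
        _require_columns(table, ["clone", "block", "protein_content"])
        self.table = table
        self.design = design

    @classmethod
    def from_raw(cls, table: pd.DataFrame, design: str = "within"):
        """Build from raw pfj_protein / dry_matter columns."""
        return cls(derive_trait(table), design=design)

    def fit(self) -> "TrialANOVAResults":
        df = self.table
        r = int(df.groupby(["clone", "year"])["block"].nunique().max()) \
            if "year" in df.columns else int(df.groupby("clone")["block"].nunique().max())
        y = int(df["year"].nunique()) if "year" in df.columns else 1
        ms = anova_mean_squares(df, model=self.design)
        vc = variance_components(
            ms, r=r, y=y if self.design == "between" else 1, model=self.design
        )
        h2 = heritability(vc, model=self.design)
        return TrialANOVAResults(
            model=self, mean_squares=ms, components=vc, H2=h2
        )


@dataclass
class TrialANOVAResults:
    """Fitted trial ANOVA: mean squares, components, heritability."""

    model: TrialANOVA
    mean_squares: dict
    components: VarianceComponents
    H2: float

    @property
    def H2_percent(self) -> float:
        return 100.0 * self.H2

    def summary(self) -> str:
        vc = self.components
        lines = [
            f"Trial ANOVA ({self.model.design}-year{'s' if self.model.design == 'between' else ''})",
            f"  replicates r = {vc.r}" + (f", years y = {vc.y}" if self.model.design == "between" else ""),
            f"  MS_G   = {vc.MS_G:.6g}",
        ]
        if vc.MS_GxY is not None:
            lines.append(f"  MS_GxY = {vc.MS_GxY:.6g}")
        lines += [
            f"  MS_E   = {vc.MS_E:.6g}",
            f"  sigma2_G   = {vc.sigma2_G:.6g}",
        ]
        if vc.sigma2_GxY is not None:
            lines.append(f"  sigma2_GxY = {vc.sigma2_GxY:.6g}")
        lines += [
            f"  sigma2_E   = {vc.sigma2_E:.6g}",
            f"  H2 = {self.H2:.3f} ({self.H2_percent:.1f}%)",
            f"  clone effect P = {self.mean_squares['p_clone']:.3g}",
        ]
        if "p_interaction" in self.mean_squares:
            lines.append(
                f"  clone x year P = {self.mean_squares['p_interaction']:.3g}"
            )
        return "\n".join(lines)
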