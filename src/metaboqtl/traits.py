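"""Nuisance adjustment of the target trait and metabotypes, and residual
correlations.

Every phenotype (the target trait and each metabotype) is adjusted by
ordinary least squares for slaughter date (fixed effect) and centered
slaughter weight (covariate):

    y = mu + SD_j + beta_s * SW + e

The residuals e feed two consumers: residual-based Pearson correlations of
each metabotype with the target trait (with significance stars), and the
PC-corrected per-SNP score test, which adds the genetic term to the model
one SNP at a time on these residuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .simdata import TARGET_TRAIT

logger = logging.getLogger(__name__)

MIN_USABLE_SAMPLES = 10
STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class FixedAdjustment:
    """OLS fit of one phenotype on slaughter date + centered weight."""

    residuals: pd.Series          # indexed by sample id, NaN where unused
    mu: float
    date_effects: dict[str, float]  # deviation of each level from the first
    beta_weight: float
    se_beta_weight: float
    n_used: int
    degenerate: bool = False
    reason: str = ""


@dataclass
class AdjustedTraits:
    """Residualized phenotypes: one :class:`FixedAdjustment` per trait."""

    entries: dict[str, FixedAdjustment] = field(default_factory=dict)

    @property
    def residual_frame(self) -> pd.DataFrame:
        ok = {t: e.residuals for t, e in self.entries.items() if not e.degenerate}
        return pd.DataFrame(ok)

    def __getitem__(self, trait: str) -> FixedAdjustment:
        return self.entries[trait]


@dataclass
class TraitTable:
    """Target trait, slaughter covariates and metabotype abundances."""

    data: pd.DataFrame  # indexed by sample_id
    target: str = TARGET_TRAIT
    date_col: str = "slaughter_date"
    weight_col: str = "slaughter_weight"

    def __post_init__(self) -> None:
        for col in (self.target, self.date_col, self.weight_col):
            if col not in self.data.columns:
                raise ValueError(f"trait table lacks column {col!r}")
        if (self.data[self.weight_col] <= 0).any():
            raise ValueError("slaughter_weight must be positive")

    @property
    def metabotype_cols(self) -> list[str]:
        skip = {self.target, self.date_col, self.weight_col}
        return [c for c in self.data.columns if c not in skip]

    @classmethod
    def from_files(cls, traits_tsv, metabotypes_tsv=None, **kw) -> "TraitTable":
        df = pd.read_csv(traits_tsv, sep="\t").set_index("sample_id")
        if metabotypes_tsv is not None:
            met = pd.read_csv(metabotypes_tsv, sep="\t").set_index("sample_id")
            shared = df.index.intersection(met.index)
            if len(shared) < len(df.index) or len(shared) < len(met.index):
                logger.warning(
                    "trait/metabotype tables share %d samples "
                    "(traits %d, metabotypes %d); using the intersection",
                    len(shared), len(df.index), len(met.index),
                )
            df = df.loc[shared].join(met.loc[shared])
        return cls(data=df, **kw)


def fit_fixed_adjustment(
    values: pd.Series, dates: pd.Series, weights: pd.Series
) -> FixedAdjustment:
    """OLS of one phenotype on date indicators + centered slaughter weight.

    Samples with a missing phenotype are dropped pairwise.  The per-SNP
    genetic term is deliberately absent here; it enters later as the score
    test.  Raises if weight is collinear with the date design.
    """
    mask = values.notna() & dates.notna() & weights.notna()
    y = values[mask].astype(float)
    d = dates[mask].astype(str)
    w = weights[mask].astype(float)
    n = len(y)
    levels = sorted(d.unique())
    if n < len(levels) + 2:
        raise ValueError(f"only {n} usable samples for {len(levels)} date levels")
    wc = w - w.mean()
    X = np.column_stack(
        [np.ones(n)]
        + [(d == lv).to_numpy(float) for lv in levels[1:]]
        + [wc.to_numpy()]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "design is rank deficient: slaughter weight is collinear with the "
            "slaughter-date indicators"
        )
    fit = sm.OLS(y.to_numpy(), X).fit()
    resid = pd.Series(np.nan, index=values.index)
    resid[mask] = fit.resid
    date_effects = {levels[0]: 0.0}
    for i, lv in enumerate(levels[1:]):
        date_effects[lv] = float(fit.params[1 + i])
    return FixedAdjustment(
        residuals=resid,
        mu=float(fit.params[0]),
        date_effects=date_effects,
        beta_weight=float(fit.params[-1]),
        se_beta_weight=float(fit.bse[-1]),
        n_used=n,
    )


def residualize_all(table: TraitTable) -> AdjustedTraits:
    """Adjust the target trait and every metabotype for the nuisance design.

    Metabotypes with fewer than 10 usable samples or zero variance are
    flagged degenerate and excluded downstream (logged); a degenerate target
    trait is an error.
    """
    adjusted = AdjustedTraits()
    dates = table.data[table.date_col]
    weights = table.data[table.weight_col]
    for trait in [table.target, *table.metabotype_cols]:
        values = table.data[trait]
        usable = values.notna() & dates.notna() & weights.notna()
        if usable.sum() < MIN_USABLE_SAMPLES:
            reason = f"only {int(usable.sum())} usable samples"
        elif np.nanstd(values.astype(float).to_numpy()) == 0:
            reason = "zero variance"
        else:
            reason = ""
        if reason:
            if trait == table.target:
                raise ValueError(f"target trait {trait!r} is degenerate: {reason}")
            logger.warning("trait %s flagged degenerate (%s); excluded", trait, reason)
            adjusted.entries[trait] = FixedAdjustment(
                residuals=pd.Series(np.nan, index=values.index),
                mu=np.nan, date_effects={}, beta_weight=np.nan,
                se_beta_weight=np.nan, n_used=int(usable.sum()),
                degenerate=True, reason=reason,
            )
            continue
        adjusted.entries[trait] = fit_fixed_adjustment(values, dates, weights)
    return adjusted


def _star(p: float) -> str:
    for thr, s in STAR_THRESHOLDS:
        if p <= thr:
            return s
    return ""


def correlate_with_target(
    adjusted: AdjustedTraits, target: str = TARGET_TRAIT
) -> pd.DataFrame:
    """Residual-based Pearson correlation of each metabotype with the target.

    Pairwise-complete residuals; two-sided t-test p on n-2 df; significance
    stars at p <= 0.05 / 0.01 / 0.001.  Components with fewer than 10 shared
    samples or zero residual variance get NaN r (marked undefined).
    """
    if target not in adjusted.entries:
        raise KeyError(f"target {target!r} not among adjusted traits")
    ty = adjusted[target].residuals
    rows = []
    for trait, entry in adjusted.entries.items():
        if trait == target or entry.degenerate:
            continue
        x = entry.residuals
        mask = ty.notna() & x.notna()
        n = int(mask.sum())
        r = p = np.nan
        if n >= MIN_USABLE_SAMPLES:
            xv = x[mask].to_numpy(float)
            yv = ty[mask].to_numpy(float)
            if xv.std() > 0 and yv.std() > 0:
                r, p = stats.pearsonr(xv, yv)
        rows.append(
            {
                "component": trait,
                "n": n,
                "r": r,
                "p_value": p,
                "star": _star(p) if np.isfinite(p) else "",
            }
        )
    return pd.DataFrame(rows).set_index("component")


def descriptive_report(table: TraitTable, correlations: pd.DataFrame) -> pd.DataFrame:
    """Per-component descriptive statistics plus the residual correlation
    (the layout of a descriptive phenotype table: mean ± sd, min, max, r)."""
    rows = []
    for comp in [table.target, *table.metabotype_cols]:
        v = table.data[comp].astype(float)
        row = {
            "component": comp,
            "mean": v.mean(),
            "sd": v.std(),
            "min": v.min(),
            "max": v.max(),
        }
        if comp in correlations.index:
            row["r"] = correlations.loc[comp, "r"]
            row["star"] = correlations.loc[comp, "star"]
        else:
            row["r"], row["star"] = np.nan, ""
        rows.append(row)
    return pd.DataFrame(rows).set_index("component")
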