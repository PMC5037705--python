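"""PC-corrected single-SNP score-test association scans.

The association statistic is the EIGENSTRAT-style score test: phenotype
residuals (already adjusted for slaughter date/weight) and mean-imputed SNP
dosages are both residualized on the top-k principal components of the
genomic kinship matrix; with r the Pearson correlation of the two residual
vectors, the statistic is chi2 = (n - k - 1) * r^2, referred to a 1-df
chi-square.  Residual stratification is monitored with the genomic inflation
factor lambda = median(chi2) / 0.4549 (0.4549 is the chi-square(1) median to
four decimals), and k is chosen per trait by scanning k = 1..10 and keeping
the k whose lambda is nearest to 1.  Multiple testing is handled with Storey
q-values per trait scan, and each SNP's explained variance is
100 * chi2 / (n - 2 + chi2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype import GenotypePanel

logger = logging.getLogger(__name__)

#: Median of the 1-df chi-square distribution to four decimals — the
#: denominator of the inflation-factor formula.
CHI2_1DF_MEDIAN = 0.4549

Q_TIERS = (0.1, 0.05, 0.01)


def chi2_1df_median(precision: int | None = 4) -> float:
    """The chi-square(1) median computed analytically (0.4549... rounded)."""
    med = float(stats.chi2.ppf(0.5, df=1))
    return round(med, precision) if precision is not None else med


@dataclass
class KinshipMatrix:
    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        K = self.values
        if K.shape[0] != K.shape[1] or K.shape[0] != len(self.sample_ids):
            raise ValueError("kinship matrix shape does not match sample ids")
        if not np.isfinite(K).all():
            raise ValueError("non-finite kinship entries")
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("kinship matrix not symmetric within 1e-10")


def genomic_kinship(panel: GenotypePanel) -> KinshipMatrix:
    """Allele-frequency-standardized genomic kinship.

    K_ij = mean over SNPs of (g_i - 2p)(g_j - 2p) / (2p(1-p)), averaged
    pairwise-complete over the SNPs where both samples are called.
    Monomorphic SNPs are skipped (count logged).
    """
    G = panel.dosages
    called = ~np.isnan(G)
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(G, axis=0) / (2 * n_called)
    poly = (p > 0) & (p < 1) & (n_called >= 2)
    n_skipped = int((~poly).sum())
    if n_skipped:
        logger.info("kinship: skipped %d monomorphic/uncallable SNPs", n_skipped)
    if not poly.any():
        raise ValueError("no polymorphic SNP for kinship estimation")
    Gp, pp, cp = G[:, poly], p[poly], called[:, poly]
    Z = (Gp - 2 * pp) / np.sqrt(2 * pp * (1 - pp))
    Z = np.where(cp, Z, 0.0)
    M = cp.astype(float)
    counts = M @ M.T
    if (counts == 0).any():
        raise ValueError("some sample pairs share no called SNP")
    K = (Z @ Z.T) / counts
    K = (K + K.T) / 2.0
    return KinshipMatrix(values=K, sample_ids=list(panel.sample_ids))


def kinship_pcs(kinship: KinshipMatrix, k: int) -> np.ndarray:
    """Top-k eigenvectors of the double-centered kinship matrix.

    Eigenvalues descending; each vector's sign is fixed so its
    largest-magnitude entry is positive (determinism).
    """
    K = kinship.values
    n = K.shape[0]
    if not 0 <= k < n:
        raise ValueError(f"k must be in [0, {n}), got {k}")
    J = np.eye(n) - np.ones((n, n)) / n
    Kc = J @ K @ J
    evals, evecs = np.linalg.eigh(Kc)
    order = np.argsort(evals)[::-1]
    V = evecs[:, order[:k]]
    for j in range(V.shape[1]):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    return V


@dataclass
class ScanResult:
    """Vectorized per-SNP scan output for one trait."""

    chi2: np.ndarray
    p_value: np.ndarray
    effect: np.ndarray
    se: np.ndarray
    n_used: int
    k_pcs: int
    tested: np.ndarray  # False where the SNP was skipped (zero residual variance)


def scan_snps(
    y: np.ndarray, G: np.ndarray, pcs: np.ndarray | None = None
) -> ScanResult:
    """Score-test every SNP column of G against phenotype residual y.

    Missing dosages are mean-imputed per SNP; y and every dosage column are
    residualized on [intercept, PCs]; chi2 = (n - k - 1) r^2 with r the
    correlation of the residual vectors.  SNPs whose dosage residual has
    (numerically) zero variance are skipped with NaN output.
    """
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(y)
    y = y[mask]
    G = np.asarray(G, dtype=float)[mask]
    n = len(y)
    k = 0 if pcs is None else pcs.shape[1]
    if k >= n - 2:
        raise ValueError(f"k={k} PCs leave no residual df at n={n}")
    # mean-impute missing dosages per SNP
    col_mean = np.nanmean(np.where(np.isnan(G), np.nan, G), axis=0)
    G = np.where(np.isnan(G), col_mean, G)

    X = np.ones((n, 1)) if pcs is None else np.column_stack([np.ones(n), pcs[mask]])
    Q, _ = np.linalg.qr(X)
    yr = y - Q @ (Q.T @ y)
    Gr = G - Q @ (Q.T @ G)
    syy = float(yr @ yr)
    sgg = np.einsum("ij,ij->j", Gr, Gr)
    sgy = Gr.T @ yr
    scale = np.maximum(sgg.max(initial=0.0), 1.0)
    tested = sgg > 1e-12 * scale
    n_skipped = int((~tested).sum())
    if n_skipped:
        logger.info("scan: skipped %d SNPs with zero dosage residual variance", n_skipped)
    chi2 = np.full(G.shape[1], np.nan)
    effect = np.full(G.shape[1], np.nan)
    se = np.full(G.shape[1], np.nan)
    if syy <= 0:
        raise ValueError("phenotype residual has zero variance")
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(tested, sgy**2 / (sgg * syy), np.nan)
        r2 = np.minimum(r2, 1.0)
        chi2 = (n - k - 1) * r2
        effect = np.where(tested, sgy / sgg, np.nan)
        dof = n - k - 2
        resvar = np.maximum(syy - np.where(tested, sgy**2 / sgg, 0.0), 0.0) / dof
        se = np.where(tested, np.sqrt(resvar / sgg), np.nan)
    p = stats.chi2.sf(chi2, df=1)
    return ScanResult(chi2=chi2, p_value=p, effect=effect, se=se,
                      n_used=n, k_pcs=k, tested=tested)


def score_test(
    y: np.ndarray, g: np.ndarray, pcs: np.ndarray | None = None
) -> tuple[float, float, float, float, int]:
    """Single-SNP convenience wrapper: returns (chi2, effect, se, p, n_used)."""
    res = scan_snps(np.asarray(y), np.asarray(g, dtype=float).reshape(-1, 1), pcs)
    if not res.tested[0]:
        raise ValueError("SNP has zero dosage residual variance")
    return (
        float(res.chi2[0]), float(res.effect[0]), float(res.se[0]),
        float(res.p_value[0]), res.n_used,
    )


def inflation_factor(chi2: np.ndarray) -> float:
    """Genomic inflation factor: median(chi2) / 0.4549."""
    chi2 = np.asarray(chi2, dtype=float)
    chi2 = chi2[np.isfinite(chi2)]
    if len(chi2) == 0:
        raise ValueError("empty statistic vector")
    if len(chi2) < 100:
        warnings.warn(
            f"inflation factor from only {len(chi2)} statistics is unstable",
            stacklevel=2,
        )
    return float(np.median(chi2) / CHI2_1DF_MEDIAN)


@dataclass
class PCSelection:
    k: int
    lam: float
    profile: dict[int, float]  # k -> lambda, including k=0 for reference


def select_pc_count(
    y: np.ndarray,
    G: np.ndarray,
    kinship: KinshipMatrix,
    k_max: int = 10,
) -> PCSelection:
    """Scan k = 1..k_max PCs and keep the k whose lambda is nearest to 1.

    Ties go to the smaller k.  lambda at k=0 is recorded in the profile for
    reference but does not compete.
    """
    V = kinship_pcs(kinship, k_max)
    profile: dict[int, float] = {}
    profile[0] = inflation_factor(scan_snps(y, G, None).chi2)
    for k in range(1, k_max + 1):
        profile[k] = inflation_factor(scan_snps(y, G, V[:, :k]).chi2)
    best = _best_k(profile)
    return PCSelection(k=best, lam=profile[best], profile=profile)


def _best_k(profile: dict[int, float]) -> int:
    """lambda-nearest-to-1 rule over k >= 1; exact ties go to the smaller k."""
    return min((k for k in profile if k >= 1), key=lambda k: (abs(profile[k] - 1.0), k))


def qvalues(
    p: np.ndarray,
    pi0: float | None = None,
    lambda_grid: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Storey q-values; returns (q, pi0_hat).

    pi0 is estimated by fitting a cubic smoother to pi0(lambda) =
    #{p > lambda} / (m (1 - lambda)) over lambda = 0.05..0.95 and evaluating
    at the grid maximum, bounded to [1/m, 1]; pass ``pi0`` explicitly to
    override (pi0=1 reproduces Benjamini–Hochberg exactly).  q is the
    running minimum of pi0 * m * p / rank down the sorted p-values, hence
    monotone in p.
    """
    p = np.asarray(p, dtype=float)
    if ((p <= 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    if pi0 is None:
        if lambda_grid is None:
            lambda_grid = np.arange(0.05, 0.951, 0.05)
        pi0_l = np.array(
            [(p > lam).sum() / (m * (1.0 - lam)) for lam in lambda_grid]
        )
        if m < 100 or np.allclose(pi0_l, pi0_l[0]):
            pi0 = float(min(1.0, pi0_l[-1]))
        else:
            coef = np.polyfit(lambda_grid, pi0_l, deg=3)
            pi0 = float(np.polyval(coef, lambda_grid.max()))
        pi0 = min(1.0, max(1.0 / m, pi0))
    elif not 0 < pi0 <= 1:
        raise ValueError("pi0 must lie in (0, 1]")
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, pi0


def explained_variance(chi2, n_used) -> np.ndarray | float:
    """Per-SNP explained phenotypic variance in percent:
    100 * chi2 / (n - 2 + chi2)."""
    chi2 = np.asarray(chi2, dtype=float)
    if np.any(chi2[np.isfinite(chi2)] < 0):
        raise ValueError("chi2 must be nonnegative")
    if np.any(np.asarray(n_used) <= 2):
        raise ValueError("need n_used > 2")
    out = 100.0 * chi2 / (n_used - 2 + chi2)
    return float(out) if out.ndim == 0 else out


def empirical_pvalues(
    y: np.ndarray,
    G: np.ndarray,
    pcs: np.ndarray | None,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Permutation p per SNP: (1 + #{chi2_perm >= chi2_obs}) / (1 + n_perm).

    The phenotype residual is permuted across samples, which preserves the
    dosage correlation structure.
    """
    if rng is None:
        rng = np.random.default_rng()
    obs = scan_snps(y, G, pcs)
    count = np.zeros(G.shape[1])
    yv = np.asarray(y, dtype=float)
    for _ in range(n_perm):
        perm = rng.permutation(len(yv))
        res = scan_snps(yv[perm], G, pcs)
        count += res.chi2 >= obs.chi2 - 1e-12
    return (1.0 + count) / (1.0 + n_perm)


@dataclass
class GwasConfig:
    k_max: int = 10
    q_thresholds: tuple[float, ...] = Q_TIERS
    empirical_p: bool = False
    n_permutations: int = 10_000
    seed: int = 0


@dataclass
class GwasResult:
    associations: pd.DataFrame
    summaries: pd.DataFrame
    pc_selections: dict[str, PCSelection] = field(default_factory=dict)


def run_gwas(
    trait_ids: list[str],
    residuals: pd.DataFrame,
    panel: GenotypePanel,
    config: GwasConfig | None = None,
) -> GwasResult:
    """Full per-trait scans with PC selection, q-values and explained variance.

    ``residuals`` holds nuisance-adjusted phenotypes indexed by sample id
    (one column per trait).  For each trait: choose the PC count by the
    lambda-nearest-to-1 rule, scan all SNPs, compute Storey q-values over
    that trait's scan and the explained-variance percentage per SNP.
    """
    if config is None:
        config = GwasConfig()
    missing = [t for t in trait_ids if t not in residuals.columns]
    if missing:
        raise KeyError(f"traits absent from adjusted set: {missing}")
    residuals = residuals.loc[list(panel.sample_ids)]
    kin = genomic_kinship(panel)
    V = kinship_pcs(kin, config.k_max)
    G = panel.dosages
    maf = np.array([s.maf for s in panel.snps])
    rng = np.random.default_rng(config.seed)

    assoc_frames = []
    summary_rows = []
    selections: dict[str, PCSelection] = {}
    for trait in trait_ids:
        y = residuals[trait].to_numpy(dtype=float)
        sel = select_pc_count(y, G, kin, k_max=config.k_max)
        selections[trait] = sel
        scan = scan_snps(y, G, V[:, : sel.k])
        finite_p = np.isfinite(scan.p_value)
        q = np.full(panel.n_snps, np.nan)
        q[finite_p], pi0 = qvalues(np.clip(scan.p_value[finite_p], 1e-300, 1.0))
        var_pct = explained_variance(np.where(finite_p, scan.chi2, np.nan), scan.n_used)
        df = pd.DataFrame(
            {
                "trait_id": trait,
                "snp_id": panel.snp_ids,
                "chrom": [s.chrom for s in panel.snps],
                "pos_bp": [s.pos_bp for s in panel.snps],
                "maf": maf,
                "effect": scan.effect,
                "se": scan.se,
                "chi2": scan.chi2,
                "p_value": scan.p_value,
                "q_value": q,
                "var_explained_pct": var_pct,
                "n_used": scan.n_used,
            }
        )
        if config.empirical_p:
            df["empirical_p"] = empirical_pvalues(
                y, G, V[:, : sel.k], config.n_permutations, rng
            )
        assoc_frames.append(df)
        tier_counts = {
            f"n_q{int(t * 100):02d}": int((q[finite_p] <= t).sum())
            for t in config.q_thresholds
        }
        summary_rows.append(
            {
                "trait_id": trait,
                "k_pcs": sel.k,
                "lambda": sel.lam,
                "n_snps_tested": int(finite_p.sum()),
                "pi0": pi0,
                "min_p": float(np.nanmin(scan.p_value)) if finite_p.any() else np.nan,
                "min_q": float(np.nanmin(q)) if finite_p.any() else np.nan,
                "max_var_pct": float(np.nanmax(var_pct)) if finite_p.any() else np.nan,
                **tier_counts,
            }
        )
        logger.info(
            "GWAS %s: k=%d lambda=%.3f, %d SNPs, %d at q<=0.1",
            trait, sel.k, sel.lam, int(finite_p.sum()), tier_counts.get("n_q10", 0),
        )
    return GwasResult(
        associations=pd.concat(assoc_frames, ignore_index=True),
        summaries=pd.DataFrame(summary_rows),
        pc_selections=selections,
    )
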