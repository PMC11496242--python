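"""Two-sample Mendelian randomization estimators and diagnostics.

All estimators consume a harmonized set of per-variant summary statistics
(bx, se_x on the exposure; by, se_y on the outcome, alleles aligned):

* Wald ratio — per-variant causal estimate by/bx.
* IVW — precision-weighted regression of by on bx through the origin;
  multiplicative random effects inflate the SE by sqrt(Q/(L-1)) when the
  instruments are heterogeneous (floored at 1).
* MR-Egger — the same weighted regression with a free intercept; a nonzero
  intercept indicates directional pleiotropy. bx are oriented non-negative
  first (InSIDE convention).
* Weighted median — the 50% point of the weight-ordered Wald ratios;
  consistent when >=50% of the weight comes from valid instruments.
* Simple/weighted mode — the kernel-density mode of the Wald ratios
  (ZEMPA: the largest group of variants with the same ratio is valid).
* Cochran's Q — heterogeneity of per-variant estimates, also in a
  two-estimate (df = 1) form used to compare stratified analyses.
* MVMR — multivariable IVW: weighted regression of by on several columns
  of exposure betas, giving each exposure's effect conditional on the rest.

Formulas are implemented directly; tests verify them against brute-force
weighted-regression oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, t as t_dist

__all__ = [
    "HarmonizedSet",
    "MRResult",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "mode_estimator",
    "cochrans_q",
    "two_estimate_heterogeneity",
    "mvmr_ivw",
]


@dataclass(frozen=True)
class MRResult:
    method: str
    beta: float
    se: float
    p: float
    n_snps: int
    Q: float | None = None
    Q_p: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None


class HarmonizedSet:
    """Aligned per-variant exposure/outcome summary statistics."""

    def __init__(self, bx, se_x, by, se_y, snp_ids=None):
        self.bx = np.asarray(bx, dtype=float)
        self.se_x = np.asarray(se_x, dtype=float)
        self.by = np.asarray(by, dtype=float)
        self.se_y = np.asarray(se_y, dtype=float)
        self.snp_ids = list(snp_ids) if snp_ids is not None else [
            f"v{i}" for i in range(len(self.bx))
        ]
        lens = {len(self.bx), len(self.se_x), len(self.by), len(self.se_y)}
        if len(lens) != 1 or len(self.bx) < 1:
            raise ValueError("bx, se_x, by, se_y must be equal-length, non-empty")
        if np.any(self.se_x <= 0) or np.any(self.se_y <= 0):
            raise ValueError("standard errors must be positive")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HarmonizedSet":
        return cls(df["bx"], df["se_x"], df["by"], df["se_y"],
                   df["SNP"] if "SNP" in df else None)

    def __len__(self) -> int:
        return len(self.bx)

    @property
    def ratios(self) -> np.ndarray:
        return self.by / self.bx

    @property
    def ratio_weights(self) -> np.ndarray:
        """Inverse-variance weights of the Wald ratios (first order)."""
        return self.bx**2 / self.se_y**2


def wald_ratio(bx: float, se_x: float, by: float, se_y: float,
               second_order: bool = False) -> MRResult:
    """Single-variant causal estimate by/bx with delta-method SE."""
    if bx == 0:
        raise ZeroDivisionError("exposure beta is zero")
    beta = by / bx
    if second_order:
        se = np.sqrt(se_y**2 / bx**2 + by**2 * se_x**2 / bx**4)
    else:
        se = se_y / abs(bx)
    z = beta / se
    return MRResult("wald_ratio", float(beta), float(se), float(2 * norm.sf(abs(z))), 1)


def _q_statistic(hs: HarmonizedSet, beta: float) -> float:
    return float(np.sum((hs.by - beta * hs.bx) ** 2 / hs.se_y**2))


def ivw(hs: HarmonizedSet, model: str = "multiplicative_random") -> MRResult:
    """Inverse-variance-weighted estimate.

    beta = sum(bx*by/se_y^2)/sum(bx^2/se_y^2); fixed-effect
    se = 1/sqrt(sum bx^2/se_y^2). The multiplicative random-effects model
    (default for L >= 2) scales the SE by max(1, sqrt(Q/(L-1))); the point
    estimate is identical under both models.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError("model must be 'fixed' or 'multiplicative_random'")
    L = len(hs)
    w = hs.bx**2 / hs.se_y**2
    beta = float(np.sum(hs.bx * hs.by / hs.se_y**2) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    q = _q_statistic(hs, beta)
    q_p = float(chi2.sf(q, L - 1)) if L >= 2 else np.nan
    if model == "multiplicative_random" and L >= 2:
        se *= max(1.0, np.sqrt(q / (L - 1)))
    z = beta / se
    return MRResult("ivw", beta, se, float(2 * norm.sf(abs(z))), L, q, q_p)


def mr_egger(hs: HarmonizedSet) -> MRResult:
    """MR-Egger weighted regression with an intercept.

    Every bx is oriented non-negative (flipping the matching by) before the
    1/se_y^2-weighted fit; the intercept estimates the average directional
    pleiotropic effect, the slope the causal effect. Inference uses a
    t distribution on L-2 df with the multiplicative overdispersion factor
    floored at 1.
    """
    L = len(hs)
    if L < 3:
        raise ValueError("MR-Egger needs at least 3 variants")
    flip = np.sign(hs.bx)
    flip[flip == 0] = 1.0
    bx = hs.bx * flip
    by = hs.by * flip
    w = 1.0 / hs.se_y**2
    X = np.column_stack([np.ones(L), bx])
    WX = X * w[:, None]
    XtWX = X.T @ WX
    coef = np.linalg.solve(XtWX, X.T @ (w * by))
    resid = by - X @ coef
    rss = float(np.sum(w * resid**2))
    phi = max(1.0, rss / (L - 2))
    cov = phi * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov))
    t_slope = coef[1] / se[1]
    t_int = coef[0] / se[0]
    return MRResult(
        "mr_egger",
        float(coef[1]),
        float(se[1]),
        float(2 * t_dist.sf(abs(t_slope), L - 2)),
        L,
        Q=rss,
        Q_p=float(chi2.sf(rss, L - 2)),
        egger_intercept=float(coef[0]),
        egger_intercept_se=float(se[0]),
        egger_intercept_p=float(2 * t_dist.sf(abs(t_int), L - 2)),
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order]
    S = np.cumsum(w)
    p = (S - w / 2.0) / S[-1]
    if 0.5 <= p[0]:
        return float(r[0])
    if 0.5 >= p[-1]:
        return float(r[-1])
    return float(np.interp(0.5, p, r))


def _parametric_bootstrap_se(hs, point_fn, n_boot, seed) -> float:
    rng = np.random.default_rng(seed)
    ests = np.empty(n_boot)
    for b in range(n_boot):
        bx = rng.normal(hs.bx, hs.se_x)
        by = rng.normal(hs.by, hs.se_y)
        ests[b] = point_fn(bx, by)
    return float(ests.std(ddof=1))


def weighted_median(hs: HarmonizedSet, n_boot: int = 5000, seed: int = 0) -> MRResult:
    """Weighted-median estimator with parametric-bootstrap SE.

    Wald ratios are ordered; with inverse-variance weights w_j the
    standardized cumulative weight of the j-th ratio is
    p_j = (S_j - w_j/2)/S_L, and the estimate interpolates linearly to
    p = 0.5. The SE resamples bx, by from their standard errors (seeded).
    """
    if len(hs) < 3:
        raise ValueError("weighted median needs at least 3 variants")

    def point(bx, by):
        return _weighted_median_point(by / bx, bx**2 / hs.se_y**2)

    beta = point(hs.bx, hs.by)
    se = _parametric_bootstrap_se(hs, point, n_boot, seed)
    z = beta / se
    return MRResult("weighted_median", beta, se, float(2 * norm.sf(abs(z))), len(hs))


def _kde_mode(ratios: np.ndarray, weights: np.ndarray, phi: float) -> float:
    mad = np.median(np.abs(ratios - np.median(ratios))) * 1.4826
    sd = ratios.std(ddof=1)
    scale = min(sd, mad) if mad > 0 else sd
    if scale == 0:
        return float(ratios[0])
    h = phi * 0.9 * scale / len(ratios) ** 0.2
    lo, hi = ratios.min() - 3 * h, ratios.max() + 3 * h
    grid = np.linspace(lo, hi, 2048)
    dens = (weights[:, None] * np.exp(-0.5 * ((grid - ratios[:, None]) / h) ** 2)).sum(0)
    return float(grid[np.argmax(dens)])


def mode_estimator(
    hs: HarmonizedSet,
    variant: str = "weighted",
    phi: float = 1.0,
    n_boot: int = 5000,
    seed: int = 0,
) -> MRResult:
    """Simple or weighted mode-based estimate.

    The mode of the Gaussian-kernel density of the Wald ratios, with
    bandwidth phi * 0.9 * min(sd, 1.4826*MAD) * L^(-1/5) (modified
    Silverman). ``simple`` uses equal weights, ``weighted`` uses
    inverse-variance ratio weights. SE by seeded parametric bootstrap.
    """
    if len(hs) < 3:
        raise ValueError("mode estimator needs at least 3 variants")
    if phi <= 0:
        raise ValueError("phi must be positive")
    if variant not in ("simple", "weighted"):
        raise ValueError("variant must be 'simple' or 'weighted'")

    def point(bx, by):
        r = by / bx
        w = bx**2 / hs.se_y**2 if variant == "weighted" else np.ones(len(r))
        return _kde_mode(r, w, phi)

    beta = point(hs.bx, hs.by)
    se = _parametric_bootstrap_se(hs, point, n_boot, seed)
    z = beta / se
    return MRResult(f"{variant}_mode", beta, se, float(2 * norm.sf(abs(z))), len(hs))


def cochrans_q(estimates, ses) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity test across per-variant (or other) estimates."""
    b = np.asarray(estimates, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size < 2:
        raise ValueError("need at least 2 estimates")
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / s**2
    bbar = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - bbar) ** 2))
    df = b.size - 1
    return q, df, float(chi2.sf(q, df))


def two_estimate_heterogeneity(b1: float, se1: float, b2: float, se2: float
                               ) -> tuple[float, float]:
    """df = 1 Cochran's Q comparing two estimates (e.g. GxE strata)."""
    q, _, p = cochrans_q([b1, b2], [se1, se2])
    return q, p


def mvmr_ivw(exposure_betas: np.ndarray, by, se_y,
             exposure_names: list[str] | None = None) -> list[MRResult]:
    """Multivariable IVW: by regressed on K columns of exposure betas.

    Weighted least squares without intercept, weights 1/se_y^2; each
    coefficient is that exposure's causal effect conditional on the others.
    Requires more instruments than exposures and a full-rank beta matrix.
    Overdispersion is handled multiplicatively (floored at 1) as in IVW.
    """
    BX = np.asarray(exposure_betas, dtype=float)
    if BX.ndim == 1:
        BX = BX[:, None]
    by = np.asarray(by, dtype=float)
    se_y = np.asarray(se_y, dtype=float)
    L, K = BX.shape
    if L <= K:
        raise ValueError(f"need more instruments ({L}) than exposures ({K})")
    if np.linalg.matrix_rank(BX) < K:
        raise ValueError("exposure beta matrix is rank deficient")
    if np.any(se_y <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / se_y**2
    XtWX = BX.T @ (BX * w[:, None])
    coef = np.linalg.solve(XtWX, BX.T @ (w * by))
    resid = by - BX @ coef
    rss = float(np.sum(w * resid**2))
    phi = max(1.0, rss / (L - K))
    cov = phi * np.linalg.inv(XtWX)
    names = exposure_names or [f"x{k}" for k in range(K)]
    out = []
    for k in range(K):
        se = float(np.sqrt(cov[k, k]))
        z = coef[k] / se
        out.append(
            MRResult(f"mvmr_ivw[{names[k]}]", float(coef[k]), se,
                     float(2 * norm.sf(abs(z))), L, Q=rss,
                     Q_p=float(chi2.sf(rss, L - K)))
        )
    return out
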