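"""Individual-level conditional Mendelian randomization in duos and trios.

The association of a maternal polygenic score with an offspring outcome is
confounded by transmission: children inherit half their alleles from each
parent, so a maternal PGS proxies the offspring's own genotype. Conditioning
on the offspring genotype (or unweighted PGS) blocks that path, isolating
the prenatal (intrauterine) route; adding the paternal genotype in trios
closes the collider opened by conditioning on the child, and the paternal
coefficient doubles as a negative control for postnatal confounding.

An optional one-variance-component mixed model (offspring GRM as the random
effect, fitted by REML through an eigendecomposition of the GRM) absorbs
cryptic relatedness; with unrelated families it reduces to OLS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2, norm

from .instruments import PGSWeights, build_pgs

__all__ = [
    "ConditionalEstimate",
    "GRM",
    "build_grm",
    "conditional_mr",
    "wald_scale",
    "gxe_stratified",
    "reml_mixed_model",
]

#: largest cohort for which the dense GRM eigendecomposition is supported
MAX_GRM_N = 20_000


@dataclass(frozen=True)
class ConditionalEstimate:
    """Coefficient on the maternal PGS conditional on the offspring block."""

    beta_maternal: float
    se: float
    p: float
    n: int
    beta_paternal: float | None = None
    se_paternal: float | None = None
    p_paternal: float | None = None
    conditioning: str = "offspring_pgs"
    stratum: str = "all"


@dataclass
class GRM:
    """Genomic relationship matrix from standardized dosages."""

    matrix: np.ndarray
    m_variants: int
    excluded_regions: list[tuple[int, int, int]]


def build_grm(
    dosages: np.ndarray,
    variants,
    exclusions: list[tuple[int, int, int]] | None = None,
) -> GRM:
    """GRM = Z Z' / m* over variants outside the excluded regions.

    ``exclusions`` is a list of (chrom, start, end) windows — typically the
    instrument loci plus 1 Mb either side, so the instrument signal is not
    modelled in both the fixed and the random part of the mixed model.
    Dosage columns are standardized to mean 0, variance 1 before the cross
    product; monomorphic variants are skipped.
    """
    d = np.asarray(dosages, dtype=float)
    exclusions = exclusions or []

    def excluded(v) -> bool:
        return any(c == v.chrom and s <= v.pos <= e for c, s, e in exclusions)

    keep = [j for j, v in enumerate(variants) if not excluded(v)]
    if not keep:
        raise ValueError("all variants fall inside excluded regions")
    z_cols = []
    for j in keep:
        col = d[:, j]
        sd = col.std()
        if sd == 0:
            continue
        z_cols.append((col - col.mean()) / sd)
    if not z_cols:
        raise ValueError("no polymorphic variants outside excluded regions")
    z = np.column_stack(z_cols)
    return GRM(z @ z.T / z.shape[1], z.shape[1], list(exclusions))


def instrument_exclusion_windows(
    weights: PGSWeights, variants, flank: int = 1_000_000
) -> list[tuple[int, int, int]]:
    """(chrom, start, end) windows of ``flank`` bp either side of each instrument."""
    by_id = {v.id: v for v in variants}
    out = []
    for vid in weights.variant_ids:
        v = by_id[vid]
        out.append((v.chrom, max(1, v.pos - flank), v.pos + flank))
    return out


def reml_mixed_model(
    y: np.ndarray, X: np.ndarray, grm: np.ndarray, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """GLS fit of y = Xb + g + e with g ~ N(0, sg^2 K) by REML.

    Eigendecomposes K once and profiles the restricted likelihood over the
    variance ratio lam = sg^2/se^2 (bounded search on log(lam)); returns
    (beta_hat, se_hat). Dense; intended for cohorts up to ~20k families.
    """
    n = len(y)
    if n > MAX_GRM_N:
        raise ValueError(f"dense REML supported up to n={MAX_GRM_N}")
    vals, vecs = np.linalg.eigh(grm)
    vals = np.clip(vals, 0.0, None)
    yt = vecs.T @ y
    Xt = vecs.T @ X
    p = X.shape[1]

    def neg_restricted_ll(log_lam: float) -> float:
        lam = np.exp(log_lam)
        v = lam * vals + 1.0
        w = 1.0 / v
        XtWX = Xt.T @ (Xt * w[:, None])
        XtWy = Xt.T @ (w * yt)
        beta = np.linalg.solve(XtWX, XtWy)
        r = yt - Xt @ beta
        rss = float(np.sum(w * r**2))
        sig2 = rss / (n - p)
        ll = -0.5 * (
            (n - p) * np.log(sig2)
            + np.sum(np.log(v))
            + np.linalg.slogdet(XtWX)[1]
            + (n - p)
        )
        return -ll

    res = minimize_scalar(
        neg_restricted_ll, bounds=(-12.0, 12.0), method="bounded",
        options={"xatol": tol},
    )
    lam = np.exp(res.x)
    # no-relatedness edge: if the boundary fit is flat, fall back to lam -> 0
    if neg_restricted_ll(-30.0) <= res.fun + tol:
        lam = 0.0
    v = lam * vals + 1.0
    w = 1.0 / v
    XtWX = Xt.T @ (Xt * w[:, None])
    beta = np.linalg.solve(XtWX, Xt.T @ (w * yt))
    r = yt - Xt @ beta
    sig2 = float(np.sum(w * r**2)) / (n - p)
    cov = sig2 * np.linalg.inv(XtWX)
    return beta, np.sqrt(np.diag(cov))


def _design(
    pheno: pd.DataFrame,
    pgs_m: np.ndarray,
    offspring_block: np.ndarray,
    pgs_f: np.ndarray | None,
    covariates: list[str] | None,
) -> tuple[np.ndarray, list[str]]:
    off = np.asarray(offspring_block, dtype=float)
    if off.size == 0:
        off = np.empty((len(pgs_m), 0))  # unconditional fit
    else:
        off = off.reshape(len(pgs_m), -1)
    cols = [np.ones(len(pgs_m)), np.asarray(pgs_m, dtype=float)]
    names = ["const", "pgs_m"]
    if pgs_f is not None:
        cols.append(np.asarray(pgs_f, dtype=float))
        names.append("pgs_f")
    for k in range(off.shape[1]):
        cols.append(off[:, k])
        names.append(f"off{k}")
    for c in covariates or []:
        cols.append(np.asarray(pheno[c], dtype=float))
        names.append(c)
    X = np.column_stack(cols)
    # collinearity of the offspring block with the maternal PGS would make
    # the conditional estimand unidentified
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design rank deficient: offspring block collinear with PGS")
    return X, names


def conditional_mr(
    pheno: pd.DataFrame,
    outcome: str,
    pgs_m: np.ndarray,
    offspring_block: np.ndarray,
    pgs_f: np.ndarray | None = None,
    covariates: list[str] | None = None,
    grm: GRM | None = None,
    conditioning: str = "offspring_pgs",
    stratum: str = "all",
) -> ConditionalEstimate:
    """Maternal-PGS coefficient conditional on the offspring (and paternal) block.

    ``offspring_block`` is either the offspring unweighted PGS (one column)
    or the offspring dosages at the instrument loci (m columns). With a
    ``grm`` the model is the REML mixed model; otherwise OLS. In trio mode
    (``pgs_f`` given) the paternal coefficient is reported as the negative
    control.
    """
    y = np.asarray(pheno[outcome], dtype=float)
    X, names = _design(pheno, pgs_m, offspring_block, pgs_f, covariates)
    if grm is not None:
        beta, se = reml_mixed_model(y, X, grm.matrix)
    else:
        XtX = X.T @ X
        bhat = np.linalg.solve(XtX, X.T @ y)
        resid = y - X @ bhat
        sig2 = float(resid @ resid) / (len(y) - X.shape[1])
        cov = sig2 * np.linalg.inv(XtX)
        beta, se = bhat, np.sqrt(np.diag(cov))
    i_m = names.index("pgs_m")
    z = beta[i_m] / se[i_m]
    est = dict(
        beta_maternal=float(beta[i_m]),
        se=float(se[i_m]),
        p=float(2 * norm.sf(abs(z))),
        n=len(y),
        conditioning=conditioning,
        stratum=stratum,
    )
    if pgs_f is not None:
        i_f = names.index("pgs_f")
        zf = beta[i_f] / se[i_f]
        est.update(
            beta_paternal=float(beta[i_f]),
            se_paternal=float(se[i_f]),
            p_paternal=float(2 * norm.sf(abs(zf))),
        )
    return ConditionalEstimate(**est)


def wald_scale(
    beta_pgs_outcome: float,
    se_out: float,
    beta_pgs_exposure: float,
    se_exp: float = 0.0,
) -> tuple[float, float]:
    """Rescale a PGS-scale coefficient to exposure units (per cup/day).

    First-order delta method: beta = b_out/b_exp, se = se_out/|b_exp|.
    """
    if beta_pgs_exposure == 0:
        raise ZeroDivisionError("PGS-exposure coefficient is zero")
    return (
        beta_pgs_outcome / beta_pgs_exposure,
        se_out / abs(beta_pgs_exposure),
    )


def gxe_stratified(
    pheno: pd.DataFrame,
    outcome: str,
    pgs_m: np.ndarray,
    offspring_block: np.ndarray,
    strata_flag: np.ndarray,
    covariates: list[str] | None = None,
) -> tuple[ConditionalEstimate, ConditionalEstimate, tuple[float, float]]:
    """Conditional MR within consumer / non-consumer strata + heterogeneity.

    A genuine intrauterine effect can only show among consumers, so similar
    estimates in both strata point to pleiotropy. Returns (consumer
    estimate, non-consumer estimate, (Q, p)) with a df=1 Cochran's Q
    comparing the two stratum estimates. The PGS should be built from
    collider-screened weights.
    """
    flag = np.asarray(strata_flag, dtype=bool)
    off = np.asarray(offspring_block, dtype=float)
    off = off.reshape(len(flag), -1) if off.size else np.empty((len(flag), 0))
    ests = []
    for name, mask in (("consumers", flag), ("non_consumers", ~flag)):
        if mask.sum() < off.shape[1] + 3 + len(covariates or []):
            raise ValueError(f"stratum {name!r} too small to fit the model")
        ests.append(
            conditional_mr(
                pheno.loc[mask].reset_index(drop=True),
                outcome,
                np.asarray(pgs_m)[mask],
                off[mask],
                covariates=covariates,
                stratum=name,
            )
        )
    b = np.array([e.beta_maternal for e in ests])
    s = np.array([e.se for e in ests])
    w = 1.0 / s**2
    bbar = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - bbar) ** 2))
    return ests[0], ests[1], (q, float(chi2.sf(q, 1)))
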