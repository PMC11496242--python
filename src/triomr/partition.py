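"""Maternal/fetal partitioning of per-variant genetic effects.

A maternal GWAS of an offspring outcome mixes the direct maternal effect
with half the direct offspring effect (children carry, on average, half of
each maternal allele), and vice versa for the offspring GWAS. With
transmission coefficient 0.5 the marginal betas satisfy

    b_m = d_m + 0.5 * d_o
    b_o = d_o + 0.5 * d_m

which this module inverts per variant — d_m = (4 b_m - 2 b_o)/3,
d_o = (4 b_o - 2 b_m)/3 — propagating the sampling covariance, including a
supplied overlap correlation between the two GWAS (in practice estimated by
bivariate LD-score regression; here a closed form on known overlap).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "PartitionedEffect",
    "per_snp_gwas",
    "overlap_correlation",
    "partition_maternal_fetal",
    "partition_table",
]

# fixed autosomal transmission coefficient under random mating
_B = np.array([[1.0, 0.5], [0.5, 1.0]])
_BINV = np.linalg.inv(_B)  # = (4/3, -2/3; -2/3, 4/3)


@dataclass(frozen=True)
class PartitionedEffect:
    """Direct maternal and direct offspring per-variant effects."""

    d_m: float
    se_dm: float
    d_o: float
    se_do: float
    cov_dm_do: float


def per_snp_gwas(
    dosages: np.ndarray,
    outcome: np.ndarray,
    variant_ids: list[str],
    covariates: np.ndarray | None = None,
    eaf: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-variant OLS of an outcome on dosage (+ shared covariates).

    Vectorized across variants by Frisch-Waugh-Lovell: outcome and every
    dosage column are residualized on the covariates (plus intercept), then
    each marginal beta is cov(d~, y~)/var(d~) with the usual OLS standard
    error on the residual degrees of freedom. Monomorphic variants are
    flagged and reported with missing beta.
    """
    d = np.asarray(dosages, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n, m = d.shape
    if covariates is not None:
        C = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    else:
        C = np.ones((n, 1))
    p_cov = C.shape[1]
    # residualize on covariates
    Q, _ = np.linalg.qr(C)
    y_r = y - Q @ (Q.T @ y)
    d_r = d - Q @ (Q.T @ d)
    ss_d = np.sum(d_r**2, axis=0)
    mono = ss_d <= 1e-12
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    ok = ~mono
    beta[ok] = (d_r[:, ok].T @ y_r) / ss_d[ok]
    resid_ss = np.sum(y_r**2) - beta[ok] ** 2 * ss_d[ok]
    dof = n - p_cov - 1
    sigma2 = resid_ss / dof
    se[ok] = np.sqrt(sigma2 / ss_d[ok])
    p = np.full(m, np.nan)
    p[ok] = 2 * norm.sf(np.abs(beta[ok] / se[ok]))
    out = pd.DataFrame(
        dict(
            SNP=variant_ids,
            BETA=beta,
            SE=se,
            P=p,
            N=n,
            EAF=(np.asarray(eaf, dtype=float) if eaf is not None else d.mean(0) / 2.0),
            monomorphic=mono,
        )
    )
    return out


def overlap_correlation(
    n_m: int, n_o: int, n_shared: int, pheno_corr: float
) -> float:
    """Sampling correlation between two GWAS with overlapping samples.

    r = n_shared * pheno_corr / sqrt(n_m * n_o); with the same families in
    both GWAS and the same outcome this reaches pheno_corr itself.
    """
    if n_m < 1 or n_o < 1 or not 0 <= n_shared <= min(n_m, n_o):
        raise ValueError("require 0 <= n_shared <= min(n_m, n_o), n_m, n_o >= 1")
    if not -1.0 <= pheno_corr <= 1.0:
        raise ValueError("pheno_corr must lie in [-1, 1]")
    return n_shared * pheno_corr / np.sqrt(n_m * n_o)


def partition_maternal_fetal(
    b_m: float, se_m: float, b_o: float, se_o: float, r_overlap: float = 0.0
) -> PartitionedEffect:
    """Un-mix marginal maternal/offspring betas into direct effects.

    Solves [b_m; b_o] = B [d_m; d_o] with B = [[1, .5], [.5, 1]];
    Var(d) = B^-1 Sigma B^-T where Sigma carries the two GWAS variances and
    their overlap covariance r * se_m * se_o. The reconstruction identity
    d_m + 0.5 d_o = b_m (and symmetrically) holds exactly.
    """
    if se_m <= 0 or se_o <= 0:
        raise ValueError("standard errors must be positive")
    if not -1.0 <= r_overlap <= 1.0:
        raise ValueError("r_overlap must lie in [-1, 1]")
    d = _BINV @ np.array([b_m, b_o])
    sigma = np.array(
        [
            [se_m**2, r_overlap * se_m * se_o],
            [r_overlap * se_m * se_o, se_o**2],
        ]
    )
    v = _BINV @ sigma @ _BINV.T
    return PartitionedEffect(
        float(d[0]), float(np.sqrt(v[0, 0])),
        float(d[1]), float(np.sqrt(v[1, 1])),
        float(v[0, 1]),
    )


def partition_table(
    maternal_gwas: pd.DataFrame, offspring_gwas: pd.DataFrame, r_overlap: float
) -> pd.DataFrame:
    """Per-variant partitioning of two aligned GWAS tables (joined on SNP)."""
    merged = maternal_gwas.merge(
        offspring_gwas, on="SNP", suffixes=("_m", "_o"), validate="one_to_one"
    )
    rows = []
    for _, row in merged.iterrows():
        pe = partition_maternal_fetal(
            row["BETA_m"], row["SE_m"], row["BETA_o"], row["SE_o"], r_overlap
        )
        rows.append(
            dict(
                SNP=row["SNP"],
                b_m=row["BETA_m"], se_m=row["SE_m"],
                b_o=row["BETA_o"], se_o=row["SE_o"],
                d_m=pe.d_m, se_dm=pe.se_dm,
                d_o=pe.d_o, se_do=pe.se_do,
                cov_dm_do=pe.cov_dm_do, r_overlap=r_overlap,
            )
        )
    return pd.DataFrame(rows)
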