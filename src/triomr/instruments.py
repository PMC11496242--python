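"""Genetic instruments: PGS construction, strength diagnostics, harmonization,
clumping and the gene-by-environment collider screen.

The polygenic score (PGS) is the single instrument used by the
individual-level analyses: a weighted PGS sums effect-allele dosages times
per-allele exposure effects (cups/day), while the unweighted PGS counts
consumption-increasing alleles (dosage is reflected, 2 - d, at variants with
a negative weight).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PGSWeights",
    "InstrumentDiagnostics",
    "build_pgs",
    "benchmark_instrument",
    "i2_gx",
    "harmonize",
    "greedy_clump",
    "collider_screen",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class PGSWeights:
    """Instrument variant list with effect alleles and per-allele weights."""

    variant_ids: tuple[str, ...]
    effect_alleles: tuple[str, ...]
    weights: tuple[float, ...]
    mode: str = "weighted"  # or "unweighted"

    def __post_init__(self) -> None:
        if not len(self.variant_ids) == len(self.effect_alleles) == len(self.weights):
            raise ValueError("variant_ids, effect_alleles and weights must align")
        if self.mode not in ("weighted", "unweighted"):
            raise ValueError("mode must be 'weighted' or 'unweighted'")

    def drop(self, exclude: set[str]) -> "PGSWeights":
        """Copy without the listed variants (e.g. after a collider screen)."""
        keep = [i for i, v in enumerate(self.variant_ids) if v not in exclude]
        if not keep:
            raise ValueError("all instrument variants excluded")
        return PGSWeights(
            tuple(self.variant_ids[i] for i in keep),
            tuple(self.effect_alleles[i] for i in keep),
            tuple(self.weights[i] for i in keep),
            self.mode,
        )


@dataclass(frozen=True)
class InstrumentDiagnostics:
    beta_gx: float
    se: float
    F: float
    n: int


def build_pgs(
    dosages: np.ndarray, weights: PGSWeights, variant_ids: list[str] | None = None
) -> np.ndarray:
    """Polygenic score from an n x m effect-allele dosage matrix.

    With ``variant_ids`` given, dosage columns are matched to the weight list
    by id; otherwise column order is assumed aligned. Weighted mode returns
    sum_j w_j d_j; unweighted mode counts consumption-increasing alleles:
    d_j when w_j > 0, else 2 - d_j.
    """
    d = np.asarray(dosages, dtype=float)
    if variant_ids is not None:
        idx = {v: i for i, v in enumerate(variant_ids)}
        missing = [v for v in weights.variant_ids if v not in idx]
        if missing:
            raise KeyError(f"instrument variants absent from dosages: {missing}")
        d = d[:, [idx[v] for v in weights.variant_ids]]
    elif d.shape[1] != len(weights.variant_ids):
        raise ValueError("dosage columns do not match the weight list")
    w = np.asarray(weights.weights, dtype=float)
    if weights.mode == "weighted":
        return d @ w
    oriented = np.where(w > 0, d, 2.0 - d)
    return oriented.sum(axis=1)


def benchmark_instrument(
    score: np.ndarray,
    exposure: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> InstrumentDiagnostics:
    """Instrument-strength check: regress exposure on PGS (+ covariates).

    The F statistic is the squared t statistic of the score coefficient;
    F > 10 is the conventional bar against weak-instrument bias.
    """
    score = np.asarray(score, dtype=float)
    if np.ptp(score) == 0:
        raise ValueError("degenerate instrument: score is constant")
    cols = [score]
    if covariates is not None:
        c = np.asarray(covariates, dtype=float)
        cols.append(c.reshape(len(score), -1))
    X = sm.add_constant(np.column_stack(cols))
    fit = sm.OLS(np.asarray(exposure, dtype=float), X).fit()
    beta, se = float(fit.params[1]), float(fit.bse[1])
    return InstrumentDiagnostics(beta, se, (beta / se) ** 2, int(fit.nobs))


def i2_gx(bx, se_x) -> float:
    """I2_GX: dilution of MR-Egger from noise in the SNP-exposure betas.

    Computed from the heterogeneity of the bx around their precision-weighted
    mean: I2 = max(0, (Q - (L-1)) / Q). Values above ~0.9 indicate MR-Egger
    is at low risk of weak-instrument (regression-dilution) bias.
    """
    bx = np.asarray(bx, dtype=float)
    se_x = np.asarray(se_x, dtype=float)
    if bx.size < 2:
        raise ValueError("need at least 2 instruments")
    if np.any(se_x <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / se_x**2
    bbar = np.sum(w * bx) / np.sum(w)
    q = float(np.sum(w * (bx - bbar) ** 2))
    if q == 0.0:
        return 0.0
    return max(0.0, (q - (bx.size - 1)) / q)


def _is_palindromic(ea: str, nea: str) -> bool:
    return _COMPLEMENT.get(ea) == nea


def harmonize(
    exposure: pd.DataFrame, outcome: pd.DataFrame
) -> tuple[pd.DataFrame, list[tuple[str, str, str]]]:
    """Align outcome rows to the exposure's effect alleles.

    Both frames need columns ``SNP, EA, NEA, BETA, SE``. Variants present in
    only one set are dropped; the outcome beta is sign-flipped when its
    effect allele is the exposure's other allele (directly or on the
    opposite strand); palindromic variants (A/T, C/G) are removed outright;
    irreconcilable allele pairs are removed. Returns the harmonized frame
    (columns ``SNP, EA, NEA, bx, se_x, by, se_y``) and an audit log of
    ``(variant, action, reason)`` tuples. Idempotent: harmonizing the result
    against itself changes nothing.
    """
    for name, df in (("exposure", exposure), ("outcome", outcome)):
        if df["SNP"].duplicated().any():
            dups = df.loc[df["SNP"].duplicated(), "SNP"].tolist()
            raise ValueError(f"duplicate variant ids in {name} set: {dups}")
    log: list[tuple[str, str, str]] = []
    out_idx = outcome.set_index("SNP")
    rows = []
    for _, ex in exposure.iterrows():
        snp = ex["SNP"]
        if snp not in out_idx.index:
            log.append((snp, "removed", "unmatched"))
            continue
        if _is_palindromic(ex["EA"], ex["NEA"]):
            log.append((snp, "removed", "palindromic"))
            continue
        oc = out_idx.loc[snp]
        ea, nea = ex["EA"], ex["NEA"]
        oea, onea = oc["EA"], oc["NEA"]
        flip: bool
        if (oea, onea) == (ea, nea):
            flip = False
        elif (oea, onea) == (nea, ea):
            flip = True
        elif (_COMPLEMENT[oea], _COMPLEMENT[onea]) == (ea, nea):
            flip = False
            log.append((snp, "kept", "strand-complement"))
        elif (_COMPLEMENT[oea], _COMPLEMENT[onea]) == (nea, ea):
            flip = True
            log.append((snp, "kept", "strand-complement"))
        else:
            log.append((snp, "removed", "allele-mismatch"))
            continue
        by = -float(oc["BETA"]) if flip else float(oc["BETA"])
        if flip:
            log.append((snp, "flipped", "effect-allele-swap"))
        rows.append(
            dict(SNP=snp, EA=ea, NEA=nea, bx=float(ex["BETA"]), se_x=float(ex["SE"]),
                 by=by, se_y=float(oc["SE"]))
        )
    for snp in out_idx.index:
        if snp not in set(exposure["SNP"]):
            log.append((snp, "removed", "unmatched"))
    return pd.DataFrame(rows, columns=["SNP", "EA", "NEA", "bx", "se_x", "by", "se_y"]), log


def greedy_clump(
    rows: pd.DataFrame,
    ld_matrix: np.ndarray,
    p_thresh: float = 5e-8,
    r2_thresh: float = 0.001,
) -> pd.DataFrame:
    """Greedy LD clumping of summary statistics.

    Rows with p >= ``p_thresh`` are discarded; the rest are visited in
    ascending p (ties broken by variant id), and a row is kept unless its r2
    with an already-kept row exceeds ``r2_thresh``. ``ld_matrix`` is indexed
    by the input row order.
    """
    ld = np.asarray(ld_matrix, dtype=float)
    if ld.shape != (len(rows), len(rows)):
        raise ValueError("ld_matrix shape does not match the number of rows")
    rows = rows.reset_index(drop=True)
    cand = rows.index[rows["P"] < p_thresh]
    order = sorted(cand, key=lambda i: (rows.loc[i, "P"], rows.loc[i, "SNP"]))
    kept: list[int] = []
    for i in order:
        if all(ld[i, j] <= r2_thresh for j in kept):
            kept.append(i)
    return rows.loc[sorted(kept)].reset_index(drop=True)


def collider_screen(
    dosage_m: np.ndarray,
    variant_ids: list[str],
    consumer_flag: np.ndarray,
    alpha: float = 0.05,
    covariates: np.ndarray | None = None,
    link: str = "linear",
) -> tuple[pd.DataFrame, list[str]]:
    """Per-variant screen for association with ever/never consumer status.

    Conditioning on consumer status in stratified MR opens a collider path
    for any variant that influences that status, so such variants are
    excluded from the stratified-analysis PGS. Default is a linear
    probability model per variant (``link='logistic'`` available); variants
    with p < ``alpha`` go on the exclusion list.
    """
    y = np.asarray(consumer_flag, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("consumer flag is constant; screen is degenerate")
    d = np.asarray(dosage_m, dtype=float)
    records = []
    for j, vid in enumerate(variant_ids):
        cols = [d[:, j]]
        if covariates is not None:
            cols.append(np.asarray(covariates, dtype=float).reshape(len(y), -1))
        X = sm.add_constant(np.column_stack(cols))
        if link == "logistic":
            fit = sm.Logit(y, X).fit(disp=0)
        else:
            fit = sm.OLS(y, X).fit()
        records.append(
            dict(SNP=vid, beta=float(fit.params[1]), se=float(fit.bse[1]),
                 p=float(fit.pvalues[1]))
        )
    table = pd.DataFrame(records)
    excluded = table.loc[table["p"] < alpha, "SNP"].tolist()
    return table, excluded
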