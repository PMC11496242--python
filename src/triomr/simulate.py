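"""Synthetic parent-offspring trio cohorts.

Generates mother/father/child genotype dosages under Hardy-Weinberg
equilibrium with Mendelian transmission, plus a family phenotype table with
the causal structure that family-based Mendelian randomization analyses
probe: a maternal exposure (coffee, cups/day) driven by a small set of
instrument variants and a latent confounder, and offspring outcomes
receiving a prenatal causal path, an offspring-genome-mediated path, a
paternal (postnatal) path and a confounder path.

All randomness flows through a single :class:`numpy.random.Generator`
seeded from ``SimConfig.seed``, so a given configuration reproduces the
same cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "VariantMeta",
    "HurdleConfig",
    "SimConfig",
    "TrioCohort",
    "default_variants",
    "default_weights",
    "simulate_trios",
    "simulate_phenotypes",
    "inject_item_missingness",
    "simulate_correlated_dosages",
]

_VALID_ALLELES = frozenset("ACGT")


@dataclass(frozen=True)
class VariantMeta:
    """A biallelic autosomal variant.

    ``maf`` is the frequency of the effect allele, restricted to (0, 0.5]
    so the effect allele is the minor (or co-equal) allele.
    """

    id: str
    chrom: int
    pos: int
    effect_allele: str
    other_allele: str
    maf: float

    def __post_init__(self) -> None:
        if self.effect_allele not in _VALID_ALLELES or self.other_allele not in _VALID_ALLELES:
            raise ValueError(f"{self.id}: alleles must be one of A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.id}: effect and other allele are identical")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"{self.id}: maf must lie in (0, 0.5], got {self.maf}")


@dataclass(frozen=True)
class HurdleConfig:
    """Consumer-status hurdle: P(consumer) = logistic(logit(base_rate) + G·loadings).

    ``snp_loadings`` are per-variant log-odds per (centred) effect-allele
    dosage; a nonzero loading makes that variant associate with ever/never
    consumer status, which is exactly what the collider screen must detect.
    """

    base_rate: float = 0.80
    snp_loadings: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_rate <= 1.0:
            raise ValueError("base_rate must be a probability")


# Default instrument panel: eight independent coffee-consumption loci.
# Positions, frequencies and weights are realistic synthetic stand-ins for
# the published instrument set, not the published values themselves.
_DEFAULT_VARIANTS = (
    VariantMeta("rs4410790", 7, 17284577, "C", "T", 0.36),
    VariantMeta("rs2472297", 15, 75027880, "T", "C", 0.26),
    VariantMeta("rs1481012", 4, 89039082, "A", "G", 0.11),
    VariantMeta("rs6265", 11, 27679916, "C", "T", 0.19),
    VariantMeta("rs1260326", 2, 27730940, "C", "T", 0.39),
    VariantMeta("rs9902453", 17, 28263980, "G", "A", 0.46),
    VariantMeta("rs78000944", 7, 73035857, "T", "C", 0.12),
    VariantMeta("rs17685", 7, 75615006, "A", "G", 0.28),
)
# cups/day per effect allele
_DEFAULT_EFFECTS = (0.10, 0.12, 0.04, 0.03, 0.04, 0.03, 0.03, 0.06)


def default_variants() -> list[VariantMeta]:
    """The default eight-variant instrument panel (synthetic stand-in)."""
    return list(_DEFAULT_VARIANTS)


def default_weights() -> np.ndarray:
    """Per-allele exposure effects (cups/day) matching :func:`default_variants`."""
    return np.array(_DEFAULT_EFFECTS)


@dataclass(frozen=True)
class SimConfig:
    """Full specification of a simulated trio cohort.

    Parameters
    ----------
    seed
        Master seed; identical configs produce identical cohorts.
    n
        Number of families.
    variants, instrument_effects
        Instrument panel and per-allele exposure effects (cups/day).
        Defaults emulate an eight-locus coffee instrument.
    beta_causal
        Prenatal causal effect: outcome units per maternal cup/day.
    delta_offspring, delta_paternal
        Outcome units per offspring- / paternal-PGS unit; nonzero values
        create the pleiotropic paths the conditional analyses must block.
    confounder_exposure, confounder_outcome
        Loadings of a latent standard-normal confounder on exposure
        (cups/day per SD) and outcome (outcome units per SD).
    hurdle
        Consumer yes/no hurdle; exposure is zero for non-consumers.
    exposure_intercept, exposure_noise_sd
        Mean and residual SD (cups/day) of the latent consumption level
        among consumers before truncation at zero.
    noise_sd
        Outcome residual SD.
    direct_maternal_snp, direct_offspring_snp
        Optional per-variant direct genetic effects on the outcome (outcome
        units per allele), used to exercise maternal/fetal partitioning.
    n_outcomes
        Number of outcome columns ``nd1..ndK``; only ``nd1`` carries the
        structural exposure model, the rest share the confounder and serve
        the multiple-testing machinery.
    """

    seed: int = 0
    n: int = 1000
    variants: tuple[VariantMeta, ...] = _DEFAULT_VARIANTS
    instrument_effects: tuple[float, ...] = _DEFAULT_EFFECTS
    beta_causal: float = 0.0
    delta_offspring: float = 0.0
    delta_paternal: float = 0.0
    confounder_exposure: float = 0.5
    confounder_outcome: float = 0.3
    hurdle: HurdleConfig = field(default_factory=HurdleConfig)
    exposure_intercept: float = 2.0
    exposure_noise_sd: float = 1.5
    noise_sd: float = 1.0
    direct_maternal_snp: tuple[float, ...] | None = None
    direct_offspring_snp: tuple[float, ...] | None = None
    n_outcomes: int = 5

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if len(self.variants) < 1:
            raise ValueError("at least one variant is required")
        if len(self.instrument_effects) != len(self.variants):
            raise ValueError(
                f"instrument_effects has {len(self.instrument_effects)} entries "
                f"for {len(self.variants)} variants"
            )
        for attr in ("direct_maternal_snp", "direct_offspring_snp"):
            v = getattr(self, attr)
            if v is not None and len(v) != len(self.variants):
                raise ValueError(f"{attr} length does not match variant count")
        if self.hurdle.snp_loadings is not None and len(self.hurdle.snp_loadings) != len(
            self.variants
        ):
            raise ValueError("hurdle.snp_loadings length does not match variant count")

    @property
    def m(self) -> int:
        return len(self.variants)

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class TrioCohort:
    """Mother/father/offspring dosage matrices plus phenotypes.

    Dosages count effect alleles, entries in {0, 1, 2}; rows are families in
    the same order across the three matrices and the phenotype table.
    """

    dosage_m: np.ndarray
    dosage_f: np.ndarray
    dosage_o: np.ndarray
    variants: list[VariantMeta]
    phenos: pd.DataFrame | None = None

    @property
    def n_families(self) -> int:
        return self.dosage_m.shape[0]

    def __post_init__(self) -> None:
        shapes = {self.dosage_m.shape, self.dosage_f.shape, self.dosage_o.shape}
        if len(shapes) != 1:
            raise ValueError(f"dosage matrices disagree in shape: {shapes}")
        if self.dosage_m.shape[1] != len(self.variants):
            raise ValueError("variant metadata does not match dosage columns")


def _draw_parent_alleles(rng: np.random.Generator, n: int, maf: float) -> np.ndarray:
    # two haplotypes per parent, Hardy-Weinberg
    return (rng.random((n, 2)) < maf).astype(np.int8)


def simulate_trios(config: SimConfig) -> TrioCohort:
    """Draw a trio cohort under Hardy-Weinberg equilibrium and random mating.

    Each parent carries two allele draws per variant; the child inherits one
    allele chosen uniformly from each parent, so every child genotype is
    Mendel-consistent with its parents by construction.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n, config.m
    dm = np.empty((n, m), dtype=np.int8)
    df = np.empty((n, m), dtype=np.int8)
    do = np.empty((n, m), dtype=np.int8)
    for j, v in enumerate(config.variants):
        am = _draw_parent_alleles(rng, n, v.maf)
        af = _draw_parent_alleles(rng, n, v.maf)
        pick_m = rng.integers(0, 2, size=n)
        pick_f = rng.integers(0, 2, size=n)
        dm[:, j] = am.sum(axis=1)
        df[:, j] = af.sum(axis=1)
        do[:, j] = am[np.arange(n), pick_m] + af[np.arange(n), pick_f]
    cohort = TrioCohort(dm, df, do, list(config.variants))
    cohort.phenos = simulate_phenotypes(cohort, config)
    return cohort


def _pgs(dosages: np.ndarray, weights: np.ndarray) -> np.ndarray:
    return dosages @ weights


def simulate_phenotypes(trios: TrioCohort, config: SimConfig) -> pd.DataFrame:
    """Generate the family phenotype table for an existing genotype draw.

    The maternal exposure is a hurdle model: consumer status is Bernoulli on
    a logistic scale (optionally loaded on the instrument variants), and the
    consumption level among consumers is a zero-truncated normal shifted by
    the weighted PGS and the latent confounder. The primary outcome ``nd1``
    is

        beta_causal * exposure_m + delta_offspring * PGS_o
        + delta_paternal * PGS_f + confounder_outcome * C + noise

    plus any per-variant direct maternal/offspring genetic effects.
    Phenotype randomness is seeded from ``config.seed`` (offset so it does
    not reuse the genotype stream).
    """
    if trios.dosage_m.shape[1] != len(config.instrument_effects):
        raise ValueError("instrument_effects do not match the cohort's variants")
    rng = np.random.default_rng((config.seed, 1))
    n = trios.n_families
    w = np.asarray(config.instrument_effects, dtype=float)
    mafs = np.array([v.maf for v in config.variants])

    pgs_m = _pgs(trios.dosage_m, w)
    pgs_f = _pgs(trios.dosage_f, w)
    pgs_o = _pgs(trios.dosage_o, w)

    conf = rng.standard_normal(n)

    # hurdle: ever/never consumer
    logit0 = np.inf if config.hurdle.base_rate == 1.0 else (
        -np.inf if config.hurdle.base_rate == 0.0
        else np.log(config.hurdle.base_rate / (1 - config.hurdle.base_rate))
    )
    eta = np.full(n, logit0)
    if config.hurdle.snp_loadings is not None and np.isfinite(logit0):
        load = np.asarray(config.hurdle.snp_loadings, dtype=float)
        eta = eta + (trios.dosage_m - 2 * mafs) @ load
    with np.errstate(over="ignore"):
        p_consume = 1.0 / (1.0 + np.exp(-eta))
    consumer = rng.random(n) < p_consume

    level = np.maximum(
        0.0,
        config.exposure_intercept
        + pgs_m
        + config.confounder_exposure * conf
        + rng.normal(0.0, config.exposure_noise_sd, n),
    )
    coffee_m = np.where(consumer, level, 0.0)
    # week-15 / week-22 reports: same latent consumption with report noise
    coffee_wk15 = np.where(consumer, np.maximum(0.0, level + rng.normal(0, 0.3, n)), 0.0)
    coffee_wk22 = np.where(consumer, np.maximum(0.0, level + rng.normal(0, 0.3, n)), 0.0)

    # paternal coffee: own PGS + shared household confounder, no hurdle
    coffee_f = np.maximum(
        0.0,
        config.exposure_intercept
        + pgs_f
        + config.confounder_exposure * conf
        + rng.normal(0.0, config.exposure_noise_sd, n),
    )

    out = {
        "family": np.arange(n),
        "consumer": consumer,
        "coffee_pre": coffee_m,
        "coffee_wk15": coffee_wk15,
        "coffee_wk22": coffee_wk22,
        "coffee_f": coffee_f,
        "caffeine_mg_day": 90.0 * coffee_m + rng.normal(0, 20, n).clip(-80, None),
        "confounder": conf,
        "smoking_cigs_week": np.maximum(0.0, 2.0 + 4.0 * conf + rng.normal(0, 3, n)),
        "alcohol_times_week": np.maximum(0.0, 0.5 + 0.5 * conf + rng.normal(0, 0.7, n)),
        "education_years": 14.0 - 1.0 * conf + rng.normal(0, 2, n),
        "income_nok": 450_000 - 40_000 * conf + rng.normal(0, 80_000, n),
        "birth_year": rng.integers(2000, 2009, n).astype(float),
        "mat_age": rng.normal(30, 4, n),
        "pat_age": rng.normal(33, 5, n),
        "pgs_m": pgs_m,
        "pgs_f": pgs_f,
        "pgs_o": pgs_o,
    }

    nd1 = (
        config.beta_causal * coffee_m
        + config.delta_offspring * pgs_o
        + config.delta_paternal * pgs_f
        + config.confounder_outcome * conf
        + rng.normal(0.0, config.noise_sd, n)
    )
    if config.direct_maternal_snp is not None:
        nd1 = nd1 + trios.dosage_m @ np.asarray(config.direct_maternal_snp, dtype=float)
    if config.direct_offspring_snp is not None:
        nd1 = nd1 + trios.dosage_o @ np.asarray(config.direct_offspring_snp, dtype=float)
    out["nd1"] = nd1
    for k in range(2, config.n_outcomes + 1):
        out[f"nd{k}"] = config.confounder_outcome * conf + rng.normal(
            0.0, config.noise_sd, n
        )
    return pd.DataFrame(out)


def inject_item_missingness(
    items: np.ndarray, rate: float, seed: int
) -> np.ndarray:
    """Set each cell of ``items`` to NaN independently with probability ``rate``.

    Deterministic under ``seed``; used to exercise the scale-score mean
    imputation rule.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"rate must lie in [0, 1), got {rate}")
    out = np.array(items, dtype=float, copy=True)
    if rate > 0.0:
        mask = np.random.default_rng(seed).random(out.shape) < rate
        out[mask] = np.nan
    return out


def simulate_correlated_dosages(
    n: int, mafs: np.ndarray, r: np.ndarray, seed: int = 0
) -> np.ndarray:
    """Dosages with pairwise LD via a Gaussian copula on latent allele draws.

    ``r`` is the target latent correlation matrix between variants. Each of
    the two haplotypes is a thresholded multivariate normal, so allele-level
    correlations approximate ``r``. Exists only to exercise clumping; the
    default instrument panel is LD-free.
    """
    mafs = np.asarray(mafs, dtype=float)
    r = np.asarray(r, dtype=float)
    if r.shape != (len(mafs), len(mafs)):
        raise ValueError("LD matrix shape does not match variant count")
    rng = np.random.default_rng(seed)
    from scipy.stats import norm

    chol = np.linalg.cholesky(r + 1e-10 * np.eye(len(mafs)))
    thresh = norm.ppf(mafs)
    d = np.zeros((n, len(mafs)), dtype=np.int8)
    for _ in range(2):
        z = rng.standard_normal((n, len(mafs))) @ chol.T
        d += (z < thresh).astype(np.int8)
    return d
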