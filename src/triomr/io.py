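"""File formats, configuration and the end-to-end pipeline runner.

Summary statistics travel as tab-separated text with columns
``SNP CHR BP EA NEA EAF BETA SE P N`` (1-based positions, uppercase
forward-strand alleles). Every result file starts with a comment header
recording the config hash and seed, so outputs are traceable to the run
that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import family_mr, instruments, observational, partition, phenotypes, summary_mr
from .simulate import HurdleConfig, SimConfig, simulate_trios

__all__ = [
    "SUMMARY_STAT_COLUMNS",
    "read_summary_stats",
    "write_summary_stats",
    "write_results",
    "read_results",
    "PipelineConfig",
    "run_pipeline",
]

SUMMARY_STAT_COLUMNS = ["SNP", "CHR", "BP", "EA", "NEA", "EAF", "BETA", "SE", "P", "N"]
_ALLELES = {"A", "C", "G", "T"}


def read_summary_stats(path) -> tuple[pd.DataFrame, list[str]]:
    """Read and validate a summary-statistic TSV.

    Returns the valid rows and a list of line-numbered rejection messages;
    a missing mandatory column raises immediately.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"SNP": str, "EA": str, "NEA": str})
    missing = [c for c in SUMMARY_STAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    messages: list[str] = []
    keep = np.ones(len(df), dtype=bool)
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        reasons = []
        if row["EA"] not in _ALLELES or row["NEA"] not in _ALLELES:
            reasons.append("non-ACGT allele")
        if not 0.0 <= row["EAF"] <= 1.0:
            reasons.append("EAF outside [0,1]")
        if not row["SE"] > 0:
            reasons.append("nonpositive SE")
        if not 0.0 < row["P"] <= 1.0:
            reasons.append("P outside (0,1]")
        if reasons:
            keep[i] = False
            messages.append(f"line {line} ({row['SNP']}): " + "; ".join(reasons))
    return df.loc[keep].reset_index(drop=True), messages


def write_summary_stats(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_results(
    df: pd.DataFrame, path, config_hash: str = "", seed: int | None = None,
    float_precision: int = 6,
) -> None:
    """Write a result table with a traceability comment header.

    Column order is preserved as given; floats are serialized at a fixed
    precision so repeated runs produce byte-identical files.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=f"%.{float_precision}g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


@dataclass
class PipelineConfig:
    """Configuration for the end-to-end simulated-cohort pipeline."""

    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    stages: dict = field(
        default_factory=lambda: dict(
            observational=True, duo=True, trio=True, gxe=True,
            two_sample=True, mvmr=True, partition=True,
        )
    )
    ivw_model: str = "multiplicative_random"
    phi: float = 1.0
    n_boot: int = 1000
    alpha_total: float = 0.05
    variance_target: float = 0.8
    p_thresh: float = 5e-8
    r2_thresh: float = 0.001
    collider_alpha: float = 0.05
    float_precision: int = 6

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["variants"] = [list(dataclasses.astuple(v)) for v in self.sim.variants]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        simd = dict(d.pop("sim", {}))
        if "variants" in simd:
            from .simulate import VariantMeta

            simd["variants"] = tuple(VariantMeta(*v) for v in simd["variants"])
        for key in ("instrument_effects", "direct_maternal_snp", "direct_offspring_snp"):
            if simd.get(key) is not None:
                simd[key] = tuple(simd[key])
        if "hurdle" in simd and isinstance(simd["hurdle"], dict):
            h = dict(simd["hurdle"])
            if h.get("snp_loadings") is not None:
                h["snp_loadings"] = tuple(h["snp_loadings"])
            simd["hurdle"] = HurdleConfig(**h)
        return cls(sim=SimConfig(**simd), **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _as_frame(results) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Run the full analysis sequence on a simulated trio cohort.

    simulate -> derive phenotypes -> instruments -> observational (+ paternal
    negative control) -> duo/trio conditional MR -> per-variant GWAS ->
    maternal/fetal partitioning -> two-sample MR (+ MVMR) -> GxE stratified
    MR. Returns a dict of result tables; with ``out_dir`` every table is
    also written as TSV with a config-hash/seed header, alongside a run log.
    Fully deterministic under ``config.seed``.
    """
    sim = config.sim.with_(seed=config.seed)
    bundle: dict = {}
    log: list[str] = [f"seed={config.seed} config_hash={config.config_hash()}"]

    def stage(name):
        on = config.stages.get(name, True)
        log.append(f"stage {name}: {'run' if on else 'skipped'}")
        return on

    trios = simulate_trios(sim)
    pheno = trios.phenos.copy()
    outcome_cols = [c for c in pheno.columns if c.startswith("nd")]
    for c in outcome_cols:
        pheno[c + "_int"] = phenotypes.rank_inverse_normal(pheno[c])
    eff = phenotypes.effective_tests_threshold(
        pheno[outcome_cols], config.variance_target, config.alpha_total
    )
    bundle["effective_tests"] = pd.DataFrame(
        [dict(n_components=eff.n_components, alpha=eff.alpha,
              n_outcomes=len(outcome_cols))]
    )
    outcome = outcome_cols[0] + "_int"

    weights = instruments.PGSWeights(
        tuple(v.id for v in sim.variants),
        tuple(v.effect_allele for v in sim.variants),
        tuple(sim.instrument_effects),
    )
    pgs_m = instruments.build_pgs(trios.dosage_m, weights)
    pgs_f = instruments.build_pgs(trios.dosage_f, weights)
    pgs_o = instruments.build_pgs(trios.dosage_o, weights)
    diag = instruments.benchmark_instrument(
        pgs_m, pheno["coffee_wk15"],
        pheno[["birth_year", "mat_age", "pat_age"]],
    )
    bundle["instrument_diagnostics"] = pd.DataFrame([dataclasses.asdict(diag)])

    if stage("observational"):
        rows = []
        for role in ("maternal", "paternal"):
            for preset in ("unadjusted", "adjusted", "intrauterine"):
                for oc in outcome_cols:
                    rows.append(
                        observational.fit_observational(pheno, role, oc + "_int", preset)
                    )
        bundle["observational"] = _as_frame(rows)

    covs = ["birth_year", "mat_age", "pat_age"]
    if stage("duo"):
        duo_pgs = family_mr.conditional_mr(
            pheno, outcome, pgs_m, pgs_o, covariates=covs,
            conditioning="offspring_pgs",
        )
        duo_geno = family_mr.conditional_mr(
            pheno, outcome, pgs_m, trios.dosage_o, covariates=covs,
            conditioning="offspring_genotypes",
        )
        bundle["duo_mr"] = _as_frame([duo_pgs, duo_geno])
    if stage("trio"):
        trio_est = family_mr.conditional_mr(
            pheno, outcome, pgs_m, trios.dosage_o, pgs_f=pgs_f,
            covariates=covs, conditioning="offspring_genotypes",
        )
        bundle["trio_mr"] = _as_frame([trio_est])

    # per-variant association of dosage with the maternal exposure: the
    # SNP-exposure side of the two-sample analyses
    exp_gwas = partition.per_snp_gwas(
        trios.dosage_m, pheno["coffee_wk15"].to_numpy(),
        [v.id for v in sim.variants],
    )
    if stage("partition") or stage("two_sample"):
        gwas_m = partition.per_snp_gwas(
            trios.dosage_m, pheno[outcome].to_numpy(), [v.id for v in sim.variants],
            covariates=pheno[covs].to_numpy(),
        )
        gwas_o = partition.per_snp_gwas(
            trios.dosage_o, pheno[outcome].to_numpy(), [v.id for v in sim.variants],
            covariates=pheno[covs].to_numpy(),
        )
        bundle["gwas_maternal"] = gwas_m
        bundle["gwas_offspring"] = gwas_o
        # both GWAS analyse the same outcome in the same families; the
        # effective correlation of their sampling errors carries the
        # parent-child genotype correlation (0.5 under random mating)
        r = partition.overlap_correlation(sim.n, sim.n, sim.n, 0.5)
        part = partition.partition_table(gwas_m, gwas_o, r)
        bundle["partitioned"] = part

    if stage("two_sample"):
        hs = summary_mr.HarmonizedSet(
            exp_gwas["BETA"], exp_gwas["SE"], part["d_m"], part["se_dm"],
            snp_ids=list(exp_gwas["SNP"]),
        )
        results = [
            summary_mr.ivw(hs, config.ivw_model),
            summary_mr.mr_egger(hs),
            summary_mr.weighted_median(hs, config.n_boot, config.seed),
            summary_mr.mode_estimator(hs, "simple", config.phi, config.n_boot, config.seed),
            summary_mr.mode_estimator(hs, "weighted", config.phi, config.n_boot, config.seed),
        ]
        ts = _as_frame(results)
        ts["i2_gx"] = instruments.i2_gx(hs.bx, hs.se_x)
        bundle["two_sample_mr"] = ts

    if stage("mvmr"):
        # condition the coffee effect on genetically proxied smoking and
        # alcohol (per-variant betas estimated in the same cohort)
        bx_smoke = partition.per_snp_gwas(
            trios.dosage_m, pheno["smoking_cigs_week"].to_numpy(),
            [v.id for v in sim.variants],
        )["BETA"]
        bx_alc = partition.per_snp_gwas(
            trios.dosage_m, pheno["alcohol_times_week"].to_numpy(),
            [v.id for v in sim.variants],
        )["BETA"]
        mv = summary_mr.mvmr_ivw(
            np.column_stack([exp_gwas["BETA"], bx_smoke, bx_alc]),
            part["d_m"], part["se_dm"],
            exposure_names=["coffee", "smoking", "alcohol"],
        )
        bundle["mvmr"] = _as_frame(mv)

    if stage("gxe"):
        screen, excluded = instruments.collider_screen(
            trios.dosage_m, [v.id for v in sim.variants],
            pheno["consumer"].to_numpy(), config.collider_alpha,
        )
        bundle["collider_screen"] = screen
        w_scr = weights.drop(set(excluded)) if excluded else weights
        ids = [v.id for v in sim.variants]
        pgs_m_scr = instruments.build_pgs(trios.dosage_m, w_scr, ids)
        keep_cols = [ids.index(v) for v in w_scr.variant_ids]
        cons, noncons, (q, p) = family_mr.gxe_stratified(
            pheno, outcome, pgs_m_scr, trios.dosage_o[:, keep_cols],
            pheno["consumer"].to_numpy(), covariates=covs,
        )
        gxe = _as_frame([cons, noncons])
        gxe["het_Q"] = q
        gxe["het_p"] = p
        gxe["n_excluded_variants"] = len(excluded)
        bundle["gxe"] = gxe

    # summary table: flag results passing the effective-tests threshold
    if "duo_mr" in bundle:
        summ = bundle["duo_mr"][["beta_maternal", "se", "p", "conditioning"]].copy()
        summ["significant"] = summ["p"] < eff.alpha
        bundle["summary"] = summ

    bundle["run_log"] = pd.DataFrame({"message": log})
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        h = config.config_hash()
        for name, df in bundle.items():
            write_results(df, out_dir / f"{name}.tsv", h, config.seed,
                          config.float_precision)
    return bundle
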