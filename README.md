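# triomr

Family-based Mendelian randomization for prenatal exposures, with a
mother–father–offspring trio simulator for end-to-end validation.

## The problem

Does a maternal exposure during pregnancy — the canonical example here is
coffee consumption — causally affect the child's neurodevelopment?
Observational associations are hopelessly confounded by shared familial
factors. Classical Mendelian randomization (instrumenting the exposure with
the mother's coffee-associated alleles) fixes that but breaks on a subtler
problem: the mother transmits half of those alleles to the child, so a
maternal polygenic score (PGS) also proxies the *child's* genotype, and any
direct effect of the child's own alleles looks like an intrauterine effect.

`triomr` implements the family-based designs that resolve this:

- **conditional MR** — the maternal-PGS effect conditional on the offspring
  genotype (and, in trios, the paternal PGS as a negative control), which
  blocks the transmission path;
- **maternal/fetal partitioning** — closed-form un-mixing of maternal and
  offspring marginal GWAS betas (`b_m = d_m + ½d_o`, `b_o = d_o + ½d_m`)
  into direct effects with correct sampling covariance;
- **two-sample summary MR** — harmonization, IVW, MR-Egger, weighted
  median, mode estimators, Cochran's Q, and multivariable IVW;
- **consumer-stratified (GxE) MR** — a genuine intake-mediated effect can
  only appear in families where the mother drinks coffee at all;
- a **trio simulator** (Hardy–Weinberg parents, Mendelian transmission,
  hurdle exposure model, structural outcome model) so every estimator can
  be pointed at a known truth.

See `docs/methods.md` for the model and estimator details.

## Worked example

A cohort of 20 000 trios with **no causal effect** and a shared familial
confounder (`examples/02_observational_bias.py`):

```
model                                  beta      se         p
maternal / unadjusted                0.2265  0.0055         0
maternal / adjusted                  0.0807  0.0049     5e-60
paternal / unadjusted                0.3298  0.0056         0
paternal / adjusted                  0.1324  0.0055  2.5e-126
maternal / + true confounder         0.0004  0.0044      0.92
```

The observational association is "significant" at any adjustment level, and
the paternal exposure — which has no intrauterine path — associates just as
strongly: the signature of confounding. The family-based MR design handles
both confounding and transmission (`examples/03_family_mr.py`):

```
true causal effect 0.2:
  maternal PGS | offspring PGS: 0.232 (se 0.084)
  paternal PGS (neg. control):  0.088 (se 0.083)

no causal effect, offspring-mediated path only:
  unconditional maternal beta:  0.233 (z 3.9) <- spurious
  conditional maternal beta:    0.021 (z 0.3) <- blocked
```

A true effect of 0.2 is recovered with a null paternal control, and a purely
transmission-mediated genetic path that fools the unconditional estimate
(z = 3.9) vanishes once the offspring genotype is conditioned on (z = 0.3).

In code:

```python
from triomr import SimConfig, simulate_trios
from triomr.family_mr import conditional_mr

t = simulate_trios(SimConfig(seed=17, n=20_000, beta_causal=0.2))
est = conditional_mr(
    t.phenos, "nd1",
    t.phenos["pgs_m"].to_numpy(),   # maternal polygenic score
    t.dosage_o,                     # offspring genotypes (the key block)
    pgs_f=t.phenos["pgs_f"].to_numpy(),
    conditioning="offspring_genotypes",
)
print(est.beta_maternal, est.se, est.beta_paternal)
```

The whole analysis sequence — simulation, phenotype derivation, instrument
QC, observational gradients, duo/trio MR, per-variant GWAS, partitioning,
two-sample MR, MVMR, collider screen, stratified MR — runs from one config:

```python
from triomr import PipelineConfig, SimConfig, run_pipeline
bundle = run_pipeline(PipelineConfig(seed=29, sim=SimConfig(n=8000)),
                      out_dir="results/demo")
```

or from the shell: `triomr pipeline --seed 29 --out-dir results/demo`
(see `triomr --help` for the per-step subcommands). Every output TSV carries
a config-hash and seed header; reruns are byte-identical.

The `examples/` scripts walk each capability with commentary:
`01_simulate_cohort.py`, `02_observational_bias.py`, `03_family_mr.py`,
`04_two_sample_mr.py`, `05_partition_and_pipeline.py`.

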