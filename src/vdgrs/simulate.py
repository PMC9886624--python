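"""Synthetic cohorts with gene–supplementation structure.

The real cohorts behind this analysis (a large population biobank and an
MS case/control study) are access-controlled, so the generator produces
cohorts with the same statistical skeleton:

* Hardy–Weinberg genotypes at the 6 panel loci, each variant independent
  (the real panel is genome-scattered), effect-allele dosages
  Binomial(2, p_j);
* a standardized serum vitamin D phenotype driven by a genetic component,
  supplementation behaviour, and BMI/age/sex covariates;
* supplementation prevalence and dose distributions that differ by MS
  status (prevalences 71.1% vs 26.7%; log-normal doses with medians 1200 vs
  571 IU/day in the study preset).

Two generative modes encode the competing explanations for why the score
stops predicting vitamin D in supplementers:

``additive``
    vd = grs_effect·g_std + supp_shift·S + dose_effect·log(1+dose)·S
         + covariates + noise.  Genetics acts equally in both strata.
``titration``
    non-supplementers as above (without the dose term); supplementers dose
    toward a target level:  vd = titration_target +
    attenuation·grs_effect·g_std + covariates + noise.  With attenuation 0
    the genetic signal vanishes in supplementers by construction.

``g_std`` is the weighted allele count standardized by its analytic HWE
moments (mean Σ2pβ, variance Σ2p(1−p)β²), so ``grs_effect`` *is* the
standardized per-SD genetic effect — the quantity the association stage
estimates.  The phenotype is finally Z-scored cohort-wide and mapped to
nmol/L as 50 + 20·Z for file output.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .association import CohortTable
from .qc import DosageMatrix
from .weights import WeightTable, packaged_weight_table

#: Default effect-allele frequencies for the packaged panel.  The source
#: paper prints no frequencies; these are plausible European-ancestry values
#: (documented in docs/methods.md), fixed once for all presets.
DEFAULT_EFFECT_ALLELE_FREQS = {
    "rs10745742": 0.40,
    "rs12785878": 0.75,
    "rs10741657": 0.40,
    "rs17216707": 0.79,
    "rs8018720": 0.82,
    "rs2282679": 0.72,
}

#: nmol/L back-transform for file output (arbitrary but documented).
VD_MEAN_NMOL = 50.0
VD_SD_NMOL = 20.0

MODES = ("additive", "titration")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Generator configuration; defaults are the study-cohort conditions.

    ``grs_effect`` is the standardized per-SD genetic effect on the vitamin D
    Z-score among non-supplementers; ``grs_effect_supp`` the supplementer
    value in additive mode (defaults to the same).  ``noise_sd`` /
    ``noise_sd_supp`` are per-stratum residual SDs.  Covariate effects are on
    the vd Z-score scale per unit of the covariate (BMI kg/m², age years,
    female indicator, MS indicator).
    """

    seed: int = 0
    n_ms: int = 315
    n_control: int = 232
    allele_freqs: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_ALLELE_FREQS))
    betas: dict | None = None  # None -> packaged panel betas
    supp_prob_ms: float = 0.711
    supp_prob_control: float = 0.267
    dose_median_ms: float = 1200.0
    dose_median_control: float = 571.0
    dose_log_sd: float = 0.5
    mode: str = "titration"
    grs_effect: float = 0.205
    grs_effect_supp: float | None = None
    covariate_effects: dict = field(
        default_factory=lambda: {"bmi": -0.035, "age": 0.010, "sex": 0.05, "ms_status": 0.0}
    )
    dose_effect: float = 0.0
    supp_shift: float = 0.0
    noise_sd: float = 0.78
    noise_sd_supp: float | None = None
    titration_target: float = 1.16
    titration_genetic_attenuation: float = 0.0
    # covariate distributions
    bmi_mean: float = 27.0
    bmi_sd: float = 4.5
    age_mean: float = 55.0
    age_sd: float = 8.0
    female_prob: float = 0.745

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"unknown mode {self.mode!r}; choose from {MODES}")
        if self.n_ms + self.n_control < 1:
            raise ConfigError("cohort size must be at least 1")
        for name, p in (("supp_prob_ms", self.supp_prob_ms), ("supp_prob_control", self.supp_prob_control),
                        ("female_prob", self.female_prob)):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        for rsid, f in self.allele_freqs.items():
            if not 0.0 < f < 1.0:
                raise ConfigError(f"allele frequency for {rsid} must be in (0, 1), got {f}")
        if self.noise_sd <= 0 or (self.noise_sd_supp is not None and self.noise_sd_supp <= 0):
            raise ConfigError("noise_sd must be positive")
        if not 0.0 <= self.titration_genetic_attenuation <= 1.0:
            raise ConfigError("titration_genetic_attenuation must be in [0, 1]")
        if self.dose_log_sd <= 0:
            raise ConfigError("dose_log_sd must be positive")

    def resolved_betas(self) -> dict:
        if self.betas is not None:
            return dict(self.betas)
        return {w.rsid: w.beta for w in packaged_weight_table()}


def expected_variance_explained(freqs: dict, betas: dict) -> float:
    """Additive genetic variance of the score on the unit-variance phenotype.

    Under HWE and linkage equilibrium the weighted allele count has variance
    Σ_j 2 p_j (1 − p_j) β_j²; with the phenotype standardized to variance 1
    this is directly the fraction of variance the score can explain.
    """
    return float(sum(2.0 * freqs[r] * (1.0 - freqs[r]) * betas[r] ** 2 for r in betas))


def simulate_genotypes(n: int, freqs: dict, rng, weights: WeightTable | None = None) -> DosageMatrix:
    """Hard-call HWE genotypes: dosage ~ Binomial(2, p_j) per variant.

    ``rng`` is a seed or a numpy Generator.  Variant metadata orients ALT as
    the effect allele of the (packaged, unless given) weight table, so the
    matrix round-trips through VCF output and :func:`vdgrs.qc.read_genotypes`.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    for rsid, f in freqs.items():
        if not 0.0 <= f <= 1.0:
            raise ConfigError(f"allele frequency for {rsid} must be in [0, 1], got {f}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    weights = weights or packaged_weight_table()
    rsids = [w.rsid for w in weights if w.rsid in freqs]
    rsids += [r for r in freqs if r not in rsids]
    dos = pd.DataFrame(
        {r: rng.binomial(2, freqs[r], size=n).astype(float) for r in rsids},
        index=pd.Index([f"S{i:06d}" for i in range(n)], name="sample_id"),
    )
    meta = {}
    for r in rsids:
        try:
            w = weights[r]
            meta[r] = {"ref": w.other_allele, "alt": w.effect_allele, "info": None,
                       "source_rsid": r, "orientation": "effect_is_alt"}
        except KeyError:
            meta[r] = {"ref": "A", "alt": "G", "info": None, "source_rsid": r,
                       "orientation": "effect_is_alt"}
    return DosageMatrix(dos, pd.DataFrame.from_dict(meta, orient="index"))


def _covariate_variance(cfg: SimConfig) -> float:
    eff = cfg.covariate_effects
    return (
        eff.get("bmi", 0.0) ** 2 * cfg.bmi_sd**2
        + eff.get("age", 0.0) ** 2 * cfg.age_sd**2
        + eff.get("sex", 0.0) ** 2 * cfg.female_prob * (1 - cfg.female_prob)
    )


def simulate_cohort(config: SimConfig):
    """Generate a genotype matrix and matching phenotype table.

    Returns ``(DosageMatrix, CohortTable)``.  Sample ids are MS####/CT####;
    the phenotype table carries vd_level (nmol/L), vd_z, supplementing, dose,
    bmi, age, sex, ms_status.  Bit-reproducible for a fixed seed.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_ms + cfg.n_control
    betas = cfg.resolved_betas()
    freqs = {r: cfg.allele_freqs[r] for r in betas}

    matrix = simulate_genotypes(n, freqs, rng)
    ids = [f"MS{i:06d}" for i in range(cfg.n_ms)] + [f"CT{i:06d}" for i in range(cfg.n_control)]
    matrix.dosages.index = pd.Index(ids, name="sample_id")

    beta_vec = np.array([betas[r] for r in matrix.variant_ids])
    p_vec = np.array([freqs[r] for r in matrix.variant_ids])
    g_raw = matrix.dosages.to_numpy() @ beta_vec
    mu_g = float(np.sum(2 * p_vec * beta_vec))
    sd_g = math.sqrt(expected_variance_explained(freqs, betas))
    g_std = (g_raw - mu_g) / sd_g

    ms = np.array([True] * cfg.n_ms + [False] * cfg.n_control)
    supp_p = np.where(ms, cfg.supp_prob_ms, cfg.supp_prob_control)
    supp = rng.random(n) < supp_p
    dose_median = np.where(ms, cfg.dose_median_ms, cfg.dose_median_control)
    dose = np.where(supp, np.exp(rng.normal(np.log(dose_median), cfg.dose_log_sd)), 0.0)

    bmi = np.clip(rng.normal(cfg.bmi_mean, cfg.bmi_sd, n), 15.0, 55.0)
    age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), 18.0, 90.0)
    female = rng.random(n) < cfg.female_prob

    eff = cfg.covariate_effects
    cov_term = (
        eff.get("bmi", 0.0) * (bmi - cfg.bmi_mean)
        + eff.get("age", 0.0) * (age - cfg.age_mean)
        + eff.get("sex", 0.0) * female
        + eff.get("ms_status", 0.0) * ms
    )

    ge_ns = cfg.grs_effect
    ge_s = cfg.grs_effect_supp if cfg.grs_effect_supp is not None else cfg.grs_effect
    sd_ns = cfg.noise_sd
    sd_s = cfg.noise_sd_supp if cfg.noise_sd_supp is not None else cfg.noise_sd
    eps = rng.normal(0.0, 1.0, n) * np.where(supp, sd_s, sd_ns)

    if cfg.mode == "additive":
        vd = (
            np.where(supp, ge_s, ge_ns) * g_std
            + cfg.supp_shift * supp
            + cfg.dose_effect * np.log1p(dose) * supp
            + cov_term
            + eps
        )
    else:  # titration
        vd_ns = ge_ns * g_std + cov_term + eps
        vd_s = (
            cfg.titration_target
            + cfg.titration_genetic_attenuation * ge_s * g_std
            + cov_term
            + eps
        )
        vd = np.where(supp, vd_s, vd_ns)

    vd_z = (vd - vd.mean()) / vd.std(ddof=1)
    pheno = pd.DataFrame(
        {
            "sample_id": ids,
            "vd_level": VD_MEAN_NMOL + VD_SD_NMOL * vd_z,
            "vd_z": vd_z,
            "supplementing": supp,
            "dose": dose,
            "bmi": bmi,
            "age": age,
            "sex": np.where(female, "F", "M"),
            "ms_status": ms,
        }
    )
    return matrix, CohortTable(pheno)


# ---------------------------------------------------------------------------
# presets


def study_preset(n_ms: int = 315, n_control: int = 232, mode: str = "titration", seed: int = 0) -> SimConfig:
    """The MS case/control study conditions (titration-calibrated defaults).

    Calibration (closed-form, see docs/methods.md): with the supplementer
    fraction ≈0.52, grs_effect 0.205, titration target 1.16, covariate
    effects (−0.035 BMI, +0.010 age, +0.05 female) and residual SD 0.78, the
    phenotype has variance ≈1, the covariate-only model explains ≈0.37 of
    it, the score adds ≈0.02, and the pooled multivariable GRS coefficient
    is ≈0.10 SD per SD.
    """
    return SimConfig(seed=seed, n_ms=n_ms, n_control=n_control, mode=mode)


def ukb_preset(
    n: int = 50_000,
    supplementers: bool | None = None,
    seed: int = 0,
    grs_effect: float = 0.14,
    grs_effect_supp: float = 0.17,
) -> SimConfig:
    """Population-biobank-like conditions (additive mode, controls only).

    ``supplementers``: None draws the 5.1% biobank supplementation rate;
    True/False fixes the whole cohort to one stratum (used for stratum-level
    validation at a chosen n).  Per-stratum residual SDs are set in closed
    form so each stratum's phenotype has unit variance, making the
    standardized within-stratum slope equal ``grs_effect`` (0.14) /
    ``grs_effect_supp`` (0.17) in expectation.
    """
    cov = {"bmi": -0.02, "age": 0.005, "sex": 0.03, "ms_status": 0.0}
    cfg = SimConfig(
        seed=seed,
        n_ms=0,
        n_control=n,
        mode="additive",
        supp_prob_ms=0.0,
        supp_prob_control={None: 0.051, True: 1.0, False: 0.0}[supplementers],
        dose_median_ms=800.0,
        dose_median_control=800.0,
        dose_effect=0.0,
        supp_shift=0.3,
        grs_effect=grs_effect,
        grs_effect_supp=grs_effect_supp,
        covariate_effects=cov,
        age_mean=57.0,
        age_sd=8.0,
        female_prob=0.533,
    )
    v_c = _covariate_variance(cfg)
    cfg.noise_sd = math.sqrt(1.0 - grs_effect**2 - v_c)
    cfg.noise_sd_supp = math.sqrt(1.0 - grs_effect_supp**2 - v_c)
    return cfg
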