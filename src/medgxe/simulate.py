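"""Synthetic cohorts for exercising the gene-diet interaction pipeline.

The generator emulates the statistical structure the analysis assumes: six
linked FTO-like SNPs in Hardy-Weinberg equilibrium (a Gaussian copula on
latent haplotype variables supplies linkage disequilibrium), right-skewed
log-normal food intakes scaled to each subject's energy, realistic covariate
prevalences, phased follow-up with incident obesity driven by a configurable
logistic model with a gene-diet interaction term, and planted exclusion
flags.  Because diet-score medians are taken in-sample on continuous
intakes, the derived Mediterranean diet score is centred at 4 with SD near
sqrt(2) by construction, matching the target population.

All randomness flows from a single integer seed through spawned child
streams, so individual stages are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import cohort as cohort_mod
from . import dietary
from .genetics import DEFAULT_PANEL, GenotypePanel, dominant_code

#: median daily intake (g/day) of each raw component at 2400 kcal
_COMPONENT_MEDIANS = {
    "vegetables_g": 300.0,
    "legumes_g": 30.0,
    "fruits_g": 250.0,
    "nuts_g": 15.0,
    "cereals_g": 350.0,
    "fish_g": 20.0,
    "meat_poultry_g": 60.0,
    "dairy_g": 250.0,
    "mufa_g": 26.0,
    "sfa_g": 25.0,
}


@dataclass
class SimConfig:
    """Generator parameters; the defaults are the study conditions.

    Minor-allele frequencies default to the control-group values of the six
    FTO variants (0.33-0.38); energy intake is log-normal with mean 2400
    kcal/day and SD 1000; covariate prevalences follow the cohort
    (education >= 14 y 24%, current smoking 15%, low activity 41%).  The
    per-phase obesity model is
    logit p = beta0 + beta_g*carrier + beta_e*quartile + beta_gxe*carrier*quartile
    + covariate terms, with the carrier flag taken from ``effect_snp``.
    """

    n_subjects: int = 8000
    phases: int = 3
    seed: int = 0
    mafs: tuple = (0.38, 0.37, 0.38, 0.34, 0.33, 0.33)
    ld_rho: float = 0.9  # copula correlation among the tightly linked SNPs
    energy_mean: float = 2400.0
    energy_sd: float = 1000.0
    intake_sigma: float = 0.5  # log-scale SD of component intakes
    sex_intake_scale: float = 1.1  # male multiplier on food and energy
    education_p: float = 0.24
    smoking_current_p: float = 0.15
    smoking_ex_p: float = 0.10
    activity_low_p: float = 0.41
    activity_high_p: float = 0.20
    beta0: float = -3.5
    beta_g: float = 0.15
    beta_e: float = -0.10
    beta_gxe: float = 0.0
    beta_cov: dict = field(
        default_factory=lambda: {
            "education_ge14": -0.2,
            "smoking_current": 0.1,
            "activity_low": 0.2,
        }
    )
    effect_snp: int = 0  # index into the panel of the interacting SNP
    exclusion_rates: dict = field(
        default_factory=lambda: {
            "weight_change_gt5kg": 0.03,
            "pregnant_lactating": 0.02,
            "weight_drug": 0.01,
            "dna_bad": 0.05,
        }
    )
    phase_weights: tuple | None = None  # optional case-accrual weights

    def __post_init__(self) -> None:
        if not all(0 < m <= 0.5 for m in self.mafs):
            raise ValueError("MAFs must lie in (0, 0.5]")
        for name in ("education_p", "smoking_current_p", "activity_low_p"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be a probability")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("mafs", "phase_weights"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["mafs"] = list(data["mafs"])
        if data["phase_weights"] is not None:
            data["phase_weights"] = list(data["phase_weights"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class SimCohort:
    """A generated cohort plus the latent truth used to generate it."""

    subjects: pd.DataFrame
    diet: pd.DataFrame
    panel: GenotypePanel
    truth: dict


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_genotypes(
    config: SimConfig, rng: np.random.Generator, panel_meta=DEFAULT_PANEL
) -> GenotypePanel:
    """Dosages of six SNPs in HWE, with copula-induced LD between SNPs.

    Each of the two haplotypes per subject draws a latent multivariate
    normal vector with equicorrelation ``ld_rho``; allele i is the minor
    (risk) allele when the latent variable falls below the MAF quantile.
    Haplotypes are independent, so every SNP is in exact HWE marginally
    while dosages are correlated across SNPs.
    """
    n, k = config.n_subjects, len(config.mafs)
    cov = np.full((k, k), config.ld_rho, dtype=float)
    np.fill_diagonal(cov, 1.0)
    chol = np.linalg.cholesky(cov)
    thresholds = stats.norm.ppf(config.mafs)
    dosage = np.zeros((n, k), dtype=float)
    for _ in range(2):  # two independent haplotypes
        z = rng.standard_normal((n, k)) @ chol.T
        dosage += (z < thresholds).astype(float)
    ids = [f"S{i:05d}" for i in range(n)]
    df = pd.DataFrame(dosage, index=ids, columns=[m.snp_id for m in panel_meta[:k]])
    return GenotypePanel(df, panel_meta[:k])


def simulate_diet(
    config: SimConfig, sex: pd.Series, rng: np.random.Generator
) -> pd.DataFrame:
    """Log-normal component intakes scaled to a log-normal energy intake.

    Component intakes are proportional to the subject's energy (so the
    energy-adjusted values are roughly energy-independent, as with real
    energy-density adjustment) with independent log-normal variation.
    """
    n = len(sex)
    male = pd.Series(sex).astype(str).str.lower().isin(["male", "m", "1"]).to_numpy()
    # moment-match the log-normal to the target energy mean and SD
    cv2 = (config.energy_sd / config.energy_mean) ** 2
    sigma_e = np.sqrt(np.log1p(cv2))
    mu_e = np.log(config.energy_mean) - sigma_e**2 / 2
    energy = np.exp(mu_e + sigma_e * rng.standard_normal(n))
    energy *= np.where(male, config.sex_intake_scale, 2 - config.sex_intake_scale)

    out = pd.DataFrame({"subject_id": pd.Series(sex).index})
    rel_energy = energy / config.energy_mean
    for col, med in _COMPONENT_MEDIANS.items():
        noise = np.exp(config.intake_sigma * rng.standard_normal(n))
        out[col] = med * rel_energy * noise
    out["energy_kcal"] = energy
    return out


def simulate_subjects(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Demographics, anthropometrics, covariates and exclusion flags."""
    n = config.n_subjects
    ids = [f"S{i:05d}" for i in range(n)]
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    age = np.clip(rng.normal(34.5, 11, n), 18, 75)
    height = np.where(sex == "male", rng.normal(171, 7, n), rng.normal(158, 6, n))
    bmi0 = np.clip(rng.normal(23.5, 2.6, n), 18.6, 29.5)  # non-obese at baseline
    education = (rng.random(n) < config.education_p).astype(int)
    u = rng.random(n)
    smoking = np.select(
        [u < config.smoking_current_p, u < config.smoking_current_p + config.smoking_ex_p],
        ["current", "ex"],
        default="never",
    )
    u = rng.random(n)
    activity = np.select(
        [u < config.activity_low_p, u < config.activity_low_p + config.activity_high_p],
        ["low", "high"],
        default="moderate",
    )
    rates = config.exclusion_rates
    return pd.DataFrame(
        {
            "id": ids,
            "age": age,
            "sex": sex,
            "height_cm": height,
            "baseline_bmi": bmi0,
            "education_ge14": education,
            "smoking": smoking,
            "activity": activity,
            "weight_change_gt5kg": (rng.random(n) < rates["weight_change_gt5kg"]).astype(int),
            "pregnant_lactating": (
                (sex == "female") & (rng.random(n) < 2 * rates["pregnant_lactating"])
            ).astype(int),
            "weight_drug": (rng.random(n) < rates["weight_drug"]).astype(int),
            "dna_quality_ok": (rng.random(n) >= rates["dna_bad"]).astype(int),
        }
    ).set_index("id", drop=False)


def simulate_outcomes(
    subjects: pd.DataFrame,
    carrier: pd.Series,
    mds_quartile: pd.Series,
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Phased incident obesity under the configured logistic model.

    Per phase, the obesity probability is
    logistic(beta0 + beta_g*carrier + beta_e*q + beta_gxe*carrier*q + covariates);
    once obese, a subject is a case at that phase.  Non-cases receive a
    ``normal_until`` phase (the last phase they are known normal-weight) and
    final anthropometrics consistent with their status.  Optional
    ``phase_weights`` tilt case accrual across phases.
    """
    n = len(subjects)
    g = np.asarray(carrier, dtype=float)
    q = np.asarray(mds_quartile, dtype=float)
    eta = (
        config.beta0
        + config.beta_g * g
        + config.beta_e * q
        + config.beta_gxe * g * q
        + config.beta_cov.get("education_ge14", 0.0) * subjects["education_ge14"].to_numpy()
        + config.beta_cov.get("smoking_current", 0.0)
        * (subjects["smoking"] == "current").to_numpy()
        + config.beta_cov.get("activity_low", 0.0)
        * (subjects["activity"] == "low").to_numpy()
    )
    p = 1.0 / (1.0 + np.exp(-eta))
    if config.phase_weights is not None:
        w = np.asarray(config.phase_weights, dtype=float)
        w = w / w.mean()
    else:
        w = np.ones(config.phases)

    phase = np.full(n, np.nan)
    for k in range(1, config.phases + 1):
        event = (rng.random(n) < np.clip(p * w[k - 1], 0, 1)) & np.isnan(phase)
        phase[event] = k

    is_case = ~np.isnan(phase)
    bmi = subjects["baseline_bmi"].to_numpy().copy()
    drift = rng.normal(0.4, 1.2, n)
    bmi = np.where(is_case, rng.uniform(30.0, 38.0, n), np.clip(bmi + drift, 17.5, 29.5))
    normal_until = np.where(
        bmi < 25.0, float(config.phases), np.floor(rng.uniform(0, config.phases, n))
    )
    normal_until[is_case] = np.nan

    out = subjects.copy()
    out["phase"] = phase
    out["is_case"] = is_case.astype(int)
    out["bmi"] = bmi
    out["normal_until"] = normal_until
    out["weight_kg"] = bmi * (out["height_cm"] / 100) ** 2
    wc = 3.0 * bmi + rng.normal(8.0, 5.0, n)
    whr = np.clip(
        rng.normal(0.84, 0.06, n) + 0.004 * (bmi - 24.0), 0.6, 1.2
    )
    out["wc"] = wc
    out["hip"] = wc / whr
    out["whr"] = whr
    return out


def simulate_cohort(config: SimConfig) -> SimCohort:
    """Generate a full cohort: genotypes, diet, subjects, phased outcomes.

    The planted gene-diet effect uses the dominant coding of
    ``config.effect_snp`` and the in-sample MDS quartile, exactly the
    quantities the downstream pipeline estimates.  The latent truth (betas,
    MAFs, per-subject carrier and quartile) rides along for recovery tests.
    """
    rng_geno, rng_subj, rng_diet, rng_out = _streams(config.seed, 4)
    subjects = simulate_subjects(config, rng_subj)
    panel = simulate_genotypes(config, rng_geno, DEFAULT_PANEL)
    panel.dosages.index = subjects.index
    diet = simulate_diet(config, subjects["sex"], rng_diet)
    diet["subject_id"] = subjects["id"].to_numpy()
    diet["energy_kcal"] = diet["energy_kcal"].to_numpy()
    subjects = subjects.assign(energy_kcal=diet["energy_kcal"].to_numpy())

    scores, medians, _ = dietary.score_profiles(diet, subjects["sex"])
    mds = pd.Series(scores["mds"].to_numpy(), index=subjects.index)
    quartile, _ = cohort_mod.assign_quartiles(mds)
    carrier = dominant_code(panel.dosages.iloc[:, config.effect_snp])

    subjects = simulate_outcomes(subjects, carrier, quartile, config, rng_out)
    subjects["mds"] = mds
    subjects["mds_quartile"] = quartile.to_numpy()
    truth = {
        "beta0": config.beta0,
        "beta_g": config.beta_g,
        "beta_e": config.beta_e,
        "beta_gxe": config.beta_gxe,
        "mafs": list(config.mafs),
        "effect_snp": panel.snps[config.effect_snp].snp_id,
        "seed": config.seed,
    }
    return SimCohort(subjects=subjects, diet=diet, panel=panel, truth=truth)


def simulate_matched_pairs(
    n_pairs: int,
    beta_g: float,
    beta_e: float,
    beta_gxe: float,
    rng: np.random.Generator,
    carrier_p: float = 0.6,
) -> pd.DataFrame:
    """Matched 1:1 case-control pairs drawn exactly from the conditional model.

    Both pair members draw a carrier flag (Bernoulli ``carrier_p``, the
    dominant-coding prevalence at MAF ~0.37) and an MDS quartile (uniform
    1-4).  Within a pair sharing its matching-factor intercept, the
    probability that member A is the case given exactly one case is
    sigmoid(eta_A - eta_B) -- the 1:1 conditional likelihood itself -- so
    conditional-logistic estimates of (beta_g, beta_e, beta_gxe) are
    consistent for the planted values.  Returns the case-minus-control
    difference design (columns carrier, mds_q, gxe), ready for
    :func:`medgxe.models.clogit_fit`.
    """
    g = (rng.random((n_pairs, 2)) < carrier_p).astype(float)
    q = rng.integers(1, 5, size=(n_pairs, 2)).astype(float)
    eta = beta_g * g + beta_e * q + beta_gxe * g * q
    p_a_case = 1.0 / (1.0 + np.exp(-(eta[:, 0] - eta[:, 1])))
    a_is_case = rng.random(n_pairs) < p_a_case
    sign = np.where(a_is_case, 1.0, -1.0)
    d_g = sign * (g[:, 0] - g[:, 1])
    d_q = sign * (q[:, 0] - q[:, 1])
    d_gxe = sign * (g[:, 0] * q[:, 0] - g[:, 1] * q[:, 1])
    return pd.DataFrame({"carrier": d_g, "mds_q": d_q, "gxe": d_gxe})


def write_cohort(cohort: SimCohort, outdir, vcf: bool = False) -> dict:
    """Emit the cohort in the dialects the reader modules consume.

    Writes subjects.csv, diet.csv, genotypes.tsv (and optionally
    genotypes.vcf) plus truth.json; returns the path map.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "subjects": os.path.join(outdir, "subjects.csv"),
        "diet": os.path.join(outdir, "diet.csv"),
        "genotypes": os.path.join(outdir, "genotypes.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    cohort.subjects.to_csv(paths["subjects"], index=False)
    cohort.diet.to_csv(paths["diet"], index=False)
    cohort.panel.dosages.to_csv(paths["genotypes"], sep="\t", index_label="id")
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=2)
    if vcf:
        paths["vcf"] = os.path.join(outdir, "genotypes.vcf")
        write_vcf(cohort.panel, paths["vcf"])
    return paths


#: plausible FTO-region coordinates for VCF emission (GRCh37-like)
_VCF_POSITIONS = {
    "rs1121980": 53809247,
    "rs1421085": 53800954,
    "rs9939973": 53800568,
    "rs8050136": 53816275,
    "rs17817449": 53813367,
    "rs3751812": 53818460,
}


def write_vcf(panel: GenotypePanel, path) -> None:
    """Write dosages as a minimal diploid VCF 4.2 (GT only, risk allele = ALT)."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=16>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(str(s) for s in panel.dosages.index)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for snp in panel.snps:
            pos = _VCF_POSITIONS.get(snp.snp_id, 53800000)
            calls = "\t".join(
                gt_map.get(d, "./.") for d in panel.dosages[snp.snp_id].to_numpy()
            )
            fh.write(
                f"16\t{pos}\t{snp.snp_id}\t{snp.other_allele}\t{snp.risk_allele}"
                f"\t.\tPASS\t.\tGT\t{calls}\n"
            )
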