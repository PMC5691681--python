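"""End-to-end orchestration: exclusions, matching, scoring, model grids.

`run_pipeline` takes the three input tables (subjects, diet, genotype panel),
applies the exclusion cascade, matches incident obesity cases 1:1 to
normal-weight controls on sex and age, scores the Mediterranean diet on the
matched analysis sample, and fits the gene-diet interaction models:

* per-SNP and GRS odds-ratio grids over the 8 groups (MDS quartile x
  genotype), conditional on the matched pairs for obesity and unconditional
  for the abdominal outcomes;
* a 1-df likelihood-ratio interaction test (carrier x ordinal quartile);
* trend tests using the per-quartile median MDS as a continuous covariate,
  with the per-stratum slope read off the full model (non-carrier slope =
  the trend coefficient; carrier slope = trend + interaction, with the
  delta-method standard error).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import cohort as cc
from . import dietary, models
from .genetics import (
    GenotypePanel,
    dichotomize_grs,
    dominant_code,
    genotype_frequency_table,
    weighted_grs,
)

__version__ = "0.1.0"

OBESITY_ADJUST = ["education_ge14"]
ABDOMINAL_ADJUST = [
    "education_ge14",
    "age",
    "male",
    "smoking_current",
    "smoking_ex",
    "activity_low",
    "activity_high",
    "energy_kcal",
]


@dataclass
class PipelineResult:
    pairs: pd.DataFrame
    analysis: pd.DataFrame
    descriptives: pd.DataFrame
    frequency: pd.DataFrame
    or_grids: dict
    interaction_tests: pd.DataFrame
    audit: pd.DataFrame
    manifest: dict
    medians: pd.DataFrame


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _prepare_covariates(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["male"] = out["sex"].astype(str).str.lower().isin(["male", "m", "1"]).astype(float)
    out["smoking_current"] = (out["smoking"] == "current").astype(float)
    out["smoking_ex"] = (out["smoking"] == "ex").astype(float)
    out["activity_low"] = (out["activity"] == "low").astype(float)
    out["activity_high"] = (out["activity"] == "high").astype(float)
    return out


def _group_dummies(group: pd.Series) -> pd.DataFrame:
    """Dummy columns for group levels 2..8 (level 1 is the reference)."""
    cols = {}
    for level in range(2, 9):
        cols[f"grp{level}"] = (group == level).astype(float)
    return pd.DataFrame(cols, index=group.index)


def _stratum_trend(fit: models.FitResult, base: str = "trend", inter: str = "gxtrend"):
    """Per-stratum trend slopes from a model with a trend x stratum product.

    Returns ((slope0, p0), (slope1, p1)): the non-carrier slope is the trend
    coefficient; the carrier slope adds the interaction, with variance
    var(b) + var(c) + 2 cov(b, c).
    """
    b = fit.beta[base]
    p0 = models.wald_p(fit, base)
    c = fit.beta[inter]
    var = (
        fit.cov.loc[base, base]
        + fit.cov.loc[inter, inter]
        + 2 * fit.cov.loc[base, inter]
    )
    z = (b + c) / np.sqrt(var)
    p1 = float(2 * stats.norm.sf(abs(z)))
    return (float(b), p0), (float(b + c), p1)


def _fit_grid_conditional(
    analysis: pd.DataFrame,
    pairs: pd.DataFrame,
    flag_col: str,
    adjust: list[str],
    reference_high: bool = False,
) -> tuple[pd.DataFrame, models.InteractionTest, dict]:
    """8-group OR grid + 1-df interaction LRT + stratum trends, conditional."""
    data = analysis.copy()
    group = cc.build_groups(data["mds_quartile"], data[flag_col], reference_high)
    covs = pd.concat([_group_dummies(group), data[adjust]], axis=1)
    terms = list(covs.columns)
    diffs = models.pair_difference_design(pairs, covs, terms)
    # group levels (or adjusters) without any discordant pair carry no
    # conditional information and are dropped from the grid fit
    informative = [c for c in diffs.columns if (diffs[c] != 0).any()]
    grid_fit = models.clogit_fit(diffs[informative], model_label=f"{flag_col}:groups")
    grid = models.or_report(grid_fit, [t for t in informative if t.startswith("grp")])

    # 1-df interaction LRT: carrier x ordinal quartile
    full_cov, red_cov = models.interaction_design(
        data, flag_col, "mds_quartile", adjust=adjust, ordinal=True
    )
    d_full = models.pair_difference_design(pairs, full_cov, list(full_cov.columns))
    d_red = models.pair_difference_design(pairs, red_cov, list(red_cov.columns))
    lrt = models.lrt_interaction(
        models.clogit_fit(d_full, f"{flag_col}:full"),
        models.clogit_fit(d_red, f"{flag_col}:reduced"),
    )

    # trend: per-quartile median MDS as a continuous covariate
    trend = models.quartile_median_covariate(data["mds_quartile"], data["mds"])
    tcov = pd.DataFrame(
        {
            flag_col: data[flag_col].astype(float),
            "trend": trend,
            "gxtrend": data[flag_col].astype(float) * trend,
        },
        index=data.index,
    )
    for a in adjust:
        tcov[a] = data[a].astype(float)
    d_t = models.pair_difference_design(pairs, tcov, list(tcov.columns))
    tfit = models.clogit_fit(d_t, f"{flag_col}:trend")
    (s0, p0), (s1, p1) = _stratum_trend(tfit)
    trends = {
        "noncarrier": {"slope": s0, "p": p0},
        "carrier": {"slope": s1, "p": p1},
    }
    return grid, lrt, trends


def _fit_grid_unconditional(
    analysis: pd.DataFrame,
    outcome_col: str,
    flag_col: str,
    adjust: list[str],
    reference_high: bool = False,
) -> tuple[pd.DataFrame, models.InteractionTest, dict]:
    """Same grid for an unconditional (abdominal-phenotype) outcome."""
    data = analysis.dropna(subset=[outcome_col]).copy()
    y = data[outcome_col].astype(float)
    group = cc.build_groups(data["mds_quartile"], data[flag_col], reference_high)
    covs = pd.concat([_group_dummies(group), data[adjust]], axis=1)
    grid_fit = models.logit_fit(covs, y, model_label=f"{flag_col}:{outcome_col}:groups")
    grid = models.or_report(grid_fit, [t for t in covs.columns if t.startswith("grp")])

    full_cov, red_cov = models.interaction_design(
        data, flag_col, "mds_quartile", adjust=adjust, ordinal=True
    )
    lrt = models.lrt_interaction(
        models.logit_fit(full_cov, y, model_label="full"),
        models.logit_fit(red_cov, y, model_label="reduced"),
    )

    trend = models.quartile_median_covariate(data["mds_quartile"], data["mds"])
    tcov = pd.DataFrame(
        {
            flag_col: data[flag_col].astype(float),
            "trend": trend,
            "gxtrend": data[flag_col].astype(float) * trend,
        },
        index=data.index,
    )
    for a in adjust:
        tcov[a] = data[a].astype(float)
    tfit = models.logit_fit(tcov, y, model_label=f"{flag_col}:{outcome_col}:trend")
    (s0, p0), (s1, p1) = _stratum_trend(tfit)
    trends = {
        "noncarrier": {"slope": s0, "p": p0},
        "carrier": {"slope": s1, "p": p1},
    }
    return grid, lrt, trends


def run_pipeline(
    subjects: pd.DataFrame,
    diet: pd.DataFrame,
    panel: GenotypePanel,
    seed: int,
    reference_high: bool = False,
    conditional_abdominal: bool = False,
    thresholds: cc.Thresholds = cc.Thresholds(),
    input_digests: dict | None = None,
) -> PipelineResult:
    """Run the full analysis; see the module docstring for the stages."""
    import datetime

    if subjects.index.name != "id":
        subjects = subjects.set_index("id", drop=False)
    counts = {"input_subjects": len(subjects)}
    subjects = cc.classify_phenotypes(subjects, thresholds)
    retained, audit = cc.apply_exclusions(subjects)
    counts["after_exclusions"] = len(retained)

    cases = retained[(retained["obese"] == 1) & retained["phase"].notna()]
    controls = retained[retained["normal_bmi"] == 1]
    pairs, unmatched = cc.match_pairs(
        cases[["id", "age", "sex", "phase"]],
        controls[["id", "age", "sex"]].assign(
            normal_until=controls.get("normal_until", np.inf)
        ),
        seed=seed,
        age_window=thresholds.age_window,
    )
    counts["cases"] = len(cases)
    counts["control_pool"] = len(controls)
    counts["pairs"] = len(pairs)

    # Mediterranean diet scoring on the pooled matched sample; pairs with a
    # rejected diet record (non-positive energy) are dropped whole.
    diet_idx = diet.set_index("subject_id", drop=False)
    _, rejected = dietary.energy_adjust(diet_idx)
    bad_ids = set(rejected["subject_id"]) if len(rejected) else set()
    if bad_ids:
        pairs = pairs[
            ~(pairs["case_id"].isin(bad_ids) | pairs["control_id"].isin(bad_ids))
        ]
    counts["pairs_with_valid_diet"] = len(pairs)
    matched_ids = pd.Index(pairs["case_id"]).append(pd.Index(pairs["control_id"]))
    analysis = retained.loc[matched_ids].copy()
    analysis["is_case"] = analysis["obese"].astype(int)

    diet_m = diet_idx.loc[matched_ids]
    adjusted, _ = dietary.energy_adjust(diet_m)
    adjusted.index = matched_ids
    medians = dietary.compute_medians(adjusted, analysis["sex"])
    scores = dietary.score_mds(adjusted, medians, analysis["sex"])
    analysis["mds"] = scores["mds"].to_numpy()
    quartile, qsummary = cc.assign_quartiles(analysis["mds"])
    analysis["mds_quartile"] = quartile

    # genetics on the matched sample
    panel_m = GenotypePanel(panel.dosages.loc[matched_ids], panel.snps)
    grs = weighted_grs(panel_m)
    analysis["grs"] = grs["grs"]
    high, grs_threshold = dichotomize_grs(analysis["grs"])
    analysis["high_grs"] = high
    for snp in panel.snps:
        analysis[f"carrier_{snp.snp_id}"] = dominant_code(panel_m.dosages[snp.snp_id])
    analysis = _prepare_covariates(analysis)

    # Table-1 analogue
    case_rows = analysis[analysis["is_case"] == 1]
    ctrl_rows = analysis[analysis["is_case"] == 0]
    descriptives = models.cohort_descriptives(
        case_rows,
        ctrl_rows,
        continuous=["age", "bmi", "wc", "energy_kcal", "mds"],
        categorical=["smoking", "activity", "education_ge14"],
    )

    # Table-2 analogue: frequencies + HWE by case status
    frequency = genotype_frequency_table(
        panel_m, analysis["is_case"].map({1: "case", 0: "control"})
    )

    # Tables 3-6 analogues
    or_grids: dict = {}
    tests = []
    complete = analysis.dropna(subset=["grs", "mds_quartile"])
    pair_ok = pairs[
        pairs["case_id"].isin(complete.index) & pairs["control_id"].isin(complete.index)
    ]
    factors = [(f"carrier_{snp.snp_id}", snp.snp_id) for snp in panel.snps]
    factors.append(("high_grs", "GRS"))
    for flag_col, label in factors:
        grid, lrt, trends = _fit_grid_conditional(
            complete, pair_ok, flag_col, OBESITY_ADJUST, reference_high
        )
        or_grids[(label, "obesity")] = grid
        tests.append(
            {
                "factor": label,
                "outcome": "obesity",
                "lr_chi2": lrt.lr_chi2,
                "df": lrt.df,
                "p_interaction": lrt.p_value,
                "trend_p_noncarrier": trends["noncarrier"]["p"],
                "trend_p_carrier": trends["carrier"]["p"],
            }
        )
        for outcome in ("abdominal_obese", "high_whr"):
            if conditional_abdominal:
                out_flag = complete[outcome]
                disc = pair_ok[
                    (out_flag.loc[pair_ok["case_id"]].to_numpy()
                     != out_flag.loc[pair_ok["control_id"]].to_numpy())
                ]
                if len(disc) < 10:
                    continue
                grid, lrt, trends = _fit_grid_conditional(
                    complete, disc, flag_col, OBESITY_ADJUST, reference_high
                )
            else:
                grid, lrt, trends = _fit_grid_unconditional(
                    complete, outcome, flag_col, ABDOMINAL_ADJUST, reference_high
                )
            or_grids[(label, outcome)] = grid
            tests.append(
                {
                    "factor": label,
                    "outcome": outcome,
                    "lr_chi2": lrt.lr_chi2,
                    "df": lrt.df,
                    "p_interaction": lrt.p_value,
                    "trend_p_noncarrier": trends["noncarrier"]["p"],
                    "trend_p_carrier": trends["carrier"]["p"],
                }
            )

    manifest = {
        "version": __version__,
        "seed": seed,
        "config_hash": _hash_obj(
            {
                "reference_high": reference_high,
                "conditional_abdominal": conditional_abdominal,
                "thresholds": thresholds.__dict__,
            }
        ),
        "input_digests": input_digests or {"mode": "in-memory"},
        "counts": counts,
        "grs_threshold": grs_threshold,
        "unmatched_cases": len(unmatched),
        "quartile_summary": qsummary.to_dict(orient="records"),
        "timestamp": datetime.datetime.now().isoformat(),
    }
    return PipelineResult(
        pairs=pairs,
        analysis=analysis,
        descriptives=descriptives,
        frequency=frequency,
        or_grids=or_grids,
        interaction_tests=pd.DataFrame(tests),
        audit=audit,
        manifest=manifest,
        medians=medians,
    )


def calibrate(
    reps: int,
    n_pairs: int,
    beta_gxe_values: list[float],
    seed: int,
    beta_g: float = 0.3,
    beta_e: float = -0.15,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Monte-Carlo rejection rates of the 1-df interaction LRT.

    For each planted interaction coefficient, simulates ``reps`` matched
    case-control samples from the exact conditional model and records the
    fraction of LRT p-values below ``alpha``, with a 95% binomial
    (Clopper-Pearson) interval.
    """
    from .simulate import simulate_matched_pairs

    if reps < 1:
        raise ValueError("reps must be >= 1")
    rows = []
    streams = np.random.SeedSequence(seed).spawn(len(beta_gxe_values))
    for bgxe, ss in zip(beta_gxe_values, streams):
        rng = np.random.default_rng(ss)
        rejections = 0
        for _ in range(reps):
            diffs = simulate_matched_pairs(n_pairs, beta_g, beta_e, bgxe, rng)
            full = models.clogit_fit(diffs)
            reduced = models.clogit_fit(diffs[["carrier", "mds_q"]])
            if models.lrt_interaction(full, reduced).p_value < alpha:
                rejections += 1
        lo = float(stats.beta.ppf(0.025, rejections, reps - rejections + 1)) if rejections else 0.0
        hi = (
            float(stats.beta.ppf(0.975, rejections + 1, reps - rejections))
            if rejections < reps
            else 1.0
        )
        rows.append(
            {
                "beta_gxe": bgxe,
                "reps": reps,
                "n_pairs": n_pairs,
                "rejection_rate": rejections / reps,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows)
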