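"""Case-control assembly: phenotype classification, exclusions, matching, grouping.

Cases are subjects who become obese (BMI >= 30 kg/m2) during follow-up; each
is individually matched by sex and age (+/- 5 years) to a randomly chosen
control with normal BMI (18.5 <= BMI < 25) at the phase the case became
obese.  Subjects also carry abdominal-obesity indicators: waist
circumference >= 95 cm in both sexes, and waist-to-hip ratio >= 0.8 in men /
>= 0.9 in women (the published cutoffs, overridable).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    """Anthropometric cutoffs and the matching age window."""

    bmi_obese: float = 30.0
    bmi_normal_low: float = 18.5
    bmi_normal_high: float = 25.0  # exclusive upper bound
    wc_abdominal: float = 95.0
    whr_high_male: float = 0.8
    whr_high_female: float = 0.9
    age_window: float = 5.0


def classify_phenotypes(
    subjects: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Add binary phenotype flags derived from BMI, WC and WHR.

    Flags: ``obese`` (BMI >= 30, boundary inclusive), ``normal_bmi``
    (18.5 <= BMI < 25), ``abdominal_obese`` (WC >= 95 cm), ``high_whr``
    (WHR >= 0.8 in men, >= 0.9 in women).  Missing anthropometrics give
    missing flags.
    """
    out = subjects.copy()
    bmi = out["bmi"].to_numpy(dtype=float)
    wc = out["wc"].to_numpy(dtype=float)
    whr = out["whr"].to_numpy(dtype=float)
    male = out["sex"].astype(str).str.lower().isin(["male", "m", "1"]).to_numpy()

    def _flag(values, cond):
        return np.where(np.isnan(values), np.nan, cond.astype(float))

    out["obese"] = _flag(bmi, bmi >= thresholds.bmi_obese)
    out["normal_bmi"] = _flag(
        bmi, (bmi >= thresholds.bmi_normal_low) & (bmi < thresholds.bmi_normal_high)
    )
    out["abdominal_obese"] = _flag(wc, wc >= thresholds.wc_abdominal)
    whr_cut = np.where(male, thresholds.whr_high_male, thresholds.whr_high_female)
    out["high_whr"] = _flag(whr, whr >= whr_cut)
    return out


#: exclusion rules applied in order; each is (rule name, boolean mask builder)
EXCLUSION_FLAGS = [
    ("weight_change_gt5kg", lambda df: df["weight_change_gt5kg"].astype(bool)),
    ("pregnant_lactating", lambda df: df["pregnant_lactating"].astype(bool)),
    ("weight_drug", lambda df: df["weight_drug"].astype(bool)),
    ("dna_quality", lambda df: ~df["dna_quality_ok"].astype(bool)),
]


def schofield_predicted_energy(subjects: pd.DataFrame) -> pd.Series:
    """Predicted daily energy intake (kcal) from a Schofield-type BMR equation.

    BMR is a sex- and age-banded linear function of body weight, multiplied
    by an activity factor (low 1.4, moderate 1.6, high 1.8).  Used as the
    default denominator of the reported/predicted energy plausibility screen.
    """
    w = subjects["weight_kg"].to_numpy(dtype=float)
    age = subjects["age"].to_numpy(dtype=float)
    male = subjects["sex"].astype(str).str.lower().isin(["male", "m", "1"]).to_numpy()
    bmr = np.where(
        male,
        np.select(
            [age < 30, age < 60], [15.057 * w + 692.2, 11.472 * w + 873.1],
            default=11.711 * w + 587.7,
        ),
        np.select(
            [age < 30, age < 60], [14.818 * w + 486.6, 8.126 * w + 845.6],
            default=9.082 * w + 658.5,
        ),
    )
    pal = (
        subjects["activity"].astype(str).map({"low": 1.4, "moderate": 1.6, "high": 1.8})
        .fillna(1.6)
        .to_numpy()
    )
    return pd.Series(bmr * pal, index=subjects.index, name="predicted_energy_kcal")


def apply_exclusions(
    subjects: pd.DataFrame,
    energy_sd_window: float = 3.0,
    predicted_energy: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the exclusion cascade; return (retained, audit log).

    Rules, in order: weight change > 5 kg in the last six months; pregnancy
    or lactation; weight-affecting medication; DNA quality failure; reported
    energy intake implausible (reported/predicted ratio outside the mean +/-
    ``energy_sd_window`` SD of the remaining sample).  ``predicted_energy``
    defaults to a ``predicted_energy_kcal`` column if present, else the
    Schofield-type equation.

    The audit log has one row per rule with the number removed; the counts
    sum to ``len(subjects) - len(retained)``.
    """
    current = subjects.copy()
    audit = []
    for rule, make_mask in EXCLUSION_FLAGS:
        if rule == "dna_quality" and "dna_quality_ok" not in current.columns:
            audit.append({"rule": rule, "n_removed": 0})
            continue
        flag_col = rule if rule != "dna_quality" else "dna_quality_ok"
        if flag_col not in current.columns:
            audit.append({"rule": rule, "n_removed": 0})
            continue
        mask = make_mask(current)
        audit.append({"rule": rule, "n_removed": int(mask.sum())})
        current = current.loc[~mask]

    if predicted_energy is None:
        if "predicted_energy_kcal" in current.columns:
            predicted_energy = current["predicted_energy_kcal"]
        else:
            predicted_energy = schofield_predicted_energy(current)
    else:
        predicted_energy = pd.Series(predicted_energy).loc[current.index]
    ratio = current["energy_kcal"] / predicted_energy
    mean, sd = float(ratio.mean()), float(ratio.std())
    if sd > 0:
        bad = (ratio < mean - energy_sd_window * sd) | (
            ratio > mean + energy_sd_window * sd
        )
    else:
        bad = pd.Series(False, index=current.index)
    audit.append({"rule": "energy_ratio_3sd", "n_removed": int(bad.sum())})
    current = current.loc[~bad]

    audit_df = pd.DataFrame(audit)
    logger.info(
        "exclusions: %d -> %d subjects (%s)",
        len(subjects),
        len(current),
        ", ".join(f"{r['rule']}={r['n_removed']}" for r in audit),
    )
    return current, audit_df


def match_pairs(
    cases: pd.DataFrame,
    controls: pd.DataFrame,
    seed: int | np.random.Generator,
    age_window: float = 5.0,
) -> tuple[pd.DataFrame, list]:
    """Randomized greedy 1:1 matching of cases to controls by sex and age.

    ``cases`` needs columns id, age, sex, phase; ``controls`` needs id, age,
    sex and optionally ``normal_until`` (last phase the subject is known to
    be normal-weight; the control must cover the case's phase).  Cases are
    visited in random order and each draws a uniformly random eligible
    unused control.  Deterministic under a fixed seed.

    Returns (pairs, unmatched_case_ids); pairs has columns case_id,
    control_id, phase.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ctrl = controls.reset_index(drop=True)
    used = np.zeros(len(ctrl), dtype=bool)
    ctrl_age = ctrl["age"].to_numpy(dtype=float)
    ctrl_sex = ctrl["sex"].to_numpy()
    has_phase = "normal_until" in ctrl.columns
    ctrl_until = ctrl["normal_until"].to_numpy(dtype=float) if has_phase else None

    pairs = []
    unmatched = []
    order = rng.permutation(len(cases))
    case_rows = cases.reset_index(drop=True)
    for i in order:
        row = case_rows.iloc[i]
        eligible = (
            ~used
            & (ctrl_sex == row["sex"])
            & (np.abs(ctrl_age - float(row["age"])) <= age_window)
        )
        if has_phase and not pd.isna(row.get("phase")):
            eligible &= ctrl_until >= float(row["phase"])
        idx = np.flatnonzero(eligible)
        if idx.size == 0:
            unmatched.append(row["id"])
            continue
        j = int(rng.choice(idx))
        used[j] = True
        pairs.append(
            {"case_id": row["id"], "control_id": ctrl.iloc[j]["id"], "phase": row.get("phase")}
        )
    if unmatched:
        warnings.warn(f"{len(unmatched)} case(s) had no eligible control and were dropped")
    pairs_df = pd.DataFrame(pairs, columns=["case_id", "control_id", "phase"])
    return pairs_df, unmatched


def assign_quartiles(
    scores: pd.Series, ties: str = "down"
) -> tuple[pd.Series, pd.DataFrame]:
    """Rank-based quartiles of a (typically discrete) score.

    Cuts fall at the ordered 25/50/75% positions and whole tie blocks stay
    in one quartile, so membership is a deterministic function of the value.
    ``ties="down"`` (default) keeps a tie block that straddles a cut in the
    lower quartile.  ``ties="nearest"`` sends the block to whichever side of
    the cut holds more of it; on a discrete 0-8 adherence score near
    Binomial(8, 1/2) this yields the quartile blocks {0-2}, {3,4}, {5},
    {6-8} whose means match the published quartile summaries.  Returns
    (quartile assignment 1-4, per-quartile summary with size and mean
    score).  Degenerate inputs with fewer distinct values than cuts collapse
    quartiles with a warning.
    """
    if ties not in ("down", "nearest"):
        raise ValueError("ties must be 'down' or 'nearest'")
    scores = pd.Series(scores)
    vals = scores.dropna().to_numpy(dtype=float)
    n = vals.size
    if n < 4:
        raise ValueError("need at least 4 subjects to form quartiles")
    v = np.sort(vals)
    cuts = []
    for k in (1, 2, 3):
        f = k / 4
        vc = v[int(np.ceil(f * n)) - 1]  # value at the cut position
        if ties == "nearest":
            lo = np.searchsorted(v, vc, "left") / n
            hi = np.searchsorted(v, vc, "right") / n
            if (lo + hi) / 2 > f:  # most of the tie block lies above the cut
                below = v[v < vc]
                vc = below[-1] if below.size else -np.inf
        cuts.append(vc)
    q = 1 + sum((scores > c).astype(float) for c in cuts)
    q[scores.isna()] = np.nan
    if len(set(cuts)) < 3 or q.nunique() < 4:
        warnings.warn("quartiles collapsed: fewer distinct score values than cuts")
    summary = (
        pd.DataFrame({"quartile": q, "score": scores})
        .dropna()
        .groupby("quartile")["score"]
        .agg(n="size", mean_score="mean")
        .reset_index()
    )
    return q, summary


def build_groups(
    quartile: pd.Series,
    genotype_flag: pd.Series,
    reference_high: bool = False,
) -> pd.Series:
    """Cross MDS quartile with a binary genotype factor into 8 group levels.

    ``genotype_flag`` is carrier (dominant coding) or high-GRS.  Levels are
    numbered 1..8 with level 1 the reference: (Q1, flag 0) by default, or
    (Q4, flag 0) when ``reference_high`` is set (the alternative reading of
    the published table footnotes).  Missing in either factor gives missing.
    """
    quartile = pd.Series(quartile)
    flag = pd.Series(np.asarray(genotype_flag, dtype=float), index=quartile.index)
    q = quartile.to_numpy(dtype=float)
    if reference_high:
        q = 5 - q  # relabel so the reference quartile is level position 1
    group = (q - 1) * 2 + flag + 1
    group[quartile.isna() | flag.isna()] = np.nan
    return pd.Series(group, index=quartile.index, name="group")
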