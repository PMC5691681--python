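"""Mediterranean diet scoring from daily food-component intakes.

The score follows the Trichopoulou-style 8-component scheme: energy-density
adjusted intakes (grams per 1000 kcal) are compared with sex-specific
population medians.  Desirable components (vegetables, legumes, fruits+nuts,
cereals, fish) earn one point at or above the median; undesirable components
(meat & poultry, dairy) earn one point below the median; the MUFA:SFA ratio
earns one point strictly above the median.  Alcohol is not scored.  The
total therefore ranges from 0 (no adherence) to 8 (maximal adherence).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: raw intake columns expected in a diet table (grams/day except energy)
RAW_COLUMNS = [
    "vegetables_g",
    "legumes_g",
    "fruits_g",
    "nuts_g",
    "cereals_g",
    "fish_g",
    "meat_poultry_g",
    "dairy_g",
    "mufa_g",
    "sfa_g",
    "energy_kcal",
]

#: components that score a point at or above the sex-specific median
DESIRABLE = ("vegetables", "legumes", "fruits_nuts", "cereals", "fish")
#: components that score a point below the sex-specific median
UNDESIRABLE = ("meat_poultry", "dairy")
#: the fat-quality ratio scores a point strictly above the median
RATIO = "mufa_sfa_ratio"

ID_COL = "subject_id"


def _components(combine_fruits_nuts: bool) -> list[str]:
    if combine_fruits_nuts:
        return list(DESIRABLE) + list(UNDESIRABLE)
    return [
        "vegetables",
        "legumes",
        "fruits",
        "nuts",
        "cereals",
        "fish",
        "meat_poultry",
        "dairy",
    ]


def read_diet_table(path) -> pd.DataFrame:
    """Read a diet table (CSV or TSV, header required, one row per subject)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in [ID_COL] + RAW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"diet table missing columns: {missing}")
    return df


def energy_adjust(
    profiles: pd.DataFrame, combine_fruits_nuts: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Energy-density adjust raw intakes to grams per 1000 kcal.

    Parameters
    ----------
    profiles
        One row per subject with the columns in :data:`RAW_COLUMNS` plus
        ``subject_id``.
    combine_fruits_nuts
        Pool fruits and nuts into a single scored component (the default
        8-component scheme).  When ``False`` they are adjusted separately,
        yielding a 9-component variant.

    Returns
    -------
    (adjusted, rejected)
        ``adjusted`` has one column per scored component in g/1000 kcal plus
        ``mufa_sfa_ratio`` and a boolean ``ratio_undefined`` flag (SFA = 0).
        ``rejected`` collects rows with non-positive energy or negative
        intakes, with a ``reject_reason`` diagnostic.
    """
    missing = [c for c in RAW_COLUMNS if c not in profiles.columns]
    if missing:
        raise ValueError(f"diet table missing columns: {missing}")

    intake_cols = [c for c in RAW_COLUMNS if c != "energy_kcal"]
    bad_energy = profiles["energy_kcal"] <= 0
    bad_intake = (profiles[intake_cols] < 0).any(axis=1)
    reasons = np.select(
        [bad_energy.to_numpy(), bad_intake.to_numpy()],
        ["non-positive energy_kcal", "negative intake"],
        default="",
    )
    rejected = profiles.loc[bad_energy | bad_intake].copy()
    rejected["reject_reason"] = reasons[(bad_energy | bad_intake).to_numpy()]
    if len(rejected):
        logger.warning("energy_adjust: rejected %d record(s)", len(rejected))

    ok = profiles.loc[~(bad_energy | bad_intake)]
    energy = ok["energy_kcal"].to_numpy(dtype=float)

    adjusted = pd.DataFrame({ID_COL: ok[ID_COL].to_numpy()})
    if combine_fruits_nuts:
        raw = {
            "vegetables": ok["vegetables_g"],
            "legumes": ok["legumes_g"],
            "fruits_nuts": ok["fruits_g"] + ok["nuts_g"],
            "cereals": ok["cereals_g"],
            "fish": ok["fish_g"],
            "meat_poultry": ok["meat_poultry_g"],
            "dairy": ok["dairy_g"],
        }
    else:
        raw = {
            "vegetables": ok["vegetables_g"],
            "legumes": ok["legumes_g"],
            "fruits": ok["fruits_g"],
            "nuts": ok["nuts_g"],
            "cereals": ok["cereals_g"],
            "fish": ok["fish_g"],
            "meat_poultry": ok["meat_poultry_g"],
            "dairy": ok["dairy_g"],
        }
    # raw * 1000 / energy in exactly this order: the contract is exact ratio
    # arithmetic, not multiplication by a precomputed reciprocal
    for name, series in raw.items():
        adjusted[name] = series.to_numpy(dtype=float) * 1000.0 / energy

    sfa = ok["sfa_g"].to_numpy(dtype=float)
    mufa = ok["mufa_g"].to_numpy(dtype=float)
    undefined = sfa == 0
    with np.errstate(divide="ignore"):
        ratio = np.where(undefined, np.inf, mufa / np.where(undefined, 1.0, sfa))
    if undefined.any():
        logger.warning(
            "energy_adjust: %d subject(s) with SFA = 0; MUFA:SFA ratio undefined "
            "(treated as infinite)",
            int(undefined.sum()),
        )
    adjusted[RATIO] = ratio
    adjusted["ratio_undefined"] = undefined
    return adjusted, rejected


def compute_medians(adjusted: pd.DataFrame, sex: pd.Series) -> pd.DataFrame:
    """Sex-specific medians of the adjusted components (the MDS cutoffs).

    ``sex`` is aligned positionally with ``adjusted``.  Returns a DataFrame
    indexed by component with one column per sex level.  Even-n medians are
    the midpoint of the two central order statistics (the standard sample
    median).  Raises if a sex stratum has fewer than two subjects.
    """
    sex = pd.Series(np.asarray(sex), index=adjusted.index)
    comp_cols = [
        c for c in adjusted.columns if c not in (ID_COL, "ratio_undefined")
    ]
    out = {}
    for level in pd.unique(sex):
        stratum = adjusted.loc[sex == level, comp_cols]
        if len(stratum) < 2:
            raise ValueError(
                f"sex stratum {level!r} has {len(stratum)} subject(s); "
                "need at least 2 to compute medians"
            )
        out[level] = stratum.median()
    medians = pd.DataFrame(out)
    medians.index.name = "component"
    return medians


def score_mds(
    adjusted: pd.DataFrame, medians: pd.DataFrame, sex: pd.Series
) -> pd.DataFrame:
    """Score each subject against the sex-specific median table.

    Tie handling follows the scheme exactly: desirable components score 1 at
    or above the median; undesirable components score 1 strictly below it
    (at-median scores 0); the MUFA:SFA ratio scores 1 strictly above it.
    An undefined (infinite) ratio scores 1, since it exceeds any finite
    median; such subjects are flagged upstream.

    Returns one row per subject: per-component binary points and ``mds``.
    """
    sex = pd.Series(np.asarray(sex), index=adjusted.index)
    desirable = [c for c in adjusted.columns if c in DESIRABLE or c in
                 ("fruits", "nuts")]
    undesirable = [c for c in adjusted.columns if c in UNDESIRABLE]
    needed = desirable + undesirable + [RATIO]
    for comp in needed:
        if comp not in medians.index:
            raise ValueError(f"median table is missing component {comp!r}")
    for level in pd.unique(sex):
        if level not in medians.columns:
            raise ValueError(f"median table is missing sex level {level!r}")

    cutoffs = {
        comp: sex.map(medians.loc[comp]).to_numpy(dtype=float) for comp in needed
    }
    points = pd.DataFrame({ID_COL: adjusted[ID_COL].to_numpy()})
    for comp in desirable:
        points[comp] = (adjusted[comp].to_numpy() >= cutoffs[comp]).astype(int)
    for comp in undesirable:
        points[comp] = (adjusted[comp].to_numpy() < cutoffs[comp]).astype(int)
    points[RATIO] = (adjusted[RATIO].to_numpy() > cutoffs[RATIO]).astype(int)
    comp_cols = desirable + undesirable + [RATIO]
    points["mds"] = points[comp_cols].sum(axis=1)
    return points


def score_profiles(
    profiles: pd.DataFrame,
    sex: pd.Series,
    combine_fruits_nuts: bool = True,
    medians: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Convenience pipeline: adjust, derive medians (if not given), score.

    Returns ``(scores, medians, rejected)``.  ``sex`` is aligned positionally
    with ``profiles`` and subset to the accepted rows automatically.
    """
    sex = pd.Series(np.asarray(sex), index=profiles.index)
    adjusted, rejected = energy_adjust(profiles, combine_fruits_nuts)
    keep = profiles.index.difference(rejected.index)
    sex_ok = sex.loc[keep].reset_index(drop=True)
    adjusted = adjusted.reset_index(drop=True)
    if medians is None:
        medians = compute_medians(adjusted, sex_ok)
    scores = score_mds(adjusted, medians, sex_ok)
    return scores, medians, rejected
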