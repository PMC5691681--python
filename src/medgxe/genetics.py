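"""Genotype coding, allele/genotype frequencies, HWE tests, and genetic risk scores.

Dosages count copies of the configured risk (BMI-increasing) allele, so each
genotype is 0, 1 or 2.  The weighted genetic risk score (GRS) for a panel of
n SNPs with literature odds-ratio weights w_i is

    GRS = (sum_i w_i * g_i) * n / sum_i w_i

which ranges from 0 to 2n regardless of the weights; each GRS point
corresponds to one risk allele.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SNPMeta:
    """Per-SNP metadata: identity, risk allele and literature OR weight."""

    snp_id: str
    risk_allele: str
    other_allele: str
    weight_or: float

    def __post_init__(self) -> None:
        if self.risk_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: risk and other allele identical")
        if not self.weight_or > 0:
            raise ValueError(f"{self.snp_id}: weight_or must be positive")


# The six FTO variants of the analysis panel.  The published analysis prints
# only the sum of the literature OR weights (8.18), not the per-SNP values,
# so the default panel carries equal weights 8.18/6; per-SNP weights can be
# supplied through configuration.
PANEL_WEIGHT_SUM = 8.18

DEFAULT_PANEL: tuple[SNPMeta, ...] = tuple(
    SNPMeta(snp_id, risk, other, PANEL_WEIGHT_SUM / 6)
    for snp_id, risk, other in [
        ("rs1121980", "A", "G"),
        ("rs1421085", "C", "T"),
        ("rs9939973", "A", "G"),
        ("rs8050136", "A", "G"),
        ("rs17817449", "G", "T"),
        ("rs3751812", "T", "G"),
    ]
)


class GenotypePanel:
    """Subjects x SNPs risk-allele dosage matrix with panel metadata.

    ``dosages`` is a DataFrame indexed by subject id with one column per
    rsID; entries are 0/1/2 or NaN (missing call).
    """

    def __init__(self, dosages: pd.DataFrame, snps: list[SNPMeta] | tuple[SNPMeta, ...]):
        snps = tuple(snps)
        ids = [s.snp_id for s in snps]
        if list(dosages.columns) != ids:
            dosages = dosages.loc[:, ids]
        vals = dosages.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0)))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        self.dosages = dosages.astype(float)
        self.snps = snps

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def sum_weights(self) -> float:
        return float(sum(s.weight_or for s in self.snps))

    def __len__(self) -> int:
        return len(self.dosages)


@dataclass(frozen=True)
class HWEResult:
    """Pearson chi-square goodness-of-fit to Hardy-Weinberg proportions."""

    chi2: float
    df: int
    p_value: float


def allele_counts(hom_major: int, het: int, hom_minor: int) -> dict:
    """Allele counts and percentages from a genotype-count triple.

    The minor-allele count is 2*hom_minor + het and the major-allele count
    2*hom_major + het; percentages are out of 2n chromosomes.  Rounded
    integer percentages are included for table-style reporting alongside the
    raw proportions.
    """
    counts = np.array([hom_major, het, hom_minor], dtype=float)
    if (counts < 0).any() or (counts != np.round(counts)).any():
        raise ValueError("genotype counts must be non-negative integers")
    n = int(counts.sum())
    if n == 0:
        raise ValueError("all genotype counts are zero")
    minor = 2 * hom_minor + het
    major = 2 * hom_major + het
    return {
        "n": n,
        "minor_count": int(minor),
        "major_count": int(major),
        "minor_freq": minor / (2 * n),
        "major_freq": major / (2 * n),
        "minor_pct": round(minor / (2 * n) * 100),
        "major_pct": round(major / (2 * n) * 100),
    }


def hwe_test(hom_major: int, het: int, hom_minor: int) -> HWEResult:
    """Pearson chi-square test of Hardy-Weinberg equilibrium (1 df).

    Expected counts are n*(p^2, 2pq, q^2) with p the sample major-allele
    frequency.  No continuity correction is applied.  A monomorphic SNP
    yields chi2 = 0 with a warning (the test is degenerate).
    """
    obs = np.array([hom_major, het, hom_minor], dtype=float)
    n = obs.sum()
    if n < 1:
        raise ValueError("need at least one genotyped subject")
    p = (2 * hom_major + het) / (2 * n)
    q = 1 - p
    if p == 0 or q == 0:
        warnings.warn("monomorphic SNP: HWE test degenerate, chi2 = 0")
        return HWEResult(0.0, 1, 1.0)
    exp = n * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return HWEResult(chi2, 1, float(stats.chi2.sf(chi2, 1)))


def genotype_frequency_table(
    panel: GenotypePanel, group: pd.Series | None = None
) -> pd.DataFrame:
    """Per-SNP (per-group) genotype and allele counts with HWE statistics.

    ``group`` labels subjects (e.g. case/control); ``None`` pools everyone.
    Genotype classes are reported with respect to the risk allele: hom_ref
    (0 copies), het (1), hom_risk (2).  Allele counts/percentages and the
    HWE chi-square follow from the genotype counts.
    """
    if group is None:
        group = pd.Series("all", index=panel.dosages.index)
    else:
        group = pd.Series(np.asarray(group), index=panel.dosages.index)
    rows = []
    for snp in panel.snps:
        col = panel.dosages[snp.snp_id]
        for level in pd.unique(group):
            d = col[group == level].dropna()
            n0, n1, n2 = int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())
            # counts of the risk allele vs the other allele
            risk_count = 2 * n2 + n1
            other_count = 2 * n0 + n1
            n = n0 + n1 + n2
            hwe = hwe_test(n0, n1, n2) if n else HWEResult(np.nan, 1, np.nan)
            rows.append(
                {
                    "snp_id": snp.snp_id,
                    "group": level,
                    "n": n,
                    "hom_ref": n0,
                    "het": n1,
                    "hom_risk": n2,
                    "risk_allele": snp.risk_allele,
                    "other_allele": snp.other_allele,
                    "risk_count": risk_count,
                    "other_count": other_count,
                    "risk_pct": round(risk_count / (2 * n) * 100) if n else np.nan,
                    "other_pct": round(other_count / (2 * n) * 100) if n else np.nan,
                    "hwe_chi2": hwe.chi2,
                    "hwe_p": hwe.p_value,
                }
            )
    return pd.DataFrame(rows)


def weighted_grs(panel: GenotypePanel) -> pd.DataFrame:
    """Weighted genetic risk score per subject.

    GRS = (sum_i w_i g_i) * n / sum_i w_i, range [0, 2n].  Subjects with any
    missing dosage get NaN (complete-case policy; no imputation).
    """
    w = np.array([s.weight_or for s in panel.snps])
    g = panel.dosages.to_numpy(dtype=float)
    grs = g @ w * (panel.n_snps / w.sum())
    grs[np.isnan(g).any(axis=1)] = np.nan
    n_missing = int(np.isnan(grs).sum())
    if n_missing:
        logger.warning("weighted_grs: %d subject(s) excluded (missing dosage)", n_missing)
    return pd.DataFrame({"grs": grs}, index=panel.dosages.index)


def dichotomize_grs(grs: pd.Series) -> tuple[pd.Series, float]:
    """Split GRS at the sample median: high = GRS >= median.

    Returns the binary flags (NaN-preserving) and the threshold used.
    """
    vals = pd.Series(grs).dropna()
    if vals.empty:
        raise ValueError("no non-missing GRS values")
    threshold = float(vals.median())
    flags = (pd.Series(grs) >= threshold).astype(float)
    flags[pd.Series(grs).isna()] = np.nan
    return flags, threshold


def dominant_code(dosage):
    """Dominant (carrier) coding: 1 if at least one risk allele, else 0.

    Accepts scalars, arrays, Series or a dosage DataFrame; missing stays
    missing.
    """
    arr = np.asarray(dosage, dtype=float)
    out = np.where(np.isnan(arr), np.nan, (arr >= 1).astype(float))
    if isinstance(dosage, pd.DataFrame):
        return pd.DataFrame(out, index=dosage.index, columns=dosage.columns)
    if isinstance(dosage, pd.Series):
        return pd.Series(out, index=dosage.index, name=dosage.name)
    if np.isscalar(dosage):
        return float(out)
    return out


def read_dosage_tsv(path, snps: list[SNPMeta] | tuple[SNPMeta, ...] = DEFAULT_PANEL) -> GenotypePanel:
    """Read a TSV dosage matrix (rows = subjects, columns = rsIDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [s.snp_id for s in snps if s.snp_id not in df.columns]
    if missing:
        raise ValueError(f"dosage matrix missing SNPs: {missing}")
    return GenotypePanel(df, snps)


def read_vcf(path, snps: list[SNPMeta] | tuple[SNPMeta, ...] = DEFAULT_PANEL) -> GenotypePanel:
    """Read genotypes from a VCF (GT field only) into risk-allele dosages.

    Only biallelic diploid records whose ID matches a panel SNP are used.
    Dosage is the count of the configured risk allele among the two called
    alleles; half-calls and no-calls are missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    by_id = {s.snp_id: s for s in snps}
    data: dict[str, np.ndarray] = {}
    for rec in vcf:
        meta = by_id.get(rec.ID)
        if meta is None:
            continue
        if len(rec.ALT) != 1:
            raise ValueError(f"{rec.ID}: only biallelic records are accepted")
        alleles = {rec.REF: "ref", rec.ALT[0]: "alt"}
        if meta.risk_allele not in alleles or meta.other_allele not in alleles:
            raise ValueError(
                f"{rec.ID}: VCF alleles {rec.REF}/{rec.ALT[0]} do not match "
                f"panel alleles {meta.risk_allele}/{meta.other_allele}"
            )
        risk_is_alt = alleles[meta.risk_allele] == "alt"
        dos = np.full(len(samples), np.nan)
        for i, gt in enumerate(rec.genotypes):
            calls = [a for a in gt[:-1] if a >= 0]
            if len(calls) != 2:  # half-call or no-call -> missing
                continue
            n_alt = sum(1 for a in calls if a == 1)
            dos[i] = n_alt if risk_is_alt else 2 - n_alt
        data[rec.ID] = dos
    missing = [s.snp_id for s in snps if s.snp_id not in data]
    if missing:
        raise ValueError(f"VCF is missing panel SNPs: {missing}")
    df = pd.DataFrame(data, index=samples)[[s.snp_id for s in snps]]
    return GenotypePanel(df, snps)
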