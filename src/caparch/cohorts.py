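"""Published reference tables for the pan-African prostate-cancer study.

These small tables describe the multi-center case/control resource
(MADCaP Network sites in Senegal, Ghana, Nigeria and South Africa plus
the Uganda and Ghana prostate-cancer studies) whose structure the
synthetic scenarios emulate: per-center recruitment counts, case Grade
Group (Gleason-derived aggressiveness) counts, and the lead
genome-wide-significant SNPs with their odds ratios and per-region
control effect-allele frequencies.  They serve as fixed inputs for
consistency checks and worked examples -- regional totals, private
allele classification, locus counting -- not as fitted data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .popgen import classify_private

__all__ = [
    "recruitment_table",
    "cohort_totals",
    "regional_totals",
    "grade_group_table",
    "aggressive_case_percent",
    "lead_snp_table",
    "lead_locus_count",
    "private_lead_alleles",
]

# (center, genotyping platform, region, cases, controls)
_RECRUITMENT = [
    ("Senegal: Hopital General de Grand Yoff", "MADCaP Array", "West", 223, 228),
    ("Ghana: 37 Military Hospital", "MADCaP Array", "West", 210, 217),
    ("Ghana: Korle-Bu Teaching Hospital", "MADCaP Array", "West", 372, 336),
    ("Ghana Prostate Study", "Illumina Omni 5 Array", "West", 623, 620),
    ("Nigeria: University College Hospital", "MADCaP Array", "West", 190, 177),
    ("Nigeria: University of Abuja Teaching Hospital", "MADCaP Array", "West", 162, 161),
    ("Uganda Prostate Cancer Study", "OncoArray", "East", 548, 471),
    ("Uganda Prostate Cancer Study", "H3Africa Array", "East", 287, 196),
    ("South Africa: Stellenbosch University", "MADCaP Array", "South", 183, 132),
    ("South Africa: University of the Witwatersrand", "MADCaP Array", "South", 1165, 971),
]

# (grade group, case count); Grade Group 1 = Gleason <= 6,
# 2+3 = Gleason 7, 4+5 = Gleason >= 8.
_GRADE_GROUPS = [
    ("1", 712),
    ("2+3", 1390),
    ("4+5", 1394),
    ("unavailable", 467),
]

# Lead genome-wide-significant SNPs: ID, chrom, position (hg38, 1-based),
# effect allele, OR with 95% CI, p-value, control effect-allele
# frequencies in West, East, South Africa and Europe.
_LEAD_SNPS = [
    ("rs72725854", "chr8", 127062570, "T", 1.96, 1.76, 2.17, 5.08e-37, 0.068, 0.062, 0.081, 0.00),
    ("rs72725879", "chr8", 127091724, "C", 1.42, 1.32, 1.52, 5.21e-24, 0.657, 0.626, 0.703, 0.802),
    ("rs7833560", "chr8", 127059774, "T", 1.28, 1.20, 1.37, 5.70e-14, 0.481, 0.491, 0.425, 0.773),
    ("rs116202395", "chr8", 126962668, "C", 1.82, 1.55, 2.14, 6.14e-13, 0.964, 0.969, 0.987, 1.000),
    ("rs11228580", "chr11", 69234875, "C", 1.32, 1.22, 1.44, 9.26e-12, 0.169, 0.157, 0.207, 0.176),
    ("rs59825493", "chr8", 127130257, "T", 1.28, 1.19, 1.37, 1.01e-11, 0.762, 0.723, 0.700, 1.000),
    ("rs339321", "chr6", 116871027, "G", 1.32, 1.22, 1.43, 1.07e-11, 0.779, 0.755, 0.767, 0.729),
    ("rs16902003", "chr8", 127175810, "C", 1.43, 1.29, 1.59, 2.03e-11, 0.076, 0.115, 0.085, 0.00),
    ("rs116719898", "chr8", 127157082, "C", 1.48, 1.32, 1.67, 4.63e-11, 0.934, 0.894, 0.948, 0.999),
    ("rs16902043", "chr8", 127219700, "G", 1.26, 1.17, 1.36, 2.49e-10, 0.215, 0.260, 0.314, 0.341),
    ("rs57010632", "chr8", 127099472, "G", 1.23, 1.15, 1.31, 1.08e-9, 0.515, 0.511, 0.391, 0.036),
    ("rs71520637", "chr8", 127188945, "C", 1.38, 1.24, 1.53, 1.44e-9, 0.895, 0.924, 0.923, 0.999),
    ("rs13254738", "chr8", 127092098, "A", 1.24, 1.16, 1.33, 1.82e-9, 0.347, 0.306, 0.355, 0.665),
    ("rs114705582", "chr8", 126887955, "C", 1.73, 1.44, 2.09, 5.85e-9, 0.027, 0.012, 0.02, 0.000),
    ("rs61732842", "chr8", 127087290, "G", 1.41, 1.25, 1.59, 3.09e-8, 0.934, 0.962, 0.917, 1.000),
]


def recruitment_table() -> pd.DataFrame:
    """Per-center recruitment counts with region assignments."""
    return pd.DataFrame(_RECRUITMENT, columns=["center", "platform", "region",
                                               "cases", "controls"])


def cohort_totals() -> tuple[int, int]:
    """Study-wide (cases, controls), summed over recruitment centers."""
    df = recruitment_table()
    return int(df["cases"].sum()), int(df["controls"].sum())


def regional_totals() -> pd.DataFrame:
    """Cases and controls per region (West/East/South), summed over centers."""
    return (recruitment_table()
            .groupby("region", sort=False)[["cases", "controls"]]
            .sum())


def grade_group_table() -> pd.DataFrame:
    """Case counts by Grade Group (1 least to 4+5 most aggressive)."""
    return pd.DataFrame(_GRADE_GROUPS, columns=["grade_group", "cases"])


def aggressive_case_percent() -> float:
    """Percent of all cases in Grade Groups 4-5 (Gleason >= 8)."""
    gg = grade_group_table().set_index("grade_group")["cases"]
    total_cases, _ = cohort_totals()
    return 100.0 * float(gg["4+5"]) / total_cases


def lead_snp_table() -> pd.DataFrame:
    """Lead SNP summary statistics with derived log-OR scale columns.

    ``BETA`` is the log odds ratio and ``SE`` is recovered from the
    95% CI as ``(ln hi - ln lo) / (2 x 1.96)``.
    """
    df = pd.DataFrame(_LEAD_SNPS, columns=[
        "ID", "CHR", "POS", "EA", "OR", "OR_LO", "OR_HI", "P",
        "FREQ_West", "FREQ_East", "FREQ_South", "FREQ_EUR"])
    df["BETA"] = np.log(df["OR"])
    df["SE"] = (np.log(df["OR_HI"]) - np.log(df["OR_LO"])) / (2 * 1.959963984540054)
    return df


def lead_locus_count(window: int = 1_000_000) -> int:
    """Number of distinct loci among the lead SNPs.

    SNPs on the same chromosome within ``window`` bp of the previous
    SNP (after sorting) are merged into one locus.
    """
    df = lead_snp_table().sort_values(["CHR", "POS"])
    loci = 0
    for _, grp in df.groupby("CHR"):
        pos = grp["POS"].to_numpy()
        loci += 1 + int(np.sum(np.diff(pos) > window))
    return loci


def private_lead_alleles(maf_threshold: float = 0.01) -> pd.DataFrame:
    """Privacy classification of each lead SNP with Africa as target.

    A SNP is private to Africa when it is polymorphic in every African
    region but effectively monomorphic (MAF <= threshold) in Europe at
    the table's printed precision.
    """
    df = lead_snp_table()
    classes = []
    for _, row in df.iterrows():
        african_maf = min(min(row[c], 1 - row[c])
                          for c in ("FREQ_West", "FREQ_East", "FREQ_South"))
        cls = classify_private({"Africa": african_maf, "EUR": row["FREQ_EUR"]},
                               target="Africa", maf_threshold=maf_threshold)
        classes.append(cls)
    out = df[["ID", "FREQ_West", "FREQ_East", "FREQ_South", "FREQ_EUR"]].copy()
    out["classification"] = classes
    return out
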