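"""Published summary tables for the TRPC6 / chemotherapy-related heart
failure association study that this package re-implements generically.

Individual-level genotypes for the underlying cohorts (a breast-cancer
clinical trial and a clinic biobank) are not public; what is public are the
summary tables: per-group minor-allele frequencies for the 16-SNP genotyping
panel, the case/control association table, demographic count tables, and a
handful of rare-variant frequencies.  Those printed numbers are the only
ground truth available, so they are embedded here as reference fixtures.
They drive two things:

* count reconstruction — turning a printed 3-decimal frequency back into an
  integer carrier/allele count at the known group size, so the association
  tests can be run on data equivalent to what was published;
* arithmetic self-checks — recomputing every percentage and frequency from
  the embedded counts and verifying it matches the printed value.
"""

from __future__ import annotations

import pandas as pd

#: Study group sizes (number of genotyped samples per group).
GROUP_SIZES = {"chemo_no_hf": 282, "hf_no_chemo": 690, "crhf_case": 38}

#: CRHF association table: per-group minor-allele frequency and the
#: published composite-null bootstrap p-value.  Frequencies are printed to
#: three decimals; groups are chemotherapy-without-HF (n=282), HF-without-
#: chemotherapy (n=690) and chemotherapy-related HF cases (n=38).
CRHF_TABLE = pd.DataFrame(
    [
        ("rs36111323", "TRPC6", "A", 0.082, 0.144, 0.066, 0.648),
        ("rs767086724", "TRPC6", "C", 0.000, 0.000, 0.013, 0.014),
        ("rs11224819", "TRPC6", "C", 0.121, 0.082, 0.079, 0.325),
        ("rs4509717", "TRPC6", "G", 0.478, 0.415, 0.368, 0.090),
        ("rs12280648", "TRPC6", "G", 0.247, 0.259, 0.237, 0.797),
        ("rs77679196", "TRPC6", "A", 0.007, 0.004, 0.026, 0.126),
        ("rs57242572", "TRPC6", "T", 0.013, 0.015, 0.053, 0.031),
        ("rs2513192", "TRPC6", "A", 0.259, 0.283, 0.276, 0.725),
        ("rs1938858", "TRPC6", "T", 0.188, 0.192, 0.224, 0.405),
        ("rs61918162", "TRPC6", "C", 0.394, 0.354, 0.276, 0.065),
        ("rs11224953", "TRPC6", "G", 0.051, 0.037, 0.053, 0.866),
        ("rs11224983", "TRPC6", "A", 0.047, 0.038, 0.066, 0.451),
        ("rs55756123", "LDB2", "T", 0.007, 0.006, 0.040, 0.030),
        ("rs4305714", "intergenic_6p22.3", "T", 0.216, 0.222, 0.263, 0.302),
        ("rs62568637", "BRINP1", "A", 0.013, 0.009, 0.026, 0.328),
        ("rs707557", "RAB22A", "T", 0.399, 0.431, 0.355, 0.473),
    ],
    columns=[
        "snp", "locus", "minor_allele",
        "freq_chemo_no_hf", "freq_hf_no_chemo", "freq_crhf_case",
        "p_published",
    ],
)

#: General heart-failure association table (cases = HF never exposed to the
#: cardiotoxic chemotherapy, n=690; controls = chemotherapy without HF,
#: n=282).  Odds ratios are sex/antihypertensive-adjusted additive-model
#: logistic estimates; the monomorphic rare variant has no estimate.
HF_TABLE = pd.DataFrame(
    [
        ("rs36111323", "TRPC6", "A", 0.082, 0.144, 2.01, 0.002),
        ("rs767086724", "TRPC6", "C", 0.000, 0.000, None, None),
        ("rs11224819", "TRPC6", "C", 0.121, 0.082, 0.69, 0.093),
        ("rs4509717", "TRPC6", "G", 0.478, 0.415, 0.75, 0.034),
        ("rs12280648", "TRPC6", "G", 0.247, 0.259, 1.11, 0.516),
        ("rs77679196", "TRPC6", "A", 0.007, 0.004, 0.90, 0.915),
        ("rs57242572", "TRPC6", "T", 0.013, 0.015, 2.48, 0.173),
        ("rs2513192", "TRPC6", "A", 0.259, 0.283, 1.21, 0.216),
        ("rs1938858", "TRPC6", "T", 0.188, 0.192, 1.01, 0.977),
        ("rs61918162", "TRPC6", "C", 0.394, 0.354, 0.80, 0.120),
        ("rs11224953", "TRPC6", "G", 0.051, 0.037, 0.80, 0.486),
        ("rs11224983", "TRPC6", "A", 0.047, 0.038, 0.85, 0.583),
        ("rs55756123", "LDB2", "T", 0.007, 0.006, 1.37, 0.718),
        ("rs4305714", "intergenic_6p22.3", "T", 0.216, 0.222, 1.14, 0.417),
        ("rs62568637", "BRINP1", "A", 0.013, 0.009, 0.71, 0.552),
        ("rs707557", "RAB22A", "T", 0.399, 0.431, 1.17, 0.251),
    ],
    columns=[
        "snp", "locus", "minor_allele",
        "freq_chemo_no_hf", "freq_hf_no_chemo",
        "or_published", "p_published",
    ],
)

#: CRHF case-group demographics (cardiologist-reviewed cases; 4 male,
#: 34 female).  Race counts with published one-decimal percentages.
CASE_RACE_COUNTS = {
    "male": {"White": 4, "Black/African American": 0, "Asian": 0, "Mixed": 0},
    "female": {"White": 29, "Black/African American": 4, "Asian": 1, "Mixed": 0},
}

#: Chemotherapy-no-HF control group: cancer-site records per sex.  The
#: published percentage denominator is the column sum of site *records*
#: (16 patients had cancer at multiple sites), not the patient count.
CHEMO_CONTROL_SITE_COUNTS = {
    "male": {
        "Breast": 3, "Blood": 24, "Sarcoma": 8, "Gastrointestinal": 6,
        "Ovarian": 0, "Lung": 3, "Bladder": 2, "Skin": 1, "Prostate": 3,
        "Unknown": 2, "Neuroendocrine": 1, "Head/neck": 1, "Testicular": 2,
        "Liver": 3, "Metastasis to lymph node axilla and upper limb": 0,
    },
    "female": {
        "Breast": 168, "Blood": 20, "Sarcoma": 14, "Gastrointestinal": 1,
        "Ovarian": 18, "Lung": 5, "Bladder": 2, "Skin": 3, "Prostate": 0,
        "Unknown": 9, "Neuroendocrine": 2, "Head/neck": 1, "Testicular": 2,
        "Liver": 3, "Metastasis to lymph node axilla and upper limb": 1,
    },
}

#: HF-no-chemotherapy control group: prior cancer-site records per sex.
HF_CONTROL_SITE_COUNTS = {
    "male": {
        "Skin": 129, "Prostate": 73, "Breast": 0, "Blood": 19,
        "Gastrointestinal": 23, "Kidney": 13, "Lung": 14, "Bladder": 11,
        "Ovarian": 0, "Neuroendocrine": 10, "Sarcoma": 3, "Endometrial": 0,
        "Cervical": 0, "Pancreas": 3, "Brain": 1, "Head/neck": 2,
        "Uterus": 0, "Heart": 0, "Lynch syndrome": 1,
    },
    "female": {
        "Skin": 91, "Prostate": 0, "Breast": 45, "Blood": 16,
        "Gastrointestinal": 9, "Kidney": 4, "Lung": 3, "Bladder": 5,
        "Ovarian": 11, "Neuroendocrine": 2, "Sarcoma": 5, "Endometrial": 7,
        "Cervical": 6, "Pancreas": 2, "Brain": 2, "Head/neck": 4,
        "Uterus": 2, "Heart": 1, "Lynch syndrome": 0,
    },
}

#: Rare missense variant N338S (rs767086724) population reference counts:
#: (alt-allele observations, genomes).  Frequencies are allele-level,
#: i.e. count / (2 * genomes).
N338S_REFERENCE_COUNTS = {
    "gnomad_overall": (7, 141_283),
    "gnomad_african": (6, 12_460),
    "gnomad_latino": (1, 17_707),
    # one heterozygous carrier among the four Black/African American
    # patients in the 38-case sequencing screen
    "screening_black_patients": (1, 4),
}

#: Published frequencies the counts above must reproduce, as printed
#: (kept as strings so the printed precision is known).
N338S_REFERENCE_FREQS = {
    "gnomad_overall": "0.000025",
    "gnomad_african": "0.00024",
    "gnomad_latino": "0.000028",
    "screening_black_patients": "0.125",
}

#: Genotyping QC: duplicate-sample concordance design.
QC_N_DUPLICATE_PAIRS = 22
QC_N_SNPS = 16
QC_N_COMPARISONS = 352  # 22 pairs x 16 SNPs, complete data
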