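"""Synthetic cohorts, reference panels and printed-table count fixtures.

No individual-level data from the chemotherapy-related heart failure (CRHF)
cohorts are public, so every downstream stage is exercised on synthetic data
generated here with the statistical structure the analysis assumes:

* genotypes — independent loci in Hardy–Weinberg equilibrium at per-group
  alternate-allele frequencies (the published per-group minor-allele
  frequencies by default);
* covariates — sex, age, antihypertensive use drawn per group, independent
  of genotype by default (per-group covariate models are the confounding
  hook: making them differ across groups induces covariate–group
  confounding);
* phenotype — ΔLVEF (lowest follow-up minus baseline left-ventricular
  ejection fraction, in percentage points) as an additive SNP model plus
  Gaussian noise;
* reference panel — paired genotypes and expression where expression is a
  sparse linear function of local dosages plus noise, standing in for a
  measured-expression training set for TWAS weight models.

Determinism: every generator takes a seed; :func:`simulate_cohort` derives
per-stage child seeds from the master seed by fixed offsets so stages can be
rerun independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import tables
from .genotype_io import GenotypeMatrix, VARIANT_COLUMNS

# fixed child-seed offsets, so each stage is independently re-runnable
_SEED_OFFSET_GENOTYPES = 1
_SEED_OFFSET_PHENOTYPES = 2
_SEED_OFFSET_MISSING = 3
_SEED_MOD = 2**31 - 1


class RoundTripWarning(UserWarning):
    """A reconstructed count does not round back to the printed frequency."""


@dataclass
class SnpSpec:
    """One simulated variant: id, metadata, per-group alt-allele frequency."""

    variant_id: str
    freqs: Mapping[str, float]
    chrom: str = "11"
    pos: int = 0
    ref: str = "A"
    alt: str = "G"
    locus: str = "TRPC6"

    def __post_init__(self) -> None:
        for g, f in self.freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(
                    f"{self.variant_id}: frequency {f} for group {g!r} outside [0, 1]"
                )


@dataclass
class CovariateModel:
    """Per-group covariate distributions (sex, antihypertensive use, age)."""

    antihtn_prob: Mapping[str, float]
    female_prob: Mapping[str, float]
    age_mean: Mapping[str, float]
    age_sd: Mapping[str, float]
    baseline_lvef_mean: float = 62.0
    baseline_lvef_sd: float = 5.0

    def __post_init__(self) -> None:
        for name, m in (("antihtn_prob", self.antihtn_prob),
                        ("female_prob", self.female_prob)):
            for g, p in m.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}[{g!r}] = {p} outside [0, 1]")
        if any(sd < 0 for sd in self.age_sd.values()) or self.baseline_lvef_sd < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass
class PhenotypeModel:
    """Additive genetic model for ΔLVEF (percentage points of LVEF)."""

    intercept: float = -4.0
    effects: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 7.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class CohortSpec:
    """Full description of one synthetic three-group cohort."""

    group_sizes: Mapping[str, int]
    snp_specs: Sequence[SnpSpec]
    covariate_model: CovariateModel
    phenotype_model: PhenotypeModel
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")


@dataclass
class ReferencePanelSpec:
    """Reference panel: genotypes plus expression for weight training."""

    n_samples: int = 159
    n_snps: int = 50
    causal_weights: Mapping[str, float] = field(default_factory=dict)
    expression_noise_sd: float = 1.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    variant_prefix: str = "panel_snp"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.expression_noise_sd < 0:
            raise ValueError("expression_noise_sd must be >= 0")

    def variant_ids(self) -> list[str]:
        width = len(str(self.n_snps))
        return [f"{self.variant_prefix}_{i:0{width}d}" for i in range(self.n_snps)]


def simulate_genotypes(
    snp_specs: Sequence[SnpSpec],
    group_sizes: Mapping[str, int],
    seed: int,
    missing_rate: float = 0.0,
) -> tuple[GenotypeMatrix, pd.Series]:
    """Draw Hardy–Weinberg genotypes per group.

    Each sample's dosage at each variant is Binomial(2, f_group).  Returns
    the matrix and a sample-id-indexed Series of group labels.
    """
    if any(n < 0 for n in group_sizes.values()):
        raise ValueError("group sizes must be >= 0")
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sample_ids: list[str] = []
    groups: list[str] = []
    blocks = []
    for g, n in group_sizes.items():
        ids = [f"{g}_{i:04d}" for i in range(n)]
        sample_ids += ids
        groups += [g] * n
        freqs = np.array([s.freqs[g] for s in snp_specs])
        blocks.append(rng.binomial(2, freqs, size=(n, len(snp_specs))).astype(float))
    dosages = np.vstack(blocks) if blocks else np.zeros((0, len(snp_specs)))
    if missing_rate > 0:
        miss = np.random.default_rng(
            (seed + _SEED_OFFSET_MISSING) % _SEED_MOD
        ).random(dosages.shape) < missing_rate
        dosages[miss] = np.nan
    variants = pd.DataFrame(
        [
            (s.variant_id, s.chrom, s.pos if s.pos else 10_000 + j,
             s.ref, s.alt, s.locus)
            for j, s in enumerate(snp_specs)
        ],
        columns=VARIANT_COLUMNS,
    )
    gm = GenotypeMatrix(sample_ids, variants, dosages)
    return gm, pd.Series(groups, index=sample_ids, name="group")


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    groups: pd.Series,
    covariate_model: CovariateModel,
    phenotype_model: PhenotypeModel,
    seed: int,
) -> pd.DataFrame:
    """Draw covariates and ΔLVEF for an existing genotype matrix.

    ΔLVEF = intercept + Σ effect·dosage + Normal(0, noise_sd); covariates
    are drawn per group and do not enter the phenotype (genotype-independent
    covariates are the default study condition).
    """
    rng = np.random.default_rng(seed)
    n = genotypes.n_samples
    glab = groups.loc[genotypes.sample_ids].to_numpy()
    p_f = np.array([covariate_model.female_prob[g] for g in glab])
    p_h = np.array([covariate_model.antihtn_prob[g] for g in glab])
    mu_a = np.array([covariate_model.age_mean[g] for g in glab])
    sd_a = np.array([covariate_model.age_sd[g] for g in glab])
    sex = np.where(rng.random(n) < p_f, "female", "male")
    antihtn = rng.random(n) < p_h
    age = rng.normal(mu_a, sd_a)
    baseline = rng.normal(
        covariate_model.baseline_lvef_mean, covariate_model.baseline_lvef_sd, n
    )
    delta = np.full(n, float(phenotype_model.intercept))
    for vid, eff in phenotype_model.effects.items():
        d = genotypes.dosage_vector(vid)  # KeyError if absent
        if np.isnan(d).any():
            raise ValueError(
                f"causal variant {vid} has missing genotypes; cannot form phenotype"
            )
        delta = delta + eff * d
    delta = delta + rng.normal(0.0, phenotype_model.noise_sd, n)
    return pd.DataFrame(
        {
            "sample_id": genotypes.sample_ids,
            "group": glab,
            "sex": sex,
            "age": age,
            "antihtn": antihtn,
            "baseline_lvef": baseline,
            "delta_lvef": delta,
        }
    )


def simulate_cohort(spec: CohortSpec) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Generate a full cohort (genotypes + sample table) from a spec."""
    gm, groups = simulate_genotypes(
        spec.snp_specs,
        spec.group_sizes,
        seed=(spec.seed + _SEED_OFFSET_GENOTYPES) % _SEED_MOD,
        missing_rate=spec.missing_rate,
    )
    samples = simulate_phenotypes(
        gm, groups, spec.covariate_model, spec.phenotype_model,
        seed=(spec.seed + _SEED_OFFSET_PHENOTYPES) % _SEED_MOD,
    )
    return gm, samples


def simulate_reference_panel(
    spec: ReferencePanelSpec,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Genotype + expression reference panel for weight training.

    Per-SNP allele frequencies are drawn uniformly from ``maf_range``;
    expression = Σ weight·dosage + Normal(0, expression_noise_sd).
    """
    rng = np.random.default_rng(spec.seed)
    vids = spec.variant_ids()
    unknown = set(spec.causal_weights) - set(vids)
    if unknown:
        raise ValueError(f"causal_weights refer to unknown variants {sorted(unknown)}")
    freqs = rng.uniform(*spec.maf_range, size=spec.n_snps)
    dosages = rng.binomial(2, freqs, size=(spec.n_samples, spec.n_snps)).astype(float)
    w = np.array([spec.causal_weights.get(v, 0.0) for v in vids])
    expr = dosages @ w + rng.normal(0.0, spec.expression_noise_sd, spec.n_samples)
    variants = pd.DataFrame(
        [(v, "11", 20_000 + j, "A", "G", "panel") for j, v in enumerate(vids)],
        columns=VARIANT_COLUMNS,
    )
    sample_ids = [f"ref_{i:04d}" for i in range(spec.n_samples)]
    return GenotypeMatrix(sample_ids, variants, dosages), expr


def reconstruct_counts_from_freq(
    freq: float, n_samples: int, level: str = "allele"
) -> int:
    """Back-compute an integer event count from a printed 3-decimal frequency.

    ``level='allele'`` uses denominator 2·n_samples (alt-allele count),
    ``level='carrier'`` uses n_samples (carrier count).  If the nearest
    count does not round back to the printed value a
    :class:`RoundTripWarning` is emitted — the printed table may have used a
    different denominator (e.g. after excluding missing genotypes).
    """
    if not 0.0 <= freq <= 1.0:
        raise ValueError(f"frequency {freq} outside [0, 1]")
    if n_samples <= 0:
        raise ValueError("n_samples must be > 0")
    if level not in ("allele", "carrier"):
        raise ValueError(f"level must be 'allele' or 'carrier', got {level!r}")
    denom = 2 * n_samples if level == "allele" else n_samples
    count = int(round(freq * denom))
    if round(count / denom, 3) != round(freq, 3):
        warnings.warn(
            f"count {count}/{denom} back-computes to {count / denom:.4f}, "
            f"which does not round to the printed frequency {freq:.3f}",
            RoundTripWarning,
            stacklevel=2,
        )
    return count


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The default study conditions: published group sizes and frequencies.

    Group sizes 38 / 282 / 690 and per-group SNP frequencies follow the
    published genotyping panel.  Covariate distributions follow the
    published demographics (sex ratios and ages per group); antihypertensive
    use is higher in the heart-failure groups.  The default phenotype model
    puts a −3 LVEF-point-per-allele effect on rs57242572 so the demo
    pipeline has signal to find.
    """
    snp_specs = [
        SnpSpec(
            variant_id=row.snp,
            freqs={
                "chemo_no_hf": row.freq_chemo_no_hf,
                "hf_no_chemo": row.freq_hf_no_chemo,
                "crhf_case": row.freq_crhf_case,
            },
            chrom={"TRPC6": "11", "LDB2": "4", "BRINP1": "9",
                   "RAB22A": "20"}.get(row.locus, "6"),
            locus=row.locus,
        )
        for row in tables.CRHF_TABLE.itertuples()
    ]
    cov = CovariateModel(
        antihtn_prob={"crhf_case": 0.5, "chemo_no_hf": 0.3, "hf_no_chemo": 0.6},
        female_prob={
            "crhf_case": 34 / 38,
            "chemo_no_hf": 237 / 282,
            "hf_no_chemo": 306 / 690,
        },
        age_mean={"crhf_case": 59.6, "chemo_no_hf": 58.7, "hf_no_chemo": 75.1},
        age_sd={"crhf_case": 12.0, "chemo_no_hf": 13.7, "hf_no_chemo": 10.8},
    )
    pheno = PhenotypeModel(
        intercept=-4.0, effects={"rs57242572": -3.0}, noise_sd=7.0
    )
    kwargs = dict(
        group_sizes=dict(tables.GROUP_SIZES),
        snp_specs=snp_specs,
        covariate_model=cov,
        phenotype_model=pheno,
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortSpec(**kwargs)
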