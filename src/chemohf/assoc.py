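"""Per-variant association tests: additive logistic, crude ORs, linear ΔLVEF.

Covers the two standard association analyses around the composite-null
test: case/control logistic regression per variant under an additive model
(dosage 0/1/2 with sex and antihypertensive-use covariates — the general
heart-failure comparison), and the GWAS-style linear model of ΔLVEF on
dosage with the standard covariate set.  Crude allele-count odds ratios
with Woolf confidence intervals are provided as a diagnostic companion to
the adjusted estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genotype_io import GenotypeMatrix

logger = logging.getLogger(__name__)

try:  # statsmodels moved this exception between versions
    from statsmodels.tools.sm_exceptions import PerfectSeparationError
except ImportError:  # pragma: no cover
    class PerfectSeparationError(Exception):
        pass


@dataclass
class LogisticResult:
    """Additive-model logistic fit for one variant.

    ``or_`` is exp(beta) per alternate allele; ``p`` is the two-sided
    normal tail of the Wald z.  Non-convergence, separation or a constant
    dosage yield a flagged result (``ok = False``) with NaN estimates
    rather than a crash.
    """

    variant_id: str
    beta: float
    se: float
    or_: float
    wald_z: float
    p: float
    n_used: int
    covariates: list[str] = field(default_factory=list)
    ok: bool = True
    note: str = ""


@dataclass(frozen=True)
class TwoByTwo:
    """Allele-count 2x2 table: a/b = case alt/ref, c/d = control alt/ref."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be >= 0")

    @classmethod
    def from_frequencies(
        cls, f_case: float, n_case: int, f_ctrl: float, n_ctrl: int
    ) -> "TwoByTwo":
        """Build allele counts from printed frequencies and sample sizes."""
        a = int(round(f_case * 2 * n_case))
        c = int(round(f_ctrl * 2 * n_ctrl))
        return cls(a, 2 * n_case - a, c, 2 * n_ctrl - c)


def additive_logistic(
    dosages: np.ndarray,
    labels: np.ndarray,
    covariates: pd.DataFrame | None = None,
    variant_id: str = "variant",
) -> LogisticResult:
    """Logistic regression of case status on allele dosage (additive model).

    ``labels`` is boolean/0-1 case status.  Complete cases only; both
    outcome classes must be present.  The Wald test is on the dosage
    coefficient.
    """
    df = pd.DataFrame({"dosage": np.asarray(dosages, float),
                       "y": np.asarray(labels).astype(float)})
    covnames: list[str] = []
    if covariates is not None:
        cov = covariates.reset_index(drop=True).astype(float)
        covnames = list(cov.columns)
        df = pd.concat([df, cov], axis=1)
    df = df.dropna()
    if df["y"].nunique() < 2:
        raise ValueError("both outcome classes must be present")

    def flagged(note: str) -> LogisticResult:
        logger.warning("%s: %s", variant_id, note)
        return LogisticResult(
            variant_id, np.nan, np.nan, np.nan, np.nan, np.nan,
            n_used=len(df), covariates=covnames, ok=False, note=note,
        )

    if df["dosage"].nunique() < 2:
        return flagged("constant dosage; no estimate (monomorphic variant)")
    X = sm.add_constant(df.drop(columns="y"), has_constant="add")
    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            # separation/non-convergence become flagged results below
            warnings.simplefilter("ignore")
            fit = sm.Logit(df["y"], X).fit(disp=0, maxiter=100)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        return flagged(f"separation or singular fit: {exc}")
    if not fit.mle_retvals.get("converged", False):
        return flagged("IRLS did not converge")
    se = float(fit.bse["dosage"])
    if not np.isfinite(se) or se > 50:
        return flagged("quasi-separation: unstable standard error")
    beta = float(fit.params["dosage"])
    z = beta / se
    return LogisticResult(
        variant_id=variant_id,
        beta=beta,
        se=se,
        or_=float(np.exp(beta)),
        wald_z=z,
        p=float(2 * stats.norm.sf(abs(z))),
        n_used=int(fit.nobs),
        covariates=covnames,
    )


def crude_allele_or(t: TwoByTwo) -> tuple[float, tuple[float, float]]:
    """Crude allele-count odds ratio with Woolf 95% CI.

    Any zero cell triggers the Haldane–Anscombe correction (0.5 added to
    all four cells).
    """
    a, b, c, d = (float(x) for x in (t.a, t.b, t.c, t.d))
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(or_) + np.array([-1, 1]) * 1.96 * se)
    return float(or_), (float(lo), float(hi))


@dataclass
class LinearResult:
    """Covariate-adjusted OLS slope of ΔLVEF on dosage."""

    variant_id: str
    beta: float
    se: float
    t: float
    p: float
    n_used: int
    covariates: list[str] = field(default_factory=list)


def linear_lvef_assoc(
    dosages: np.ndarray,
    delta_lvef: np.ndarray,
    covariates: pd.DataFrame | None = None,
    variant_id: str = "variant",
) -> LinearResult:
    """OLS of ΔLVEF on allele dosage with covariate adjustment."""
    df = pd.DataFrame({"dosage": np.asarray(dosages, float),
                       "delta_lvef": np.asarray(delta_lvef, float)})
    covnames: list[str] = []
    if covariates is not None:
        cov = covariates.reset_index(drop=True).astype(float)
        covnames = list(cov.columns)
        df = pd.concat([df, cov], axis=1)
    df = df.dropna()
    X = sm.add_constant(df.drop(columns="delta_lvef"), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        from .twas import _collinear_columns

        bad = _collinear_columns(X)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    fit = sm.OLS(df["delta_lvef"], X).fit()
    return LinearResult(
        variant_id=variant_id,
        beta=float(fit.params["dosage"]),
        se=float(fit.bse["dosage"]),
        t=float(fit.tvalues["dosage"]),
        p=float(fit.pvalues["dosage"]),
        n_used=int(fit.nobs),
        covariates=covnames,
    )


class CaseControlScan:
    """Additive logistic association of every variant in a matrix.

    Mirrors the general heart-failure comparison: one group is declared
    cases, another controls, and each variant is tested by additive-model
    logistic regression with the requested covariates (default sex and
    antihypertensive use).
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        samples: pd.DataFrame,
        case_group: str,
        control_group: str,
        covariates: Sequence[str] = ("sex", "antihtn"),
    ):
        self.genotypes = genotypes
        keep = samples["group"].isin([case_group, control_group])
        self.samples = samples.loc[keep].reset_index(drop=True)
        if self.samples.empty:
            raise ValueError("no samples in the requested groups")
        self.case_group = case_group
        self.control_group = control_group
        self.covariates = list(covariates)

    def _covariate_frame(self) -> pd.DataFrame:
        cov = pd.DataFrame(index=self.samples.index)
        for c in self.covariates:
            if c == "sex":
                cov["sex"] = (self.samples["sex"] == "female").astype(float)
            elif c not in self.samples.columns:
                raise KeyError(f"covariate {c!r} not in sample table")
            else:
                cov[c] = pd.to_numeric(self.samples[c])
        return cov

    def fit(self, bonferroni: bool = False) -> pd.DataFrame:
        """Per-variant table mirroring the published layout: SNP, locus,
        minor allele, per-group frequencies, odds ratio, p-value."""
        from .genotype_io import allele_frequency

        idx = [self.genotypes.sample_index(s) for s in self.samples["sample_id"]]
        labels = (self.samples["group"] == self.case_group).to_numpy()
        cov = self._covariate_frame()
        rows = []
        for vid in self.genotypes.variant_ids:
            d = self.genotypes.dosage_vector(vid)[idx]
            meta = self.genotypes.variants.iloc[self.genotypes.variant_index(vid)]
            res = additive_logistic(d, labels, cov, variant_id=vid)
            freqs = {}
            for g in (self.control_group, self.case_group):
                ids = self.samples.loc[self.samples["group"] == g, "sample_id"]
                freqs[g] = allele_frequency(self.genotypes, vid, list(ids))
            rows.append(
                {
                    "snp": vid,
                    "locus": meta["locus"],
                    "minor_allele": meta["alt"],
                    f"freq_{self.control_group}": freqs[self.control_group],
                    f"freq_{self.case_group}": freqs[self.case_group],
                    "odds_ratio": res.or_,
                    "p": res.p,
                    "ok": res.ok,
                    "note": res.note,
                }
            )
        out = pd.DataFrame(rows)
        if bonferroni:
            m = out["p"].notna().sum()
            out["p_bonferroni"] = (out["p"] * m).clip(upper=1.0)
        return out
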