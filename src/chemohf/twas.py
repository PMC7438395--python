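"""Transcriptome-wide association: weight training, imputation, association.

The TWAS stage asks whether the genetically regulated component of a gene's
expression predicts decline in left-ventricular ejection fraction (ΔLVEF).
Three steps:

1. ``train_weights`` — per gene, elastic-net regression of measured
   expression on standardized SNP dosages in a reference panel (paired
   genotypes + expression), penalty strength chosen by k-fold
   cross-validation.  Models with non-positive cross-validated R² are
   flagged unusable.
2. ``impute_expression`` — dosage-weighted expression score in a target
   cohort, standardizing dosages with the *reference panel's* means and
   scales (which travel with the weight model).
3. ``associate_expression`` — ordinary least squares of ΔLVEF on the score,
   adjusted for age, baseline LVEF, antihypertensive use and the first two
   genotype principal components; t-test on the score coefficient.

``TwasAnalysis`` runs steps 2–3 over a library of weight models and ranks
genes by p-value; ``qq_data`` exports observed-vs-expected −log10 p pairs
for calibration plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .genotype_io import GenotypeMatrix

logger = logging.getLogger(__name__)

#: Default covariate set for the ΔLVEF association models.
DEFAULT_COVARIATES = ["age", "baseline_lvef", "antihtn", "pc1", "pc2"]


@dataclass
class WeightModel:
    """Sparse SNP→expression weights for one gene.

    Weights apply to dosages standardized by ``ref_mean``/``ref_scale``
    (the training panel's statistics), so imputation is reproducible in any
    cohort.  ``cv_r2`` is the k-fold cross-validated prediction R²; models
    with ``cv_r2 <= 0`` predict no better than the mean and are unusable.
    """

    gene_id: str
    variant_ids: list[str]
    weights: np.ndarray
    ref_mean: np.ndarray
    ref_scale: np.ndarray
    training_n: int
    cv_r2: float
    l1_ratio: float = 0.5
    alpha: float = np.nan
    note: str = ""

    @property
    def usable(self) -> bool:
        return self.cv_r2 > 0 and bool(np.any(self.weights != 0))

    def nonzero(self) -> dict[str, float]:
        return {
            v: float(w)
            for v, w in zip(self.variant_ids, self.weights)
            if w != 0
        }


@dataclass
class TwasResult:
    """Per-gene association of imputed expression with ΔLVEF."""

    gene_id: str
    beta: float
    se: float
    t: float
    p: float
    n_used: int
    rank: int | None = None


def train_weights(
    ref_genotypes: GenotypeMatrix,
    ref_expression: np.ndarray,
    gene_id: str = "gene",
    l1_ratio: float = 0.5,
    n_folds: int = 5,
    seed: int = 0,
) -> WeightModel:
    """Elastic-net expression weights with cross-validated penalty strength.

    ``l1_ratio`` mixes ridge (0) and lasso (1); 0.5 is the conventional
    choice for expression prediction.  Constant expression or all-constant
    genotypes yield an unusable model (``cv_r2 = -inf``) rather than a
    crash.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    y = np.asarray(ref_expression, dtype=float)
    if y.shape[0] != ref_genotypes.n_samples:
        raise ValueError("expression length does not match panel samples")
    X = ref_genotypes.dosages
    if np.isnan(X).any():
        raise ValueError("reference panel must be complete (no missing dosages)")
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    keep = scale > 0
    empty = WeightModel(
        gene_id=gene_id,
        variant_ids=ref_genotypes.variant_ids,
        weights=np.zeros(ref_genotypes.n_variants),
        ref_mean=mean,
        ref_scale=np.where(keep, scale, 1.0),
        training_n=ref_genotypes.n_samples,
        cv_r2=-np.inf,
        l1_ratio=l1_ratio,
    )
    if y.std(ddof=0) == 0:
        empty.note = "constant expression"
        return empty
    if not keep.any():
        empty.note = "all genotypes constant"
        return empty
    Z = (X[:, keep] - mean[keep]) / scale[keep]
    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    enet = ElasticNetCV(l1_ratio=l1_ratio, cv=cv, alphas=50, max_iter=5000)
    enet.fit(Z, y)
    # cross-validated R^2 at the selected penalty, from the CV MSE path
    best = np.unravel_index(np.argmin(enet.mse_path_.mean(axis=-1)), enet.alphas_.shape)
    cv_mse = enet.mse_path_.mean(axis=-1)[best]
    cv_r2 = 1.0 - cv_mse / y.var(ddof=0)
    w = np.zeros(ref_genotypes.n_variants)
    w[keep] = enet.coef_
    model = WeightModel(
        gene_id=gene_id,
        variant_ids=ref_genotypes.variant_ids,
        weights=w,
        ref_mean=mean,
        ref_scale=np.where(keep, scale, 1.0),
        training_n=ref_genotypes.n_samples,
        cv_r2=float(cv_r2),
        l1_ratio=l1_ratio,
        alpha=float(enet.alpha_),
    )
    if not model.usable:
        model.note = "cv_r2 <= 0 or no nonzero weights"
    return model


def impute_expression(
    cohort_genotypes: GenotypeMatrix, model: WeightModel
) -> np.ndarray:
    """Dosage-weighted expression score per cohort sample.

    Variants in the model but absent from the cohort contribute zero; the
    dropped fraction of absolute weight mass is logged and an error is
    raised above 50%.  Missing dosages at model variants are mean-imputed
    with the reference-panel mean (i.e. contribute zero after
    standardization).
    """
    present = [v in cohort_genotypes._vindex for v in model.variant_ids]
    present = np.asarray(present)
    mass = np.abs(model.weights).sum()
    if mass > 0:
        missing_mass = np.abs(model.weights[~present]).sum() / mass
        if missing_mass > 0.5:
            raise ValueError(
                f"{model.gene_id}: {100 * missing_mass:.0f}% of weight mass "
                "is on variants absent from the cohort"
            )
        if missing_mass > 0:
            logger.warning(
                "%s: %.1f%% of weight mass missing from cohort",
                model.gene_id, 100 * missing_mass,
            )
    scores = np.zeros(cohort_genotypes.n_samples)
    for j, vid in enumerate(model.variant_ids):
        w = model.weights[j]
        if w == 0 or not present[j]:
            continue
        d = cohort_genotypes.dosage_vector(vid)
        z = (np.where(np.isnan(d), model.ref_mean[j], d) - model.ref_mean[j])
        scores += w * z / model.ref_scale[j]
    return scores


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Columns that are (numerically) linear combinations of the others."""
    arr = X.to_numpy(dtype=float)
    bad = []
    for j, col in enumerate(X.columns):
        others = np.delete(arr, j, axis=1)
        resid = arr[:, j] - others @ np.linalg.lstsq(others, arr[:, j], rcond=None)[0]
        denom = np.linalg.norm(arr[:, j]) or 1.0
        if np.linalg.norm(resid) / denom < 1e-8:
            bad.append(col)
    return bad


def associate_expression(
    scores: np.ndarray,
    delta_lvef: np.ndarray,
    covariates: pd.DataFrame | None = None,
    gene_id: str = "gene",
) -> TwasResult:
    """OLS of ΔLVEF on the imputed expression score with covariates.

    Complete cases only (listwise deletion, logged).  A rank-deficient
    design raises an error naming the collinear columns.
    """
    df = pd.DataFrame({"score": np.asarray(scores, float),
                       "delta_lvef": np.asarray(delta_lvef, float)})
    if covariates is not None:
        cov = covariates.reset_index(drop=True).astype(float)
        df = pd.concat([df, cov], axis=1)
    n0 = len(df)
    df = df.dropna()
    if len(df) < n0:
        logger.info("%s: dropped %d incomplete cases", gene_id, n0 - len(df))
    X = sm.add_constant(df.drop(columns="delta_lvef"), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        bad = _collinear_columns(X)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    fit = sm.OLS(df["delta_lvef"], X).fit()
    return TwasResult(
        gene_id=gene_id,
        beta=float(fit.params["score"]),
        se=float(fit.bse["score"]),
        t=float(fit.tvalues["score"]),
        p=float(fit.pvalues["score"]),
        n_used=int(fit.nobs),
    )


def compute_genotype_pcs(
    genotypes: GenotypeMatrix, k: int = 2, scale: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Principal components of the dosage matrix.

    Missing dosages are mean-imputed per variant, columns are centered
    (optionally scaled), and the SVD taken.  Each component's sign is fixed
    so its largest-magnitude variant loading is positive.  Returns
    (scores ``n x k``, variance-explained fractions).
    """
    X = genotypes.dosages.copy()
    mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(mean, inds[1])
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=0)
        X = X / np.where(sd > 0, sd, 1.0)
    rank = np.linalg.matrix_rank(X)
    if k > min(X.shape) or k > rank:
        raise ValueError(f"k = {k} exceeds matrix rank {rank}")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    for i in range(k):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    scores = U[:, :k] * S[:k]
    var_explained = S[:k] ** 2 / (S**2).sum()
    return scores, var_explained


def qq_data(pvalues: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Expected vs observed −log10 p pairs for a QQ plot.

    Observed p-values sorted ascending are paired with uniform quantiles
    i/(G+1).
    """
    p = np.sort(np.asarray(pvalues, dtype=float))
    if p.size == 0:
        raise ValueError("no p-values")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    expected = np.arange(1, p.size + 1) / (p.size + 1)
    return -np.log10(expected), -np.log10(p)


class TwasAnalysis:
    """Run the imputation + association stage over a weight-model library.

    Parameters are the cohort genotypes, the sample table (must carry
    ``delta_lvef`` and the covariate columns), and a list of
    :class:`WeightModel`.  Genotype PCs are computed from the cohort matrix
    when ``pc1``/``pc2`` are requested but absent from the sample table.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        samples: pd.DataFrame,
        weight_models: Sequence[WeightModel],
        covariates: Sequence[str] = tuple(DEFAULT_COVARIATES),
    ):
        self.genotypes = genotypes
        self.samples = samples.reset_index(drop=True)
        self.weight_models = [m for m in weight_models if m.usable]
        self.n_unusable = len(weight_models) - len(self.weight_models)
        self.covariates = list(covariates)
        cov = pd.DataFrame(index=self.samples.index)
        for c in self.covariates:
            if c in self.samples.columns:
                cov[c] = pd.to_numeric(self.samples[c])
            elif c in ("pc1", "pc2"):
                pcs, _ = compute_genotype_pcs(genotypes, k=2)
                cov["pc1"] = pcs[:, 0]
                cov["pc2"] = pcs[:, 1]
            else:
                raise KeyError(f"covariate {c!r} not in sample table")
        self.covariate_frame = cov.loc[:, self.covariates]

    def fit(self) -> "TwasResults":
        rows = []
        for model in self.weight_models:
            scores = impute_expression(self.genotypes, model)
            res = associate_expression(
                scores,
                self.samples["delta_lvef"].to_numpy(),
                self.covariate_frame,
                gene_id=model.gene_id,
            )
            rows.append(res)
        if not rows:
            raise ValueError("no usable weight models")
        table = pd.DataFrame([r.__dict__ for r in rows]).drop(columns="rank")
        table = table.sort_values("p", kind="mergesort").reset_index(drop=True)
        table["rank"] = np.arange(1, len(table) + 1)
        return TwasResults(table, self.covariates, self.n_unusable)


@dataclass
class TwasResults:
    """Ranked per-gene TWAS association table."""

    table: pd.DataFrame
    covariates: list[str]
    n_unusable: int = 0

    def gene(self, gene_id: str) -> pd.Series:
        hit = self.table[self.table["gene_id"] == gene_id]
        if hit.empty:
            raise KeyError(f"gene {gene_id!r} not tested")
        return hit.iloc[0]

    def qq_data(self) -> tuple[np.ndarray, np.ndarray]:
        return qq_data(self.table["p"].to_numpy())

    def with_bh_qvalues(self) -> pd.DataFrame:
        """Optional Benjamini–Hochberg q-values (extension; the reference
        analysis reports raw p-values and ranks only)."""
        from statsmodels.stats.multitest import multipletests

        out = self.table.copy()
        out["q_bh"] = multipletests(out["p"], method="fdr_bh")[1]
        return out

    def summary(self, top: int = 10) -> str:
        g = len(self.table)
        lines = [
            f"TWAS: {g} genes tested ({self.n_unusable} unusable models "
            f"excluded), covariates: {', '.join(self.covariates)}",
            "",
            self.table.head(top).to_string(
                index=False,
                formatters={"p": "{:.3g}".format, "beta": "{:.3f}".format,
                            "se": "{:.3f}".format, "t": "{:.2f}".format},
            ),
        ]
        return "\n".join(lines)

    def plot_qq(self, ax=None):
        """QQ plot of observed vs expected −log10 p (requires matplotlib)."""
        import matplotlib.pyplot as plt

        exp, obs = self.qq_data()
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(exp, obs, s=8)
        lim = max(exp.max(), obs.max()) * 1.05
        ax.plot([0, lim], [0, lim], color="grey", lw=1)
        ax.set_xlabel("expected -log10 p")
        ax.set_ylabel("observed -log10 p")
        return ax


def write_weights(models: Sequence[WeightModel], path) -> None:
    """weights.tsv: gene, variant_id, weight, ref_mean, ref_scale, cv_r2."""
    rows = []
    for m in models:
        for j, vid in enumerate(m.variant_ids):
            if m.weights[j] == 0:
                continue
            rows.append(
                (m.gene_id, vid, m.weights[j], m.ref_mean[j], m.ref_scale[j], m.cv_r2)
            )
    pd.DataFrame(
        rows, columns=["gene", "variant_id", "weight", "ref_mean", "ref_scale", "cv_r2"]
    ).to_csv(path, sep="\t", index=False)


def read_weights(path) -> list[WeightModel]:
    df = pd.read_csv(path, sep="\t")
    models = []
    for gene, grp in df.groupby("gene", sort=False):
        models.append(
            WeightModel(
                gene_id=str(gene),
                variant_ids=list(grp["variant_id"]),
                weights=grp["weight"].to_numpy(float),
                ref_mean=grp["ref_mean"].to_numpy(float),
                ref_scale=grp["ref_scale"].to_numpy(float),
                training_n=0,
                cv_r2=float(grp["cv_r2"].iloc[0]),
            )
        )
    return models
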