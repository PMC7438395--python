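"""Composite-null likelihood-ratio test for a three-group variant frequency.

The scientific question: is a variant's frequency in chemotherapy-related
heart-failure (CRHF) cases different from *both* control groups — patients
who received the same chemotherapy without developing heart failure, and
patients with heart failure never exposed to that chemotherapy?  A variant
elevated relative to only one control group is not specific to CRHF, so the
null hypothesis is composite (intersection-type):

    H0:  p_case = p_ctrlA   OR   p_case = p_ctrlB

against the alternative that the case frequency differs from both.  Each
group's event count (variant carriers out of samples, or alternate alleles
out of 2·samples) is modelled as an independent binomial.  The test:

1. maximise the likelihood unconstrained (per-group MLEs k/n);
2. maximise under each null scenario — tie the case proportion to one
   control (pooled MLE) leaving the other control free — and keep the
   scenario with the larger likelihood (the null MLE of a union null);
3. LRT = 2·(unconstrained − constrained) log-likelihood;
4. calibrate by parametric bootstrap under the constrained null MLEs,
   with two one-sided tests (case frequency above / below the tied-control
   null frequency) combined by the min-P rule: the two-sided p-value is
   twice the smaller one-sided p-value, capped at 1.

Because the null distribution must be generated *under the constrained
null*, the bootstrap is parametric (binomial resampling at the null MLEs),
not case resampling.  An exact enumeration oracle over the full outcome
space is provided for small problems to verify the bootstrap.

The one-sided statistics are T+ = LRT·1[case MLE > tied-control null
frequency] and T− symmetric; a zero LRT falls in neither tail.  Bootstrap
p-values use the (b+1)/(B+1) estimator so they are never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import reconstruct_counts_from_freq

__all__ = [
    "ThreeGroupCounts",
    "CompositeTestResult",
    "CompositeNullTest",
    "loglik",
    "fit_null",
    "lrt_statistic",
    "bootstrap_test",
    "exact_oracle_pvalue",
]

_MAX_ORACLE_SPACE = 10**6


@dataclass(frozen=True)
class ThreeGroupCounts:
    """Event counts and totals for case, control A, control B.

    ``level`` records whether counts are carriers out of samples or
    alternate alleles out of 2·samples; it does not change the arithmetic,
    only the interpretation and provenance of the counts.
    """

    k_case: int
    n_case: int
    k_ctrl_a: int
    n_ctrl_a: int
    k_ctrl_b: int
    n_ctrl_b: int
    level: str = "carrier"

    def __post_init__(self) -> None:
        for k, n, g in [
            (self.k_case, self.n_case, "case"),
            (self.k_ctrl_a, self.n_ctrl_a, "ctrlA"),
            (self.k_ctrl_b, self.n_ctrl_b, "ctrlB"),
        ]:
            if n <= 0:
                raise ValueError(f"{g}: total must be > 0, got {n}")
            if not 0 <= k <= n:
                raise ValueError(f"{g}: count {k} outside [0, {n}]")
        if self.level not in ("carrier", "allele"):
            raise ValueError(f"level must be 'carrier' or 'allele', got {self.level!r}")

    @property
    def ks(self) -> np.ndarray:
        return np.array([self.k_case, self.k_ctrl_a, self.k_ctrl_b], dtype=float)

    @property
    def ns(self) -> np.ndarray:
        return np.array([self.n_case, self.n_ctrl_a, self.n_ctrl_b], dtype=float)

    @property
    def freqs(self) -> np.ndarray:
        """Unconstrained per-group MLEs k/n (case, ctrlA, ctrlB)."""
        return self.ks / self.ns


def _binom_ll(k, n, p):
    """Binomial log-likelihood up to the constant binomial coefficient.

    Vectorised; uses the 0·log 0 = 0 convention so degenerate proportions
    (p = 0 with k = 0, p = 1 with k = n) contribute 0, while impossible
    data (k > 0 at p = 0) yield −inf.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(k > 0, k * np.log(p), 0.0)
        t2 = np.where(n - k > 0, (n - k) * np.log1p(-p), 0.0)
    return t1 + t2


def loglik(counts: ThreeGroupCounts, freqs: Sequence[float]) -> float:
    """Joint log-likelihood of the three groups at given frequencies.

    Binomial coefficients are omitted (constant in the frequencies).
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (3,):
        raise ValueError("freqs must be three values (case, ctrlA, ctrlB)")
    if ((freqs < 0) | (freqs > 1)).any():
        raise ValueError("frequencies must lie in [0, 1]")
    return float(_binom_ll(counts.ks, counts.ns, freqs).sum())


def _stat_components(kc, nc, ka, na, kb, nb):
    """Vectorised LRT machinery shared by the observed fit, the bootstrap
    and the enumeration oracle.

    Returns (lrt, sign, tie_a, tied_freq, ll_null, ll_alt) where ``sign``
    compares the case MLE with the tied-control pooled null frequency and
    ``tie_a`` marks datasets whose null MLE ties the case to control A
    (ties between scenarios break toward A).
    """
    kc = np.asarray(kc, dtype=float)
    ka = np.asarray(ka, dtype=float)
    kb = np.asarray(kb, dtype=float)
    fc, fa, fb = kc / nc, ka / na, kb / nb
    ll_alt = (
        _binom_ll(kc, nc, fc) + _binom_ll(ka, na, fa) + _binom_ll(kb, nb, fb)
    )
    pool_a = (kc + ka) / (nc + na)
    pool_b = (kc + kb) / (nc + nb)
    ll_a = (
        _binom_ll(kc, nc, pool_a)
        + _binom_ll(ka, na, pool_a)
        + _binom_ll(kb, nb, fb)
    )
    ll_b = (
        _binom_ll(kc, nc, pool_b)
        + _binom_ll(kb, nb, pool_b)
        + _binom_ll(ka, na, fa)
    )
    tie_a = ll_a >= ll_b
    ll_null = np.where(tie_a, ll_a, ll_b)
    tied_freq = np.where(tie_a, pool_a, pool_b)
    lrt = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    sign = np.sign(fc - tied_freq)
    return lrt, sign, tie_a, tied_freq, ll_null, ll_alt


def fit_null(counts: ThreeGroupCounts) -> tuple[np.ndarray, str, float]:
    """Constrained MLE under the composite null.

    Scenario A ties the case to control A at the pooled proportion
    (k_case+k_A)/(n_case+n_A) with control B free at its own MLE; scenario B
    is symmetric.  The scenario with the larger likelihood wins (ties break
    toward A).  Returns (null_mles for case/ctrlA/ctrlB, tied control
    'A' or 'B', constrained log-likelihood).
    """
    lrt, sign, tie_a, tied_freq, ll_null, _ = _stat_components(
        counts.k_case, counts.n_case,
        counts.k_ctrl_a, counts.n_ctrl_a,
        counts.k_ctrl_b, counts.n_ctrl_b,
    )
    tied = "A" if bool(tie_a) else "B"
    f = counts.freqs
    tf = float(tied_freq)
    null_mles = (
        np.array([tf, tf, f[2]]) if tied == "A" else np.array([tf, f[1], tf])
    )
    return null_mles, tied, float(ll_null)


def lrt_statistic(counts: ThreeGroupCounts) -> float:
    """Likelihood-ratio statistic 2·(unconstrained − constrained), >= 0."""
    lrt, *_ = _stat_components(
        counts.k_case, counts.n_case,
        counts.k_ctrl_a, counts.n_ctrl_a,
        counts.k_ctrl_b, counts.n_ctrl_b,
    )
    return float(lrt)


@dataclass
class CompositeTestResult:
    """Result of the composite-null test for one variant.

    ``p_two = min(1, 2·min(p_one_high, p_one_low))`` (min-P combination of
    the two one-sided bootstrap tests).
    """

    counts: ThreeGroupCounts
    lrt: float
    tied_control: str
    null_mles: np.ndarray
    alt_mles: np.ndarray
    p_one_high: float
    p_one_low: float
    p_two: float
    B: int
    seed: int | None
    method: str = "parametric-bootstrap"
    variant_id: str | None = None

    def summary(self) -> str:
        c = self.counts
        lines = [
            "Composite-null variant-frequency test "
            f"({c.level} level, {self.method})",
            "=" * 64,
            f"variant:        {self.variant_id or '-'}",
            f"counts:         case {c.k_case}/{c.n_case}, "
            f"ctrlA {c.k_ctrl_a}/{c.n_ctrl_a}, ctrlB {c.k_ctrl_b}/{c.n_ctrl_b}",
            "frequencies:    case {:.4f}, ctrlA {:.4f}, ctrlB {:.4f}".format(
                *self.alt_mles
            ),
            f"null ties case to control {self.tied_control} at "
            f"{self.null_mles[0]:.4f}",
            f"LRT:            {self.lrt:.4f}",
            f"one-sided p:    high {self.p_one_high:.4g}, low {self.p_one_low:.4g}",
            f"two-sided p:    {self.p_two:.4g}   "
            f"(min-P: twice the smaller one-sided p)",
            f"replicates:     B = {self.B}, seed = {self.seed}",
        ]
        return "\n".join(lines)

    def to_row(self) -> dict:
        c = self.counts
        return {
            "variant_id": self.variant_id,
            "level": c.level,
            "freq_case": c.k_case / c.n_case,
            "freq_ctrl_a": c.k_ctrl_a / c.n_ctrl_a,
            "freq_ctrl_b": c.k_ctrl_b / c.n_ctrl_b,
            "lrt": self.lrt,
            "tied_control": self.tied_control,
            "p_one_high": self.p_one_high,
            "p_one_low": self.p_one_low,
            "p_two": self.p_two,
            "B": self.B,
            "seed": self.seed,
        }


def bootstrap_test(
    counts: ThreeGroupCounts, B: int = 100_000, seed: int | None = 0
) -> CompositeTestResult:
    """Parametric-bootstrap composite-null test.

    Resamples the three binomials under the constrained null MLEs; each
    replicate is refitted exactly like the observed data.  One-sided
    p-values are (#{T* >= T_obs} + 1)/(B + 1) for T+ and T− as defined in
    the module docstring; the two-sided p doubles the smaller one.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if B < 1000:
        warnings.warn(
            f"B = {B} gives a coarse p-value resolution of {1 / (B + 1):.3g}",
            UserWarning,
            stacklevel=2,
        )
    null_mles, tied, _ = fit_null(counts)
    lrt_obs, sign_obs, *_ = _stat_components(
        counts.k_case, counts.n_case,
        counts.k_ctrl_a, counts.n_ctrl_a,
        counts.k_ctrl_b, counts.n_ctrl_b,
    )
    t_high_obs = float(lrt_obs) if sign_obs > 0 else 0.0
    t_low_obs = float(lrt_obs) if sign_obs < 0 else 0.0

    rng = np.random.default_rng(seed)
    ns = counts.ns.astype(int)
    ks = rng.binomial(ns, null_mles, size=(B, 3))
    lrt_b, sign_b, *_ = _stat_components(
        ks[:, 0], ns[0], ks[:, 1], ns[1], ks[:, 2], ns[2]
    )
    t_high = np.where(sign_b > 0, lrt_b, 0.0)
    t_low = np.where(sign_b < 0, lrt_b, 0.0)
    p_high = (np.count_nonzero(t_high >= t_high_obs) + 1) / (B + 1)
    p_low = (np.count_nonzero(t_low >= t_low_obs) + 1) / (B + 1)
    p_two = min(1.0, 2.0 * min(p_high, p_low))
    return CompositeTestResult(
        counts=counts,
        lrt=float(lrt_obs),
        tied_control=tied,
        null_mles=null_mles,
        alt_mles=counts.freqs,
        p_one_high=float(p_high),
        p_one_low=float(p_low),
        p_two=float(p_two),
        B=B,
        seed=seed,
    )


def exact_oracle_pvalue(counts: ThreeGroupCounts) -> CompositeTestResult:
    """Exact test by full enumeration of the outcome space under the null.

    Enumerates every (k_case, k_A, k_B) triple, weights it by the product
    of binomial pmfs at the constrained null MLEs, and sums the probability
    of outcomes with a one-sided statistic at least as large as observed.
    Sides are combined exactly as in :func:`bootstrap_test` (without the
    +1 bootstrap smoothing, which is a Monte-Carlo device).

    Only for small groups: the space (n_case+1)(n_A+1)(n_B+1) must not
    exceed 10^6.
    """
    space = (counts.n_case + 1) * (counts.n_ctrl_a + 1) * (counts.n_ctrl_b + 1)
    if space > _MAX_ORACLE_SPACE:
        raise ValueError(
            f"outcome space {space} exceeds {_MAX_ORACLE_SPACE}; "
            "use bootstrap_test instead"
        )
    null_mles, tied, _ = fit_null(counts)
    lrt_obs, sign_obs, *_ = _stat_components(
        counts.k_case, counts.n_case,
        counts.k_ctrl_a, counts.n_ctrl_a,
        counts.k_ctrl_b, counts.n_ctrl_b,
    )
    t_high_obs = float(lrt_obs) if sign_obs > 0 else 0.0
    t_low_obs = float(lrt_obs) if sign_obs < 0 else 0.0

    ns = counts.ns.astype(int)
    grids = np.meshgrid(
        np.arange(ns[0] + 1), np.arange(ns[1] + 1), np.arange(ns[2] + 1),
        indexing="ij",
    )
    pmfs = [
        stats.binom.pmf(np.arange(ns[i] + 1), ns[i], null_mles[i])
        for i in range(3)
    ]
    prob = (
        pmfs[0][:, None, None] * pmfs[1][None, :, None] * pmfs[2][None, None, :]
    )
    lrt_g, sign_g, *_ = _stat_components(
        grids[0], ns[0], grids[1], ns[1], grids[2], ns[2]
    )
    t_high = np.where(sign_g > 0, lrt_g, 0.0)
    t_low = np.where(sign_g < 0, lrt_g, 0.0)
    # clamp against pmf rounding (sums can exceed 1 by ~1e-16)
    p_high = float(min(1.0, prob[t_high >= t_high_obs].sum()))
    p_low = float(min(1.0, prob[t_low >= t_low_obs].sum()))
    p_two = min(1.0, 2.0 * min(p_high, p_low))
    return CompositeTestResult(
        counts=counts,
        lrt=float(lrt_obs),
        tied_control=tied,
        null_mles=null_mles,
        alt_mles=counts.freqs,
        p_one_high=p_high,
        p_one_low=p_low,
        p_two=p_two,
        B=0,
        seed=None,
        method="exact-enumeration",
    )


class CompositeNullTest:
    """Model object for the composite-null frequency test.

    Built from :class:`ThreeGroupCounts` (directly, from printed per-group
    frequencies, or from a genotype matrix plus sample table); ``fit``
    runs the parametric bootstrap and returns a
    :class:`CompositeTestResult`.
    """

    def __init__(self, counts: ThreeGroupCounts, variant_id: str | None = None):
        self.counts = counts
        self.variant_id = variant_id

    @classmethod
    def from_frequencies(
        cls,
        f_case: float,
        n_case: int,
        f_ctrl_a: float,
        n_ctrl_a: int,
        f_ctrl_b: float,
        n_ctrl_b: int,
        level: str = "allele",
        variant_id: str | None = None,
    ) -> "CompositeNullTest":
        """Reconstruct integer counts from printed per-group frequencies."""
        counts = ThreeGroupCounts(
            reconstruct_counts_from_freq(f_case, n_case, level), _denom(n_case, level),
            reconstruct_counts_from_freq(f_ctrl_a, n_ctrl_a, level), _denom(n_ctrl_a, level),
            reconstruct_counts_from_freq(f_ctrl_b, n_ctrl_b, level), _denom(n_ctrl_b, level),
            level=level,
        )
        return cls(counts, variant_id=variant_id)

    @classmethod
    def from_genotypes(
        cls,
        matrix,
        samples: pd.DataFrame,
        variant_id: str,
        case_group: str = "crhf_case",
        ctrl_a_group: str = "chemo_no_hf",
        ctrl_b_group: str = "hf_no_chemo",
        level: str = "carrier",
    ) -> "CompositeNullTest":
        """Count events per group directly from a genotype matrix."""
        def group_counts(group: str) -> tuple[int, int]:
            ids = samples.loc[samples["group"] == group, "sample_id"]
            d = matrix.dosage_vector(variant_id)
            idx = [matrix.sample_index(s) for s in ids]
            d = d[idx]
            d = d[~np.isnan(d)]
            if d.size == 0:
                raise ValueError(f"group {group!r}: no non-missing genotypes")
            if level == "carrier":
                return int((d >= 1).sum()), int(d.size)
            return int(d.sum()), 2 * int(d.size)

        kc, nc = group_counts(case_group)
        ka, na = group_counts(ctrl_a_group)
        kb, nb = group_counts(ctrl_b_group)
        return cls(
            ThreeGroupCounts(kc, nc, ka, na, kb, nb, level=level),
            variant_id=variant_id,
        )

    def fit(self, B: int = 100_000, seed: int | None = 0) -> CompositeTestResult:
        res = bootstrap_test(self.counts, B=B, seed=seed)
        res.variant_id = self.variant_id
        return res

    def fit_exact(self) -> CompositeTestResult:
        res = exact_oracle_pvalue(self.counts)
        res.variant_id = self.variant_id
        return res


def _denom(n_samples: int, level: str) -> int:
    return 2 * n_samples if level == "allele" else n_samples
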