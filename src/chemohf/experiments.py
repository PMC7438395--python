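"""Self-contained validation experiments for the statistical machinery.

These are the package's own operating-characteristic checks, run on
synthetic data at reduced but statistically meaningful problem sizes:

* :func:`composite_size_calibration` — empirical type-I error of the
  composite-null bootstrap test at a boundary null (case frequency equal to
  one control's) at the study's group sizes;
* :func:`composite_power_curve` — rejection rate as the case frequency
  moves away from both controls;
* :func:`bootstrap_vs_exact` — bootstrap p-values against the exact
  enumeration oracle on tiny instances;
* :func:`twas_rank_experiment` — end-to-end TWAS (panel simulation, weight
  training, imputation, association) checking that a single causal gene
  among decoys ranks first;
* :func:`weight_recovery_cosine` — cosine similarity between trained and
  true per-dosage weight vectors on a sparse-causal panel.
"""

from __future__ import annotations

import numpy as np

from .composite import ThreeGroupCounts, bootstrap_test, exact_oracle_pvalue
from .genotype_io import GenotypeMatrix
from .simulate import ReferencePanelSpec, simulate_reference_panel
from .twas import associate_expression, impute_expression, train_weights

STUDY_GROUP_NS = (38, 282, 690)  # case, chemo-no-HF, HF-no-chemo


def composite_size_calibration(
    n_sims: int = 2000,
    B: int = 1000,
    seed: int = 0,
    p_boundary: float = 0.15,
    p_other: float = 0.30,
    alpha: float = 0.05,
    group_ns: tuple[int, int, int] = STUDY_GROUP_NS,
) -> float:
    """Empirical rejection rate at a boundary null.

    Data are drawn with the case carrier probability exactly equal to
    control A's (``p_boundary``) and control B elsewhere (``p_other``) — a
    point on the composite null's boundary, where the test's size is
    largest.  Returns the fraction of ``n_sims`` datasets with two-sided
    bootstrap p <= ``alpha``.
    """
    rng = np.random.default_rng(seed)
    nc, na, nb = group_ns
    rej = 0
    for _ in range(n_sims):
        counts = ThreeGroupCounts(
            int(rng.binomial(nc, p_boundary)), nc,
            int(rng.binomial(na, p_boundary)), na,
            int(rng.binomial(nb, p_other)), nb,
        )
        res = bootstrap_test(counts, B=B, seed=int(rng.integers(2**31 - 1)))
        rej += res.p_two <= alpha
    return rej / n_sims


def composite_power_curve(
    case_freqs: tuple[float, ...] = (0.20, 0.30, 0.40),
    ctrl_freq: float = 0.20,
    n_sims: int = 1000,
    B: int = 300,
    seed: int = 0,
    alpha: float = 0.05,
    group_ns: tuple[int, int, int] = STUDY_GROUP_NS,
) -> list[float]:
    """Rejection rate at increasing case-frequency displacement.

    Both controls sit at ``ctrl_freq``; the case frequency moves away.
    """
    rng = np.random.default_rng(seed)
    nc, na, nb = group_ns
    rates = []
    for pc in case_freqs:
        rej = 0
        for _ in range(n_sims):
            counts = ThreeGroupCounts(
                int(rng.binomial(nc, pc)), nc,
                int(rng.binomial(na, ctrl_freq)), na,
                int(rng.binomial(nb, ctrl_freq)), nb,
            )
            res = bootstrap_test(counts, B=B, seed=int(rng.integers(2**31 - 1)))
            rej += res.p_two <= alpha
        rates.append(rej / n_sims)
    return rates


def random_tiny_counts(rng: np.random.Generator) -> ThreeGroupCounts:
    """A random small instance with a tractable enumeration space."""
    ns = rng.integers(2, 13, size=3)
    ks = [int(rng.integers(0, n + 1)) for n in ns]
    return ThreeGroupCounts(ks[0], int(ns[0]), ks[1], int(ns[1]), ks[2], int(ns[2]))


def bootstrap_vs_exact(
    n_instances: int = 20, B: int = 20_000, seed: int = 0
) -> list[dict]:
    """Compare bootstrap and exact one-sided p-values on tiny instances.

    Returns one record per instance with both p-values and the binomial
    Monte-Carlo standard error of the bootstrap estimate.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_instances):
        counts = random_tiny_counts(rng)
        exact = exact_oracle_pvalue(counts)
        boot = bootstrap_test(counts, B=B, seed=int(rng.integers(2**31 - 1)))
        for side in ("p_one_high", "p_one_low"):
            p = getattr(exact, side)
            out.append(
                {
                    "counts": counts,
                    "side": side,
                    "p_exact": p,
                    "p_boot": getattr(boot, side),
                    "mc_se": float(np.sqrt(p * (1 - p) / B)),
                }
            )
    return out


_CAUSAL_WEIGHTS = (1.0, -0.8, 0.6)


def weight_recovery_cosine(
    n_samples: int = 500,
    n_snps: int = 50,
    noise_sd: float = 1.2,
    seed: int = 0,
) -> float:
    """Train on a 3-causal-SNP panel; cosine(trained, true) per-dosage weights.

    The noise level puts the genetic signal and the noise on comparable
    scales (signal-to-noise near 1 per causal SNP).
    """
    rng = np.random.default_rng(seed)
    vids = ReferencePanelSpec(
        n_samples=n_samples, n_snps=n_snps, variant_prefix="panel_snp"
    ).variant_ids()
    causal_idx = rng.choice(n_snps, size=3, replace=False)
    causal = {vids[i]: w for i, w in zip(causal_idx, _CAUSAL_WEIGHTS)}
    spec = ReferencePanelSpec(
        n_samples=n_samples,
        n_snps=n_snps,
        causal_weights=causal,
        expression_noise_sd=noise_sd,
        seed=int(rng.integers(2**31 - 1)),
    )
    panel, expr = simulate_reference_panel(spec)
    model = train_weights(panel, expr, seed=int(rng.integers(2**31 - 1)))
    true = np.array([causal.get(v, 0.0) for v in panel.variant_ids])
    w_dosage = model.weights / model.ref_scale  # back to per-dosage scale
    denom = np.linalg.norm(w_dosage) * np.linalg.norm(true)
    return float(w_dosage @ true / denom) if denom > 0 else 0.0


def twas_rank_experiment(
    n_replicates: int = 100,
    n_genes: int = 50,
    snps_per_gene: int = 6,
    panel_n: int = 300,
    cohort_n: int = 400,
    expression_effect: float = -2.0,
    phenotype_noise_sd: float = 5.0,
    seed: int = 0,
) -> float:
    """Fraction of end-to-end replicates in which the causal gene ranks 1.

    Each replicate simulates, per gene, a fresh reference panel (the causal
    gene's expression driven by three of its SNPs), trains elastic-net
    weights, simulates a cohort at the panel allele frequencies, imputes
    expression, builds ΔLVEF from the causal gene's true genetic score, and
    ranks genes by association p-value.  The effect size is chosen for
    near-complete single-gene power, so the causal gene should win the
    ranking almost always.
    """
    rng = np.random.default_rng(seed)
    wins = 0
    for _ in range(n_replicates):
        pvals = {}
        causal_score = None
        causal_gene = 0
        for g in range(n_genes):
            prefix = f"g{g}_snp"
            causal = {}
            if g == causal_gene:
                causal = {
                    f"{prefix}_{j}": w for j, w in enumerate(_CAUSAL_WEIGHTS)
                }
            spec = ReferencePanelSpec(
                n_samples=panel_n,
                n_snps=snps_per_gene,
                causal_weights=causal,
                expression_noise_sd=1.0,
                variant_prefix=prefix,
                seed=int(rng.integers(2**31 - 1)),
            )
            panel, expr = simulate_reference_panel(spec)
            model = train_weights(
                panel, expr, gene_id=f"gene{g}",
                seed=int(rng.integers(2**31 - 1)),
            )
            freqs = panel.dosages.mean(axis=0) / 2
            dos = rng.binomial(
                2, freqs, size=(cohort_n, snps_per_gene)
            ).astype(float)
            cohort = GenotypeMatrix(
                [f"s{i:04d}" for i in range(cohort_n)], panel.variants, dos
            )
            if g == causal_gene:
                true_w = np.array(
                    [causal.get(v, 0.0) for v in panel.variant_ids]
                )
                causal_score = dos @ true_w
            if model.usable:
                pvals[g] = (model, cohort)
        y = (
            -4.0
            + expression_effect * causal_score
            + rng.normal(0, phenotype_noise_sd, cohort_n)
        )
        gene_p = {
            g: associate_expression(
                impute_expression(cohort, model), y, gene_id=str(g)
            ).p
            for g, (model, cohort) in pvals.items()
        }
        wins += min(gene_p, key=gene_p.get) == causal_gene
    return wins / n_replicates
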