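"""Synthetic joint genotype / expression / phenotype data with planted truth.

The generator plants a low-rank cross-block covariance: latent subject
factors z_k drive both a continuous genetic block (discretised to 0/1/2
genotypes by quantile thresholding at Hardy-Weinberg proportions) and the
phenotype block (which additionally receives covariate confounding).
Because the planted saliences and effect sizes are returned alongside the
data, every downstream stage — covariate removal, SVD, permutation test,
bootstrap feature selection — can be validated against ground truth.

A separate longitudinal simulator emits visit-level MDS-UPDRS item scores
following per-subject linear trends, plus medication logs with known LEDD,
so the slope-fitting and dose-conversion code paths have exact oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    GenotypeMatrix,
    MedicationRecord,
    PhenotypeBlock,
    PTIF_FEATURES,
    VisitRecord,
)
from .preprocess import load_subscore_map

__all__ = ["SyntheticTruth", "simulate_joint_dataset", "simulate_longitudinal_clinic"]


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated dataset."""

    n_components: int
    x_saliences: np.ndarray          # p_snps x K, unit-norm columns, sparse
    expr_saliences: np.ndarray       # p_transcripts x K, unit-norm columns
    y_saliences: np.ndarray          # q x K, unit-norm columns
    effect_sizes: np.ndarray         # K non-negative, descending
    noise_sd: float
    confound_coefs: np.ndarray | None
    maf: np.ndarray | None = None    # per-SNP minor allele frequency
    true_slopes: pd.DataFrame | None = None
    true_ledd: pd.Series | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        assert np.allclose(np.linalg.norm(self.x_saliences, axis=0), 1)
        assert np.allclose(np.linalg.norm(self.y_saliences, axis=0), 1)
        assert (np.diff(self.effect_sizes) <= 1e-12).all(), "effect sizes must be descending"


def _sparse_unit_vectors(rng: np.random.Generator, p: int, K: int,
                         sparsity: float) -> np.ndarray:
    """K unit-norm columns with a `sparsity` fraction of nonzero entries."""
    W = np.zeros((p, K))
    n_active = max(1, int(round(sparsity * p)))
    for k in range(K):
        support = rng.choice(p, size=n_active, replace=False)
        W[support, k] = rng.normal(size=n_active)
        W[:, k] /= np.linalg.norm(W[:, k])
    return W


def simulate_joint_dataset(
    n: int = 294,
    p_snps: int = 500,
    p_transcripts: int = 300,
    q_features: int = 7,
    n_components: int = 1,
    effect_sizes=None,
    noise_sd: float = 1.0,
    snp_sparsity: float = 0.05,
    maf_range: tuple[float, float] = (0.05, 0.5),
    confounding: bool = True,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, ExpressionMatrix, PhenotypeBlock, pd.DataFrame, SyntheticTruth]:
    """Simulate subjects with genotypes, expression, phenotypes and covariates.

    The default sample size mirrors a baseline cohort of 294 patients with
    genetic, clinical, medication and demographic data. Latent factors
    z_k ~ N(0,1) per subject generate the continuous genetic block
    X* = sum_k effect_k z_k u_k' + noise; each SNP column of X* is then
    quantile-thresholded at Hardy-Weinberg proportions (1-f)^2 : 2f(1-f) :
    f^2 for a minor-allele frequency f drawn uniformly from ``maf_range``.
    Expression is the softplus of an analogous latent block (non-negative,
    TPM-like). Phenotypes are Y = sum_k effect_k z_k v_k' + covariate
    confounding + noise, with ``q_features`` columns (named as the 7 pTIF
    features when q=7).

    Returns (genotypes, expression, phenotypes, covariates, truth); the
    same seed gives bit-identical output.
    """
    if n < 10:
        raise ValueError("need at least 10 subjects")
    K = int(n_components)
    if K > min(p_snps, q_features):
        raise ValueError(f"planted rank {K} exceeds min(p, q) = {min(p_snps, q_features)}")
    rng = np.random.default_rng(seed)
    # deterministic per-purpose streams from the master seed
    streams = {name: np.random.default_rng(s) for name, s in zip(
        ("latent", "saliences", "genotype", "expression", "phenotype", "covariates"),
        rng.integers(0, 2**31 - 1, size=6),
    )}

    if effect_sizes is None:
        effect_sizes = np.array([3.0] * K) if K else np.empty(0)
    effect_sizes = np.asarray(effect_sizes, dtype=float)
    if len(effect_sizes) != K:
        raise ValueError("effect_sizes length must equal n_components")
    order = np.argsort(-effect_sizes)
    effect_sizes = effect_sizes[order]

    subject_ids = [f"S{i:04d}" for i in range(n)]
    z = streams["latent"].normal(size=(n, K))

    u = _sparse_unit_vectors(streams["saliences"], p_snps, K, snp_sparsity)
    g = _sparse_unit_vectors(streams["saliences"], p_transcripts, K, min(1.0, snp_sparsity * 4))
    v = np.linalg.qr(streams["saliences"].normal(size=(q_features, max(K, 1))))[0][:, :K]
    # sign convention: largest-|entry| positive, mirroring the model output
    for k in range(K):
        for W in (u, g, v):
            if W[np.argmax(np.abs(W[:, k])), k] < 0:
                W[:, k] = -W[:, k]

    signal_x = z @ (effect_sizes[:, None] * u.T) if K else 0.0
    latent_x = signal_x + streams["genotype"].normal(scale=noise_sd, size=(n, p_snps))
    maf = streams["genotype"].uniform(*maf_range, size=p_snps)
    genotypes = _threshold_to_genotypes(latent_x, maf)
    snp_ids = [f"snp{j:05d}" for j in range(p_snps)]
    # place SNPs on a toy genome: 1 Mb chromosome chunks of 25 SNPs each
    chroms = [f"chr{1 + j // 25}" for j in range(p_snps)]
    positions = [1000 + 40_000 * (j % 25) for j in range(p_snps)]
    geno = GenotypeMatrix(
        pd.DataFrame(genotypes, index=subject_ids, columns=snp_ids),
        pd.Series(chroms, index=snp_ids),
        pd.Series(positions, index=snp_ids),
    )

    signal_e = z @ (effect_sizes[:, None] * g.T) if K else 0.0
    latent_e = signal_e + streams["expression"].normal(scale=noise_sd, size=(n, p_transcripts))
    tpm = np.log1p(np.exp(latent_e + 2.0)) * 10.0  # softplus, scaled to TPM-like range
    expr = ExpressionMatrix(pd.DataFrame(
        tpm, index=subject_ids, columns=[f"tx{j:05d}" for j in range(p_transcripts)]))

    cov_rng = streams["covariates"]
    covariates = pd.DataFrame(
        {
            "age": cov_rng.normal(62, 10, size=n),
            "sex": cov_rng.integers(0, 2, size=n).astype(float),
            "education": np.clip(cov_rng.normal(14, 3, size=n), 6, 24),
            "handedness": (cov_rng.random(n) < 0.9).astype(float),
            "baseline_updrs": np.clip(cov_rng.normal(21, 9, size=n), 0, 80),
            "ledd": np.clip(cov_rng.normal(450, 200, size=n), 0, None),
        },
        index=subject_ids,
    )
    covariates.index.name = "subject_id"

    if confounding:
        confound_coefs = streams["phenotype"].normal(scale=0.5,
                                                     size=(covariates.shape[1], q_features))
    else:
        confound_coefs = np.zeros((covariates.shape[1], q_features))
    cov_std = (covariates - covariates.mean()) / covariates.std(ddof=1).replace(0, 1)
    signal_y = z @ (effect_sizes[:, None] * v.T) if K else 0.0
    Y = (signal_y + cov_std.to_numpy() @ confound_coefs
         + streams["phenotype"].normal(scale=noise_sd, size=(n, q_features)))
    y_names = PTIF_FEATURES if q_features == 7 else [f"pheno{j}" for j in range(q_features)]
    pheno = PhenotypeBlock(pd.DataFrame(Y, index=subject_ids, columns=y_names))

    truth = SyntheticTruth(
        n_components=K,
        x_saliences=u,
        expr_saliences=g,
        y_saliences=v,
        effect_sizes=effect_sizes,
        noise_sd=noise_sd,
        confound_coefs=confound_coefs,
        maf=maf,
        seed=seed,
    )
    return geno, expr, pheno, covariates, truth


def _threshold_to_genotypes(latent: np.ndarray, maf: np.ndarray) -> np.ndarray:
    """Per-SNP quantile thresholding of a latent column at Hardy-Weinberg
    proportions for the given minor-allele frequency."""
    n, p = latent.shape
    out = np.zeros((n, p))
    p0 = (1 - maf) ** 2
    p1 = 2 * maf * (1 - maf)
    for j in range(p):
        col = latent[:, j]
        t0 = np.quantile(col, p0[j])
        t1 = np.quantile(col, p0[j] + p1[j])
        out[:, j] = np.where(col <= t0, 0.0, np.where(col <= t1, 1.0, 2.0))
    return out


def simulate_longitudinal_clinic(
    n: int = 216,
    n_visits: int = 5,
    slope_mean: float = 1.0,
    slope_sd: float = 1.0,
    item_noise_sd: float = 0.3,
    visit_interval_years: float = 1.0,
    paired_off: bool = False,
    off_on_gap: float = 8.0,
    seed: int | None = None,
) -> tuple[list[VisitRecord], list[MedicationRecord], SyntheticTruth]:
    """Simulate longitudinal MDS-UPDRS motor assessments and medication logs.

    Per subject, a true yearly slope for each of the four motor subscores
    is drawn from N(slope_mean, slope_sd); each item inside a subscore
    group carries an equal share of the group slope, so the summed group
    score follows exactly the planted linear trend (before noise and
    clipping to the 0-4 item range). Item scores are trend + N(0,
    item_noise_sd) noise, clipped to [0, 4]. ``paired_off=True``
    additionally emits an OFF-state assessment at every visit with totals
    elevated by ``off_on_gap`` points (the absolute levodopa response).

    Medication logs give each subject levodopa at a known dose x frequency,
    and the implied LEDD is returned in the truth object.
    """
    if n_visits < 3:
        raise ValueError("need at least 3 visits per subject (inclusion rule)")
    rng = np.random.default_rng(seed)
    mapping = load_subscore_map()
    groups = ["tremor", "bradykinesia", "rigidity", "axial"]
    visits: list[VisitRecord] = []
    meds: list[MedicationRecord] = []
    slope_rows = {}
    ledd_truth = {}
    for i in range(n):
        sid = f"S{i:04d}"
        group_slopes = rng.normal(slope_mean, slope_sd, size=len(groups))
        slope_rows[sid] = dict(zip(groups, group_slopes))
        slope_rows[sid]["total"] = float(group_slopes.sum())
        # per-item baselines chosen so trend + noise rarely clips
        baselines = {}
        for g, gslope in zip(groups, group_slopes):
            items = mapping[g]
            per_item_slope = gslope / len(items)
            max_drift = abs(per_item_slope) * (n_visits - 1) * visit_interval_years
            lo = max(0.0, -per_item_slope * (n_visits - 1) * visit_interval_years) + 0.5
            hi = max(lo + 0.1, 3.5 - max_drift)
            for item in items:
                baselines[item] = (rng.uniform(lo, hi), per_item_slope)
        for visit_idx in range(n_visits):
            t = visit_idx * visit_interval_years
            scores = {}
            for item, (b0, sl) in baselines.items():
                noise = rng.normal(0, item_noise_sd) if item_noise_sd > 0 else 0.0
                scores[item] = float(np.clip(b0 + sl * t + noise, 0.0, 4.0))
            visits.append(VisitRecord(sid, t, scores, "ON"))
            if paired_off:
                off_scores = {
                    item: float(np.clip(s + off_on_gap / 33.0, 0.0, 4.0))
                    for item, s in scores.items()
                }
                visits.append(VisitRecord(sid, t, off_scores, "OFF"))
        dose = float(rng.choice([50, 100, 150, 200]))
        freq = float(rng.integers(2, 5))
        meds.append(MedicationRecord(sid, "levodopa", dose, "mg", freq))
        ledd_truth[sid] = dose * freq
    true_slopes = pd.DataFrame.from_dict(slope_rows, orient="index")
    true_slopes.index.name = "subject_id"
    dummy = np.ones((1, 1))
    truth = SyntheticTruth(
        n_components=0,
        x_saliences=np.empty((1, 0)),
        expr_saliences=np.empty((1, 0)),
        y_saliences=np.empty((1, 0)),
        effect_sizes=np.empty(0),
        noise_sd=item_noise_sd,
        confound_coefs=None,
        true_slopes=true_slopes.sort_index(),
        true_ledd=pd.Series(ledd_truth).sort_index(),
        seed=seed,
    )
    return visits, meds, truth
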