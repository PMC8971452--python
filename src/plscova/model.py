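"""Two-block cross-correlation SVD ("PLS-SVD") with resampling inference.

The model decomposes the p x q cross-correlation matrix R = X'Y / (n-1)
between two column-standardised blocks into R = U S V', pairing each
component's genetic salience (column of U) with a phenotype salience
(column of V). A component's explained covariance is its squared singular
value as a fraction of the total; component significance is assessed by a
max-statistic permutation test (familywise-error controlling), and feature
significance by subject-resampling bootstrap ratios and percentile
confidence intervals.

Usage follows the model/results convention of mainstream statistics
packages::

    model = CrossBlockSVD(X_adj, Y_adj)
    res = model.fit()
    perm = res.permutation_test(n_permutations=1000, seed=7)
    boot = res.bootstrap_features(n_bootstrap=1000, seed=7)
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CrossBlockSVD",
    "CrossBlockSVDResults",
    "PermutationResult",
    "BootstrapResult",
    "cross_block_matrix",
    "added_explained_covariance",
    "select_significant_features",
]


def cross_block_matrix(X: np.ndarray, Y: np.ndarray, *, check: bool = True) -> np.ndarray:
    """Cross-correlation matrix R = X'Y / (n-1) of two standardised blocks.

    Both blocks must hold the same subjects in the same row order, with
    columns at mean 0, sd 1 — then every entry of R is a Pearson
    correlation.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError(
            f"subject mismatch: X has {X.shape[0]} rows, Y has {Y.shape[0]}"
        )
    if check:
        for name, block in (("X", X), ("Y", Y)):
            if not np.allclose(block.mean(axis=0), 0, atol=1e-6) or not np.allclose(
                block.std(axis=0, ddof=1), 1, atol=1e-6
            ):
                raise ValueError(f"{name} block is not column-standardised")
    return X.T @ Y / (X.shape[0] - 1)


def _svd_saliences(R: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Thin SVD of R with the sign convention applied.

    Each component pair is flipped so the x-salience entry of largest
    magnitude is positive; SVD signs are otherwise arbitrary and a fixed
    convention keeps bootstrap replicates and reruns comparable.
    """
    if not np.isfinite(R).all():
        raise ValueError("cross-block matrix contains non-finite values")
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    U, s, V = U[:, :n_components], s[:n_components], Vt.T[:, :n_components]
    for k in range(U.shape[1]):
        anchor = np.argmax(np.abs(U[:, k]))
        if U[anchor, k] < 0:
            U[:, k] = -U[:, k]
            V[:, k] = -V[:, k]
    return U, s, V


class CrossBlockSVD:
    """Cross-block SVD model of two preprocessed subject-aligned blocks.

    Parameters
    ----------
    X, Y : array-like or DataFrame, shape (n, p) and (n, q)
        Column-standardised (covariate-adjusted) blocks. Row i of X and of
        Y must be the same subject.
    x_names, y_names : sequence of str, optional
        Feature labels; taken from DataFrame columns when available.
    """

    def __init__(self, X, Y, x_names=None, y_names=None):
        if isinstance(X, pd.DataFrame):
            x_names = x_names if x_names is not None else list(X.columns)
        if isinstance(Y, pd.DataFrame):
            y_names = y_names if y_names is not None else list(Y.columns)
        self.X = np.asarray(X, dtype=float)
        self.Y = np.asarray(Y, dtype=float)
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y must have the same number of subjects")
        self.nobs = self.X.shape[0]
        self.x_names = list(x_names) if x_names is not None else [
            f"x{j}" for j in range(self.X.shape[1])
        ]
        self.y_names = list(y_names) if y_names is not None else [
            f"y{j}" for j in range(self.Y.shape[1])
        ]

    @classmethod
    def from_dataframes(cls, X: pd.DataFrame, Y: pd.DataFrame) -> "CrossBlockSVD":
        """Build from two DataFrames, aligning on their (subject) index."""
        common = X.index.intersection(Y.index)
        if len(common) < 3:
            raise ValueError(f"only {len(common)} shared subjects between blocks")
        common = common.sort_values()
        return cls(X.loc[common], Y.loc[common])

    @property
    def n_components(self) -> int:
        return min(self.X.shape[1], self.Y.shape[1], self.nobs - 1)

    def fit(self) -> "CrossBlockSVDResults":
        R = cross_block_matrix(self.X, self.Y, check=False)
        U, s, V = _svd_saliences(R, self.n_components)
        return CrossBlockSVDResults(self, R, U, s, V)


@dataclass
class PermutationResult:
    """Max-statistic permutation null for component significance."""

    n_permutations: int
    null_max_stat: np.ndarray        # max sigma^2 per permutation
    null_explained_pct: np.ndarray   # explained-cov % of the top permuted component
    p_fwe: np.ndarray                # per-component FWE-corrected p-value
    added_explained_pct: float       # observed PC1 % minus null mean %
    seed: int | None

    def __post_init__(self) -> None:
        assert len(self.null_max_stat) == self.n_permutations


@dataclass
class BootstrapResult:
    """Per-feature bootstrap salience ratios and percentile CIs for one side."""

    n_bootstrap: int
    feature_names: list[str]
    salience: np.ndarray
    se: np.ndarray
    ratio: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    significant: np.ndarray
    component: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "salience": self.salience,
                "ratio": self.ratio,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "significant": self.significant,
            },
            index=pd.Index(self.feature_names, name="feature"),
        )


def added_explained_covariance(observed_pct: float, null_pcts: np.ndarray) -> float:
    """Observed explained covariance minus the permutation-null mean, in
    percentage points."""
    null_pcts = np.asarray(null_pcts, dtype=float)
    if null_pcts.size == 0:
        raise ValueError("empty permutation null")
    return float(observed_pct - null_pcts.mean())


def select_significant_features(result: BootstrapResult) -> list[str]:
    """Feature ids whose bootstrap CI excludes zero (either sign)."""
    return [n for n, sig in zip(result.feature_names, result.significant) if sig]


class CrossBlockSVDResults:
    """Fitted cross-block SVD: saliences, scores, explained covariance,
    and resampling-based inference."""

    def __init__(self, model: CrossBlockSVD, R, U, s, V):
        self.model = model
        self.cross_corr = R
        self.x_saliences = U
        self.singular_values = s
        self.y_saliences = V
        self.x_scores = model.X @ U
        self.y_scores = model.Y @ V
        self.nobs = model.nobs

    @property
    def n_components(self) -> int:
        return len(self.singular_values)

    @property
    def explained_covariance(self) -> np.ndarray:
        """Fraction of squared singular values per component (sums to 1)."""
        s2 = self.singular_values ** 2
        total = s2.sum()
        if total == 0:
            raise ValueError("all singular values are zero: no covariance structure")
        return s2 / total

    @property
    def explained_covariance_pct(self) -> np.ndarray:
        return 100.0 * self.explained_covariance

    def top_feature_contributions(self, component: int = 1, side: str = "x") -> pd.DataFrame:
        """Features ranked by |salience| on a component (1-based), signed
        values retained; ties keep feature order."""
        if not 1 <= component <= self.n_components:
            raise ValueError(f"component {component} out of range 1..{self.n_components}")
        if side == "x":
            weights, names = self.x_saliences[:, component - 1], self.model.x_names
        elif side == "y":
            weights, names = self.y_saliences[:, component - 1], self.model.y_names
        else:
            raise ValueError(f"side must be 'x' or 'y', got {side!r}")
        order = np.argsort(-np.abs(weights), kind="stable")
        return pd.DataFrame(
            {"salience": weights[order]},
            index=pd.Index([names[i] for i in order], name="feature"),
        )

    # ------------------------------------------------------------------
    # Permutation inference
    # ------------------------------------------------------------------
    def permutation_test(self, n_permutations: int = 1000,
                         seed: int | np.random.Generator | None = None) -> PermutationResult:
        """Max-statistic permutation test of component significance.

        Rows of Y are permuted (X fixed) after all preprocessing, which
        destroys only the X-Y link while preserving each block's internal
        covariance. Per permutation the maximum squared singular value
        across components is recorded; the FWE-corrected p-value of
        component i is (1 + #{null max >= observed sigma_i^2}) / (B + 1),
        so p is never below 1/(B+1).
        """
        if n_permutations < 100:
            raise ValueError("need at least 100 permutations for usable p-resolution")
        rng = np.random.default_rng(seed)
        X, Y = self.model.X, self.model.Y
        n = self.nobs
        K = self.n_components
        null_max = np.empty(n_permutations)
        null_pct = np.empty(n_permutations)
        for b in range(n_permutations):
            perm = rng.permutation(n)
            Rb = X.T @ Y[perm] / (n - 1)
            sb = np.linalg.svd(Rb, compute_uv=False)[:K]
            s2 = sb ** 2
            null_max[b] = s2.max()
            null_pct[b] = 100.0 * s2.max() / s2.sum()
        obs = self.singular_values ** 2
        p_fwe = (1.0 + (null_max[None, :] >= obs[:, None]).sum(axis=1)) / (n_permutations + 1.0)
        added = added_explained_covariance(self.explained_covariance_pct[0], null_pct)
        return PermutationResult(
            n_permutations=n_permutations,
            null_max_stat=null_max,
            null_explained_pct=null_pct,
            p_fwe=p_fwe,
            added_explained_pct=added,
            seed=seed if isinstance(seed, int) else None,
        )

    # ------------------------------------------------------------------
    # Bootstrap inference
    # ------------------------------------------------------------------
    def bootstrap_features(self, n_bootstrap: int = 1000,
                           seed: int | np.random.Generator | None = None,
                           component: int = 1,
                           ci_level: float = 0.95,
                           min_unique: int = 10) -> dict[str, BootstrapResult]:
        """Bootstrap feature significance on one component, both sides.

        Subjects are resampled with replacement jointly in X and Y; per
        replicate the SVD is recomputed and components matched to the
        original by maximal |inner product| of y-saliences, then
        sign-aligned, before the per-feature spread is accumulated. The
        ratio is the original salience over its bootstrap standard error;
        a feature is significant when its percentile CI excludes zero.

        Returns ``{"x": BootstrapResult, "y": BootstrapResult}``.
        """
        if n_bootstrap < 100:
            raise ValueError("need at least 100 bootstrap iterations")
        if not 1 <= component <= self.n_components:
            raise ValueError(f"component {component} out of range 1..{self.n_components}")
        rng = np.random.default_rng(seed)
        X, Y = self.model.X, self.model.Y
        n = self.nobs
        K = self.n_components
        k0 = component - 1
        u_ref = self.x_saliences[:, k0]
        v_ref = self.y_saliences[:, k0]
        boot_u = np.empty((n_bootstrap, X.shape[1]))
        boot_v = np.empty((n_bootstrap, Y.shape[1]))
        for b in range(n_bootstrap):
            while True:
                idx = rng.integers(0, n, size=n)
                if len(np.unique(idx)) >= min_unique:
                    break
            Xb, Yb = X[idx], Y[idx]
            # bootstrap rows are not exactly standardised; re-centre/scale so
            # the decomposed matrix stays a correlation matrix
            Xb = _restandardise(Xb)
            Yb = _restandardise(Yb)
            Rb = Xb.T @ Yb / (n - 1)
            Ub, sb, Vbt = np.linalg.svd(Rb, full_matrices=False)
            Vb = Vbt.T
            # axis alignment: match to the original component by |<v_b, v_ref>|
            match = int(np.argmax(np.abs(v_ref @ Vb[:, :K])))
            sign = np.sign(v_ref @ Vb[:, match]) or 1.0
            boot_u[b] = sign * Ub[:, match]
            boot_v[b] = sign * Vb[:, match]
        alpha = 1.0 - ci_level
        results = {}
        for side, ref, boot, names in (
            ("x", u_ref, boot_u, self.model.x_names),
            ("y", v_ref, boot_v, self.model.y_names),
        ):
            se = boot.std(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(se > 0, ref / se, np.inf * np.sign(ref))
            ci_low = np.quantile(boot, alpha / 2, axis=0)
            ci_high = np.quantile(boot, 1 - alpha / 2, axis=0)
            significant = (ci_low > 0) | (ci_high < 0)
            results[side] = BootstrapResult(
                n_bootstrap=n_bootstrap,
                feature_names=list(names),
                salience=ref.copy(),
                se=se,
                ratio=ratio,
                ci_low=ci_low,
                ci_high=ci_high,
                significant=significant,
                component=component,
                seed=seed if isinstance(seed, int) else None,
            )
        return results

    def summary(self, permutation: PermutationResult | None = None) -> str:
        """Plain-text component table: singular value, explained covariance,
        and (when a permutation result is supplied) FWE p-values."""
        lines = [
            "Cross-block SVD results",
            "=" * 58,
            f"subjects: {self.nobs}   X features: {len(self.model.x_names)}   "
            f"Y features: {len(self.model.y_names)}",
            "-" * 58,
            f"{'component':>9} {'sigma':>10} {'expl.cov %':>11}"
            + (f" {'p (FWE)':>9}" if permutation is not None else ""),
        ]
        for k in range(self.n_components):
            row = (f"{k + 1:>9d} {self.singular_values[k]:>10.4f} "
                   f"{self.explained_covariance_pct[k]:>11.2f}")
            if permutation is not None:
                row += f" {permutation.p_fwe[k]:>9.4f}"
            lines.append(row)
        if permutation is not None:
            lines.append("-" * 58)
            lines.append(
                f"added explained covariance (PC1): "
                f"{permutation.added_explained_pct:.2f} pp "
                f"({permutation.n_permutations} permutations)"
            )
        return "\n".join(lines)


def _restandardise(A: np.ndarray) -> np.ndarray:
    sd = A.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (A - A.mean(axis=0)) / sd
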