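"""Data conditioning upstream of the cross-block SVD.

The per-analysis pipeline is: complete-case subject intersection ->
Box-Cox + z-score of covariates -> Box-Cox + z-score (or rank transform)
of the variables -> robust-regression covariate removal (intercept +
residuals) -> re-standardisation of the adjusted columns, so that the
cross-product of the two blocks is a correlation matrix.

Also implements the clinical derivations feeding the phenotype block:
per-subject longitudinal slopes of the MDS-UPDRS motor subscores, the
absolute levodopa response (OFF minus ON totals), and the levodopa
equivalent daily dose (LEDD) from medication logs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import yaml

from .datatypes import (
    MedicationRecord,
    PhenotypeBlock,
    UPDRS_FEATURES,
    VisitRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AdjustedBlock",
    "adjust_covariates",
    "boxcox_zscore",
    "rank_transform",
    "zscore",
    "fit_slopes",
    "group_updrs_subscores",
    "compute_ledd",
    "compute_alr",
    "filter_nonvariable",
    "add_drug_dummies",
    "load_subscore_map",
    "load_ledd_table",
    "HUBER_TUNING",
]

#: Huber M-estimator tuning constant (95% efficiency under normality).
HUBER_TUNING = 1.345


@dataclass
class AdjustedBlock:
    """A transformed block with its per-feature Box-Cox parameters."""

    values: pd.DataFrame
    lambdas: pd.Series | None = None
    shifts: pd.Series | None = None


def _as_frame(block) -> pd.DataFrame:
    if isinstance(block, pd.DataFrame):
        return block
    if hasattr(block, "values") and isinstance(block.values, pd.DataFrame):
        return block.values
    return pd.DataFrame(block)


def zscore(block) -> pd.DataFrame:
    """Column-wise standardisation to mean 0, sd 1 (ddof=1)."""
    df = _as_frame(block)
    sd = df.std(ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"cannot z-score constant columns: {bad[:5]}")
    return (df - df.mean()) / sd


def boxcox_zscore(block, lambda_bounds: tuple[float, float] = (-5.0, 5.0),
                  lmbda: float | None = None) -> AdjustedBlock:
    """Box-Cox transform each column (profile-likelihood lambda), then z-score.

    Columns with non-positive values are shifted by ``1 - min`` to strict
    positivity first; the shift and the fitted lambda are recorded so the
    transform is reportable. ``lmbda`` fixes the exponent for every column
    instead of estimating it (0 gives the log transform).
    """
    df = _as_frame(block).astype(float)
    out = {}
    lambdas = {}
    shifts = {}
    for col in df.columns:
        x = df[col].to_numpy()
        if not np.isfinite(x).all():
            raise ValueError(f"column {col!r} contains non-finite values")
        if np.ptp(x) == 0:
            raise ValueError(f"column {col!r} is constant; cannot Box-Cox/z-score")
        shift = 1.0 - x.min() if x.min() <= 0 else 0.0
        xp = x + shift
        if lmbda is None:
            lam = scipy.stats.boxcox_normmax(xp, brack=lambda_bounds, method="mle")
            lam = float(np.clip(lam, *lambda_bounds))
        else:
            lam = float(lmbda)
        transformed = scipy.stats.boxcox(xp, lmbda=lam)
        transformed = (transformed - transformed.mean()) / transformed.std(ddof=1)
        out[col] = transformed
        lambdas[col] = lam
        shifts[col] = shift
    values = pd.DataFrame(out, index=df.index)[df.columns]
    return AdjustedBlock(values, pd.Series(lambdas), pd.Series(shifts))


def rank_transform(block) -> pd.DataFrame:
    """Per-column ascending ranks 1..n, ties receiving average ranks."""
    df = _as_frame(block)
    ranked = df.apply(lambda col: scipy.stats.rankdata(col, method="average"))
    return pd.DataFrame(ranked, index=df.index, columns=df.columns)


def adjust_covariates(block, covariates: pd.DataFrame, method: str = "huber",
                      maxiter: int = 50, tol: float = 1e-8) -> pd.DataFrame:
    """Remove covariate effects from each feature column.

    Each column y is regressed on the covariates (robust Huber M-estimation
    by default, ``method='ols'`` for ordinary least squares) and replaced by
    intercept + residuals, so the covariate-explained part is removed while
    the column keeps its location.
    """
    df = _as_frame(block).astype(float)
    cov = covariates.loc[df.index].astype(float)
    X = sm.add_constant(cov.to_numpy(), has_constant="add")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify collinear columns by checking rank drop when removed
        collinear = []
        for j, name in enumerate(cov.columns):
            reduced = np.delete(X, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                collinear.append(name)
        raise ValueError(f"rank-deficient covariate matrix; collinear columns: {collinear}")
    out = {}
    for col in df.columns:
        y = df[col].to_numpy()
        if method == "huber":
            model = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=HUBER_TUNING))
            fit = model.fit(maxiter=maxiter, tol=tol)
        elif method == "ols":
            fit = sm.OLS(y, X).fit()
        else:
            raise ValueError(f"unknown adjustment method: {method!r}")
        out[col] = fit.params[0] + fit.resid
    return pd.DataFrame(out, index=df.index)[df.columns]


def load_subscore_map(path: str | Path | None = None) -> dict[str, list[str]]:
    """Load the item -> subscore grouping (default: shipped clinical map)."""
    if path is None:
        text = resources.files("plscova.data").joinpath("updrs_subscores.yaml").read_text()
        mapping = yaml.safe_load(text)
    else:
        with open(path) as fh:
            mapping = yaml.safe_load(fh)
    all_items = [i for items in mapping.values() for i in items]
    if len(all_items) != len(set(all_items)):
        raise ValueError("subscore map assigns some item to more than one group")
    return mapping


def group_updrs_subscores(visit: VisitRecord,
                          subscore_map: dict[str, list[str]] | None = None) -> dict[str, float]:
    """Collapse the 33 motor items to 4 subscores plus the total.

    Returns tremor, bradykinesia, rigidity and axial sums plus
    ``total`` = sum of all 33 items. The four groups partition the items,
    so the subscores always sum to the total.
    """
    mapping = subscore_map if subscore_map is not None else load_subscore_map()
    out: dict[str, float] = {}
    for group in ("tremor", "bradykinesia", "rigidity", "axial"):
        total = 0.0
        for item in mapping[group]:
            if item not in visit.items:
                raise KeyError(f"visit for {visit.subject_id} missing item {item!r}")
            total += visit.items[item]
        out[group] = total
    out["total"] = float(sum(visit.items.values()))
    return out


def fit_slopes(visits: list[VisitRecord],
               subscore_map: dict[str, list[str]] | None = None,
               min_visits: int = 3,
               medication_state: str = "ON") -> PhenotypeBlock:
    """Per-subject least-squares slope of each subscore against time.

    Time is measured in years since the subject's first included visit.
    Subjects with fewer than ``min_visits`` assessments in the requested
    medication state are excluded and logged, mirroring the inclusion rule
    of at least three on-medication motor evaluations.
    """
    mapping = subscore_map if subscore_map is not None else load_subscore_map()
    by_subject: dict[str, list[VisitRecord]] = {}
    for v in visits:
        if v.medication_state == medication_state:
            by_subject.setdefault(v.subject_id, []).append(v)
    rows = {}
    for subject, svisits in by_subject.items():
        if len(svisits) < min_visits:
            logger.info("excluding subject %s: %d %s-state visits (< %d)",
                        subject, len(svisits), medication_state, min_visits)
            continue
        svisits = sorted(svisits, key=lambda v: v.visit_time)
        t = np.array([v.visit_time for v in svisits], dtype=float)
        t = t - t[0]
        features = pd.DataFrame([group_updrs_subscores(v, mapping) for v in svisits])
        slopes = {}
        for feat in UPDRS_FEATURES:
            slopes[feat] = np.polyfit(t, features[feat].to_numpy(), 1)[0]
        rows[subject] = slopes
    if not rows:
        raise ValueError("no subject satisfies the minimum-visit inclusion rule")
    values = pd.DataFrame.from_dict(rows, orient="index")[UPDRS_FEATURES]
    values.index.name = "subject_id"
    return PhenotypeBlock(values.sort_index())


def compute_alr(visits: list[VisitRecord],
                subscore_map: dict[str, list[str]] | None = None,
                time_tol: float = 1e-6) -> pd.DataFrame:
    """Absolute levodopa response per paired visit: OFF total minus ON total.

    Visits are paired by identical visit time; positive values mean
    improvement under drug. Subjects with no paired OFF/ON assessment are
    excluded with a log entry. Longitudinal summaries (slopes of aLR) are
    obtained by feeding the result to a slope fit.
    """
    mapping = subscore_map if subscore_map is not None else load_subscore_map()
    rows = []
    by_subject: dict[str, list[VisitRecord]] = {}
    for v in visits:
        by_subject.setdefault(v.subject_id, []).append(v)
    for subject, svisits in by_subject.items():
        on = {round(v.visit_time, 6): v for v in svisits if v.medication_state == "ON"}
        off = {round(v.visit_time, 6): v for v in svisits if v.medication_state == "OFF"}
        paired = sorted(set(on) & set(off))
        if not paired:
            logger.info("excluding subject %s: no paired OFF/ON visits", subject)
            continue
        for t in paired:
            off_total = group_updrs_subscores(off[t], mapping)["total"]
            on_total = group_updrs_subscores(on[t], mapping)["total"]
            rows.append({"subject_id": subject, "visit_time": t, "alr": off_total - on_total})
    if not rows:
        raise ValueError("no subject has paired OFF/ON visits")
    return pd.DataFrame(rows)


def load_ledd_table(path: str | Path | None = None) -> dict:
    """Load the LEDD conversion table (default: shipped table)."""
    if path is None:
        text = resources.files("plscova.data").joinpath("ledd_table.yaml").read_text()
        return yaml.safe_load(text)
    with open(path) as fh:
        return yaml.safe_load(fh)


def _match_drug(name: str, table: dict) -> tuple[str, dict] | None:
    """Keyword match a medication name against a conversion table section."""
    lowered = name.lower()
    # longest-keyword-first so 'levodopa controlled release' beats 'levodopa'
    candidates = []
    for key, entry in table.items():
        keywords = [key.replace("_", " ")] + list(entry.get("keywords", []))
        for kw in keywords:
            if kw in lowered:
                candidates.append((len(kw), key, entry))
    if not candidates:
        return None
    _, key, entry = max(candidates)
    return key, entry


def compute_ledd(records: list[MedicationRecord],
                 conversion_table: dict | None = None) -> float:
    """Total levodopa-equivalent daily dose (mg/day) from a medication log.

    LEDD = sum over drugs of dose x frequency x factor. COMT inhibitors do
    not contribute a dose of their own: they multiply the subject's
    concurrent levodopa equivalents (e.g. entacapone x1.33).
    """
    table = conversion_table if conversion_table is not None else load_ledd_table()
    drugs = table.get("drugs", {})
    comt = table.get("comt_inhibitors", {})
    levodopa_ledd = 0.0
    other_ledd = 0.0
    multiplier = 1.0
    for rec in records:
        comt_hit = _match_drug(rec.drug_name, comt)
        if comt_hit is not None:
            multiplier = max(multiplier, float(comt_hit[1]["levodopa_multiplier"]))
            continue
        hit = _match_drug(rec.drug_name, drugs)
        if hit is None:
            logger.warning("skipping unrecognised medication %r", rec.drug_name)
            continue
        key, entry = hit
        expected_unit = entry.get("unit", "mg")
        if rec.unit.lower() != expected_unit:
            raise ValueError(
                f"unknown unit {rec.unit!r} for {rec.drug_name!r} (expected {expected_unit})"
            )
        contribution = rec.dose * rec.frequency * float(entry["factor"])
        if key.startswith("levodopa"):
            levodopa_ledd += contribution
        else:
            other_ledd += contribution
    return levodopa_ledd * multiplier + other_ledd


def filter_nonvariable(block) -> tuple[pd.DataFrame, list]:
    """Drop zero-variance columns; return (filtered block, kept column ids)."""
    df = _as_frame(block)
    variable = df.columns[df.std(ddof=0) > 0]
    return df[variable], list(variable)


def add_drug_dummies(covariates: pd.DataFrame, drug_flags: pd.DataFrame) -> pd.DataFrame:
    """Append 0/1 drug-use indicator columns to the covariate table.

    Constant (all-zero or all-one) flag columns are dropped — they carry no
    information and would break the regression design.
    """
    flags = drug_flags.loc[covariates.index]
    arr = flags.to_numpy()
    if not np.isin(arr, [0, 1]).all():
        raise ValueError("drug flags must be binary 0/1")
    keep = [c for c in flags.columns if flags[c].nunique() > 1]
    dropped = sorted(set(flags.columns) - set(keep))
    if dropped:
        logger.info("dropping constant drug-flag columns: %s", dropped)
    return pd.concat([covariates, flags[keep].astype(float)], axis=1)
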