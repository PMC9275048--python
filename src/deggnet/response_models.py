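"""Pairwise logistic models of treatment response with a gene-ratio term.

For a pair of network-linked genes the binary treatment response
(Good = 1, None = 0; Moderate responders are excluded to sharpen the
contrast) is modelled as

    outcome ~ 1 + gene_1 + gene_2 + ratio_term + covariates

On log-scale expression a literal log-ratio (difference) is exactly
collinear with the two additive gene terms, so the default ratio term is
the centered product of the two log-expressions; a raw-scale ratio
(2^g1 / 2^g2) is available via ``term_mode="raw-ratio"``.  Predictive value
is quantified by the in-sample ROC AUC of the model with and without the
ratio term.

Logistic fits go through statsmodels (Newton/IRLS maximum likelihood); the
ROC/AUC computation is authored here with the rank (Mann-Whitney) formula,
tie-corrected, and is cross-checked against the trapezoidal curve integral.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

from .diff_interaction import DifferentialEdgeResult, _check_design, _reference_level
from .exceptions import ValidationError
from .io_formats import ExpressionMatrix, SampleAnnotation, _write_table

logger = logging.getLogger(__name__)

SEPARATION_BETA = 50.0  # |coef| bound on standardized inputs flagging separation
LOGIT_TOL = 1e-8
LOGIT_MAX_ITER = 100


@dataclass
class ROCCurve:
    """Threshold sweep of a score against binary labels."""

    thresholds: np.ndarray  # decreasing
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float  # rank (Mann-Whitney) AUC, ties counted 1/2

    @property
    def auc_trapezoid(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))


@dataclass
class RatioModelResult:
    """Logistic response model for one gene pair."""

    gene_1: str
    gene_2: str
    coefficients: dict[str, float]
    interaction_p: float
    auc_with: float
    auc_without: float
    n_good: int
    n_none: int
    separation_flag: bool = False
    loglike_with: float = field(default=float("nan"))
    loglike_without: float = field(default=float("nan"))
    term_mode: str = "product"

    def as_record(self) -> dict:
        rec: dict = {"gene_1": self.gene_1, "gene_2": self.gene_2}
        for name, val in self.coefficients.items():
            rec[f"coef_{name}"] = val
        rec.update(
            interaction_p=self.interaction_p,
            auc_with=self.auc_with,
            auc_without=self.auc_without,
            n_good=self.n_good,
            n_none=self.n_none,
            separation_flag=self.separation_flag,
        )
        return rec


def select_response_samples(annot: SampleAnnotation, min_per_class: int = 3) -> SampleAnnotation:
    """Keep Good and None responders only (Moderate and missing dropped)."""
    resp = annot.response
    keep = resp.isin(["Good", "None"])
    kept = annot.subset(list(annot.frame.index[keep]))
    n_good = int((kept.response == "Good").sum())
    n_none = int((kept.response == "None").sum())
    if n_good < min_per_class or n_none < min_per_class:
        raise ValidationError(
            f"need >= {min_per_class} samples per response class; got Good={n_good}, None={n_none}"
        )
    return kept


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """ROC curve and AUC for a score vector against binary labels.

    AUC uses the rank (Mann-Whitney) formula with ties counted 1/2; the
    curve is a threshold sweep over the unique scores and its trapezoidal
    integral equals the rank AUC to numerical precision.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must have equal length")
    pos = labels == 1
    neg = labels == 0
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both outcome classes must be present")

    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    tpr = np.array([(scores[pos] >= t).sum() / n_pos for t in thresholds])
    fpr = np.array([(scores[neg] >= t).sum() / n_neg for t in thresholds])
    return ROCCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=float(auc))


def _fit_logit(y: np.ndarray, X: np.ndarray):
    """Newton ML fit; falls back to BFGS when the Newton step degenerates
    (perfect separation makes the Hessian singular)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return sm.Logit(y, X).fit(
                method="newton", tol=LOGIT_TOL, maxiter=LOGIT_MAX_ITER, disp=0
            )
        except Exception:  # singular Hessian / separation
            return sm.Logit(y, X).fit(method="bfgs", maxiter=LOGIT_MAX_ITER, disp=0)


def _ratio_term(g1: np.ndarray, g2: np.ndarray, mode: str) -> tuple[np.ndarray, str]:
    if mode == "product":
        return (g1 - g1.mean()) * (g2 - g2.mean()), "ratio_product"
    if mode == "raw-ratio":
        return np.exp2(g1) / np.exp2(g2), "ratio_raw"
    raise ValidationError(f"unknown ratio-term mode {mode!r}")


def fit_ratio_logistic(
    expr: ExpressionMatrix,
    annot_binary: SampleAnnotation,
    gene_1: str,
    gene_2: str,
    covariates: list[str] | None = None,
    term_mode: str = "product",
) -> RatioModelResult:
    """Fit outcome ~ gene_1 + gene_2 + ratio term (+ covariates).

    The design is standardized internally for numerical stability and
    separation detection (|coef| > 50 on standardized inputs flags a
    diverged fit: interaction p is set to missing, AUCs still reported);
    reported coefficients are back-transformed to the raw scale.
    """
    gene_1, gene_2 = gene_1.upper(), gene_2.upper()
    outcome = annot_binary.outcome
    samples = [
        s
        for s in annot_binary.sample_ids
        if s in set(expr.sample_ids) and np.isfinite(outcome.loc[s])
    ]
    annot_s = annot_binary.subset(samples)
    y = annot_s.outcome.to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValidationError("both outcome classes must be present")

    g1 = expr.gene(gene_1).loc[samples].to_numpy(dtype=float)
    g2 = expr.gene(gene_2).loc[samples].to_numpy(dtype=float)
    ratio, ratio_name = _ratio_term(g1, g2, term_mode)

    cols = [np.ones(len(y)), g1, g2, ratio]
    names = ["intercept", gene_1, gene_2, ratio_name]
    if covariates:
        cov_df = annot_s.frame[list(covariates)]
        if cov_df.isna().any().any():
            raise ValidationError("missing covariate values among fitted samples")
        for name in cov_df.columns:
            col = cov_df[name]
            if pd.api.types.is_numeric_dtype(col):
                cols.append(col.to_numpy(dtype=float))
                names.append(name)
            else:
                cref = _reference_level(col)
                for lev in sorted(set(col.unique()) - {cref}):
                    cols.append((col == lev).to_numpy(dtype=float))
                    names.append(f"{name}[{lev}]")
    X = np.column_stack(cols)
    _check_design(X, names, len(y))

    # standardize all non-intercept columns (binary dummies included; the
    # Wald p of each term is invariant to column scaling)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    mu[0], sd[0] = 0.0, 1.0
    sd[sd == 0] = 1.0
    Xz = (X - mu) / sd

    fit_with = _fit_logit(y, Xz)
    # diverging standardized coefficients or a perfect in-sample fit both
    # indicate separation: the MLE does not exist
    fitted = 1.0 / (1.0 + np.exp(-(Xz @ fit_with.params)))
    separated = bool(
        np.any(np.abs(fit_with.params) > SEPARATION_BETA)
        or np.max(np.abs(y - fitted)) < 1e-4
    )
    ratio_idx = names.index(ratio_name)
    interaction_p = float("nan") if separated else float(fit_with.pvalues[ratio_idx])

    scores_with = Xz @ fit_with.params
    auc_with = roc_auc(scores_with, y).auc

    keep = [i for i in range(len(names)) if i != ratio_idx]
    fit_without = _fit_logit(y, Xz[:, keep])
    scores_without = Xz[:, keep] @ fit_without.params
    auc_without = roc_auc(scores_without, y).auc

    # back-transform standardized coefficients to the raw scale
    beta_z = fit_with.params
    beta_raw = beta_z / sd
    beta_raw[0] = beta_z[0] - float(np.sum(beta_z[1:] * mu[1:] / sd[1:]))
    return RatioModelResult(
        gene_1=gene_1,
        gene_2=gene_2,
        coefficients=dict(zip(names, beta_raw.tolist())),
        interaction_p=interaction_p,
        auc_with=float(auc_with),
        auc_without=float(auc_without),
        n_good=int((y == 1).sum()),
        n_none=int((y == 0).sum()),
        separation_flag=separated,
        loglike_with=float(fit_with.llf),
        loglike_without=float(fit_without.llf),
        term_mode=term_mode,
    )


def evaluate_pairs(
    edge_results: list[DifferentialEdgeResult],
    expr: ExpressionMatrix,
    annot_binary: SampleAnnotation,
    covariates: list[str] | None = None,
    alpha: float = 0.05,
    term_mode: str = "product",
) -> list[RatioModelResult]:
    """Ratio-logistic model for every differential edge with p_raw < alpha.

    Results are sorted by in-sample AUC of the full model, descending;
    pairs whose logistic fit fails a precondition are skipped and logged.
    """
    out = []
    for res in edge_results:
        if not (res.p_raw < alpha):
            continue
        try:
            out.append(
                fit_ratio_logistic(
                    expr, annot_binary, res.gene_a, res.gene_b, covariates, term_mode
                )
            )
        except (ValidationError, KeyError) as exc:
            logger.info("evaluate_pairs: skipping %s-%s: %s", res.gene_a, res.gene_b, exc)
    out.sort(key=lambda r: (-r.auc_with, r.gene_1, r.gene_2))
    return out


MODEL_TABLE_BASE_COLUMNS = [
    "gene_1",
    "gene_2",
    "interaction_p",
    "auc_with",
    "auc_without",
    "n_good",
    "n_none",
    "separation_flag",
]


def write_model_table(results: list[RatioModelResult], path, header_lines=()) -> None:
    """Write ratio-model results as TSV (base header only when empty)."""
    rows = [r.as_record() for r in results]
    df = pd.DataFrame(rows) if rows else pd.DataFrame(columns=MODEL_TABLE_BASE_COLUMNS)
    _write_table(df, path, header_lines)
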