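"""Ranking-performance statistics for continuous risk metrics.

Given a continuous metric per drug and three-level risk labels
(low / intermediate / high), this module computes:

* ROC AUC on the two printed dichotomies (low vs intermediate+high and
  low+intermediate vs high), as the midrank Mann-Whitney estimator;
* a univariable maximum-likelihood logistic regression with the
  likelihood-ratio chi-square against the intercept-only null;
* Pearson r-squared against a reference metric;
* a two-sample t-test (Welch by default) between the low group and the
  rest.

Metric orientation is explicit per metric; evaluation never guesses
direction from data. AUC tie handling is midrank throughout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats
from scipy.special import expit

from .errors import DegenerateStatisticsError, ValidationError
from .panel_io import DrugPanel, Risk

__all__ = [
    "Dichotomy",
    "LOW_VS_REST",
    "HIGH_VS_REST",
    "RocResult",
    "LogisticFit",
    "TTestResult",
    "MetricEvaluation",
    "EvaluationReport",
    "roc_auc",
    "logistic_fit",
    "pearson_r2",
    "two_sample_t",
    "evaluate_metrics",
]


@dataclass(frozen=True)
class Dichotomy:
    """A binarization of the three risk levels."""

    name: str
    positive_classes: frozenset[Risk]

    def labels(self, risks: Sequence[Risk]) -> np.ndarray:
        return np.array([1 if r in self.positive_classes else 0 for r in risks])


LOW_VS_REST = Dichotomy("low_vs_rest", frozenset({Risk.INTERMEDIATE, Risk.HIGH}))
HIGH_VS_REST = Dichotomy("high_vs_rest", frozenset({Risk.HIGH}))


@dataclass(frozen=True)
class RocResult:
    auc: float
    n_pos: int
    n_neg: int
    dichotomy: Dichotomy | None = None
    orientation_applied: bool = False


@dataclass(frozen=True)
class LogisticFit:
    intercept: float
    slope: float
    loglik_model: float
    loglik_null: float
    chi2: float
    converged: bool
    separation_detected: bool


class TTestResult(NamedTuple):
    t: float
    df: float
    p: float


def _as_arrays(scores: Sequence[float], labels: Sequence[int]):
    x = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("scores and labels must be 1-D sequences of equal length")
    if not np.all(np.isfinite(x)):
        raise ValidationError("scores must be finite")
    if not np.all((y == 0) | (y == 1)):
        raise ValidationError("labels must be binary (0/1)")
    return x, y


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[int],
    higher_is_positive: bool = True,
    dichotomy: Dichotomy | None = None,
) -> RocResult:
    """Midrank Mann-Whitney ROC AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    x, y = _as_arrays(scores, labels)
    orientation_applied = False
    if not higher_is_positive:
        x = -x
        orientation_applied = True
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DegenerateStatisticsError(
            "ROC AUC undefined: both classes must be present "
            f"(n_pos={n_pos}, n_neg={n_neg})"
        )
    ranks = stats.rankdata(x, method="average")
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return RocResult(
        auc=float(auc),
        n_pos=n_pos,
        n_neg=n_neg,
        dichotomy=dichotomy,
        orientation_applied=orientation_applied,
    )


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + e^eta), computed stably
    return float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))


def _detect_separation(x: np.ndarray, y: np.ndarray) -> bool:
    """Complete or quasi-complete separation for a univariable logit.

    Holds iff a threshold splits the classes with at most boundary ties.
    """
    pos, neg = x[y == 1], x[y == 0]
    return bool(pos.min() >= neg.max() or neg.min() >= pos.max())


def logistic_fit(
    scores: Sequence[float],
    labels: Sequence[int],
    *,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticFit:
    """Maximum-likelihood fit of ``logit(p) = a + b * score``.

    Newton iterations with step halving until the gradient's infinity
    norm drops below ``tol``. ``chi2`` is the likelihood-ratio statistic
    ``2 * (loglik_model - loglik_null)`` against the intercept-only null.
    Complete/quasi-complete separation is reported from the last stable
    iterate with ``converged=False``.
    """
    x, y = _as_arrays(scores, labels)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == len(y):
        raise DegenerateStatisticsError(
            "logistic fit undefined: both classes must be present"
        )
    pbar = y.mean()
    loglik_null = float(
        len(y) * (pbar * math.log(pbar) + (1 - pbar) * math.log(1 - pbar))
    )
    if np.ptp(x) == 0:
        # constant score: slope 0, model reduces to the null
        return LogisticFit(
            intercept=float(math.log(pbar / (1 - pbar))),
            slope=0.0,
            loglik_model=loglik_null,
            loglik_null=loglik_null,
            chi2=0.0,
            converged=True,
            separation_detected=False,
        )
    separated = _detect_separation(x, y)
    design = np.column_stack([np.ones_like(x), x])
    beta = np.array([math.log(pbar / (1 - pbar)), 0.0])
    loglik = _bernoulli_loglik(design @ beta, y)
    converged = False
    iter_cap = 25 if separated else max_iter
    for _ in range(iter_cap):
        eta = design @ beta
        p = expit(eta)
        grad = design.T @ (y - p)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        w = p * (1.0 - p)
        hessian = design.T @ (design * w[:, None])
        try:
            step = np.linalg.solve(hessian, grad)
        except np.linalg.LinAlgError:
            break
        # step halving keeps the likelihood monotone
        for _ in range(30):
            candidate = beta + step
            cand_loglik = _bernoulli_loglik(design @ candidate, y)
            if cand_loglik >= loglik - 1e-12:
                break
            step = step / 2.0
        beta = beta + step
        loglik = cand_loglik
    if separated:
        converged = False
    chi2 = max(0.0, 2.0 * (loglik - loglik_null))
    return LogisticFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        loglik_model=float(loglik),
        loglik_null=loglik_null,
        chi2=float(chi2),
        converged=converged,
        separation_detected=separated,
    )


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Square of the Pearson product-moment correlation."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValidationError("pearson_r2 needs two equal-length sequences, n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateStatisticsError("correlation undefined for constant input")
    r = stats.pearsonr(a, b).statistic
    return float(r * r)


def two_sample_t(
    a: Sequence[float], b: Sequence[float], *, equal_var: bool = False
) -> TTestResult:
    """Two-sided two-sample t-test; Welch by default, pooled on request."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateStatisticsError("each group needs at least 2 observations")
    result = stats.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = float(len(a) + len(b) - 2)
    else:
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        df = float(
            (va + vb) ** 2
            / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        )
    return TTestResult(t=float(result.statistic), df=df, p=float(result.pvalue))


# --------------------------------------------------------------------------
# Batch evaluation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MetricEvaluation:
    """All statistics for one metric column."""

    metric: str
    higher_is_riskier: bool
    roc: Mapping[str, RocResult]
    logistic: LogisticFit
    logistic_dichotomy: str
    t_test: TTestResult | None = None
    r2_vs_reference: float | None = None


@dataclass
class EvaluationReport:
    metrics: dict[str, MetricEvaluation] = field(default_factory=dict)
    reference_metric: str | None = None
    n_drugs: int = 0

    def to_dict(self) -> dict:
        out: dict = {"n_drugs": self.n_drugs, "reference_metric": self.reference_metric,
                     "metrics": {}}
        for name, ev in self.metrics.items():
            out["metrics"][name] = {
                "higher_is_riskier": ev.higher_is_riskier,
                "roc_auc": {
                    dname: {
                        "auc": r.auc,
                        "n_pos": r.n_pos,
                        "n_neg": r.n_neg,
                        "orientation_applied": r.orientation_applied,
                    }
                    for dname, r in ev.roc.items()
                },
                "logistic": {
                    "dichotomy": ev.logistic_dichotomy,
                    "intercept": ev.logistic.intercept,
                    "slope": ev.logistic.slope,
                    "chi2": ev.logistic.chi2,
                    "loglik_model": ev.logistic.loglik_model,
                    "loglik_null": ev.logistic.loglik_null,
                    "converged": ev.logistic.converged,
                    "separation_detected": ev.logistic.separation_detected,
                },
                "t_test": (
                    {"t": ev.t_test.t, "df": ev.t_test.df, "p": ev.t_test.p}
                    if ev.t_test is not None
                    else None
                ),
                "r2_vs_reference": ev.r2_vs_reference,
            }
        return out

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_csv_rows(self) -> list[dict]:
        """Flat rows mirroring the printed performance table."""
        rows = []
        for name, ev in self.metrics.items():
            rows.append(
                {
                    "metric": name,
                    "roc_auc_low_vs_rest": ev.roc["low_vs_rest"].auc,
                    "roc_auc_high_vs_rest": ev.roc["high_vs_rest"].auc,
                    "r2_vs_reference": (
                        "" if ev.r2_vs_reference is None else ev.r2_vs_reference
                    ),
                    "chi2": ev.logistic.chi2,
                    "t": "" if ev.t_test is None else ev.t_test.t,
                    "p": "" if ev.t_test is None else ev.t_test.p,
                }
            )
        return rows


def evaluate_metrics(
    panel: DrugPanel | Sequence[Risk],
    metric_columns: Mapping[str, Sequence[float]],
    reference_metric: str | None = None,
    *,
    orientations: Mapping[str, bool] | None = None,
    logistic_dichotomy: Dichotomy = LOW_VS_REST,
    equal_var_t: bool = False,
) -> EvaluationReport:
    """Evaluate named metric columns against three-level risk labels.

    ``panel`` is either a :class:`DrugPanel` (risk taken from its labeled
    drugs; every metric column must align with ``panel.drugs``) or a bare
    sequence of :class:`Risk` labels aligned with the columns.
    ``orientations`` maps metric name -> higher_is_riskier (default True);
    declare lower-is-riskier reference metrics explicitly.
    """
    if isinstance(panel, DrugPanel):
        risks_all = [d.risk for d in panel]
    else:
        risks_all = list(panel)
    keep = [i for i, r in enumerate(risks_all) if r is not None]
    if not keep:
        raise ValidationError("no risk-labeled drugs to evaluate")
    risks = [risks_all[i] for i in keep]
    orientations = dict(orientations or {})

    columns: dict[str, np.ndarray] = {}
    for name, values in metric_columns.items():
        values = np.asarray(values, dtype=float)
        if len(values) != len(risks_all):
            raise ValidationError(
                f"metric {name!r} has {len(values)} values for {len(risks_all)} drugs"
            )
        col = values[keep]
        if not np.all(np.isfinite(col)):
            raise ValidationError(f"metric {name!r} has missing values on labeled drugs")
        columns[name] = col
    if reference_metric is not None and reference_metric not in columns:
        raise ValidationError(f"reference metric {reference_metric!r} not among columns")

    low_mask = np.array([r is Risk.LOW for r in risks])
    report = EvaluationReport(reference_metric=reference_metric, n_drugs=len(risks))
    for name, col in columns.items():
        higher_is_riskier = orientations.get(name, True)
        roc = {}
        for dichotomy in (LOW_VS_REST, HIGH_VS_REST):
            roc[dichotomy.name] = roc_auc(
                col,
                dichotomy.labels(risks),
                higher_is_positive=higher_is_riskier,
                dichotomy=dichotomy,
            )
        oriented = col if higher_is_riskier else -col
        logistic = logistic_fit(oriented, logistic_dichotomy.labels(risks))
        t_test = None
        if low_mask.sum() >= 2 and (~low_mask).sum() >= 2:
            t_test = two_sample_t(col[~low_mask], col[low_mask], equal_var=equal_var_t)
        r2 = None
        if reference_metric is not None and name != reference_metric:
            r2 = pearson_r2(col, columns[reference_metric])
        report.metrics[name] = MetricEvaluation(
            metric=name,
            higher_is_riskier=higher_is_riskier,
            roc=roc,
            logistic=logistic,
            logistic_dichotomy=logistic_dichotomy.name,
            t_test=t_test,
            r2_vs_reference=r2,
        )
    return report
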