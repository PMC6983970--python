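"""Genome-wide univariate Cox screening and group survival comparison.

The per-gene fit maximizes the Cox partial likelihood with Efron handling of
tied event times by a Newton iteration with step-halving (single covariate,
so the whole screen is vectorizable per gene and fast genome-wide). The Wald
p-value of the coefficient drives the favourable / unfavourable call.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.special import ndtr

from .datatypes import ExpressionMatrix, SurvivalTable

__all__ = [
    "GeneSurvivalResult",
    "filter_zero_heavy",
    "cox_screen",
    "select_network_genes",
    "compare_groups",
    "cox_univariate",
]

log = logging.getLogger(__name__)


@dataclass
class GeneSurvivalResult:
    gene_id: str
    coef: float
    hazard_ratio: float
    p_value: float
    direction: str  # favourable | unfavourable | none
    converged: bool = True

    @staticmethod
    def classify(coef: float, p_value: float, p_threshold: float = 0.05) -> str:
        if p_value < p_threshold and coef > 0:
            return "unfavourable"
        if p_value < p_threshold and coef < 0:
            return "favourable"
        return "none"


def filter_zero_heavy(expr: ExpressionMatrix, max_zero_frac: float = 0.7) -> ExpressionMatrix:
    """Drop genes whose fraction of exactly-zero entries exceeds the threshold."""
    if not 0.0 <= max_zero_frac <= 1.0:
        raise ValueError("max_zero_frac must lie in [0, 1]")
    zero_frac = np.mean(expr.values == 0.0, axis=1)
    keep = zero_frac <= max_zero_frac
    if not keep.any():
        warnings.warn("zero-fraction filter removed every gene", stacklevel=2)
    kept = [g for g, k in zip(expr.gene_ids, keep) if k]
    return ExpressionMatrix(kept, list(expr.sample_ids), expr.values[keep])


def _efron_loglik_derivs(beta: float, x: np.ndarray, order_stats: dict) -> tuple[float, float, float]:
    """Log partial likelihood, gradient and information at beta (Efron ties).

    ``order_stats`` carries the time-sorted covariate, event flags and tie
    group boundaries prepared by :func:`cox_univariate`.
    """
    xs = order_stats["x"]
    starts = order_stats["group_starts"]  # risk-set start index per event group
    dsets = order_stats["event_groups"]  # arrays of event indices per group

    theta = np.exp(beta * xs)
    xtheta = xs * theta
    x2theta = xs * xs * theta
    # reverse cumulative sums: risk set at index s is xs[s:]
    r0 = np.concatenate([np.cumsum(theta[::-1])[::-1], [0.0]])
    r1 = np.concatenate([np.cumsum(xtheta[::-1])[::-1], [0.0]])
    r2 = np.concatenate([np.cumsum(x2theta[::-1])[::-1], [0.0]])

    ll = 0.0
    grad = 0.0
    info = 0.0
    for s, d_idx in zip(starts, dsets):
        d = len(d_idx)
        sd0 = theta[d_idx].sum()
        sd1 = xtheta[d_idx].sum()
        sd2 = x2theta[d_idx].sum()
        ll += beta * xs[d_idx].sum()
        grad += xs[d_idx].sum()
        frac = np.arange(d) / d
        denom = r0[s] - frac * sd0
        num1 = r1[s] - frac * sd1
        num2 = r2[s] - frac * sd2
        ll -= np.log(denom).sum()
        xbar = num1 / denom
        grad -= xbar.sum()
        info += (num2 / denom - xbar**2).sum()
    return ll, grad, info


def _prepare_order_stats(x: np.ndarray, time: np.ndarray, event: np.ndarray) -> dict:
    order = np.argsort(time, kind="stable")
    t, xs, ev = time[order], x[order], event[order]
    starts = []
    dsets = []
    for ut in np.unique(t[ev == 1]):
        s = int(np.searchsorted(t, ut, side="left"))
        d_idx = np.nonzero((t == ut) & (ev == 1))[0]
        starts.append(s)
        dsets.append(d_idx)
    return {"x": xs, "group_starts": starts, "event_groups": dsets}


def cox_univariate(
    x: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> tuple[float, float, float, bool]:
    """Fit a single-covariate Cox model; returns (coef, se, p_value, converged).

    Constant covariates get (0, inf, 1, True) immediately.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0.0 or event.sum() == 0:
        return 0.0, np.inf, 1.0, True
    xc = x - x.mean()  # centering: pure numerical stabilization
    stats = _prepare_order_stats(xc, np.asarray(time, float), np.asarray(event, int))

    beta = 0.0
    ll, grad, info = _efron_loglik_derivs(beta, xc, stats)
    converged = False
    for _ in range(max_iter):
        if info <= 0:
            break
        step = grad / info
        # step-halving on decrease of the log partial likelihood
        new_beta = beta + step
        for _ in range(30):
            new_ll, new_grad, new_info = _efron_loglik_derivs(new_beta, xc, stats)
            if np.isfinite(new_ll) and new_ll >= ll - 1e-14:
                break
            new_beta = (beta + new_beta) / 2.0
        rel = abs(new_ll - ll) / max(1.0, abs(ll))
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if rel < tol:
            converged = True
            break
    if info <= 0 or not np.isfinite(beta):
        return 0.0, np.inf, 1.0, False
    se = 1.0 / np.sqrt(info)
    z = beta / se
    p = float(2.0 * ndtr(-abs(z)))
    p = max(p, np.finfo(float).tiny)
    return float(beta), float(se), p, converged


def cox_screen(
    expr: ExpressionMatrix,
    surv: SurvivalTable,
    p_threshold: float = 0.05,
    standardize: bool = False,
) -> list[GeneSurvivalResult]:
    """Univariate Cox fit per gene with direction calls at ``p_threshold``.

    Samples missing from the survival table are dropped with a warning.
    """
    common = [s for s in expr.sample_ids if s in set(surv.sample_ids)]
    if len(common) < expr.n_samples:
        log.warning("dropping %d samples without survival records", expr.n_samples - len(common))
        expr = expr.subset_samples(common)
    surv = surv.align(expr.sample_ids)
    if surv.event.sum() < 2:
        raise ValueError("need at least 2 observed events")

    results = []
    for gi, gene in enumerate(expr.gene_ids):
        x = expr.values[gi]
        if standardize and np.std(x) > 0:
            x = (x - x.mean()) / x.std()
        constant = np.ptp(x) == 0.0
        coef, _se, p, converged = cox_univariate(x, surv.time, surv.event)
        if constant or not converged:
            results.append(GeneSurvivalResult(gene, coef, float(np.exp(coef)), p, "none", converged=False))
            continue
        direction = GeneSurvivalResult.classify(coef, p, p_threshold)
        results.append(GeneSurvivalResult(gene, coef, float(np.exp(coef)), p, direction))
    return results


def select_network_genes(
    results: list[GeneSurvivalResult],
    p_max: float = 0.01,
    min_abs_coef: float = 0.2,
) -> list[str]:
    """Strict-inequality selection: p < p_max and |coef| > min_abs_coef."""
    if not results:
        raise ValueError("results must be nonempty")
    return [r.gene_id for r in results if r.p_value < p_max and abs(r.coef) > min_abs_coef]


def compare_groups(surv: SurvivalTable, labels: dict[str, str] | list[str]) -> dict:
    """Two-group log-rank test plus Kaplan-Meier curves per group."""
    if isinstance(labels, dict):
        lab = np.array([labels[s] for s in surv.sample_ids])
    else:
        lab = np.asarray(labels)
        if lab.shape != (surv.n_samples,):
            raise ValueError("labels length must match samples")
    groups = sorted(set(lab.tolist()))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(groups)}")
    masks = {g: lab == g for g in groups}
    for g, m in masks.items():
        if surv.event[m].sum() < 1:
            raise ValueError(f"group {g!r} has no observed events")

    a, b = groups
    res = logrank_test(
        surv.time[masks[a]], surv.time[masks[b]],
        event_observed_A=surv.event[masks[a]], event_observed_B=surv.event[masks[b]],
    )
    km_curves = {}
    for g in groups:
        kmf = KaplanMeierFitter()
        kmf.fit(surv.time[masks[g]], surv.event[masks[g]])
        sf = kmf.survival_function_
        km_curves[g] = (sf.index.to_numpy(float), sf.iloc[:, 0].to_numpy(float))
    return {
        "logrank_chi2": float(res.test_statistic),
        "logrank_p": float(res.p_value),
        "km_curves": km_curves,
    }


def results_to_frame(results: list[GeneSurvivalResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene_id for r in results],
            "coef": [r.coef for r in results],
            "HR": [r.hazard_ratio for r in results],
            "p": [r.p_value for r in results],
            "direction": [r.direction for r in results],
            "converged": [r.converged for r in results],
        }
    )


def write_results(results: list[GeneSurvivalResult], path: str | Path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        results_to_frame(results).to_csv(fh, sep="\t", index=False)
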