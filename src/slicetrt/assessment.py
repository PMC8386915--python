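"""Bayesian model assessment from posterior draws: DIC and pseudo-Bayes factor.

DIC uses the conditional parameterization: the deviance is evaluated given
all sampled quantities (item parameters, abilities, testlet effects), the
plug-in point is the posterior mean of each, and

    p_D  = D_bar - D_hat,       DIC = D_bar + p_D = 2 D_bar - D_hat,

with smaller DIC indicating better fit.

The pseudo-Bayes factor compares models through cross-validation predictive
densities (CVPD).  Each cell's CVPD is estimated by the harmonic mean of its
per-draw Bernoulli likelihoods,

    CVPD_ij = [ (1/M) sum_m 1 / p(y_ij | Xi^(m)) ]^{-1},

accumulated in log space (streaming log-sum-exp over draws) so that
well-fit cells cannot overflow the reciprocal terms.  The per-model score is
``sum_ij log CVPD_ij`` (larger is better); the log pseudo-Bayes factor of
model A over model B is the difference of their scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    P_GUARD,
    ItemParameters,
    PersonParameters,
    TestletDesign,
    canonical_model,
    log_likelihood,
)
from .sampler import ParameterState, PosteriorDraws

__all__ = [
    "AssessmentResult",
    "deviance",
    "dic_from_deviances",
    "dic",
    "cvpd_matrix",
    "log_psbf",
    "compare_models",
]


@dataclass(frozen=True)
class AssessmentResult:
    model: str
    dic: float
    d_bar: float
    d_hat: float
    p_d: float
    log_cvpd_sum: float
    n_draws: int
    log_cvpd_cells: np.ndarray | None = None


def deviance(Y, items: ItemParameters, persons: PersonParameters,
             design: TestletDesign, model="n2pltm") -> float:
    """-2 x Bernoulli log-likelihood at one parameter configuration."""
    return -2.0 * log_likelihood(Y, items, persons, design, model)


def dic_from_deviances(deviances, d_hat: float):
    """(DIC, D_bar, p_D) from per-draw deviances and the plug-in deviance."""
    d_bar = float(np.mean(deviances))
    p_d = d_bar - d_hat
    return d_bar + p_d, d_bar, p_d


def _draw_probabilities(draws: PosteriorDraws, assign: np.ndarray, model: str,
                        sl: slice) -> np.ndarray:
    """(c, n, J) clamped cell probabilities for a chunk of draws."""
    a = draws.a[sl]
    b = draws.b[sl]
    theta = draws.theta[sl]
    z = a[:, None, :] * (theta[:, :, None] - b[:, None, :])
    if model != "2pl":
        eta = draws.eta[sl]
        if model == "n2pltm":
            K = eta.shape[2]
            sums = np.zeros((a.shape[0], K))
            np.add.at(sums.T, assign, a.T)
            sizes = np.bincount(assign, minlength=K)
            load = (sums / sizes)[:, assign]
        else:
            load = a
        z = z + load[:, None, :] * eta[:, :, assign]
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-z))
    return np.clip(p, P_GUARD, 1.0 - P_GUARD)


def _scan_draws(draws: PosteriorDraws, Y, design: TestletDesign, model: str,
                chunk: int = 200):
    """One pass over the draws: per-draw deviances and per-cell streaming
    log-sum-exp of the negative log cell likelihoods (the CVPD accumulator)."""
    Y = np.asarray(Y)
    assign = design.assignment
    M = draws.n_draws
    devs = np.empty(M)
    run_max = np.full(Y.shape, -np.inf)
    run_sum = np.zeros(Y.shape)
    for start in range(0, M, chunk):
        sl = slice(start, min(start + chunk, M))
        p = _draw_probabilities(draws, assign, model, sl)
        cell_ll = np.where(Y[None] == 1, np.log(p), np.log1p(-p))
        devs[sl] = -2.0 * cell_ll.sum(axis=(1, 2))
        neg = -cell_ll  # log(1 / likelihood) per draw and cell
        cmax = neg.max(axis=0)
        new_max = np.maximum(run_max, cmax)
        run_sum = run_sum * np.exp(run_max - new_max) + \
            np.exp(neg - new_max[None]).sum(axis=0)
        run_max = new_max
    lse = run_max + np.log(run_sum)  # log sum_m 1/lik_m, per cell
    log_cvpd = np.log(M) - lse
    return devs, log_cvpd


def dic(draws: PosteriorDraws, Y, design: TestletDesign, model: str | None = None,
        keep_cells: bool = False) -> AssessmentResult:
    """DIC, p_D and the summed log-CVPD from one set of posterior draws.

    ``draws`` may pool several chains (see ``PosteriorDraws.concatenate``);
    at least 100 stored draws are required.  The plug-in configuration uses
    the posterior mean of every sampled quantity.
    """
    model = canonical_model(model or draws.model)
    if draws.n_draws < 100:
        raise ValueError("model assessment requires at least 100 draws")
    devs, log_cvpd = _scan_draws(draws, Y, design, model)
    hat = draws.eap_state()
    d_hat = deviance(Y, hat.items, hat.persons, design, model)
    dic_val, d_bar, p_d = dic_from_deviances(devs, d_hat)
    return AssessmentResult(
        model=model, dic=float(dic_val), d_bar=d_bar, d_hat=float(d_hat),
        p_d=float(p_d), log_cvpd_sum=float(log_cvpd.sum()), n_draws=draws.n_draws,
        log_cvpd_cells=log_cvpd if keep_cells else None,
    )


def cvpd_matrix(draws: PosteriorDraws, Y, design: TestletDesign,
                model: str | None = None) -> np.ndarray:
    """n x J matrix of harmonic-mean cross-validation predictive densities.

    Entries lie in (0, 1]; the harmonic mean never exceeds the best per-draw
    cell likelihood.
    """
    model = canonical_model(model or draws.model)
    if draws.n_draws < 100:
        raise ValueError("model assessment requires at least 100 draws")
    _, log_cvpd = _scan_draws(draws, Y, design, model)
    return np.exp(log_cvpd)


def log_psbf(result_a: AssessmentResult, result_b: AssessmentResult) -> float:
    """Log pseudo-Bayes factor of model A over model B (positive favors A)."""
    return result_a.log_cvpd_sum - result_b.log_cvpd_sum


def compare_models(results: list[AssessmentResult]) -> pd.DataFrame:
    """Rank fitted models: smaller DIC is better, larger log-CVPD is better.

    Ties (within 1e-9) share a rank, so identical fits report no arbitrary
    winner.
    """
    df = pd.DataFrame(
        [{"model": r.model, "DIC": r.dic, "D_bar": r.d_bar, "D_hat": r.d_hat,
          "p_D": r.p_d, "log_CVPD_sum": r.log_cvpd_sum} for r in results]
    )
    dic_r = np.round(df["DIC"].to_numpy(), 9)
    cv_r = np.round(df["log_CVPD_sum"].to_numpy(), 9)
    df["rank_dic"] = pd.Series(dic_r).rank(method="min").astype(int).to_numpy()
    df["rank_psbf"] = pd.Series(-cv_r).rank(method="min").astype(int).to_numpy()
    return df.sort_values("DIC", kind="stable").reset_index(drop=True)
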