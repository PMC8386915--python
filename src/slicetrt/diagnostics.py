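"""Convergence diagnostics and posterior summaries.

The potential scale reduction factor (PSRF, R-hat) is the classic
Gelman-Rubin point estimate: with M >= 2 chains of T draws,
``W`` the mean within-chain variance and ``B/T`` the variance of the chain
means, ``R-hat = sqrt(((T-1)/T * W + B/T) / W)``.  Chains are judged
converged when the maximum R-hat over all monitored parameters is below 1.1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sampler import PosteriorDraws

__all__ = ["psrf", "max_psrf", "summarize", "Summary", "summary_table",
           "CONVERGENCE_THRESHOLD"]

CONVERGENCE_THRESHOLD = 1.1


def psrf(chains) -> float:
    """Gelman-Rubin R-hat for one scalar parameter.

    ``chains`` is an (M, T) array (or list of equal-length 1-d arrays) with
    M >= 2 chains and T >= 2 draws.  Identical constant chains return 1.0 by
    convention.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("psrf needs >= 2 chains of >= 2 draws each")
    return float(_psrf_nd(arr[:, :, None])[0])


def _psrf_nd(arr: np.ndarray) -> np.ndarray:
    """Vectorized R-hat: arr is (M, T, P) -> (P,)."""
    M, T = arr.shape[:2]
    W = arr.var(axis=1, ddof=1).mean(axis=0)
    B_over_T = arr.mean(axis=1).var(axis=0, ddof=1)
    var_plus = (T - 1) / T * W + B_over_T
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sqrt(var_plus / W)
    return np.where(W > 0, r, 1.0)


def max_psrf(chains: list[PosteriorDraws]) -> float:
    """Maximum R-hat over every stored scalar (a, b, theta, eta, variances)."""
    if len(chains) < 2:
        raise ValueError("convergence diagnostic needs at least two chains")
    worst = 1.0
    for key in chains[0].blocks():
        stacked = np.stack([c.blocks()[key] for c in chains])  # (M, T, ...)
        flat = stacked.reshape(stacked.shape[0], stacked.shape[1], -1)
        worst = max(worst, float(_psrf_nd(flat).max()))
    return worst


@dataclass(frozen=True)
class Summary:
    eap: float
    sd: float
    hpdi: tuple


def summarize(draws, level: float = 0.95) -> Summary:
    """EAP (posterior mean), SD, and the highest-posterior-density interval.

    The HPDI is the shortest contiguous interval of sorted draws containing
    ``level`` of the sample.  Requires >= 100 draws.
    """
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    if x.size < 100:
        raise ValueError("summarize requires at least 100 draws")
    m = int(np.ceil(level * x.size))
    widths = x[m - 1:] - x[: x.size - m + 1]
    i = int(np.argmin(widths))
    return Summary(float(x.mean()), float(x.std(ddof=1)), (float(x[i]), float(x[i + m - 1])))


def _scalar_series(draws: PosteriorDraws):
    """Yield (label, (M,) array) for every stored scalar; labels are 1-based."""
    yield from ((f"a[{j + 1}]", draws.a[:, j]) for j in range(draws.a.shape[1]))
    yield from ((f"b[{j + 1}]", draws.b[:, j]) for j in range(draws.b.shape[1]))
    yield from ((f"theta[{i + 1}]", draws.theta[:, i]) for i in range(draws.theta.shape[1]))
    for i in range(draws.eta.shape[1]):
        for k in range(draws.eta.shape[2]):
            yield f"eta[{i + 1},{k + 1}]", draws.eta[:, i, k]
    yield "sigma2_a", draws.sigma2_a
    yield "sigma2_b", draws.sigma2_b
    yield from ((f"sigma2_eta[{k + 1}]", draws.sigma2_eta[:, k])
                for k in range(draws.sigma2_eta.shape[1]))


def summary_table(chains: list[PosteriorDraws], level: float = 0.95,
                  include_persons: bool = False) -> pd.DataFrame:
    """Per-parameter EAP, SD, HPDI and (with >= 2 chains) R-hat.

    Person parameters (theta, eta) are skipped unless requested; item and
    variance parameters are always reported.
    """
    pooled = PosteriorDraws.concatenate(chains) if len(chains) > 1 else chains[0]
    rows = []
    per_chain = [dict(_scalar_series(c)) for c in chains]
    for label, series in _scalar_series(pooled):
        if not include_persons and label.startswith(("theta[", "eta[")):
            continue
        s = summarize(series, level)
        rhat = (psrf([pc[label] for pc in per_chain])
                if len(chains) > 1 else np.nan)
        rows.append({"parameter": label, "EAP": s.eap, "SD": s.sd,
                     "HPDI_low": s.hpdi[0], "HPDI_high": s.hpdi[1], "R_hat": rhat})
    return pd.DataFrame(rows)
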