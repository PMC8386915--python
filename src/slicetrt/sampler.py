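"""Auxiliary-variable slice-Gibbs sampler for the logistic testlet models.

The sampler augments each Bernoulli cell with a uniform slice variable:
``lambda_ij ~ U(0, p_ij)`` where ``y_ij = 1`` and ``phi_ij ~ U(0, q_ij)``
where ``y_ij = 0``.  Conditional on the slice variables every model
parameter has a truncated-normal (or truncated-uniform) full conditional
whose bounds come from solving the slice inequalities

    y=1:  a_j (theta_i - b_j) + alpha_{d(j)} eta_{i,d(j)} >= logit(lambda_ij)
    y=0:  a_j (theta_i - b_j) + alpha_{d(j)} eta_{i,d(j)} <= log((1-phi_ij)/phi_ij)

for the parameter being updated (with ``alpha`` replaced by ``a_j`` under the
t2pltm and dropped under the 2PL).  The prior variances have conjugate
inverse-gamma updates.  No draw is ever rejected: every update is sampled
inside bounds under which all slice constraints stay satisfied.

Two execution paths produce identical science: a numba kernel (default,
:mod:`slicetrt._kernel`) and a pure-numpy reference path (``validate=True``)
that additionally asserts the slice indicators after every sub-step of every
sweep.  The per-step bound functions below are the reference path's building
blocks and the unit-test surface.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from scipy.special import ndtr, ndtri

from . import _kernel
from .model import (
    MODELS,
    P_GUARD,
    ItemParameters,
    PersonParameters,
    PriorConfig,
    TestletDesign,
    VarianceState,
    canonical_model,
    probability_matrix,
    testlet_discrimination,
    validate_responses,
)

__all__ = [
    "MCMCConfig",
    "ParameterState",
    "PosteriorDraws",
    "UpdateFlags",
    "SliceInvariantError",
    "sample_auxiliary",
    "slice_targets",
    "discrimination_bounds",
    "difficulty_bounds",
    "ability_bounds",
    "testlet_effect_bounds",
    "sample_truncated_normal",
    "sample_variance_a",
    "sample_variance_b",
    "sample_variance_eta",
    "log_unnormalized_posterior",
    "run_chain",
    "run_chains",
    "default_initial_state",
    "overdispersed_initial_state",
]


log = logging.getLogger(__name__)


class SliceInvariantError(RuntimeError):
    """A slice constraint was violated or a truncation interval inverted."""


@dataclass(frozen=True)
class UpdateFlags:
    """Which parameter blocks the sweeps update (others stay clamped)."""

    a: bool = True
    b: bool = True
    theta: bool = True
    eta: bool = True
    variances: bool = True


@dataclass(frozen=True)
class MCMCConfig:
    """Chain configuration.  Defaults follow the reference analysis protocol:

    20,000 iterations with the first 10,000 discarded, four chains from
    overdispersed starts, no thinning.
    """

    iterations: int = 20000
    burn_in: int = 10000
    chains: int = 4
    seed: int = 0
    thinning: int = 1
    prior: PriorConfig = field(default_factory=PriorConfig)
    start: str = "overdispersed"  # or "fixed"
    update: UpdateFlags = field(default_factory=UpdateFlags)
    validate: bool = False

    def __post_init__(self):
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("need 0 <= burn_in < iterations")
        if self.chains < 1 or self.thinning < 1:
            raise ValueError("chains and thinning must be >= 1")
        if self.start not in ("fixed", "overdispersed"):
            raise ValueError("start must be 'fixed' or 'overdispersed'")


@dataclass(frozen=True)
class ParameterState:
    """One full parameter configuration Omega = (theta, a, b, eta, variances)."""

    items: ItemParameters
    persons: PersonParameters
    variances: VarianceState


@dataclass
class PosteriorDraws:
    """Post-burn-in states of one chain, stored as per-block arrays.

    ``a``/``b`` are (M, J); ``theta`` is (M, n); ``eta`` is (M, n, K);
    variance draws are (M,) or (M, K).  Labels in reports are 1-based:
    ``a[2]``, ``theta[17]``, ``eta[3,1]``, ``sigma2_eta[2]``.
    """

    a: np.ndarray
    b: np.ndarray
    theta: np.ndarray
    eta: np.ndarray
    sigma2_a: np.ndarray
    sigma2_b: np.ndarray
    sigma2_eta: np.ndarray
    model: str = "n2pltm"
    seed: int | None = None

    @property
    def n_draws(self) -> int:
        return int(self.a.shape[0])

    def eap_state(self, fixed=(0,)) -> ParameterState:
        """Posterior-mean (EAP) configuration across the stored draws."""
        return ParameterState(
            items=ItemParameters(self.a.mean(0), self.b.mean(0), fixed=fixed),
            persons=PersonParameters(self.theta.mean(0), self.eta.mean(0)),
            variances=VarianceState(
                float(self.sigma2_a.mean()),
                float(self.sigma2_b.mean()),
                self.sigma2_eta.mean(0),
            ),
        )

    def blocks(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "theta": self.theta,
            "eta": self.eta,
            "sigma2_a": self.sigma2_a,
            "sigma2_b": self.sigma2_b,
            "sigma2_eta": self.sigma2_eta,
        }

    @staticmethod
    def concatenate(chains: list["PosteriorDraws"]) -> "PosteriorDraws":
        return PosteriorDraws(
            **{
                k: np.concatenate([c.blocks()[k] for c in chains], axis=0)
                for k in chains[0].blocks()
            },
            model=chains[0].model,
            seed=chains[0].seed,
        )


# ---------------------------------------------------------------------------
# Elementary operations (reference path / unit-test surface)
# ---------------------------------------------------------------------------

def sample_auxiliary(Y, state: ParameterState, design, model, rng):
    """Step 1: draw the uniform slice variables given the current state.

    Returns ``(lam, phi)`` as n x J arrays; the entry not matching ``y_ij``
    is set to NaN (it plays no role in any conditional).
    """
    P = probability_matrix(state.items, state.persons, design, model)
    U = rng.random(P.shape)
    U = np.maximum(U, 1e-300)
    lam = np.where(Y == 1, U * P, np.nan)
    phi = np.where(Y == 0, U * (1.0 - P), np.nan)
    return lam, phi


def slice_targets(Y, lam, phi):
    """Logit-scale constraint per cell: lower bound on the linear predictor
    where y=1 (``log(lam/(1-lam))``), upper bound where y=0
    (``log((1-phi)/phi)``)."""
    with np.errstate(divide="ignore"):
        t1 = np.log(lam) - np.log1p(-lam)
        t0 = np.log1p(-phi) - np.log(phi)
    return np.where(Y == 1, t1, t0)


def _linear_loading(a, design, model):
    """Coefficient multiplying eta in the linear predictor, per item."""
    if model == "n2pltm":
        return testlet_discrimination(a, design)[design.assignment]
    if model == "t2pltm":
        return np.asarray(a, dtype=float)
    return np.zeros(len(a))


def discrimination_bounds(j, Y, lam, phi, state, design, model="n2pltm"):
    """Truncation interval (a_L, a_U) for item j's discrimination.

    Each constraining cell gives a linear inequality ``a_j c_i >= t_i``
    (y=1) or ``a_j c_i <= t_i`` (y=0); cells with ``c_i = 0`` impose
    nothing, and empty candidate sets leave (0, inf).  For the item's own
    column, ``c_i = theta_i - b_j + eta_{i,d(j)}/n_d`` and ``t_i`` subtracts
    the residual ``sum_{m in S_d - {j}} (a_m / n_d) eta_{i,d(j)}``.  Under
    the n2pltm, a_j also enters every sibling item's predictor through the
    testlet discrimination ``alpha_d``, so sibling cells constrain a_j too,
    with coefficient ``eta_{i,d(j)} / n_d``.
    """
    model = canonical_model(model)
    a, b = state.items.a, state.items.b
    theta, eta = state.persons.theta, state.persons.eta
    k = design.assignment[j]
    T = slice_targets(Y, lam, phi)
    Y = np.asarray(Y)
    cells = []  # (c, t, y1) blocks of constraining cells
    if model == "n2pltm":
        nd = design.sizes[k]
        sum_others = a[design.members(k)].sum() - a[j]
        resid = (sum_others / nd) * eta[:, k]
        for jj in design.members(k):
            if jj == j:
                c = theta - b[j] + eta[:, k] / nd
                t = T[:, j] - resid
            else:
                c = eta[:, k] / nd
                t = T[:, jj] - a[jj] * (theta - b[jj]) - resid
            cells.append((c, t, Y[:, jj] == 1))
    elif model == "t2pltm":
        cells.append((theta - b[j] + eta[:, k], T[:, j], Y[:, j] == 1))
    else:
        cells.append((theta - b[j], T[:, j], Y[:, j] == 1))
    lo, hi = 0.0, np.inf
    for c, t, y1 in cells:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = t / c
        lower = ratio[(y1 & (c > 0)) | (~y1 & (c < 0))]
        upper = ratio[(y1 & (c < 0)) | (~y1 & (c > 0))]
        if lower.size:
            lo = max(lo, float(lower.max()))
        if upper.size:
            hi = min(hi, float(upper.min()))
    return lo, hi


def difficulty_bounds(j, Y, lam, phi, state, design, model="n2pltm"):
    """Truncation interval (b_L, b_U) for item j's difficulty."""
    model = canonical_model(model)
    a = state.items.a
    theta, eta = state.persons.theta, state.persons.eta
    k = design.assignment[j]
    load = _linear_loading(a, design, model)[j]
    T = slice_targets(Y, lam, phi)[:, j]
    m = theta - (T - load * eta[:, k]) / a[j]
    y1 = np.asarray(Y)[:, j] == 1
    hi = float(m[y1].min()) if y1.any() else np.inf
    lo = float(m[~y1].max()) if (~y1).any() else -np.inf
    return lo, hi


def ability_bounds(Y, lam, phi, state, design, model="n2pltm"):
    """Truncation intervals for all abilities at once: (theta_L, theta_U), (n,)."""
    model = canonical_model(model)
    a, b = state.items.a, state.items.b
    eta = state.persons.eta
    load = _linear_loading(a, design, model)
    T = slice_targets(Y, lam, phi)
    V = (T - load[None, :] * eta[:, design.assignment]) / a[None, :] + b[None, :]
    y1 = np.asarray(Y) == 1
    lo = np.where(y1, V, -np.inf).max(axis=1)
    hi = np.where(~y1, V, np.inf).min(axis=1)
    return lo, hi


def testlet_effect_bounds(k, Y, lam, phi, state, design, model="n2pltm"):
    """Truncation intervals for column k of eta: (eta_L, eta_U), (n,).

    All items of testlet k constrain eta_ik simultaneously: the lower bound
    is the max over the testlet's y=1 items, the upper the min over its y=0
    items.
    """
    model = canonical_model(model)
    a, b = state.items.a, state.items.b
    theta = state.persons.theta
    items = design.members(k)
    load = _linear_loading(a, design, model)[items]
    T = slice_targets(Y, lam, phi)[:, items]
    V = (T - a[items][None, :] * (theta[:, None] - b[items][None, :])) / load[None, :]
    y1 = np.asarray(Y)[:, items] == 1
    lo = np.where(y1, V, -np.inf).max(axis=1)
    hi = np.where(~y1, V, np.inf).min(axis=1)
    return lo, hi


def sample_truncated_normal(mu, sigma, lo, hi, rng):
    """Vectorized N(mu, sigma^2) truncated to [lo, hi].

    Inverse CDF on the normal-CDF scale; elements whose standardized interval
    sits more than 5 SDs into a tail (where the CDF difference underflows)
    fall back to exponential rejection (Robert, 1995).
    """
    mu, sigma = np.broadcast_arrays(np.asarray(mu, float), np.asarray(sigma, float))
    lo, hi = np.broadcast_arrays(np.asarray(lo, float), np.asarray(hi, float))
    mu, sigma, lo, hi = np.broadcast_arrays(mu, sigma, lo, hi)
    al = (lo - mu) / sigma
    be = (hi - mu) / sigma
    out = np.empty(al.shape)
    main = (al <= 5.0) & (be >= -5.0)
    if main.any():
        pa = ndtr(al[main])
        pb = ndtr(be[main])
        u = pa + rng.random(pa.shape) * (pb - pa)
        u = np.clip(u, 1e-300, 1.0 - 1e-16)
        out[main] = np.clip(ndtri(u), al[main], be[main])
    tail = ~main
    if tail.any():
        a_t = np.where(al[tail] > 5.0, al[tail], -be[tail])
        b_t = np.where(al[tail] > 5.0, be[tail], -al[tail])
        flip = ~(al[tail] > 5.0)
        z = np.array([_robert_tail(ai, bi, rng) for ai, bi in zip(a_t, b_t)])
        out[tail] = np.where(flip, -z, z)
    x = mu + sigma * out
    res = np.clip(x, lo, hi)
    return float(res) if res.ndim == 0 else res


def _robert_tail(lo, hi, rng):
    rate = 0.5 * (lo + math.sqrt(lo * lo + 4.0))
    for _ in range(20000):
        u = max(rng.random(), 1e-300)
        z = lo - math.log(u) / rate
        if z <= hi and rng.random() <= math.exp(-0.5 * (z - rate) ** 2):
            return z
    for _ in range(200000):
        z = lo + rng.random() * (hi - lo)
        if rng.random() <= math.exp(0.5 * (lo * lo - z * z)):
            return z
    return lo


def _sample_item(mu, sigma2, lo, hi, prior_bounds, family, rng, positive=False):
    if positive:
        lo = max(lo, 0.0)
    if family == "uniform":
        l2, h2 = max(lo, prior_bounds[0]), min(hi, prior_bounds[1])
        if h2 < l2:
            raise SliceInvariantError(f"empty truncation interval ({l2}, {h2})")
        return l2 + rng.random() * (h2 - l2)
    if hi < lo:
        raise SliceInvariantError(f"inverted truncation interval ({lo}, {hi})")
    return float(sample_truncated_normal(mu, math.sqrt(sigma2), lo, hi, rng))


def sample_variance_a(a, prior: PriorConfig, rng):
    """Step 6: exact conjugate draw
    sigma2_a ~ IG(J/2 + v1, sum_j (a_j - mu_a)^2 / 2 + tau1)."""
    a = np.asarray(a, float)
    shape = a.size / 2.0 + prior.v1
    scale = np.sum((a - prior.mu_a) ** 2) / 2.0 + prior.tau1
    return float(stats.invgamma.rvs(shape, scale=scale, random_state=rng))


def sample_variance_b(b, prior: PriorConfig, rng):
    """Step 7: sigma2_b ~ IG(J/2 + v2, sum_j (b_j - mu_b)^2 / 2 + tau2)."""
    b = np.asarray(b, float)
    shape = b.size / 2.0 + prior.v2
    scale = np.sum((b - prior.mu_b) ** 2) / 2.0 + prior.tau2
    return float(stats.invgamma.rvs(shape, scale=scale, random_state=rng))


def sample_variance_eta(eta_col, prior: PriorConfig, rng):
    """Step 8: sigma2_eta_k ~ IG(n/2 + v3, sum_i (eta_ik - mu_eta)^2 / 2 + tau3)."""
    e = np.asarray(eta_col, float)
    shape = e.size / 2.0 + prior.v3
    scale = np.sum((e - prior.mu_eta) ** 2) / 2.0 + prior.tau3
    return float(stats.invgamma.rvs(shape, scale=scale, random_state=rng))


def log_unnormalized_posterior(state: ParameterState, Y, design, prior: PriorConfig,
                               model="n2pltm") -> float:
    """Log joint posterior density up to an additive constant.

    Likelihood plus the theta, a, b, eta prior terms and the inverse-gamma
    hyperprior terms.  Used as the analytic oracle for the sampler; returns
    -inf outside the support (any a_j <= 0 or non-positive variance).
    """
    from .model import log_likelihood

    a, b = state.items.a, state.items.b
    theta, eta = state.persons.theta, state.persons.eta
    v = state.variances
    if np.any(a <= 0) or v.sigma2_a <= 0 or v.sigma2_b <= 0 or np.any(v.sigma2_eta <= 0):
        return -np.inf
    lp = log_likelihood(Y, state.items, state.persons, design, model)
    lp += -0.5 * np.sum(theta**2)
    J = a.size
    if prior.family == "uniform":
        alo, ahi = prior.a_bounds
        blo, bhi = prior.b_bounds
        if np.any(a < alo) or np.any(a > ahi) or np.any(b < blo) or np.any(b > bhi):
            return -np.inf
    else:
        s2a = v.sigma2_a if prior.hierarchical_item_variances else prior.sigma2_a
        s2b = v.sigma2_b if prior.hierarchical_item_variances else prior.sigma2_b
        lp += -0.5 * J * math.log(s2a) - np.sum((a - prior.mu_a) ** 2) / (2 * s2a)
        lp += -0.5 * J * math.log(s2b) - np.sum((b - prior.mu_b) ** 2) / (2 * s2b)
        if prior.hierarchical_item_variances:
            lp += -(prior.v1 + 1) * math.log(s2a) - prior.tau1 / s2a
            lp += -(prior.v2 + 1) * math.log(s2b) - prior.tau2 / s2b
    if model != "2pl":
        n = theta.size
        for k in range(design.n_testlets):
            s2 = v.sigma2_eta[k]
            lp += -0.5 * n * math.log(s2) - np.sum((eta[:, k] - prior.mu_eta) ** 2) / (2 * s2)
            lp += -(prior.v3 + 1) * math.log(s2) - prior.tau3 / s2
    return float(lp)


# ---------------------------------------------------------------------------
# Chain drivers
# ---------------------------------------------------------------------------

def default_initial_state(design: TestletDesign, n_persons: int,
                          fixed=(0,)) -> ParameterState:
    """a_j = 1, b_j = 0, theta = 0, eta = 0, all variances 1."""
    J, K = design.n_items, design.n_testlets
    return ParameterState(
        items=ItemParameters(np.ones(J), np.zeros(J), fixed=fixed),
        persons=PersonParameters(np.zeros(n_persons), np.zeros((n_persons, K))),
        variances=VarianceState(1.0, 1.0, np.ones(K)),
    )


def overdispersed_initial_state(design: TestletDesign, n_persons: int, rng,
                                fixed=(0,)) -> ParameterState:
    """Default start jittered by +-2 prior SDs (identification-fixed items pinned)."""
    J, K = design.n_items, design.n_testlets
    a = np.maximum(0.05, 1.0 + 2.0 * rng.uniform(-1, 1, J))
    b = 2.0 * rng.uniform(-1, 1, J)
    for j in fixed:
        a[j], b[j] = 1.0, 0.0
    return ParameterState(
        items=ItemParameters(a, b, fixed=fixed),
        persons=PersonParameters(
            2.0 * rng.uniform(-1, 1, n_persons),
            2.0 * rng.uniform(-1, 1, (n_persons, K)),
        ),
        variances=VarianceState(
            float(np.exp(rng.uniform(-1, 1))),
            float(np.exp(rng.uniform(-1, 1))),
            np.exp(rng.uniform(-1, 1, K)),
        ),
    )


def _chain_seed(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


def run_chain(Y, design: TestletDesign, model: str, config: MCMCConfig,
              initial_state: ParameterState | None = None,
              chain_seed: int | None = None) -> PosteriorDraws:
    """Run one chain and return its post-burn-in draws.

    Deterministic under a fixed ``chain_seed`` (defaults to ``config.seed``).
    Identification-fixed item parameters never change.  With
    ``config.validate=True`` the pure-numpy path is used and the slice
    indicators are asserted after every sub-step of every sweep.
    """
    model = canonical_model(model)
    Y = validate_responses(Y)
    if not (Y.any() and (1 - Y).any()):
        raise ValueError("degenerate response matrix: needs at least one 0 and one 1")
    n, J = Y.shape
    if J != design.n_items:
        raise ValueError("response matrix and design disagree on the item count")
    if chain_seed is None:
        chain_seed = config.seed
    state = initial_state or default_initial_state(design, n)
    prior = config.prior
    fixed_mask = np.zeros(J, dtype=np.uint8)
    for j in state.items.fixed:
        fixed_mask[j] = 1

    n_store = (config.iterations - config.burn_in + config.thinning - 1) // config.thinning
    K = design.n_testlets
    if config.validate:
        return _reference_chain(Y, design, model, config, state, chain_seed, n_store)

    a = state.items.a.copy()
    b = state.items.b.copy()
    theta = state.persons.theta.copy()
    eta = np.ascontiguousarray(state.persons.eta, dtype=float).copy()
    s2eta = state.variances.sigma2_eta.copy()
    s2a = prior.sigma2_a if not prior.hierarchical_item_variances else state.variances.sigma2_a
    s2b = prior.sigma2_b if not prior.hierarchical_item_variances else state.variances.sigma2_b
    out = {
        "a": np.empty((n_store, J)),
        "b": np.empty((n_store, J)),
        "theta": np.empty((n_store, n)),
        "eta": np.empty((n_store, n, K)),
        "sigma2_a": np.empty(n_store),
        "sigma2_b": np.empty(n_store),
        "sigma2_eta": np.empty((n_store, K)),
    }
    upd = config.update
    err = _kernel.run_chain_kernel(
        np.ascontiguousarray(Y, dtype=np.int8),
        np.ascontiguousarray(design.assignment, dtype=np.int64),
        np.ascontiguousarray(design.sizes, dtype=np.int64),
        _kernel.MODEL_CODE[model],
        _kernel.FAMILY_CODE[prior.family],
        prior.mu_a, prior.mu_b, prior.mu_eta,
        1 if prior.hierarchical_item_variances else 0,
        prior.a_bounds[0], prior.a_bounds[1], prior.b_bounds[0], prior.b_bounds[1],
        prior.v1, prior.tau1, prior.v2, prior.tau2, prior.v3, prior.tau3,
        a, b, theta, eta, float(s2a), float(s2b), s2eta,
        fixed_mask,
        1 if upd.a else 0, 1 if upd.b else 0, 1 if upd.theta else 0,
        1 if upd.eta else 0, 1 if upd.variances else 0,
        config.iterations, config.burn_in, config.thinning, chain_seed,
        out["a"], out["b"], out["theta"], out["eta"],
        out["sigma2_a"], out["sigma2_b"], out["sigma2_eta"],
    )
    if err:
        raise SliceInvariantError(
            f"{err} truncation-bound inversions during the run "
            f"(model={model}, seed={chain_seed})"
        )
    return PosteriorDraws(**out, model=model, seed=chain_seed)


def run_chains(Y, design, model, config: MCMCConfig) -> list[PosteriorDraws]:
    """Run ``config.chains`` chains with per-chain sub-seeds.

    Chain starts follow ``config.start``: chain 0 always starts at the
    default state; later chains start overdispersed when requested.
    """
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.chains)
    out = []
    n = np.asarray(Y).shape[0]
    for c, child in enumerate(children):
        rng = np.random.default_rng(child)
        if config.start == "overdispersed" and c > 0:
            init = overdispersed_initial_state(design, n, rng)
        else:
            init = default_initial_state(design, n)
        t0 = time.perf_counter()
        out.append(run_chain(Y, design, model, config,
                             initial_state=init, chain_seed=_chain_seed(child)))
        log.info("chain %d/%d finished: %d iterations (%d stored) in %.1fs",
                 c + 1, config.chains, config.iterations,
                 out[-1].n_draws, time.perf_counter() - t0)
    return out


# ---------------------------------------------------------------------------
# Pure-numpy reference path (oracle / debug mode)
# ---------------------------------------------------------------------------

def _check_indicators(Y, T, state, design, model, where):
    z = _linear_predictor(state, design, model)
    y1 = Y == 1
    bad = (y1 & (z < T - 1e-8)) | (~y1 & (z > T + 1e-8))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise SliceInvariantError(
            f"slice indicator violated after {where} at cell ({i}, {j})"
        )


def _linear_predictor(state, design, model):
    a, b = state.items.a, state.items.b
    theta, eta = state.persons.theta, state.persons.eta
    z = a[None, :] * (theta[:, None] - b[None, :])
    load = _linear_loading(a, design, model)
    if model != "2pl":
        z = z + load[None, :] * eta[:, design.assignment]
    return z


def _reference_chain(Y, design, model, config, state, chain_seed, n_store):
    rng = np.random.default_rng(chain_seed)
    prior = config.prior
    upd = config.update
    n, J = Y.shape
    K = design.n_testlets
    items, persons, var = state.items, state.persons, state.variances
    a, b = items.a.copy(), items.b.copy()
    theta, eta = persons.theta.copy(), persons.eta.copy()
    s2a = prior.sigma2_a if not prior.hierarchical_item_variances else var.sigma2_a
    s2b = prior.sigma2_b if not prior.hierarchical_item_variances else var.sigma2_b
    s2eta = var.sigma2_eta.copy()
    fixed = set(items.fixed)
    out = {k: np.empty(s) for k, s in {
        "a": (n_store, J), "b": (n_store, J), "theta": (n_store, n),
        "eta": (n_store, n, K), "sigma2_a": (n_store,), "sigma2_b": (n_store,),
        "sigma2_eta": (n_store, K)}.items()}
    store = 0

    def cur():
        return ParameterState(
            ItemParameters(a, b, fixed=tuple(fixed)),
            PersonParameters(theta, eta),
            VarianceState(s2a, s2b, s2eta),
        )

    for it in range(config.iterations):
        st = cur()
        lam, phi = sample_auxiliary(Y, st, design, model, rng)
        T = slice_targets(Y, lam, phi)
        _check_indicators(Y, T, st, design, model, f"step 1 (iter {it})")
        if upd.a:
            for j in range(J):
                if j in fixed:
                    continue
                lo, hi = discrimination_bounds(j, Y, lam, phi, cur(), design, model)
                a[j] = _sample_item(prior.mu_a, s2a, lo, hi, prior.a_bounds,
                                    prior.family, rng, positive=True)
                _check_indicators(Y, T, cur(), design, model, f"step 2 item {j}")
        if upd.b:
            for j in range(J):
                if j in fixed:
                    continue
                lo, hi = difficulty_bounds(j, Y, lam, phi, cur(), design, model)
                b[j] = _sample_item(prior.mu_b, s2b, lo, hi, prior.b_bounds,
                                    prior.family, rng)
                _check_indicators(Y, T, cur(), design, model, f"step 3 item {j}")
        if upd.theta:
            lo, hi = ability_bounds(Y, lam, phi, cur(), design, model)
            if np.any(hi < lo):
                raise SliceInvariantError("inverted ability bounds")
            theta[:] = sample_truncated_normal(0.0, 1.0, lo, hi, rng)
            _check_indicators(Y, T, cur(), design, model, "step 4")
        if upd.eta and model != "2pl":
            for k in range(K):
                lo, hi = testlet_effect_bounds(k, Y, lam, phi, cur(), design, model)
                if np.any(hi < lo):
                    raise SliceInvariantError(f"inverted eta bounds, testlet {k}")
                eta[:, k] = sample_truncated_normal(
                    prior.mu_eta, math.sqrt(s2eta[k]), lo, hi, rng)
                _check_indicators(Y, T, cur(), design, model, f"step 5 testlet {k}")
        if upd.variances:
            if prior.family == "normal" and prior.hierarchical_item_variances:
                s2a = sample_variance_a(a, prior, rng)
                s2b = sample_variance_b(b, prior, rng)
            if model != "2pl":
                for k in range(K):
                    s2eta[k] = sample_variance_eta(eta[:, k], prior, rng)
        if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0:
            out["a"][store] = a
            out["b"][store] = b
            out["theta"][store] = theta
            out["eta"][store] = eta
            out["sigma2_a"][store] = s2a
            out["sigma2_b"][store] = s2b
            out["sigma2_eta"][store] = s2eta
            store += 1
    return PosteriorDraws(**out, model=model, seed=chain_seed)
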