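"""Logistic testlet response models and forward simulation.

Three dichotomous response models are supported, all sharing discrimination
``a_j > 0``, difficulty ``b_j`` and latent ability ``theta_i``:

``2pl``
    Standard two-parameter logistic model,
    ``p_ij = logistic(a_j (theta_i - b_j))``, assuming local independence.

``t2pltm``
    Random-effects testlet model: items are grouped into mutually exclusive,
    exhaustive testlets and a person-by-testlet effect ``eta_ik`` shifts the
    ability inside the item's testlet,
    ``p_ij = logistic(a_j (theta_i - b_j + eta_{i,d(j)}))``.

``n2pltm``
    Testlet model in which the random effect is loaded by the *testlet
    discrimination* ``alpha_d``, the arithmetic mean of the item
    discriminations within testlet ``d``:
    ``p_ij = logistic(a_j (theta_i - b_j) + alpha_{d(j)} eta_{i,d(j)})``.

The variance of each ``eta`` column measures the amount of local dependence
induced by that testlet; at ``sigma2_eta = 0`` both testlet models collapse to
the 2PL, and when all items in a testlet share the same discrimination the
``n2pltm`` and ``t2pltm`` cell probabilities coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MODELS",
    "P_GUARD",
    "TestletDesign",
    "ItemParameters",
    "PersonParameters",
    "VarianceState",
    "PriorConfig",
    "validate_responses",
    "testlet_discrimination",
    "response_probability",
    "probability_matrix",
    "simulate_responses",
    "log_likelihood",
]

MODELS = ("2pl", "t2pltm", "n2pltm")

#: Probabilities are clamped to [P_GUARD, 1 - P_GUARD] before logs and before
#: the uniform slice draws: the slice indicators need strictly positive p and q.
P_GUARD = 1e-12

_MODEL_ALIASES = {
    "2pl": "2pl", "2plm": "2pl",
    "t2plt": "t2pltm", "t2pltm": "t2pltm",
    "n2plt": "n2pltm", "n2pltm": "n2pltm",
}


def canonical_model(name: str) -> str:
    try:
        return _MODEL_ALIASES[name.lower()]
    except KeyError:
        raise ValueError(f"unknown model {name!r}; expected one of {MODELS}") from None


def _clamp(p: np.ndarray | float):
    return np.clip(p, P_GUARD, 1.0 - P_GUARD)


@dataclass(frozen=True)
class TestletDesign:
    """Partition of ``J`` items into ``K`` mutually exclusive, exhaustive testlets.

    ``assignment[j]`` is the 0-based testlet index of item ``j`` (items are
    0-based internally; file formats and reports use 1-based labels).
    """

    assignment: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.assignment, dtype=np.int64)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("testlet assignment must be a non-empty 1-d sequence")
        labels = np.unique(arr)
        if labels[0] != 0 or labels[-1] != labels.size - 1:
            raise ValueError(
                "testlet indices must be contiguous 0..K-1; every testlet needs >= 1 item"
            )
        object.__setattr__(self, "assignment", arr)

    @property
    def n_items(self) -> int:
        return int(self.assignment.size)

    @property
    def n_testlets(self) -> int:
        return int(self.assignment.max()) + 1

    @property
    def sizes(self) -> np.ndarray:
        """Number of items per testlet, length ``K``."""
        return np.bincount(self.assignment, minlength=self.n_testlets)

    def members(self, k: int) -> np.ndarray:
        """0-based item indices belonging to testlet ``k``."""
        return np.flatnonzero(self.assignment == k)

    @classmethod
    def uniform(cls, n_testlets: int, items_per_testlet: int) -> "TestletDesign":
        return cls(np.repeat(np.arange(n_testlets), items_per_testlet))

    @classmethod
    def from_groups(cls, groups: dict) -> "TestletDesign":
        """Build from ``{"1": [1, 2, ...], ...}`` with 1-based item indices.

        Validates that the groups are mutually exclusive and exhaustive over
        ``1..J``; offenders are listed in the error message.
        """
        keys = sorted(groups, key=lambda s: int(s))
        if [int(k) for k in keys] != list(range(1, len(keys) + 1)):
            raise ValueError(f"testlet labels must be 1..K, got {sorted(groups)}")
        items = [int(i) for k in keys for i in groups[k]]
        J = len(items)
        seen = np.bincount(np.asarray(items, dtype=int), minlength=J + 1)[1:]
        dupes = np.flatnonzero(seen > 1) + 1
        missing = np.flatnonzero(seen == 0) + 1
        if dupes.size or missing.size or min(items, default=1) < 1 or max(items, default=1) > J:
            raise ValueError(
                "testlet design must partition items 1..J exactly once: "
                f"duplicated={dupes.tolist()} missing={missing.tolist()}"
            )
        assignment = np.empty(J, dtype=np.int64)
        for k_idx, key in enumerate(keys):
            for item in groups[key]:
                assignment[int(item) - 1] = k_idx
        return cls(assignment)

    def to_groups(self) -> dict:
        return {
            str(k + 1): (self.members(k) + 1).tolist() for k in range(self.n_testlets)
        }


@dataclass(frozen=True)
class ItemParameters:
    """Discriminations ``a_j > 0`` and difficulties ``b_j``.

    ``fixed`` lists the 0-based items whose parameters are pinned for
    identification (default item 1 of the test: ``a_1 = 1, b_1 = 0``).
    """

    a: np.ndarray
    b: np.ndarray
    fixed: tuple = (0,)

    def __post_init__(self):
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("a and b must be 1-d vectors of equal length")
        if np.any(a <= 0):
            raise ValueError("all discriminations must be strictly positive")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "fixed", tuple(self.fixed))

    @property
    def n_items(self) -> int:
        return int(self.a.size)


@dataclass(frozen=True)
class PersonParameters:
    """Abilities ``theta_i`` and person-by-testlet effects ``eta_ik`` (n x K)."""

    theta: np.ndarray
    eta: np.ndarray

    def __post_init__(self):
        theta = np.asarray(self.theta, dtype=float)
        eta = np.asarray(self.eta, dtype=float)
        if theta.ndim != 1 or eta.ndim != 2 or eta.shape[0] != theta.size:
            raise ValueError("theta must be (n,), eta must be (n, K)")
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "eta", eta)

    @property
    def n_persons(self) -> int:
        return int(self.theta.size)


@dataclass(frozen=True)
class VarianceState:
    """Prior variances sampled by the Gibbs steps; all strictly positive."""

    sigma2_a: float
    sigma2_b: float
    sigma2_eta: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.sigma2_eta, dtype=float)
        if self.sigma2_a <= 0 or self.sigma2_b <= 0 or np.any(s <= 0):
            raise ValueError("all variances must be strictly positive")
        object.__setattr__(self, "sigma2_eta", s)


@dataclass(frozen=True)
class PriorConfig:
    """Priors for item parameters, testlet effects and their variances.

    ``family`` selects the item-parameter prior: ``"normal"`` gives
    ``a_j ~ N(mu_a, sigma2_a) I(0, inf)`` and ``b_j ~ N(mu_b, sigma2_b)``;
    ``"uniform"`` gives flat priors on ``a_bounds`` / ``b_bounds``.

    Under the normal family, ``hierarchical_item_variances`` decides whether
    ``sigma2_a`` and ``sigma2_b`` carry IG(v, tau) hyperpriors and are sampled
    (the Gibbs variance steps) or stay fixed at the values below.  The testlet
    variance ``sigma2_eta_k`` is always hierarchical with an IG(v3, tau3)
    hyperprior.  Defaults: all prior means 0, IG hyperparameters 0.001.
    """

    family: str = "normal"
    mu_a: float = 0.0
    mu_b: float = 0.0
    mu_eta: float = 0.0
    hierarchical_item_variances: bool = True
    sigma2_a: float = 1.0
    sigma2_b: float = 1.0
    a_bounds: tuple = (0.0, 100.0)
    b_bounds: tuple = (-100.0, 100.0)
    v1: float = 1e-3
    tau1: float = 1e-3
    v2: float = 1e-3
    tau2: float = 1e-3
    v3: float = 1e-3
    tau3: float = 1e-3

    def __post_init__(self):
        if self.family not in ("normal", "uniform"):
            raise ValueError("prior family must be 'normal' or 'uniform'")
        for v in (self.v1, self.tau1, self.v2, self.tau2, self.v3, self.tau3):
            if v <= 0:
                raise ValueError("inverse-gamma hyperparameters must be positive")
        for lo, hi in (self.a_bounds, self.b_bounds):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError("uniform prior bounds must be finite with lower < upper")
        if self.sigma2_a <= 0 or self.sigma2_b <= 0:
            raise ValueError("prior variances must be positive")

    # The three prior types exercised in the prior-sensitivity study.
    @classmethod
    def hierarchical(cls) -> "PriorConfig":
        """Sampled item-prior variances with IG(0.001, 0.001) hyperpriors."""
        return cls()

    @classmethod
    def informative(cls) -> "PriorConfig":
        """Type I: a ~ N(0,1)I(0,inf), b ~ N(0,1), variances fixed."""
        return cls(hierarchical_item_variances=False, sigma2_a=1.0, sigma2_b=1.0)

    @classmethod
    def noninformative_normal(cls) -> "PriorConfig":
        """Type II: a ~ N(0,100)I(0,inf), b ~ N(0,100), variances fixed."""
        return cls(hierarchical_item_variances=False, sigma2_a=100.0, sigma2_b=100.0)

    @classmethod
    def noninformative_uniform(cls) -> "PriorConfig":
        """Type III: a ~ U(0,100), b ~ U(-100,100)."""
        return cls(family="uniform")


def validate_responses(Y: np.ndarray) -> np.ndarray:
    """Check a person x item response matrix: binary, 2-d, no missing cells.

    Returns the validated ``int8`` matrix.  A matrix that is entirely 0 or
    entirely 1 is rejected as degenerate (no parameter is identified from it).
    """
    Y = np.asarray(Y)
    if Y.ndim != 2 or Y.size == 0:
        raise ValueError("response matrix must be 2-d and non-empty")
    if not np.isin(Y, (0, 1)).all():
        bad = np.argwhere(~np.isin(Y, (0, 1)))[0]
        raise ValueError(
            f"non-binary response at row {bad[0] + 1}, column {bad[1] + 1}"
        )
    return Y.astype(np.int8)


def testlet_discrimination(a: np.ndarray, design: TestletDesign) -> np.ndarray:
    """Per-testlet discrimination ``alpha_d``: mean of ``a_j`` over testlet ``d``.

    This is the loading applied to the testlet effect under the ``n2pltm``.
    """
    a = np.asarray(a, dtype=float)
    if a.shape != (design.n_items,):
        raise ValueError(
            f"discrimination vector has length {a.size}, design has {design.n_items} items"
        )
    if np.any(a <= 0):
        raise ValueError("discriminations must be strictly positive")
    sums = np.bincount(design.assignment, weights=a, minlength=design.n_testlets)
    return sums / design.sizes


def response_probability(model, theta, a, b, eta=0.0, alpha=None):
    """Correct-response probability for one (person, item) configuration.

    Broadcasts over array arguments.  ``alpha`` (the testlet discrimination)
    is required for ``n2pltm``; ``eta`` is ignored by ``2pl``.  The value is
    clamped to lie strictly inside (0, 1).
    """
    model = canonical_model(model)
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise ValueError("discrimination must be strictly positive")
    if model == "n2pltm":
        if alpha is None:
            raise ValueError("n2pltm requires the testlet discrimination alpha")
        z = a * (np.asarray(theta) - b) + np.asarray(alpha) * np.asarray(eta)
    elif model == "t2pltm":
        z = a * (np.asarray(theta) - b + np.asarray(eta))
    else:
        z = a * (np.asarray(theta) - b)
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-z))
    p = _clamp(p)
    return p if isinstance(p, np.ndarray) and p.ndim else float(p)


def probability_matrix(
    items: ItemParameters,
    persons: PersonParameters,
    design: TestletDesign,
    model: str = "n2pltm",
) -> np.ndarray:
    """n x J matrix of cell probabilities under the given model (clamped)."""
    model = canonical_model(model)
    if items.n_items != design.n_items:
        raise ValueError("item parameters and design disagree on J")
    if persons.eta.shape[1] != design.n_testlets:
        raise ValueError("eta has wrong number of testlet columns")
    z = items.a[None, :] * (persons.theta[:, None] - items.b[None, :])
    if model == "n2pltm":
        alpha = testlet_discrimination(items.a, design)
        z = z + alpha[design.assignment][None, :] * persons.eta[:, design.assignment]
    elif model == "t2pltm":
        z = z + items.a[None, :] * persons.eta[:, design.assignment]
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-z))
    return _clamp(p)


def simulate_responses(
    items: ItemParameters,
    persons: PersonParameters,
    design: TestletDesign,
    model: str = "n2pltm",
    seed=None,
) -> np.ndarray:
    """Draw ``y_ij ~ Bernoulli(p_ij)`` independently given the parameters.

    ``seed`` may be an int, a SeedSequence or a Generator; fixed seeds
    reproduce the matrix bit-for-bit.
    """
    rng = np.random.default_rng(seed)
    p = probability_matrix(items, persons, design, model)
    return (rng.random(p.shape) < p).astype(np.int8)


def log_likelihood(
    Y: np.ndarray,
    items: ItemParameters,
    persons: PersonParameters,
    design: TestletDesign,
    model: str = "n2pltm",
) -> float:
    """Bernoulli log-likelihood ``sum_ij [y log p + (1-y) log(1-p)]``.

    Finite for every valid state thanks to the probability guard.
    """
    Y = np.asarray(Y)
    p = probability_matrix(items, persons, design, model)
    if Y.shape != p.shape:
        raise ValueError(f"response matrix shape {Y.shape} != model shape {p.shape}")
    return float(np.sum(np.where(Y == 1, np.log(p), np.log1p(-p))))
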