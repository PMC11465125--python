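"""Mk-family models of discrete character evolution on phylogenies.

Implements continuous-time Markov (Mk) likelihoods by Felsenstein's
pruning algorithm, maximum-likelihood rate estimation with random
restarts, AIC model selection over the fourteen binary-character model
variants used for eye-color presence/absence (plain ER/ARD, gamma
edge-rate ER/ARD, hidden-rates models with 2 or 3 rate classes and the
one-sided hidden-when-present / hidden-when-absent variants, and the
two irreversible models), and marginal ancestral state reconstruction
with >50% presence calls.

States of a hidden-rates model (HRM) are expanded (observed state, rate
class) pairs; simultaneous observed-and-class transitions have rate
zero, and reconstruction marginalizes the hidden classes out.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.linalg import expm as _scipy_expm
from scipy.optimize import minimize
from scipy.stats import gamma as _gamma_dist

from .trees import Phylogeny

__all__ = [
    "MkModel",
    "MkFit",
    "MarginalReconstruction",
    "transition_matrix",
    "mk_loglik",
    "fit_mk",
    "candidate_models",
    "mk_model",
    "select_model",
    "marginal_asr",
    "polymorphic_state_space",
]

_LOG_RATE_LO, _LOG_RATE_HI = np.log(1e-8), np.log(1e3)
_NEG_INF_SENTINEL = -1e290

try:  # pruning inner loop is hot in the simulation studies
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _prune_py(child_flat, child_start, child_count, P, L, root_prior):
    n, k = L.shape
    logscale = 0.0
    for i in range(n):
        cc = child_count[i]
        if cc == 0:
            continue
        v = np.ones(k)
        for ci in range(cc):
            c = child_flat[child_start[i] + ci]
            v = v * (P[c] @ L[c])
        m = v.max()
        if not (m > 0.0) or not np.isfinite(m):
            return _NEG_INF_SENTINEL * 2
        L[i] = v / m
        logscale += np.log(m)
    s = float(root_prior @ L[n - 1])
    if not (s > 0.0):
        return _NEG_INF_SENTINEL * 2
    return np.log(s) + logscale


if _HAVE_NUMBA:

    @njit(cache=False, fastmath=False)
    def _prune_nb(child_flat, child_start, child_count, P, L, root_prior):  # pragma: no cover
        n = L.shape[0]
        k = L.shape[1]
        tmp = np.empty(k)
        logscale = 0.0
        for i in range(n):
            cc = child_count[i]
            if cc == 0:
                continue
            for a in range(k):
                L[i, a] = 1.0
            for ci in range(cc):
                c = child_flat[child_start[i] + ci]
                for a in range(k):
                    s = 0.0
                    for b in range(k):
                        s += P[c, a, b] * L[c, b]
                    tmp[a] = s
                for a in range(k):
                    L[i, a] *= tmp[a]
            m = 0.0
            for a in range(k):
                if L[i, a] > m:
                    m = L[i, a]
            if m <= 0.0 or m != m:
                return -1e300
            for a in range(k):
                L[i, a] /= m
            logscale += np.log(m)
        s = 0.0
        for a in range(k):
            s += root_prior[a] * L[n - 1, a]
        if s <= 0.0:
            return -1e300
        return np.log(s) + logscale

    _prune = _prune_nb
else:  # pragma: no cover
    _prune = _prune_py


# ---------------------------------------------------------------------------
# transition probabilities


def _edge_probs(Q: np.ndarray, blen: np.ndarray) -> np.ndarray:
    """P(t) = expm(Q t) for every edge length in ``blen`` at once.

    Uses the eigendecomposition of Q when it is well conditioned and
    falls back to per-edge scipy ``expm`` otherwise (defective Q).
    """
    k = Q.shape[0]
    try:
        w, V = np.linalg.eig(Q)
        Vi = np.linalg.inv(V)
        if np.linalg.cond(V) < 1e8:
            E = np.exp(np.outer(blen, w))
            P = np.einsum("ij,ej,jl->eil", V, E, Vi).real
            np.clip(P, 0.0, None, out=P)
            return np.ascontiguousarray(P)
    except np.linalg.LinAlgError:
        pass
    P = np.empty((len(blen), k, k))
    for e, t in enumerate(blen):
        P[e] = _scipy_expm(Q * t)
    np.clip(P, 0.0, None, out=P)
    return P


def transition_matrix(Q: np.ndarray, t: float) -> np.ndarray:
    """Stochastic matrix expm(Q t) for a single duration ``t`` >= 0."""
    Q = np.asarray(Q, dtype=float)
    _check_generator(Q)
    if t < 0:
        raise ValueError("t must be nonnegative")
    return _edge_probs(Q, np.array([float(t)]))[0]


def _check_generator(Q: np.ndarray) -> None:
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("generator must be square")
    off = Q - np.diag(np.diag(Q))
    if np.any(off < -1e-12):
        raise ValueError("off-diagonal rates must be nonnegative")
    if np.any(np.abs(Q.sum(axis=1)) > 1e-8 * max(1.0, np.abs(Q).max())):
        raise ValueError("generator rows must sum to zero")


def gamma_category_rates(alpha: float, K: int = 4) -> np.ndarray:
    """Mean-one discrete gamma rates, K equal-probability categories.

    Each category's rate is the mean of the gamma density over its
    quantile interval (the mean-of-interval convention).
    """
    edges = _gamma_dist.ppf(np.linspace(0, 1, K + 1), a=alpha, scale=1.0 / alpha)
    upper = _gamma_dist.cdf(edges, a=alpha + 1, scale=1.0 / alpha)
    return np.diff(upper) * K


# ---------------------------------------------------------------------------
# model definitions


@dataclass(frozen=True)
class MkModel:
    """A rate-model structure: how a rate vector becomes a generator.

    ``obs_of`` maps expanded states to observed states; for models
    without hidden classes it is the identity. When ``gamma`` is set the
    last free parameter is the gamma shape alpha and edge rates are
    integrated over ``gamma_k`` equal-probability categories.
    """

    name: str
    n_obs: int
    n_expanded: int
    n_params: int
    build_Q: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    obs_of: tuple = ()
    gamma: bool = False
    gamma_k: int = 4

    def __post_init__(self):
        if not self.obs_of:
            object.__setattr__(self, "obs_of", tuple(range(self.n_expanded)))

    @property
    def n_rate_params(self) -> int:
        return self.n_params - (1 if self.gamma else 0)

    def generator(self, rates: np.ndarray) -> np.ndarray:
        rates = np.asarray(rates, dtype=float)
        if rates.shape != (self.n_rate_params,):
            raise ValueError(f"{self.name}: expected {self.n_rate_params} rates, got {rates.shape}")
        if np.any(rates < 0):
            raise ValueError("rates must be nonnegative")
        Q = self.build_Q(rates)
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q


def _pair_builder(n: int, pairs: Sequence[tuple[int, int, int]]) -> Callable:
    """Generator builder from (from, to, rate-index) triples."""

    def build(rates: np.ndarray) -> np.ndarray:
        Q = np.zeros((n, n))
        for i, j, ri in pairs:
            Q[i, j] += rates[ri]
        return Q

    return build


def mk_model(structure: str, n_states: int = 2, gamma: bool = False, gamma_k: int = 4) -> MkModel:
    """Plain multistate Mk model, ``structure`` in {"ER", "ARD"}."""
    pairs = []
    if structure == "ER":
        for i in range(n_states):
            for j in range(n_states):
                if i != j:
                    pairs.append((i, j, 0))
        nrate = 1
    elif structure == "ARD":
        ri = 0
        for i in range(n_states):
            for j in range(n_states):
                if i != j:
                    pairs.append((i, j, ri))
                    ri += 1
        nrate = ri
    else:
        raise ValueError("structure must be 'ER' or 'ARD'")
    name = f"Mk-{structure}" + ("+G" if gamma else "")
    return MkModel(
        name=name,
        n_obs=n_states,
        n_expanded=n_states,
        n_params=nrate + (1 if gamma else 0),
        build_Q=_pair_builder(n_states, pairs),
        gamma=gamma,
        gamma_k=gamma_k,
    )


def _hrm_model(n_classes: int, structure: str) -> MkModel:
    """Binary HRM with ``n_classes`` rate classes; expanded state = 2*class + obs.

    ER: one symmetric flip rate per class plus one symmetric
    class-switch rate (ladder between adjacent classes). ARD:
    directional flip rates per class plus directional ladder rates.
    """
    pairs = []
    if structure == "ER":
        for c in range(n_classes):
            pairs += [(2 * c, 2 * c + 1, c), (2 * c + 1, 2 * c, c)]
        s = n_classes
        for c in range(n_classes - 1):
            for o in (0, 1):
                pairs += [(2 * c + o, 2 * (c + 1) + o, s), (2 * (c + 1) + o, 2 * c + o, s)]
        nrate = n_classes + 1
    else:
        for c in range(n_classes):
            pairs += [(2 * c, 2 * c + 1, 2 * c), (2 * c + 1, 2 * c, 2 * c + 1)]
        up, down = 2 * n_classes, 2 * n_classes + 1
        for c in range(n_classes - 1):
            for o in (0, 1):
                pairs += [(2 * c + o, 2 * (c + 1) + o, up), (2 * (c + 1) + o, 2 * c + o, down)]
        nrate = 2 * n_classes + 2
    obs_of = tuple(o for _ in range(n_classes) for o in (0, 1))
    return MkModel(
        name=f"HRM{n_classes}-{structure}",
        n_obs=2,
        n_expanded=2 * n_classes,
        n_params=nrate,
        build_Q=_pair_builder(2 * n_classes, pairs),
        obs_of=obs_of,
    )


def _one_sided_hrm(side: str, structure: str) -> MkModel:
    """HRM with a hidden class only when the color is present (or only when absent).

    hidden-when-present states: A, P1, P2 (obs 0, 1, 1); transitions
    A<->P1, A<->P2 and the class switch P1<->P2. hidden-when-absent is
    the mirror image.
    """
    if structure == "ER":
        pairs = [(0, 1, 0), (1, 0, 0), (0, 2, 1), (2, 0, 1), (1, 2, 2), (2, 1, 2)]
        nrate = 3
    else:
        pairs = [(0, 1, 0), (1, 0, 1), (0, 2, 2), (2, 0, 3), (1, 2, 4), (2, 1, 5)]
        nrate = 6
    if side == "present":
        obs_of = (0, 1, 1)
    elif side == "absent":
        obs_of = (1, 0, 0)
    else:
        raise ValueError("side must be 'present' or 'absent'")
    return MkModel(
        name=f"HRM-hidden-{side}-{structure}",
        n_obs=2,
        n_expanded=3,
        n_params=nrate,
        build_Q=_pair_builder(3, pairs),
        obs_of=obs_of,
    )


def _irreversible(direction: str) -> MkModel:
    if direction == "gain-only":  # a color cannot be lost after it is gained
        pairs = [(0, 1, 0)]
    elif direction == "loss-only":  # cannot be gained after it is lost
        pairs = [(1, 0, 0)]
    else:
        raise ValueError(direction)
    return MkModel(
        name=f"Mk-{direction}",
        n_obs=2,
        n_expanded=2,
        n_params=1,
        build_Q=_pair_builder(2, pairs),
    )


def candidate_models() -> list[MkModel]:
    """The fourteen binary-presence model variants compared by AIC.

    ER and ARD versions of: plain Mk, gamma edge-rate Mk, HRM with 2
    rate classes, HRM with 3 rate classes, HRM hidden-when-present,
    HRM hidden-when-absent; plus the gain-only and loss-only
    irreversible Mk models.
    """
    models = []
    for structure in ("ER", "ARD"):
        models.append(mk_model(structure, 2))
        models.append(mk_model(structure, 2, gamma=True))
        models.append(_hrm_model(2, structure))
        models.append(_hrm_model(3, structure))
        models.append(_one_sided_hrm("present", structure))
        models.append(_one_sided_hrm("absent", structure))
    models.append(_irreversible("gain-only"))
    models.append(_irreversible("loss-only"))
    return models


# ---------------------------------------------------------------------------
# likelihood


def _root_prior_vector(model: MkModel, root_prior, Q: np.ndarray | None) -> np.ndarray:
    k = model.n_expanded
    if root_prior is None or root_prior == "equal":
        return np.full(k, 1.0 / k)
    if isinstance(root_prior, str) and root_prior == "stationary":
        if Q is None:
            raise ValueError("stationary prior needs a generator")
        w, V = np.linalg.eig(Q.T)
        i = int(np.argmin(np.abs(w)))
        pi = np.real(V[:, i])
        pi = np.clip(pi, 0, None)
        return pi / pi.sum()
    pi = np.asarray(root_prior, dtype=float)
    if pi.shape != (k,) or abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("custom root prior must be a length-k simplex vector")
    return pi


def _tip_partials(tree: Phylogeny, character: Mapping[str, object], model: MkModel, states: Sequence) -> np.ndarray:
    arr = tree.arrays
    state_index = {s: i for i, s in enumerate(states)}
    L = np.zeros((arr.n, model.n_expanded))
    obs_of = np.array(model.obs_of)
    seen = set()
    for t in arr.tip_indices:
        label = arr.names[t]
        if label not in character:
            raise KeyError(f"tip {label!r} has no character state")
        seen.add(label)
        s = character[label]
        if s is None or (isinstance(s, float) and np.isnan(s)):
            L[t, :] = 1.0  # missing: uninformative
            continue
        if s not in state_index:
            raise ValueError(f"state {s!r} of tip {label!r} not in alphabet {list(states)}")
        L[t, obs_of == state_index[s]] = 1.0
    extra = set(character) - seen
    if extra:
        raise KeyError(f"character has entries for unknown tips: {sorted(extra)}")
    return L


def _loglik_arrays(arr, L0, model: MkModel, rates: np.ndarray, root_prior) -> float:
    rates = np.asarray(rates, dtype=float)
    if model.gamma:
        alpha = rates[-1]
        Q = model.generator(rates[:-1])
        cat = gamma_category_rates(alpha, model.gamma_k)
        P = np.zeros((arr.n, model.n_expanded, model.n_expanded))
        for r in cat:
            P += _edge_probs(Q, arr.blen * r)
        P /= len(cat)
    else:
        Q = model.generator(rates)
        P = _edge_probs(Q, arr.blen)
    pi = _root_prior_vector(model, root_prior, Q)
    res = _prune(arr.child_flat, arr.child_start, arr.child_count, P, L0.copy(), pi)
    return -np.inf if res < _NEG_INF_SENTINEL else float(res)


def mk_loglik(
    tree: Phylogeny,
    character: Mapping[str, object],
    model: MkModel,
    rates,
    states: Sequence | None = None,
    root_prior="equal",
) -> float:
    """Pruning-algorithm log-likelihood of a discrete character.

    ``character`` maps tip labels to states (``None``/NaN = missing);
    ``states`` fixes the observed-state alphabet (default: 0..n_obs-1).
    Impossible data (e.g. zero rates with discordant tips) yield
    ``-inf`` explicitly.
    """
    if states is None:
        states = list(range(model.n_obs))
    L0 = _tip_partials(tree, character, model, states)
    return _loglik_arrays(tree.arrays, L0, model, np.asarray(rates, dtype=float), root_prior)


@dataclass
class MkFit:
    model: MkModel
    rates: np.ndarray
    loglik: float
    aic: float
    converged: bool
    boundary: bool
    restarts_used: int
    states: tuple
    root_prior: object = "equal"

    @property
    def n_params(self) -> int:
        return self.model.n_params


def fit_mk(
    tree: Phylogeny,
    character: Mapping[str, object],
    model: MkModel,
    restarts: int = 10,
    seed: int = 0,
    states: Sequence | None = None,
    root_prior="equal",
) -> MkFit:
    """Maximum-likelihood rates by bounded multi-start L-BFGS-B on log rates.

    The first start is a heuristic (all rates ~ 1/tree height); the
    rest are lognormal draws around it. Non-convergence is flagged and
    the best point found is returned. A fit with any rate within a
    factor ~2 of the box bounds is flagged ``boundary``.
    """
    if states is None:
        states = sorted({v for v in character.values() if v is not None and v == v})
        if len(states) < model.n_obs:
            states = list(range(model.n_obs)) if all(isinstance(s, (int, np.integer)) for s in states) else states
    observed = {v for v in character.values() if v is not None and v == v}
    arr = tree.arrays
    L0 = _tip_partials(tree, character, model, states)
    height = max(tree.height, 1e-9)
    rng = np.random.default_rng(seed)

    def objective(x):
        if model.gamma:
            r = np.concatenate([np.exp(x[:-1]), [np.exp(x[-1])]])
        else:
            r = np.exp(x)
        ll = _loglik_arrays(arr, L0, model, r, root_prior)
        return 1e12 if ll == -np.inf else -ll

    npar = model.n_params
    base = np.full(npar, np.log(1.0 / height))
    if model.gamma:
        base[-1] = 0.0  # alpha ~ 1
    best_x, best_ll, ok = None, -np.inf, False
    bounds = [(_LOG_RATE_LO, _LOG_RATE_HI)] * npar
    for s in range(max(1, restarts)):
        x0 = base if s == 0 else base + rng.normal(0, 1.5, npar)
        x0 = np.clip(x0, _LOG_RATE_LO + 1e-6, _LOG_RATE_HI - 1e-6)
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
        if -res.fun > best_ll:
            best_ll, best_x, ok = -res.fun, res.x, bool(res.success)
    rates = np.exp(best_x)
    boundary = bool(np.any(best_x < _LOG_RATE_LO + 0.7) or np.any(best_x > _LOG_RATE_HI - 0.7))
    fit = MkFit(
        model=model,
        rates=rates,
        loglik=float(best_ll),
        aic=2.0 * npar - 2.0 * float(best_ll),
        converged=ok and len(observed) >= 2,
        boundary=boundary,
        restarts_used=max(1, restarts),
        states=tuple(states),
        root_prior=root_prior,
    )
    if len(observed) < 2:
        fit.converged = False  # degenerate: single observed state
    return fit


def select_model(fits: Sequence[MkFit]) -> tuple[MkFit, "np.ndarray"]:
    """Lowest-AIC fit and Akaike weights; AIC ties go to fewer parameters."""
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("model selection needs at least two fits")
    aics = np.array([f.aic for f in fits])
    d = aics - aics.min()
    w = np.exp(-d / 2.0)
    w /= w.sum()
    order = sorted(range(len(fits)), key=lambda i: (aics[i], fits[i].n_params))
    return fits[order[0]], w


# ---------------------------------------------------------------------------
# marginal ancestral state reconstruction


@dataclass
class MarginalReconstruction:
    """Per-node marginal state probabilities (hidden classes summed out)."""

    states: tuple
    node_probs: dict  # node name -> probability vector over observed states
    calls: dict  # node name -> called state (binary: presence bool)
    tie_flagged: tuple = ()

    def presence_calls(self) -> dict:
        """For binary 0/1 characters: node -> bool, P(present) > 0.5 strictly."""
        return {n: bool(c) for n, c in self.calls.items()}


def marginal_asr(
    tree: Phylogeny,
    character: Mapping[str, object],
    fit: MkFit,
) -> MarginalReconstruction:
    """Marginal probabilities at every node at the fitted MLE rates.

    Combines tipward (pruning) and rootward partial likelihoods; valid
    for arbitrary (including irreversible and hidden-state) generators.
    A node whose presence probability is exactly 0.5 is called absent
    and flagged, matching the strict ">50%" presence rule.
    """
    model, states = fit.model, list(fit.states)
    arr = tree.arrays
    L = _tip_partials(tree, character, model, states)
    rates = np.asarray(fit.rates, dtype=float)
    if model.gamma:
        Q = model.generator(rates[:-1])
        cat = gamma_category_rates(rates[-1], model.gamma_k)
        P = np.zeros((arr.n, model.n_expanded, model.n_expanded))
        for r in cat:
            P += _edge_probs(Q, arr.blen * r)
        P /= len(cat)
    else:
        Q = model.generator(rates)
        P = _edge_probs(Q, arr.blen)
    pi = _root_prior_vector(model, fit.root_prior, Q)
    n, k = arr.n, model.n_expanded
    # tipward pass (rescaled; rescaling cancels in the normalized marginals)
    through = np.zeros((n, k))  # through[c] = P_c @ L_c
    for i in range(n):
        kids = arr.children_of(i)
        if len(kids) == 0:
            continue
        v = np.ones(k)
        for c in kids:
            through[c] = P[c] @ L[c]
            v = v * through[c]
        m = v.max()
        if not (m > 0):
            raise ValueError("data have zero likelihood under the fitted model")
        L[i] = v / m
    # rootward pass
    G = np.zeros((n, k))
    G[n - 1] = pi
    for i in range(n - 1, -1, -1):
        kids = arr.children_of(i)
        if len(kids) == 0:
            continue
        for c in kids:
            others = G[i].copy()
            for c2 in kids:
                if c2 != c:
                    others *= through[c2]
            G[c] = others @ P[c]
            m = G[c].max()
            if m > 0:
                G[c] /= m
    obs_of = np.array(model.obs_of)
    node_probs, calls, flagged = {}, {}, []
    for i in range(n):
        post = L[i] * G[i]
        tot = post.sum()
        if not (tot > 0):
            raise ValueError("zero marginal likelihood at a node")
        post /= tot
        obs = np.array([post[obs_of == s].sum() for s in range(model.n_obs)])
        name = arr.names[i]
        node_probs[name] = obs
        if model.n_obs == 2 and set(states) <= {0, 1}:
            p1 = obs[states.index(1)] if 1 in states else 0.0
            if abs(p1 - 0.5) < 1e-12:
                flagged.append(name)
                calls[name] = 0
            else:
                calls[name] = int(p1 > 0.5)
        else:
            calls[name] = states[int(np.argmax(obs))]
    return MarginalReconstruction(
        states=tuple(states), node_probs=node_probs, calls=calls, tie_flagged=tuple(flagged)
    )


# ---------------------------------------------------------------------------
# polymorphic state space utility


def polymorphic_state_space(colors: Sequence[str] = ("brown", "green", "yellow", "gray", "blue")) -> list:
    """All non-empty color combinations as a polymorphic state space.

    For the five felid eye colors this enumerates 2**5 - 1 = 31 states.
    """
    colors = list(colors)
    out = []
    for r in range(1, len(colors) + 1):
        for combo in itertools.combinations(colors, r):
            out.append(frozenset(combo))
    return out
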