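"""Phylogenetically informed correlation of binary traits.

Pagel-style correlated evolution: two binary traits evolve jointly on
{(0,0),(0,1),(1,0),(1,1)} with simultaneous double transitions
forbidden; the independent model (4 free rates, each trait's gain and
loss rates unaffected by the other trait's state) is compared to the
dependent model (8 free rates) by maximum likelihood. The comparison
is summarized by a log Bayes factor operationalized as 2 x the
log-likelihood difference of the two fits, averaged over replicate
refits from fresh random starts, significant above 2. A tetrachoric
correlation (ML under a thresholded bivariate normal) gives the
direction of each association, and Jenks natural breaks discretize
continuous shade averages before testing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._util import spawn_seed
from .mk import MkModel, fit_mk, mk_loglik
from .trees import Phylogeny, align_to_tips

__all__ = [
    "PagelComparison",
    "binarize_traits",
    "joint_chain_generator",
    "pagel_model",
    "fit_pagel",
    "log_bayes_factor",
    "tetrachoric_r",
    "jenks_breaks",
    "correlate_all",
]

_JOINT_STATES = ((0, 0), (0, 1), (1, 0), (1, 1))

# dependent-rate order: (from joint state -> to joint state)
DEPENDENT_RATE_ORDER = (
    ((0, 0), (0, 1)),  # B gained while A absent
    ((0, 0), (1, 0)),  # A gained while B absent
    ((0, 1), (0, 0)),  # B lost while A absent
    ((0, 1), (1, 1)),  # A gained while B present
    ((1, 0), (0, 0)),  # A lost while B absent
    ((1, 0), (1, 1)),  # B gained while A present
    ((1, 1), (0, 1)),  # A lost while B present
    ((1, 1), (1, 0)),  # B lost while A present
)


def joint_chain_generator(model: str, rates) -> np.ndarray:
    """4-state generator for a pair of binary traits.

    ``independent`` takes 4 rates (a01, a10, b01, b10): each trait's
    gain/loss rate is the same regardless of the other trait's state.
    ``dependent`` takes 8 rates in ``DEPENDENT_RATE_ORDER``. Double
    transitions (both traits flipping at once) always have rate 0.
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    idx = {s: i for i, s in enumerate(_JOINT_STATES)}
    Q = np.zeros((4, 4))
    if model == "independent":
        if rates.shape != (4,):
            raise ValueError("independent model takes 4 rates")
        a01, a10, b01, b10 = rates
        for (a, b), i in idx.items():
            Q[i, idx[(1 - a, b)]] = a01 if a == 0 else a10
            Q[i, idx[(a, 1 - b)]] = b01 if b == 0 else b10
    elif model == "dependent":
        if rates.shape != (8,):
            raise ValueError("dependent model takes 8 rates")
        for r, (src, dst) in zip(rates, DEPENDENT_RATE_ORDER):
            Q[idx[src], idx[dst]] = r
    else:
        raise ValueError("model must be 'independent' or 'dependent'")
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def pagel_model(model: str) -> MkModel:
    """The 4-state joint chain as an MkModel (states indexed 0..3)."""
    if model == "independent":
        build = lambda r: joint_chain_generator("independent", r)
        npar = 4
    elif model == "dependent":
        build = lambda r: joint_chain_generator("dependent", r)
        npar = 8
    else:
        raise ValueError(model)
    return MkModel(
        name=f"pagel-{model}", n_obs=4, n_expanded=4, n_params=npar, build_Q=build
    )


def _joint_character(tree, trait_a, trait_b):
    a = dict(zip(tree.tip_labels, align_to_tips(tree, dict(trait_a))))
    b = dict(zip(tree.tip_labels, align_to_tips(tree, dict(trait_b))))
    idx = {s: i for i, s in enumerate(_JOINT_STATES)}
    char = {}
    for t in tree.tip_labels:
        va, vb = a[t], b[t]
        if va is None or vb is None:
            char[t] = None
        else:
            char[t] = idx[(int(va), int(vb))]
    return char


def fit_pagel(
    tree: Phylogeny, trait_a, trait_b, model: str = "dependent", restarts: int = 1, seed: int = 0
):
    """ML fit of the independent or dependent joint chain (MkFit)."""
    va = {v for v in trait_a.values() if v is not None}
    vb = {v for v in trait_b.values() if v is not None}
    if len(va) < 2 or len(vb) < 2:
        raise ValueError("both traits must vary across tips")
    char = _joint_character(tree, trait_a, trait_b)
    return fit_mk(tree, char, pagel_model(model), restarts=restarts, seed=seed, states=[0, 1, 2, 3])


@dataclass
class PagelComparison:
    trait_a: str
    trait_b: str
    loglik_indep: float
    loglik_dep: float
    replicate_logbf: list = field(default_factory=list)
    mean_logbf: float = np.nan
    significant: bool = False
    tetrachoric: float | None = None
    n_reps_used: int = 0
    n_reps_failed: int = 0
    skipped_reason: str | None = None


def log_bayes_factor(
    tree: Phylogeny,
    trait_a,
    trait_b,
    replicates: int = 100,
    restarts: int = 1,
    seed: int = 0,
    names: tuple = ("A", "B"),
) -> PagelComparison:
    """Averaged log Bayes factor for a trait pair.

    Per replicate, both models are refit from fresh random starts and
    the replicate logBF is 2*(logL_dep - logL_indep); the mean over
    replicates is reported and flagged significant above 2 (positive
    evidence for dependent evolution). Replicates whose fits fail are
    excluded with the count reported.
    """
    va = {v for v in trait_a.values() if v is not None}
    vb = {v for v in trait_b.values() if v is not None}
    if len(va) < 2 or len(vb) < 2:
        return PagelComparison(names[0], names[1], np.nan, np.nan, skipped_reason="invariant trait")
    char = _joint_character(tree, trait_a, trait_b)
    mi, md = pagel_model("independent"), pagel_model("dependent")
    bfs = []
    best_l0, best_l1 = -np.inf, -np.inf
    failed = 0
    for rep in range(replicates):
        s = spawn_seed(seed, "pagel", rep)
        f0 = fit_mk(tree, char, mi, restarts=restarts, seed=s, states=[0, 1, 2, 3])
        f1 = fit_mk(tree, char, md, restarts=restarts, seed=s + 1, states=[0, 1, 2, 3])
        if not np.isfinite(f0.loglik) or not np.isfinite(f1.loglik):
            failed += 1
            continue
        best_l0, best_l1 = max(best_l0, f0.loglik), max(best_l1, f1.loglik)
        bfs.append(2.0 * (f1.loglik - f0.loglik))
    mean_bf = float(np.mean(bfs)) if bfs else np.nan
    return PagelComparison(
        trait_a=names[0],
        trait_b=names[1],
        loglik_indep=best_l0,
        loglik_dep=best_l1,
        replicate_logbf=bfs,
        mean_logbf=mean_bf,
        significant=bool(mean_bf > 2.0),
        n_reps_used=len(bfs),
        n_reps_failed=failed,
    )


# ---------------------------------------------------------------------------
# tetrachoric correlation


def tetrachoric_r(table) -> float:
    """ML tetrachoric correlation of a 2x2 count table [[n00, n01], [n10, n11]].

    Thresholds come from the margins of a latent bivariate standard
    normal; the correlation maximizes the multinomial likelihood of the
    quadrant probabilities. Boundary tables return exactly +/-1: a zero
    concordant cell (both-present or both-absent) with positive
    remaining cells gives -1, a zero discordant cell gives +1. Tables
    with a constant margin are degenerate and raise.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("expected a nonnegative 2x2 count table")
    n = t.sum()
    if n < 1:
        raise ValueError("empty table")
    n00, n01, n10, n11 = t[0, 0], t[0, 1], t[1, 0], t[1, 1]
    row1, col1 = t[1].sum(), t[:, 1].sum()
    if row1 == 0 or row1 == n or col1 == 0 or col1 == n:
        raise ValueError("degenerate margins: a trait is constant")
    concordant_zero = (n11 == 0 and n00 > 0 and n01 > 0 and n10 > 0) or (
        n00 == 0 and n11 > 0 and n01 > 0 and n10 > 0
    )
    discordant_zero = (n01 == 0 or n10 == 0) and n00 > 0 and n11 > 0
    if concordant_zero and not discordant_zero:
        return -1.0
    if discordant_zero and not concordant_zero:
        return 1.0
    ta = stats.norm.ppf(1.0 - row1 / n)  # threshold for trait A (rows)
    tb = stats.norm.ppf(1.0 - col1 / n)

    def cell_probs(rho):
        both = stats.multivariate_normal.cdf(
            [-ta, -tb], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
        )  # P(A=1, B=1) via symmetry
        pa, pb = row1 / n, col1 / n
        p11 = both
        p10 = pa - p11
        p01 = pb - p11
        p00 = 1.0 - pa - pb + p11
        return np.clip(np.array([p00, p01, p10, p11]), 1e-12, 1.0)

    counts = np.array([n00, n01, n10, n11])

    def nll(rho):
        return -float(counts @ np.log(cell_probs(rho)))

    res = optimize.minimize_scalar(nll, bounds=(-0.9999, 0.9999), method="bounded")
    return float(res.x)


# ---------------------------------------------------------------------------
# Jenks natural breaks


def jenks_breaks(values, nclasses: int = 2) -> list:
    """Exact Jenks natural breaks by dynamic programming.

    Partitions the sorted values into ``nclasses`` contiguous classes
    minimizing the total within-class sum of squared deviations;
    boundaries are reported as the class maxima (last boundary = data
    maximum).
    """
    x = np.sort(np.asarray(list(values), dtype=float))
    n = len(x)
    if nclasses < 2:
        raise ValueError("nclasses must be >= 2")
    if len(np.unique(x)) < nclasses:
        raise ValueError("need at least as many distinct values as classes")
    # prefix sums for O(1) within-class SSE
    cs, cs2 = np.concatenate([[0.0], np.cumsum(x)]), np.concatenate([[0.0], np.cumsum(x**2)])

    def sse(i, j):  # values x[i..j] inclusive
        m = j - i + 1
        s = cs[j + 1] - cs[i]
        return (cs2[j + 1] - cs2[i]) - s * s / m

    INF = np.inf
    cost = np.full((nclasses, n), INF)
    back = np.zeros((nclasses, n), dtype=int)
    for j in range(n):
        cost[0, j] = sse(0, j)
    for k in range(1, nclasses):
        for j in range(k, n):
            for i in range(k, j + 1):  # class k starts at i
                c = cost[k - 1, i - 1] + sse(i, j)
                if c < cost[k, j]:
                    cost[k, j] = c
                    back[k, j] = i
    bounds = []
    j = n - 1
    for k in range(nclasses - 1, 0, -1):
        i = back[k, j]
        bounds.append(x[i - 1])
        j = i - 1
    bounds.reverse()
    bounds.append(x[-1])
    return [float(b) for b in bounds]


def jenks_classes(values, nclasses: int = 2) -> np.ndarray:
    """Class index (0 = lowest) per value under jenks_breaks boundaries."""
    x = np.asarray(list(values), dtype=float)
    bounds = jenks_breaks(x, nclasses)
    return np.searchsorted(np.asarray(bounds[:-1]), x, side="left")


# ---------------------------------------------------------------------------
# trait table utilities


def binarize_traits(table: pd.DataFrame, multistate: Sequence[str] = ()) -> pd.DataFrame:
    """Expand a taxon x trait table into binary indicator columns.

    Columns named in ``multistate`` hold category strings, possibly
    several joined with '+' (taxa may fall into multiple categories,
    e.g. 'nocturnal+crepuscular' or a 'pink+black' nose); each observed
    category becomes its own 0/1 column. Remaining columns must already
    be 0/1 and pass through unchanged.
    """
    out = {}
    for col in table.columns:
        if col in multistate:
            cats = sorted(
                {c.strip() for cell in table[col].dropna() for c in str(cell).split("+") if c.strip()}
            )
            if not cats:
                raise ValueError(f"column {col!r} has no categories")
            for c in cats:
                out[f"{col}_{c}"] = table[col].map(
                    lambda cell: int(c in [p.strip() for p in str(cell).split("+")])
                    if pd.notna(cell)
                    else np.nan
                )
        else:
            vals = set(table[col].dropna().unique())
            if not vals <= {0, 1}:
                raise ValueError(f"column {col!r} is not binary; list it in `multistate`")
            out[col] = table[col]
    return pd.DataFrame(out, index=table.index)


def correlate_all(
    tree: Phylogeny,
    presence: pd.DataFrame,
    factors: pd.DataFrame | None = None,
    shade_averages: pd.DataFrame | None = None,
    replicates: int = 10,
    restarts: int = 1,
    seed: int = 0,
    jenks_nclasses: int = 2,
) -> pd.DataFrame:
    """All eye-color x eye-color and eye-color x factor comparisons.

    Continuous shade averages are discretized with Jenks breaks and
    coded so the lighter class is 1 (a positive association then means
    the trait goes with lighter shades). Taxa with missing values are
    dropped per pair with the count reported. Returns a long-format
    table of mean logBF, tetrachoric r and significance flags.
    """
    tables = {c: presence[c] for c in presence.columns}
    if factors is not None:
        for c in factors.columns:
            tables[c] = factors[c]
    if shade_averages is not None:
        for c in shade_averages.columns:
            vals = shade_averages[c].dropna()
            cls = jenks_classes(vals.to_numpy(), jenks_nclasses)
            light = pd.Series(
                (cls == cls.max()).astype(int), index=vals.index
            )  # lighter (higher) class coded 1
            tables[f"{c}_light"] = light.reindex(shade_averages.index)
    colors = list(presence.columns)
    others = [c for c in tables if c not in colors]
    pairs = [(a, b) for a, b in itertools.combinations_with_replacement(colors, 2)] + [
        (c, o) for c in colors for o in others
    ]
    rows = []
    for i, (a, b) in enumerate(pairs):
        sa, sb = tables[a], tables[b]
        both = pd.concat([sa, sb], axis=1, keys=["a", "b"]).dropna()
        keep = [t for t in both.index if t in set(tree.tip_labels)]
        dropped = len(tree.tip_labels) - len(keep)
        sub = tree.prune_keep(keep) if dropped else tree
        ta = {t: int(both.loc[t, "a"]) for t in keep}
        tb = {t: int(both.loc[t, "b"]) for t in keep}
        cmp_ = log_bayes_factor(
            sub, ta, tb, replicates=replicates, restarts=restarts, seed=spawn_seed(seed, a, b), names=(a, b)
        )
        if cmp_.skipped_reason is None:
            ct = np.zeros((2, 2))
            for t in keep:
                ct[ta[t], tb[t]] += 1
            try:
                cmp_.tetrachoric = tetrachoric_r(ct)
            except ValueError:
                cmp_.tetrachoric = np.nan
        rows.append(
            {
                "traitA": a,
                "traitB": b,
                "mean_logBF": cmp_.mean_logbf,
                "r": cmp_.tetrachoric,
                "significant": cmp_.significant,
                "n_reps_used": cmp_.n_reps_used,
                "n_taxa": len(keep),
                "n_dropped": dropped,
                "skipped": cmp_.skipped_reason or "",
            }
        )
    return pd.DataFrame(rows)
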