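"""Quantitative reconstruction of shade RGB values at ancestral nodes.

For each (node, color) called present, a subset tree keeps only the
descendants connected to the node through an unbroken chain of
presence calls — lineages where the color was lost, or lost and later
re-arose, carry no information about the ancestral shade and are
excluded. On the subset tree each channel of each dark/medium/light
tier is reconstructed under Brownian motion by maximum likelihood: the
estimate at a node equals the generalized-least-squares root estimate
of the tree rerooted at that node, with 95% confidence intervals from
the estimation variance. Shade counts and primary-tier identities are
reconstructed as unordered multistate characters through the Mk
machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .mk import MarginalReconstruction, fit_mk, marginal_asr, mk_model, select_model
from .trees import Phylogeny, align_to_tips

__all__ = [
    "BMReconstruction",
    "bm_asr",
    "subset_color_tree",
    "retained_tips",
    "reconstruct_color_shades",
    "shade_count_asr",
    "tier_identity_asr",
]


@dataclass
class BMReconstruction:
    """Per-node BM estimates: value, variance and CI95 = estimate +/- 1.96 sd."""

    estimates: dict  # node name -> float
    variances: dict
    sigma2_mle: float
    root_estimate: float

    def ci95(self, node: str) -> tuple[float, float]:
        e, v = self.estimates[node], self.variances[node]
        half = 1.96 * np.sqrt(max(v, 0.0))
        return (e - half, e + half)


def _node_tip_structure(tree: Phylogeny):
    """Distances needed for rerooted GLS at every node.

    Returns (arr, tips, depth, M, desc) where M[a, b] is the
    root-to-MRCA distance between tips a and b (diagonal: tip depths)
    and desc[i] the descendant tip indices of node i.
    """
    arr = tree.arrays
    tips, M = arr.tip_shared_depths()
    return arr, tips, arr.depths(), M, arr.descendant_tips()


def bm_asr(tree: Phylogeny, values: Mapping[str, float]) -> BMReconstruction:
    """ML Brownian-motion ancestral states with rerooted-GLS estimates.

    sigma^2 is the ML estimate at the root; each node's estimate and
    variance come from the GLS mean of the tip values under the
    covariance of the tree rerooted at that node (so the root estimate
    of a two-tip equal-branch tree is the tip midpoint). Zero-length
    star degeneracies (a tip at distance 0 from the evaluation node)
    are handled by pinning the estimate to that tip's value.
    """
    vals = np.array([float(v) for v in align_to_tips(tree, dict(values))], dtype=float)
    if len(vals) < 2:
        raise ValueError("BM reconstruction needs at least 2 tips with values")
    if not np.all(np.isfinite(vals)):
        raise ValueError("tip values must be finite")
    arr, tips, depth, M, desc = _node_tip_structure(tree)
    pos = {int(t): a for a, t in enumerate(tips)}
    m = len(tips)
    tipd = np.diag(M).copy()
    # tip-tip distances
    D = tipd[:, None] + tipd[None, :] - 2.0 * M
    # order of `vals` follows tree.tip_labels == postorder tip order == tips order
    estimates, variances, denoms = {}, {}, {}
    ridge = 1e-12
    sigma2 = None
    root_est = None
    for i in range(arr.n):
        if arr.is_tip[i]:
            estimates[arr.names[i]] = float(vals[pos[i]])
            variances[arr.names[i]] = 0.0
            continue
        # distance from node i to every tip
        di = np.empty(m)
        below = desc[i]
        below_pos = np.array([pos[int(t)] for t in below])
        inside = np.zeros(m, dtype=bool)
        inside[below_pos] = True
        di[below_pos] = tipd[below_pos] - depth[i]
        if not np.all(inside):
            t0 = below_pos[0]
            out = ~inside
            di[out] = depth[i] + tipd[out] - 2.0 * M[t0, out]
        # covariance of tips when rooted at node i
        C = 0.5 * (di[:, None] + di[None, :] - D)
        C[np.diag_indices(m)] = di
        zero = np.flatnonzero(di <= 1e-12)
        if len(zero):  # a tip sits exactly at this node
            estimates[arr.names[i]] = float(vals[zero[0]])
            variances[arr.names[i]] = 0.0
            continue
        Ci = np.linalg.solve(C + ridge * np.eye(m), np.eye(m))
        one = np.ones(m)
        denom = float(one @ Ci @ one)
        est = float(one @ Ci @ vals) / denom
        estimates[arr.names[i]] = est
        denoms[arr.names[i]] = denom
        if i == arr.root:
            resid = vals - est
            sigma2 = float(resid @ Ci @ resid) / m
            root_est = est
    if sigma2 is None:  # root was degenerate (tip sitting at the root)
        sigma2 = 0.0
        root_est = estimates[arr.names[arr.root]]
    for name, denom in denoms.items():
        variances[name] = sigma2 / denom if denom > 1e-300 else np.inf
    return BMReconstruction(
        estimates=estimates, variances=variances, sigma2_mle=sigma2, root_estimate=float(root_est)
    )


# ---------------------------------------------------------------------------
# subset-tree rule


def retained_tips(tree: Phylogeny, presence: Mapping[str, int], focal: str) -> list:
    """Tips connected to ``focal`` through an unbroken chain of presence calls.

    ``presence`` maps every node and tip name to a 0/1 call for one
    color. A tip below any absent-called internal node is excluded even
    if itself present (the color was lost and re-arose independently,
    so its shade says nothing about the focal ancestor's).
    """
    arr = tree.arrays
    if focal not in arr.index:
        raise KeyError(f"focal node {focal!r} not in tree")
    fi = arr.index[focal]
    for name in arr.names:
        if name not in presence:
            raise KeyError(f"presence call missing for node {name!r}")
    if not presence[focal]:
        raise ValueError(f"focal node {focal!r} is not called present")
    out = []
    stack = [fi]
    while stack:
        i = stack.pop()
        if not presence[arr.names[i]]:
            continue  # chain broken: nothing below contributes
        if arr.is_tip[i]:
            out.append(arr.names[i])
        else:
            stack.extend(arr.children_of(i))
    return sorted(out)


def subset_color_tree(tree: Phylogeny, presence: Mapping[str, int], focal: str) -> Phylogeny:
    """Subset tree for reconstructing one color's shades at ``focal``."""
    keep = retained_tips(tree, presence, focal)
    if not keep:
        raise ValueError(f"no tips retained under {focal!r}")
    clade_tips = keep
    return tree.prune_keep(clade_tips, allow_single=True)


# ---------------------------------------------------------------------------
# full-shade reconstruction


def reconstruct_color_shades(
    tree: Phylogeny,
    profiles: Mapping[tuple, object],
    presence_by_color: Mapping[str, Mapping[str, int]],
    colors: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Reconstruct 3 tiers x RGB (9 channels) per (node, color) with CIs.

    ``profiles`` maps (taxon, color) to a tiered GroupShadeProfile;
    ``presence_by_color`` maps color -> node/tip -> 0/1 call from the
    selected discrete model. Estimates outside [0, 255] are flagged,
    never clipped; nodes whose subset retains fewer than 2 tips are
    skipped with the reason recorded.
    """
    from .shades import TIERS

    if colors is None:
        colors = sorted(presence_by_color)
    arr = tree.arrays
    rows = []
    for color in colors:
        presence = presence_by_color[color]
        for i in range(arr.n):
            node = arr.names[i]
            if arr.is_tip[i] or not presence.get(node, 0):
                continue
            try:
                keep = retained_tips(tree, presence, node)
            except (KeyError, ValueError) as exc:
                rows.append(_skip_row(node, color, str(exc)))
                continue
            keep = [t for t in keep if (t, color) in profiles]
            if len(keep) < 2:
                rows.append(_skip_row(node, color, f"only {len(keep)} retained tips with profiles"))
                continue
            sub = tree.prune_keep(keep)
            for tier in TIERS:
                for ch, ci in (("r", 0), ("g", 1), ("b", 2)):
                    vals = {
                        t: float(np.asarray(profiles[(t, color)].tiered()[tier].rgb)[ci]) for t in keep
                    }
                    rec = bm_asr(sub, vals)
                    est = rec.root_estimate
                    lo, hi = rec.ci95(sub.arrays.names[sub.arrays.root])
                    rows.append(
                        {
                            "node": node,
                            "color": color,
                            "tier": tier,
                            "channel": ch,
                            "estimate": est,
                            "display": int(round_half_up(min(max(est, 0), 255))),
                            "var": rec.variances[sub.arrays.names[sub.arrays.root]],
                            "ci_lo": lo,
                            "ci_hi": hi,
                            "out_of_range": bool(est < 0 or est > 255),
                            "n_tips": len(keep),
                            "skipped": "",
                        }
                    )
    return pd.DataFrame(rows)


def _skip_row(node, color, reason):
    return {
        "node": node,
        "color": color,
        "tier": "",
        "channel": "",
        "estimate": np.nan,
        "display": np.nan,
        "var": np.nan,
        "ci_lo": np.nan,
        "ci_hi": np.nan,
        "out_of_range": False,
        "n_tips": 0,
        "skipped": reason,
    }


# ---------------------------------------------------------------------------
# discrete shade summaries


def _multistate_asr(tree: Phylogeny, char: Mapping[str, object], states, restarts: int, seed: int):
    observed = sorted({v for v in char.values() if v is not None})
    if len(observed) == 1:  # degenerate: every node that state
        arr = tree.arrays
        probs = {n: np.array([1.0 if s == observed[0] else 0.0 for s in states]) for n in arr.names}
        return MarginalReconstruction(
            states=tuple(states), node_probs=probs, calls={n: observed[0] for n in arr.names}
        )
    k = len(states)
    fits = [
        fit_mk(tree, char, mk_model(s, k), restarts=restarts, seed=seed, states=states)
        for s in ("ER", "ARD")
    ]
    best, _ = select_model(fits)
    return marginal_asr(tree, char, best)


def shade_count_asr(
    tree: Phylogeny, counts: Mapping[str, int], restarts: int = 5, seed: int = 0
) -> MarginalReconstruction:
    """Reconstruct the number of shades (1-4) per eye as a multistate character."""
    for v in counts.values():
        if v is not None and v not in (1, 2, 3, 4):
            raise ValueError(f"shade counts must be 1-4, got {v}")
    states = sorted({v for v in counts.values() if v is not None})
    if len(states) < 2:
        states = states or [2]
    return _multistate_asr(tree, counts, states, restarts, seed)


def tier_identity_asr(
    tree: Phylogeny, tiers: Mapping[str, str], restarts: int = 5, seed: int = 0
) -> MarginalReconstruction:
    """Reconstruct the primary (or secondary) shade tier as a 3-state character."""
    valid = {"dark", "medium", "light"}
    for v in tiers.values():
        if v is not None and v not in valid:
            raise ValueError(f"tier must be one of {sorted(valid)}, got {v!r}")
    states = [t for t in ("dark", "medium", "light") if t in set(tiers.values())]
    if not states:
        raise ValueError("no tier states observed")
    return _multistate_asr(tree, tiers, states, restarts, seed)
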