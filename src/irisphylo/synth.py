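"""Synthetic inputs with known ground truth.

Generates everything the pipeline consumes: multi-shade iris pixel
matrices (optionally rendered to PNG as concentric rings, emulating
central heterochromia with distinct pigment zones), pure-birth
ultrametric trees, discrete characters evolved under Mk-type processes,
continuous channel values under Brownian motion, and paired binary
traits under a dependent four-state chain. Every generator is
bit-reproducible under a fixed seed and records complete node-level
truth for recovery tests.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field

import numpy as np

from ._util import check_rgb
from .mk import _edge_probs
from .trees import Phylogeny

__all__ = [
    "ShadeSpec",
    "SimTruth",
    "SyntheticIris",
    "gen_iris",
    "save_iris_png",
    "gen_tree",
    "sim_mk",
    "sim_bm",
    "sim_pagel",
]


@dataclass(frozen=True)
class ShadeSpec:
    """One pigment shade: an RGB centroid and its pixel-share of the iris."""

    centroid: tuple
    proportion: float
    label: str = ""

    def __post_init__(self):
        check_rgb(self.centroid)
        if not (0.0 <= self.proportion <= 1.0):
            raise ValueError(f"proportion must be in [0, 1], got {self.proportion}")


@dataclass
class SimTruth:
    """Ground truth of a simulation: every node's state/value plus parameters."""

    node_states: dict
    parameters: dict = field(default_factory=dict)
    seed: int = 0


@dataclass
class SyntheticIris:
    """A generated iris: pixel matrix plus the per-pixel shade assignment."""

    pixels: np.ndarray  # (n, 3) int
    shade_labels: np.ndarray  # (n,) index into shades
    shades: tuple
    layout: str
    seed: int


def _largest_remainder_counts(n: int, proportions: np.ndarray) -> np.ndarray:
    raw = proportions * n
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    short = n - counts.sum()
    # deterministic: largest remainders first, ties to earlier shades
    order = np.lexsort((np.arange(len(rem)), -rem))
    counts[order[:short]] += 1
    return counts


def gen_iris(
    n_pixels: int,
    shades,
    noise_sd: float = 0.0,
    layout: str = "rings",
    seed: int = 0,
) -> SyntheticIris:
    """Generate an iris of ``n_pixels`` pixels from 1-4 shade specs.

    Pixel counts per shade follow largest-remainder allocation of the
    proportions (deterministic); each pixel is its shade centroid plus
    iid Gaussian channel noise, clipped to [0, 255] and rounded. The
    ``rings`` layout keeps shades in contiguous blocks (pupil-adjacent
    first, matching concentric annuli); ``mixed`` shuffles pixel order.
    """
    shades = tuple(s if isinstance(s, ShadeSpec) else ShadeSpec(*s) for s in shades)
    if not (1 <= len(shades) <= 4):
        raise ValueError("between 1 and 4 shades required")
    if n_pixels < 1:
        raise ValueError("n_pixels must be positive")
    props = np.array([s.proportion for s in shades], dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"shade proportions must sum to 1, got {props.sum()}")
    cents = [check_rgb(s.centroid) for s in shades]
    if len({c for c in cents}) != len(cents):
        raise ValueError("shade centroids must be distinct")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if layout not in ("rings", "mixed"):
        raise ValueError("layout must be 'rings' or 'mixed'")
    counts = _largest_remainder_counts(n_pixels, props)
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(len(shades)), counts)
    base = np.array(cents, dtype=float)[labels]
    noisy = base + rng.normal(0.0, noise_sd, size=base.shape) if noise_sd > 0 else base
    pixels = np.clip(np.floor(noisy + 0.5), 0, 255).astype(int)
    if layout == "mixed":
        perm = rng.permutation(n_pixels)
        pixels, labels = pixels[perm], labels[perm]
    return SyntheticIris(pixels=pixels, shade_labels=labels, shades=shades, layout=layout, seed=seed)


def save_iris_png(iris: SyntheticIris, path, size: int = 64) -> None:
    """Render the iris as an RGBA disc (transparent outside; rings by proportion)."""
    from PIL import Image

    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    r = np.sqrt((xx - c) ** 2 + (yy - c) ** 2) / (size / 2.0)
    img = np.zeros((size, size, 4), dtype=np.uint8)
    props = np.array([s.proportion for s in iris.shades])
    edges = np.sqrt(np.concatenate([[0.0], np.cumsum(props)]))  # equal-area annuli
    by_shade = [iris.pixels[iris.shade_labels == k] for k in range(len(iris.shades))]
    rng = np.random.default_rng(iris.seed)
    inside = r <= 1.0
    for k in range(len(iris.shades)):
        mask = inside & (r >= edges[k]) & (r <= edges[k + 1])
        npx = int(mask.sum())
        if npx == 0 or len(by_shade[k]) == 0:
            continue
        draw = by_shade[k][rng.integers(0, len(by_shade[k]), npx)]
        img[mask, :3] = draw
        img[mask, 3] = 255
    Image.fromarray(img, mode="RGBA").save(path)


# ---------------------------------------------------------------------------
# trees and characters


def gen_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0, height: float = 1.0) -> Phylogeny:
    """Pure-birth (Yule) rooted binary ultrametric tree, scaled to ``height``.

    Tip labels are T1..Tn; topology and branch lengths are
    bit-reproducible for a fixed seed.
    """
    from dendropy.simulate import treesim

    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = _random.Random(int(seed))
    dtree = treesim.birth_death_tree(
        birth_rate=float(birth_rate), death_rate=0.0, num_extant_tips=int(n_tips), rng=rng
    )
    # the simulator stops at the n-th birth event, leaving zero-length
    # pendant edges; the Yule process conditioned on n tips continues for
    # a final Exp(n * birth_rate) waiting time before the present
    grace = rng.expovariate(n_tips * birth_rate)
    for lf in dtree.leaf_node_iter():
        lf.edge.length = (lf.edge.length or 0.0) + grace
    dtree.seed_node.edge.length = None  # a root edge carries no information here
    h = max(lf.distance_from_root() for lf in dtree.leaf_node_iter())
    scale = height / h
    for edge in dtree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    return Phylogeny(dtree)


def _preorder(arr):
    return range(arr.n - 1, -1, -1)


def sim_mk(tree: Phylogeny, Q: np.ndarray, root_state: int, seed: int = 0):
    """Evolve a discrete state down the tree under generator ``Q``.

    Returns (tip states by label, SimTruth with every node's state).
    """
    Q = np.asarray(Q, dtype=float)
    from .mk import _check_generator

    _check_generator(Q)
    k = Q.shape[0]
    if not (0 <= root_state < k):
        raise ValueError("root_state outside the state space")
    arr = tree.arrays
    P = _edge_probs(Q, arr.blen)
    rng = np.random.default_rng(seed)
    state = np.empty(arr.n, dtype=int)
    state[arr.root] = root_state
    for i in _preorder(arr):
        for c in arr.children_of(i):
            p = P[c][state[i]]
            p = p / p.sum()
            state[c] = rng.choice(k, p=p)
    truth = SimTruth(
        node_states={arr.names[i]: int(state[i]) for i in range(arr.n)},
        parameters={"Q": Q, "root_state": int(root_state)},
        seed=seed,
    )
    tips = {arr.names[t]: int(state[t]) for t in arr.tip_indices}
    return tips, truth


def sim_bm(tree: Phylogeny, root_value: float, sigma2: float, seed: int = 0):
    """Brownian motion: child = parent + Normal(0, sigma2 * branch length)."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    arr = tree.arrays
    rng = np.random.default_rng(seed)
    val = np.empty(arr.n)
    val[arr.root] = float(root_value)
    for i in _preorder(arr):
        for c in arr.children_of(i):
            val[c] = val[i] + rng.normal(0.0, np.sqrt(sigma2 * arr.blen[c]))
    truth = SimTruth(
        node_states={arr.names[i]: float(val[i]) for i in range(arr.n)},
        parameters={"root_value": float(root_value), "sigma2": float(sigma2)},
        seed=seed,
    )
    tips = {arr.names[t]: float(val[t]) for t in arr.tip_indices}
    return tips, truth


def sim_pagel(tree: Phylogeny, rates, seed: int = 0, root_state: tuple | None = None):
    """Paired binary traits evolved jointly under the 8-rate dependent chain.

    The joint state lives on {(0,0),(0,1),(1,0),(1,1)} with simultaneous
    double transitions forbidden. Returns (trait A tips, trait B tips,
    SimTruth with joint node states as (a, b) tuples).
    """
    from .correlation import joint_chain_generator

    Q = joint_chain_generator("dependent", rates)
    rng = np.random.default_rng(seed)
    if root_state is None:
        joint_root = int(rng.integers(0, 4))
    else:
        a, b = root_state
        joint_root = 2 * int(a) + int(b)
    tips, truth = sim_mk(tree, Q, joint_root, seed=int(rng.integers(0, 2**31)))
    decode = {0: (0, 0), 1: (0, 1), 2: (1, 0), 3: (1, 1)}
    truth.node_states = {n: decode[s] for n, s in truth.node_states.items()}
    truth.parameters = {"rates": np.asarray(rates, dtype=float), "root_state": decode[joint_root]}
    truth.seed = seed
    trait_a = {t: decode[s][0] for t, s in tips.items()}
    trait_b = {t: decode[s][1] for t, s in tips.items()}
    return trait_a, trait_b, truth
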