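"""Within-eye shade extraction per taxon x color group.

Felid irises are rarely homogeneous — a darker pigment often rings the
pupil with a lighter periphery (central heterochromia) — so each
taxon x color group is summarized by 2-4 "shades". Per image: embed
the pixels in 2-D (UMAP for local structure, or PCA for a fully
deterministic run), pick k with an automated elbow criterion, and
k-means cluster the embedding, averaging member pixels in the original
RGB space. Across a group's images: round the mean k to a consensus,
re-cluster every image at that k, match clusters between images by the
minimum-SSE assignment over all permutations, and merge with
pixel-count weighting (more pixels, more influence). Merged shades are
ranked by prevalence and slotted into dark/medium/light tiers by
distance from black, with fill rules so every profile exposes three
tiers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from ._util import distance_from_black, round_half_up

__all__ = [
    "ImageShadeSet",
    "GroupShadeProfile",
    "Shade",
    "TierReference",
    "embed_pixels",
    "select_k_elbow",
    "cluster_image",
    "consensus_k",
    "match_shades",
    "merge_group",
    "assign_tiers",
    "tier_reference_from_profiles",
    "extract_group_profile",
    "stability_curve",
]

TIERS = ("dark", "medium", "light")


@dataclass(frozen=True)
class Shade:
    rgb: tuple
    count: int
    rank: int | None = None
    tier: str | None = None


@dataclass
class ImageShadeSet:
    image: str
    k: int
    clusters: list  # list of (mean_rgb ndarray, pixel count)
    method: str = "pca"
    seed: int = 0

    @property
    def n_pixels(self) -> int:
        return int(sum(c for _, c in self.clusters))


@dataclass
class GroupShadeProfile:
    taxon: str
    color: str
    k: int
    shades: list  # of Shade, sorted by prevalence rank
    n_images: int = 1

    @property
    def primary(self) -> Shade:
        return self.shades[0]

    @property
    def secondary(self) -> Shade | None:
        return self.shades[1] if len(self.shades) > 1 else None

    def tiered(self) -> dict:
        return {s.tier: s for s in self.shades if s.tier}


@dataclass(frozen=True)
class TierReference:
    """Mean dark/medium/light RGB over three-shade profiles, used to slot 2-shade eyes."""

    dark: tuple
    medium: tuple
    light: tuple

    def nearest(self, rgb) -> str:
        rgb = np.asarray(rgb, dtype=float)
        d = {t: np.linalg.norm(rgb - np.asarray(getattr(self, t), dtype=float)) for t in TIERS}
        return min(TIERS, key=lambda t: d[t])


# ---------------------------------------------------------------------------
# embedding and clustering


def embed_pixels(pixels: np.ndarray, method: str = "pca", seed: int = 0) -> np.ndarray:
    """2-D embedding of an (n, 3) pixel matrix.

    ``umap`` (15 neighbors, min_dist 0.1, Euclidean) preserves the
    local structure fine shade differences live in and is deterministic
    under a fixed seed; ``pca`` projects onto the first two principal
    components and is the fully deterministic fallback.
    """
    X = np.asarray(getattr(pixels, "pixels", pixels), dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("expected an (n, 3) pixel matrix")
    if method == "pca":
        if len(X) < 2:
            raise ValueError("need at least 2 pixels for a pca embedding")
        Xc = X - X.mean(axis=0)
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        V = Vt[:2].T
        for j in range(V.shape[1]):
            if V[np.argmax(np.abs(V[:, j])), j] < 0:
                V[:, j] = -V[:, j]
        return Xc @ V
    if method == "umap":
        if len(X) < 10:
            raise ValueError("need at least 10 pixels for a umap embedding")
        import umap

        reducer = umap.UMAP(
            n_components=2, n_neighbors=15, min_dist=0.1, metric="euclidean", random_state=int(seed)
        )
        return np.asarray(reducer.fit_transform(X), dtype=float)
    raise ValueError("method must be 'umap' or 'pca'")


def _kmeans_sse(emb: np.ndarray, k: int, seed: int):
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(emb)
    return float(km.inertia_), labels


def select_k_elbow(embedding: np.ndarray, kmin: int = 1, kmax: int = 6, seed: int = 0) -> int:
    """Automated elbow: k with the sharpest kink in the SSE curve.

    The within-cluster SSE is computed for k in [kmin, kmax] (capped at
    the number of distinct points) and the chosen k maximizes the
    relative drop SSE[k-1] / SSE[k] — the discrete curvature of the
    log-SSE curve, which is scale-free, so the kink lands on the
    planted cluster count for well-separated shades regardless of how
    the earlier drops dwarf the later ones. A vanishing SSE (perfect
    clustering) wins outright; ties go to the smaller k. Degenerate
    all-identical input yields k = 1.
    """
    emb = np.asarray(embedding, dtype=float)
    if not (1 <= kmin <= kmax):
        raise ValueError("need kmax >= kmin >= 1")
    distinct = len(np.unique(emb, axis=0))
    if distinct == 1:
        return 1
    kmax = min(kmax, distinct)
    ks = list(range(kmin, kmax + 1))
    if len(ks) == 1:
        return ks[0]
    sse = {}
    for k in ks:
        if k == 1:
            sse[1] = float(((emb - emb.mean(axis=0)) ** 2).sum())
        else:
            sse[k], _ = _kmeans_sse(emb, k, seed)
    scale = max(sse.values())
    eps = 1e-12 * max(scale, 1.0)
    best_k, best_ratio = None, -np.inf
    for k in ks[1:]:
        if sse[k] <= eps:
            ratio = np.inf if sse[k - 1] > eps else 1.0
        else:
            ratio = sse[k - 1] / sse[k]
        if ratio > best_ratio + 1e-12:
            best_k, best_ratio = k, ratio
    return ks[0] if best_k is None else best_k


def cluster_image(
    pixels: np.ndarray, embedding: np.ndarray, k: int, seed: int = 0, image: str = "img", method: str = "pca"
) -> ImageShadeSet:
    """k-means on the 2-D embedding; cluster mean RGB taken in original space."""
    X = np.asarray(getattr(pixels, "pixels", pixels), dtype=float)
    emb = np.asarray(embedding, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    distinct = len(np.unique(emb, axis=0))
    if k > distinct:
        raise ValueError(f"k={k} exceeds the {distinct} distinct embedded points")
    if k == 1:
        labels = np.zeros(len(X), dtype=int)
    else:
        _, labels = _kmeans_sse(emb, k, seed)
    clusters = []
    for c in range(k):
        sel = labels == c
        clusters.append((X[sel].mean(axis=0), int(sel.sum())))
    return ImageShadeSet(image=image, k=k, clusters=clusters, method=method, seed=seed)


def consensus_k(ks) -> int:
    """Arithmetic mean of per-image k values, rounded half-up."""
    ks = list(ks)
    if not ks:
        raise ValueError("empty k list")
    return int(round_half_up(float(np.mean(ks))))


def match_shades(reference: ImageShadeSet, other: ImageShadeSet) -> tuple:
    """Permutation aligning ``other``'s clusters to the reference's.

    Exhaustive search over all k! assignments for the minimum total
    squared Euclidean RGB distance between matched cluster means; ties
    break to the lexicographically smallest permutation. Returns perm
    with other.clusters[perm[i]] matched to reference cluster i.
    """
    if reference.k != other.k:
        raise ValueError(f"cluster counts differ: {reference.k} vs {other.k}")
    ref = np.array([c[0] for c in reference.clusters], dtype=float)
    oth = np.array([c[0] for c in other.clusters], dtype=float)
    d2 = ((ref[:, None, :] - oth[None, :, :]) ** 2).sum(axis=2)
    best_perm, best_cost = None, np.inf
    for perm in itertools.permutations(range(reference.k)):
        cost = sum(d2[i, perm[i]] for i in range(reference.k))
        if cost < best_cost - 1e-12 or (abs(cost - best_cost) <= 1e-12 and perm < best_perm):
            best_perm, best_cost = perm, min(cost, best_cost)
    return best_perm


def merge_group(shade_sets, taxon: str = "", color: str = "") -> GroupShadeProfile:
    """Pixel-count-weighted merge of matched shade sets into one profile.

    All sets must already share a common cluster labeling (index i of
    every set refers to the same shade). Merged shade i is the
    count-weighted mean of the per-image cluster means — images are
    deliberately not resized upstream so higher-quality images with
    more pixels contribute more. Prevalence ranks by total pixel count,
    ties going to the darker shade.
    """
    shade_sets = list(shade_sets)
    if not shade_sets:
        raise ValueError("empty input")
    k = shade_sets[0].k
    if any(s.k != k for s in shade_sets):
        raise ValueError("all shade sets must have the same k")
    shades = []
    for i in range(k):
        means = np.array([s.clusters[i][0] for s in shade_sets], dtype=float)
        counts = np.array([s.clusters[i][1] for s in shade_sets], dtype=float)
        rgb = (means * counts[:, None]).sum(axis=0) / counts.sum()
        shades.append(Shade(rgb=tuple(rgb), count=int(counts.sum())))
    order = sorted(
        range(k), key=lambda i: (-shades[i].count, distance_from_black(shades[i].rgb))
    )
    ranked = [replace(shades[i], rank=r + 1) for r, i in enumerate(order)]
    return GroupShadeProfile(taxon=taxon, color=color, k=k, shades=ranked, n_images=len(shade_sets))


# ---------------------------------------------------------------------------
# tiers


def _weighted_merge_two(a: Shade, b: Shade) -> Shade:
    wa, wb = a.count, b.count
    rgb = tuple(
        (np.asarray(a.rgb) * wa + np.asarray(b.rgb) * wb) / (wa + wb)
    )
    return Shade(rgb=rgb, count=wa + wb)


def assign_tiers(
    profile: GroupShadeProfile, reference_tiers: TierReference | None = None
) -> GroupShadeProfile:
    """Slot a profile's shades into dark/medium/light tiers.

    Three shades: ordered by increasing distance from black. Two
    shades: each takes the nearest of the reference tier averages, and
    the vacant tier is filled (missing dark or light duplicates medium;
    missing medium averages dark and light). One shade: duplicated into
    all three tiers. Four shades: the two closest shades are merged
    with pixel-count weighting, then treated as three. The result
    always populates exactly three tiers.
    """
    shades = list(profile.shades)
    if not (1 <= len(shades) <= 4):
        raise ValueError("profiles must have between 1 and 4 shades")
    if len(shades) == 4:
        pairs = list(itertools.combinations(range(4), 2))
        dist = lambda i, j: np.linalg.norm(np.asarray(shades[i].rgb) - np.asarray(shades[j].rgb))
        i, j = min(pairs, key=lambda ij: dist(*ij))
        merged = _weighted_merge_two(shades[i], shades[j])
        shades = [s for t, s in enumerate(shades) if t not in (i, j)] + [merged]
    tiered: dict = {}
    if len(shades) == 3:
        by_dist = sorted(shades, key=lambda s: distance_from_black(s.rgb))
        for t, s in zip(TIERS, by_dist):
            tiered[t] = replace(s, tier=t)
    elif len(shades) == 2:
        if reference_tiers is None:
            raise ValueError(
                "two-shade profiles need reference tier averages (none available from 3-shade profiles)"
            )
        a, b = sorted(shades, key=lambda s: distance_from_black(s.rgb))
        ta, tb = reference_tiers.nearest(a.rgb), reference_tiers.nearest(b.rgb)
        if ta == tb:  # both nearest the same slot: keep order by darkness
            tb = {"dark": "medium", "medium": "light", "light": "light"}[ta]
            if tb == ta:
                ta = "medium"
        tiered[ta] = replace(a, tier=ta)
        tiered[tb] = replace(b, tier=tb)
        missing = [t for t in TIERS if t not in tiered]
        for t in missing:
            if t in ("dark", "light"):
                src = tiered["medium"]
                tiered[t] = replace(src, tier=t)
            else:
                d, l = np.asarray(tiered["dark"].rgb), np.asarray(tiered["light"].rgb)
                tiered["medium"] = Shade(
                    rgb=tuple((d + l) / 2.0),
                    count=int((tiered["dark"].count + tiered["light"].count) / 2),
                    rank=None,
                    tier="medium",
                )
    else:  # single shade duplicated into all tiers
        s = shades[0]
        for t in TIERS:
            tiered[t] = replace(s, tier=t)
    ranked = sorted(
        profile.shades, key=lambda s: s.rank if s.rank else 99
    )
    out_shades = [tiered[t] for t in TIERS]
    # keep prevalence ranks where the tiered shade is one of the originals
    orig = {tuple(np.round(np.asarray(s.rgb), 9)): s.rank for s in ranked}
    out_shades = [
        replace(s, rank=orig.get(tuple(np.round(np.asarray(s.rgb), 9)), s.rank)) for s in out_shades
    ]
    return GroupShadeProfile(
        taxon=profile.taxon, color=profile.color, k=profile.k, shades=out_shades, n_images=profile.n_images
    )


def tier_reference_from_profiles(profiles) -> TierReference:
    """Global dark/medium/light averages over all tiered three-shade profiles."""
    acc = {t: [] for t in TIERS}
    for p in profiles:
        tiers = p.tiered()
        if len(p.shades) == 3 and set(tiers) == set(TIERS):
            for t in TIERS:
                acc[t].append(np.asarray(tiers[t].rgb, dtype=float))
    if not acc["dark"]:
        raise ValueError("no three-shade profiles available for a tier reference")
    return TierReference(
        **{t: tuple(np.mean(acc[t], axis=0)) for t in TIERS}
    )


# ---------------------------------------------------------------------------
# group pipeline


def extract_group_profile(
    images: dict,
    taxon: str = "",
    color: str = "",
    method: str = "pca",
    seed: int = 0,
    kmin: int = 1,
    kmax: int = 6,
) -> GroupShadeProfile:
    """Full pipeline for one taxon x color group (pre-tier profile).

    Per image: embed, elbow-select k. Across images: consensus k
    (mean, half-up), re-cluster every image at the consensus,
    match clusters to the reference image (the one with the most
    pixels), and merge with pixel-count weighting.
    """
    if not images:
        raise ValueError("no images")
    items = list(images.items())
    embeddings, ks = {}, {}
    for name, px in items:
        emb = embed_pixels(px, method=method, seed=seed)
        embeddings[name] = emb
        ks[name] = select_k_elbow(emb, kmin=kmin, kmax=kmax, seed=seed)
    k = consensus_k(list(ks.values()))
    sets = []
    for name, px in items:
        distinct = len(np.unique(embeddings[name], axis=0))
        kk = min(k, distinct)
        sets.append(cluster_image(px, embeddings[name], kk, seed=seed, image=name, method=method))
    # reference = image with the most pixels; others matched to it
    ref_i = max(range(len(sets)), key=lambda i: (sets[i].n_pixels, -i))
    ref = sets[ref_i]
    aligned = []
    for s in sets:
        if s.k != ref.k:
            # an image with fewer distinct points than the consensus k cannot
            # be matched cluster-for-cluster; pad by duplicating nothing —
            # drop it from the merge with its pixels unused
            continue
        perm = match_shades(ref, s)
        aligned.append(
            ImageShadeSet(
                image=s.image,
                k=s.k,
                clusters=[s.clusters[perm[i]] for i in range(s.k)],
                method=s.method,
                seed=s.seed,
            )
        )
    return merge_group(aligned, taxon=taxon, color=color)


def stability_curve(
    images: dict,
    taxon: str = "",
    color: str = "",
    method: str = "pca",
    seed: int = 0,
    tolerance: float = 5.0,
) -> tuple:
    """Per-shade RGB as the image sample grows, plus a convergence flag.

    The group profile is recomputed on image prefixes of size 1..N;
    convergence means the maximum per-channel change over the last step
    is below ``tolerance`` (default 5 channel units). Leveling-off
    indicates the sample is large enough to overcome lighting noise.
    """
    names = list(images)
    if len(names) < 2:
        raise ValueError("need at least 2 images for a stability curve")
    rows = []
    prev = None
    converged = False
    for n in range(1, len(names) + 1):
        prof = extract_group_profile(
            {nm: images[nm] for nm in names[:n]}, taxon=taxon, color=color, method=method, seed=seed
        )
        rgbs = np.array([s.rgb for s in prof.shades], dtype=float)
        rows.append({"n_images": n, "k": prof.k, "shade_rgbs": rgbs})
        if prev is not None and prev.shape == rgbs.shape:
            converged = bool(np.max(np.abs(rgbs - prev)) < tolerance)
        elif prev is not None:
            converged = False
        prev = rgbs
    return rows, converged
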