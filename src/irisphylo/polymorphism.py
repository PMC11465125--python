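"""Are discrete iris color categories statistically meaningful?

Pixel-level covariance PCA of RGB values, binned mean colors along each
component (to visualize what color axis a component captures), a linear
mixed model testing the category effect on component scores with image
nested in taxon as random intercepts, and per-species Kruskal-Wallis /
pairwise Mann-Whitney tests along PC2. Channels share units, so the
PCA is centered but not scaled.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PCAResult",
    "fit_pixel_pca",
    "binned_pc_colors",
    "lmm_category_effect",
    "per_species_pc2_test",
]


@dataclass
class PCAResult:
    mean: np.ndarray
    loadings: np.ndarray  # columns are components, orthonormal
    variance_fractions: np.ndarray
    scores: np.ndarray

    def project(self, pixels: np.ndarray) -> np.ndarray:
        return (np.asarray(pixels, dtype=float) - self.mean) @ self.loadings


def fit_pixel_pca(pixels: np.ndarray) -> PCAResult:
    """Covariance PCA of an (n, 3) pixel matrix.

    Components are ordered by decreasing variance; the sign convention
    makes each loading vector's largest-magnitude element positive.
    With three channels the three components always account for all of
    the variance.
    """
    X = np.asarray(getattr(pixels, "pixels", pixels), dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("expected an (n, 3) pixel matrix")
    if len(X) < 3:
        raise ValueError("need at least 3 pixels")
    mean = X.mean(axis=0)
    Xc = X - mean
    total = (Xc**2).sum()
    if total <= 0:
        raise ValueError("constant pixel data: zero total variance")
    _, s, Vt = np.linalg.svd(Xc, full_matrices=True)
    var = np.zeros(3)
    var[: len(s)] = s**2
    loadings = Vt.T
    for j in range(3):  # deterministic sign
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
    return PCAResult(
        mean=mean,
        loadings=loadings,
        variance_fractions=var / var.sum(),
        scores=Xc @ loadings,
    )


def binned_pc_colors(
    pca: PCAResult, pixels: np.ndarray, component: int = 1, nbins: int = 20
) -> pd.DataFrame:
    """Mean RGB in equally spaced score bins along one component.

    Bins span [min, max] of the scores with the last bin right-closed;
    empty bins are reported with NaN color, never as zeros.
    """
    if component not in (1, 2, 3):
        raise ValueError("component must be 1, 2 or 3")
    if nbins < 2:
        raise ValueError("nbins must be >= 2")
    X = np.asarray(getattr(pixels, "pixels", pixels), dtype=float)
    sc = pca.project(X)[:, component - 1]
    lo, hi = sc.min(), sc.max()
    if hi - lo <= 0:
        raise ValueError("degenerate score range")
    edges = np.linspace(lo, hi, nbins + 1)
    idx = np.clip(np.digitize(sc, edges[1:-1], right=False), 0, nbins - 1)
    rows = []
    for b in range(nbins):
        sel = idx == b
        mean = X[sel].mean(axis=0) if sel.any() else np.full(3, np.nan)
        rows.append(
            {
                "component": component,
                "bin": b,
                "lo": edges[b],
                "hi": edges[b + 1],
                "r": mean[0],
                "g": mean[1],
                "b": mean[2],
                "n": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mixed model


@dataclass
class CategoryEffectResult:
    component: int
    statistic: float
    df: float
    pvalue: float
    pvalue_adj: float
    singular: bool
    pairwise: pd.DataFrame | None = None


def lmm_category_effect(
    scores: np.ndarray,
    category,
    taxon,
    image,
    component: int = 1,
    n_comparisons: int = 3,
    alpha: float = 0.05,
) -> CategoryEffectResult:
    """Mixed-model test of the category effect on one component's scores.

    Fits score ~ category with random intercepts for taxon and for
    image nested in taxon, tests the category terms with an omnibus
    Wald chi-square, and Bonferroni-adjusts across the three
    components. When the omnibus test is significant, all category
    pairs are compared with a studentized-range (Tukey-style)
    adjustment. Singular fits are flagged in the result, not raised.
    """
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {
            "score": np.asarray(scores, dtype=float),
            "category": pd.Categorical(category),
            "taxon": list(taxon),
            "image": list(image),
        }
    )
    cats = list(df["category"].cat.categories)
    if len(cats) < 2:
        raise ValueError("need at least 2 categories to test a category effect")
    if df["taxon"].nunique() < 2:
        raise ValueError("need at least 2 taxa for the nested random effects")
    singular = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "score ~ C(category)",
            df,
            groups="taxon",
            re_formula="1",
            vc_formula={"image": "0 + C(image)"},
        )
        try:
            fit = model.fit(reml=True)
        except Exception:
            fit = model.fit(reml=True, method="lbfgs")
        if not fit.converged or np.any(~np.isfinite(fit.bse_fe)):
            singular = True
    names = fit.model.exog_names
    ix = [i for i, nm in enumerate(names) if "category" in nm]
    beta = np.asarray(fit.fe_params)[ix]
    V = np.asarray(fit.cov_params())[np.ix_(ix, ix)]
    stat = float(beta @ np.linalg.solve(V, beta))
    dfc = float(len(ix))
    p = float(stats.chi2.sf(stat, dfc))
    p_adj = min(1.0, p * n_comparisons)
    pairwise = None
    if p_adj < alpha:
        pairwise = _tukey_pairs(fit, names, cats)
    return CategoryEffectResult(
        component=component,
        statistic=stat,
        df=dfc,
        pvalue=p,
        pvalue_adj=p_adj,
        singular=singular,
        pairwise=pairwise,
    )


def _tukey_pairs(fit, names, cats) -> pd.DataFrame:
    """All-pairs category contrasts with studentized-range adjustment."""
    beta = np.asarray(fit.fe_params)
    cov = np.asarray(fit.cov_params())[: len(names), : len(names)]
    k = len(cats)
    col_of = {}
    for i, nm in enumerate(names):
        for c in cats:
            if nm == f"C(category)[T.{c}]":
                col_of[c] = i
    rows = []
    for a, b in itertools.combinations(cats, 2):
        v = np.zeros(len(names))
        if a in col_of:
            v[col_of[a]] += 1
        if b in col_of:
            v[col_of[b]] -= 1
        est = float(v @ beta)
        se = float(np.sqrt(v @ cov @ v))
        t = est / se if se > 0 else np.inf
        # studentized-range on |t|*sqrt(2), large-sample df
        p = float(stats.studentized_range.sf(abs(t) * np.sqrt(2), k, 1e6))
        rows.append({"a": a, "b": b, "estimate": est, "se": se, "t": t, "p_tukey": min(1.0, p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-species nonparametric tests


@dataclass
class SpeciesPC2Result:
    species: str
    h_statistic: float | None
    pvalue: float | None
    pvalue_adj: float | None
    pairwise: pd.DataFrame | None
    skipped_reason: str | None = None


def per_species_pc2_test(
    scores: np.ndarray, category, species, alpha: float = 0.05
) -> list[SpeciesPC2Result]:
    """Kruskal-Wallis across color categories within each species along PC2.

    Bonferroni correction is applied over species; significant species
    get two-sided pairwise Mann-Whitney tests, Bonferroni-corrected
    over category pairs, all adjusted p values capped at 1. Species
    with fewer than two categories are skipped with the reason
    recorded. Ranks use midranks with the standard tie correction.
    """
    df = pd.DataFrame(
        {"score": np.asarray(scores, dtype=float), "category": list(category), "species": list(species)}
    )
    species_list = sorted(df["species"].unique())
    testable = [
        sp for sp in species_list if df.loc[df["species"] == sp, "category"].nunique() >= 2
    ]
    n_tests = max(1, len(testable))
    out = []
    for sp in species_list:
        sub = df[df["species"] == sp]
        groups = [g["score"].to_numpy() for _, g in sub.groupby("category", observed=True)]
        cats = sorted(sub["category"].unique())
        if len(groups) < 2:
            out.append(
                SpeciesPC2Result(sp, None, None, None, None, skipped_reason="fewer than 2 categories")
            )
            continue
        try:
            h, p = stats.kruskal(*groups)
        except ValueError:  # all values identical across groups
            h, p = 0.0, 1.0
        p_adj = min(1.0, p * n_tests)
        pairwise = None
        if p_adj < alpha:
            pairs = list(itertools.combinations(range(len(cats)), 2))
            rows = []
            by_cat = {c: sub.loc[sub["category"] == c, "score"].to_numpy() for c in cats}
            for i, j in pairs:
                a, b = cats[i], cats[j]
                method = "exact" if (len(by_cat[a]) <= 8 and len(by_cat[b]) <= 8) else "asymptotic"
                res = stats.mannwhitneyu(by_cat[a], by_cat[b], alternative="two-sided", method=method)
                rows.append(
                    {
                        "a": a,
                        "b": b,
                        "u": float(res.statistic),
                        "p": float(res.pvalue),
                        "p_adj": min(1.0, float(res.pvalue) * len(pairs)),
                    }
                )
            pairwise = pd.DataFrame(rows)
        out.append(SpeciesPC2Result(sp, float(h), float(p), p_adj, pairwise))
    return out
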