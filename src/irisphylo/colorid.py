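"""Impartial iris color categorization.

Each iris image is reduced to its mean RGB, encoded as a hex code,
matched to a named color, and assigned to one of eleven basic color
categories (white, black, red, green, yellow, blue, brown, purple,
pink, orange, gray; hazel counts as green and beige as yellow). A
taxon's surveyed images then yield category frequencies and the "most
common" color set under predominance thresholds: four colors each
>20%, else three each >26.6%, else two each >40%, else the single
plurality color.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .colornames import BASIC_CATEGORIES

__all__ = [
    "TaxonColorSurvey",
    "load_pixels",
    "mean_rgb",
    "rgb_to_hex",
    "hex_to_rgb",
    "name_color",
    "assign_category",
    "most_common_colors",
    "categorize_image",
    "survey_taxon",
    "presence_matrix",
]

_ALIASES = {"hazel": "green", "beige": "yellow", "grey": "gray"}


class UnresolvableColorError(ValueError):
    """A color name carries neither a category token nor a usable descriptor."""


# ---------------------------------------------------------------------------
# pixels and codes


def load_pixels(path) -> np.ndarray:
    """Pixel matrix (n, 3) from a PNG/JPEG image or an r,g,b CSV.

    Fully transparent pixels (alpha == 0) are excluded — transparency
    is the masking mechanism standing in for manual iris cropping. Row
    order is raster order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".csv", ".tsv", ".txt"):
        df = pd.read_csv(path, sep="\t" if path.suffix.lower() == ".tsv" else ",")
        cols = [c.strip().lower() for c in df.columns]
        if not {"r", "g", "b"} <= set(cols):
            raise ValueError(f"{path}: pixel CSV needs r,g,b columns, found {list(df.columns)}")
        df.columns = cols
        px = df[["r", "g", "b"]].to_numpy(dtype=int)
    else:
        from PIL import Image

        with Image.open(path) as im:
            im = im.convert("RGBA")
            arr = np.asarray(im).reshape(-1, 4)
        px = arr[arr[:, 3] > 0, :3].astype(int)
    if len(px) == 0:
        raise ValueError(f"{path}: no unmasked pixels")
    if px.min() < 0 or px.max() > 255:
        raise ValueError(f"{path}: channel values outside [0, 255]")
    return px


def mean_rgb(pixels: np.ndarray) -> tuple[int, int, int]:
    """Per-channel arithmetic mean, rounded half-up to integers."""
    px = np.asarray(getattr(pixels, "pixels", pixels), dtype=float)
    if px.ndim != 2 or px.shape[1] != 3 or len(px) == 0:
        raise ValueError("pixel matrix must be nonempty with 3 channels")
    m = round_half_up(px.mean(axis=0))
    return int(m[0]), int(m[1]), int(m[2])


def rgb_to_hex(rgb) -> str:
    r, g, b = rgb
    for c in (r, g, b):
        if not (0 <= int(c) <= 255):
            raise ValueError(f"channel out of range: {rgb}")
    return f"#{int(r):02X}{int(g):02X}{int(b):02X}"


def hex_to_rgb(code: str) -> tuple[int, int, int]:
    m = re.fullmatch(r"#?([0-9A-Fa-f]{6})", code.strip())
    if not m:
        raise ValueError(f"invalid hex code: {code!r}")
    h = m.group(1)
    return tuple(int(h[i : i + 2], 16) for i in (0, 2, 4))


# ---------------------------------------------------------------------------
# naming and categorization


def name_color(code: str, table: pd.DataFrame) -> str:
    """Closest named color for a hex code.

    Exact hex match wins; otherwise the entry with the minimum
    Euclidean RGB distance, ties broken lexicographically by name.
    """
    if table is None or len(table) == 0:
        raise ValueError("empty color table")
    code = rgb_to_hex(hex_to_rgb(code))
    exact = table.loc[table["hex"].str.upper() == code, "name"]
    if len(exact):
        return exact.iloc[0]
    rgb = np.array(hex_to_rgb(code), dtype=float)
    cands = np.array([hex_to_rgb(h) for h in table["hex"]], dtype=float)
    d2 = ((cands - rgb) ** 2).sum(axis=1)
    best = np.flatnonzero(d2 == d2.min())
    names = sorted(table["name"].iloc[i] for i in best)
    return names[0]


def _category_token(text: str) -> str | None:
    """Last whole-word basic-category token (or alias) in ``text``."""
    found = None
    for word in re.findall(r"[A-Za-z]+", text.lower()):
        if word in _ALIASES:
            found = _ALIASES[word]
        elif word in BASIC_CATEGORIES:
            found = word
    return found


def assign_category(name: str, table: pd.DataFrame | None = None, descriptor: str | None = None) -> str:
    """Basic category of a color name.

    The name's own category token wins when present (the last hue word,
    following descriptor conventions where the final noun is the hue);
    otherwise the ISCC-style descriptor — passed directly or looked up
    in ``table`` — supplies it. Unresolvable names raise, never guess.
    """
    tok = _category_token(name)
    if tok:
        return tok
    if descriptor is None and table is not None:
        row = table.loc[table["name"].str.lower() == name.lower()]
        if len(row):
            descriptor = row["iscc"].iloc[0] or None
    if descriptor:
        tok = _category_token(descriptor)
        if tok:
            return tok
    raise UnresolvableColorError(f"cannot resolve a basic category for {name!r}")


def categorize_image(pixels, table: pd.DataFrame) -> dict:
    """Full per-image record: mean RGB -> hex -> name -> category."""
    rgb = mean_rgb(pixels)
    code = rgb_to_hex(rgb)
    name = name_color(code, table)
    return {"rgb": rgb, "hex": code, "name": name, "category": assign_category(name, table)}


# ---------------------------------------------------------------------------
# per-taxon surveys


def most_common_colors(frequencies: Mapping[str, float]) -> set:
    """Predominant color set from category frequencies.

    First matching rule wins: four categories each >20%; else three
    each >26.6%; else two each >40%; else the single plurality category
    (frequency ties broken lexicographically).
    """
    if not frequencies:
        raise ValueError("empty frequency table")
    tot = sum(frequencies.values())
    if abs(tot - 1.0) > 1e-6:
        raise ValueError(f"frequencies must sum to 1, got {tot}")
    ranked = sorted(frequencies.items(), key=lambda kv: (-kv[1], kv[0]))
    for count, cutoff in ((4, 0.20), (3, 0.266), (2, 0.40)):
        if len(ranked) >= count and all(f > cutoff for _, f in ranked[:count]):
            return {c for c, _ in ranked[:count]}
    return {ranked[0][0]}


@dataclass
class TaxonColorSurvey:
    taxon: str
    image_records: list = field(default_factory=list)  # per-image dicts
    frequencies: dict = field(default_factory=dict)
    observed: set = field(default_factory=set)
    most_common: set = field(default_factory=set)


def survey_taxon(taxon: str, images: Mapping[str, np.ndarray], table: pd.DataFrame) -> TaxonColorSurvey:
    """Categorize every image of a taxon and summarize its color set."""
    if not images:
        raise ValueError("at least one image required")
    records = []
    for label, px in images.items():
        rec = categorize_image(px, table)
        rec["image"] = label
        records.append(rec)
    cats = [r["category"] for r in records]
    freqs = {c: cats.count(c) / len(cats) for c in sorted(set(cats))}
    return TaxonColorSurvey(
        taxon=taxon,
        image_records=records,
        frequencies=freqs,
        observed=set(cats),
        most_common=most_common_colors(freqs),
    )


def presence_matrix(surveys: Sequence[TaxonColorSurvey], most_common: bool = False) -> pd.DataFrame:
    """Taxa x 11 categories 0/1 table from surveys (observed or most-common sets)."""
    rows = {}
    for s in surveys:
        colors = s.most_common if most_common else s.observed
        rows[s.taxon] = {c: int(c in colors) for c in BASIC_CATEGORIES}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(BASIC_CATEGORIES))
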