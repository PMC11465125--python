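"""Curated color-name fixture.

A small stand-in for the large open-source color-name databases used to
name iris colors impartially: each record is (name, hex, ISCC-NBS-style
descriptor or empty). Names whose text already contains one of the
eleven basic category tokens need no descriptor; the rest carry a
descriptor whose hue noun supplies the category (e.g. "Burnt Coffee" ->
"moderate brown" -> brown). The table covers all eleven basic
categories with at least five entries each.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["COLOR_RECORDS", "make_color_table", "BASIC_CATEGORIES"]

BASIC_CATEGORIES = (
    "white",
    "black",
    "red",
    "green",
    "yellow",
    "blue",
    "brown",
    "purple",
    "pink",
    "orange",
    "gray",
)

# (name, hex, ISCC-NBS descriptor or "")
COLOR_RECORDS = [
    # blue
    ("Air Superiority Blue", "#72A0C1", ""),
    ("Navy Blue", "#000080", ""),
    ("Sky Blue", "#87CEEB", ""),
    ("Powder Blue", "#B0E0E6", ""),
    ("Steel Blue", "#4682B4", ""),
    ("Cerulean", "#007BA7", "strong blue"),
    # brown
    ("Burnt Coffee", "#251D0E", "moderate brown"),
    ("Saddle Brown", "#8B4513", ""),
    ("Sandy Brown", "#F4A460", ""),
    ("Dark Brown", "#654321", ""),
    ("Walnut Brown", "#5D432C", ""),
    ("Sepia", "#704214", "moderate brown"),
    ("Chocolate", "#7B3F00", "strong brown"),
    # gray
    ("Slate Gray", "#708090", ""),
    ("Battleship Gray", "#848482", ""),
    ("Ash Gray", "#B2BEB5", ""),
    ("Dim Gray", "#696969", ""),
    ("Silver", "#C0C0C0", "light gray"),
    ("Charcoal", "#36454F", "dark gray"),
    # green
    ("Forest Green", "#228B22", ""),
    ("Sea Green", "#2E8B57", ""),
    ("Fern Green", "#4F7942", ""),
    ("Moss Green", "#8A9A5B", ""),
    ("Olive Green", "#BAB86C", ""),
    ("Emerald", "#50C878", "brilliant green"),
    ("Hazel", "#8E7618", ""),
    # yellow
    ("Lemon Yellow", "#FFF44F", ""),
    ("Golden Yellow", "#FFDF00", ""),
    ("Mustard Yellow", "#FFDB58", ""),
    ("Canary Yellow", "#FFEF00", ""),
    ("Amber", "#FFBF00", "vivid yellow"),
    ("Beige", "#F5F5DC", ""),
    # white
    ("White", "#FFFFFF", ""),
    ("Snow White", "#FFFAFA", ""),
    ("Antique White", "#FAEBD7", ""),
    ("Ghost White", "#F8F8FF", ""),
    ("Floral White", "#FFFAF0", ""),
    ("Ivory", "#FFFFF0", "yellowish white"),
    # black
    ("Black", "#000000", ""),
    ("Jet Black", "#0A0A0A", ""),
    ("Raisin Black", "#242124", ""),
    ("Smoky Black", "#100C08", ""),
    ("Eerie Black", "#1B1B1B", ""),
    ("Licorice", "#1A1110", "black"),
    # red
    ("Fire Engine Red", "#CE2029", ""),
    ("Ruby Red", "#9B111E", ""),
    ("Brick Red", "#CB4154", ""),
    ("Cherry Red", "#D2042D", ""),
    ("Crimson", "#DC143C", "vivid red"),
    ("Scarlet", "#FF2400", "vivid red"),
    # purple
    ("Royal Purple", "#7851A9", ""),
    ("Tyrian Purple", "#66023C", ""),
    ("Purple Heart", "#69359C", ""),
    ("Dark Purple", "#301934", ""),
    ("Lavender", "#E6E6FA", "very pale purple"),
    ("Violet", "#8F00FF", "vivid purple"),
    # pink
    ("Hot Pink", "#FF69B4", ""),
    ("Baby Pink", "#F4C2C2", ""),
    ("Salmon Pink", "#FF91A4", ""),
    ("Rose Pink", "#FF66CC", ""),
    ("Carnation Pink", "#FFA6C9", ""),
    ("Fuchsia", "#FF00FF", "vivid purplish pink"),
    # orange
    ("Burnt Orange", "#CC5500", ""),
    ("Safety Orange", "#FF7800", ""),
    ("Orange Peel", "#FF9F00", ""),
    ("Tangerine", "#F28500", "vivid orange"),
    ("Pumpkin", "#FF7518", "vivid orange"),
    ("Apricot", "#FBCEB1", "pale orange"),
]


def make_color_table() -> pd.DataFrame:
    """Color-name table with columns name, hex, iscc, category.

    The category is resolved from the name's own category token when it
    has one (hazel -> green, beige -> yellow) and from the ISCC-style
    descriptor otherwise.
    """
    from .colorid import assign_category

    df = pd.DataFrame(COLOR_RECORDS, columns=["name", "hex", "iscc"])
    df["category"] = [
        assign_category(name, descriptor=iscc or None) for name, iscc in zip(df["name"], df["iscc"])
    ]
    return df
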