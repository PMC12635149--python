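"""Descriptive surfaces: site color cards, PCA scatter data, summaries.

Color cards reconstruct the mean coloration of model and mimic at each
site on the *raw* RGB scale (the display scale; all statistics elsewhere
run on sqrt-channels — the two scales never mix).  The mesosoma card
color is the unweighted mean of the pronotum, mesonotum and propodeum
channels.  Cards render as a small SVG strip: ant glyphs with a
triangle-shaped gaster for models and a round gaster for mimics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .schema import CHANNELS, SiteRegistry

CARD_PARTS = ("head", "mesosoma", "petiole", "gaster")
_PART_SOURCES = {
    "head": ("he",),
    "mesosoma": ("pr", "me", "pp"),
    "petiole": ("pe",),
    "gaster": ("ga",),
}


@dataclass
class SiteColorCard:
    """Raw-scale mean display colors of one genus at one site."""

    site_id: int
    group: str                    # "model" or "mimic"
    taxon: str
    colors: dict[str, tuple[float, float, float]]   # part -> (R, G, B)
    n_specimens: int


def site_color_cards(specimens: pd.DataFrame, registry: SiteRegistry
                     ) -> list[SiteColorCard]:
    """Per-site, per-genus mean raw RGB for head/mesosoma/petiole/gaster."""
    cards = []
    for site in registry.sites:
        sub = specimens[specimens["site_id"] == site]
        if sub.empty:
            warnings.warn(f"site {site}: no records, skipped", stacklevel=2)
            continue
        for group in ("model", "mimic"):
            rows = sub[sub["group"] == group]
            if rows.empty:
                warnings.warn(
                    f"site {site}: no {group} records, skipped", stacklevel=2
                )
                continue
            colors = {}
            for part, sources in _PART_SOURCES.items():
                colors[part] = tuple(
                    float(np.mean([rows[f"{ch}_{s}"].mean()
                                   for s in sources]))
                    for ch in CHANNELS
                )
            taxon = registry.model_taxon(site) if group == "model" \
                else registry.category("mimic", site)
            cards.append(SiteColorCard(
                site_id=site, group=group, taxon=taxon,
                colors=colors, n_specimens=len(rows),
            ))
    return cards


def cards_to_frame(cards: list[SiteColorCard]) -> pd.DataFrame:
    rows = []
    for c in cards:
        rec = {"site_id": c.site_id, "group": c.group, "taxon": c.taxon,
               "n_specimens": c.n_specimens}
        for part in CARD_PARTS:
            for ch, v in zip(CHANNELS, c.colors[part]):
                rec[f"{part}_{ch}"] = v
        rows.append(rec)
    return pd.DataFrame(rows)


def _rgb(color) -> str:
    r, g, b = (int(round(v)) for v in color)
    return f"rgb({r},{g},{b})"


def _ant_glyph(x: float, y: float, card: SiteColorCard) -> str:
    """One schematic ant: head circle, mesosoma box, petiole dot, gaster
    (triangle = model, circle = mimic)."""
    c = card.colors
    parts = [
        f'<circle cx="{x + 15}" cy="{y + 12}" r="9" '
        f'fill="{_rgb(c["head"])}" stroke="black"/>',
        f'<rect x="{x + 8}" y="{y + 23}" width="14" height="22" '
        f'fill="{_rgb(c["mesosoma"])}" stroke="black"/>',
        f'<circle cx="{x + 15}" cy="{y + 49}" r="4" '
        f'fill="{_rgb(c["petiole"])}" stroke="black"/>',
    ]
    if card.group == "model":
        parts.append(
            f'<polygon points="{x + 15},{y + 72} {x + 4},{y + 55} '
            f'{x + 26},{y + 55}" '
            f'fill="{_rgb(c["gaster"])}" stroke="black"/>'
        )
    else:
        parts.append(
            f'<circle cx="{x + 15}" cy="{y + 63}" r="10" '
            f'fill="{_rgb(c["gaster"])}" stroke="black"/>'
        )
    return "\n".join(parts)


def cards_to_svg(cards: list[SiteColorCard]) -> str:
    """A site-indexed strip of model/mimic glyph pairs (SVG text)."""
    sites = sorted({c.site_id for c in cards})
    col_w, height = 80, 110
    width = max(col_w * len(sites), col_w)
    out = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}">',
        '<rect width="100%" height="100%" fill="white"/>',
    ]
    by_key = {(c.site_id, c.group): c for c in cards}
    for i, site in enumerate(sites):
        x0 = i * col_w
        out.append(
            f'<text x="{x0 + 35}" y="14" font-size="12" '
            f'text-anchor="middle">site {site}</text>'
        )
        for j, group in enumerate(("model", "mimic")):
            card = by_key.get((site, group))
            if card is not None:
                out.append(_ant_glyph(x0 + 5 + j * 35, 22, card))
    out.append("</svg>")
    return "\n".join(out)


@dataclass
class ConfidenceEllipse:
    """95% Gaussian confidence ellipse of a 2-D point cloud."""

    center: np.ndarray            # (2,)
    width: float                  # full axis length, major
    height: float                 # full axis length, minor
    angle_deg: float              # major-axis angle, counter-clockwise

    def contains(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float) - self.center
        theta = np.deg2rad(self.angle_deg)
        rot = np.array([[np.cos(theta), np.sin(theta)],
                        [-np.sin(theta), np.cos(theta)]])
        loc = pts @ rot.T
        return ((loc[:, 0] / (self.width / 2)) ** 2
                + (loc[:, 1] / (self.height / 2)) ** 2) <= 1.0


def confidence_ellipse(points, coverage: float = 0.95) -> ConfidenceEllipse:
    """Ellipse from the 2×2 sample covariance scaled by the χ²₂ quantile."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least three points for an ellipse")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = stats.chi2.ppf(coverage, df=2)
    width, height = 2.0 * np.sqrt(np.clip(eigvals, 0, None) * scale)
    angle = float(np.degrees(np.arctan2(eigvecs[1, 0], eigvecs[0, 0])))
    return ConfidenceEllipse(center=center, width=float(width),
                             height=float(height), angle_deg=angle)


def pca_scatter(scores, labels, coverage: float = 0.95
                ) -> tuple[pd.DataFrame, dict[str, ConfidenceEllipse]]:
    """Plot-ready score table plus per-group 95% confidence ellipses.

    ``scores`` is (n, ≥2); only the first two components are plotted.
    Groups with fewer than three points get no ellipse (warning).
    """
    scores = np.asarray(scores, dtype=float)[:, :2]
    labels = np.asarray(labels, dtype=object)
    table = pd.DataFrame(
        {"PC1": scores[:, 0], "PC2": scores[:, 1], "group": labels}
    )
    ellipses = {}
    for g in pd.unique(labels):
        pts = scores[labels == g]
        if pts.shape[0] < 3:
            warnings.warn(f"group {g!r}: <3 points, no ellipse",
                          stacklevel=2)
            continue
        ellipses[str(g)] = confidence_ellipse(pts, coverage=coverage)
    return table, ellipses


def summary_table(specimens: pd.DataFrame, value_columns) -> pd.DataFrame:
    """Means ± sample SD of the given columns per species/category.

    One row per (group, category) with ``<col>_mean`` / ``<col>_sd``
    columns and n; SD uses the n−1 convention (SD 0 for single rows).
    """
    rows = []
    for (group, category), sub in specimens.groupby(["group", "category"]):
        rec = {"group": group, "category": category, "n": len(sub)}
        for col in value_columns:
            vals = sub[col].to_numpy(dtype=float)
            rec[f"{col}_mean"] = float(vals.mean())
            rec[f"{col}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 \
                else 0.0
        rows.append(rec)
    return pd.DataFrame(rows)
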