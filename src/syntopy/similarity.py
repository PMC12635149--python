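"""Syntopic vs. allotopic model–mimic similarity.

The mimicry statistic: for every collection site, compare how close the
local mimic nests are to their *syntopic* model nests versus to model
nests from the 17 *foreign* sites.  Color distances are Euclidean
distances between nest means in a pooled principal-component space
(components retained until ≥80% cumulative variance); size differences
are absolute differences of nest-mean cephalic size in µm.  Site-level
syntopic and allotopic values are paired and tested one-sided (syntopic
smaller) with a paired t-test.

The allotopic value of a site is the unweighted mean of the 17 per-
foreign-site means — not a pooled mean over all foreign nest pairs — so
sites contribute equally regardless of how many nests they hold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .schema import SQRT_COLOR_COLUMNS, SiteRegistry, nest_means
from .transforms import reduce_cumulative


class SimilarityError(ValueError):
    """Structural problem in the distance computation (missing genus, …)."""


def euclidean_distance(a, b) -> float:
    """Plain Euclidean distance √Σ(aᵢ−bᵢ)² between equal-length vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise SimilarityError(
            f"length mismatch: {a.shape} vs {b.shape}"
        )
    return float(np.linalg.norm(a - b))


def paired_one_sided_t(syntopic, allotopic) -> tuple[float, int, float]:
    """Paired t-test of H1: mean(syntopic − allotopic) < 0.

    Returns ``(t, df, p)`` with df = n − 1.  Values are paired by site.
    """
    syn = np.asarray(syntopic, dtype=float)
    allo = np.asarray(allotopic, dtype=float)
    if syn.shape != allo.shape:
        raise SimilarityError("syntopic/allotopic length mismatch")
    n = syn.size
    if n < 2:
        raise SimilarityError("need at least two paired sites")
    d = syn - allo
    if np.allclose(d, d[0]) and np.isclose(np.std(d, ddof=1), 0.0):
        if np.allclose(d, 0.0):
            # all pairs identical: t = 0, one-sided p = 0.5 by convention
            return 0.0, n - 1, 0.5
        raise SimilarityError("zero variance of paired differences")
    res = stats.ttest_rel(syn, allo, alternative="less")
    return float(res.statistic), n - 1, float(res.pvalue)


@dataclass
class DistanceSummary:
    """Per-site syntopic/allotopic means plus the global paired test."""

    per_site: pd.DataFrame        # site_id, syntopic, allotopic, difference
    syntopic_mean: float
    syntopic_sd: float
    allotopic_mean: float
    allotopic_sd: float
    t: float
    df: int
    p: float
    metric: str                   # "color" or "size"

    def to_csv(self, path) -> None:
        self.per_site.to_csv(path, index=False)


def _pairwise_mean(mimic_rows: np.ndarray, model_rows: np.ndarray) -> float:
    # mean distance over the full mimic-nest x model-nest cross product
    diff = mimic_rows[:, None, :] - model_rows[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=2)).mean())


def _site_summary(frame: pd.DataFrame, value_columns, metric: str
                  ) -> DistanceSummary:
    sites = sorted(frame["site_id"].unique())
    by_site: dict[int, dict[str, np.ndarray]] = {}
    for site in sites:
        sub = frame[frame["site_id"] == site]
        groups = {}
        for g in ("mimic", "model"):
            rows = sub[sub["group"] == g]
            if rows.empty:
                raise SimilarityError(f"site {site} has no {g} nests")
            groups[g] = rows[list(value_columns)].to_numpy(dtype=float)
        by_site[site] = groups
    records = []
    for site in sites:
        mimic = by_site[site]["mimic"]
        syn = _pairwise_mean(mimic, by_site[site]["model"])
        foreign = [
            _pairwise_mean(mimic, by_site[other]["model"])
            for other in sites if other != site
        ]
        allo = float(np.mean(foreign))
        records.append({
            "site_id": site, "syntopic": syn, "allotopic": allo,
            "difference": allo - syn,
        })
    per_site = pd.DataFrame(records)
    syn_vals = per_site["syntopic"].to_numpy()
    allo_vals = per_site["allotopic"].to_numpy()
    t, df, p = paired_one_sided_t(syn_vals, allo_vals)
    return DistanceSummary(
        per_site=per_site,
        syntopic_mean=float(syn_vals.mean()),
        syntopic_sd=float(syn_vals.std(ddof=1)),
        allotopic_mean=float(allo_vals.mean()),
        allotopic_sd=float(allo_vals.std(ddof=1)),
        t=t, df=df, p=p, metric=metric,
    )


def site_distance_table(nest_scores: pd.DataFrame,
                        score_columns) -> DistanceSummary:
    """Color-distance summary from reduced nest-mean PC scores.

    ``nest_scores`` must carry ``site_id``, ``group`` and the score
    columns (from :func:`syntopy.transforms.reduce_cumulative` on pooled
    nest means); every site needs nests of both genera.
    """
    return _site_summary(nest_scores, score_columns, metric="color")


def size_difference_table(nests: pd.DataFrame) -> DistanceSummary:
    """|ΔCS| (µm) summary between mimic and model nest means, aggregated
    exactly like the color distances."""
    return _site_summary(nests, ["CS"], metric="size")


def color_similarity(specimens: pd.DataFrame,
                     registry: SiteRegistry | None = None,
                     threshold: float = 0.8
                     ) -> tuple[DistanceSummary, DistanceSummary]:
    """Full similarity pipeline from a validated specimen table.

    Computes nest means (sqrt-channel scale), reduces the pooled 18-
    variable nest-mean matrix to the leading components reaching the
    cumulative-variance ``threshold``, and returns the color and size
    :class:`DistanceSummary` pair.
    """
    nests = nest_means(specimens)
    scores, model = reduce_cumulative(
        nests[list(SQRT_COLOR_COLUMNS)].to_numpy(dtype=float),
        threshold=threshold,
        variables=list(SQRT_COLOR_COLUMNS),
    )
    score_cols = [f"PC{i + 1}" for i in range(model.k)]
    frame = nests[["site_id", "group", "nest_id", "CS"]].copy()
    frame[score_cols] = scores
    color = site_distance_table(frame, score_cols)
    size = size_difference_table(frame)
    return color, size
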