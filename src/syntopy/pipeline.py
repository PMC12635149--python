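"""High-level drivers wiring the analysis stages together.

Mirrors the three research questions: (1) per-body-part PC1 and size
comparisons under the nested mixed model, (2) syntopic vs. allotopic
nest-mean distances, (3) stepwise LDA calibration on the model species
with wild-card allocation of the mimics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import discriminant, mixed_model, reporting, similarity
from .schema import (
    BODY_PARTS,
    CHANNELS,
    COLOR_COLUMNS,
    SQRT_COLOR_COLUMNS,
    SiteRegistry,
)
from .transforms import pc1_scores, sqrt_transform


def sqrt_channels(specimens: pd.DataFrame) -> pd.DataFrame:
    """Append sqrt-scale channel columns (sqrtR_he … sqrtB_ga)."""
    out = specimens.copy()
    for raw, sq in zip(COLOR_COLUMNS, SQRT_COLOR_COLUMNS):
        out[sq] = sqrt_transform(out[raw].to_numpy(dtype=float))
    return out


def body_part_pc1(specimens: pd.DataFrame
                  ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-specimen PC1 of each body part's three sqrt channels.

    Models and mimics are pooled into one PCA per body part (both genera
    share each PC1 axis).  Returns the table with ``PC1_<part>`` columns
    appended and a dict of PC1 explained-variance fractions per part.
    """
    work = sqrt_channels(specimens)
    explained: dict[str, float] = {}
    for part in BODY_PARTS:
        cols = [f"sqrt{ch}_{part}" for ch in CHANNELS]
        scores, frac = pc1_scores(work[cols].to_numpy(dtype=float))
        work[f"PC1_{part}"] = scores
        explained[part] = frac
    return work, explained


def run_traits(specimens: pd.DataFrame, alpha: float = 0.05
               ) -> tuple[pd.DataFrame, dict[str, float]]:
    """RQ1: nested-LMM contrasts of the six PC1 traits and CS."""
    n_model = specimens.loc[specimens["group"] == "model",
                            "category"].nunique()
    n_mimic = specimens.loc[specimens["group"] == "mimic",
                            "category"].nunique()
    if max(n_model, n_mimic) < 3:
        raise ValueError(
            "need 3 groups within a genus for the pairwise-letter display"
        )
    with_pc1, explained = body_part_pc1(specimens)
    traits = [f"PC1_{p}" for p in BODY_PARTS] + ["CS"]
    table = mixed_model.trait_comparison_table(with_pc1, traits, alpha=alpha)
    return table, explained


def run_distances(specimens: pd.DataFrame, threshold: float = 0.8
                  ) -> tuple[similarity.DistanceSummary,
                             similarity.DistanceSummary]:
    """RQ2: syntopic/allotopic color and size summaries."""
    return similarity.color_similarity(specimens, threshold=threshold)


def run_lda(specimens: pd.DataFrame, registry: SiteRegistry,
            f_enter: float = discriminant.F_ENTER_DEFAULT,
            f_remove: float = discriminant.F_REMOVE_DEFAULT,
            priors=None) -> dict:
    """RQ3: stepwise selection, LOO confusion, wild-card allocation.

    Returns a dict with the selected variables, stepwise trace, fitted
    model, LOO confusion (percent), and the allocation table.
    """
    work = sqrt_channels(specimens)
    models = work[work["group"] == "model"]
    mimics = work[work["group"] == "mimic"]
    X_cal = models[list(SQRT_COLOR_COLUMNS)].to_numpy(dtype=float)
    y_cal = models["taxon"].to_numpy(dtype=object)
    selected, trace = discriminant.stepwise_select(
        X_cal, y_cal, variables=list(SQRT_COLOR_COLUMNS),
        f_enter=f_enter, f_remove=f_remove,
    )
    idx = [list(SQRT_COLOR_COLUMNS).index(v) for v in selected]
    model = discriminant.fit_lda(X_cal[:, idx], y_cal, variables=selected,
                                 priors=priors)
    confusion = discriminant.loo_confusion(X_cal[:, idx], y_cal,
                                           variables=selected, priors=priors)
    allocation = discriminant.wildcard_allocate(
        model, mimics[selected].to_numpy(dtype=float),
        mimics["site_id"].to_numpy(), registry,
    )
    return {
        "selected": selected,
        "trace": trace,
        "model": model,
        "confusion": confusion,
        "allocation": allocation,
        "mimic_scores": mimics,
    }


def run_report(specimens: pd.DataFrame, registry: SiteRegistry) -> dict:
    """Descriptive outputs: color cards (+SVG) and the S1-style summary."""
    cards = reporting.site_color_cards(specimens, registry)
    summary = reporting.summary_table(
        specimens, list(COLOR_COLUMNS) + ["CS"]
    )
    return {
        "cards": cards,
        "cards_frame": reporting.cards_to_frame(cards),
        "svg": reporting.cards_to_svg(cards),
        "summary": summary,
    }
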