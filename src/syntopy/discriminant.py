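"""Stepwise linear discriminant analysis with wild-card allocation.

Calibration uses only the model-species specimens (the defended species
are what a predator learns); mimic specimens are then classified as
"wild cards" against that calibration without influencing it.

Variable selection is stepwise Wilks'-lambda minimization with partial-F
entry/removal thresholds (defaults F_enter = 3.84, F_remove = 2.71, the
conventional defaults of the stepwise DA workflow).  Classification uses
Fisher linear classification functions — the Gaussian equal-covariance
Bayes rule with configurable class priors (equal by default).
Cross-validation is leave-one-out with the selected variable set held
fixed; only the class statistics are re-estimated per held-out specimen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import MODEL_TAXA, SiteRegistry

F_ENTER_DEFAULT = 3.84
F_REMOVE_DEFAULT = 2.71


class DiscriminantError(ValueError):
    """Singular covariance or otherwise unusable calibration data."""


def _class_order(labels) -> list:
    """Deterministic class order; model taxa keep their canonical order."""
    uniq = list(pd.unique(np.asarray(labels, dtype=object)))
    if set(uniq) <= set(MODEL_TAXA):
        return [t for t in MODEL_TAXA if t in uniq]
    return sorted(uniq)


def _sscp(X: np.ndarray, y: np.ndarray, classes) -> tuple[np.ndarray,
                                                          np.ndarray]:
    """Within-group and total SSCP matrices."""
    grand = X.mean(axis=0)
    T = (X - grand).T @ (X - grand)
    W = np.zeros_like(T)
    for c in classes:
        sub = X[y == c]
        cen = sub - sub.mean(axis=0)
        W += cen.T @ cen
    return W, T


def wilks_lambda(X, y, columns=None) -> float:
    """Wilks' Λ = |W| / |T| on the given columns (all columns if None).

    Λ near 0 means strong group separation, Λ = 1 none.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    if columns is not None:
        X = X[:, list(columns)]
    classes = _class_order(y)
    W, T = _sscp(X, y, classes)
    detT = np.linalg.det(T)
    if detT <= 0:
        raise DiscriminantError("singular total SSCP")
    return float(np.linalg.det(W) / detT)


def stepwise_select(X, y, variables=None,
                    f_enter: float = F_ENTER_DEFAULT,
                    f_remove: float = F_REMOVE_DEFAULT
                    ) -> tuple[list[str], pd.DataFrame]:
    """Stepwise Wilks'-lambda variable selection.

    At each step the candidate with the smallest resulting Λ (largest
    partial F-to-enter) enters if its F ≥ ``f_enter``; afterwards any
    entered variable whose F-to-remove < ``f_remove`` leaves.  The
    partial F for moving between nested sets with p and p+1 variables is

        F = ((n − g − p) / (g − 1)) · (Λ_p / Λ_{p+1} − 1).

    Returns the selected variable names (entry order) and a trace table
    (step, action, variable, Λ, F).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    n, n_vars = X.shape
    if variables is None:
        variables = [f"x{i + 1}" for i in range(n_vars)]
    classes = _class_order(y)
    g = len(classes)
    if g < 2:
        raise DiscriminantError("need at least two classes")

    def lam(cols):
        if not cols:
            return 1.0
        try:
            return wilks_lambda(X, y, cols)
        except DiscriminantError:
            return None

    selected: list[int] = []
    trace: list[dict] = []
    step = 0
    while True:
        p = len(selected)
        lam_p = lam(selected)
        # --- entry ---
        best = None
        for j in range(n_vars):
            if j in selected:
                continue
            lam_new = lam(selected + [j])
            if lam_new is None or lam_new <= 0 or lam_new >= lam_p:
                if lam_new is None:
                    warnings.warn(
                        f"variable {variables[j]} skipped: singular SSCP",
                        stacklevel=2,
                    )
                continue
            F = ((n - g - p) / (g - 1)) * (lam_p / lam_new - 1.0)
            if best is None or lam_new < best[1]:
                best = (j, lam_new, F)
        changed = False
        if best is not None and best[2] >= f_enter and n - g - p > 0:
            selected.append(best[0])
            step += 1
            trace.append({"step": step, "action": "enter",
                          "variable": variables[best[0]],
                          "wilks_lambda": best[1], "F": best[2]})
            changed = True
        # --- removal ---
        removed = True
        while removed and len(selected) > 1:
            removed = False
            p = len(selected)
            lam_p = lam(selected)
            worst = None
            for j in selected:
                reduced = [k for k in selected if k != j]
                lam_red = lam(reduced)
                if lam_red is None:
                    continue
                F = ((n - g - p + 1) / (g - 1)) * (lam_red / lam_p - 1.0)
                if worst is None or F < worst[1]:
                    worst = (j, F, lam_red)
            if worst is not None and worst[1] < f_remove:
                selected.remove(worst[0])
                step += 1
                trace.append({"step": step, "action": "remove",
                              "variable": variables[worst[0]],
                              "wilks_lambda": worst[2], "F": worst[1]})
                changed = True
                removed = True
        if not changed:
            break
    names = [variables[j] for j in selected]
    return names, pd.DataFrame(
        trace, columns=["step", "action", "variable", "wilks_lambda", "F"]
    )


@dataclass
class DiscriminantModel:
    """Fisher linear classification functions on a fixed variable set."""

    variables: list[str]
    classes: list
    class_means: np.ndarray       # (g, p)
    pooled_cov: np.ndarray        # (p, p), within-class, ddof = n - g
    priors: np.ndarray            # (g,), sums to 1
    coef: np.ndarray              # (g, p): Σ⁻¹ μ_k
    intercept: np.ndarray         # (g,): −½ μΣ⁻¹μ + ln π

    def scores(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.coef.T + self.intercept

    def predict(self, X) -> np.ndarray:
        """Argmax class score; ties broken by class order."""
        idx = np.argmax(self.scores(X), axis=1)
        return np.asarray(self.classes, dtype=object)[idx]


def fit_lda(X, y, variables=None, priors=None) -> DiscriminantModel:
    """Fit linear classification functions from class means and the
    pooled within-class covariance; priors equal unless given."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    classes = _class_order(y)
    g = len(classes)
    n, p = X.shape
    if variables is None:
        variables = [f"x{i + 1}" for i in range(p)]
    if priors is None:
        priors = np.full(g, 1.0 / g)
    priors = np.asarray(priors, dtype=float)
    if not np.isclose(priors.sum(), 1.0):
        raise DiscriminantError("priors must sum to 1")
    means = np.vstack([X[y == c].mean(axis=0) for c in classes])
    W, _ = _sscp(X, y, classes)
    pooled = W / (n - g)
    try:
        inv = np.linalg.inv(pooled)
    except np.linalg.LinAlgError:
        raise DiscriminantError(
            "singular pooled covariance: reduce the variable set"
        ) from None
    coef = means @ inv
    intercept = -0.5 * np.einsum("ij,ij->i", coef, means) + np.log(priors)
    return DiscriminantModel(
        variables=list(variables), classes=classes, class_means=means,
        pooled_cov=pooled, priors=priors, coef=coef, intercept=intercept,
    )


def loo_confusion(X, y, variables=None, priors=None) -> pd.DataFrame:
    """Leave-one-out confusion matrix (row-normalized percentages).

    The variable set is held fixed; per held-out specimen only the class
    means and pooled covariance are re-estimated.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    classes = _class_order(y)
    for c in classes:
        if (y == c).sum() < 3:
            raise DiscriminantError(
                f"class {c!r} too small for leave-one-out"
            )
    counts = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    mask = np.ones(len(y), dtype=bool)
    for i in range(len(y)):
        mask[i] = False
        model = fit_lda(X[mask], y[mask], variables=variables, priors=priors)
        pred = model.predict(X[i][None, :])[0]
        counts.loc[y[i], pred] += 1
        mask[i] = True
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    pct.index.name = "true_class"
    return pct


def wildcard_allocate(model: DiscriminantModel, X_mimic, sites,
                      registry: SiteRegistry) -> pd.DataFrame:
    """Allocate mimic specimens to model species; tabulate percentages.

    Rows: each site, then one total row per mimic category
    (``all <taxon> sites``); columns: n, one percentage column per model
    class, ``correct_pct`` (allocation to the syntopic model) and the
    syntopic model taxon.  Percentages are row-normalized to 100.
    """
    X_mimic = np.asarray(X_mimic, dtype=float)
    sites = np.asarray(sites, dtype=int)
    pred = model.predict(X_mimic)
    rows = []

    def _row(label, syntopic, mask):
        n = int(mask.sum())
        rec = {"row": label, "syntopic_model": syntopic, "n": n}
        for c in model.classes:
            rec[f"{c}_pct"] = float((pred[mask] == c).sum()) / n * 100.0
        rec["correct_pct"] = rec[f"{syntopic}_pct"]
        return rec

    for site in sorted(np.unique(sites)):
        syn = registry.model_taxon(int(site))
        rows.append(_row(f"site {site}", syn, sites == site))
    for taxon in [t for t in model.classes
                  if t in set(registry.site_model.values())]:
        taxon_sites = [s for s, t in registry.site_model.items()
                       if t == taxon]
        mask = np.isin(sites, taxon_sites)
        if mask.any():
            rows.append(_row(f"all {taxon} sites", taxon, mask))
    return pd.DataFrame(rows)
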