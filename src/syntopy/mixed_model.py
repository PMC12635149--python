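"""Nested-random-effects comparisons of group trait means.

Each per-specimen trait (a body-part color PC1, or cephalic size) is
modelled as

    y = μ + β_group + u_site + v_nest(site) + ε,

a Gaussian linear mixed model with the group (model species or mimic
category) as fixed effect and random intercepts for site and for nest
nested within site, fitted by REML.  Pairwise group differences are
tested with Wald z statistics on the fixed-effect contrasts (an
approximation; no small-sample degrees-of-freedom correction), and the
family of pairwise p-values is controlled at a global α with the
Holm step-down procedure.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM


class FitError(RuntimeError):
    """The REML optimization failed to converge."""


@dataclass
class LMMFit:
    """REML fit of the nested two-level Gaussian mixed model."""

    groups: list[str]
    beta: np.ndarray                 # fixed-effect group means
    cov_beta: np.ndarray             # REML covariance of beta
    sigma2_site: float
    sigma2_nest: float
    sigma2_resid: float
    loglike: float                   # restricted log-likelihood
    n_obs: int
    n_sites: int
    n_nests: int
    converged: bool

    def group_mean(self, group: str) -> float:
        return float(self.beta[self.groups.index(group)])


def fit_lmm(trait, groups, sites, nests) -> LMMFit:
    """Fit the nested mixed model for one trait.

    Parameters are parallel per-specimen sequences: trait values, group
    labels, site ids, and nest ids (nests must be unique within site; a
    composite id is formed internally so reused nest labels across sites
    stay nested).
    """
    df = pd.DataFrame({
        "y": np.asarray(trait, dtype=float),
        "group": np.asarray(groups, dtype=object),
        "site": np.asarray(sites, dtype=object).astype(str),
        "nest": np.asarray(nests, dtype=object).astype(str),
    })
    if df["y"].isna().any():
        raise ValueError("trait contains missing values")
    levels = sorted(df["group"].unique())
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    df["nest"] = df["site"] + "/" + df["nest"]
    n_sites = df["site"].nunique()
    n_nests = df["nest"].nunique()
    if n_nests == n_sites:
        warnings.warn(
            "one nest per site: site and nest variance are confounded",
            stacklevel=2,
        )
    model = MixedLM.from_formula(
        "y ~ 0 + C(group)",
        groups="site",
        re_formula="1",
        vc_formula={"nest": "0 + C(nest)"},
        data=df,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=True, method=["lbfgs", "powell"])
    if not result.converged:
        raise FitError(
            "REML did not converge "
            f"(n={len(df)}, sites={n_sites}, nests={n_nests})"
        )
    k = len(levels)
    beta = np.asarray(result.fe_params, dtype=float)
    cov_beta = np.asarray(result.cov_params())[:k, :k]
    return LMMFit(
        groups=levels,
        beta=beta,
        cov_beta=cov_beta,
        sigma2_site=max(float(result.cov_re.iloc[0, 0]), 0.0),
        sigma2_nest=max(float(result.vcomp[0]), 0.0),
        sigma2_resid=float(result.scale),
        loglike=float(result.llf),
        n_obs=len(df),
        n_sites=n_sites,
        n_nests=n_nests,
        converged=bool(result.converged),
    )


def holm_correct(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Holm step-down decisions, mapped back to input order.

    Sort p ascending and reject while p_(i) ≤ α/(m − i + 1); the first
    non-rejection stops the procedure.  Controls family-wise error at α.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


def pairwise_contrasts(fit: LMMFit, pairs=None,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Wald z tests of all (or given) pairwise fixed-effect differences.

    Returns one row per pair with estimate, SE, z, two-sided p and the
    Holm decision at the global α.
    """
    if pairs is None:
        pairs = list(itertools.combinations(fit.groups, 2))
    rows = []
    for a, b in pairs:
        if a not in fit.groups or b not in fit.groups:
            raise ValueError(f"pair ({a}, {b}) not among fitted groups")
        i, j = fit.groups.index(a), fit.groups.index(b)
        est = fit.beta[i] - fit.beta[j]
        var = fit.cov_beta[i, i] + fit.cov_beta[j, j] - 2 * fit.cov_beta[i, j]
        se = float(np.sqrt(max(var, 0.0)))
        if se == 0.0:
            z, p = 0.0, 1.0
        else:
            z = float(est / se)
            p = float(2.0 * stats.norm.sf(abs(z)))
        rows.append({"group_a": a, "group_b": b, "estimate": float(est),
                     "se": se, "z": z, "p": p})
    out = pd.DataFrame(rows)
    out["holm_reject"] = holm_correct(out["p"].to_numpy(), alpha=alpha)
    return out


def significance_letters(groups: list[str],
                         contrasts: pd.DataFrame) -> dict[str, str]:
    """Compact letter display from Holm decisions (insert-and-absorb).

    Groups sharing a letter are not significantly different.
    """
    sig = {
        frozenset((r.group_a, r.group_b))
        for r in contrasts.itertuples() if r.holm_reject
    }
    sets: list[set[str]] = [set(groups)]
    for pair in sig:
        a, b = tuple(pair)
        for s in [s for s in sets if a in s and b in s]:
            sets.remove(s)
            for drop in (a, b):
                cand = s - {drop}
                if cand and not any(cand <= o for o in sets):
                    sets.append(cand)
    sets.sort(key=lambda s: sorted(groups.index(g) for g in s))
    letters = {g: "" for g in groups}
    for i, s in enumerate(sets):
        for g in sorted(s, key=groups.index):
            letters[g] += chr(ord("a") + i)
    return letters


def trait_comparison_table(specimens: pd.DataFrame, trait_columns,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Fit the nested model per trait and genus; tabulate all contrasts.

    Models (species) and mimics (categories) are compared within genus,
    mirroring the two letter families of the boxplot figures.  Returns a
    long table: trait × genus × pair × estimate × p × Holm decision.
    """
    rows = []
    for genus_group in ("model", "mimic"):
        sub = specimens[specimens["group"] == genus_group]
        if sub.empty:
            continue
        for trait in trait_columns:
            fit = fit_lmm(sub[trait], sub["category"],
                          sub["site_id"], sub["nest_id"])
            con = pairwise_contrasts(fit, alpha=alpha)
            con.insert(0, "trait", trait)
            con.insert(1, "genus_group", genus_group)
            rows.append(con)
    return pd.concat(rows, ignore_index=True)
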