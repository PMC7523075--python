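"""Iterative-subsampling alpha diversity, response transforms, and ANOVA.

Diversity is estimated by repeatedly subsampling every sample to a common
depth (default 1500 reads, 1000 iterations) and averaging three estimators
over the draws: observed richness ``S_obs``, the complement of Simpson's
diversity ``1 - D``, and Simpson's evenness ``E_D = (1/D)/S_obs``. The
bias-corrected Simpson estimator ``D = sum n_i(n_i - 1) / (N(N - 1))`` is
used throughout.

Estimates are variance-stabilized before linear modelling: logit for the
two proportion-scale estimators, Box-Cox (fixed per-compartment lambda by
default) for richness.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .tables import OtuTable, eligible_samples

__all__ = [
    "iterative_alpha",
    "TransformSpec",
    "transform_response",
    "factorial_anova",
    "tukey_hsd",
    "BOXCOX_LAMBDA_BY_COMPARTMENT",
]

# fixed Box-Cox exponents for richness, per compartment
BOXCOX_LAMBDA_BY_COMPARTMENT = {
    "rhizosphere": 1.6,
    "root": 0.0,
    "leaf": -0.2,
    "nodule": -0.2,
}


def iterative_alpha(
    table: OtuTable,
    depth: int = 1500,
    iterations: int = 1000,
    seed: int | None = None,
    chunk: int = 200,
) -> pd.DataFrame:
    """Average alpha-diversity estimators over repeated subsampling draws.

    Returns one row per eligible sample (total count >= ``depth``; others are
    excluded with a warning) with columns ``s_obs``, ``simpson_complement``,
    ``simpson_evenness``, ``n_iterations``, ``depth``.
    """
    if depth < 2:
        raise ValueError("depth must be >= 2 for the Simpson estimator")
    keep = eligible_samples(table, depth)
    rng = np.random.default_rng(seed)
    nn1 = depth * (depth - 1)
    rows = {}
    for sid in keep:
        col = table.counts[sid].to_numpy()
        s_obs = np.empty(iterations)
        comp = np.empty(iterations)
        even = np.empty(iterations)
        done = 0
        while done < iterations:
            m = min(chunk, iterations - done)
            draws = rng.multivariate_hypergeometric(col, depth, size=m)
            s = (draws > 0).sum(axis=1)
            d_hat = (draws * (draws - 1)).sum(axis=1) / nn1
            s_obs[done : done + m] = s
            comp[done : done + m] = 1.0 - d_hat
            with np.errstate(divide="ignore"):
                even[done : done + m] = np.where(
                    d_hat > 0, 1.0 / (d_hat * s), np.nan
                )
            done += m
        if np.isnan(even).any():
            warnings.warn(
                f"sample {sid}: {int(np.isnan(even).sum())} draw(s) with D=0 "
                "skipped for evenness",
                stacklevel=2,
            )
        rows[sid] = {
            "s_obs": s_obs.mean(),
            "simpson_complement": comp.mean(),
            "simpson_evenness": np.nanmean(even),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out["n_iterations"] = iterations
    out["depth"] = depth
    out.index.name = "sample_id"
    return out


@dataclass(frozen=True)
class TransformSpec:
    """Response transform: ``kind`` in {"logit", "box-cox"}; ``lam`` is the
    Box-Cox exponent (ignored for logit)."""

    kind: str
    lam: float = 0.0


def transform_response(
    values, spec: TransformSpec, clamp_eps: float | None = None
) -> np.ndarray:
    """Apply a logit or Box-Cox transform to a response vector.

    logit(p) = ln(p/(1-p)); values of exactly 0 or 1 are clamped to
    [eps, 1-eps] with a warning when ``clamp_eps`` is given, and rejected
    otherwise. box-cox(x, lam) = (x^lam - 1)/lam, or ln x at lam = 0;
    requires strictly positive input.
    """
    x = np.asarray(values, dtype=float)
    if spec.kind == "logit":
        if clamp_eps is not None:
            bad = (x <= 0) | (x >= 1)
            if bad.any():
                warnings.warn(
                    f"clamping {int(bad.sum())} logit input(s) to "
                    f"[{clamp_eps}, {1 - clamp_eps}]",
                    stacklevel=2,
                )
                x = np.clip(x, clamp_eps, 1 - clamp_eps)
        if ((x <= 0) | (x >= 1)).any():
            off = x[(x <= 0) | (x >= 1)][0]
            raise ValueError(f"logit input {off} outside (0, 1)")
        return scipy.special.logit(x)
    if spec.kind == "box-cox":
        if (x <= 0).any():
            off = x[x <= 0][0]
            raise ValueError(f"box-cox input {off} is not strictly positive")
        return scipy.stats.boxcox(x, lmbda=spec.lam)
    raise ValueError(f"unknown transform kind {spec.kind!r}")


def estimate_boxcox_lambda(values) -> float:
    """Profile-MLE Box-Cox exponent for new data sets."""
    x = np.asarray(values, dtype=float)
    if (x <= 0).any():
        raise ValueError("box-cox input must be strictly positive")
    _, lam = scipy.stats.boxcox(x)
    return float(lam)


def _check_balance(factors: pd.DataFrame, tol_ratio: float) -> None:
    cell_sizes = factors.groupby(list(factors.columns), observed=True).size()
    if cell_sizes.min() == 0:
        raise ValueError("empty design cell; factorial ANOVA requires all cells")
    ratio = cell_sizes.max() / cell_sizes.min()
    if ratio > tol_ratio:
        raise ValueError(
            f"design unbalanced beyond tolerance (max/min cell size {ratio:.2f} "
            f"> {tol_ratio}); sequential sums of squares would be order-dependent"
        )
    if cell_sizes.max() != cell_sizes.min():
        warnings.warn(
            "mildly unbalanced design: sequential (Type I) sums of squares "
            "depend on term order",
            stacklevel=3,
        )


def factorial_anova(
    response,
    factors: pd.DataFrame,
    terms: list[str] | None = None,
    balance_tol_ratio: float = 2.0,
) -> pd.DataFrame:
    """Fixed-effects factorial ANOVA (sequential sums of squares).

    ``factors`` holds one categorical column per factor; ``terms`` lists the
    model terms as factor names joined by ``:`` (default: the full factorial
    expansion of all columns). Returns the ANOVA table with one row per term
    plus a Residual row (columns sum_sq, df, F, p).
    """
    y = np.asarray(response, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant response: no variance to partition")
    factors = factors.reset_index(drop=True)
    for col in factors.columns:
        if factors[col].nunique() < 2:
            raise ValueError(f"factor {col!r} has fewer than 2 levels")
    _check_balance(factors, balance_tol_ratio)
    if terms is None:
        cols = list(factors.columns)
        terms = [
            ":".join(c)
            for r in range(1, len(cols) + 1)
            for c in itertools.combinations(cols, r)
        ]
    data = factors.copy()
    data["_y"] = y
    rhs = " + ".join(
        ":".join(f"C({f})" for f in term.split(":")) for term in terms
    )
    model = smf.ols(f"_y ~ {rhs}", data=data).fit()
    if model.df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    tab = sm.stats.anova_lm(model, typ=1)
    rename = {
        ":".join(f"C({f})" for f in term.split(":")): term for term in terms
    }
    tab = tab.rename(
        index=rename, columns={"PR(>F)": "p", "mean_sq": "mean_sq"}
    )
    return tab[["sum_sq", "df", "F", "p"]]


def tukey_hsd(
    response, group, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict[str, str]]:
    """All-pairs Tukey HSD with a compact letter display.

    Returns ``(pairwise, letters)``: a tidy table of pairwise comparisons and
    a compact letter display where groups sharing any letter are not
    significantly different at ``alpha``.
    """
    y = np.asarray(response, dtype=float)
    g = pd.Series(group).reset_index(drop=True)
    levels = list(pd.unique(g))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [y[(g == lev).to_numpy()] for lev in levels]
    for lev, arr in zip(levels, arrays):
        if len(arr) < 2:
            raise ValueError(f"group {lev!r} has n < 2")
    res = scipy.stats.tukey_hsd(*arrays)
    rows = []
    for i, j in itertools.combinations(range(len(levels)), 2):
        rows.append(
            {
                "group_a": levels[i],
                "group_b": levels[j],
                "mean_diff": arrays[i].mean() - arrays[j].mean(),
                "p": res.pvalue[i, j],
                "significant": res.pvalue[i, j] < alpha,
            }
        )
    pairwise = pd.DataFrame(rows)
    letters = _compact_letter_display(levels, arrays, res.pvalue, alpha)
    return pairwise, letters


def _compact_letter_display(levels, arrays, pvalue, alpha) -> dict[str, str]:
    """Letters from maximal cliques of the not-significantly-different graph."""
    import networkx as nx

    k = len(levels)
    graph = nx.Graph()
    graph.add_nodes_from(range(k))
    for i, j in itertools.combinations(range(k), 2):
        if pvalue[i, j] >= alpha:
            graph.add_edge(i, j)
    cliques = list(nx.find_cliques(graph))
    # order cliques by descending best group mean for stable letter order
    means = [np.mean(a) for a in arrays]
    cliques.sort(key=lambda c: -max(means[i] for i in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    assigned: dict[int, list[str]] = {i: [] for i in range(k)}
    for letter, clique in zip(alphabet, cliques):
        for i in clique:
            assigned[i].append(letter)
    return {levels[i]: "".join(sorted(assigned[i])) for i in range(k)}
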