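"""Beta diversity: subsampled Bray-Curtis, NMDS, PerMANOVA, and modified PVCA.

The community-composition workflow is:

1. :func:`iterative_bray_curtis` — average pairwise Bray-Curtis dissimilarity
   over repeated subsampling draws at a fixed depth.
2. :func:`nmds` — nonmetric multidimensional scaling (SMACOF majorization
   with monotone/isotonic regression of fitted distances on the observed
   dissimilarities), minimizing Kruskal stress-1 over random restarts.
3. :func:`permanova` — one-way permutational multivariate ANOVA on the
   averaged dissimilarity matrix (Anderson's pseudo-F).
4. :func:`pvca` — the modified principal variance component analysis: each
   of the first ``n_axes`` NMDS axis-score vectors is modelled with an
   all-random-effects variance-component model (REML); per-axis percent
   variance components are combined with per-axis R-squared weights and
   rescaled to total 100%.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .tables import OtuTable, eligible_samples

__all__ = [
    "DissimilarityMatrix",
    "OrdinationResult",
    "PermanovaResult",
    "bray_curtis",
    "iterative_bray_curtis",
    "nmds",
    "axis_r_squared",
    "permanova",
    "axis_score_test",
    "pvca",
    "pvca_from_scores",
    "PVCA_TERMS",
]


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarities in [0, 1] with provenance fields."""

    sample_ids: list
    values: np.ndarray
    n_iterations: int = 1
    depth: int | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be a square matrix")
        if v.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length must match matrix size")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0, atol=1e-10):
            raise ValueError("diagonal must be zero")
        if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError("dissimilarities must lie in [0, 1]")
        self.values = v

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.sample_ids)

    def submatrix(self, sample_ids) -> "DissimilarityMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DissimilarityMatrix(
            list(sample_ids),
            self.values[np.ix_(idx, idx)],
            n_iterations=self.n_iterations,
            depth=self.depth,
        )

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def read_tsv(cls, path) -> "DissimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy())

    def write_phylip(self, path) -> None:
        """Lower-triangle (phylip-style) writer."""
        with open(path, "w") as fh:
            fh.write(f"{self.n_samples}\n")
            for i, sid in enumerate(self.sample_ids):
                vals = "\t".join(f"{self.values[i, j]:.6f}" for j in range(i))
                fh.write(f"{sid}\t{vals}".rstrip() + "\n")

    @classmethod
    def read_phylip(cls, path) -> "DissimilarityMatrix":
        with open(path) as fh:
            n = int(fh.readline())
            ids, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                ids.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        mat = np.zeros((n, n))
        for i, row in enumerate(rows):
            mat[i, : len(row)] = row
        mat = mat + mat.T
        return cls(ids, mat)


def bray_curtis(x, y) -> float:
    """BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(np.abs(x - y).sum() / denom)


def iterative_bray_curtis(
    table: OtuTable,
    depth: int = 1500,
    iterations: int = 1000,
    seed: int | None = None,
    chunk: int = 50,
) -> DissimilarityMatrix:
    """Element-wise mean Bray-Curtis over repeated subsampling draws.

    Every eligible sample (total >= ``depth``) is subsampled to ``depth``
    reads in each iteration; the pairwise matrix is averaged across
    iterations.
    """
    keep = eligible_samples(table, depth)
    if len(keep) < 2:
        raise ValueError("need at least 2 samples with total >= depth")
    cols = [table.counts[s].to_numpy() for s in keep]
    rng = np.random.default_rng(seed)
    n = len(keep)
    acc = np.zeros(n * (n - 1) // 2)
    done = 0
    while done < iterations:
        m = min(chunk, iterations - done)
        draws = np.stack(
            [rng.multivariate_hypergeometric(c, depth, size=m) for c in cols]
        )  # (samples, m, otus)
        for it in range(m):
            acc += pdist(draws[:, it, :], metric="braycurtis")
        done += m
    mat = squareform(acc / iterations)
    return DissimilarityMatrix(keep, mat, n_iterations=iterations, depth=depth)


# -- NMDS ----------------------------------------------------------------

@dataclass
class OrdinationResult:
    """NMDS configuration: coordinates (principal-axis rotated), Kruskal
    stress-1, per-axis R-squared, dimensionality, and convergence flag."""

    coordinates: pd.DataFrame
    stress: float
    axis_r2: np.ndarray
    k: int
    seed: int | None = None
    converged: bool = True
    stress_trace: np.ndarray = field(default=None, repr=False)


def _kruskal_stress(dist: np.ndarray, dhat: np.ndarray) -> float:
    denom = (dist**2).sum()
    if denom == 0:
        return np.inf
    return float(np.sqrt(((dist - dhat) ** 2).sum() / denom))


def _smacof_single(diss, k, max_iter, tol, rng, x0=None):
    n = squareform(diss).shape[0]
    order = np.argsort(diss, kind="stable")
    iso = IsotonicRegression(increasing=True)
    x = x0 if x0 is not None else rng.normal(size=(n, k))
    best_x, best_stress = x, np.inf
    trace = []
    prev = np.inf
    for _ in range(max_iter):
        dist = pdist(x)
        dhat = np.empty_like(dist)
        dhat[order] = iso.fit_transform(np.arange(len(diss)), dist[order])
        np.maximum(dhat, 0, out=dhat)
        stress = _kruskal_stress(dist, dhat)
        if stress > prev + 1e-12:
            break  # majorization no longer improves stress-1; keep best seen
        trace.append(stress)
        if stress < best_stress:
            best_stress, best_x = stress, x
        if prev - stress < tol:
            prev = stress
            break
        prev = stress
        # Guttman transform
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, dhat / dist, 0.0)
        b = -squareform(ratio)
        np.fill_diagonal(b, -b.sum(axis=1))
        x = b @ x / n
    return best_x, best_stress, np.array(trace)


def _classical_mds_start(diss, k):
    d2 = squareform(diss) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    idx = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[idx], 0, None)
    return vecs[:, idx] * np.sqrt(vals)


def nmds(
    d: DissimilarityMatrix,
    k: int = 3,
    restarts: int = 32,
    max_iter: int = 500,
    tol: float = 1e-7,
    seed: int | None = None,
) -> OrdinationResult:
    """Nonmetric MDS minimizing Kruskal stress-1.

    The first start is the classical (metric) MDS configuration; the
    remaining ``restarts - 1`` starts are random. The best configuration is
    centered and rotated to its principal axes, and per-axis R-squared values
    are attached via :func:`axis_r_squared`.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= d.n_samples:
        raise ValueError("k must be smaller than the number of samples")
    diss = d.condensed()
    rng = np.random.default_rng(seed)
    best = (None, np.inf, None)
    for r in range(max(restarts, 1)):
        x0 = _classical_mds_start(diss, k) if r == 0 else None
        x, stress, trace = _smacof_single(diss, k, max_iter, tol, rng, x0=x0)
        if stress < best[1]:
            best = (x, stress, trace)
    x, stress, trace = best
    converged = bool(len(trace) < max_iter)
    if not converged:
        warnings.warn("NMDS did not converge; returning best configuration",
                      stacklevel=2)
    # center and rotate to principal axes
    x = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    coords = pd.DataFrame(
        x, index=d.sample_ids, columns=[f"axis{i + 1}" for i in range(k)]
    )
    result = OrdinationResult(coords, stress, np.zeros(k), k, seed=seed,
                              converged=converged, stress_trace=trace)
    result.axis_r2 = axis_r_squared(d, result)
    return result


def axis_r_squared(d: DissimilarityMatrix, ordination: OrdinationResult) -> np.ndarray:
    """Per-axis share of community variation.

    R-squared of axis *a* is the squared Pearson correlation between the
    observed dissimilarities and the inter-sample distances computed from
    axis *a* alone.
    """
    diss = d.condensed()
    out = np.zeros(ordination.k)
    for a in range(ordination.k):
        axis = ordination.coordinates.iloc[:, a].to_numpy()
        dist_a = pdist(axis[:, None])
        if np.ptp(dist_a) == 0 or np.ptp(diss) == 0:
            warnings.warn(f"axis {a + 1} is constant; R^2 set to 0",
                          stacklevel=2)
            continue
        r, _ = scipy.stats.pearsonr(diss, dist_a)
        out[a] = r * r
    return out


# -- PerMANOVA -----------------------------------------------------------

@dataclass
class PermanovaResult:
    pseudo_F: float
    df_num: int
    df_den: int
    p_value: float
    n_permutations: int
    seed: int | None = None


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """Anderson's pseudo-F from a squared-dissimilarity square matrix."""
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.where(labels == g)[0]
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += np.triu(sub, 1).sum() / len(idx)
    a = len(groups)
    ss_between = ss_total - ss_within
    if ss_within == 0:
        return np.inf
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(
    d: DissimilarityMatrix,
    group,
    permutations: int | str = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PerMANOVA on a dissimilarity matrix.

    ``permutations="exact"`` enumerates every distinct assignment of the
    observed labels to samples (feasible for small n) and reports
    p = #(F_perm >= F_obs) / #assignments; otherwise ``permutations`` random
    relabellings are drawn and p = (b + 1)/(m + 1).
    """
    labels = np.asarray(pd.Series(group))
    if len(labels) != d.n_samples:
        raise ValueError("group length must match number of samples")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if counts.min() == 0:
        raise ValueError("empty group")
    d2 = d.values**2
    f_obs = _pseudo_f(d2, labels)
    a, n = len(uniq), d.n_samples
    if permutations == "exact":
        perms = set(itertools.permutations(labels))
        hits = sum(_pseudo_f(d2, np.array(p)) >= f_obs - 1e-12 for p in perms)
        p_value = hits / len(perms)
        n_perm = len(perms)
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(int(permutations)):
            if _pseudo_f(d2, rng.permutation(labels)) >= f_obs - 1e-12:
                hits += 1
        p_value = (hits + 1) / (int(permutations) + 1)
        n_perm = int(permutations)
    return PermanovaResult(
        pseudo_F=float(f_obs),
        df_num=a - 1,
        df_den=n - a,
        p_value=float(p_value),
        n_permutations=n_perm,
        seed=seed if permutations != "exact" else None,
    )


def axis_score_test(ordination: OrdinationResult, axis: int, group) -> pd.DataFrame:
    """One-way ANOVA of one NMDS axis' loading scores across groups."""
    if not 1 <= axis <= ordination.k:
        raise ValueError(f"axis must be in 1..{ordination.k}")
    from .alpha import factorial_anova

    scores = ordination.coordinates.iloc[:, axis - 1].to_numpy()
    factors = pd.DataFrame({"group": pd.Series(group).to_numpy()})
    return factorial_anova(scores, factors, terms=["group"],
                           balance_tol_ratio=np.inf)


# -- modified PVCA -------------------------------------------------------

PVCA_TERMS = (
    "soil_origin",
    "genotype",
    "compartment",
    "soil_origin:genotype",
    "soil_origin:compartment",
    "genotype:compartment",
    "soil_origin:genotype:compartment",
)


def _term_indicator(design: pd.DataFrame, term: str) -> np.ndarray:
    """n x levels indicator matrix for a (possibly interaction) term."""
    key = design[term.split(":")].astype(str).agg("|".join, axis=1)
    return pd.get_dummies(key).to_numpy(dtype=float)


def _restricted_neg_loglik(theta, gram, y, x):
    """-2 x restricted log-likelihood at log-variances ``theta``.

    V = sum_k exp(theta_k) Z_k Z_k' + exp(theta_resid) I; the last theta is
    the residual. Profile of the REML criterion for an intercept-only mean
    model.
    """
    n = len(y)
    v = np.exp(theta[-1]) * np.eye(n)
    for t, g in zip(theta[:-1], gram):
        v += np.exp(t) * g
    try:
        chol = np.linalg.cholesky(v)
    except np.linalg.LinAlgError:
        return np.inf
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    vinv_yx = scipy.linalg.cho_solve((chol, True), np.column_stack([y, x]))
    vinv_y, vinv_x = vinv_yx[:, 0], vinv_yx[:, 1]
    xtvx = float(x @ vinv_x)
    y_p_y = float(y @ vinv_y) - float(x @ vinv_y) ** 2 / xtvx
    return logdet + np.log(xtvx) + y_p_y


def _axis_variance_components(y, design: pd.DataFrame, terms) -> pd.Series | None:
    """REML variance components of one axis-score vector; None on failure.

    All design terms enter as random effects alongside the residual. The
    restricted log-likelihood is maximized directly over log-variances
    (the unconstrained parametrization enforces non-negativity) from several
    starting points; effectively-zero components come back as ~0.
    """
    from scipy.optimize import minimize

    y = np.asarray(y, dtype=float)
    v0 = y.var(ddof=1)
    if not np.isfinite(v0) or v0 <= 0:
        return None
    ys = (y - y.mean()) / np.sqrt(v0)
    gram = [
        (z := _term_indicator(design, term)) @ z.T for term in terms
    ]
    x = np.ones(len(ys))
    k = len(terms) + 1
    starts = [
        np.full(k, np.log(1.0 / k)),
        np.concatenate([np.full(k - 1, np.log(1e-3)), [0.0]]),
        np.concatenate([np.full(k - 1, np.log(0.3)), [np.log(0.1)]]),
    ]
    best = None
    for t0 in starts:
        res = minimize(
            _restricted_neg_loglik,
            t0,
            args=(gram, ys, x),
            method="L-BFGS-B",
            bounds=[(-25.0, 6.0)] * k,
            options={"maxiter": 500, "ftol": 1e-12},
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        return None
    sigma2 = np.exp(best.x) * v0
    comps = pd.Series(sigma2, index=list(terms) + ["residual"])
    # components at the lower bound are numerically zero
    comps[comps < 1e-8 * v0] = 0.0
    if comps.sum() <= 0:
        return None
    return comps


def pvca_from_scores(
    scores: pd.DataFrame,
    weights,
    design: pd.DataFrame,
    terms=PVCA_TERMS,
) -> pd.Series:
    """Weighted REML variance partitioning of precomputed axis scores.

    ``scores`` has one column per ordination axis; ``weights`` are the
    per-axis community-variation shares (R-squared). Axes whose REML fit
    fails are dropped with a warning and the weights renormalized. The
    returned percentages sum to 100.
    """
    weights = np.asarray(weights, dtype=float)
    if len(weights) != scores.shape[1]:
        raise ValueError("one weight per score column required")
    missing = [c for c in {f.strip() for t in terms for f in t.split(":")}
               if c not in design.columns]
    if missing:
        raise ValueError(f"design lacks required columns: {missing}")
    per_axis = {}
    for a, col in enumerate(scores.columns):
        comps = _axis_variance_components(scores[col].to_numpy(), design, terms)
        if comps is None:
            warnings.warn(f"REML failed on axis {col}; axis dropped",
                          stacklevel=2)
            continue
        per_axis[a] = comps / comps.sum()
    if not per_axis:
        raise ValueError("REML failed on every axis")
    w = np.array([weights[a] for a in per_axis])
    if w.sum() <= 0:
        w = np.ones_like(w)
    w = w / w.sum()
    combined = sum(wi * comps for wi, comps in zip(w, per_axis.values()))
    out = 100.0 * combined / combined.sum()
    out.name = "percent_variance"
    return out


def pvca(
    d: DissimilarityMatrix,
    design: pd.DataFrame,
    n_axes: int = 10,
    k: int | None = None,
    seed: int | None = None,
    terms=PVCA_TERMS,
    restarts: int = 8,
    ordination: OrdinationResult | None = None,
) -> pd.Series:
    """Modified PVCA: NMDS axis scores -> REML variance components -> R²-weighted
    percentages summing to 100.

    ``n_axes`` NMDS axes are extracted (``k`` defaults to ``n_axes``); each
    axis-score vector is partitioned into the design variance components and
    the per-axis percentages are combined with axis R-squared weights.
    """
    k = n_axes if k is None else max(k, n_axes)
    if ordination is None:
        ordination = nmds(d, k=k, restarts=restarts, seed=seed)
    if n_axes > ordination.k:
        raise ValueError("n_axes exceeds the ordination dimensionality")
    design = design.loc[ordination.coordinates.index]
    scores = ordination.coordinates.iloc[:, :n_axes]
    weights = ordination.axis_r2[:n_axes]
    return pvca_from_scores(scores, weights, design, terms=terms)
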