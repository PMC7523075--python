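"""Sparse compositional correlation (SparCC) for OTU co-association networks.

Read counts are compositional: correlations computed directly on relative
abundances are distorted by the unit-sum constraint. SparCC instead works
from the variance of pairwise log-ratios,

    t_ij = Var[ ln(x_i / x_j) ] = w_i^2 + w_j^2 - 2 rho_ij w_i w_j,

where w_i^2 is the variance of the (unobserved) log basis abundance of OTU
i. Under the sparsity assumption that most pairs are uncorrelated, the row
sums of t yield a linear system for the basis variances, from which

    rho_ij = (w_i^2 + w_j^2 - t_ij) / (2 w_i w_j).

Strongly correlated pairs violate the assumption, so the strongest pair
above an exclusion threshold is removed from the system and the solve
repeated for a fixed number of rounds. Estimates are averaged over Dirichlet
posterior draws of the underlying fractions, and significance is assessed by
permuting each OTU's counts across samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import OtuTable

__all__ = [
    "SparccResult",
    "log_ratio_variance",
    "sparcc_correlations",
    "sparcc_pvalues",
    "sparcc_filter",
]


@dataclass
class SparccResult:
    otu_ids: list
    rho: pd.DataFrame
    basis_variances: np.ndarray
    p_values: pd.DataFrame | None
    n_inference_iterations: int
    exclusion_threshold: float
    n_draws: int
    pseudocount: float
    n_permutations: int | None = None
    filter_spec: str = ""

    def edge_list(self, p_threshold: float = 0.05) -> pd.DataFrame:
        """Tidy (otu_a, otu_b, rho, p) rows for pairs with p < threshold."""
        if self.p_values is None:
            raise ValueError("run sparcc_pvalues first")
        rows = []
        ids = self.otu_ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                p = self.p_values.iloc[i, j]
                if p < p_threshold:
                    rows.append(
                        {
                            "otu_a": ids[i],
                            "otu_b": ids[j],
                            "rho": self.rho.iloc[i, j],
                            "p": p,
                        }
                    )
        return pd.DataFrame(rows)


def _as_matrix(counts) -> tuple[np.ndarray, list]:
    if isinstance(counts, OtuTable):
        return counts.counts.to_numpy(dtype=float), counts.otu_ids
    if isinstance(counts, pd.DataFrame):
        return counts.to_numpy(dtype=float), list(counts.index)
    arr = np.asarray(counts, dtype=float)
    return arr, [f"otu{i + 1}" for i in range(arr.shape[0])]


def _fractions(mat, pseudocount, rng=None):
    """Per-sample fractions; posterior Dirichlet draw when ``rng`` given."""
    if rng is None:
        f = mat + pseudocount
        return f / f.sum(axis=0, keepdims=True)
    out = np.empty_like(mat)
    for j in range(mat.shape[1]):
        out[:, j] = rng.dirichlet(mat[:, j] + pseudocount)
    return out


def _t_matrix(fractions) -> np.ndarray:
    logf = np.log(fractions)
    v = logf.var(axis=1, ddof=1)
    c = np.cov(logf)
    t = v[:, None] + v[None, :] - 2 * np.atleast_2d(c)
    np.fill_diagonal(t, 0.0)
    return np.maximum(t, 0.0)


def log_ratio_variance(counts, pseudocount: float = 1.0) -> np.ndarray:
    """Matrix of log-ratio variances t_ij (n-1 denominator), zero diagonal."""
    mat, _ = _as_matrix(counts)
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 OTUs")
    if mat.shape[1] < 3:
        raise ValueError("need at least 3 samples for a stable variance")
    return _t_matrix(_fractions(mat, pseudocount))


def _basis_solve(t: np.ndarray, included: np.ndarray) -> np.ndarray:
    """Solve for basis variances from row sums of t over included pairs.

    ``included`` is a boolean matrix of pairs still considered uncorrelated;
    with all pairs included the system is M = (D-2)I + ones.
    """
    d = t.shape[0]
    m = included.astype(float)
    np.fill_diagonal(m, 0.0)
    deg = m.sum(axis=1)
    a = np.diag(deg) + m  # full inclusion: (D-2)I + ones
    rhs = (t * m).sum(axis=1)
    try:
        w2 = np.linalg.solve(a, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("basis-variance system singular after exclusions") from exc
    if (w2 <= 0).any():
        warnings.warn("negative basis variance clamped", stacklevel=3)
        w2 = np.maximum(w2, 1e-10)
    return w2


def _rho_from_t(t: np.ndarray, inference_iterations: int,
                exclusion_threshold: float) -> tuple[np.ndarray, np.ndarray]:
    d = t.shape[0]
    included = np.ones((d, d), dtype=bool)
    np.fill_diagonal(included, False)
    w2 = _basis_solve(t, included)
    rho = _rho(t, w2)
    for _ in range(inference_iterations):
        cand = np.abs(rho)
        cand[~included] = 0.0
        np.fill_diagonal(cand, 0.0)
        # never strip an OTU below 2 remaining partners
        deg = included.sum(axis=1)
        cand[deg <= 2, :] = 0.0
        cand[:, deg <= 2] = 0.0
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= exclusion_threshold:
            break
        included[i, j] = included[j, i] = False
        w2 = _basis_solve(t, included)
        rho = _rho(t, w2)
    return rho, w2


def _rho(t: np.ndarray, w2: np.ndarray) -> np.ndarray:
    w = np.sqrt(w2)
    rho = (w2[:, None] + w2[None, :] - t) / (2 * np.outer(w, w))
    np.fill_diagonal(rho, 1.0)
    return np.clip(rho, -1.0, 1.0)


def sparcc_correlations(
    counts,
    inference_iterations: int = 10,
    exclusion_threshold: float = 0.1,
    n_draws: int = 10,
    pseudocount: float = 1.0,
    seed: int | None = None,
    filter_spec: str = "",
) -> SparccResult:
    """Estimate basis correlations from a (filtered) OTU count matrix.

    ``inference_iterations`` strong-pair exclusion rounds are run per
    estimate, and estimates are averaged over ``n_draws`` Dirichlet draws of
    the underlying fractions (``n_draws=0`` uses the single point estimate).
    """
    mat, otu_ids = _as_matrix(counts)
    if mat.shape[0] < 2 or mat.shape[1] < 3:
        raise ValueError("need >= 2 OTUs and >= 3 samples")
    rng = np.random.default_rng(seed)
    draws = max(int(n_draws), 0)
    rhos, w2s = [], []
    for k in range(max(draws, 1)):
        frac = _fractions(mat, pseudocount, rng=rng if draws else None)
        t = _t_matrix(frac)
        rho, w2 = _rho_from_t(t, inference_iterations, exclusion_threshold)
        rhos.append(rho)
        w2s.append(w2)
    rho = np.clip(np.mean(rhos, axis=0), -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return SparccResult(
        otu_ids=otu_ids,
        rho=pd.DataFrame(rho, index=otu_ids, columns=otu_ids),
        basis_variances=np.mean(w2s, axis=0),
        p_values=None,
        n_inference_iterations=inference_iterations,
        exclusion_threshold=exclusion_threshold,
        n_draws=draws,
        pseudocount=pseudocount,
        filter_spec=filter_spec,
    )


def sparcc_pvalues(
    counts,
    result: SparccResult,
    permutations: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Two-tailed permutation p-values for the SparCC correlations.

    Each OTU's counts are permuted independently across samples, breaking all
    between-OTU association while preserving per-OTU count distributions; the
    full estimator (point-estimate fractions) is recomputed per permutation.
    p = (#{|rho_null| >= |rho_obs|} + 1)/(permutations + 1).
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    mat, otu_ids = _as_matrix(counts)
    if otu_ids != result.otu_ids:
        raise ValueError("counts do not match the SparccResult's OTUs")
    rng = np.random.default_rng(seed)
    obs = np.abs(result.rho.to_numpy())
    hits = np.zeros_like(obs)
    for _ in range(permutations):
        perm = np.empty_like(mat)
        for i in range(mat.shape[0]):
            perm[i] = mat[i, rng.permutation(mat.shape[1])]
        t = _t_matrix(_fractions(perm, result.pseudocount))
        rho_null, _ = _rho_from_t(
            t, result.n_inference_iterations, result.exclusion_threshold
        )
        hits += np.abs(rho_null) >= obs - 1e-12
    p = (hits + 1) / (permutations + 1)
    np.fill_diagonal(p, np.nan)
    pdf = pd.DataFrame(p, index=otu_ids, columns=otu_ids)
    result.p_values = pdf
    result.n_permutations = permutations
    return pdf


def sparcc_filter(
    table: OtuTable, min_mean: float = 1.0, min_prevalence: float = 0.2
) -> tuple[OtuTable, str]:
    """Default SparCC input filter: OTUs with mean count >= ``min_mean`` and
    presence in >= ``min_prevalence`` of samples. Returns the filtered table
    and a human-readable filter_spec string."""
    counts = table.counts
    keep = (counts.mean(axis=1) >= min_mean) & (
        (counts > 0).mean(axis=1) >= min_prevalence
    )
    spec = f"mean>={min_mean},prevalence>={min_prevalence}"
    filtered = OtuTable(
        counts.loc[keep],
        taxonomy=table.taxonomy[keep] if table.taxonomy is not None else None,
    )
    return filtered, spec
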