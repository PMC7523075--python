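"""Null-model community-assembly inference.

Raup-Crick beta diversity (beta_RC) asks whether two communities share more
or fewer taxa than expected if each were assembled at random from the
species pool, holding each community's richness fixed and drawing species
with probability proportional to how often they occur across the reference
sample set. beta_RC is scaled to [-1, 1]; values below -0.95 mean the pair
is more similar than ~97.5% of null assemblages ("deterministic
establishment"), values above +0.95 mean less similar than null.

Co-occurrence structure is tested with the COMBO metric (number of distinct
species combinations across samples) against SIM-family randomizations of
the presence/absence matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .tables import OtuTable

__all__ = [
    "raup_crick",
    "deterministic_assembly_rates",
    "fisher_exact",
    "combo_metric",
    "cooccurrence_ses",
]


def _weighted_sample_wor(rng, weights, size, n_draws):
    """Efraimidis-Spirakis weighted sampling without replacement.

    Returns an (n_draws, size) array of indices; each row is distributed as
    successive draws without replacement with probability proportional to
    ``weights``.
    """
    keys = np.log(weights)[None, :] + rng.gumbel(size=(n_draws, len(weights)))
    return np.argpartition(keys, -size, axis=1)[:, -size:]


def raup_crick(
    table: OtuTable,
    pairs: list[tuple[str, str]],
    replicates: int = 1000,
    seed: int | None = None,
    reference_samples: list[str] | None = None,
) -> pd.DataFrame:
    """Pairwise beta_RC for the given sample pairs.

    Presence is >= 1 read. Occurrence frequencies (the null draw weights)
    are computed over ``reference_samples`` (default: every sample of
    ``table``); the species pool is the set of OTUs occurring at least once
    there. Per pair, ``replicates`` null assemblage pairs are drawn with each
    sample's observed richness fixed, and

        percentile = (#null shared > observed + 0.5 * #ties) / replicates
        beta_RC    = 2 * percentile - 1

    so beta_RC < -0.95 flags pairs sharing more taxa than the null
    ("more_similar"; deterministic assembly).
    """
    presence = table.counts > 0
    ref = reference_samples if reference_samples is not None else table.sample_ids
    freq = presence[ref].sum(axis=1)
    pool = freq.index[freq > 0]
    if len(pool) == 0:
        raise ValueError("empty species pool over the reference samples")
    weights = freq[pool].to_numpy(dtype=float)
    pool_presence = presence.loc[pool]
    rng = np.random.default_rng(seed)
    design = None
    try:
        design = table.design()
    except ValueError:
        pass  # non-standard sample names: plant/compartment left blank

    records = []
    n_pool = len(pool)
    for sid_a, sid_b in pairs:
        pa = pool_presence[sid_a].to_numpy()
        pb = pool_presence[sid_b].to_numpy()
        ra, rb = int(pa.sum()), int(pb.sum())
        if ra == 0 or rb == 0:
            raise ValueError(f"empty sample in pair ({sid_a}, {sid_b})")
        if ra > n_pool or rb > n_pool:
            raise ValueError("sample richness exceeds species pool size")
        observed = int((pa & pb).sum())
        draws_a = _weighted_sample_wor(rng, weights, ra, replicates)
        draws_b = _weighted_sample_wor(rng, weights, rb, replicates)
        shared = np.empty(replicates, dtype=np.int64)
        occ = np.zeros(n_pool, dtype=bool)
        for r in range(replicates):
            occ[:] = False
            occ[draws_a[r]] = True
            shared[r] = occ[draws_b[r]].sum()
        greater = int((shared > observed).sum())
        ties = int((shared == observed).sum())
        percentile = (greater + 0.5 * ties) / replicates
        beta_rc = 2.0 * percentile - 1.0
        significant = abs(beta_rc) > 0.95
        direction = (
            "more_similar" if beta_rc < -0.95
            else "less_similar" if beta_rc > 0.95
            else "null"
        )
        rec = {
            "sample_a": sid_a,
            "sample_b": sid_b,
            "beta_rc": beta_rc,
            "significant": significant,
            "direction": direction,
            "observed_shared": observed,
            "replicates": replicates,
        }
        if design is not None:
            rec["plant_id"] = (
                design.loc[sid_a, "plant_id"]
                if design.loc[sid_a, "plant_id"] == design.loc[sid_b, "plant_id"]
                else ""
            )
            rec["compartment_pair"] = (
                design.loc[sid_a, "compartment"],
                design.loc[sid_b, "compartment"],
            )
        records.append(rec)
    return pd.DataFrame(records)


def fisher_exact(table_2x2) -> float:
    """Two-tailed Fisher exact p-value for a 2x2 table (point-probability
    rule: sum of all fixed-margin tables no more probable than observed)."""
    t = np.asarray(table_2x2)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table must contain non-negative integers")
    _, p = scipy.stats.fisher_exact(np.round(t).astype(np.int64),
                                    alternative="two-sided")
    return float(p)


def deterministic_assembly_rates(
    results_a: pd.DataFrame, results_b: pd.DataFrame
) -> tuple[float, float, float]:
    """Compare significant-beta_RC rates between two sets of pairings.

    Returns ``(rate_a, rate_b, fisher_p)`` where each rate is the fraction
    of pairs with |beta_RC| > 0.95 and the p-value is a two-tailed Fisher
    exact test on the 2x2 significant-vs-not table.
    """
    if len(results_a) == 0 or len(results_b) == 0:
        raise ValueError("both result sets must be non-empty")
    sig_a = int(results_a["significant"].sum())
    sig_b = int(results_b["significant"].sum())
    n_a, n_b = len(results_a), len(results_b)
    p = fisher_exact([[sig_a, n_a - sig_a], [sig_b, n_b - sig_b]])
    return sig_a / n_a, sig_b / n_b, p


def combo_metric(presence) -> int:
    """Number of distinct species combinations (unique columns) across samples."""
    mat = np.asarray(presence, dtype=bool)
    if mat.ndim != 2:
        raise ValueError("presence matrix must be 2-D")
    packed = np.packbits(mat, axis=0)
    return len({col.tobytes() for col in packed.T})


def _null_sim6(rng, shape, fill, col_weights):
    """Equiprobable species x richness-proportional samples, fill preserved."""
    n_rows, n_cols = shape
    w = np.repeat(col_weights[None, :], n_rows, axis=0).ravel()
    idx = _weighted_sample_wor(rng, w, fill, 1)[0]
    mat = np.zeros(n_rows * n_cols, dtype=bool)
    mat[idx] = True
    return mat.reshape(shape)


def _null_sim2(rng, presence):
    """Row (species occurrence) totals fixed, samples equiprobable."""
    n_rows, n_cols = presence.shape
    out = np.zeros_like(presence)
    order = np.argsort(rng.random((n_rows, n_cols)), axis=1)
    for i in range(n_rows):
        k = presence[i].sum()
        out[i, order[i, :k]] = True
    return out


def _null_sim4(rng, presence, col_weights):
    """Row totals fixed, sample probabilities proportional to richness."""
    n_rows, n_cols = presence.shape
    out = np.zeros_like(presence)
    for i in range(n_rows):
        k = int(presence[i].sum())
        if k:
            out[i, _weighted_sample_wor(rng, col_weights, k, 1)[0]] = True
    return out


def cooccurrence_ses(
    table: OtuTable,
    algorithm: str = "sim6",
    iterations: int = 10_000,
    exclude_otus: list[str] | None = None,
    seed: int | None = None,
) -> dict:
    """Standardized effect size of the COMBO metric against a SIM null model.

    ``sim6`` (default) holds the total number of occurrences fixed, treats
    species as equiprobable, and fills samples with probability proportional
    to their observed richness — the constraint set matching colonization
    dynamics where richer samples are more likely to gain occupants. ``sim2``
    fixes each species' occurrence count with equiprobable samples; ``sim4``
    fixes species occurrences with richness-proportional samples.
    """
    counts = table.counts
    if exclude_otus:
        counts = counts.drop(index=list(exclude_otus), errors="ignore")
    presence = (counts.to_numpy() > 0)
    presence = presence[presence.sum(axis=1) > 0]  # drop never-observed OTUs
    if presence.shape[0] < 2 or presence.shape[1] < 2:
        raise ValueError("need >= 2 OTUs and >= 2 samples after exclusions")
    observed = combo_metric(presence)
    col_weights = presence.sum(axis=0).astype(float)
    if (col_weights == 0).any():
        col_weights = col_weights + 0.5  # empty samples stay drawable
    fill = int(presence.sum())
    rng = np.random.default_rng(seed)
    null = np.empty(iterations)
    for it in range(iterations):
        if algorithm == "sim6":
            mat = _null_sim6(rng, presence.shape, fill, col_weights)
        elif algorithm == "sim2":
            mat = _null_sim2(rng, presence)
        elif algorithm == "sim4":
            mat = _null_sim4(rng, presence, col_weights)
        else:
            raise ValueError(f"unknown algorithm {algorithm!r}; use sim6/sim2/sim4")
        null[it] = combo_metric(mat)
    null_mean, null_sd = null.mean(), null.std(ddof=1)
    if null_sd == 0:
        raise ValueError("degenerate null: all null COMBO values identical")
    z = (observed - null_mean) / null_sd
    extreme = int((np.abs(null - null_mean) >= abs(observed - null_mean) - 1e-12).sum())
    p = (extreme + 1) / (iterations + 1)
    return {
        "metric_name": "combo",
        "observed": observed,
        "null_mean": float(null_mean),
        "null_sd": float(null_sd),
        "z_score": float(z),
        "p_value": float(p),
        "iterations": iterations,
        "algorithm": algorithm,
    }
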