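"""Within-plant paired effect sizes, core taxa, presence sets, and
Monte-Carlo contingency tests.

The paired effect size for an OTU between two compartments of the same plant
is ES = (relA - relB)/(relA + relB) on per-sample relative abundances:
+1 when the OTU occurs only in compartment A, -1 when only in B, 0 when its
relative abundance is identical. Plants where the OTU is absent from both
compartments contribute nothing to that OTU's ES distribution.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import scipy.stats

from .tables import COMPARTMENTS, OtuTable, to_relative_abundance

__all__ = [
    "paired_effect_size",
    "wilcoxon_signed_rank",
    "core_taxa",
    "compartment_presence_sets",
    "monte_carlo_chi_square",
]


def wilcoxon_signed_rank(differences) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test on a difference vector.

    Zeros are dropped; the exact null distribution is used for n <= 25
    without ties, the tie-corrected normal approximation otherwise.
    """
    diffs = np.asarray(differences, dtype=float)
    nonzero = diffs[diffs != 0]
    if len(nonzero) == 0:
        raise ValueError("all differences are zero; test undefined")
    has_ties = len(np.unique(np.abs(nonzero))) < len(nonzero)
    method = "exact" if (len(nonzero) <= 25 and not has_ties) else "approx"
    res = scipy.stats.wilcoxon(
        diffs, zero_method="wilcox", alternative="two-sided", method=method
    )
    return float(res.statistic), float(res.pvalue)


def paired_effect_size(
    table: OtuTable,
    pair: tuple[str, str],
    top_n: int = 20,
) -> pd.DataFrame:
    """Paired effect sizes for the ``top_n`` most abundant OTUs.

    For every plant possessing both compartments of ``pair``, computes
    ES = (relA - relB)/(relA + relB) per OTU. Returns one row per OTU with
    the ES quintiles (min, q25, median, q75, max), the per-plant values
    (``es_values``), and a two-sided Wilcoxon signed-rank test of ES against
    zero.
    """
    comp_a, comp_b = pair
    for c in pair:
        if c not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {c!r}")
    design = table.design()
    rel = to_relative_abundance(table)
    plants = {}
    for plant_id, sub in design.groupby("plant_id"):
        comps = dict(zip(sub["compartment"], sub.index))
        if comp_a in comps and comp_b in comps:
            plants[plant_id] = (comps[comp_a], comps[comp_b])
    if not plants:
        raise ValueError(f"no plant has both {comp_a} and {comp_b} samples")
    top = table.otu_totals().sort_values(ascending=False).index[:top_n]
    records = []
    for otu in top:
        es = []
        for sid_a, sid_b in plants.values():
            ra, rb = rel.loc[otu, sid_a], rel.loc[otu, sid_b]
            if ra == 0 and rb == 0:
                continue
            es.append((ra - rb) / (ra + rb))
        es = np.asarray(es)
        if len(es) == 0:
            continue
        try:
            stat, p = wilcoxon_signed_rank(es)
        except ValueError:
            stat, p = np.nan, np.nan
        records.append(
            {
                "otu_id": otu,
                "compartment_a": comp_a,
                "compartment_b": comp_b,
                "n_pairs": len(es),
                "es_min": es.min(),
                "es_q25": np.quantile(es, 0.25),
                "es_median": np.median(es),
                "es_q75": np.quantile(es, 0.75),
                "es_max": es.max(),
                "wilcoxon_statistic": stat,
                "p_value": p,
                "es_values": es,
            }
        )
    return pd.DataFrame(records)


def core_taxa(
    table: OtuTable,
    compartment: str,
    prevalence_threshold: float = 0.5,
) -> pd.DataFrame:
    """OTUs present (>= 1 read) in strictly more than ``prevalence_threshold``
    of the compartment's samples, with their prevalences, most prevalent
    first."""
    sub = table.select_compartment(compartment)
    prevalence = (sub.counts > 0).mean(axis=1)
    core = prevalence[prevalence > prevalence_threshold].sort_values(
        ascending=False
    )
    out = core.rename("prevalence").rename_axis("otu_id").reset_index()
    out["n_samples"] = sub.n_samples
    return out


def compartment_presence_sets(
    table: OtuTable, min_reads: int = 10
) -> dict:
    """Per-compartment OTU presence sets and exclusive Venn-region counts.

    An OTU is present in a compartment iff its summed read count there is
    strictly greater than ``min_reads``. Returns ``{"sets": {...},
    "regions": {...}, "unique": {...}, "shared_all": int}`` where ``regions``
    maps each non-empty compartment combination (sorted tuple) to the number
    of OTUs present in exactly those compartments.
    """
    design = table.design()
    comps = [c for c in COMPARTMENTS if (design["compartment"] == c).any()]
    if len(comps) < 2:
        raise ValueError("need samples from at least 2 compartments")
    sets = {}
    for comp in comps:
        samples = design.index[design["compartment"] == comp]
        totals = table.counts[samples].sum(axis=1)
        sets[comp] = set(totals.index[totals > min_reads])
    regions = {}
    for r in range(1, len(comps) + 1):
        for combo in itertools.combinations(comps, r):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set.union(
                *(sets[c] for c in comps if c not in combo), set()
            )
            regions[tuple(sorted(combo))] = len(inside - outside)
    unique = {c: regions[(c,)] for c in comps}
    shared_all = regions[tuple(sorted(comps))]
    return {
        "sets": sets,
        "regions": regions,
        "unique": unique,
        "shared_all": shared_all,
    }


def monte_carlo_chi_square(
    contingency,
    replications: int = 10_000,
    seed: int | None = None,
) -> dict:
    """Pearson chi-square with a Monte-Carlo p-value under fixed margins.

    Null tables are sampled with both margins fixed (Patefield's algorithm);
    p = (#null chi-square >= observed + 1)/(replications + 1). Suited to
    sparse tables where the asymptotic chi-square reference is unreliable.
    """
    obs = np.asarray(contingency)
    if obs.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if np.any(obs < 0) or not np.issubdtype(obs.dtype, np.integer):
        if not np.allclose(obs, np.round(obs)) or np.any(obs < 0):
            raise ValueError("table must contain non-negative integers")
        obs = np.round(obs).astype(np.int64)
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero row or column margin")
    expected = np.outer(row, col) / obs.sum()
    chi2_obs = float(((obs - expected) ** 2 / expected).sum())
    rng = np.random.default_rng(seed)
    dist = scipy.stats.random_table(row, col)
    tables = dist.rvs(replications, method="patefield", random_state=rng)
    chi2_null = ((tables - expected) ** 2 / expected).sum(axis=(1, 2))
    hits = int((chi2_null >= chi2_obs - 1e-12).sum())
    p = (hits + 1) / (replications + 1)
    return {
        "chi_square": chi2_obs,
        "p_value": float(p),
        "replications": replications,
    }
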