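"""Replicon read-depth ratios: what fraction of symbiont cells carry each
symbiosis plasmid?

Because the chromosome is present in every cell while an accessory plasmid
is present only in the cells that carry it, the per-megabase read depth of a
plasmid divided by the per-megabase read depth of the chromosome estimates
the plasmid-carrying cell fraction (assuming single copy per cell). Samples
with too little symbiont signal — fewer than 20 reads on the single-copy
marker gene rpoB — are excluded before comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "read_replicon_table",
    "replicon_ratio",
    "mann_whitney_u",
    "compare_compartments",
    "features_to_replicons",
]

_REQUIRED = ["sample_id", "compartment", "replicon", "length", "reads", "rpob_reads"]


def read_replicon_table(path) -> pd.DataFrame:
    """Read the tidy per-replicon count TSV (one row per sample x replicon)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"replicon table lacks columns: {missing}")
    return df


def features_to_replicons(
    feature_counts: pd.DataFrame, feature_to_replicon: dict
) -> pd.DataFrame:
    """Aggregate per-feature (e.g. per-CDS) read counts to per-replicon totals.

    ``feature_counts`` needs columns sample_id, feature_id, reads; unknown
    features raise.
    """
    unknown = set(feature_counts["feature_id"]) - set(feature_to_replicon)
    if unknown:
        raise ValueError(f"features without a replicon assignment: {sorted(unknown)[:5]}")
    df = feature_counts.copy()
    df["replicon"] = df["feature_id"].map(feature_to_replicon)
    return (
        df.groupby(["sample_id", "replicon"], as_index=False)["reads"].sum()
    )


def replicon_ratio(
    table: pd.DataFrame,
    chromosome_id: str = "chromosome",
    min_rpob_reads: int = 20,
) -> pd.DataFrame:
    """Per-sample plasmid:chromosome reads-per-megabase ratios.

    ratio = (plasmid reads / plasmid Mb) / (chromosome reads / chromosome Mb).
    Samples whose rpoB read count is below ``min_rpob_reads`` are flagged
    ``excluded`` (kept in the output for the exclusion log, dropped from
    downstream tests).
    """
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"replicon table lacks columns: {missing}")
    rows = []
    for sid, sub in table.groupby("sample_id"):
        sub = sub.set_index("replicon")
        if chromosome_id not in sub.index:
            raise ValueError(f"sample {sid}: replicon {chromosome_id!r} missing")
        chrom = sub.loc[chromosome_id]
        if chrom["reads"] == 0:
            raise ValueError(f"sample {sid}: zero chromosome reads")
        chrom_per_mb = chrom["reads"] / (chrom["length"] / 1e6)
        excluded = bool(sub["rpob_reads"].iloc[0] < min_rpob_reads)
        for rep, row in sub.iterrows():
            if rep == chromosome_id:
                continue
            per_mb = row["reads"] / (row["length"] / 1e6)
            rows.append(
                {
                    "sample_id": sid,
                    "compartment": row["compartment"],
                    "plasmid": rep,
                    "ratio": per_mb / chrom_per_mb,
                    "rpob_reads": int(row["rpob_reads"]),
                    "excluded": excluded,
                }
            )
    return pd.DataFrame(rows)


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney rank-sum test.

    Exact null distribution for small tie-free samples (both n <= 25),
    tie-corrected normal approximation otherwise. Returns (U of group_a, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (not has_ties and max(len(a), len(b)) <= 25) else "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_compartments(
    ratios: pd.DataFrame,
    compartment_a: str = "root",
    compartment_b: str = "nodule",
) -> pd.DataFrame:
    """Per-plasmid Mann-Whitney comparison of ratios between two compartments,
    with per-compartment medians and quartiles (excluded samples dropped)."""
    kept = ratios[~ratios["excluded"]]
    rows = []
    for plasmid, sub in kept.groupby("plasmid"):
        ra = sub.loc[sub["compartment"] == compartment_a, "ratio"].to_numpy()
        rb = sub.loc[sub["compartment"] == compartment_b, "ratio"].to_numpy()
        stat, p = mann_whitney_u(ra, rb)
        rows.append(
            {
                "plasmid": plasmid,
                "n_a": len(ra),
                "n_b": len(rb),
                f"median_{compartment_a}": float(np.median(ra)),
                f"median_{compartment_b}": float(np.median(rb)),
                f"q25_{compartment_a}": float(np.quantile(ra, 0.25)),
                f"q75_{compartment_a}": float(np.quantile(ra, 0.75)),
                f"q25_{compartment_b}": float(np.quantile(rb, 0.25)),
                f"q75_{compartment_b}": float(np.quantile(rb, 0.75)),
                "U": stat,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
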