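"""End-to-end analysis pipeline over an OTU table (plus optional replicon
counts), reproducing the full compartment-microbiome analysis graph:

io -> alpha diversity (+ ANOVA/Tukey) -> Bray-Curtis/NMDS -> PVCA ->
per-compartment PerMANOVAs -> paired effect sizes -> core taxa -> Raup-Crick
(+ Fisher rate comparison) -> co-occurrence -> SparCC -> replicon ratios.

Every stage writes TSV outputs into the run directory and records its
parameters, derived seed, and output hashes in ``manifest.json``. Reruns
with an unchanged configuration skip stages whose recorded output hashes
still match on disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alpha import (
    BOXCOX_LAMBDA_BY_COMPARTMENT,
    TransformSpec,
    factorial_anova,
    iterative_alpha,
    transform_response,
    tukey_hsd,
)
from .assembly import cooccurrence_ses, deterministic_assembly_rates, raup_crick
from .beta import iterative_bray_curtis, nmds, permanova, pvca
from .effects import compartment_presence_sets, core_taxa, paired_effect_size
from .replicon import compare_compartments, read_replicon_table, replicon_ratio
from .simulate import SimulationConfig, generate_experiment, generate_replicon_counts
from .sparcc import sparcc_correlations, sparcc_filter, sparcc_pvalues
from .tables import filter_rare_otus, read_otu_table, write_otu_table

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = (
    "simulate",
    "alpha",
    "beta",
    "pvca",
    "permanova",
    "effectsize",
    "core",
    "raupcrick",
    "cooccur",
    "sparcc",
    "replicon",
)


@dataclass
class PipelineConfig:
    """All pipeline knobs; defaults are the study-stated values.

    Either ``otu_table_path`` points at an existing table or the ``simulate``
    stage generates one from ``simulation``. ``stages`` selects which stages
    run (dependencies must be included by the caller).
    """

    output_dir: str = "pipeline_out"
    otu_table_path: str | None = None
    otu_table_dialect: str = "tsv"
    replicon_table_path: str | None = None
    stages: tuple = STAGES
    depth: int = 1500
    iterations: int = 1000
    nmds_k: int = 3
    pvca_axes: int = 10
    nmds_restarts: int = 8
    permutations: int = 999
    beta_rc_replicates: int = 1000
    cooccurrence_iterations: int = 10_000
    sparcc_inference_iterations: int = 10
    sparcc_permutations: int = 1000
    core_prevalence: float = 0.5
    presence_min_reads: int = 10
    beta_rc_cutoff: float = 0.95
    min_rpob_reads: int = 20
    rare_otu_min_total: int = 10
    top_n_effect_size: int = 20
    master_seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    simulate_replicons: bool = False

    def stage_seed(self, stage: str) -> int:
        idx = STAGES.index(stage)
        ss = np.random.SeedSequence(self.master_seed, spawn_key=(idx,))
        return int(ss.generate_state(1)[0] % (2**31))


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_fingerprint(config: PipelineConfig) -> str:
    d = dataclasses.asdict(config)
    d["simulation"]["dominance"] = dict(d["simulation"]["dominance"])
    d["simulation"]["concentration"] = dict(d["simulation"]["concentration"])
    return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the manifest dictionary.

    Stage preconditions are checked before any stage executes, so a missing
    input fails fast rather than mid-run.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = tuple(config.stages)
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    if "replicon" in stages and not (
        config.replicon_table_path or config.simulate_replicons
    ):
        raise ValueError(
            "replicon stage requested but no replicon table or simulation configured"
        )
    if "simulate" not in stages and config.otu_table_path is None and any(
        s in stages for s in STAGES[1:-1]
    ):
        raise ValueError("no OTU table: provide otu_table_path or include 'simulate'")

    manifest_path = out / "manifest.json"
    fingerprint = _config_fingerprint(config)
    manifest = {"version": __version__, "config_fingerprint": fingerprint,
                "master_seed": config.master_seed, "stages": {}}
    previous = {}
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_fingerprint") == fingerprint:
            previous = old.get("stages", {})

    def fresh(stage: str, outputs: list[str]) -> bool:
        entry = previous.get(stage)
        if not entry:
            return False
        for f, h in entry.get("outputs", {}).items():
            p = out / f
            if not p.exists() or _hash_file(p) != h:
                return False
        manifest["stages"][stage] = entry
        return True

    def record(stage: str, outputs: list[str], **params) -> None:
        manifest["stages"][stage] = {
            "seed": config.stage_seed(stage),
            "params": params,
            "outputs": {f: _hash_file(out / f) for f in outputs},
        }
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))

    # -- input table -----------------------------------------------------
    table_file = out / "otu_table.tsv"
    if "simulate" in stages:
        if not fresh("simulate", ["otu_table.tsv"]):
            sim = dataclasses.replace(
                config.simulation, seed=config.stage_seed("simulate")
            )
            write_otu_table(generate_experiment(sim), table_file)
            record("simulate", ["otu_table.tsv"], seed=sim.seed)
        table = read_otu_table(table_file)
    elif config.otu_table_path:
        table = read_otu_table(config.otu_table_path, config.otu_table_dialect)
    else:
        table = None
    if table is not None and config.rare_otu_min_total > 0:
        table = filter_rare_otus(table, config.rare_otu_min_total)
    design = table.design() if table is not None else None

    def run_stage(stage, outputs, fn):
        if stage not in stages:
            return
        if fresh(stage, outputs):
            return
        params = fn()
        record(stage, outputs, **(params or {}))

    # -- alpha -----------------------------------------------------------
    def _alpha():
        seed = config.stage_seed("alpha")
        records = iterative_alpha(
            table, depth=config.depth, iterations=config.iterations, seed=seed
        )
        dsub = design.loc[records.index]
        records = records.join(dsub)
        transformed = {}
        for comp, grp in records.groupby("compartment", observed=True):
            lam = BOXCOX_LAMBDA_BY_COMPARTMENT.get(comp, 0.0)
            eps = 1 / (2 * config.depth)
            transformed[comp] = pd.DataFrame(
                {
                    "logit_simpson_complement": transform_response(
                        grp["simpson_complement"], TransformSpec("logit"),
                        clamp_eps=eps,
                    ),
                    "logit_simpson_evenness": transform_response(
                        grp["simpson_evenness"].clip(upper=1 - eps),
                        TransformSpec("logit"), clamp_eps=eps,
                    ),
                    "boxcox_s_obs": transform_response(
                        grp["s_obs"], TransformSpec("box-cox", lam)
                    ),
                },
                index=grp.index,
            )
        records = records.join(pd.concat(transformed.values()))
        records.to_csv(out / "alpha_diversity.tsv", sep="\t")
        anova_rows = []
        factors = records[["compartment", "soil_origin", "genotype"]]
        for resp in ("logit_simpson_complement", "logit_simpson_evenness",
                     "boxcox_s_obs"):
            try:
                tab = factorial_anova(
                    records[resp].to_numpy(), factors, balance_tol_ratio=np.inf
                )
            except ValueError as exc:
                warnings.warn(f"ANOVA on {resp} failed: {exc}", stacklevel=2)
                continue
            tab = tab.assign(response=resp).rename_axis("term").reset_index()
            anova_rows.append(tab)
        pd.concat(anova_rows).to_csv(out / "alpha_anova.tsv", sep="\t",
                                     index=False)
        letters_rows = []
        for resp in ("logit_simpson_complement", "logit_simpson_evenness",
                     "boxcox_s_obs"):
            _, letters = tukey_hsd(records[resp].to_numpy(),
                                   records["compartment"])
            for comp, letter in letters.items():
                letters_rows.append(
                    {"response": resp, "compartment": comp, "letters": letter}
                )
        pd.DataFrame(letters_rows).to_csv(out / "alpha_tukey_letters.tsv",
                                          sep="\t", index=False)
        return {"depth": config.depth, "iterations": config.iterations}

    run_stage("alpha", ["alpha_diversity.tsv", "alpha_anova.tsv",
                        "alpha_tukey_letters.tsv"], _alpha)

    # -- beta ------------------------------------------------------------
    dmat = ordination = None

    def _ensure_beta():
        nonlocal dmat, ordination
        if dmat is None:
            from .beta import DissimilarityMatrix

            bc_file = out / "bray_curtis.tsv"
            if bc_file.exists() and "beta" in manifest["stages"]:
                dmat = DissimilarityMatrix.read_tsv(bc_file)
            else:
                dmat = iterative_bray_curtis(
                    table, depth=config.depth, iterations=config.iterations,
                    seed=config.stage_seed("beta"),
                )
        if ordination is None:
            k = max(config.nmds_k, config.pvca_axes)
            ordination = nmds(dmat, k=k, restarts=config.nmds_restarts,
                              seed=config.stage_seed("beta"))

    def _beta():
        _ensure_beta()
        dmat.write_tsv(out / "bray_curtis.tsv")
        ordination.coordinates.to_csv(out / "nmds_coordinates.tsv", sep="\t")
        pd.DataFrame(
            {"axis": ordination.coordinates.columns,
             "r_squared": ordination.axis_r2}
        ).to_csv(out / "nmds_axis_r2.tsv", sep="\t", index=False)
        return {"stress": ordination.stress, "k": ordination.k}

    run_stage("beta", ["bray_curtis.tsv", "nmds_coordinates.tsv",
                       "nmds_axis_r2.tsv"], _beta)

    def _pvca():
        _ensure_beta()
        comps = pvca(
            dmat, design, n_axes=config.pvca_axes,
            seed=config.stage_seed("pvca"), ordination=ordination,
        )
        comps.rename_axis("term").reset_index().to_csv(
            out / "pvca.tsv", sep="\t", index=False
        )
        return {"n_axes": config.pvca_axes}

    run_stage("pvca", ["pvca.tsv"], _pvca)

    def _permanova():
        _ensure_beta()
        rows = []
        seed = config.stage_seed("permanova")
        dsub = design.loc[dmat.sample_ids]
        rows.append(_permanova_row(dmat, dsub["compartment"], "all",
                                   "compartment", config, seed))
        for comp in dsub["compartment"].unique():
            ids = dsub.index[dsub["compartment"] == comp].tolist()
            sub = dmat.submatrix(ids)
            for factor in ("soil_origin", "genotype"):
                rows.append(_permanova_row(
                    sub, dsub.loc[ids, factor], comp, factor, config, seed
                ))
        pd.DataFrame(rows).to_csv(out / "permanova.tsv", sep="\t", index=False)
        return {"permutations": config.permutations}

    run_stage("permanova", ["permanova.tsv"], _permanova)

    # -- composition -----------------------------------------------------
    def _effectsize():
        frames = []
        for pair in (("nodule", "root"), ("nodule", "rhizosphere")):
            es = paired_effect_size(table, pair, top_n=config.top_n_effect_size)
            frames.append(es.drop(columns=["es_values"]))
        pd.concat(frames).to_csv(out / "effect_sizes.tsv", sep="\t", index=False)
        venn = compartment_presence_sets(table, min_reads=config.presence_min_reads)
        rows = [
            {"compartments": "+".join(k), "n_otus": v}
            for k, v in venn["regions"].items()
        ]
        pd.DataFrame(rows).to_csv(out / "presence_regions.tsv", sep="\t",
                                  index=False)
        return {"top_n": config.top_n_effect_size}

    run_stage("effectsize", ["effect_sizes.tsv", "presence_regions.tsv"],
              _effectsize)

    def _core():
        core = core_taxa(table, "nodule",
                         prevalence_threshold=config.core_prevalence)
        core.to_csv(out / "core_nodule_taxa.tsv", sep="\t", index=False)
        return {"prevalence_threshold": config.core_prevalence}

    run_stage("core", ["core_nodule_taxa.tsv"], _core)

    def _raupcrick():
        seed = config.stage_seed("raupcrick")
        results = {}
        for i, source in enumerate(("root", "rhizosphere")):
            pairs, ids = _plant_pairs(design, source, "nodule")
            sub = table.select_samples(ids)
            results[source] = raup_crick(
                sub, pairs, replicates=config.beta_rc_replicates, seed=seed + i
            )
        combined = pd.concat(
            [df.assign(source_compartment=s) for s, df in results.items()]
        )
        combined.to_csv(out / "raup_crick.tsv", sep="\t", index=False)
        rate_root, rate_rhizo, p = deterministic_assembly_rates(
            results["root"], results["rhizosphere"]
        )
        pd.DataFrame(
            [{"rate_root_nodule": rate_root,
              "rate_rhizosphere_nodule": rate_rhizo, "fisher_p": p}]
        ).to_csv(out / "assembly_rates.tsv", sep="\t", index=False)
        return {"replicates": config.beta_rc_replicates}

    run_stage("raupcrick", ["raup_crick.tsv", "assembly_rates.tsv"], _raupcrick)

    def _cooccur():
        seed = config.stage_seed("cooccur")
        nod = table.select_compartment("nodule")
        rows = []
        for label, exclude in (("all", None), ("without_otu1", [table.otu_ids[0]])):
            try:
                res = cooccurrence_ses(
                    nod, iterations=config.cooccurrence_iterations,
                    exclude_otus=exclude, seed=seed,
                )
            except ValueError as exc:
                # degenerate null (every null COMBO identical) is a data
                # property, not a pipeline failure — record and move on
                warnings.warn(f"co-occurrence ({label}): {exc}", stacklevel=2)
                res = {"metric_name": "combo", "z_score": np.nan,
                       "p_value": np.nan, "note": str(exc)}
            res["subset"] = label
            rows.append(res)
        pd.DataFrame(rows).to_csv(out / "cooccurrence.tsv", sep="\t", index=False)
        return {"iterations": config.cooccurrence_iterations}

    run_stage("cooccur", ["cooccurrence.tsv"], _cooccur)

    def _sparcc():
        seed = config.stage_seed("sparcc")
        nod = table.select_compartment("nodule")
        filtered, spec = sparcc_filter(nod)
        res = sparcc_correlations(
            filtered,
            inference_iterations=config.sparcc_inference_iterations,
            seed=seed, filter_spec=spec,
        )
        sparcc_pvalues(filtered, res,
                       permutations=config.sparcc_permutations, seed=seed)
        res.rho.to_csv(out / "sparcc_rho.tsv", sep="\t")
        res.p_values.to_csv(out / "sparcc_p.tsv", sep="\t")
        res.edge_list(0.05).to_csv(out / "sparcc_edges.tsv", sep="\t",
                                   index=False)
        return {"filter_spec": spec,
                "permutations": config.sparcc_permutations}

    run_stage("sparcc", ["sparcc_rho.tsv", "sparcc_p.tsv", "sparcc_edges.tsv"],
              _sparcc)

    def _replicon():
        if config.replicon_table_path:
            rtab = read_replicon_table(config.replicon_table_path)
        else:
            rtab = generate_replicon_counts(
                n_samples=15, seed=config.stage_seed("replicon")
            )
        ratios = replicon_ratio(rtab, min_rpob_reads=config.min_rpob_reads)
        ratios.to_csv(out / "replicon_ratios.tsv", sep="\t", index=False)
        compare_compartments(ratios).to_csv(
            out / "replicon_tests.tsv", sep="\t", index=False
        )
        return {"min_rpob_reads": config.min_rpob_reads}

    run_stage("replicon", ["replicon_ratios.tsv", "replicon_tests.tsv"],
              _replicon)

    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _permanova_row(dmat, labels, compartment, factor, config, seed):
    res = permanova(dmat, labels, permutations=config.permutations, seed=seed)
    return {
        "compartment": compartment,
        "factor": factor,
        "pseudo_F": res.pseudo_F,
        "df_num": res.df_num,
        "df_den": res.df_den,
        "p_value": res.p_value,
        "n_permutations": res.n_permutations,
    }


def _plant_pairs(design, comp_a, comp_b):
    """Same-plant sample-id pairs between two compartments, plus the union of
    sample ids involved (the Raup-Crick reference set)."""
    pairs = []
    ids = set()
    for _, sub in design.groupby("plant_id"):
        comps = dict(zip(sub["compartment"], sub.index))
        if comp_a in comps and comp_b in comps:
            pairs.append((comps[comp_a], comps[comp_b]))
            ids.update([comps[comp_a], comps[comp_b]])
    if not pairs:
        raise ValueError(f"no plant has both {comp_a} and {comp_b}")
    return pairs, sorted(ids)
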