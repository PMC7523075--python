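"""Synthetic compartment-structured microbiome experiments.

Emulates a paired common-garden design: plants of three genotypes grown in
soil from two origins, with ~5 replicate plants per soil x genotype cell and
four communities sampled per plant (rhizosphere, root endosphere, nodule,
leaf). The generator encodes the structure the downstream statistics are
meant to detect:

* one dominant taxon (OTU1, the rhizobial symbiont analogue) in every
  compartment, strongest in nodules;
* a diversity gradient rhizosphere > root/leaf > nodule, driven by a
  per-compartment Dirichlet concentration;
* soil-origin effects confined to the rhizosphere and genotype effects
  confined to the root endosphere, as per-OTU log-fold abundance multipliers;
* nodule communities optionally subsampled from their own plant's realized
  root community (deterministic nested colonization).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .tables import COMPARTMENT_CODES, OtuTable

__all__ = ["SimulationConfig", "generate_experiment", "generate_replicon_counts"]

_SOILS = {"Corsica": "C", "France": "F"}
_GENOTYPES = {"G1": "1", "G27": "27", "G96": "96"}
_COMP_LETTER = {v: k for k, v in COMPARTMENT_CODES.items()}
_REPLICATES = "abcde"


def _default_dominance() -> dict:
    return {"rhizosphere": 0.10, "root": 0.40, "leaf": 0.40, "nodule": 0.85}


def _default_concentration() -> dict:
    return {"rhizosphere": 200.0, "root": 60.0, "leaf": 60.0, "nodule": 15.0}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    ``dominance`` maps compartment -> target relative abundance of OTU1;
    ``concentration`` maps compartment -> Dirichlet concentration scalar (the
    single diversity knob: high = rich/even, low = sparse/uneven).
    ``sigma_soil`` and ``sigma_geno`` are the standard deviations of the
    per-OTU log-fold effects applied in the rhizosphere and root only.
    """

    n_otus: int = 300
    n_replicates: int = 5
    depth_log_mean: float = float(np.log(20000.0))
    depth_log_sd: float = 0.3
    dominance: Mapping[str, float] = field(default_factory=_default_dominance)
    concentration: Mapping[str, float] = field(default_factory=_default_concentration)
    sigma_soil: float = 0.8
    sigma_geno: float = 0.8
    rank_abundance_sd: float = 1.5
    nodule_from_root: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_otus < 2:
            raise ValueError("n_otus must be >= 2")
        if not 1 <= self.n_replicates <= len(_REPLICATES):
            raise ValueError(
                f"n_replicates must be in 1..{len(_REPLICATES)} (replicate codes a..e)"
            )
        for comp in ("rhizosphere", "root", "nodule", "leaf"):
            d = self.dominance[comp]
            if not 0 < d < 1:
                raise ValueError(f"dominance[{comp}] must be in (0,1), got {d}")
            if self.concentration[comp] <= 0:
                raise ValueError(f"concentration[{comp}] must be > 0")
        if self.sigma_soil < 0 or self.sigma_geno < 0:
            raise ValueError("effect sigmas must be >= 0")
        if self.depth_log_sd < 0:
            raise ValueError("depth_log_sd must be >= 0")


def _force_dominance(props: np.ndarray, target: float) -> np.ndarray:
    """Pin OTU1 (index 0) to ``target`` and rescale the remaining mass."""
    out = props.astype(float).copy()
    rest = out[1:].sum()
    out[0] = target
    if rest > 0:
        out[1:] *= (1.0 - target) / rest
    else:
        out[1:] = (1.0 - target) / (len(out) - 1)
    return out


def generate_experiment(config: SimulationConfig) -> OtuTable:
    """Simulate one full experiment and return its :class:`OtuTable`.

    Identical config + seed gives bit-identical output. Sample names follow
    the field code (e.g. ``C27cS``), so design metadata parses downstream
    without special-casing synthetic data.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_otus

    # lognormal rank-abundance base profile; OTU1 is the most abundant taxon
    base = np.sort(rng.lognormal(0.0, config.rank_abundance_sd, size=n))[::-1]
    base /= base.sum()

    soil_eff = {
        s: np.exp(rng.normal(0.0, config.sigma_soil, size=n)) for s in _SOILS
    }
    geno_eff = {
        g: np.exp(rng.normal(0.0, config.sigma_geno, size=n)) for g in _GENOTYPES
    }

    columns: dict[str, np.ndarray] = {}
    for soil, soil_code in _SOILS.items():
        for geno, geno_code in _GENOTYPES.items():
            for rep in _REPLICATES[: config.n_replicates]:
                rhizo = base * soil_eff[soil]
                rhizo = _force_dominance(rhizo / rhizo.sum(),
                                         config.dominance["rhizosphere"])
                root = rhizo * geno_eff[geno]
                root = _force_dominance(root / root.sum(),
                                        config.dominance["root"])
                leaf = _force_dominance(root, config.dominance["leaf"])

                sample_of = {}
                root_counts = None
                for comp in ("rhizosphere", "root", "leaf", "nodule"):
                    if comp == "nodule":
                        if config.nodule_from_root:
                            # nested colonization: seed the nodule from the
                            # realized root community of the same plant
                            src = root_counts.astype(float)
                            if src.sum() == 0:
                                src = root
                            expected = _force_dominance(
                                src / src.sum(), config.dominance["nodule"]
                            )
                        else:
                            expected = _force_dominance(
                                base, config.dominance["nodule"]
                            )
                    elif comp == "rhizosphere":
                        expected = rhizo
                    elif comp == "root":
                        expected = root
                    else:
                        expected = leaf
                    depth = int(
                        np.round(
                            rng.lognormal(config.depth_log_mean, config.depth_log_sd)
                        )
                    )
                    depth = max(depth, 1)
                    alpha = config.concentration[comp] * expected
                    # Dirichlet-multinomial: overdispersed relative to plain
                    # multinomial sampling at the same expectation
                    p = rng.dirichlet(np.maximum(alpha, 1e-9))
                    counts = rng.multinomial(depth, p)
                    if comp == "root":
                        root_counts = counts
                    name = f"{soil_code}{geno_code}{rep}{_COMP_LETTER[comp]}"
                    sample_of[name] = counts
                columns.update(sample_of)

    otu_ids = [f"Otu{i + 1:04d}" for i in range(n)]
    counts = pd.DataFrame(columns, index=otu_ids)
    return OtuTable(counts)


_DEFAULT_REPLICONS = {"chromosome": 3_780_000, "pSymA": 1_570_000, "pSymB": 1_245_000}
_RPOB_LENGTH = 4_100  # bases; single-copy chromosomal marker gene


def generate_replicon_counts(
    n_samples: int,
    fraction_with_plasmid: Mapping[str, float] | float = 0.5,
    depth: int = 100_000,
    replicon_lengths: Mapping[str, int] | None = None,
    compartments: tuple = ("root", "nodule"),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-replicon read counts for the plasmid-ratio analysis.

    Reads fall on each replicon in proportion to its length times the
    fraction of cells carrying it (the chromosome is carried by every cell),
    so the expected plasmid:chromosome reads-per-megabase ratio equals
    ``fraction_with_plasmid``. ``fraction_with_plasmid`` may be a single
    proportion or a per-compartment map. Output is tidy: one row per
    sample x replicon with columns sample_id, compartment, replicon, length,
    reads, rpob_reads.
    """
    if replicon_lengths is None:
        replicon_lengths = dict(_DEFAULT_REPLICONS)
    if "chromosome" not in replicon_lengths:
        raise ValueError("replicon_lengths must include 'chromosome'")
    if not isinstance(fraction_with_plasmid, Mapping):
        fraction_with_plasmid = {c: float(fraction_with_plasmid) for c in compartments}
    for c, f in fraction_with_plasmid.items():
        if not 0 <= f <= 1:
            raise ValueError(f"fraction_with_plasmid[{c}] must be in [0,1], got {f}")
    for r, length in replicon_lengths.items():
        if length <= 0:
            raise ValueError(f"replicon length for {r!r} must be > 0")

    rng = np.random.default_rng(seed)
    rows = []
    for comp in compartments:
        frac = fraction_with_plasmid[comp]
        for i in range(n_samples):
            sid = f"{comp}_{i + 1:02d}"
            weights = {
                rep: length * (1.0 if rep == "chromosome" else frac)
                for rep, length in replicon_lengths.items()
            }
            rate = depth / sum(weights.values())
            rpob = rng.poisson(rate * _RPOB_LENGTH)
            for rep, length in replicon_lengths.items():
                reads = rng.poisson(rate * weights[rep])
                rows.append(
                    {
                        "sample_id": sid,
                        "compartment": comp,
                        "replicon": rep,
                        "length": length,
                        "reads": int(reads),
                        "rpob_reads": int(rpob),
                    }
                )
    return pd.DataFrame(rows)
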