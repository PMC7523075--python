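"""OTU count tables, sample-name design metadata, and count-matrix utilities.

The central container is :class:`OtuTable`, an OTUs x samples matrix of
non-negative integer read counts with optional per-OTU taxonomy strings and
per-sample experimental design metadata. Sample names encode the design in a
compact code — soil origin letter, genotype number, replicate letter, and a
compartment letter — e.g. ``"C96bN"`` is the nodule sample of replicate plant
``b`` of genotype G96 grown in Corsican soil.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "DesignKey",
    "OtuTable",
    "parse_sample_name",
    "read_otu_table",
    "write_otu_table",
    "filter_rare_otus",
    "to_relative_abundance",
    "subsample_counts",
]

SOIL_CODES = {"C": "Corsica", "F": "France"}
GENOTYPE_CODES = {"1": "G1", "27": "G27", "96": "G96"}
REPLICATE_CODES = ("a", "b", "c", "d", "e")
COMPARTMENT_CODES = {"L": "leaf", "N": "nodule", "R": "root", "S": "rhizosphere"}
COMPARTMENTS = ("rhizosphere", "root", "nodule", "leaf")

_NAME_RE = re.compile(r"^([A-Z])(\d+)([a-z])([A-Z])$")


@dataclass(frozen=True)
class DesignKey:
    """Parsed experimental design coordinates of one sample.

    ``plant_id`` is shared by the (up to four) compartment samples taken from
    the same physical plant, and is the pairing key for within-plant
    comparisons.
    """

    soil_origin: str
    genotype: str
    replicate: str
    compartment: str

    @property
    def plant_id(self) -> str:
        return f"{self.soil_origin}:{self.genotype}:{self.replicate}"


def parse_sample_name(name: str) -> DesignKey:
    """Decode a sample name like ``"C96bN"`` into a :class:`DesignKey`.

    The code is ``<soil><genotype><replicate><compartment>`` with soil in
    {C, F}, genotype in {1, 27, 96}, replicate in {a..e} and compartment in
    {L, N, R, S}.
    """
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(
            f"sample name {name!r} does not match <soil><genotype><replicate>"
            f"<compartment>; valid codes: soil {sorted(SOIL_CODES)}, genotype "
            f"{sorted(GENOTYPE_CODES)}, replicate {list(REPLICATE_CODES)}, "
            f"compartment {sorted(COMPARTMENT_CODES)}"
        )
    soil_c, geno_c, rep_c, comp_c = m.groups()
    if soil_c not in SOIL_CODES:
        raise ValueError(f"unknown soil code {soil_c!r}; valid: {sorted(SOIL_CODES)}")
    if geno_c not in GENOTYPE_CODES:
        raise ValueError(
            f"unknown genotype code {geno_c!r}; valid: {sorted(GENOTYPE_CODES)}"
        )
    if rep_c not in REPLICATE_CODES:
        raise ValueError(
            f"unknown replicate code {rep_c!r}; valid: {list(REPLICATE_CODES)}"
        )
    if comp_c not in COMPARTMENT_CODES:
        raise ValueError(
            f"unknown compartment code {comp_c!r}; valid: {sorted(COMPARTMENT_CODES)}"
        )
    return DesignKey(
        soil_origin=SOIL_CODES[soil_c],
        genotype=GENOTYPE_CODES[geno_c],
        replicate=rep_c,
        compartment=COMPARTMENT_CODES[comp_c],
    )


class OtuTable:
    """OTUs x samples count matrix with taxonomy and design metadata.

    Parameters
    ----------
    counts
        DataFrame (index = OTU ids, columns = sample ids) of non-negative
        integer read counts. A 2-D array plus explicit ``otu_ids`` /
        ``sample_ids`` is also accepted.
    taxonomy
        Optional per-OTU lineage strings.
    """

    def __init__(self, counts, otu_ids=None, sample_ids=None, taxonomy=None):
        if isinstance(counts, pd.DataFrame):
            df = counts.copy()
        else:
            df = pd.DataFrame(np.asarray(counts), index=otu_ids, columns=sample_ids)
        arr = df.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                bad = np.argwhere(arr != np.round(arr))[0]
                raise ValueError(
                    f"non-integer count at OTU {df.index[bad[0]]!r}, "
                    f"sample {df.columns[bad[1]]!r}"
                )
            arr = np.round(arr).astype(np.int64)
            df = pd.DataFrame(arr, index=df.index, columns=df.columns)
        if arr.size and arr.min() < 0:
            bad = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at OTU {df.index[bad[0]]!r}, "
                f"sample {df.columns[bad[1]]!r}"
            )
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].tolist()
            raise ValueError(f"duplicate OTU ids: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        df = df.astype(np.int64)
        df.index.name = None
        df.columns.name = None
        self.counts = df
        if taxonomy is not None:
            taxonomy = pd.Series(taxonomy).reindex(df.index)
        self.taxonomy = taxonomy

    # -- basic accessors -------------------------------------------------
    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def otu_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def design(self) -> pd.DataFrame:
        """Per-sample design metadata parsed from the sample names."""
        keys = [parse_sample_name(s) for s in self.sample_ids]
        return pd.DataFrame(
            {
                "soil_origin": [k.soil_origin for k in keys],
                "genotype": [k.genotype for k in keys],
                "replicate": [k.replicate for k in keys],
                "compartment": [k.compartment for k in keys],
                "plant_id": [k.plant_id for k in keys],
            },
            index=self.sample_ids,
        )

    def select_samples(self, sample_ids: Iterable[str]) -> "OtuTable":
        sub = self.counts.loc[:, list(sample_ids)]
        return OtuTable(sub, taxonomy=self.taxonomy)

    def select_compartment(self, compartment: str) -> "OtuTable":
        design = self.design()
        keep = design.index[design["compartment"] == compartment]
        if len(keep) == 0:
            raise ValueError(f"no samples in compartment {compartment!r}")
        return self.select_samples(keep)

    def __eq__(self, other) -> bool:
        return isinstance(other, OtuTable) and self.counts.equals(other.counts)

    def __repr__(self) -> str:
        return f"OtuTable({self.n_otus} OTUs x {self.n_samples} samples)"


# -- I/O -----------------------------------------------------------------

def read_otu_table(path, dialect: str = "tsv") -> OtuTable:
    """Read an OTU table from ``tsv``, mothur ``shared``, or BIOM v1 JSON.

    The TSV dialect has OTUs as rows and a header of sample names; a final
    ``taxonomy`` column is detected and split off. The mothur shared dialect
    (``label``/``Group``/``numOtus`` leading columns, samples as rows) is
    transposed to the OTUs x samples orientation on read.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        taxonomy = None
        if "taxonomy" in df.columns:
            taxonomy = df.pop("taxonomy")
        return OtuTable(_validate_cells(df), taxonomy=taxonomy)
    if dialect == "mothur-shared":
        df = pd.read_csv(path, sep="\t")
        required = {"label", "Group", "numOtus"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"mothur shared file must have columns {sorted(required)}"
            )
        counts = df.drop(columns=["label", "numOtus"]).set_index("Group").T
        counts.index.name = None
        return OtuTable(_validate_cells(counts))
    if dialect == "biom":
        return _read_biom_v1(path)
    raise ValueError(f"unknown dialect {dialect!r}; use tsv, mothur-shared or biom")


def _validate_cells(df: pd.DataFrame) -> pd.DataFrame:
    arr = df.to_numpy()
    if arr.dtype == object or not np.issubdtype(arr.dtype, np.number):
        for j, col in enumerate(df.columns):
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                row = df.index[vals.isna().to_numpy().argmax()]
                raise ValueError(
                    f"non-numeric cell at OTU {row!r}, sample {col!r}"
                )
        df = df.apply(pd.to_numeric)
    return df


def _read_biom_v1(path) -> OtuTable:
    with open(path) as fh:
        doc = json.load(fh)
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    shape = (len(otu_ids), len(sample_ids))
    mat = np.zeros(shape)
    if doc.get("matrix_type") == "dense":
        mat[:] = np.asarray(doc["data"])
    else:
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    taxonomy = None
    if doc["rows"] and doc["rows"][0].get("metadata"):
        tax = [
            "; ".join(r["metadata"].get("taxonomy", []))
            if r.get("metadata")
            else ""
            for r in doc["rows"]
        ]
        taxonomy = pd.Series(tax, index=otu_ids)
    return OtuTable(mat, otu_ids=otu_ids, sample_ids=sample_ids, taxonomy=taxonomy)


def write_otu_table(table: OtuTable, path) -> None:
    """Write in the TSV dialect (OTUs as rows; taxonomy as final column)."""
    df = table.counts.copy()
    if table.taxonomy is not None:
        df["taxonomy"] = table.taxonomy
    df.to_csv(path, sep="\t", index_label="otu_id")


# -- count-matrix utilities ---------------------------------------------

def filter_rare_otus(table: OtuTable, min_total: int = 10) -> OtuTable:
    """Drop OTUs whose dataset-wide total read count falls below ``min_total``.

    Idempotent at a fixed threshold; the sample set is never changed.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = table.otu_totals() >= min_total
    tax = table.taxonomy[keep] if table.taxonomy is not None else None
    return OtuTable(table.counts.loc[keep], taxonomy=tax)


def to_relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Per-sample relative abundances; every column sums to 1."""
    totals = table.sample_totals()
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"all-zero sample(s): {zero}")
    return table.counts / totals


def subsample_counts(column, depth: int, seed=None, rng=None) -> np.ndarray:
    """Draw ``depth`` reads without replacement from one sample's counts.

    A multivariate hypergeometric draw: the expectation of each OTU's
    subsampled count is ``depth * count/total``, and every draw sums exactly
    to ``depth``.
    """
    col = np.asarray(column, dtype=np.int64)
    total = int(col.sum())
    if depth > total:
        raise ValueError(
            f"subsampling depth {depth} exceeds sample total {total}; "
            "exclude the sample upstream"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(col, depth)


def eligible_samples(table: OtuTable, depth: int) -> list[str]:
    """Samples whose total count meets the subsampling depth; warns on drops."""
    totals = table.sample_totals()
    keep = totals.index[totals >= depth].tolist()
    dropped = totals.index[totals < depth].tolist()
    if dropped:
        warnings.warn(
            f"excluding {len(dropped)} sample(s) with total < {depth}: {dropped}",
            stacklevel=2,
        )
    return keep
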