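"""Core data containers and readers/writers for the pipeline's external formats.

The containers here are the join points between the analysis stages: a
specimen-by-variable morphometric table, an aligned DNA sequence set, labelled
distance matrices, a rooted tree, GPS points, and tip-to-area range tables.
Specimen/sequence/tip identifiers are the join key across every module;
identifier collisions are hard errors.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "MorphoTable",
    "SequenceSet",
    "DistanceMatrix",
    "GeoPoints",
    "TipRangeTable",
    "read_morpho_table",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "resolve_polytomies",
    "patristic_matrix",
]

#: variable kinds accepted in a morphometric schema
VARIABLE_KINDS = ("morphometric_SL", "morphometric_HL", "meristic", "SL")

IUPAC_DNA = set("ACGTRYSWKMBDHVN-")


class SchemaError(ValueError):
    """Raised when an input file violates a container invariant."""


# ---------------------------------------------------------------------------
# MorphoTable
# ---------------------------------------------------------------------------

@dataclass
class MorphoTable:
    """Specimens x variables matrix with group labels and per-variable typing.

    Morphometric variables are lengths in mm; meristic variables are counts on
    a half-unit grid (plates counted to the nearest half-plate).  Exactly one
    variable is flagged ``SL`` (standard length), which may never be missing
    because it is the allometric covariate used for imputation and
    standardization.  Missing cells are ``NaN``.
    """

    values: pd.DataFrame                 # index: specimen ids, columns: variables
    group_labels: pd.Series              # index aligned with values
    variable_kind: dict[str, str]        # variable -> kind
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = self.values.index
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].tolist()
            raise SchemaError(f"duplicate specimen ids: {dup}")
        if not self.group_labels.index.equals(ids):
            self.group_labels = self.group_labels.reindex(ids)
        if self.group_labels.isna().any():
            missing = ids[self.group_labels.isna()].tolist()
            raise SchemaError(f"specimens without group label: {missing}")
        unknown = set(self.variable_kind.values()) - set(VARIABLE_KINDS)
        if unknown:
            raise SchemaError(f"unknown variable kind(s): {sorted(unknown)}")
        missing_kind = [c for c in self.values.columns if c not in self.variable_kind]
        if missing_kind:
            raise SchemaError(f"variables without a declared kind: {missing_kind}")
        sl_cols = [c for c, k in self.variable_kind.items() if k == "SL"]
        if len(sl_cols) != 1:
            raise SchemaError(f"exactly one SL variable required, got {sl_cols}")
        self._sl_col = sl_cols[0]
        if self.values[self._sl_col].isna().any():
            bad = ids[self.values[self._sl_col].isna()].tolist()
            raise SchemaError(f"SL missing for specimens: {bad}")
        for col, kind in self.variable_kind.items():
            if kind == "meristic":
                v = self.values[col].dropna()
                if not np.allclose(v * 2, np.round(v * 2), atol=1e-9):
                    raise SchemaError(f"meristic column {col!r} not on the 0.5 grid")

    # -- convenience views -------------------------------------------------
    @property
    def specimen_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def variable_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sl_column(self) -> str:
        return self._sl_col

    @property
    def sl(self) -> pd.Series:
        return self.values[self._sl_col]

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def morphometric_columns(self) -> list[str]:
        return [c for c, k in self.variable_kind.items()
                if k in ("morphometric_SL", "morphometric_HL")]

    def meristic_columns(self) -> list[str]:
        return [c for c, k in self.variable_kind.items() if k == "meristic"]

    def subset(self, ids) -> "MorphoTable":
        ids = list(ids)
        return MorphoTable(self.values.loc[ids].copy(),
                           self.group_labels.loc[ids].copy(),
                           dict(self.variable_kind), dict(self.meta))

    def write_csv(self, path, group_column: str = "group") -> None:
        out = self.values.copy()
        out.insert(0, group_column, self.group_labels)
        out.to_csv(path, na_rep="NA", index_label="specimen_id")


def read_morpho_table(path, schema) -> MorphoTable:
    """Read a specimen table from CSV.

    ``schema`` is a mapping (or path to a JSON file) with keys ``id_column``,
    ``group_column`` and ``kinds`` (variable name -> kind).  Empty cells and
    "NA" (case-insensitive) are parsed as missing.
    """
    if isinstance(schema, (str, bytes)) or hasattr(schema, "__fspath__"):
        with open(schema) as fh:
            schema = json.load(fh)
    id_col = schema.get("id_column", "specimen_id")
    group_col = schema.get("group_column", "group")
    kinds = dict(schema["kinds"])

    df = pd.read_csv(path, dtype={id_col: str, group_col: str},
                     na_values=["NA", "na", "Na", ""], keep_default_na=False)
    if id_col not in df.columns or group_col not in df.columns:
        raise SchemaError(f"CSV must contain {id_col!r} and {group_col!r} columns")
    df = df.set_index(id_col)
    groups = df[group_col]
    values = df[[c for c in df.columns if c in kinds]].astype(float)
    extra = set(kinds) - set(values.columns)
    if extra:
        raise SchemaError(f"schema names absent columns: {sorted(extra)}")
    return MorphoTable(values, groups, kinds)


# ---------------------------------------------------------------------------
# SequenceSet
# ---------------------------------------------------------------------------

@dataclass
class SequenceSet:
    """An aligned set of DNA sequences with optional group (species) labels."""

    ids: list[str]
    sequences: list[str]
    group_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            seen: set[str] = set()
            dup = [i for i in self.ids if i in seen or seen.add(i)]
            raise SchemaError(f"duplicate sequence ids: {dup}")
        if len(self.sequences) != len(self.ids):
            raise SchemaError("ids and sequences differ in length")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise SchemaError(f"ragged alignment: lengths {sorted(lengths)}")
        self.sequences = [s.upper() for s in self.sequences]
        for sid, s in zip(self.ids, self.sequences):
            bad = set(s) - IUPAC_DNA
            if bad:
                raise SchemaError(f"illegal characters {sorted(bad)} in {sid!r}")
        if self.group_labels is not None and len(self.group_labels) != len(self.ids):
            raise SchemaError("group_labels length mismatch")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def alignment_length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0


def read_fasta(path, id_group_sep: str | None = "|") -> SequenceSet:
    """Read an aligned FASTA.  Headers of the form ``id|group`` (configurable
    separator) populate group labels; otherwise labels are None."""
    ids, seqs, groups = [], [], []
    any_group = False
    for rec in SeqIO.parse(path, "fasta"):
        header = rec.id
        if id_group_sep and id_group_sep in header:
            sid, grp = header.split(id_group_sep, 1)
            any_group = True
        else:
            sid, grp = header, ""
        ids.append(sid)
        groups.append(grp)
        seqs.append(str(rec.seq))
    return SequenceSet(ids, seqs, groups if any_group else None)


def write_fasta(seqset: SequenceSet, path, id_group_sep: str = "|") -> None:
    records = []
    for i, (sid, s) in enumerate(zip(seqset.ids, seqset.sequences)):
        header = sid
        if seqset.group_labels is not None:
            header = f"{sid}{id_group_sep}{seqset.group_labels[i]}"
        records.append(SeqRecord(Seq(s), id=header, description=""))
    SeqIO.write(records, path, "fasta")


# ---------------------------------------------------------------------------
# DistanceMatrix
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Labelled symmetric non-negative matrix with zero diagonal.

    Entries may be NaN to flag an undefined distance (e.g. a K2P pair whose
    log argument is non-positive); NaNs are excluded from summaries
    downstream.
    """

    labels: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.labels)
        if self.D.shape != (n, n):
            raise SchemaError(f"matrix shape {self.D.shape} != ({n},{n})")
        if len(set(self.labels)) != n:
            raise SchemaError("duplicate labels in distance matrix")
        with np.errstate(invalid="ignore"):
            if not np.allclose(np.nan_to_num(self.D), np.nan_to_num(self.D.T),
                               atol=1e-10):
                raise SchemaError("asymmetric distance matrix")
            if np.nanmax(np.abs(np.diag(self.D))) > 1e-12:
                raise SchemaError("nonzero diagonal")
            if np.nanmin(self.D) < -1e-12:
                raise SchemaError("negative distances")

    def __len__(self) -> int:
        return len(self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.labels, columns=self.labels)

    def to_long(self) -> pd.DataFrame:
        """Long-format (row, col, distance) table of the upper triangle,
        suitable for levelplot-style rendering."""
        rows = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append((self.labels[i], self.labels[j], self.D[i, j]))
        return pd.DataFrame(rows, columns=["a", "b", "distance"])

    def submatrix(self, labels) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.D[np.ix_(idx, idx)])

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="")

    @classmethod
    def read_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(c) for c in df.columns], df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def read_newick(path_or_string) -> dendropy.Tree:
    """Read a rooted Newick tree (path or literal string)."""
    s = path_or_string
    if isinstance(s, str) and s.strip().startswith("(") and s.strip().endswith(";"):
        tree = dendropy.Tree.get(data=s, schema="newick",
                                 preserve_underscores=True)
    else:
        tree = dendropy.Tree.get(path=s, schema="newick",
                                 preserve_underscores=True)
    for e in tree.preorder_edge_iter():
        if e.length is not None and e.length < 0:
            raise SchemaError(f"negative branch length {e.length}")
    labels = [t.taxon.label for t in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise SchemaError("duplicate tip labels")
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


def resolve_polytomies(tree: dendropy.Tree, mode: str = "zero_branch_ladder",
                       seed: int | None = None) -> dendropy.Tree:
    """Resolve polytomies into bifurcations by inserting zero-length branches.

    ``zero_branch_ladder`` is deterministic (caterpillar resolution in child
    order); ``zero_branch_random`` shuffles the resolution under ``seed``.
    Either way the patristic distance matrix is unchanged because every
    inserted branch has length zero.
    """
    if mode not in ("zero_branch_ladder", "zero_branch_random"):
        raise ValueError(f"unknown mode {mode!r}")
    tree = tree.clone(depth=1)
    rng = random.Random(seed) if mode == "zero_branch_random" else None
    tree.resolve_polytomies(limit=2, update_bipartitions=False, rng=rng)
    for e in tree.preorder_edge_iter():
        if e.length is None and e.head_node is not tree.seed_node:
            e.length = 0.0
    return tree


def patristic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Sum of branch lengths along the tip-to-tip path, for every tip pair."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(labels, D)


# ---------------------------------------------------------------------------
# GeoPoints
# ---------------------------------------------------------------------------

@dataclass
class GeoPoints:
    """Specimen GPS coordinates in decimal degrees."""

    ids: list[str]
    latitude: np.ndarray
    longitude: np.ndarray

    def __post_init__(self) -> None:
        self.latitude = np.asarray(self.latitude, dtype=float)
        self.longitude = np.asarray(self.longitude, dtype=float)
        if len(set(self.ids)) != len(self.ids):
            raise SchemaError("duplicate point ids")
        if not (len(self.ids) == len(self.latitude) == len(self.longitude)):
            raise SchemaError("ids/lat/lon length mismatch")
        if np.any(np.abs(self.latitude) > 90):
            raise SchemaError("latitude out of [-90, 90]")
        if np.any(np.abs(self.longitude) > 180):
            raise SchemaError("longitude out of [-180, 180]")

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, ids) -> "GeoPoints":
        pos = {i: k for k, i in enumerate(self.ids)}
        idx = [pos[i] for i in ids]
        return GeoPoints(list(ids), self.latitude[idx], self.longitude[idx])

    @classmethod
    def read_csv(cls, path) -> "GeoPoints":
        df = pd.read_csv(path, dtype={"id": str})
        return cls(df["id"].tolist(), df["latitude"].to_numpy(),
                   df["longitude"].to_numpy())

    def write_csv(self, path) -> None:
        pd.DataFrame({"id": self.ids, "latitude": self.latitude,
                      "longitude": self.longitude}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# TipRangeTable
# ---------------------------------------------------------------------------

@dataclass
class TipRangeTable:
    """Tip id -> set of occupied area codes, against a declared area list."""

    areas: list[str]
    ranges: dict[str, frozenset]

    def __post_init__(self) -> None:
        declared = set(self.areas)
        fixed = {}
        for tip, rng in self.ranges.items():
            rng = frozenset(rng)
            if not rng:
                raise SchemaError(f"empty range for tip {tip!r}")
            if not rng <= declared:
                raise SchemaError(f"undeclared areas {sorted(rng - declared)} "
                                  f"for tip {tip!r}")
            fixed[tip] = rng
        self.ranges = fixed

    def check_covers(self, tree: dendropy.Tree) -> None:
        tips = {t.taxon.label for t in tree.leaf_node_iter()}
        uncovered = tips - set(self.ranges)
        if uncovered:
            raise SchemaError(f"tree tips without ranges: {sorted(uncovered)}")

    @classmethod
    def read_tsv(cls, path, areas) -> "TipRangeTable":
        ranges = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                tip, codes = line.split("\t")
                ranges[tip] = frozenset(codes.split(","))
        return cls(list(areas), ranges)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for tip in sorted(self.ranges):
                fh.write(f"{tip}\t{','.join(sorted(self.ranges[tip]))}\n")
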