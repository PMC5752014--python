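"""Orchestration of the integrative workflow: restrict the three data sources
to their common individuals, run the preliminary ordinations, the pairwise RV
permutation tests, and the multiple co-inertia analysis, and emit a
compromise-table report.

The morphometric table enters the multi-table stage with within-population
variability removed: specimens are replaced by their population-mean rows,
which are then replicated back to the individuals so the three tables stay
row-conformable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import morphometrics, multitable, ordination
from .tables import (GeoPoints, MorphoTable, read_morpho_table, read_newick,
                     resolve_polytomies)

__all__ = ["restrict_common", "IntegrativeReport", "run_integrative",
           "integrative_analysis", "relative_abundance", "StudyConfig"]

logger = logging.getLogger("integrotax")


def restrict_common(morpho: MorphoTable, tree_or_ids, gps: GeoPoints):
    """Restrict the three sources to individuals present in all of them.

    ``tree_or_ids`` may be a dendropy tree (tip labels), a SequenceSet, or a
    plain id collection. Returns ``(morpho, ids, gps, dropped)`` where
    ``ids`` is the common id list (morpho row order) and ``dropped`` maps
    source name to the ids it lost.
    """
    if hasattr(tree_or_ids, "leaf_node_iter"):
        other_ids = [t.taxon.label for t in tree_or_ids.leaf_node_iter()]
    elif hasattr(tree_or_ids, "ids"):
        other_ids = list(tree_or_ids.ids)
    else:
        other_ids = list(tree_or_ids)
    sets = {"morpho": set(morpho.specimen_ids),
            "tree": set(other_ids),
            "gps": set(gps.ids)}
    common = sets["morpho"] & sets["tree"] & sets["gps"]
    if not common:
        raise ValueError("no individuals shared by the three sources")
    ids = [i for i in morpho.specimen_ids if i in common]
    dropped = {k: sorted(v - common) for k, v in sets.items()}
    for k, v in dropped.items():
        if v:
            logger.warning("restrict_common: dropping %d id(s) from %s", len(v), k)
    return morpho.subset(ids), ids, gps.subset(ids), dropped


def population_mean_rows(X: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Replace each specimen row by its population mean (rows replicated back
    to specimens so downstream tables stay row-conformable)."""
    means = X.groupby(groups.reindex(X.index)).transform("mean")
    return means


@dataclass
class StudyConfig:
    """Paths and options for a full integrative run."""

    morpho_csv: str
    morpho_schema: str
    tree_newick: str
    gps_csv: str
    out_dir: str
    min_sl: float = 20.0
    n_perm: int = 9999
    seed: int = 0
    correction: str = "cailliez"
    mcoa_axes: int = 2
    mcoa_weights: str = "uniform"

    @classmethod
    def from_json(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class IntegrativeReport:
    """Everything the multi-table stage produced."""

    ids: list
    rv_matrix: pd.DataFrame          # RV upper triangle, p-values lower
    rv_pvalues: pd.DataFrame
    mcoa: multitable.MCOAResults
    ordinations: dict                # name -> Ordination
    dropped: dict
    manifest: dict = field(default_factory=dict)

    def table3_style(self) -> pd.DataFrame:
        """Inertia / Co-Inertia / Cos2 / Cov2 blocks, tables as columns."""
        m = self.mcoa
        blocks = {"Inertia": m.table_inertia, "Co-Inertia": m.coinertia,
                  "Cos2": m.cos2, "Cov2": m.cov2}
        rows = []
        for name, df in blocks.items():
            for ax in df.columns:
                rows.append(pd.Series(df[ax], name=(name, ax)))
        out = pd.DataFrame(rows)
        out.index = pd.MultiIndex.from_tuples(out.index, names=["block", "axis"])
        return out

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.rv_matrix.to_csv(out / "rv_tests.tsv", sep="\t")
        self.rv_pvalues.to_csv(out / "rv_pvalues.tsv", sep="\t")
        self.table3_style().to_csv(out / "table3_style.tsv", sep="\t")
        self.mcoa.compromise_scores.to_csv(out / "compromise_scores.tsv", sep="\t")
        for name, sc in self.mcoa.table_scores.items():
            sc.to_csv(out / f"scores_{name}.tsv", sep="\t")
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2)


def integrative_analysis(morpho: MorphoTable, tree, gps: GeoPoints,
                         min_sl: float = 20.0, n_perm: int = 9999,
                         seed: int = 0, correction: str = "cailliez",
                         mcoa_axes: int = 2,
                         mcoa_weights="uniform") -> IntegrativeReport:
    """Run the three preliminary analyses, RV tests and MCOA on in-memory
    objects (the object-level core of :func:`run_integrative`)."""
    t0 = time.time()
    morpho = morphometrics.filter_juveniles(morpho, min_sl=min_sl)
    morpho_r, ids, gps_r, dropped = restrict_common(morpho, tree, gps)

    # morphometric table: impute, standardize, population means
    imputed = morphometrics.impute_missing(morpho_r)
    Z = morphometrics.standardize(imputed)
    Zpop = population_mean_rows(Z, morpho_r.group_labels)
    morpho_ord = ordination.pca(Zpop)

    # phylogeny: patristic distances restricted to the common tips
    patr = ordination.patristic(tree).submatrix(ids)
    phylo_ord = ordination.pcoa(patr, correction=correction)

    geo = ordination.geodesic(gps_r)
    geo_ord = ordination.pcoa(geo, correction=correction)

    # each preliminary score table enters with total inertia scaled to 1 so the
    # compromise decomposition is unit-free (geodesic meters would otherwise
    # swamp substitution-scale patristic axes)
    def unit_inertia(df: pd.DataFrame) -> pd.DataFrame:
        X = df - df.mean(axis=0)
        total = float((X.to_numpy() ** 2).sum() / len(X))
        return X / np.sqrt(total)

    tables = {"phylogeny": unit_inertia(phylo_ord.row_scores.loc[ids]),
              "morphology": unit_inertia(morpho_ord.row_scores.loc[ids]),
              "geography": unit_inertia(geo_ord.row_scores.loc[ids])}

    names = list(tables)
    rv_m = pd.DataFrame(np.nan, index=names, columns=names)
    rv_p = pd.DataFrame(np.nan, index=names, columns=names)
    rng = np.random.default_rng(seed)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = multitable.rv_test(tables[a], tables[b], n_perm=n_perm,
                                     seed=int(rng.integers(2 ** 31)))
            rv_m.loc[a, b] = rv_m.loc[b, a] = res.rv
            rv_p.loc[a, b] = rv_p.loc[b, a] = res.p_value
            logger.info("RV(%s, %s) = %.4f (p = %.4g)", a, b, res.rv, res.p_value)

    mc = multitable.MCOA(tables, weights=mcoa_weights).fit(n_axes=mcoa_axes)
    logger.info("integrative analysis finished in %.1f s", time.time() - t0)
    return IntegrativeReport(ids=ids, rv_matrix=rv_m, rv_pvalues=rv_p,
                             mcoa=mc,
                             ordinations={"phylogeny": phylo_ord,
                                          "morphology": morpho_ord,
                                          "geography": geo_ord},
                             dropped=dropped)


def _file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_integrative(config: StudyConfig) -> IntegrativeReport:
    """File-level front end: load the inputs named in ``config``, run
    :func:`integrative_analysis`, and write the report with a manifest."""
    morpho = read_morpho_table(config.morpho_csv, config.morpho_schema)
    tree = read_newick(config.tree_newick)
    tree = resolve_polytomies(tree)
    gps = GeoPoints.read_csv(config.gps_csv)
    report = integrative_analysis(
        morpho, tree, gps, min_sl=config.min_sl, n_perm=config.n_perm,
        seed=config.seed, correction=config.correction,
        mcoa_axes=config.mcoa_axes, mcoa_weights=config.mcoa_weights)
    report.manifest = {
        "seed": config.seed, "n_perm": config.n_perm,
        "inputs": {k: _file_hash(getattr(config, k))
                   for k in ("morpho_csv", "tree_newick", "gps_csv")},
        "n_common": len(report.ids),
    }
    report.write(config.out_dir)
    return report


def relative_abundance(collection: pd.DataFrame, k: float = 0.0) -> pd.DataFrame:
    """Per-locality species proportions from (species, locality, n_specimens)
    rows; a readability constant ``k`` may be added to each count before the
    share computation (occurrence + abundance convention).

    Returns a long DataFrame with a ``proportion`` column; the overall share
    of each species across all specimens is attached as ``df.attrs['overall']``.
    """
    req = {"species", "locality", "n_specimens"}
    if not req <= set(collection.columns):
        raise ValueError(f"collection table needs columns {sorted(req)}")
    if (collection["n_specimens"] < 0).any():
        raise ValueError("negative counts")
    df = collection.copy()
    df["adjusted"] = df["n_specimens"] + k
    totals = df.groupby("locality")["adjusted"].transform("sum")
    df["proportion"] = df["adjusted"] / totals
    grand = df.groupby("species")["n_specimens"].sum()
    df.attrs["overall"] = (grand / grand.sum()).to_dict()
    return df.drop(columns="adjusted")
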