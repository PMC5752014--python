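"""DNA-barcode divergence analysis: K2P distances, group summaries,
barcoding-gap diagnostics and identification-threshold optimization.

The Kimura two-parameter (K2P) distance separates transition (P) and
transversion (Q) proportions:

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

computed with *pairwise deletion*: a site contributes to a pair only when both
sequences carry an unambiguous A/C/G/T there. Ambiguity codes never partially
match (R vs A is deleted, not half-counted). When the argument of either log
is non-positive, or no comparable site remains, the distance is undefined and
propagates as NaN, excluded from summaries.

The barcoding gap for an individual is the difference between its closest
heterospecific distance and its furthest conspecific distance; a non-positive
gap flags an individual the barcode cannot identify unambiguously. Threshold
optimization scans a distance grid and classifies each individual by its
sub-threshold neighbour set, reporting per-threshold false positives/negatives
and the threshold(s) minimizing the cumulative error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import DistanceMatrix, SequenceSet

__all__ = ["k2p", "k2p_matrix", "group_distance_summary",
           "GroupDistanceSummary", "barcode_gap", "GapRecord",
           "optimize_threshold", "ThresholdTable"]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_UNAMBIGUOUS = frozenset("ACGT")


def k2p(seq_a: str, seq_b: str) -> float:
    """K2P distance (substitutions/site) between two aligned sequences.

    Returns ``nan`` when undefined (saturated divergence or no shared
    unambiguous sites).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(f"length mismatch: {len(seq_a)} vs {len(seq_b)}")
    n = transitions = transversions = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a not in _UNAMBIGUOUS or b not in _UNAMBIGUOUS:
            continue
        n += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            transitions += 1
        else:
            transversions += 1
    if n == 0:
        return math.nan
    P = transitions / n
    Q = transversions / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return math.nan
    return -0.5 * math.log(w1 * math.sqrt(w2))


def _encode(seqs: list[str]) -> np.ndarray:
    """Map sequences to integer codes: A=0 G=1 C=2 T=3, anything else -1."""
    lut = np.full(256, -1, dtype=np.int8)
    for i, c in enumerate("AGCT"):
        lut[ord(c)] = i
    arr = np.frombuffer("".join(seqs).upper().encode(), dtype=np.uint8)
    return lut[arr].reshape(len(seqs), -1)


def k2p_matrix(seqs: SequenceSet) -> DistanceMatrix:
    """Symmetric matrix of pairwise K2P distances for an aligned set.

    Undefined pairs are NaN; a warning reports their count.
    """
    codes = _encode(seqs.sequences)
    m = len(seqs)
    D = np.zeros((m, m))
    purine = codes <= 1          # A, G
    valid = codes >= 0
    n_undefined = 0
    for i in range(m):
        for j in range(i + 1, m):
            both = valid[i] & valid[j]
            n = int(both.sum())
            if n == 0:
                D[i, j] = D[j, i] = np.nan
                n_undefined += 1
                continue
            diff = both & (codes[i] != codes[j])
            ts = int((diff & (purine[i] == purine[j])).sum())
            tv = int(diff.sum()) - ts
            w1 = 1.0 - (2.0 * ts + tv) / n
            w2 = 1.0 - 2.0 * tv / n
            if w1 <= 0 or w2 <= 0:
                D[i, j] = D[j, i] = np.nan
                n_undefined += 1
            else:
                D[i, j] = D[j, i] = -0.5 * math.log(w1 * math.sqrt(w2))
    if n_undefined:
        warnings.warn(f"{n_undefined} pair(s) with undefined K2P distance "
                      "(excluded from summaries)")
    return DistanceMatrix(list(seqs.ids), D)


# ---------------------------------------------------------------------------
# group summaries
# ---------------------------------------------------------------------------

@dataclass
class GroupDistanceSummary:
    within: np.ndarray               # pooled within-group distances
    between: np.ndarray              # pooled between-group distances
    per_pair: pd.DataFrame           # group_a, group_b, n, min, mean, max
    n_undefined: int

    @staticmethod
    def _stats(v: np.ndarray) -> dict:
        if v.size == 0:
            return {"n": 0, "min": math.nan, "mean": math.nan, "max": math.nan}
        return {"n": int(v.size), "min": float(v.min()),
                "mean": float(v.mean()), "max": float(v.max())}

    @property
    def within_stats(self) -> dict:
        return self._stats(self.within)

    @property
    def between_stats(self) -> dict:
        return self._stats(self.between)

    def summary(self) -> str:
        w, b = self.within_stats, self.between_stats
        return ("K2P group-distance summary\n"
                f"within-group :  n={w['n']}  min={w['min']:.4f} "
                f"mean={w['mean']:.4f} max={w['max']:.4f}\n"
                f"between-group:  n={b['n']}  min={b['min']:.4f} "
                f"mean={b['mean']:.4f} max={b['max']:.4f}")


def group_distance_summary(D: DistanceMatrix, labels) -> GroupDistanceSummary:
    """Pooled within/between distance lists plus per-group-pair statistics.

    Groups of size one contribute no within-group distances. NaN (undefined)
    entries are excluded and counted.
    """
    labels = list(labels)
    if len(labels) != len(D):
        raise ValueError("one label per individual required")
    lab = np.asarray(labels)
    n = len(D)
    iu = np.triu_indices(n, k=1)
    d = D.D[iu]
    same = lab[iu[0]] == lab[iu[1]]
    defined = ~np.isnan(d)
    within = d[same & defined]
    between = d[~same & defined]

    rows = []
    groups = sorted(set(labels))
    for a_i, ga in enumerate(groups):
        for gb in groups[a_i:]:
            if ga == gb:
                mask = same & (lab[iu[0]] == ga)
            else:
                mask = (~same
                        & (((lab[iu[0]] == ga) & (lab[iu[1]] == gb))
                           | ((lab[iu[0]] == gb) & (lab[iu[1]] == ga))))
            v = d[mask & defined]
            rows.append({"group_a": ga, "group_b": gb,
                         **GroupDistanceSummary._stats(v)})
    return GroupDistanceSummary(within, between, pd.DataFrame(rows),
                                int((~defined).sum()))


# ---------------------------------------------------------------------------
# barcoding gap
# ---------------------------------------------------------------------------

@dataclass
class GapRecord:
    """Per-individual barcoding-gap diagnostic.

    ``gap = min_inter - max_intra``; non-positive means the barcode gap is
    absent for this individual.
    """

    id: str
    max_intra: float
    min_inter: float

    @property
    def gap(self) -> float:
        return self.min_inter - self.max_intra

    @property
    def has_gap(self) -> bool:
        return self.gap > 0


def barcode_gap(D: DistanceMatrix, labels) -> tuple[list[GapRecord], list[str]]:
    """One GapRecord per individual having at least one conspecific.

    Returns ``(records, singletons)`` where singletons are ids whose label has
    a single member (no conspecific, so no gap is defined).
    """
    labels = list(labels)
    lab = np.asarray(labels)
    records, singletons = [], []
    for i, sid in enumerate(D.labels):
        conspecific = (lab == lab[i])
        conspecific[i] = False
        if not conspecific.any():
            singletons.append(sid)
            continue
        intra = D.D[i, conspecific]
        inter = D.D[i, ~conspecific & (np.arange(len(D)) != i)]
        intra = intra[~np.isnan(intra)]
        inter = inter[~np.isnan(inter)]
        if intra.size == 0 or inter.size == 0:
            singletons.append(sid)
            continue
        records.append(GapRecord(sid, float(intra.max()), float(inter.min())))
    return records, singletons


# ---------------------------------------------------------------------------
# threshold optimization
# ---------------------------------------------------------------------------

@dataclass
class ThresholdTable:
    """Per-threshold identification counts and the optimal threshold(s).

    At threshold ``t`` an individual's neighbour set is every other individual
    within K2P distance ``t``.  An individual without conspecifics in the data
    is a true negative if its neighbour set is empty, else a false positive.
    An individual with conspecifics is a false negative if the set is empty, a
    true positive if the set contains only conspecifics, and a false positive
    otherwise. ``cumulative_error = false_pos + false_neg``.
    """

    table: pd.DataFrame     # threshold, true_pos, true_neg, false_pos, false_neg, cumulative_error
    optima: list[float]     # all minimizing thresholds, ascending

    @property
    def optimum(self) -> float:
        return self.optima[0]

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def default_grid(start: float = 0.001, stop: float = 0.10,
                 step: float = 0.001) -> np.ndarray:
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)


def optimize_threshold(D: DistanceMatrix, labels,
                       grid=None) -> ThresholdTable:
    """Scan a threshold grid and classify each individual (see ThresholdTable)."""
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly ascending")
    labels = list(labels)
    lab = np.asarray(labels)
    n = len(D)
    Dm = D.D.copy()
    np.fill_diagonal(Dm, np.nan)

    rows = []
    for t in grid:
        tp = tn = fp = fn = 0
        for i in range(n):
            neighbours = np.flatnonzero(~np.isnan(Dm[i]) & (Dm[i] <= t))
            has_conspecific = np.any((lab == lab[i])
                                     & (np.arange(n) != i))
            if not has_conspecific:
                if neighbours.size == 0:
                    tn += 1
                else:
                    fp += 1
            else:
                if neighbours.size == 0:
                    fn += 1
                elif np.all(lab[neighbours] == lab[i]):
                    tp += 1
                else:
                    fp += 1
        rows.append({"threshold": float(t), "true_pos": tp, "true_neg": tn,
                     "false_pos": fp, "false_neg": fn,
                     "cumulative_error": fp + fn})
    table = pd.DataFrame(rows)
    best = table["cumulative_error"].min()
    optima = table.loc[table["cumulative_error"] == best, "threshold"].tolist()
    return ThresholdTable(table, sorted(optima))
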