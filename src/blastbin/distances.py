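"""Pairwise sample distances from count tables: ecological indices + UniFrac.

Six ecological indices are computed on column-relative abundances
(x, y the two samples' relative profiles over rows i):

* Bray-Curtis      sum|x_i - y_i| / sum(x_i + y_i)
* Euclidean        sqrt(sum (x_i - y_i)^2)
* Hellinger        sqrt(sum (sqrt x_i - sqrt y_i)^2)
* Chi-square       sqrt(sum (x_i - y_i)^2 / w_i), w_i the row's mean
                   relative abundance over all samples (zero-mass rows drop)
* Kulczynski       1 - 1/2 (sum min(x,y)/sum x + sum min(x,y)/sum y)
* Goodall          probabilistic similarity: per row, the pair's agreement
                   1 - |x_i - y_i|/range_i is converted to the fraction
                   p_i of all sample pairs at least that similar; the p_i
                   are Fisher-combined (chi2 = -2 sum ln p_i on 2m d.f.)
                   and the distance is the upper-tail probability, so
                   unusually high agreement across many rows -> small
                   distance.  With no variable rows the samples are
                   indistinguishable and the distance is 0 by convention.

UniFrac is computed on the hierarchy with unit branch lengths; every
non-root node contributes the branch to its parent, whose subtree mass is
the total count assigned at or below it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import chi2

from .errors import DegenerateInputError, FormatError
from .profiles import ComparisonTable, normalize
from .reference import Hierarchy

__all__ = [
    "DistanceMatrix",
    "ECOLOGICAL_INDICES",
    "ecological_distance",
    "unifrac",
    "export_network",
    "read_phylip",
]


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal matrix of pairwise sample distances."""

    sample_ids: list[str]
    values: np.ndarray
    name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match sample count")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.sample_ids.index(pair[0])
        j = self.sample_ids.index(pair[1])
        return float(self.values[i, j])


def _relative(table: ComparisonTable) -> tuple[np.ndarray, list[str]]:
    table = table.drop_bins()
    if len(table.sample_ids) < 2:
        raise DegenerateInputError("need at least 2 samples for a distance matrix")
    rel = normalize(table, "relative")
    return rel.data.to_numpy(dtype=float), list(table.sample_ids)


def _bray_curtis(X: np.ndarray, i: int, j: int) -> float:
    x, y = X[:, i], X[:, j]
    denom = (x + y).sum()
    return float(np.abs(x - y).sum() / denom) if denom else 0.0


def _euclidean(X: np.ndarray, i: int, j: int) -> float:
    return float(np.sqrt(((X[:, i] - X[:, j]) ** 2).sum()))


def _hellinger(X: np.ndarray, i: int, j: int) -> float:
    return float(np.sqrt(((np.sqrt(X[:, i]) - np.sqrt(X[:, j])) ** 2).sum()))


def _chi_square(X: np.ndarray, i: int, j: int) -> float:
    w = X.mean(axis=1)
    keep = w > 0
    x, y = X[keep, i], X[keep, j]
    return float(np.sqrt(((x - y) ** 2 / w[keep]).sum()))


def _kulczynski(X: np.ndarray, i: int, j: int) -> float:
    x, y = X[:, i], X[:, j]
    m = np.minimum(x, y).sum()
    sx, sy = x.sum(), y.sum()
    if sx == 0 or sy == 0:
        return 0.0
    return float(1.0 - 0.5 * (m / sx + m / sy))


def _goodall_matrix(X: np.ndarray) -> np.ndarray:
    n = X.shape[1]
    pairs = [(j, k) for j in range(n) for k in range(j + 1, n)]
    rng = X.max(axis=1) - X.min(axis=1)
    rows = np.nonzero(rng > 0)[0]
    m = len(rows)
    out = np.zeros((n, n))
    if m == 0:
        return out  # all columns identical: perfectly similar
    # s[i, p]: similarity of pair p in row i
    s = np.empty((m, len(pairs)))
    for pi, (j, k) in enumerate(pairs):
        s[:, pi] = 1.0 - np.abs(X[rows, j] - X[rows, k]) / rng[rows]
    # p_i(pair) = fraction of pairs with similarity >= this pair's
    chi = np.zeros(len(pairs))
    for ri in range(m):
        order = s[ri]
        p = (order[None, :] >= order[:, None] - 1e-12).mean(axis=1)
        chi += -2.0 * np.log(p)
    dist = chi2.sf(chi, df=2 * m)
    for pi, (j, k) in enumerate(pairs):
        out[j, k] = out[k, j] = dist[pi]
    return out


_PAIRWISE = {
    "bray-curtis": _bray_curtis,
    "euclidean": _euclidean,
    "hellinger": _hellinger,
    "chi-square": _chi_square,
    "kulczynski": _kulczynski,
}

ECOLOGICAL_INDICES = ("goodall", "bray-curtis", "euclidean", "hellinger", "chi-square", "kulczynski")


def ecological_distance(table: ComparisonTable, index: str) -> DistanceMatrix:
    """Pairwise distances between the table's samples under one index.

    Counts are converted to column-relative abundances internally; bin rows
    are excluded.  Rows should be at one hierarchy level (e.g. the role
    table) so that no read is counted both at a node and its ancestor.
    """
    if index not in ECOLOGICAL_INDICES:
        raise ValueError(
            f"unknown index {index!r}; expected one of {', '.join(ECOLOGICAL_INDICES)}"
        )
    X, samples = _relative(table)
    n = len(samples)
    if index == "goodall":
        values = _goodall_matrix(X)
    else:
        fn = _PAIRWISE[index]
        values = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                values[i, j] = values[j, i] = fn(X, i, j)
    return DistanceMatrix(samples, values, index)


def unifrac(
    table: ComparisonTable, h: Hierarchy, variant: str = "unweighted"
) -> DistanceMatrix:
    """UniFrac between samples over the hierarchy (unit branch lengths).

    ``table`` holds per-node *assigned* counts (rows are node ids of
    ``h``); subtree masses are accumulated here.  Unweighted: the fraction
    of read-carrying branches unique to one sample.  Weighted-normalized:
    sum_b |A_b/A_T - B_b/B_T| / sum_b (A_b/A_T + B_b/B_T).
    """
    if variant not in ("unweighted", "weighted-normalized"):
        raise ValueError(f"unknown UniFrac variant {variant!r}")
    table = table.drop_bins()
    samples = table.sample_ids
    if len(samples) < 2:
        raise DegenerateInputError("need at least 2 samples for a distance matrix")
    for row in table.data.index:
        if row not in h:
            raise FormatError(f"table row {row!r} is not a node of the hierarchy")
    totals = table.data.sum(axis=0)
    zero = [s for s, t in totals.items() if t == 0]
    if zero:
        raise DegenerateInputError("zero-mass sample(s): " + ", ".join(map(str, zero)))

    # subtree mass per (branch, sample); a branch is any non-root node
    branches = [n for n in h.dfs() if n != h.root]
    mass = {n: np.zeros(len(samples)) for n in h.nodes}
    for row in table.data.index:
        mass[row] = mass[row] + table.data.loc[row].to_numpy(dtype=float)
    for node in sorted(h.nodes, key=h.depth, reverse=True):
        if node != h.root:
            mass[h.parent[node]] = mass[h.parent[node]] + mass[node]

    n = len(samples)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if variant == "unweighted":
                unique = shared = 0
                for b in branches:
                    a_has, b_has = mass[b][i] > 0, mass[b][j] > 0
                    if a_has or b_has:
                        shared += 1
                        if a_has != b_has:
                            unique += 1
                values[i, j] = values[j, i] = unique / shared if shared else 0.0
            else:
                num = den = 0.0
                ai, aj = totals.iloc[i], totals.iloc[j]
                for b in branches:
                    pa, pb = mass[b][i] / ai, mass[b][j] / aj
                    num += abs(pa - pb)
                    den += pa + pb
                values[i, j] = values[j, i] = num / den if den else 0.0
    name = "unifrac" if variant == "unweighted" else "weighted-unifrac"
    return DistanceMatrix(samples, values, name)


# -- matrix export -------------------------------------------------------


def export_network(dm: DistanceMatrix, path: str | Path, format: str = "phylip-matrix") -> None:
    """Write a distance matrix for external network/ordination tools.

    Formats: ``phylip-matrix`` (square, header line = sample count),
    ``nexus-distances`` (a NEXUS Distances block), ``edge-tsv`` (one line
    per unordered sample pair).  Values use 6 decimal digits.
    """
    path = Path(path)
    n = len(dm.sample_ids)
    if format == "phylip-matrix":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{n}\n")
            for i, s in enumerate(dm.sample_ids):
                row = " ".join(f"{dm.values[i, j]:.6f}" for j in range(n))
                fh.write(f"{s}\t{row}\n")
    elif format == "nexus-distances":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#NEXUS\n\nBEGIN Taxa;\n")
            fh.write(f"DIMENSIONS ntax={n};\nTAXLABELS\n")
            for s in dm.sample_ids:
                fh.write(f"  '{s}'\n")
            fh.write(";\nEND;\n\nBEGIN Distances;\n")
            fh.write(f"DIMENSIONS ntax={n};\nFORMAT triangle=both labels diagonal;\nMATRIX\n")
            for i, s in enumerate(dm.sample_ids):
                row = " ".join(f"{dm.values[i, j]:.6f}" for j in range(n))
                fh.write(f"  '{s}' {row}\n")
            fh.write(";\nEND;\n")
    elif format == "edge-tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#sample_a\tsample_b\tdistance\n")
            for i in range(n):
                for j in range(i + 1, n):
                    fh.write(f"{dm.sample_ids[i]}\t{dm.sample_ids[j]}\t{dm.values[i, j]:.6f}\n")
    else:
        raise ValueError(f"unknown export format {format!r}")


def read_phylip(path: str | Path, name: str = "distance") -> DistanceMatrix:
    """Read a square PHYLIP distance matrix written by :func:`export_network`."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    try:
        n = int(lines[0].strip())
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path.name}: missing PHYLIP taxon-count header") from exc
    if len(lines) - 1 != n:
        raise FormatError(f"{path.name}: expected {n} rows, found {len(lines) - 1}")
    samples: list[str] = []
    values = np.zeros((n, n))
    for i, line in enumerate(lines[1:]):
        fields = line.replace("\t", " ").split()
        if len(fields) != n + 1:
            raise FormatError(f"{path.name}: row {i + 1} has {len(fields) - 1} values, expected {n}")
        samples.append(fields[0])
        values[i] = [float(v) for v in fields[1:]]
    return DistanceMatrix(samples, values, name)
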