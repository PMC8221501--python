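"""Signed partial-correlation network inference for one patient class.

The estimator is the analytic-shrinkage correlation estimate: the sample
correlation matrix R is replaced by R* = (1 - lambda) R + lambda I, with
the data-driven intensity lambda* = sum Var(r_ij) / sum r_ij^2 over the
off-diagonal entries, clipped to [0, 1].  Because lambda* > 0 whenever the
sample correlations are noisy, R* is invertible even with more genes than
samples.  Partial correlations follow from the scaled inverse
Omega = R*^-1 as r_ij = -omega_ij / sqrt(omega_ii omega_jj).

Edges are then ranked by partial-correlation magnitude and the strongest
fraction (default the top 1% of all candidate pairs) is retained as a
signed undirected network.  An alternative reading of the "1%" cut — keep
pairs with |r| > 0.01 — is available as ``mode="magnitude"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, InferenceError
from .preprocess import ExpressionMatrix

#: minimum pairwise-complete samples for a correlation; below it the pair's
#: partial correlation is reported as 0
MIN_PAIR_OVERLAP = 10


@dataclass
class PartialCorrelationMatrix:
    """Symmetric partial correlations with unit diagonal.

    ``shrinkage_intensity`` records the lambda* actually used and
    ``dropped_genes`` the zero-variance genes removed before estimation.
    """

    values: pd.DataFrame
    shrinkage_intensity: float
    n_samples: int
    dropped_genes: list[str] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


def _shrinkage_lambda(z: np.ndarray) -> float:
    """Ledoit-Wolf-style intensity for shrinking correlations to identity.

    ``z`` is the n x p matrix of standardised observations (unit variance,
    zero mean, sd with denominator n-1).  lambda* = sum of estimated
    variances of the off-diagonal sample correlations over the sum of their
    squares, clipped to [0, 1].
    """
    n = z.shape[0]
    r = (z.T @ z) / (n - 1)
    w_bar = (z.T @ z) / n
    sq = (z ** 2).T @ (z ** 2)
    var_r = n / (n - 1) ** 3 * (sq - n * w_bar ** 2)
    off = ~np.eye(r.shape[0], dtype=bool)
    denom = float((r[off] ** 2).sum())
    if denom == 0.0:
        return 1.0
    return float(min(1.0, max(0.0, var_r[off].sum() / denom)))


def _pairwise_correlation(values: pd.DataFrame, min_overlap: int) -> np.ndarray:
    """Pairwise-complete correlations; pairs under the overlap floor get 0."""
    r = values.T.corr(min_periods=min_overlap).to_numpy()
    r[np.isnan(r)] = 0.0
    np.fill_diagonal(r, 1.0)
    return r


def shrinkage_partial_correlations(
    m: ExpressionMatrix,
    shrinkage: float | None = None,
    min_overlap: int = MIN_PAIR_OVERLAP,
) -> PartialCorrelationMatrix:
    """Estimate partial correlations among genes from one class's samples.

    Zero-variance genes are removed before estimation (recorded in
    ``dropped_genes``) because the correlation scaling is undefined for
    them.  ``shrinkage`` overrides the data-driven lambda*; passing 0.0
    gives the unshrunk estimate, which requires more samples than genes.
    """
    values = m.values
    n_samples = values.shape[1]
    if n_samples < 3:
        raise DataError(f"need at least 3 samples, got {n_samples}")
    sd = values.std(axis=1, ddof=1, skipna=True)
    zero_var = list(values.index[(sd == 0) | sd.isna()])
    if zero_var:
        values = values.drop(index=zero_var)
    if values.shape[0] < 2:
        raise DataError("fewer than 2 genes with non-zero variance")

    x = values.to_numpy(dtype=float).T  # samples x genes
    has_missing = np.isnan(x).any()
    if has_missing:
        r = _pairwise_correlation(values, min_overlap)
        col_mean = np.nanmean(x, axis=0)
        col_sd = np.nanstd(x, axis=0, ddof=1)
        z = (x - col_mean) / col_sd
        z = np.where(np.isnan(z), 0.0, z)
    else:
        z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
        r = (z.T @ z) / (n_samples - 1)
        np.fill_diagonal(r, 1.0)

    lam = _shrinkage_lambda(z) if shrinkage is None else float(shrinkage)
    if not (0.0 <= lam <= 1.0):
        raise ConfigurationError("shrinkage intensity must be in [0, 1]")
    r_star = (1.0 - lam) * r
    np.fill_diagonal(r_star, 1.0)

    try:
        omega = np.linalg.inv(r_star)
    except np.linalg.LinAlgError as exc:
        raise InferenceError(
            "shrunk correlation matrix is singular; set a positive shrinkage "
            "floor (this can only occur at lambda = 0)"
        ) from exc
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    pcor = (pcor + pcor.T) / 2.0
    np.fill_diagonal(pcor, 1.0)

    return PartialCorrelationMatrix(
        values=pd.DataFrame(pcor, index=values.index, columns=values.index),
        shrinkage_intensity=lam,
        n_samples=n_samples,
        dropped_genes=zero_var,
    )


def partial_correlations_by_regression(x: np.ndarray) -> np.ndarray:
    """Brute-force oracle: r_ij from residual regression.

    Regresses gene i and gene j each on all remaining genes (least squares
    with intercept) and correlates the two residual vectors.  Exact for
    n > p; used only to validate the matrix-inversion path at lambda = 0.
    """
    n, p = x.shape
    out = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            others = [k for k in range(p) if k not in (i, j)]
            design = np.column_stack([np.ones(n), x[:, others]])
            res_i = x[:, i] - design @ np.linalg.lstsq(design, x[:, i], rcond=None)[0]
            res_j = x[:, j] - design @ np.linalg.lstsq(design, x[:, j], rcond=None)[0]
            r = np.corrcoef(res_i, res_j)[0, 1]
            out[i, j] = out[j, i] = r
    return out


def rank_edges(p: PartialCorrelationMatrix) -> list[tuple[str, str, float]]:
    """All unordered gene pairs sorted by |partial correlation| descending.

    Equal magnitudes are ordered by the lexicographically smallest
    (gene_i, gene_j) pair, so the ranking is fully deterministic.
    """
    genes = p.gene_ids
    vals = p.values.to_numpy()
    edges = [
        (genes[i], genes[j], float(vals[i, j]))
        for i in range(len(genes))
        for j in range(i + 1, len(genes))
    ]
    edges.sort(key=lambda e: (-abs(e[2]), e[0], e[1]))
    return edges


@dataclass
class SignedNetwork:
    """Signed undirected network of retained partial correlations.

    Edge attributes on ``graph``: ``weight`` (the partial correlation) and
    ``sign`` ("positive"/"negative").  Isolated genes stay in the node set;
    ``isolated`` lists them separately.
    """

    graph: nx.Graph
    name: str = ""
    cohort: str = ""

    @property
    def isolated(self) -> list[str]:
        return sorted(n for n, deg in self.graph.degree() if deg == 0)

    @property
    def edge_count(self) -> int:
        return self.graph.number_of_edges()


def threshold_top_fraction(
    ranked: list[tuple[str, str, float]],
    fraction: float = 0.01,
    mode: str = "rank",
    name: str = "",
    cohort: str = "",
) -> SignedNetwork:
    """Retain the strongest edges of a ranked pair list as a network.

    ``mode="rank"`` (default) keeps the first ceil(fraction * total pairs)
    edges — the marginalised-thresholding reading of a "1%" cut.
    ``mode="magnitude"`` keeps every pair with |weight| > fraction instead.
    Pairs with weight exactly 0 are never turned into edges.
    """
    if not (0.0 < fraction <= 1.0):
        raise ConfigurationError("fraction must be in (0, 1]")
    if mode not in ("rank", "magnitude"):
        raise ConfigurationError(f"unknown threshold mode {mode!r}")
    graph = nx.Graph()
    nodes = sorted({g for i, j, _ in ranked for g in (i, j)})
    graph.add_nodes_from(nodes)
    if mode == "rank":
        kept = ranked[: math.ceil(fraction * len(ranked))]
    else:
        kept = [e for e in ranked if abs(e[2]) > fraction]
    for i, j, w in kept:
        if w == 0.0:
            continue
        graph.add_edge(i, j, weight=w, sign="positive" if w > 0 else "negative")
    return SignedNetwork(graph=graph, name=name, cohort=cohort)


def write_edge_list(net: SignedNetwork, path) -> None:
    """Three-column TSV: gene_i, gene_j, partial correlation (6 sig. digits)."""
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["gene_i", "gene_j", "partial_correlation"])
        for i, j, data in sorted(net.graph.edges(data=True)):
            writer.writerow([i, j, f"{data['weight']:.6g}"])


def write_graphml(net: SignedNetwork, path) -> None:
    nx.write_graphml(net.graph, path)
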