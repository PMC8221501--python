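"""Bayesian hierarchical clustering of samples on discretised expression.

Each gene is discretised into three bins (low / mid / high by per-gene
tertiles), so a sample is a vector of categorical observations.  Samples
are then clustered by the greedy Bayesian hierarchical clustering (BHC)
algorithm of Heller & Ghahramani: starting from singletons, the pair of
trees whose merge has the highest posterior probability under a
Dirichlet-process mixture of product-multinomial components is merged,
until one tree remains.  Each internal node stores the natural-log
posterior odds of "these two subtrees are one cluster" versus "they are
separate"; positive log-odds mark preferred merges.

Clusters are the maximal subtrees whose internal merges are all preferred;
classes consolidate clusters by re-splitting the dendrogram top-down at
the latest fusions, and are labelled dominant / insubstantially dominant /
ambiguous by their subtype composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .errors import ConfigurationError, DataError
from .preprocess import ExpressionMatrix, SampleAnnotation, Subtype

N_BINS = 3


@dataclass
class DiscretizedMatrix:
    """Three-bin codes per gene and sample.

    ``codes`` is genes x samples with values in {0, 1, 2}; ``bin_edges``
    holds each gene's (lower, upper) thresholds; ``constant_genes`` lists
    genes whose values were all identical (coded all-middle).
    """

    codes: pd.DataFrame
    bin_edges: pd.DataFrame
    constant_genes: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.codes.columns)


def discretize_three_bins(
    m: ExpressionMatrix, lower_q: float = 1 / 3, upper_q: float = 2 / 3
) -> DiscretizedMatrix:
    """Per-gene tertile discretisation into low (0), mid (1), high (2).

    Values strictly below the lower quantile code 0, strictly above the
    upper quantile code 2, everything else — including ties with either
    edge and missing values — codes 1 (the middle, "signal" bin).
    Quantiles are rank-based, so any monotone per-gene transformation
    leaves the codes unchanged.
    """
    if not (0 < lower_q <= upper_q < 1):
        raise ConfigurationError("quantiles must satisfy 0 < lower <= upper < 1")
    values = m.values.to_numpy(dtype=float)
    lower = np.nanquantile(values, lower_q, axis=1)
    upper = np.nanquantile(values, upper_q, axis=1)
    codes = np.ones_like(values, dtype=np.int8)
    codes[values < lower[:, None]] = 0
    codes[values > upper[:, None]] = 2
    codes[np.isnan(values)] = 1
    constant = [
        g
        for g, row in zip(m.gene_ids, values)
        if np.unique(row[~np.isnan(row)]).size <= 1
    ]
    return DiscretizedMatrix(
        codes=pd.DataFrame(codes, index=m.values.index, columns=m.values.columns),
        bin_edges=pd.DataFrame(
            {"lower": lower, "upper": upper}, index=m.values.index
        ),
        constant_genes=constant,
    )


@dataclass
class DendrogramNode:
    """Node of the BHC dendrogram.

    Internal nodes carry ``log_odds``: the natural-log posterior odds of
    the merged hypothesis against the best split into the two children's
    subtree partitions.  Leaves have ``log_odds`` None.
    """

    id: int
    members: tuple[str, ...]
    left: "DendrogramNode | None" = None
    right: "DendrogramNode | None" = None
    log_odds: float | None = None
    step: int = 0  # merge order; leaves are 0, later merges are larger
    log_evidence: float = 0.0  # log p(D | T) of this subtree

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def internal_nodes(self):
        if not self.is_leaf:
            yield self
            yield from self.left.internal_nodes()
            yield from self.right.internal_nodes()

    def leaves(self):
        if self.is_leaf:
            yield self
        else:
            yield from self.left.leaves()
            yield from self.right.leaves()


def _dm_log_marginal(counts: np.ndarray, n: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Dirichlet-multinomial log marginal likelihood, product over genes.

    ``counts``: (..., g, 3) bin counts; ``n``: (...,) cluster sizes;
    ``beta``: (3,) pseudocounts.  Genes are independent given the cluster.
    """
    beta0 = beta.sum()
    per_gene = (
        gammaln(beta0)
        - gammaln(beta0 + np.asarray(n, dtype=float)[..., None])
        + (gammaln(beta + counts) - gammaln(beta)).sum(axis=-1)
    )
    return per_gene.sum(axis=-1)


class _Cluster:
    """Mutable per-tree state used by the greedy agglomeration."""

    __slots__ = ("node", "size", "counts", "log_d", "log_p")

    def __init__(self, node, size, counts, log_d, log_p):
        self.node = node
        self.size = size
        self.counts = counts  # (g, 3) bin counts
        self.log_d = log_d
        self.log_p = log_p


def bhc_cluster(
    d: DiscretizedMatrix,
    alpha: float = 1.0,
    prior_pseudocounts: Sequence[float] = (1.0, 1.0, 1.0),
) -> DendrogramNode:
    """Greedy BHC over samples with per-gene Dirichlet-multinomial models.

    At every step the pair with the highest posterior merge probability is
    merged (ties broken by the lexicographically smallest pair of subtree
    ids, so the result is deterministic).  ``alpha`` is the Dirichlet
    process concentration; ``prior_pseudocounts`` the symmetric-by-default
    Dirichlet prior over the three bins.
    """
    if alpha <= 0:
        raise ConfigurationError("alpha must be positive")
    beta = np.asarray(prior_pseudocounts, dtype=float)
    if beta.shape != (N_BINS,) or np.any(beta <= 0):
        raise ConfigurationError("prior_pseudocounts must be three positive numbers")

    samples = d.sample_ids
    if not samples:
        raise DataError("no samples to cluster")
    codes = d.codes.to_numpy()  # genes x samples
    n_genes = codes.shape[0]
    log_alpha = np.log(alpha)

    clusters: dict[int, _Cluster] = {}
    for idx, sid in enumerate(samples):
        counts = np.zeros((n_genes, N_BINS))
        counts[np.arange(n_genes), codes[:, idx]] = 1.0
        log_p = float(_dm_log_marginal(counts, np.array(1.0), beta))
        node = DendrogramNode(id=idx, members=(sid,), log_evidence=log_p)
        clusters[idx] = _Cluster(
            node=node, size=1, counts=counts, log_d=log_alpha, log_p=log_p
        )
    if len(clusters) == 1:
        return clusters[0].node

    def pair_stats(ci: _Cluster, cj: _Cluster):
        """log merge score r, log-odds, and merged-node bookkeeping."""
        n = ci.size + cj.size
        counts = ci.counts + cj.counts
        log_dh = log_alpha + gammaln(n)
        log_d = np.logaddexp(log_dh, ci.log_d + cj.log_d)
        log_pi = log_dh - log_d
        log_1mpi = ci.log_d + cj.log_d - log_d
        log_h1 = log_pi + _dm_log_marginal(counts, np.array(float(n)), beta)
        log_h2 = log_1mpi + ci.log_p + cj.log_p
        log_p = np.logaddexp(log_h1, log_h2)
        return log_h1 - log_p, log_h1 - log_h2, log_d, log_p, counts, n

    # score cache: (id_i, id_j) -> log merge posterior
    scores: dict[tuple[int, int], float] = {}

    def batch_scores(new_id: int) -> None:
        """Vectorised merge scores between ``new_id`` and all other clusters."""
        ci = clusters[new_id]
        others = [k for k in clusters if k != new_id]
        if not others:
            return
        sizes = np.array([clusters[k].size for k in others], dtype=float)
        counts = np.stack([clusters[k].counts for k in others]) + ci.counts
        log_ds = np.array([clusters[k].log_d for k in others])
        log_ps = np.array([clusters[k].log_p for k in others])
        n = sizes + ci.size
        log_dh = log_alpha + gammaln(n)
        log_d = np.logaddexp(log_dh, log_ds + ci.log_d)
        log_h1 = (log_dh - log_d) + _dm_log_marginal(counts, n, beta)
        log_h2 = (log_ds + ci.log_d - log_d) + log_ps + ci.log_p
        log_p = np.logaddexp(log_h1, log_h2)
        log_r = log_h1 - log_p
        for k, r in zip(others, log_r):
            scores[(min(k, new_id), max(k, new_id))] = float(r)

    ids = sorted(clusters)
    for pos, cid in enumerate(ids):
        ci = clusters[cid]
        others = ids[pos + 1:]
        if not others:
            continue
        sizes = np.array([clusters[k].size for k in others], dtype=float)
        counts = np.stack([clusters[k].counts for k in others]) + ci.counts
        log_ds = np.array([clusters[k].log_d for k in others])
        log_ps = np.array([clusters[k].log_p for k in others])
        n = sizes + ci.size
        log_dh = log_alpha + gammaln(n)
        log_d = np.logaddexp(log_dh, log_ds + ci.log_d)
        log_h1 = (log_dh - log_d) + _dm_log_marginal(counts, n, beta)
        log_h2 = (log_ds + ci.log_d - log_d) + log_ps + ci.log_p
        log_r = log_h1 - np.logaddexp(log_h1, log_h2)
        for k, r in zip(others, log_r):
            scores[(cid, k)] = float(r)

    next_id = len(samples)
    step = 0
    while len(clusters) > 1:
        best = max(scores.items(), key=lambda kv: (kv[1], (-kv[0][0], -kv[0][1])))
        # ties: highest score wins; among equal scores the lexicographically
        # smallest (i, j) pair (max over negated ids realises that)
        (i, j), _ = best
        ci, cj = clusters[i], clusters[j]
        log_r, log_odds, log_d, log_p, counts, n = pair_stats(ci, cj)
        step += 1
        node = DendrogramNode(
            id=next_id,
            members=tuple(ci.node.members + cj.node.members),
            left=ci.node,
            right=cj.node,
            log_odds=float(log_odds),
            step=step,
            log_evidence=float(log_p),
        )
        merged = _Cluster(node=node, size=n, counts=counts, log_d=log_d, log_p=float(log_p))
        del clusters[i], clusters[j]
        for key in [k for k in scores if i in k or j in k]:
            del scores[key]
        clusters[next_id] = merged
        batch_scores(next_id)
        next_id += 1

    return next(iter(clusters.values())).node


def tree_evidence(
    root: DendrogramNode,
    d: DiscretizedMatrix,
    alpha: float = 1.0,
    prior_pseudocounts: Sequence[float] = (1.0, 1.0, 1.0),
) -> float:
    """Slow, independent re-evaluation of log p(D | T) for a given tree.

    Plain recursive implementation of the subtree-evidence recursion with
    per-gene loops; used as an oracle against the vectorised construction.
    """
    beta = list(prior_pseudocounts)
    beta0 = sum(beta)
    col_of = {sid: k for k, sid in enumerate(d.sample_ids)}
    codes = d.codes.to_numpy()
    n_genes = codes.shape[0]

    def marginal(members) -> float:
        total = 0.0
        for g in range(n_genes):
            cnt = [0, 0, 0]
            for sid in members:
                cnt[codes[g, col_of[sid]]] += 1
            total += gammaln(beta0) - gammaln(beta0 + len(members))
            for b in range(N_BINS):
                total += gammaln(beta[b] + cnt[b]) - gammaln(beta[b])
        return total

    def recurse(node) -> tuple[float, float]:
        """returns (log_d, log_p)"""
        if node.is_leaf:
            return np.log(alpha), marginal(node.members)
        log_d_l, log_p_l = recurse(node.left)
        log_d_r, log_p_r = recurse(node.right)
        n = len(node.members)
        log_dh = np.log(alpha) + gammaln(n)
        log_d = logsumexp([log_dh, log_d_l + log_d_r])
        log_pi = log_dh - log_d
        log_1mpi = log_d_l + log_d_r - log_d
        log_p = logsumexp(
            [log_pi + marginal(node.members), log_1mpi + log_p_l + log_p_r]
        )
        return log_d, log_p

    return float(recurse(root)[1])


def cut_to_clusters(root: DendrogramNode) -> list[set[str]]:
    """Clusters = maximal subtrees whose internal merges all have positive
    log-odds.  Merges with log-odds <= 0 sit above the clusters in the
    hierarchy and are not applied."""

    def all_preferred(node: DendrogramNode) -> bool:
        return all(n.log_odds > 0 for n in node.internal_nodes())

    clusters: list[set[str]] = []

    def walk(node: DendrogramNode) -> None:
        if all_preferred(node):
            clusters.append(set(node.members))
        else:
            walk(node.left)
            walk(node.right)

    walk(root)
    return clusters


def consolidate_classes(
    root: DendrogramNode, clusters: list[set[str]], max_classes: int
) -> list[set[str]]:
    """Split the dendrogram top-down at the latest fusions into classes.

    Classes are unions of whole clusters: splitting never descends below a
    cluster's subtree root.  The frontier starts at the root and the node
    created by the most recent (highest) fusion is split first, until the
    number of groups reaches ``min(max_classes, number of clusters)`` or no
    group can be split further.  Classes are returned in dendrogram
    left-to-right order.
    """
    if max_classes < 2:
        raise ConfigurationError("max_classes must be at least 2")
    cluster_roots = {frozenset(c) for c in clusters}

    def splittable(node: DendrogramNode) -> bool:
        return not node.is_leaf and frozenset(node.members) not in cluster_roots

    target = min(max_classes, max(len(clusters), 1))
    frontier: list[DendrogramNode] = [root]
    while len(frontier) < target:
        candidates = [n for n in frontier if splittable(n)]
        if not candidates:
            break
        node = max(candidates, key=lambda n: n.step)
        pos = frontier.index(node)
        frontier[pos: pos + 1] = [node.left, node.right]
    return [set(node.members) for node in frontier]


@dataclass
class ClassLabel:
    kind: str  # "dominant" | "insubstantial_dominant" | "ambiguous"
    subtype: Subtype | None = None

    def __str__(self) -> str:
        if self.subtype is None:
            return self.kind
        return f"{self.kind}({self.subtype.value})"


@dataclass
class ClassAssignment:
    """Patient classes with per-class subtype composition and dominance label."""

    classes: list[set[str]]
    composition: list[dict[Subtype, int]]
    labels: list[ClassLabel]

    def dominant_classes(self, subtype: Subtype, include_insubstantial: bool = True):
        """Indices of classes dominated by ``subtype``."""
        kinds = {"dominant"}
        if include_insubstantial:
            kinds.add("insubstantial_dominant")
        return [
            i
            for i, lab in enumerate(self.labels)
            if lab.kind in kinds and lab.subtype == subtype
        ]


def label_classes(
    classes: list[set[str]],
    annotations: Sequence[SampleAnnotation],
    dominance_frac: float = 0.85,
    insubstantial_frac: float = 0.60,
) -> ClassAssignment:
    """Label each class by its largest subtype fraction f.

    f >= ``dominance_frac``: dominant(subtype);
    ``insubstantial_frac`` <= f < ``dominance_frac``: insubstantially
    dominant; below that: ambiguous.  Symmetric in the subtypes.
    """
    if not (0 < insubstantial_frac <= dominance_frac <= 1):
        raise ConfigurationError(
            "need 0 < insubstantial_frac <= dominance_frac <= 1"
        )
    by_id = {a.sample_id: a.subtype for a in annotations}
    composition: list[dict[Subtype, int]] = []
    labels: list[ClassLabel] = []
    for cls in classes:
        missing = [s for s in cls if s not in by_id]
        if missing:
            raise DataError(
                f"clustered sample(s) lack annotation: {', '.join(sorted(missing)[:5])}"
            )
        comp: dict[Subtype, int] = {}
        for sid in cls:
            comp[by_id[sid]] = comp.get(by_id[sid], 0) + 1
        composition.append(comp)
        top_subtype, top_count = max(comp.items(), key=lambda kv: (kv[1], kv[0].value))
        f = top_count / len(cls)
        if f >= dominance_frac:
            labels.append(ClassLabel("dominant", top_subtype))
        elif f >= insubstantial_frac:
            labels.append(ClassLabel("insubstantial_dominant", top_subtype))
        else:
            labels.append(ClassLabel("ambiguous"))
    return ClassAssignment(classes=classes, composition=composition, labels=labels)


def to_newick(root: DendrogramNode) -> str:
    """Newick serialisation with log-odds as internal node labels."""

    def fmt(node: DendrogramNode) -> str:
        if node.is_leaf:
            return node.members[0]
        return f"({fmt(node.left)},{fmt(node.right)}){node.log_odds:.6g}"

    return fmt(root) + ";"


def write_class_table(assignment: ClassAssignment, path) -> None:
    """Two-column TSV (sample_id, class index), class order preserved."""
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["sample_id", "class"])
        for idx, cls in enumerate(assignment.classes):
            for sid in sorted(cls):
                writer.writerow([sid, idx])


def write_composition_table(assignment: ClassAssignment, path) -> None:
    """Per-class subtype composition and dominance label as TSV."""
    import csv
    from pathlib import Path

    subtypes = sorted(
        {s for comp in assignment.composition for s in comp}, key=lambda s: s.value
    )
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["class", *(s.value for s in subtypes), "size", "label"])
        for idx, (comp, label) in enumerate(
            zip(assignment.composition, assignment.labels)
        ):
            writer.writerow(
                [
                    idx,
                    *(comp.get(s, 0) for s in subtypes),
                    sum(comp.values()),
                    str(label),
                ]
            )
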