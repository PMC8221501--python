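"""Synthetic cohorts with known class structure and planted network motifs.

The generator produces everything the real cohorts provide — an expression
table and PAM50-style subtype labels — plus the ground truth the real data
lack: which latent class each sample belongs to, which genes are hubs of
the residual dependence graph, and which signed three-gene motifs were
planted.  Residuals are drawn from a zero-mean Gaussian graphical model
whose sparse precision matrix encodes the planted edges; class structure is
added as mean shifts on a subset of "informative" genes.

Sign convention: a planted *positive* partial correlation between genes i
and j is encoded by a *negative* off-diagonal precision entry (and vice
versa), because r_ij = -p_ij / sqrt(p_ii p_jj).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .motifs import signs_for_code
from .preprocess import ExpressionMatrix, SampleAnnotation, Subtype

#: diagonal loading target: smallest eigenvalue of the precision matrix
MIN_EIGENVALUE = 0.1


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``class_mean_shift`` is the between-class separation on an informative
    gene, in units of that gene's residual standard deviation.  With two
    classes the two mean profiles sit at +/- shift/2 on every informative
    gene, so their distance is exactly ``class_mean_shift`` residual SDs.
    """

    n_genes: int = 50
    n_samples_per_subtype: dict[Subtype, int] = field(
        default_factory=lambda: {Subtype.Basal: 60, Subtype.LuminalA: 60}
    )
    n_classes: int = 3
    class_mean_shift: float = 3.0
    fraction_informative_genes: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if len(self.n_samples_per_subtype) != 2:
            raise ConfigurationError("exactly two subtypes are simulated")
        if any(n <= 0 for n in self.n_samples_per_subtype.values()):
            raise ConfigurationError("sample counts must be positive")
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be at least 2")
        if not (0.0 < self.fraction_informative_genes <= 1.0):
            raise ConfigurationError("fraction_informative_genes must be in (0, 1]")
        if self.class_mean_shift < 0:
            raise ConfigurationError("class_mean_shift must be non-negative")


@dataclass
class PlantedStructure:
    """Ground truth of a simulated cohort.

    ``precision`` is the gene x gene precision matrix of the residuals;
    ``edge_signs`` maps planted gene-index pairs to the sign (+1/-1) of the
    implied partial correlation.  ``class_of_sample`` and ``class_means``
    are filled in by :func:`simulate_cohort`.
    """

    precision: np.ndarray
    gene_ids: list[str]
    hub_genes: list[str]
    planted_triads: list[tuple[str, str, str, str]]
    edge_signs: dict[tuple[int, int], int]
    class_of_sample: dict[str, int] = field(default_factory=dict)
    class_means: np.ndarray | None = None
    informative_genes: list[str] = field(default_factory=list)


def gene_name(i: int) -> str:
    return f"G{i:03d}"


def partial_correlation_from_precision(precision: np.ndarray) -> np.ndarray:
    """Exact partial correlations implied by a precision matrix.

    r_ij = -p_ij / sqrt(p_ii p_jj), with a unit diagonal.  This is the
    closed-form oracle used to verify both the planted sign patterns and
    the estimator in the network-inference stage.
    """
    precision = np.asarray(precision, dtype=float)
    d = np.sqrt(np.diag(precision))
    if np.any(d <= 0):
        raise ConfigurationError("precision matrix must have positive diagonal")
    r = -precision / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return r


def plant_precision_matrix(
    n_genes: int,
    hub_count: int = 1,
    hub_degree: int = 10,
    triads: list[tuple[int, int, int, str]] | None = None,
    base_weight: float = 0.3,
    seed: int = 0,
) -> PlantedStructure:
    """Build a sparse precision matrix with hub stars and signed triads.

    Genes ``0 .. hub_count-1`` are hubs; each receives ``hub_degree``
    positive-partial-correlation spokes to genes drawn at random from the
    non-hub pool (avoiding triad members so planted signs never conflict).
    Each triad ``(i, j, k, code)`` plants the edges its NPU code implies,
    assigning signs to the pairs (i,j), (i,k), (j,k) in that order:
    negatives first, then positives, then absent pairs.

    The matrix starts as I - R_off, where R_off holds the requested partial
    correlations with flipped sign; if its smallest eigenvalue falls below
    ``MIN_EIGENVALUE`` it is diagonally loaded up to that floor, which
    shrinks the implied magnitudes slightly but preserves every sign.
    """
    triads = list(triads or [])
    if hub_count < 0 or hub_degree < 0:
        raise ConfigurationError("hub_count and hub_degree must be non-negative")
    if not (0 < abs(base_weight) < 1):
        raise ConfigurationError("base_weight must have magnitude in (0, 1)")
    rng = np.random.default_rng(seed)

    edge_signs: dict[tuple[int, int], int] = {}

    def request(i: int, j: int, sign: int) -> None:
        if i == j:
            raise ConfigurationError(f"self-edge requested on gene {i}")
        key = (min(i, j), max(i, j))
        if key in edge_signs and edge_signs[key] != sign:
            raise ConfigurationError(
                f"conflicting signs requested for edge {key[0]}-{key[1]}"
            )
        edge_signs[key] = sign

    triad_members: set[int] = set()
    planted_triads: list[tuple[str, str, str, str]] = []
    for i, j, k, code in triads:
        if len({i, j, k}) != 3:
            raise ConfigurationError(f"triad genes must be distinct: {(i, j, k)}")
        if max(i, j, k) >= n_genes:
            raise ConfigurationError("triad gene index outside gene range")
        pair_signs = signs_for_code(code)
        for (a, b), s in zip(((i, j), (i, k), (j, k)), pair_signs):
            if s != 0:
                request(a, b, s)
        triad_members.update((i, j, k))
        planted_triads.append((gene_name(i), gene_name(j), gene_name(k), code))

    hubs = list(range(hub_count))
    pool = [g for g in range(hub_count, n_genes) if g not in triad_members]
    if hub_count * hub_degree > len(pool):
        raise ConfigurationError(
            f"hub request needs {hub_count * hub_degree} spoke genes, "
            f"only {len(pool)} available"
        )
    spokes = rng.choice(pool, size=hub_count * hub_degree, replace=False)
    for h in hubs:
        for g in spokes[h * hub_degree: (h + 1) * hub_degree]:
            request(h, int(g), +1)

    r_off = np.zeros((n_genes, n_genes))
    for (i, j), sign in edge_signs.items():
        r_off[i, j] = r_off[j, i] = sign * abs(base_weight)
    precision = np.eye(n_genes) - r_off
    smallest = float(np.linalg.eigvalsh(precision)[0])
    if smallest < MIN_EIGENVALUE:
        precision += (MIN_EIGENVALUE - smallest) * np.eye(n_genes)

    return PlantedStructure(
        precision=precision,
        gene_ids=[gene_name(i) for i in range(n_genes)],
        hub_genes=[gene_name(h) for h in hubs],
        planted_triads=planted_triads,
        edge_signs=edge_signs,
    )


def _class_composition(
    cfg: SimulationConfig,
) -> list[dict[Subtype, int]]:
    """Integer subtype counts per class.

    Classes 0 and 1 are near-pure in the first and second subtype (95/5);
    class 2, when present, is a 50/50 mixture built from 30% of each
    subtype's samples — the minimal structure needed to exercise dominant
    and ambiguous labelling.  Further classes alternate subtype purity.
    """
    subtypes = list(cfg.n_samples_per_subtype)
    totals = dict(cfg.n_samples_per_subtype)
    comp: list[dict[Subtype, int]] = [dict.fromkeys(subtypes, 0) for _ in range(cfg.n_classes)]

    mixed = [c for c in range(cfg.n_classes) if c == 2]
    pure = [c for c in range(cfg.n_classes) if c != 2]
    for c in mixed:
        for s in subtypes:
            comp[c][s] = max(1, round(0.3 * totals[s]))
    remaining = {s: totals[s] - sum(comp[c][s] for c in mixed) for s in subtypes}

    # Pure classes: 95% of the budget goes to the class's own subtype,
    # the rest is sprinkled as minority members.
    own = {c: subtypes[i % 2] for i, c in enumerate(pure)}
    per_class = {
        s: [c for c in pure if own[c] == s] for s in subtypes
    }
    for s in subtypes:
        owners = per_class[s]
        others = [c for c in pure if own[c] != s]
        minority = min(
            remaining[s] - len(owners), max(0, round(0.05 * remaining[s]))
        ) if others else 0
        minority = max(0, minority)
        majority = remaining[s] - minority
        for idx, c in enumerate(owners):
            share = majority // len(owners) + (1 if idx < majority % len(owners) else 0)
            comp[c][s] += share
        for idx in range(minority):
            comp[others[idx % len(others)]][s] += 1
    return comp


def simulate_cohort(
    cfg: SimulationConfig, structure: PlantedStructure
) -> tuple[ExpressionMatrix, list[SampleAnnotation], PlantedStructure]:
    """Draw a cohort from the planted model.

    Each sample's expression is its class mean plus a Gaussian residual
    with covariance ``inverse(precision)``.  Subtype labels follow the
    class composition of :func:`_class_composition`, so one class is
    overwhelmingly one subtype and (with three or more classes) one class
    mixes the two subtypes evenly.  Fully deterministic under ``cfg.seed``.
    """
    cfg.validate()
    if structure.precision.shape != (cfg.n_genes, cfg.n_genes):
        raise ConfigurationError(
            f"precision is {structure.precision.shape}, config wants "
            f"({cfg.n_genes}, {cfg.n_genes})"
        )
    eigs = np.linalg.eigvalsh(structure.precision)
    if eigs[0] <= 0:
        raise ConfigurationError("precision matrix is not positive definite")

    rng = np.random.default_rng(cfg.seed)
    covariance = np.linalg.inv(structure.precision)
    residual_sd = np.sqrt(np.diag(covariance))

    n_informative = max(1, round(cfg.fraction_informative_genes * cfg.n_genes))
    informative = np.sort(rng.choice(cfg.n_genes, size=n_informative, replace=False))

    # Class mean profiles: +/- shift/2 per informative gene.  Two classes get
    # complementary sign patterns (exact separation = shift); further classes
    # get independent patterns, re-drawn if they collide with an earlier one.
    patterns = np.zeros((cfg.n_classes, n_informative))
    patterns[0] = rng.choice([-1.0, 1.0], size=n_informative)
    for c in range(1, cfg.n_classes):
        if c == 1:
            patterns[1] = -patterns[0]
            continue
        while True:
            cand = rng.choice([-1.0, 1.0], size=n_informative)
            if not any(np.array_equal(cand, patterns[p]) for p in range(c)):
                patterns[c] = cand
                break
    class_means = np.zeros((cfg.n_classes, cfg.n_genes))
    class_means[:, informative] = (
        0.5 * cfg.class_mean_shift * patterns * residual_sd[informative]
    )

    comp = _class_composition(cfg)
    class_of_sample: dict[str, int] = {}
    subtype_of_sample: dict[str, Subtype] = {}
    counter = 0
    for c, sub_counts in enumerate(comp):
        for subtype, count in sub_counts.items():
            for _ in range(count):
                sid = f"S{counter:04d}"
                class_of_sample[sid] = c
                subtype_of_sample[sid] = subtype
                counter += 1
    sample_ids = list(class_of_sample)
    order = rng.permutation(len(sample_ids))
    sample_ids = [sample_ids[i] for i in order]

    chol = np.linalg.cholesky(covariance)
    z = rng.standard_normal((len(sample_ids), cfg.n_genes))
    residuals = z @ chol.T
    values = np.empty((len(sample_ids), cfg.n_genes))
    for row, sid in enumerate(sample_ids):
        values[row] = class_means[class_of_sample[sid]] + residuals[row]

    frame = pd.DataFrame(
        values.T, index=pd.Index(structure.gene_ids, name="gene"), columns=sample_ids
    )
    annotations = [SampleAnnotation(sid, subtype_of_sample[sid]) for sid in sample_ids]
    structure.class_of_sample = class_of_sample
    structure.class_means = class_means
    structure.informative_genes = [structure.gene_ids[g] for g in informative]
    return ExpressionMatrix(values=frame, centred=False), annotations, structure


def sample_residuals(precision: np.ndarray, n_samples: int, seed: int = 0) -> np.ndarray:
    """Draw ``n_samples`` x ``n_genes`` residuals from N(0, inverse(precision))."""
    eigs = np.linalg.eigvalsh(precision)
    if eigs[0] <= 0:
        raise ConfigurationError("precision matrix is not positive definite")
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(np.linalg.inv(precision))
    return rng.standard_normal((n_samples, precision.shape[0])) @ chol.T


def write_ground_truth(structure: PlantedStructure, path) -> None:
    """JSON sidecar with class assignments, hubs and planted triads."""
    import json
    from pathlib import Path

    payload = {
        "class_of_sample": structure.class_of_sample,
        "hub_genes": structure.hub_genes,
        "planted_triads": [list(t) for t in structure.planted_triads],
        "informative_genes": structure.informative_genes,
        "edge_signs": {
            f"{gene_name(i)}|{gene_name(j)}": sign
            for (i, j), sign in sorted(structure.edge_signs.items())
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
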