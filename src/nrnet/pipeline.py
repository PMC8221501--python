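"""End-to-end orchestration: preprocess -> cluster -> networks -> motifs.

A single :class:`PipelineConfig` drives the whole run.  Two input modes
exist: ``synthetic`` simulates two cohorts from one planted ground-truth
structure (so cross-cohort conservation has something to find), and
``files`` consumes cBioPortal-style expression/clinical tables.  Every
stage writes its artifact under the output directory and the run finishes
with a machine-readable JSON report; re-running with the same config and
seed reproduces the outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import cluster as bhc
from . import degree as deg
from . import motifs as mot
from . import network as netinf
from . import preprocess as prep
from . import simulate as sim
from .errors import ConfigurationError
from .preprocess import Subtype

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class CohortFiles:
    """One cohort's input files for ``files`` mode."""

    name: str
    expression: str
    clinical: str
    sample_column: str = "PATIENT_ID"
    subtype_column: str = "CLAUDIN_SUBTYPE"


@dataclass
class SyntheticSettings:
    """Planted ground truth shared by the simulated cohorts."""

    n_genes: int = 50
    n_samples_per_subtype: dict[str, int] = field(
        default_factory=lambda: {"Basal": 60, "LuminalA": 60}
    )
    n_classes: int = 2
    class_mean_shift: float = 3.0
    fraction_informative_genes: float = 0.4
    hub_count: int = 1
    hub_degree: int = 4
    triads: list[list] = field(
        default_factory=lambda: [[0, 20, 21, "030"], [0, 22, 23, "111"]]
    )
    base_weight: float = 0.3
    n_cohorts: int = 2


@dataclass
class PipelineConfig:
    mode: str = "synthetic"  # "synthetic" | "files"
    synthetic: SyntheticSettings = field(default_factory=SyntheticSettings)
    cohorts: list[CohortFiles] = field(default_factory=list)
    gene_list: str | None = None
    subtype_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [("Basal", "LuminalA")]
    )
    target_subtype: str = "Basal"
    median_center: bool = True
    lower_q: float = 1 / 3
    upper_q: float = 2 / 3
    alpha: float = 1.0
    pseudocounts: tuple[float, float, float] = (1.0, 1.0, 1.0)
    max_classes: int = 5
    dominance_frac: float = 0.85
    insubstantial_frac: float = 0.60
    edge_fraction: float = 0.01
    threshold_mode: str = "rank"
    hub_k: int = 2
    min_networks: int = 2
    min_cohorts: int = 2
    include_insubstantial: bool = True
    outdir: str = "nrnet_out"
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "synthetic" in data and isinstance(data["synthetic"], dict):
            data["synthetic"] = SyntheticSettings(**data["synthetic"])
        if "cohorts" in data:
            data["cohorts"] = [
                c if isinstance(c, CohortFiles) else CohortFiles(**c)
                for c in data["cohorts"]
            ]
        if "subtype_pairs" in data:
            data["subtype_pairs"] = [tuple(p) for p in data["subtype_pairs"]]
        if "pseudocounts" in data:
            data["pseudocounts"] = tuple(data["pseudocounts"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        """Hash of every result-affecting setting (the output path is not one)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def validate_config(config: PipelineConfig) -> list[str]:
    """All range and consistency checks, aggregated (never raises)."""
    errors: list[str] = []
    if config.mode not in ("synthetic", "files"):
        errors.append(f"mode must be 'synthetic' or 'files', got {config.mode!r}")
    if config.mode == "files" and not config.cohorts:
        errors.append("files mode requires at least one cohort entry")
    if not (0 < config.lower_q <= config.upper_q < 1):
        errors.append("discretisation quantiles must satisfy 0 < lower <= upper < 1")
    if config.alpha <= 0:
        errors.append("alpha must be positive")
    if any(b <= 0 for b in config.pseudocounts):
        errors.append("pseudocounts must be positive")
    if config.max_classes < 2:
        errors.append("max_classes must be at least 2")
    if not (0 < config.insubstantial_frac <= config.dominance_frac <= 1):
        errors.append("need 0 < insubstantial_frac <= dominance_frac <= 1")
    if not (0 < config.edge_fraction <= 1):
        errors.append("edge_fraction must be in (0, 1]")
    if config.threshold_mode not in ("rank", "magnitude"):
        errors.append(f"threshold_mode must be 'rank' or 'magnitude', got {config.threshold_mode!r}")
    if config.hub_k < 1:
        errors.append("hub_k must be at least 1")
    if config.min_networks < 1:
        errors.append("min_networks must be at least 1")
    if config.min_cohorts < 1:
        errors.append("min_cohorts must be at least 1")
    if not config.subtype_pairs:
        errors.append("at least one subtype pair is required")
    for a, b in config.subtype_pairs:
        if a == b:
            errors.append(f"subtype pair must be distinct: ({a}, {b})")
        for s in (a, b):
            if s not in Subtype.__members__:
                errors.append(f"unknown subtype {s!r}")
    if config.mode == "synthetic":
        syn = config.synthetic
        if syn.n_genes <= 0:
            errors.append("synthetic.n_genes must be positive")
        if syn.n_classes < 2:
            errors.append("synthetic.n_classes must be at least 2")
        if not (0 < syn.fraction_informative_genes <= 1):
            errors.append("synthetic.fraction_informative_genes must be in (0, 1]")
        if syn.n_cohorts < 1:
            errors.append("synthetic.n_cohorts must be at least 1")
    return errors


def _load_cohort(config: PipelineConfig, cohort: CohortFiles):
    matrix = prep.read_expression_table(cohort.expression)
    annotations = prep.read_subtype_labels(
        cohort.clinical,
        sample_column=cohort.sample_column,
        subtype_column=cohort.subtype_column,
    )
    if config.gene_list:
        genes = prep.read_gene_list(config.gene_list)
        matrix, absent = prep.restrict_to_gene_list(matrix, genes)
        logger.info("cohort %s: %d gene-list genes absent", cohort.name, len(absent))
    return matrix, annotations


def _simulated_cohorts(config: PipelineConfig):
    """Simulate ``n_cohorts`` cohorts sharing one planted structure."""
    syn = config.synthetic
    structure = sim.plant_precision_matrix(
        n_genes=syn.n_genes,
        hub_count=syn.hub_count,
        hub_degree=syn.hub_degree,
        triads=[tuple(t) for t in syn.triads],
        base_weight=syn.base_weight,
        seed=config.seed,
    )
    cohorts = []
    for c in range(syn.n_cohorts):
        cfg = sim.SimulationConfig(
            n_genes=syn.n_genes,
            n_samples_per_subtype={
                Subtype(k): v for k, v in syn.n_samples_per_subtype.items()
            },
            n_classes=syn.n_classes,
            class_mean_shift=syn.class_mean_shift,
            fraction_informative_genes=syn.fraction_informative_genes,
            seed=config.seed * 1000 + c + 1,
        )
        matrix, annotations, structure = sim.simulate_cohort(cfg, structure)
        cohorts.append((f"cohort{chr(ord('A') + c)}", matrix, annotations))
    return structure, cohorts


def run_full(config: PipelineConfig) -> dict:
    """Execute the whole pipeline and return the run report (also written
    to ``<outdir>/report.json``)."""
    errors = validate_config(config)
    if errors:
        raise ConfigurationError("; ".join(errors))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "cohorts": {},
        "networks": {},
    }

    structure = None
    if config.mode == "synthetic":
        structure, cohorts = _simulated_cohorts(config)
        sim.write_ground_truth(structure, outdir / "ground_truth.json")
        report["planted"] = {
            "hub_genes": structure.hub_genes,
            "planted_triads": [list(t) for t in structure.planted_triads],
        }
    else:
        cohorts = []
        for cf in config.cohorts:
            matrix, annotations = _load_cohort(config, cf)
            cohorts.append((cf.name, matrix, annotations))

    target = Subtype(config.target_subtype)
    networks: list[netinf.SignedNetwork] = []

    for cohort_name, matrix, annotations in cohorts:
        cohort_report: dict = {"n_samples": matrix.shape[1], "pairs": {}}
        if config.median_center:
            matrix = prep.median_center(matrix)
        prep.write_expression_table(
            matrix, outdir / f"{cohort_name}_expression.tsv"
        )
        for a_name, b_name in config.subtype_pairs:
            a, b = Subtype(a_name), Subtype(b_name)
            pair_tag = f"{a.value}_vs_{b.value}"
            cohort_m, cohort_ann = prep.build_pairwise_cohort(matrix, annotations, a, b)
            disc = bhc.discretize_three_bins(cohort_m, config.lower_q, config.upper_q)
            root = bhc.bhc_cluster(disc, config.alpha, config.pseudocounts)
            (outdir / f"{cohort_name}_{pair_tag}_dendrogram.nwk").write_text(
                bhc.to_newick(root) + "\n"
            )
            clusters = bhc.cut_to_clusters(root)
            classes = bhc.consolidate_classes(root, clusters, config.max_classes)
            assignment = bhc.label_classes(
                classes, cohort_ann, config.dominance_frac, config.insubstantial_frac
            )
            bhc.write_class_table(assignment, outdir / f"{cohort_name}_{pair_tag}_classes.tsv")
            bhc.write_composition_table(
                assignment, outdir / f"{cohort_name}_{pair_tag}_composition.tsv"
            )
            pair_report = {
                "n_clusters": len(clusters),
                "n_classes": len(classes),
                "classes": [
                    {
                        "size": len(cls),
                        "label": str(lab),
                        "composition": {s.value: n for s, n in sorted(
                            comp.items(), key=lambda kv: kv[0].value)},
                    }
                    for cls, comp, lab in zip(
                        assignment.classes, assignment.composition, assignment.labels
                    )
                ],
            }
            cohort_report["pairs"][pair_tag] = pair_report

            for idx in assignment.dominant_classes(
                target, include_insubstantial=config.include_insubstantial
            ):
                members = sorted(assignment.classes[idx])
                class_m = prep.ExpressionMatrix(
                    values=cohort_m.values[members], centred=cohort_m.centred
                )
                if class_m.shape[1] < 3:
                    logger.warning(
                        "%s %s class %d too small for network inference",
                        cohort_name, pair_tag, idx,
                    )
                    continue
                pcor = netinf.shrinkage_partial_correlations(class_m)
                ranked = netinf.rank_edges(pcor)
                net_name = f"{cohort_name}_{pair_tag}_class{idx}"
                net = netinf.threshold_top_fraction(
                    ranked,
                    fraction=config.edge_fraction,
                    mode=config.threshold_mode,
                    name=net_name,
                    cohort=cohort_name,
                )
                networks.append(net)
                netinf.write_edge_list(net, outdir / f"{net_name}_edges.tsv")
                netinf.write_graphml(net, outdir / f"{net_name}.graphml")
                report["networks"][net_name] = {
                    "cohort": cohort_name,
                    "class_index": idx,
                    "n_samples": class_m.shape[1],
                    "shrinkage_intensity": round(pcor.shrinkage_intensity, 6),
                    "n_edges": net.edge_count,
                    "n_isolated": len(net.isolated),
                }
        report["cohorts"][cohort_name] = cohort_report

    if networks:
        summary = deg.total_degree(networks)
        deg.write_degree_summary(summary, outdir / "degree_summary.tsv")
        hubs = deg.identify_hubs(summary, k=min(config.hub_k, len(summary.rank)))
        report["hubs"] = {
            "genes": hubs.genes,
            "tie_expanded": hubs.tie_expanded,
            "total_degree": {g: int(summary.total[g]) for g in hubs.genes},
        }

        tables: list[mot.MotifOccurrenceTable] = []
        for net in networks:
            for hub in hubs.genes:
                if hub not in net.graph:
                    continue
                local = mot.hub_local_network(net, hub)
                counts, records = mot.census_hub_motifs(local)
                tables.append(
                    mot.MotifOccurrenceTable(
                        hub=hub,
                        network_id=net.name,
                        cohort=net.cohort,
                        counts=counts,
                        records=records,
                    )
                )
        mot.write_census_table(tables, outdir / "motif_census.tsv")
        mot.write_triad_records(tables, outdir / "triad_records.jsonl")
        report["census"] = {
            f"{t.hub}@{t.network_id}": t.counts for t in tables
        }

        if len({net.name for net in networks}) >= 2:
            effective_min = min(config.min_networks, len(networks))
            conserved = mot.cross_network_conservation(
                tables, min_networks=effective_min, min_cohorts=config.min_cohorts
            )
            mot.write_conservation_table(
                conserved, [net.name for net in networks], outdir / "conserved_motifs.tsv"
            )
            report["conserved_triples"] = [
                {
                    "genes": list(c.genes),
                    "n_networks": c.n_networks,
                    "cohorts": list(c.cohorts),
                    "per_network": c.per_network,
                }
                for c in conserved
            ]
            report["conservation_min_networks"] = effective_min
    else:
        report["hubs"] = {"genes": [], "tie_expanded": False, "total_degree": {}}
        report["conserved_triples"] = []

    (outdir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True) + "\n"
    )
    return report
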