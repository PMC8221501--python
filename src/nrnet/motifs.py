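"""Signed 3-node motif classification and census (NPU triad census).

Every unordered gene triple in a signed undirected network falls into one
of ten classes identified by its NPU code: a three-digit string counting
Negative, Positive and Un-associated gene pairs (the digits sum to 3).
Examples: ``021`` is a two-positive-edge path, ``030`` an all-positive
triangle, ``003`` three mutually unassociated genes.  The census adapts
the classic directed triad census of social-network analysis to signed
undirected graphs.

Census tables count, per hub-associated local network, the seven
edge-bearing motif types {021, 201, 111, 120, 210, 030, 300}: the three
linear (two-edge) codes and the four complete (triangle) codes.  Complete
motifs are *coherent* when their edge-sign product is positive, i.e. when
they contain an even number of negative edges — the structural-balance
convention.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx

from .errors import ConfigurationError, DataError

#: pair order used when a triad (i, j, k) is expanded to edges
NPU_EDGE_ORDER = ((0, 1), (0, 2), (1, 2))

#: the seven edge-bearing motif types of the census tables
CENSUS_CODES = ("021", "201", "111", "120", "210", "030", "300")

LINEAR_CODES = ("021", "201", "111")
COMPLETE_CODES = ("120", "210", "030", "300")

_SIGN_OF = {"negative": -1, "positive": 1, "absent": 0, -1: -1, 1: 1, 0: 0}


def npu_code(signs) -> str:
    """NPU code of three pair states (order-invariant).

    ``signs`` holds three items, each ``-1``/``+1``/``0`` or the strings
    ``"negative"``/``"positive"``/``"absent"``.
    """
    states = [_SIGN_OF[s] for s in signs]
    if len(states) != 3:
        raise ConfigurationError("a triad has exactly three gene pairs")
    n_neg = states.count(-1)
    n_pos = states.count(1)
    n_un = states.count(0)
    return f"{n_neg}{n_pos}{n_un}"


def signs_for_code(code: str) -> tuple[int, int, int]:
    """One canonical sign assignment realising an NPU code.

    Negatives are placed on the first pairs of :data:`NPU_EDGE_ORDER`,
    positives next, absent pairs last.
    """
    if len(code) != 3 or not code.isdigit():
        raise ConfigurationError(f"malformed NPU code {code!r}")
    n_neg, n_pos, n_un = (int(c) for c in code)
    if n_neg + n_pos + n_un != 3:
        raise ConfigurationError(f"NPU digits must sum to 3: {code!r}")
    return tuple([-1] * n_neg + [1] * n_pos + [0] * n_un)


@dataclass
class TriadRecord:
    """One observed gene triple with its motif classification.

    ``centre`` is, for linear motifs, the gene incident to both edges
    (the paper-style middle node of e.g. JUN-FOS-NR4A2); ``None`` otherwise.
    """

    genes: tuple[str, str, str]
    code: str
    edge_signs: dict[frozenset, int]
    topology: str = "unclassified"
    coherence: str = "n/a"
    centre: str | None = None

    @property
    def key(self) -> frozenset:
        return frozenset(self.genes)


def make_triad(genes, pair_signs) -> TriadRecord:
    """Build and classify a triad from its three genes and pair signs.

    ``pair_signs`` follows :data:`NPU_EDGE_ORDER` over the sorted genes.
    """
    genes = tuple(sorted(genes))
    if len(set(genes)) != 3:
        raise ConfigurationError("triad genes must be three distinct identifiers")
    states = [_SIGN_OF[s] for s in pair_signs]
    edge_signs = {
        frozenset((genes[a], genes[b])): s for (a, b), s in zip(NPU_EDGE_ORDER, states)
    }
    record = TriadRecord(genes=genes, code=npu_code(states), edge_signs=edge_signs)
    return classify_topology(record)


def classify_topology(t: TriadRecord) -> TriadRecord:
    """Fill in topology, coherence and (for linear motifs) the centre gene.

    Two present edges make a *linear* motif, three a *complete* one.
    A complete motif is coherent iff its number of negative edges is even
    (equivalently, the product of its edge signs is positive).
    """
    n_edges = sum(1 for s in t.edge_signs.values() if s != 0)
    t.topology = {0: "empty", 1: "one_edge", 2: "linear", 3: "complete"}[n_edges]
    if t.topology == "complete":
        n_neg = sum(1 for s in t.edge_signs.values() if s == -1)
        t.coherence = "coherent" if n_neg % 2 == 0 else "incoherent"
    else:
        t.coherence = "n/a"
    if t.topology == "linear":
        incidence = Counter()
        for pair, s in t.edge_signs.items():
            if s != 0:
                incidence.update(pair)
        t.centre = next(g for g, c in incidence.items() if c == 2)
    else:
        t.centre = None
    return t


@dataclass
class ConfigurationCensus:
    """Exhaustive summary of all ordered sign assignments on three pairs."""

    total_configurations: int
    configurations_per_code: dict[str, int]
    n_distinct_codes: int
    linear_configurations: int
    complete_configurations: int


def enumerate_configurations() -> ConfigurationCensus:
    """Enumerate every ordered assignment of {negative, positive, absent}
    to the three pairs of a labelled triad.

    There are 3^3 = 27 configurations collapsing to 10 NPU codes; the three
    linear codes account for 12 configurations (the hub can sit at either
    end or in the middle) and the four complete codes for 8 sign
    configurations.
    """
    per_code: Counter = Counter()
    linear = 0
    complete = 0
    total = 0
    for assignment in itertools.product((-1, 1, 0), repeat=3):
        total += 1
        code = npu_code(assignment)
        per_code[code] += 1
        n_edges = sum(1 for s in assignment if s != 0)
        if n_edges == 2:
            linear += 1
        elif n_edges == 3:
            complete += 1
    return ConfigurationCensus(
        total_configurations=total,
        configurations_per_code=dict(sorted(per_code.items())),
        n_distinct_codes=len(per_code),
        linear_configurations=linear,
        complete_configurations=complete,
    )


@dataclass
class LocalNetwork:
    """Radius-2 neighbourhood of a hub: the hub, its neighbours, their
    neighbours, and every parent-network edge among those nodes."""

    hub: str
    nodes: set
    graph: nx.Graph


def _edge_sign(graph: nx.Graph, u, v) -> int:
    if graph.has_edge(u, v):
        return 1 if graph.edges[u, v]["weight"] > 0 else -1
    return 0


def hub_local_network(net, hub: str) -> LocalNetwork:
    """Induced subgraph on all nodes within graph distance 2 of ``hub``."""
    graph = net.graph if hasattr(net, "graph") else net
    if hub not in graph:
        raise DataError(f"hub {hub!r} not present in network")
    nodes = {hub}
    for n1 in graph.neighbors(hub):
        nodes.add(n1)
        nodes.update(graph.neighbors(n1))
    return LocalNetwork(hub=hub, nodes=nodes, graph=graph.subgraph(nodes).copy())


def census_hub_motifs(
    local: LocalNetwork, require_hub: bool = True
) -> tuple[dict[str, int], list[TriadRecord]]:
    """Count edge-bearing motifs (>= 2 present edges) in a local network.

    By default only triples containing the hub are counted, matching
    hub-centred census tables; ``require_hub=False`` enumerates every
    triple in the local network instead.
    """
    counts = {code: 0 for code in CENSUS_CODES}
    records: list[TriadRecord] = []
    others = sorted(n for n in local.nodes if n != local.hub)
    if require_hub:
        triples = (
            (local.hub, a, b) for a, b in itertools.combinations(others, 2)
        )
    else:
        triples = itertools.combinations(sorted(local.nodes), 3)
    for triple in triples:
        genes = tuple(sorted(triple))
        signs = [
            _edge_sign(local.graph, genes[a], genes[b]) for a, b in NPU_EDGE_ORDER
        ]
        if sum(1 for s in signs if s != 0) < 2:
            continue
        record = make_triad(genes, signs)
        counts[record.code] += 1
        records.append(record)
    return counts, records


@dataclass
class MotifOccurrenceTable:
    """Census result for one (hub, network) pair."""

    hub: str
    network_id: str
    cohort: str
    counts: dict[str, int]
    records: list[TriadRecord] = field(default_factory=list)


@dataclass
class ConservedTriple:
    """A gene triple observed as an edge-bearing hub motif in several
    networks spanning more than one cohort."""

    genes: tuple[str, str, str]
    n_networks: int
    cohorts: tuple[str, ...]
    per_network: dict[str, str]  # network id -> "Present(<topology>, <code>)" / "Absent"


def cross_network_conservation(
    tables: list[MotifOccurrenceTable],
    min_networks: int = 6,
    min_cohorts: int = 2,
) -> list[ConservedTriple]:
    """Report gene triples recurring across networks and cohorts.

    A triple qualifies when it appears as an edge-bearing hub motif in at
    least ``min_networks`` distinct networks drawn from at least
    ``min_cohorts`` distinct cohort tags.  A triple whose motif type varies
    between networks (say linear 021 in one, complete 030 in another) is
    reported once, with the per-network type spelled out.
    """
    network_ids: list[str] = []
    cohort_of: dict[str, str] = {}
    for t in tables:
        if t.network_id not in network_ids:
            network_ids.append(t.network_id)
        cohort_of[t.network_id] = t.cohort
    if len(network_ids) < 2:
        raise ConfigurationError("conservation analysis needs at least 2 networks")
    if min_networks > len(network_ids):
        raise ConfigurationError(
            f"min_networks={min_networks} exceeds the {len(network_ids)} networks supplied"
        )

    seen: dict[frozenset, dict[str, TriadRecord]] = {}
    for t in tables:
        for record in t.records:
            seen.setdefault(record.key, {}).setdefault(t.network_id, record)

    conserved: list[ConservedTriple] = []
    for key, per_net in sorted(seen.items(), key=lambda kv: tuple(sorted(kv[0]))):
        present = sorted(per_net, key=network_ids.index)
        cohorts = tuple(sorted({cohort_of[n] for n in present}))
        if len(present) < min_networks or len(cohorts) < min_cohorts:
            continue
        report = {}
        for nid in network_ids:
            if nid in per_net:
                r = per_net[nid]
                report[nid] = f"Present({r.topology}, {r.code})"
            else:
                report[nid] = "Absent"
        conserved.append(
            ConservedTriple(
                genes=tuple(sorted(key)),
                n_networks=len(present),
                cohorts=cohorts,
                per_network=report,
            )
        )
    return conserved


def write_census_table(tables: list[MotifOccurrenceTable], path) -> None:
    """TSV with one row per (hub, network) and one column per census code."""
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["hub", "network", "cohort", *CENSUS_CODES])
        for t in tables:
            writer.writerow(
                [t.hub, t.network_id, t.cohort, *(t.counts[c] for c in CENSUS_CODES)]
            )


def write_triad_records(tables: list[MotifOccurrenceTable], path) -> None:
    """All observed triad records as JSON lines (one record per line)."""
    import json
    from pathlib import Path

    with Path(path).open("w") as fh:
        for t in tables:
            for r in t.records:
                fh.write(json.dumps({
                    "hub": t.hub,
                    "network": t.network_id,
                    "cohort": t.cohort,
                    "genes": list(r.genes),
                    "code": r.code,
                    "topology": r.topology,
                    "coherence": r.coherence,
                    "centre": r.centre,
                    "edge_signs": {
                        "|".join(sorted(pair)): s for pair, s in sorted(
                            r.edge_signs.items(), key=lambda kv: sorted(kv[0])
                        )
                    },
                }, sort_keys=True) + "\n")


def write_conservation_table(
    conserved: list[ConservedTriple], network_ids: list[str], path
) -> None:
    """TSV with one row per conserved triple, one column per network."""
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["triple", *network_ids])
        for c in conserved:
            writer.writerow(
                ["-".join(c.genes), *(c.per_network.get(n, "Absent") for n in network_ids)]
            )
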