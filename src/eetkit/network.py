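"""Transfer-network products: time-constant classes, antenna groups, routes.

The time-constant map of a pigment or domain rate matrix is summarized three
ways, mirroring how light-harvesting EET networks are reported:

* **edge classes** — each directional pair binned by its time constant τ into
  <1 ps (FAST), 1–10 ps (MID), 10–20 ps (SLOW) and ≥20 ps (OMITTED); bins are
  half-open on the left;
* **antenna groups** — connected components of the undirected graph over
  antenna domains with an edge whenever the better direction satisfies
  min(τ_DA, τ_AD) ≤ cutoff (default: the 20 ps omission threshold);
* **ranked routes** — simple paths from a source to a target domain ranked by
  their bottleneck (slowest-step) τ, which captures mediated transfer through
  intermediate antennae; a summed-τ score is available behind a flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import networkx as nx
import numpy as np

from .constants import CONSTANTS_VERSION
from .errors import NetworkError
from .forster import RateMatrix
from .generalized_forster import DomainRateMatrix

DEFAULT_BINS = (1.0, 10.0, 20.0)
DEFAULT_GROUP_CUTOFF_PS = 20.0


class TauClass(str, Enum):
    FAST = "FAST"
    MID = "MID"
    SLOW = "SLOW"
    OMITTED = "OMITTED"


@dataclass(frozen=True)
class EdgeClass:
    donor: str
    acceptor: str
    tau_ps: float
    tau_class: TauClass


@dataclass(frozen=True)
class RouteResult:
    domains: tuple[str, ...]
    step_tau_ps: tuple[float, ...]
    bottleneck_ps: float
    rank: int

    def __post_init__(self) -> None:
        if len(set(self.domains)) != len(self.domains):
            raise NetworkError("route visits a domain twice")


def _directional_taus(rates: RateMatrix | DomainRateMatrix):
    ids = rates.ids if isinstance(rates, RateMatrix) else rates.domain_ids
    tau = rates.tau
    for i, d in enumerate(ids):
        for j, a in enumerate(ids):
            if i != j:
                yield d, a, float(tau[i, j])


def classify_tau(tau: float, bins=DEFAULT_BINS) -> TauClass:
    """Bin one time constant; half-open [lo, hi) bins, ≥ last edge → OMITTED."""
    if tau < bins[0]:
        return TauClass.FAST
    if tau < bins[1]:
        return TauClass.MID
    if tau < bins[2]:
        return TauClass.SLOW
    return TauClass.OMITTED


def classify_edges(
    rates: RateMatrix | DomainRateMatrix, bins=DEFAULT_BINS
) -> list[EdgeClass]:
    """Classify every directional pair by its time constant."""
    bins = tuple(float(b) for b in bins)
    if len(bins) != 3:
        raise NetworkError(f"expected 3 bin edges, got {len(bins)}")
    if not (0 < bins[0] < bins[1] < bins[2]):
        raise NetworkError(f"bin edges must be positive and ascending: {bins}")
    return [
        EdgeClass(d, a, tau, classify_tau(tau, bins))
        for d, a, tau in _directional_taus(rates)
    ]


def group_antennae(
    rates: DomainRateMatrix,
    *,
    cutoff_ps: float = DEFAULT_GROUP_CUTOFF_PS,
    core_id: str | None = "CORE",
) -> list[list[str]]:
    """Partition antenna domains into groups by mutual transfer reach.

    Connected components of the undirected graph over non-core domains with
    an edge when min(τ_DA, τ_AD) ≤ cutoff. Groups are sorted by their
    smallest member id, members sorted within each group.
    """
    if cutoff_ps <= 0:
        raise NetworkError("cutoff must be positive")
    ids = list(rates.domain_ids)
    if core_id is not None:
        if core_id not in ids:
            raise NetworkError(f"unknown core domain {core_id!r}")
        ids = [d for d in ids if d != core_id]
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    for i, d in enumerate(ids):
        for a in ids[i + 1 :]:
            best = min(rates.tau_of(d, a), rates.tau_of(a, d))
            if best <= cutoff_ps:
                graph.add_edge(d, a)
    groups = [sorted(c) for c in nx.connected_components(graph)]
    return sorted(groups, key=lambda g: g[0])


def rank_routes(
    rates: DomainRateMatrix,
    source: str,
    target: str,
    *,
    max_steps: int = 3,
    top_k: int | None = None,
    score: str = "bottleneck",
) -> list[RouteResult]:
    """Enumerate simple source→target paths of ≤ max_steps edges, ranked.

    Default ranking is ascending bottleneck τ (the slowest step limits the
    route); ``score="sum"`` ranks by total τ instead. Ties break by path
    length, then lexicographic domain ids.
    """
    ids = rates.domain_ids
    for dom in (source, target):
        if dom not in ids:
            raise NetworkError(f"unknown domain {dom!r}")
    if source == target:
        raise NetworkError("source and target must differ")
    if max_steps < 1:
        raise NetworkError("max_steps must be >= 1")
    if score not in ("bottleneck", "sum"):
        raise NetworkError(f"unknown score {score!r}")
    graph = nx.DiGraph()
    graph.add_nodes_from(ids)
    for d, a, tau in _directional_taus(rates):
        if np.isfinite(tau):
            graph.add_edge(d, a, tau=tau)
    results = []
    for path in nx.all_simple_paths(graph, source, target, cutoff=max_steps):
        taus = tuple(graph[u][v]["tau"] for u, v in zip(path, path[1:]))
        results.append((tuple(path), taus, max(taus), sum(taus)))
    key = (lambda r: (r[2], len(r[0]), r[0])) if score == "bottleneck" else (
        lambda r: (r[3], len(r[0]), r[0])
    )
    results.sort(key=key)
    if top_k is not None:
        results = results[:top_k]
    return [
        RouteResult(domains=p, step_tau_ps=t, bottleneck_ps=b, rank=i + 1)
        for i, (p, t, b, _) in enumerate(results)
    ]


def export_network(
    rates: RateMatrix | DomainRateMatrix,
    classes: list[EdgeClass],
    groups: list[list[str]] | None,
    outdir: str | Path,
    *,
    bins=DEFAULT_BINS,
    cutoff_ps: float = DEFAULT_GROUP_CUTOFF_PS,
) -> dict[str, Path]:
    """Write edge-list CSV (all edges), GraphML (OMITTED dropped) and a JSON
    summary with the binning/grouping metadata. Returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    edges_csv = outdir / "edges.csv"
    graphml = outdir / "network.graphml"
    summary_json = outdir / "summary.json"

    with open(edges_csv, "w") as fh:
        fh.write("donor,acceptor,tau_ps,tau_class\n")
        for e in classes:
            fh.write(f"{e.donor},{e.acceptor},{e.tau_ps!r},{e.tau_class.value}\n")

    graph = nx.DiGraph()
    ids = rates.ids if isinstance(rates, RateMatrix) else rates.domain_ids
    graph.add_nodes_from(ids)
    for e in classes:
        if e.tau_class is not TauClass.OMITTED:
            graph.add_edge(e.donor, e.acceptor, tau_ps=e.tau_ps, tau_class=e.tau_class.value)
    nx.write_graphml(graph, graphml)

    summary = {
        "bins_ps": list(bins),
        "group_cutoff_ps": cutoff_ps,
        "constants_version": CONSTANTS_VERSION,
        "n_nodes": len(ids),
        "n_edges_kept": graph.number_of_edges(),
        "class_counts": {
            c.value: sum(1 for e in classes if e.tau_class is c) for c in TauClass
        },
        "groups": groups,
    }
    summary_json.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return {"edges_csv": edges_csv, "graphml": graphml, "summary_json": summary_json}
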