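"""Condition-specific ceRNA networks: assembly, gain/loss extraction, topology.

A ceRNA network has lncRNA and mRNA nodes; an edge connects a pair that
significantly competes for at least one miRNA.  Each edge carries the set
of mediating miRNAs (the union over that pair's significant triples), the
best (maximum) deltaI and the best (minimum) permutation p-value.

The gain network holds cancer-network edges whose two endpoints are both
up-regulated in cancer; the loss network holds normal-network edges whose
endpoints are both down-regulated in cancer.  Pairs present in both input
networks are removed first, then the strongest 5% of sign-passing edges
are kept, ranked by the link score (sum of the two endpoints' mean log2
expression differences, cancer minus normal).
"""
from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    CANCER,
    NORMAL,
    ConditionTable,
    ExpressionMatrix,
    GeneAnnotation,
    ParseError,
    ValidationError,
)
from .inference import SpongeTriple

DEFAULT_TOP_FRACTION = 0.05
DEFAULT_HUB_MIN_DEGREE = 15

_NETWORK_HEADER = ["lncrna_id", "mrna_id", "mirna_ids", "best_delta_i", "best_p"]


@dataclass(frozen=True)
class EdgeData:
    mirnas: frozenset[str]
    best_delta_i: float
    best_p: float


@dataclass
class CeRNANetwork:
    """lncRNA-mRNA competition network for one condition."""

    condition: str
    edges: dict[tuple[str, str], EdgeData]

    def __post_init__(self) -> None:
        for (lnc, mrna), data in self.edges.items():
            if not data.mirnas:
                raise ValidationError(f"edge ({lnc}, {mrna}) has an empty miRNA set")

    @property
    def lncrnas(self) -> frozenset[str]:
        return frozenset(l for l, _ in self.edges)

    @property
    def mrnas(self) -> frozenset[str]:
        return frozenset(g for _, g in self.edges)

    @property
    def mirnas(self) -> frozenset[str]:
        out: set[str] = set()
        for data in self.edges.values():
            out |= data.mirnas
        return frozenset(out)

    @property
    def nodes(self) -> frozenset[str]:
        return self.lncrnas | self.mrnas

    def __len__(self) -> int:
        return len(self.edges)

    def to_graph(self) -> nx.Graph:
        """Bipartite lncRNA-mRNA graph view (miRNA sets as edge attributes)."""
        graph = nx.Graph()
        for lnc in self.lncrnas:
            graph.add_node(lnc, feature_class="lncRNA")
        for mrna in self.mrnas:
            graph.add_node(mrna, feature_class="mRNA")
        for (lnc, mrna), data in self.edges.items():
            graph.add_edge(
                lnc, mrna, mirnas=data.mirnas, best_delta_i=data.best_delta_i,
                best_p=data.best_p,
            )
        return graph


def assemble_network(triples: Sequence[SpongeTriple], condition: str) -> CeRNANetwork:
    """Group significant triples into one edge per (lncRNA, mRNA) pair."""
    wrong = [t for t in triples if t.condition != condition]
    if wrong:
        raise ValidationError(
            f"{len(wrong)} triples are not from condition {condition!r}"
        )
    edges: dict[tuple[str, str], EdgeData] = {}
    for t in triples:
        key = (t.lncrna, t.mrna)
        if key in edges:
            prev = edges[key]
            edges[key] = EdgeData(
                prev.mirnas | {t.mirna},
                max(prev.best_delta_i, t.delta_i),
                min(prev.best_p, t.p_value),
            )
        else:
            edges[key] = EdgeData(frozenset({t.mirna}), t.delta_i, t.p_value)
    return CeRNANetwork(condition, edges)


def write_network(network: CeRNANetwork, path: str | Path) -> None:
    rows = [
        {
            "lncrna_id": lnc,
            "mrna_id": mrna,
            "mirna_ids": ",".join(sorted(data.mirnas)),
            "best_delta_i": repr(data.best_delta_i),
            "best_p": repr(data.best_p),
        }
        for (lnc, mrna), data in sorted(network.edges.items())
    ]
    header = "# condition=" + network.condition + "\n"
    body = pd.DataFrame(rows, columns=_NETWORK_HEADER).to_csv(sep="\t", index=False)
    Path(path).write_text(header + body)


def read_network(path: str | Path) -> CeRNANetwork:
    text = Path(path).read_text().splitlines()
    if not text or not text[0].startswith("# condition="):
        raise ParseError(f"{path}: missing '# condition=' line")
    condition = text[0].split("=", 1)[1]
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if list(df.columns) != _NETWORK_HEADER:
        raise ParseError(f"{path}: expected header {_NETWORK_HEADER}")
    edges: dict[tuple[str, str], EdgeData] = {}
    for row in df.itertuples(index=False):
        mirnas = frozenset(str(row.mirna_ids).split(","))
        if "" in mirnas or not mirnas:
            raise ParseError(
                f"{path}: malformed miRNA list for edge ({row.lncrna_id}, {row.mrna_id})"
            )
        edges[(row.lncrna_id, row.mrna_id)] = EdgeData(
            mirnas, float(row.best_delta_i), float(row.best_p)
        )
    return CeRNANetwork(condition, edges)


# ---------------------------------------------------------------------------
# Gain / loss extraction
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class LinkScoreRecord:
    """Per-edge between-condition expression change (cancer minus normal)."""

    edge: tuple[str, str]
    delta_lnc: float
    delta_mrna: float

    @property
    def link_score(self) -> float:
        return self.delta_lnc + self.delta_mrna


def _condition_mean(
    expr: ExpressionMatrix, feature: str, samples: Sequence[str]
) -> float:
    return float(np.mean(expr.vector(feature, list(samples))))


def link_score(
    edge: tuple[str, str],
    expr_lnc: ExpressionMatrix,
    expr_mrna: ExpressionMatrix,
    conditions: ConditionTable,
) -> LinkScoreRecord:
    """Mean log2 difference (cancer - normal) for both endpoints of an edge."""
    lnc, mrna = edge
    cancer = conditions.samples(CANCER)
    normal = conditions.samples(NORMAL)
    delta_lnc = _condition_mean(expr_lnc, lnc, cancer) - _condition_mean(
        expr_lnc, lnc, normal
    )
    delta_mrna = _condition_mean(expr_mrna, mrna, cancer) - _condition_mean(
        expr_mrna, mrna, normal
    )
    return LinkScoreRecord(edge, delta_lnc, delta_mrna)


def extract_gain_loss(
    cancer_net: CeRNANetwork,
    normal_net: CeRNANetwork,
    expr_lnc: ExpressionMatrix,
    expr_mrna: ExpressionMatrix,
    conditions: ConditionTable,
    top_frac: float = DEFAULT_TOP_FRACTION,
) -> tuple[CeRNANetwork, CeRNANetwork]:
    """Extract the gain and loss subnetworks.

    Shared (lncRNA, mRNA) pairs are dropped from both networks first.  Gain
    keeps cancer-specific edges with both endpoint deltas > 0, ranked by
    link score descending; loss keeps normal-specific edges with both
    deltas < 0, ranked ascending (most negative first).  Each side retains
    the top ``ceil(top_frac * n_eligible)`` edges; ties break by edge ids.
    """
    if not 0 < top_frac <= 1:
        raise ValidationError(f"top_frac must be in (0, 1], got {top_frac}")
    common = set(cancer_net.edges) & set(normal_net.edges)

    def _pick(net: CeRNANetwork, sign: int) -> dict[tuple[str, str], EdgeData]:
        eligible: list[tuple[LinkScoreRecord, tuple[str, str]]] = []
        for edge in net.edges:
            if edge in common:
                continue
            rec = link_score(edge, expr_lnc, expr_mrna, conditions)
            if sign * rec.delta_lnc > 0 and sign * rec.delta_mrna > 0:
                eligible.append((rec, edge))
        if not eligible:
            return {}
        k = max(1, ceil(top_frac * len(eligible)))
        eligible.sort(key=lambda t: (-sign * t[0].link_score, t[1]))
        return {edge: net.edges[edge] for _, edge in eligible[:k]}

    gain = CeRNANetwork(CANCER, _pick(cancer_net, +1))
    loss = CeRNANetwork(NORMAL, _pick(normal_net, -1))
    return gain, loss


# ---------------------------------------------------------------------------
# Topology and property analyses
# ---------------------------------------------------------------------------
def node_degrees(net: CeRNANetwork, count_mirnas: bool = False) -> dict[str, int]:
    """Distinct-neighbor degree per node.

    With ``count_mirnas`` the distinct mediating miRNAs on a node's edges
    are added to its connectivity (the convention under which a hub lncRNA
    is described by its mRNA partners plus its sponged miRNAs).
    """
    graph = net.to_graph()
    degrees = {node: int(deg) for node, deg in graph.degree()}
    if count_mirnas:
        for node in degrees:
            mediators: set[str] = set()
            for _, _, attrs in graph.edges(node, data=True):
                mediators |= attrs["mirnas"]
            degrees[node] += len(mediators)
    return degrees


def find_hubs(
    net: CeRNANetwork,
    min_degree: int = DEFAULT_HUB_MIN_DEGREE,
    count_mirnas: bool = False,
) -> list[str]:
    """Nodes with degree strictly greater than ``min_degree``, best first."""
    degrees = node_degrees(net, count_mirnas=count_mirnas)
    hubs = [n for n, d in degrees.items() if d > min_degree]
    return sorted(hubs, key=lambda n: (-degrees[n], n))


@dataclass(frozen=True)
class PropertyComparison:
    property_name: str
    mean_in: float
    mean_out: float
    median_in: float
    median_out: float
    fold_change: float  # mean_in / mean_out
    u_statistic: float
    p_value: float  # two-sided, normal approximation with tie correction


def compare_lncrna_properties(
    network_lncrnas: Iterable[str],
    all_lncrnas: Iterable[str],
    annotation: GeneAnnotation,
) -> dict[str, PropertyComparison]:
    """Mann-Whitney U comparison of transcript length and exon count.

    ``network_lncrnas`` (lncRNA-IN) are compared against the remaining
    lncRNAs (lncRNA-OUT) for each annotated property.
    """
    in_ids = sorted(set(network_lncrnas))
    out_ids = sorted(set(all_lncrnas) - set(in_ids))
    if not in_ids or not out_ids:
        raise ValidationError("both lncRNA-IN and lncRNA-OUT must be non-empty")
    out: dict[str, PropertyComparison] = {}
    for prop, getter in (
        ("length", annotation.lengths),
        ("exons", annotation.exon_counts),
    ):
        x_in = getter(in_ids)
        x_out = getter(out_ids)
        res = stats.mannwhitneyu(x_in, x_out, alternative="two-sided", method="asymptotic")
        out[prop] = PropertyComparison(
            property_name=prop,
            mean_in=float(np.mean(x_in)),
            mean_out=float(np.mean(x_out)),
            median_in=float(np.median(x_in)),
            median_out=float(np.median(x_out)),
            fold_change=float(np.mean(x_in) / np.mean(x_out)),
            u_statistic=float(res.statistic),
            p_value=float(res.pvalue),
        )
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    overlap: int  # k
    reference_size: int  # K
    sample_size: int  # n
    universe_size: int  # N
    p_value: float  # P(X >= k), hypergeometric upper tail


def set_enrichment(
    hits: Iterable[str], reference: Iterable[str], universe_size: int
) -> EnrichmentResult:
    """Hypergeometric upper-tail enrichment of ``hits`` in ``reference``."""
    hits, reference = set(hits), set(reference)
    k = len(hits & reference)
    big_k, n = len(reference), len(hits)
    if universe_size < 1 or big_k > universe_size or n > universe_size:
        raise ValidationError(
            f"impossible counts: N={universe_size}, K={big_k}, n={n}"
        )
    p = float(stats.hypergeom.sf(k - 1, universe_size, big_k, n))
    return EnrichmentResult(k, big_k, n, universe_size, min(p, 1.0))
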