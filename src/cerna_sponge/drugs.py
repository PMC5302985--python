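"""Map drug -> miRNA regulation records onto the gain/loss networks.

A drug that up-regulates a miRNA mediating gain edges would strengthen
miRNA repression of the cancer-up-regulated pair, so it is nominated
against the gain network; a drug that down-regulates a miRNA mediating
loss edges would de-repress the pair lost in cancer, so it is nominated
against the loss network.  Other combinations are direction mismatches.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

from .datatypes import DrugEffectTable
from .network import CeRNANetwork

logger = logging.getLogger("cerna_sponge")

GAIN = "gain"
LOSS = "loss"


@dataclass(frozen=True)
class DrugCandidate:
    drug_name: str
    mirna_id: str
    network: str  # "gain" | "loss"
    direction: str  # "up" | "down"
    affected_edges: tuple[tuple[str, str], ...]


def _mirna_to_edges(net: CeRNANetwork) -> dict[str, tuple[tuple[str, str], ...]]:
    index: dict[str, list[tuple[str, str]]] = {}
    for edge, data in net.edges.items():
        for mirna in data.mirnas:
            index.setdefault(mirna, []).append(edge)
    return {m: tuple(sorted(edges)) for m, edges in index.items()}


def infer_drug_candidates(
    gain: CeRNANetwork, loss: CeRNANetwork, drugs: DrugEffectTable
) -> list[DrugCandidate]:
    """Relational join of drug records with the mediator miRNAs of each network.

    "up" records match the gain network, "down" records the loss network;
    a drug whose miRNA mediates no edge of the matching network is omitted.
    Conflicting records (same drug and miRNA in both directions) yield both
    candidates with a logged warning.
    """
    gain_index = _mirna_to_edges(gain)
    loss_index = _mirna_to_edges(loss)
    seen_directions: dict[tuple[str, str], set[str]] = {}
    out: list[DrugCandidate] = []
    for drug, mirna, direction in drugs.records.itertuples(index=False):
        dirs = seen_directions.setdefault((drug, mirna), set())
        dirs.add(direction)
        if len(dirs) > 1:
            logger.warning(
                "conflicting drug records: %s regulates %s both up and down", drug, mirna
            )
        index = gain_index if direction == "up" else loss_index
        edges = index.get(mirna)
        if edges:
            out.append(
                DrugCandidate(
                    drug_name=drug,
                    mirna_id=mirna,
                    network=GAIN if direction == "up" else LOSS,
                    direction=direction,
                    affected_edges=edges,
                )
            )
    out.sort(key=lambda c: (c.network, c.drug_name, c.mirna_id))
    return out
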