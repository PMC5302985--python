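"""High-expression lncRNA selection and candidate triple enumeration.

A lncRNA can only titrate miRNAs away from an mRNA if it is abundant, so
the first filter keeps the most highly expressed lncRNAs per condition
(top 5% by mean, following the convention that sponges are drawn from the
top of the expression distribution).  The second filter requires a
lncRNA-mRNA pair to share most of their miRNA regulators: with N_A miRNAs
targeting the lncRNA, N_B targeting the mRNA and n shared, the pair is a
candidate when the Jaccard index n / (N_A + N_B - n) >= 0.7.  One
candidate triple is emitted per shared miRNA.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .datatypes import ExpressionMatrix, TargetMap, ValidationError

logger = logging.getLogger("cerna_sponge")

DEFAULT_OVERLAP_THRESHOLD = 0.7
DEFAULT_TOP_FRACTION = 0.05


@dataclass(frozen=True, order=True)
class CandidateTriple:
    """A (lncRNA, mRNA, miRNA) triple passing the shared-regulator filter."""

    lncrna: str
    mrna: str
    mirna: str
    overlap_score: float
    condition: str


def select_high_expression(
    expr: ExpressionMatrix,
    condition_samples: Sequence[str],
    fraction: float = DEFAULT_TOP_FRACTION,
    top_k: int | None = None,
) -> list[str]:
    """Top lncRNAs by mean expression over ``condition_samples``.

    Returns the top ``floor(fraction * N)`` ids (at least one), sorted by
    mean descending with ties broken by id ascending.  ``top_k`` overrides
    the fraction with an absolute count.
    """
    condition_samples = list(condition_samples)
    if not condition_samples:
        raise ValidationError("condition sample set is empty")
    if not 0 < fraction <= 1:
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    missing = set(condition_samples) - set(expr.sample_ids)
    if missing:
        raise ValidationError(f"samples not in matrix: {sorted(missing)[:5]}")
    means = expr.data[condition_samples].mean(axis=1)
    order = sorted(means.index, key=lambda i: (-means[i], i))
    k = top_k if top_k is not None else max(1, int(fraction * len(order)))
    return order[:k]


def shared_mirna_score(mirnas_a: Iterable[str], mirnas_b: Iterable[str]) -> float:
    """Jaccard index |A n B| / |A u B| of two miRNA regulator sets."""
    a, b = set(mirnas_a), set(mirnas_b)
    if not a and not b:
        logger.warning("shared_mirna_score: both regulator sets empty; score 0")
        return 0.0
    return len(a & b) / len(a | b)


def enumerate_candidate_triples(
    targets: TargetMap,
    high_lncrnas: Sequence[str],
    mrna_ids: Iterable[str],
    threshold: float = DEFAULT_OVERLAP_THRESHOLD,
    condition: str = "cancer",
) -> list[CandidateTriple]:
    """All triples (L, G, M) with Jaccard(miRNAs(L), miRNAs(G)) >= threshold.

    The comparison is inclusive and one triple is emitted per shared miRNA,
    ordered (lncRNA, mRNA, miRNA) lexicographically.
    """
    out: list[CandidateTriple] = []
    for lnc in sorted(set(high_lncrnas)):
        mirnas_l = targets.mirnas_of(lnc)
        if not mirnas_l:
            continue
        for mrna in sorted(set(mrna_ids)):
            mirnas_g = targets.mirnas_of(mrna)
            if not mirnas_g:
                continue
            score = shared_mirna_score(mirnas_l, mirnas_g)
            if score >= threshold:
                out.extend(
                    CandidateTriple(lnc, mrna, m, score, condition)
                    for m in sorted(mirnas_l & mirnas_g)
                )
    return out
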