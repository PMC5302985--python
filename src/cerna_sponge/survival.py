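"""Prognostic value of ceRNA pairs: K-means stratification + log-rank test.

For each lncRNA-mRNA edge, patients are clustered into two groups by
K-means (K = 2) on the pair's standardized expression, and overall
survival of the two groups is compared with a Kaplan-Meier estimate and
the two-group log-rank test.  A pair is called prognostic when the
log-rank p-value passes the chosen level.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from sklearn.cluster import KMeans

from .datatypes import ClinicalTable, ExpressionMatrix, ValidationError
from .network import CeRNANetwork

logger = logging.getLogger("cerna_sponge")


class DegenerateClusteringError(ValueError):
    """Raised when the two-group clustering collapses to one group."""


@dataclass(frozen=True)
class KMCurve:
    """One group's Kaplan-Meier step function."""

    times: np.ndarray  # event times, ascending
    survival: np.ndarray  # S(t) immediately after each event time
    at_risk: np.ndarray  # risk-set size just before each event time


@dataclass(frozen=True)
class PrognosticResult:
    lncrna: str
    mrna: str
    n_group0: int
    n_group1: int
    logrank_chi2: float
    p_value: float
    km_curves: dict[int, KMCurve]


def kmeans_two_groups(
    pair_expr: np.ndarray, seed: int = 0, n_restarts: int = 10
) -> np.ndarray:
    """Cluster patients into two groups on (lncRNA, mRNA) expression.

    Columns are standardized to zero mean / unit variance before Lloyd's
    algorithm with k-means++ seeding (best of ``n_restarts``).  Labels are
    canonical: group 1 is the cluster with the higher mean lncRNA
    expression (first column), so the labeling does not depend on
    initialization or row order.
    """
    x = np.asarray(pair_expr, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValidationError(f"pair_expr must be (n_patients, 2), got {x.shape}")
    if x.shape[0] < 4:
        raise ValidationError("need at least 4 patients to cluster")
    if np.allclose(x, x[0]):
        raise DegenerateClusteringError("all patients identical: degenerate")
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(z)
    if len(np.unique(labels)) < 2:
        raise DegenerateClusteringError("clustering produced a single group")
    mean_lnc = [x[labels == grp, 0].mean() for grp in (0, 1)]
    if mean_lnc[0] > mean_lnc[1]:
        labels = 1 - labels
    return labels


def km_estimate(
    times: np.ndarray, events: np.ndarray, labels: np.ndarray
) -> dict[int, KMCurve]:
    """Product-limit survival estimate per group label."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    labels = np.asarray(labels)
    if (times < 0).any():
        raise ValidationError("negative survival times")
    out: dict[int, KMCurve] = {}
    for grp in np.unique(labels):
        mask = labels == grp
        fitter = KaplanMeierFitter()
        fitter.fit(times[mask], events[mask])
        table = fitter.event_table.iloc[1:]  # drop the t=0 anchor row
        event_rows = table[table["observed"] > 0]
        out[int(grp)] = KMCurve(
            times=event_rows.index.to_numpy(dtype=float),
            survival=fitter.survival_function_at_times(event_rows.index).to_numpy(),
            at_risk=event_rows["at_risk"].to_numpy(dtype=float),
        )
    return out


def logrank_test(
    times: np.ndarray, events: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p) with 1 degree of freedom."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValidationError(f"need exactly 2 non-empty groups, got {len(groups)}")
    a, b = groups
    res = _lifelines_logrank(
        times[labels == a], times[labels == b],
        event_observed_A=events[labels == a], event_observed_B=events[labels == b],
    )
    return float(res.test_statistic), float(res.p_value)


def scan_prognostic_pairs(
    net: CeRNANetwork,
    expr_lnc: ExpressionMatrix,
    expr_mrna: ExpressionMatrix,
    clinical: ClinicalTable,
    alpha: float = 0.05,
    seed: int = 0,
    n_restarts: int = 10,
) -> list[PrognosticResult]:
    """K-means + log-rank over every network edge; keep pairs with p < alpha.

    Only patients present in the clinical table and both expression
    matrices are used.  Edges whose clustering degenerates are skipped with
    a logged reason.  Results are sorted by ascending p, then ids.
    """
    patients = sorted(
        set(clinical.sample_ids) & set(expr_lnc.sample_ids) & set(expr_mrna.sample_ids)
    )
    if not patients:
        raise ValidationError("no patients with both clinical and expression data")
    times, events = clinical.aligned(patients)
    results: list[PrognosticResult] = []
    for lnc, mrna in sorted(net.edges):
        pair = np.column_stack(
            [expr_lnc.vector(lnc, patients), expr_mrna.vector(mrna, patients)]
        )
        try:
            labels = kmeans_two_groups(pair, seed=seed, n_restarts=n_restarts)
        except DegenerateClusteringError as exc:
            logger.warning("skipping pair (%s, %s): %s", lnc, mrna, exc)
            continue
        chi2, p = logrank_test(times, events, labels)
        if p < alpha:
            results.append(
                PrognosticResult(
                    lncrna=lnc,
                    mrna=mrna,
                    n_group0=int(np.sum(labels == 0)),
                    n_group1=int(np.sum(labels == 1)),
                    logrank_chi2=chi2,
                    p_value=p,
                    km_curves=km_estimate(times, events, labels),
                )
            )
    results.sort(key=lambda r: (r.p_value, r.lncrna, r.mrna))
    return results
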