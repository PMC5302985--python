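"""Synthetic two-condition expression dataset with planted ceRNA structure.

The generator emulates a matched lncRNA / mRNA / miRNA expression study
of cancer and normal samples, together with every side table the
pipeline consumes (miRNA-target map, gene annotation, clinical follow-up,
reference sets, drug effects) and a ground-truth record for evaluation.

Generative model (all expression on log2 scale)
-----------------------------------------------
* miRNA expression  m ~ Normal(mu_m, 1) i.i.d. per sample, mu_m ~ U(3, 7).
* Background lncRNAs and mRNAs are independent Gaussian noise around
  their feature means.
* For a planted sponge triple (L, M, G) in condition c, the lncRNA gates
  miRNA repression of the mRNA through a logistic de-repression term:

      G = alpha - beta * a_M * g(L) + eps,     g(L) = 1 / (1 + exp(L - mu_L))

  where a_M = (m - mu_m) + 1 is the miRNA's activity around a baseline of
  one, beta is the sponge coupling strength, and eps ~ Normal(0, sigma).
  When L is high, g -> 0 and the repression (and the miRNA-mRNA
  dependence) vanishes; when L is low, g -> 1 and repression is full.
  The miRNA term is centered so the lncRNA contributes modulation and a
  modest mean de-repression rather than dominating the mRNA's variance.
  In the other condition the same mRNA keeps plain, unmodulated
  repression (gate fixed at 1/2), so the sponge relation is specific to c.
* Matched decoy mRNAs repeat the unmodulated-repression construction in
  every sample: they share the planted pair's regulator overlap but carry
  no sponge signal, providing the false-positive control.
* Planted lncRNAs draw their means from the upper tail (99.5th-99.99th
  percentile) of the background mean distribution so they pass the
  top-5% high-expression filter; triples share lncRNAs (at most 6 triples
  per lncRNA) so all planted lncRNAs fit inside that 5% list and each
  pair's regulator Jaccard stays at 7/9.
* Differential (gain / loss) edges: the first ``n_diff_edges`` planted
  pairs of the cancer (resp. normal) condition have both endpoints
  shifted +2 (resp. -2) in cancer samples relative to normal.
* Survival: the planted prognostic pair is the first gain pair; cancer
  patients are split by two-group clustering of that pair's expression,
  the high-expression cluster is "poor", and poor patients draw
  exponential survival times at ``hazard_ratio`` times the baseline
  rate; 20% of patients are independently censored.
* Annotation mirrors the observation that sponge lncRNAs are longer and
  exon-richer: planted lncRNAs ~ Normal(1683, 300) nt with 1+Poisson(3)
  exons, others ~ Normal(935, 300) nt with 1+Poisson(2) exons.

Everything is deterministic given ``SyntheticConfig.seed``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    CANCER,
    NORMAL,
    ClinicalTable,
    ConditionTable,
    DrugEffectTable,
    ExpressionMatrix,
    GeneAnnotation,
    ReferenceSets,
    TargetMap,
    ValidationError,
    write_clinical_table,
    write_condition_table,
    write_drug_effect_table,
    write_expression_matrix,
    write_gene_annotation,
    write_target_map,
)

# fixed distributional constants of the simulated cohort
LNC_MEAN_LOC, LNC_MEAN_SCALE = 5.0, 1.5
MRNA_BASELINE = 8.0
MIRNA_MEAN_RANGE = (3.0, 7.0)
MIRNA_ACTIVITY_BASELINE = 1.0
DIFF_SHIFT = 2.0
MIRNAS_PER_SPONGE = 8
TRIPLES_PER_LNC = 6
CENSORING_FRACTION = 0.2
BASELINE_MEDIAN_SURVIVAL = 60.0  # months
PLANTED_LNC_QUANTILES = (0.995, 0.9999)
LEN_IN, LEN_OUT = 1683.0, 935.0
LEN_SD = 300.0
EXONS_IN_RATE, EXONS_OUT_RATE = 3.0, 2.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic study; defaults define the standard conditions."""

    n_cancer: int = 60
    n_normal: int = 30
    n_lncrna: int = 300
    n_mrna: int = 1000
    n_mirna: int = 80
    n_planted_triples: int = 30  # per condition
    sponge_strength: float = 1.5  # beta
    noise_sd: float = 0.5  # sigma
    n_diff_edges: int = 10  # gain and loss counts
    hazard_ratio: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_cancer, self.n_normal, self.n_lncrna, self.n_mrna,
            self.n_mirna, self.n_planted_triples,
        )
        if any(c < 1 for c in counts):
            raise ValidationError("all counts must be positive")
        if self.sponge_strength < 0:
            raise ValidationError("sponge_strength (beta) must be >= 0")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd (sigma) must be > 0")
        if self.hazard_ratio <= 0:
            raise ValidationError("hazard_ratio must be > 0")
        if self.n_diff_edges > self.n_planted_triples:
            raise ValidationError("n_diff_edges cannot exceed n_planted_triples")
        if self.n_mrna < 4 * self.n_planted_triples:
            raise ValidationError("n_mrna too small for planted + decoy mRNAs")
        if self.n_mirna < MIRNAS_PER_SPONGE + 2:
            raise ValidationError("n_mirna too small for regulator pools")
        n_pool = 2 * ceil(self.n_planted_triples / TRIPLES_PER_LNC)
        if self.n_lncrna < 4 * n_pool:
            raise ValidationError("n_lncrna too small for planted lncRNA pools")


def full_cohort_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A 111-cancer / 28-normal layout typical of matched exon-array cohorts."""
    kwargs = dict(n_cancer=111, n_normal=28, seed=seed)
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth: what was planted, for evaluating the pipeline."""

    planted_triples: frozenset[tuple[str, str, str, str]]  # (L, M, G, condition)
    decoy_triples: frozenset[tuple[str, str, str, str]]
    planted_gain_edges: frozenset[tuple[str, str]]
    planted_loss_edges: frozenset[tuple[str, str]]
    prognostic_pairs: frozenset[tuple[str, str]]
    group_labels: dict[str, str]  # cancer sample -> "good" | "poor"

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_triples": sorted(map(list, self.planted_triples)),
                "decoy_triples": sorted(map(list, self.decoy_triples)),
                "planted_gain_edges": sorted(map(list, self.planted_gain_edges)),
                "planted_loss_edges": sorted(map(list, self.planted_loss_edges)),
                "prognostic_pairs": sorted(map(list, self.prognostic_pairs)),
                "group_labels": self.group_labels,
            },
            indent=1,
        )


@dataclass
class SyntheticDataset:
    expr_lnc: ExpressionMatrix
    expr_mrna: ExpressionMatrix
    expr_mirna: ExpressionMatrix
    conditions: ConditionTable
    targets: TargetMap
    annotation: GeneAnnotation
    clinical: ClinicalTable
    references: ReferenceSets
    drugs: DrugEffectTable
    truth: SyntheticTruth
    config: SyntheticConfig = field(default_factory=SyntheticConfig)


def _plan_triples(cfg: SyntheticConfig) -> dict[str, list[int]]:
    """Indices of planted lncRNAs per condition (disjoint pools)."""
    n_pool = ceil(cfg.n_planted_triples / TRIPLES_PER_LNC)
    return {CANCER: list(range(n_pool)), NORMAL: list(range(n_pool, 2 * n_pool))}


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate the full synthetic study for one configuration."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    beta, sigma = cfg.sponge_strength, cfg.noise_sd

    lnc_ids = [f"LNC{i + 1:04d}" for i in range(cfg.n_lncrna)]
    mrna_ids = [f"MRNA{i + 1:04d}" for i in range(cfg.n_mrna)]
    mirna_ids = [f"MIR{i + 1:03d}" for i in range(cfg.n_mirna)]
    samples = [f"C{i + 1:03d}" for i in range(cfg.n_cancer)] + [
        f"N{i + 1:03d}" for i in range(cfg.n_normal)
    ]
    is_cancer = np.array([s.startswith("C") for s in samples])
    n_samples = len(samples)
    conditions = ConditionTable(
        {s: CANCER if c else NORMAL for s, c in zip(samples, is_cancer)}
    )

    # ---- miRNA expression -------------------------------------------------
    mirna_means = rng.uniform(*MIRNA_MEAN_RANGE, size=cfg.n_mirna)
    mirna_values = mirna_means[:, None] + rng.normal(size=(cfg.n_mirna, n_samples))

    # ---- lncRNA means and planted pools -----------------------------------
    lnc_means = rng.normal(LNC_MEAN_LOC, LNC_MEAN_SCALE, size=cfg.n_lncrna)
    pools = _plan_triples(cfg)
    planted_lnc_idx = pools[CANCER] + pools[NORMAL]
    upper = rng.uniform(*PLANTED_LNC_QUANTILES, size=len(planted_lnc_idx))
    lnc_means[planted_lnc_idx] = stats.norm.ppf(upper, LNC_MEAN_LOC, LNC_MEAN_SCALE)

    lnc_base = lnc_means[:, None] + rng.normal(size=(cfg.n_lncrna, n_samples))
    lnc_shift = np.zeros((cfg.n_lncrna, n_samples))

    # ---- target map and triple layout -------------------------------------
    records: list[tuple[str, str, str]] = []
    planted: list[tuple[str, str, str, str]] = []  # (L, M, G, condition)
    decoys: list[tuple[str, str, str, str]] = []
    pair_order: dict[str, list[tuple[str, str, str]]] = {CANCER: [], NORMAL: []}

    mrna_values = MRNA_BASELINE + rng.normal(size=(cfg.n_mrna, n_samples))
    next_mrna = 0
    lnc_regulators: dict[int, list[int]] = {}

    for cond in (CANCER, NORMAL):
        cond_mask = is_cancer if cond == CANCER else ~is_cancer
        other_mask = ~cond_mask
        for t in range(cfg.n_planted_triples):
            li = pools[cond][t // TRIPLES_PER_LNC]
            if li not in lnc_regulators:
                lnc_regulators[li] = sorted(
                    rng.choice(cfg.n_mirna, size=MIRNAS_PER_SPONGE, replace=False)
                )
                records += [
                    (mirna_ids[m], lnc_ids[li], "lncRNA") for m in lnc_regulators[li]
                ]
            pool = lnc_regulators[li]
            mi = pool[t % TRIPLES_PER_LNC]

            gi, di = next_mrna, next_mrna + 1
            next_mrna += 2
            # regulators of the planted mRNA and its decoy: drop one non-coupled
            # pool member, add one private miRNA -> Jaccard 7/9 with the lncRNA
            for target_idx in (gi, di):
                droppable = [m for m in pool if m != mi]
                drop = droppable[int(rng.integers(len(droppable)))]
                outside = [m for m in range(cfg.n_mirna) if m not in pool]
                private = outside[int(rng.integers(len(outside)))]
                target_pool = sorted(set(pool) - {drop} | {private})
                records += [
                    (mirna_ids[m], mrna_ids[target_idx], "mRNA") for m in target_pool
                ]

            activity = mirna_values[mi] - mirna_means[mi] + MIRNA_ACTIVITY_BASELINE
            gate = 1.0 / (1.0 + np.exp(lnc_base[li] - lnc_means[li]))
            coupled = (
                MRNA_BASELINE
                - beta * activity * gate
                + rng.normal(0, sigma, n_samples)
            )
            flat = (
                MRNA_BASELINE
                - beta * activity * 0.5
                + rng.normal(0, sigma, n_samples)
            )
            mrna_values[gi] = np.where(cond_mask, coupled, flat)
            mrna_values[di] = (
                MRNA_BASELINE - beta * activity * 0.5 + rng.normal(0, sigma, n_samples)
            )
            planted.append((lnc_ids[li], mirna_ids[mi], mrna_ids[gi], cond))
            decoys.append((lnc_ids[li], mirna_ids[mi], mrna_ids[di], cond))
            pair_order[cond].append((lnc_ids[li], mrna_ids[gi], mirna_ids[mi]))

    # ---- background target assignments ------------------------------------
    planted_mrna_ids = {g for _, _, g, _ in planted} | {d for _, _, d, _ in decoys}
    planted_lnc_ids = {l for l, _, _, _ in planted}
    for fid in lnc_ids:
        if fid not in planted_lnc_ids:
            k = int(rng.integers(1, 4))
            for m in rng.choice(cfg.n_mirna, size=k, replace=False):
                records.append((mirna_ids[m], fid, "lncRNA"))
    for fid in mrna_ids:
        if fid not in planted_mrna_ids:
            k = int(rng.integers(1, 4))
            for m in rng.choice(cfg.n_mirna, size=k, replace=False):
                records.append((mirna_ids[m], fid, "mRNA"))
    targets = TargetMap(pd.DataFrame(records, columns=["mirna_id", "target_id", "target_class"]))

    # ---- differential (gain / loss) edges ----------------------------------
    gain_pairs = [(l, g) for l, g, _ in pair_order[CANCER][: cfg.n_diff_edges]]
    loss_pairs = [(l, g) for l, g, _ in pair_order[NORMAL][: cfg.n_diff_edges]]
    mrna_index = {fid: i for i, fid in enumerate(mrna_ids)}
    lnc_index = {fid: i for i, fid in enumerate(lnc_ids)}
    for pairs, shift in ((gain_pairs, DIFF_SHIFT), (loss_pairs, -DIFF_SHIFT)):
        for l, g in pairs:
            lnc_shift[lnc_index[l], is_cancer] = shift
            mrna_values[mrna_index[g], is_cancer] += shift
    lnc_values = lnc_base + lnc_shift

    # ---- survival ----------------------------------------------------------
    # One planted prognostic pair; its "poor" group is the high-expression
    # cluster of the pair's own cancer expression, so the planted labels are
    # exactly what a two-group clustering of that pair defines.
    from .survival import kmeans_two_groups

    anchor = (gain_pairs or [(l, g) for l, g, _ in pair_order[CANCER][:1]])[0]
    prognostic_pairs = [anchor]
    cancer_samples = [s for s, c in zip(samples, is_cancer) if c]
    pair_block = np.column_stack(
        [
            lnc_values[lnc_index[anchor[0]], is_cancer],
            mrna_values[mrna_index[anchor[1]], is_cancer],
        ]
    )
    poor = kmeans_two_groups(pair_block, seed=cfg.seed).astype(bool)
    group_labels = {
        s: ("poor" if flag else "good") for s, flag in zip(cancer_samples, poor)
    }
    lam = np.log(2.0) / BASELINE_MEDIAN_SURVIVAL
    rates = np.where(poor, lam * cfg.hazard_ratio, lam)
    event_times = rng.exponential(1.0 / rates)
    censored = rng.random(len(cancer_samples)) < CENSORING_FRACTION
    obs_times = np.where(
        censored, event_times * rng.uniform(0.1, 0.9, len(cancer_samples)), event_times
    )
    clinical = ClinicalTable(
        pd.DataFrame(
            {"time": np.round(obs_times, 3), "event": ~censored},
            index=pd.Index(cancer_samples, name="sample_id"),
        )
    )

    # ---- annotation ---------------------------------------------------------
    lengths = np.maximum(
        rng.normal(LEN_OUT, LEN_SD, cfg.n_lncrna), 200.0
    )
    exons = 1 + rng.poisson(EXONS_OUT_RATE, cfg.n_lncrna)
    planted_idx = [lnc_index[l] for l in sorted(planted_lnc_ids)]
    lengths[planted_idx] = np.maximum(
        rng.normal(LEN_IN, LEN_SD, len(planted_idx)), 200.0
    )
    exons[planted_idx] = 1 + rng.poisson(EXONS_IN_RATE, len(planted_idx))
    mrna_lengths = np.maximum(rng.normal(2500.0, 800.0, cfg.n_mrna), 200.0)
    mrna_exons = 1 + rng.poisson(8.0, cfg.n_mrna)
    annotation = GeneAnnotation(
        pd.DataFrame(
            {
                "length": np.round(np.concatenate([lengths, mrna_lengths]), 1),
                "exons": np.concatenate([exons, mrna_exons]),
            },
            index=pd.Index(lnc_ids + mrna_ids, name="feature_id"),
        )
    )

    # ---- reference sets and drugs ------------------------------------------
    loss_mrnas = [g for _, g in loss_pairs]
    background_mrnas = [f for f in mrna_ids if f not in planted_mrna_ids]
    ts_extra = list(
        rng.choice(background_mrnas, size=min(20, len(background_mrnas)), replace=False)
    )
    gain_mirnas = sorted({m for l, g, m in pair_order[CANCER][: cfg.n_diff_edges]})
    loss_mirnas = sorted({m for l, g, m in pair_order[NORMAL][: cfg.n_diff_edges]})
    planted_mirnas = {m for _, m, _, _ in planted}
    background_mirnas = [m for m in mirna_ids if m not in planted_mirnas]
    dm_extra = list(rng.choice(background_mirnas, size=min(10, len(background_mirnas)), replace=False))
    references = ReferenceSets(
        tumor_suppressors=frozenset(loss_mrnas) | frozenset(ts_extra),
        disease_mirnas=frozenset(gain_mirnas) | frozenset(loss_mirnas) | frozenset(dm_extra),
        universe_size=cfg.n_lncrna + cfg.n_mrna,
    )
    drug_records = [
        (f"gainomycin-{i + 1}", m, "up") for i, m in enumerate(gain_mirnas)
    ] + [
        (f"lossine-{i + 1}", m, "down") for i, m in enumerate(loss_mirnas)
    ] + [
        (f"inertol-{i + 1}", m, d)
        for i, (m, d) in enumerate(
            zip(dm_extra[:6], ["up", "down", "up", "down", "up", "down"])
        )
    ]
    drugs = DrugEffectTable(
        pd.DataFrame(drug_records, columns=["drug_name", "mirna_id", "direction"])
    )

    truth = SyntheticTruth(
        planted_triples=frozenset(planted),
        decoy_triples=frozenset(decoys),
        planted_gain_edges=frozenset(gain_pairs),
        planted_loss_edges=frozenset(loss_pairs),
        prognostic_pairs=frozenset(prognostic_pairs),
        group_labels=group_labels,
    )

    def _matrix(values: np.ndarray, ids: list[str], klass: str) -> ExpressionMatrix:
        return ExpressionMatrix(
            pd.DataFrame(np.round(values, 6), index=ids, columns=samples), klass
        )

    return SyntheticDataset(
        expr_lnc=_matrix(lnc_values, lnc_ids, "lncRNA"),
        expr_mrna=_matrix(mrna_values, mrna_ids, "mRNA"),
        expr_mirna=_matrix(mirna_values, mirna_ids, "miRNA"),
        conditions=conditions,
        targets=targets,
        annotation=annotation,
        clinical=clinical,
        references=references,
        drugs=drugs,
        truth=truth,
        config=cfg,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every table of the dataset (plus truth.json) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expr_lnc": outdir / "expr_lncrna.tsv",
        "expr_mrna": outdir / "expr_mrna.tsv",
        "expr_mirna": outdir / "expr_mirna.tsv",
        "conditions": outdir / "conditions.tsv",
        "targets": outdir / "targets.tsv",
        "annotation": outdir / "annotation.tsv",
        "clinical": outdir / "clinical.tsv",
        "tumor_suppressors": outdir / "tumor_suppressors.tsv",
        "disease_mirnas": outdir / "disease_mirnas.tsv",
        "drugs": outdir / "drug_effects.tsv",
        "truth": outdir / "truth.json",
    }
    write_expression_matrix(dataset.expr_lnc, paths["expr_lnc"])
    write_expression_matrix(dataset.expr_mrna, paths["expr_mrna"])
    write_expression_matrix(dataset.expr_mirna, paths["expr_mirna"])
    write_condition_table(dataset.conditions, paths["conditions"])
    write_target_map(dataset.targets, paths["targets"])
    write_gene_annotation(dataset.annotation, paths["annotation"])
    write_clinical_table(dataset.clinical, paths["clinical"])
    from .datatypes import write_id_set

    write_id_set(dataset.references.tumor_suppressors, paths["tumor_suppressors"])
    write_id_set(dataset.references.disease_mirnas, paths["disease_mirnas"])
    write_drug_effect_table(dataset.drugs, paths["drugs"])
    paths["truth"].write_text(dataset.truth.to_json())
    return paths
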