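"""End-to-end orchestration: config -> staged analysis -> reports.

The pipeline runs, in order: per-condition high-expression lncRNA
selection, candidate triple enumeration, deltaI + permutation inference,
condition network assembly, gain/loss extraction, topology / property /
enrichment reports, prognostic-pair scanning and drug mapping.  Every
intermediate is written as TSV next to a JSON manifest of parameters,
seed and per-stage record counts; two runs with the same config and
inputs produce byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import candidates as _cand
from . import drugs as _drugs
from . import inference as _inf
from . import network as _net
from . import survival as _surv
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
    read_clinical_table,
    read_condition_table,
    read_drug_effect_table,
    read_expression_matrix,
    read_gene_annotation,
    read_id_set,
    read_target_map,
)

logger = logging.getLogger("cerna_sponge")


@dataclass
class PipelineConfig:
    """File locations plus every analysis parameter, YAML-loadable."""

    expr_lnc: str = ""
    expr_mrna: str = ""
    expr_mirna: str = ""
    conditions: str = ""
    targets: str = ""
    annotation: str = ""
    clinical: str = ""
    tumor_suppressors: str = ""
    disease_mirnas: str = ""
    drugs: str = ""
    outdir: str = "results"

    fraction: float = 0.05
    top_k: int | None = None
    joint_top: bool = False
    overlap_threshold: float = 0.7
    n_perm: int = 1000
    alpha: float = 0.01
    n_bins: int = 8
    top_frac: float = 0.05
    min_degree: int = 15
    count_mirnas: bool = False
    survival_alpha: float = 0.05
    already_log2: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    high_lncrnas: dict[str, list[str]]
    candidates: list[_cand.CandidateTriple]
    sponge_triples: list[_inf.SpongeTriple]
    cancer_net: _net.CeRNANetwork
    normal_net: _net.CeRNANetwork
    gain: _net.CeRNANetwork
    loss: _net.CeRNANetwork
    hubs: dict[str, list[str]]
    properties: dict[str, _net.PropertyComparison]
    enrichment: dict[str, _net.EnrichmentResult]
    prognostic: dict[str, list[_surv.PrognosticResult]]
    drug_candidates: list[_drugs.DrugCandidate]
    manifest: dict = field(default_factory=dict)


def run_analysis(
    expr_lnc: ExpressionMatrix,
    expr_mrna: ExpressionMatrix,
    expr_mirna: ExpressionMatrix,
    conditions: ConditionTable,
    targets: TargetMap,
    annotation: GeneAnnotation | None = None,
    clinical: ClinicalTable | None = None,
    references: ReferenceSets | None = None,
    drugs: DrugEffectTable | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run every stage on in-memory objects; side tables are optional."""
    cfg = config or PipelineConfig()
    mi_cfg = _inf.MIEstimatorConfig(n_bins=cfg.n_bins)
    stage_t0 = time.perf_counter()

    def _tick(stage: str, count: int) -> None:
        nonlocal stage_t0
        logger.info("%s: %d records (%.1fs)", stage, count, time.perf_counter() - stage_t0)
        stage_t0 = time.perf_counter()

    # 1. high-expression lncRNAs, per condition (or one joint list)
    if cfg.joint_top:
        joint = _cand.select_high_expression(
            expr_lnc, list(conditions.labels), cfg.fraction, cfg.top_k
        )
        high = {CANCER: joint, NORMAL: joint}
    else:
        high = {
            cond: _cand.select_high_expression(
                expr_lnc, conditions.samples(cond), cfg.fraction, cfg.top_k
            )
            for cond in (CANCER, NORMAL)
        }
    _tick("high-expression lncRNAs", sum(map(len, high.values())))

    # 2. candidate triples per condition
    mrnas = targets.targets("mRNA") & set(expr_mrna.feature_ids)
    cands: list[_cand.CandidateTriple] = []
    for cond in (CANCER, NORMAL):
        cands += _cand.enumerate_candidate_triples(
            targets, high[cond], mrnas, cfg.overlap_threshold, cond
        )
    _tick("candidate triples", len(cands))

    # 3. deltaI + permutation test
    sponges = _inf.infer_sponge_triples(
        cands, expr_lnc, expr_mrna, expr_mirna, conditions,
        alpha=cfg.alpha, n_perm=cfg.n_perm, seed=cfg.seed, cfg=mi_cfg,
    )
    _tick("significant sponge triples", len(sponges))

    # 4. condition networks
    cancer_net = _net.assemble_network(
        [t for t in sponges if t.condition == CANCER], CANCER
    )
    normal_net = _net.assemble_network(
        [t for t in sponges if t.condition == NORMAL], NORMAL
    )
    _tick("condition networks", len(cancer_net) + len(normal_net))

    # 5. gain / loss
    gain, loss = _net.extract_gain_loss(
        cancer_net, normal_net, expr_lnc, expr_mrna, conditions, cfg.top_frac
    )
    _tick("gain/loss edges", len(gain) + len(loss))

    # 6. topology, properties, enrichment
    hubs = {
        name: _net.find_hubs(net, cfg.min_degree, cfg.count_mirnas)
        for name, net in (("gain", gain), ("loss", loss))
    }
    properties: dict[str, _net.PropertyComparison] = {}
    network_lncrnas = cancer_net.lncrnas | normal_net.lncrnas
    if annotation is not None and network_lncrnas:
        outside = set(expr_lnc.feature_ids) - network_lncrnas
        if outside:
            properties = _net.compare_lncrna_properties(
                network_lncrnas, expr_lnc.feature_ids, annotation
            )
    enrichment: dict[str, _net.EnrichmentResult] = {}
    if references is not None:
        if references.tumor_suppressors and len(loss):
            enrichment["tumor_suppressors_in_loss"] = _net.set_enrichment(
                loss.nodes, references.tumor_suppressors, references.universe_size
            )
        if references.disease_mirnas:
            for name, net in (("gain", gain), ("loss", loss)):
                if len(net):
                    enrichment[f"disease_mirnas_in_{name}"] = _net.set_enrichment(
                        net.mirnas,
                        references.disease_mirnas,
                        len(expr_mirna.feature_ids),
                    )
    _tick("topology/enrichment", len(hubs["gain"]) + len(hubs["loss"]))

    # 7. prognosis on the gain and loss networks
    prognostic: dict[str, list[_surv.PrognosticResult]] = {"gain": [], "loss": []}
    if clinical is not None:
        for name, net in (("gain", gain), ("loss", loss)):
            if len(net):
                prognostic[name] = _surv.scan_prognostic_pairs(
                    net, expr_lnc, expr_mrna, clinical,
                    alpha=cfg.survival_alpha, seed=cfg.seed,
                )
    _tick("prognostic pairs", sum(map(len, prognostic.values())))

    # 8. drug mapping
    drug_candidates: list[_drugs.DrugCandidate] = []
    if drugs is not None:
        drug_candidates = _drugs.infer_drug_candidates(gain, loss, drugs)
    _tick("drug candidates", len(drug_candidates))

    manifest = {
        "parameters": {
            f.name: getattr(cfg, f.name)
            for f in dataclasses.fields(cfg)
            if f.name not in ("outdir",)
        },
        "counts": {
            "high_lncrnas_cancer": len(high[CANCER]),
            "high_lncrnas_normal": len(high[NORMAL]),
            "candidate_triples": len(cands),
            "sponge_triples": len(sponges),
            "cancer_edges": len(cancer_net),
            "normal_edges": len(normal_net),
            "gain_edges": len(gain),
            "loss_edges": len(loss),
            "gain_hubs": len(hubs["gain"]),
            "loss_hubs": len(hubs["loss"]),
            "prognostic_pairs": sum(map(len, prognostic.values())),
            "drug_candidates": len(drug_candidates),
        },
    }
    return PipelineResult(
        high, cands, sponges, cancer_net, normal_net, gain, loss,
        hubs, properties, enrichment, prognostic, drug_candidates, manifest,
    )


# ---------------------------------------------------------------------------
# File-level entry point and writers
# ---------------------------------------------------------------------------
def write_candidates(cands: list[_cand.CandidateTriple], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "lncrna_id": c.lncrna, "mrna_id": c.mrna, "mirna_id": c.mirna,
                "overlap_score": repr(c.overlap_score), "condition": c.condition,
            }
            for c in sorted(cands)
        ]
    ).to_csv(path, sep="\t", index=False)


def read_candidates(path: str | Path) -> list[_cand.CandidateTriple]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        _cand.CandidateTriple(
            r.lncrna_id, r.mrna_id, r.mirna_id, float(r.overlap_score), r.condition
        )
        for r in df.itertuples(index=False)
    ]


def write_sponge_triples(triples: list[_inf.SpongeTriple], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "lncrna_id": t.lncrna, "mirna_id": t.mirna, "mrna_id": t.mrna,
                "delta_i": repr(t.delta_i), "p_value": repr(t.p_value),
                "condition": t.condition, "n_permutations": t.n_permutations,
            }
            for t in triples
        ]
    ).to_csv(path, sep="\t", index=False)


def read_sponge_triples(path: str | Path) -> list[_inf.SpongeTriple]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        _inf.SpongeTriple(
            r.lncrna_id, r.mirna_id, r.mrna_id, float(r.delta_i),
            float(r.p_value), r.condition, int(r.n_permutations),
        )
        for r in df.itertuples(index=False)
    ]


def write_prognostic(
    results: dict[str, list[_surv.PrognosticResult]], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "network": name, "lncrna_id": r.lncrna, "mrna_id": r.mrna,
                "n_group0": r.n_group0, "n_group1": r.n_group1,
                "logrank_chi2": repr(r.logrank_chi2), "p_value": repr(r.p_value),
            }
            for name in sorted(results)
            for r in results[name]
        ]
    ).to_csv(path, sep="\t", index=False)


def write_drug_candidates(cands: list[_drugs.DrugCandidate], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "drug_name": c.drug_name, "mirna_id": c.mirna_id,
                "network": c.network, "direction": c.direction,
                "affected_edges": ";".join(f"{l},{g}" for l, g in c.affected_edges),
            }
            for c in cands
        ]
    ).to_csv(path, sep="\t", index=False)


def load_inputs(cfg: PipelineConfig) -> dict:
    """Read every input file declared in the config (optional ones when set)."""
    data = {
        "expr_lnc": read_expression_matrix(cfg.expr_lnc, "lncRNA", cfg.already_log2),
        "expr_mrna": read_expression_matrix(cfg.expr_mrna, "mRNA", cfg.already_log2),
        "expr_mirna": read_expression_matrix(cfg.expr_mirna, "miRNA", cfg.already_log2),
        "conditions": read_condition_table(cfg.conditions),
        "targets": read_target_map(cfg.targets),
        "annotation": read_gene_annotation(cfg.annotation) if cfg.annotation else None,
        "clinical": read_clinical_table(cfg.clinical) if cfg.clinical else None,
        "drugs": read_drug_effect_table(cfg.drugs) if cfg.drugs else None,
        "references": None,
    }
    if cfg.tumor_suppressors or cfg.disease_mirnas:
        tsg = read_id_set(cfg.tumor_suppressors) if cfg.tumor_suppressors else frozenset()
        dm = read_id_set(cfg.disease_mirnas) if cfg.disease_mirnas else frozenset()
        universe = len(data["expr_lnc"].feature_ids) + len(data["expr_mrna"].feature_ids)
        data["references"] = ReferenceSets(tsg, dm, universe)
    return data


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """File-to-file run: read inputs, run the analysis, write all outputs."""
    inputs = load_inputs(cfg)
    result = run_analysis(config=cfg, **inputs)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    for cond, ids in result.high_lncrnas.items():
        pd.DataFrame({"lncrna_id": ids}).to_csv(
            outdir / f"high_lncrnas_{cond}.tsv", sep="\t", index=False
        )
    write_candidates(result.candidates, outdir / "candidate_triples.tsv")
    write_sponge_triples(result.sponge_triples, outdir / "sponge_triples.tsv")
    _net.write_network(result.cancer_net, outdir / "network_cancer.tsv")
    _net.write_network(result.normal_net, outdir / "network_normal.tsv")
    _net.write_network(result.gain, outdir / "network_gain.tsv")
    _net.write_network(result.loss, outdir / "network_loss.tsv")
    pd.DataFrame(
        [{"network": name, "node_id": n} for name in sorted(result.hubs) for n in result.hubs[name]]
    ).to_csv(outdir / "hubs.tsv", sep="\t", index=False)
    pd.DataFrame([dataclasses.asdict(p) for p in result.properties.values()]).to_csv(
        outdir / "lncrna_properties.tsv", sep="\t", index=False
    )
    (outdir / "enrichment.json").write_text(
        json.dumps(
            {k: dataclasses.asdict(v) for k, v in sorted(result.enrichment.items())},
            indent=1, sort_keys=True,
        )
    )
    write_prognostic(result.prognostic, outdir / "prognostic_pairs.tsv")
    write_drug_candidates(result.drug_candidates, outdir / "drug_candidates.tsv")
    (outdir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=1, sort_keys=True, default=str)
    )
    return result
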