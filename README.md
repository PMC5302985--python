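# cerna-sponge

Inference of condition-specific **competing endogenous RNA (ceRNA)
networks** from matched lncRNA / mRNA / miRNA expression profiles, with
extraction of the ceRNA relationships *gained* or *lost* in cancer and
the downstream hub, enrichment, prognostic and drug-mapping analyses.

A lncRNA can act as a **miRNA sponge**: when highly expressed, it
sequesters a miRNA and de-represses that miRNA's mRNA targets. The
package screens (lncRNA, miRNA, mRNA) triples for this behaviour with
the conditional-mutual-information statistic

```
ΔI = I(miR; mRNA | lncRNA) − I(miR; mRNA)
```

scored by a permutation test that shuffles only the lncRNA's sample
assignment. Candidate triples are pre-filtered by lncRNA abundance (top
5% per condition) and by regulator sharing (Jaccard index of the two
miRNA-regulator sets ≥ 0.7). Significant triples are assembled into
cancer and normal networks; edges present in only one network and
concordantly up- (down-) regulated in cancer form the **gain** (**loss**)
network; ceRNA pairs are then tested for prognostic value (K-means K=2
patient stratification + Kaplan–Meier / log-rank) and matched against
drug→miRNA regulation records to nominate therapeutics.

The package is aimed at computational biologists who want a tested,
reproducible, download-free reference implementation of this workflow:
every stage is exposed as a library function and a CLI subcommand, and a
synthetic-data generator with planted ground truth stands in for the
external resources (expression cohort, target predictions, tumor
suppressor / disease-miRNA / drug databases) that such studies consume.

## Worked example

```python
import cerna_sponge as cs

ds = cs.generate_dataset(cs.SyntheticConfig(seed=1))   # 60 cancer / 30 normal
res = cs.run_analysis(
    ds.expr_lnc, ds.expr_mrna, ds.expr_mirna, ds.conditions, ds.targets,
    ds.annotation, ds.clinical, ds.references, ds.drugs,
    cs.PipelineConfig(n_perm=200, seed=1),
)
print(res.manifest["counts"])
```

```
{'high_lncrnas_cancer': 15, 'high_lncrnas_normal': 15,
 'candidate_triples': 1518, 'sponge_triples': 7,
 'cancer_edges': 4, 'normal_edges': 3, 'gain_edges': 1, 'loss_edges': 1,
 'gain_hubs': 0, 'loss_hubs': 0, 'prognostic_pairs': 0, 'drug_candidates': 0}
```

Reading the counts: 15 lncRNAs pass the per-condition top-5% abundance
filter; 1,518 triples pass the ≥ 0.7 regulator-overlap filter; 7 survive
the ΔI permutation test at p < 0.01 (the screen is highly specific but,
at 60 samples, weakly sensitive — the planted sponges mostly stay below
the permutation noise floor), and the surviving edges split into one
gained and one lost ceRNA relation.

The property and survival analyses work on any node sets, e.g. against
the generator's ground truth:

```python
props = cs.compare_lncrna_properties(
    {t[0] for t in ds.truth.planted_triples}, ds.expr_lnc.feature_ids, ds.annotation)
L = props["length"]
print(f"mean_in={L.mean_in:.0f}nt mean_out={L.mean_out:.0f}nt "
      f"fold={L.fold_change:.2f} p={L.p_value:.2e}")
```

```
mean_in=1704nt mean_out=929nt fold=1.83 p=1.52e-07
```

Sponge lncRNAs are ~1.8-fold longer than the background, and the
Mann–Whitney U test calls the contrast at p ≈ 1.5e-07. Scanning the
planted prognostic pair:

```python
net = cs.CeRNANetwork("cancer", {p: cs.EdgeData(frozenset({"MIR001"}), 0.1, 1e-3)
                                 for p in ds.truth.prognostic_pairs})
for r in cs.scan_prognostic_pairs(net, ds.expr_lnc, ds.expr_mrna, ds.clinical,
                                  alpha=0.05, seed=1):
    print(r.lncrna, r.mrna, f"chi2={r.logrank_chi2:.2f}", f"p={r.p_value:.2e}")
```

```
LNC0001 MRNA0001 chi2=9.13 p=2.51e-03
```

K-means splits the 60 patients 31/29 on the pair's expression and the
log-rank test separates their survival at p ≈ 0.0025 (the generator
planted a hazard ratio of 3 between the pair-defined groups).

## Command line

```bash
cerna-sponge simulate --out data/ --seed 1        # synthetic study + truth.json
cerna-sponge run --config cfg.yaml                # full pipeline, TSVs + manifest
# or stage by stage, each reading the previous stage's TSV output:
cerna-sponge candidates ...   # high-expression + overlap filters
cerna-sponge infer ...        # deltaI + permutation test
cerna-sponge network ...      # assemble condition networks
cerna-sponge gainloss ...     # differential extraction
cerna-sponge topology ...     # degrees and hubs
cerna-sponge survival ...     # K-means + log-rank per pair
cerna-sponge drugs ...        # drug->miRNA mapping
```

Every output is a tab-separated text file plus a JSON manifest of
parameters, seed and per-stage counts; reruns with the same config are
byte-identical.

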