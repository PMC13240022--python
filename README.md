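# regfate

Linking single-cell terminal states to state-specific transcription-factor
regulatory networks — and carrying the resulting TF signatures to patient-level
survival.

Single-cell studies of tumours (the motivating system is hepatocellular
carcinoma) often end with a set of terminal cell states inferred from
transition dynamics and a catalogue of regulons — each a transcription factor
(TF) together with its directly regulated target genes. `regfate` implements
the downstream analysis that turns those two ingredients into biology:

1. **Regulon activity per cell** — the rank-based AUC of the gene-set recovery
   curve: genes are ordered by decreasing expression within each cell and the
   score is the area under the cumulative hit curve over the top
   `T = ⌊top_fraction·n_genes⌋` ranks, normalised to `[0, 1]`.
2. **Regulon specificity (RSS)** — `RSS = 1 − JSD(P^R, P^C)` where `P^R` is
   the regulon's activity normalised to sum 1 over cells, `P^C` the normalised
   indicator of a cell state, and JSD the Jensen–Shannon divergence with
   base-2 logarithms (so RSS ∈ [0, 1]).
3. **Co-activity specificity (CSI)** — for a regulon pair (A, B) with Pearson
   correlation `PCC(A,B)` across cells, the fraction of the other `N − 2`
   regulons `i` with `PCC(A,i) < PCC(A,B)` or `PCC(B,i) < PCC(A,B)`;
   average-linkage clustering of `1 − CSI` yields regulatory modules.
4. **State-specific regulons** — regulons with significantly elevated activity
   in one terminal state (`z > 1.5` and one-sided Wilcoxon rank-sum
   `p < 0.05`, state versus rest).
5. **Fate networks and CoreScore** — selected regulons' targets are
   intersected with each fate's driver genes (FDR < 0.05) to build a directed
   TF → target network; in-degree, out-degree, betweenness, closeness and
   clustering coefficient are z-scored and averaged with equal weights into a
   composite CoreScore, and the top 30% of nodes are core regulatory nodes.
6. **Clinical signature** — per-patient mean of gene-wise z-scored bulk
   expression over the network's TFs; quartile stratification with a Q4-vs-Q1
   log-rank test and Cox proportional-hazards models (hazard ratios per 1-SD
   of the signature), univariable and stage/age-adjusted.
7. **Integration QC** — per-cell batch-mixing and tissue-separation scores
   over the 30 nearest embedding neighbours.

Every pipeline input (expression + cell annotations, regulon GMT, fate-driver
tables, a bulk survival cohort) can be simulated by the built-in generators
with planted ground truth — state-specific regulons, hub TFs, driver overlap
and a true log-hazard — so the whole pipeline is testable without any
external download.

## Worked example

`examples/` contains one narrative script per capability. For instance the
survival stage (`python examples/05_survival_signature.py`) simulates a
380-patient cohort whose latent factor drives a 26-TF signature and the
hazard of death (true log-hazard 0.6/SD, ~30% censoring), and prints:

```
events observed: 253/380
univariable HR per 1-SD: 1.55 (95% CI 1.36-1.77, p=2.93e-11)
stage/age-adjusted HR:   1.55 (95% CI 1.36-1.77, p=3.53e-11)
log-rank Q4 vs Q1: chi2=30.89, p=2.73e-08
stage association (Kruskal-Wallis): p=0.605 (stages were drawn independently ...)
```

The hazard ratio ≈ e^0.55 recovers the planted effect (slightly attenuated
because the signature is a noisy proxy of the latent factor); stages carry no
signal by construction, and the Kruskal–Wallis test correctly finds none.

The full pipeline in one call (`python examples/06_full_pipeline.py`):

```
wrote 19 files to scratch/pipeline_demo
regulons kept after scoring: 62
state-specific calls: 9
  fate0: 0 nodes, 0 edges
  fate1: 0 nodes, 0 edges
  fate2: 160 nodes, 151 edges
signature HR per 1-SD in the synthetic cohort: 1.86 (true log-hazard planted at 0.6)
```

Only the smallest state (fate2, 25% of cells) yields a network at the
`z > 1.5` selection threshold — a geometric consequence of the selection
criterion discussed in `docs/methods.md`.

A thin CLI wraps the same library calls:

```bash
regfate simulate --outdir sim --n-cells 1000 --seed 1
regfate run --seed 17 --outdir results_dir
regfate qc --cells sim/cells.tsv --k 30 --out cells_qc.tsv
regfate signature --cohort-expression sim/cohort_expression.tsv \
    --cohort-survival sim/cohort_survival.tsv --genes g0020,g0021 --out sig.tsv
```

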