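# cernaforge

Inference of circRNA–miRNA–mRNA competing-endogenous-RNA (ceRNA)
networks from paired tumor/normal RNA-seq counts, with hub-gene ranking
and a penalized-Cox survival signature — built as a reproducible
analysis chain and validated end-to-end on synthetic data with planted
ground truth.

## The problem

Circular RNAs (circRNAs) can act as miRNA sponges: by sequestering a
shared miRNA they relieve its repression of target mRNAs, so circRNA
and mRNA abundances move together. A ceRNA analysis therefore chains
several steps, each with its own statistics:

1. **Quantification & differential expression.** mRNAs are quantified
   as FPKM = counts / ((library size / 10⁶) · exon length in kb);
   circRNAs by back-splice junction reads as SRPBM = junction reads /
   (library size / 10⁹). Libraries are scaled by TMM (trimmed mean of
   M-values; two-sided 30 %/5 % trims on M and A, precision-weighted).
   The two-group test is an exact conditional binomial on TMM-adjusted
   group count sums (the Poisson-limit analogue of the count-based
   exact test), with Benjamini–Hochberg correction. Screens: mRNA
   |log₂FC| > 2 and adjusted p < 0.05; circRNA |log₂FC| > 2 and raw
   p < 0.05.
2. **miRNA target prediction.** A miRanda-lineage local alignment of
   the miRNA (3'→5') against the target (5'→3'): Watson–Crick pair +5,
   G:U wobble +1, mismatch −3, gaps −9/−4, seed positions 2–8 doubled;
   plus a nearest-neighbor duplex free energy (Turner-lab Watson–Crick
   stack table, kcal/mol). Sites must score > 140 with energy
   < −20 kcal/mol.
3. **ceRNA network.** circRNA and mRNA are linked when they share
   predicted miRNAs, change in the same direction, and bind strongly:
   summing each shared miRNA's best site energy on both molecules must
   fall below −90 kcal/mol.
4. **Hub genes.** Nodes of the protein–protein interaction network are
   ranked by Maximal Clique Centrality, MCC(v) = Σ_{maximal cliques
   C ∋ v} (|C|−1)!, and the top ten taken as hubs.
5. **Prognostic signature.** Hub genes are screened by univariate Cox
   regression, a LASSO-penalized Cox model picks the gene combination,
   and the risk score Σ βᵢxᵢ (median split: high vs low risk) is
   evaluated by Kaplan–Meier/log-rank and IPCW time-dependent ROC AUC
   at 3, 5 and 7 years.
6. **Enrichment.** A weighted Kolmogorov–Smirnov GSEA statistic with a
   gene-label permutation null; sets are called at |NES| > 2 and
   p < 0.05.

Because every stage consumes the previous stage's output, errors
compound silently. `cernaforge` plants known signal at every stage —
fold-changes, binding sites, cliques, hazard coefficients — and checks
that the chain recovers exactly what was planted.

## Worked example

Run the numbered drivers in order (each works from the previous
stage's files under `results/`):

```bash
python analysis/01_simulate_inputs.py --seed 0
python analysis/02_differential_expression.py
python analysis/03_target_scan.py
python analysis/04_cerna_network.py
python analysis/05_enrichment.py --seed 0
python analysis/06_ppi_hubs.py
python analysis/07_risk_signature.py --seed 0
```

Output for seed 0:

```
called 148 DE mRNAs and 35 DE circRNAs
planted-feature sensitivity 0.984, false-call rate 0.000
scanned 10 miRNAs against 16 DE circRNAs and 20 DE mRNAs
15 circRNA sites and 15 mRNA sites passed both screens
network: 6 circRNAs, 7 miRNAs, 6 mRNAs, 12 triples
vs planted truth: precision 1.000, recall 1.000
PLANTED_UP: ES 1.000, NES 2.51, p 0.000999 -> significant
RANDOM_CONTROL: ES 0.703, NES 1.76, p 0.001998 -> not significant
PPI: 75 edges; top-10 hubs: GENE0472, GENE1388, GENE0131, ...
planted clique members recovered in top-10: 100%
univariate Cox screen: 3/10 hub genes associated with survival
signature: 3 genes ['GENE0131', 'GENE0374', 'GENE0472'] (planted: same)
high-vs-low log-rank p = 9.02e-16
AUC at 3 years: 0.895 / 5 years: 0.896 / 7 years: 0.908
signature subnetwork: 6 triples around the three signature genes
```

Reading this: the DE screen recovered 98 % of the planted
fold-changes with no false calls; every site the scanner reported was
a planted one, and the assembled network matched the planted triples
exactly (precision = recall = 1). The planted 6-clique dominated the
MCC hub list, the survival stage re-identified exactly the three genes
whose hazards were planted (β = 1 each), and the risk score separates
high- from low-risk patients with AUC ≈ 0.9 at all three horizons.
The single `cernaforge.pipeline.run_all` entry point runs the same
chain from one config and writes a manifest plus a truth-vs-output
report.

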