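# mucimine

Mining mucin-degrading enzymes (mucinases) from gut shotgun metagenomes.

Gut bacteria secrete proteases that cleave the heavily O-glycosylated mucins
of the intestinal mucus layer. Shifts in the abundance of these enzymes —
and in the genera producing them — accompany diseases of barrier
dysfunction such as colorectal cancer. `mucimine` quantifies profile-HMM-
defined enzyme families across metagenome-assembled genomes (MAGs) and
samples, filters them by prevalence, screens for families that differ
between two host-status groups (case vs control), tests the concordance of
enzyme and community profiles, and attributes family abundance to producer
genera. A seeded simulator generates complete pipeline inputs with planted
ground truth, so every stage is testable end to end.

## The statistic

Given `N_ij`, the number of significant hmmsearch hits of profile HMM *j*
among the predicted proteins of dereplicated MAG *i* (full-sequence
E ≤ 10⁻⁵, one count per protein), the per-sample family abundance is built
in three steps:

1. hit density, per kilo-match-state of profile (`L_j`, kb) and per megabase
   of genome (`G_i`, Mb):  `RA_ij = N_ij / (L_j · G_i)`
2. coverage weighting with the mean depth `A_ik` of MAG *i* in sample *k*
   (CoverM-style):  `H_ijk = A_ik · RA_ij`
3. per-sample total:  `T_jk = Σ_i H_ijk`

`T` (HMM × sample) feeds the screen: families are retained when
`Σ_k T_jk > 16` and they are non-zero in more than 5 subjects (both
strict); a NIPALS PLS-DA (5 components, 10-fold stratified CV) with a
per-feature VIP label-permutation test and an unpaired pooled-variance
t-test with Benjamini–Hochberg adjustment then flag group-differential
families. PCA/PCoA ordinations, PERMANOVA (999 permutations) and a
symmetric Procrustes test (r = √(1 − m²)) quantify group separation and
enzyme-vs-community concordance. Contribution fractions `H_ijk / T_jk`
aggregated over samples give genus-level producer profiles per group.

The library-preparation helpers cover protein length QC (300–3000 aa,
inclusive) and CD-HIT-style greedy clustering at 80% global-alignment
identity; multiple alignment and HMM construction are delegated to MAFFT
and HMMER via recorded commands.

## Worked example

```python
from mucimine.synth import SimulationConfig, simulate_dataset
from mucimine.quantify import relative_abundance, normalized_hits, hmm_sample_abundance
from mucimine.screen import FilterThresholds, screen_abundance
from mucimine.sourcetrack import genus_contributions, group_source_summary

cfg = SimulationConfig(n_case=30, n_control=30, n_mags=80, n_hmms=120,
                       n_differential=10, effect_size=2.5, seed=7)
ds = simulate_dataset(cfg)
L = {p.hmm_id: p.length_kb for p in ds.profiles}
G = {m.mag_id: m.genome_length_mb for m in ds.mags}
H = normalized_hits(relative_abundance(ds.hit_matrix, L, G), ds.coverage)
T = hmm_sample_abundance(H)
groups = {m.sample_id: m.group for m in ds.metadata}
table, acc = screen_abundance(T, groups, FilterThresholds(16, 5), seed=7)
print(T.shape, int(table["retained"].sum()), round(acc, 3))
```

prints `(120, 60) 106 0.917`: of 120 simulated families, 106 pass the
abundance/prevalence filter, and the 5-component PLS-DA separates the 30
case from the 30 control subjects with 91.7% cross-validated accuracy. At
the stringent gate (BH q < 10⁻⁴) 4 of the 10 planted families are called;
relaxing to q < 0.05 recovers all 10 with no false positives. Producer
attribution of the planted families:

```python
contrib = genus_contributions(H, {t.mag_id: t.genus for t in ds.taxonomy},
                              groups, hmm_subset=ds.truth.differential_hmm_ids)
print(group_source_summary(contrib, top_n=3))
```

```
  group       genus  fraction  abundance
   case  Prevotella     0.277    648.608
   case Phocaeicola     0.184    430.840
   case   Alistipes     0.162    378.727
   case      others     0.377    881.051
control  Prevotella     0.252    237.888
...
```

i.e. *Prevotella* MAGs account for ~28% of the planted families' abundance
in cases. The same analyses are available from the shell:

```sh
mucimine simulate --out data/ --seed 7
mucimine run --hits data/hits.tbl --coverage data/coverage.tsv \
  --taxonomy data/taxonomy.tsv --metadata data/metadata.tsv \
  --profiles data/profiles.tsv --mags data/mags.tsv --out run/ --seed 7
```

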