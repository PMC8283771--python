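# splicepairs

Base-pair geometry of snRNA:splice-site interactions, with resampling
statistics.

## The problem

Human splice sites are poorly conserved: apart from the intron-terminal
GU…AG, the branchpoint A, the ~82 %-conserved exon-end guanine (−1G) and
the ~80 %-conserved intron +5G, almost every position varies.  Yet splicing
is precise to the nucleotide.  One proposed mechanism is that the snRNAs of
the pre-catalytic spliceosome — U5 Loop1 binding both exon ends at the
splice junction, the U6 ACAGAGA box binding the intron start — recognize
their variable targets by *base-pair geometry*: canonical Watson–Crick
pairs (G=C, A-U) are selected for, mismatches that can mimic Watson–Crick
geometry through tautomerization or protonation (G-U, U-U, C-U, A-C —
"isosteric" pairs) are tolerated, and geometry-breaking pairs (purine·purine,
C·C — "non-isosteric") are excluded.  If U5 and U6 jointly secure the 5′
splice site, substitutions of the conserved +5G should be compensated by
extra Watson–Crick pairs between U5 and the 5′-exon end, and vice versa.

`splicepairs` implements that analysis as a tested pipeline:

* **pair geometry** — normalization of (modified) residues and the
  three-way classification of all 16 ordered base pairs (4 Watson–Crick,
  7 isosteric, 5 non-isosteric), with reference loop models for U5 Loop1
  (positions 36–46, junction at C39|C38, the 8+3 register), the U6 box
  (intron +5..+10 against positions 42..37), the U1 5′ end, and the
  homologous Group IIA intron Id3 loop;
* **register scanning** — the grid procedure that superimposes a 15-nt
  window on an 11-nt loop in the five registers keeping the 5′-side helix
  longer (6+5 … 10+1), chooses maxima by Watson–Crick count and reports
  ties;
* **dataset building** — per-intron extraction of the 11-nt splice
  junction (exon −8..−1 | +1..+3), the first 10 nt and last 60 nt of the
  intron from genome FASTA + GTF or a prepared TSV, with classification
  into major / +2-substituted / U12-type introns and partitioning by the
  conserved positions (+5G, −1G, −3C);
* **resampling statistics** — symmetrized Kullback–Leibler divergence
  over position subsites with disjoint-subset resampling controls,
  bootstrap difference (BD) tests of every (position, class) frequency
  with P(H0) = the smaller tail of the BD distribution beyond zero, a
  per-nucleotide bootstrap, and Bonferroni–Dunn correction with the
  correlated-test adjustment m′ = (m+1) − [1 + (m−1)R] applied groupwise;
* **PSI re-analysis** — grouping of 14 published exon-start +1G
  mutations by whether the mutant exon offers +2C or +3G (Watson–Crick
  partners of U5 C36/Gm37) and comparison of exon inclusion between
  groups (Welch ANOVA, Kruskal–Wallis);
* **synthetic data** — a generator reproducing the marginal conservation
  levels and a tunable −1G/+5G (and −3C/+1G) dependency, so the whole
  pipeline is testable without downloads.

## Worked example

Generate 2,000 synthetic introns with a −1G/+5G dependency of δ = 0.15,
partition by intron +5G, and run the full comparison:

```python
from splicepairs import (SpliceSiteComparison, SiteFrequencyModel,
                         generate_dataset)
from splicepairs.dataset import classify_dataset

ds = generate_dataset(SiteFrequencyModel(delta_5ss=0.15), 2000, seed=7)
classify_dataset(ds)
res = SpliceSiteComparison(ds, criterion="plus5G").fit(
    iterations=2000, seed=7, nucleotide_position="exon:-3")
print(res.summary())
```

```
Splice-site base-pair comparison
================================================
criterion:      plus5G
loop model:     U5_loop1
groups:         conserved n=1583, substituted n=417
iterations:     2000   seed: 7
tests:          m=32 (alpha'=0.0016), m'=20 (alpha'=0.0025)

sKL divergence by subsite (phi = mean case / mean control)
    subsite  mean_case_skl  mean_control_skl  mean_ratio_phi
exon_-8..-6        0.02253           0.03515          0.6411
exon_-5..-3        0.01288            0.0191          0.6742
exon_-2..-1         0.3737            0.0214           17.47
exon_+1..+3         0.0309           0.04733          0.6527

bootstrap cells significant at alpha' = 0.0025 (3 of 28):
position    pair_class  mean_bd   p_h0  p_value  significant_plain  significant_adjusted
 exon:-1  watson_crick   0.1551      0        0               True                  True
 exon:-1     isosteric  -0.1242      0        0               True                  True
 exon:-1 non_isosteric -0.03089 0.0015    0.003               True                  True

nucleotide bootstrap at exon:-3: P(H0) = A:0.298, C:0.344, G:0.175, U:0.2215
```

Reading the output: the injected dependency shows up exactly where it was
placed — the sKL divergence between the +5G-substituted group and random
+5G-conserved subsets is ~17× its resampling control at exon −2..−1, and
the bootstrap finds a +0.155 increase in Watson–Crick frequency at exon −1
(mirrored by the isosteric decrease, since the classes exchange), while
every 3′-exon cell stays at the null.  `m=32` counts one test per defined
(position, class) cell — positions paired with a U5 uridine admit only two
classes — plus the four nucleotide tests at exon −3; `m′=20` is the
correlated-test adjustment.

The same pipeline runs from the shell:

```sh
splicepairs simulate --n 2000 --seed 7 --delta-5ss 0.15 --out ds.tsv
splicepairs bootstrap --dataset ds.tsv --criterion plus5G \
    --iterations 10000 --seed 7 --out-prefix run
splicepairs correct --m 28 --groups 3:0.5,3:0.5,3:0.5,3:0.5,3:0.5,3:0.5,2:1,2:1,2:1,2:1,2:1
splicepairs psi
```

## Layout

```
src/splicepairs/
  pairing.py    base normalization, pair classes, loop models
  dataset.py    intron records, extraction, classification, partitioning
  genome.py     FASTA + GTF transcript loading
  registers.py  five-register window scanning and composition summaries
  stats.py      frequencies, sKL, bootstrap, Dunn correction
  psi.py        +1G mutation grouping and PSI comparison
  simulate.py   synthetic dataset generator
  model.py      Model/Results front-end (fit() -> summary())
  cli.py        `splicepairs` console script
docs/methods.md  model, assumptions, parameter choices, limitations
```
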