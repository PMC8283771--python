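# Methods

## Base-pair geometry model

Every ordered pair of RNA bases is assigned to exactly one of three
geometric classes:

| class | pairs | rationale |
|---|---|---|
| `watson_crick` | G=C/C=G, A-U/U-A | canonical |
| `isosteric` | G-U/U-G, U-U, C-U/U-C, A-C/C-A | can adopt Watson–Crick-like geometry via rare tautomers or protonation |
| `non_isosteric` | A·G/G·A, A·A, G·G, C·C | cannot; perturb the recognition helix |

The partition is 4 / 7 / 5 over the 16 ordered pairs and is symmetric:
orientation and strand bookkeeping live entirely in the loop pairing maps.
Post-transcriptional modifications (pseudouridine, 2′-O-methyl,
N6-methyl) are annotation only; classification always uses the parent
base, because modified loop residues pair like their parents in this
scheme.  Input sequences are accepted in DNA or RNA alphabet, any case,
and normalized to uppercase RNA.

A structural consequence used throughout: a uridine partner can never
produce a non-isosteric pair, so the five U5 Loop1 positions that present
uridines to exon −2..−6 carry only two defined classes.  "Defined"
(position, class) cells drive both the frequency tables and the
multiple-testing accounting.

## Loop models

Loop models are data, not code: ordered residues with integer position
labels plus a pairing map `substrate position -> loop position`,
serializable as YAML.  Defaults:

* **U5 Loop1**, positions 36–46: C, Gm, C, C, U, Um, U, Ψ, U, A, C.  The
  proposed binding register places the exon junction at C39|C38 (8+3
  split): exon −1..−8 against 39..46, exon +1..+3 against 38..36.
  Residues 45–46 are not printed machine-readably in the primary
  literature; A45/C46 is the internally consistent choice (it keeps
  exactly five uracils, with the uridine block exactly at exon −2..−6)
  and is overridable.
* **U6 ACAGAGA region**, positions 37–47 (C,G,A,U,A,C,A,G,A,G,A): intron
  +5..+10 against 42..37, so +5G meets C42.
* **U1 5′ end**, positions 1–11 (A,U,A,C,Ψ,Ψ,A,C,C,U,G): exon −3..−1
  against 11..9, intron +1..+8 against 8..1.
* **LtrB Id3 loop**, positions 275–285: a synthetic reconstruction
  (exact sequence unavailable as text) constrained by the published
  interaction pattern — junction-coordinating guanines at 278/279, G282
  opposite exon −4, five uracils.  EBS1 (279–285) pairs exon −1..−7, δ
  (275–278) pairs exon +1..+4.  Intended as a working default for the
  register engine, not as reference data.

## Register scanning

A 15-nt window (last 10 nt upstream + first 5 nt downstream of a declared
boundary) is superimposed on an 11-nt loop in the five registers that keep
the upstream helix longer: splits 6+5 … 10+1, i.e. the covered 11-mer
slides one position at a time while the loop is read in fixed descending
position order (antiparallel pairing).  The register(s) maximizing the
Watson–Crick count are reported; ties are never broken, because ambiguous
windows are themselves informative.  A secondary vector counting pairs in
the preference order WC, G-U/U-G, U-U, C-U/U-C, A-C/C-A, non-isosteric is
recorded for inspection but does not influence the choice.

## Dataset construction

Per intron: `junction11` (last 8 nt of the upstream exon + first 3 nt of
the downstream exon, boundary fixed at 8|9), `intron_start10`,
`intron_end60`.  Annotation coordinates are treated as 1-based inclusive
(GTF convention); minus-strand transcripts are reverse-complemented before
extraction; one transcript per gene is chosen as the isoform with the most
exons, ties broken lexicographically.  Introns shorter than 60 nt keep
their full sequence (flagged); exons shorter than the flank flag or drop
the record per configuration.  Files store DNA alphabet; memory uses RNA.

Intron classes: `minor` when intron +3..+8 equals the U12-type core
ATCCTT (a configurable approximation of the U6atac-complementary motif;
zero mismatches by default), else `atypical_plus2` when +2 ≠ U (GC..AG
and GA..AG starts), else `major`.  The +5G and −1G partitions admit only
major introns; the −3C partition also admits `atypical_plus2`, i.e.
everything processed by the major spliceosome.  Partitions are disjoint
and exhaustive over eligible records.

## Resampling statistics

**Frequencies.** For a record set and loop model, the class frequency at
each mapped position is count/N; undefined cells are masked.

**sKL divergence.** For subsites (defaults: exon −8..−6, −5..−3, −2..−1,
+1..+3 for U5; dinucleotides +5..+6, +7..+8, +9..+10 for U6),
sKL(P,Q) = Σ (p log2 p/q + q log2 q/p) over the subsite's (position,
class) cells, with an increment of 0.0001 added to every probability and
no renormalization — the increment is part of the statistic's definition
here, so sKL(P,P) = 0 and symmetry hold with the shared increment.

**Control experiment.** Each of `iterations` rounds draws two disjoint
subsets of the case-group size from the larger reference group (indices
without replacement; no record repeats within a subset, none shared
between the pair).  Control = sKL between the two subsets; case = sKL
between the first subset and the case group; the same subset pair is
reused across subsites within a round (recorded in provenance).  The
headline summary is φ = mean(case)/mean(control).  Note that for a single
fixed case set, φ is dominated by that set's own sampling deviation (a
chi-square-like term over the subsite's cells), so under the null φ ≈ 1
only in expectation over case realizations; the property suite averages
over independent case draws accordingly.

**Bootstrap differences.** Each iteration resamples group A at size |A|
and group B at size |B| with replacement (implemented exactly as
multinomial weights over records, which vectorizes as a matrix product)
and records BD = freq_A* − freq_B* for every defined cell.
P(H0) = min(#{BD ≤ 0}, #{BD ≥ 0}) / iterations — the smaller tail beyond
zero, with ties counted in both tails (effect ≤ 1e-4 at 10,000
iterations).  Significance calls against Dunn thresholds use P(H0),
matching the published convention.  Because the smaller tail falls below
α with probability ~2α under a true null, results also carry the standard
two-sided bootstrap p-value `p_value = min(1, 2·P(H0))`, whose type-I
error is the nominal α; calibration checks use `p_value`.  The
nucleotide-level bootstrap at a single position (used at exon −3, where
U1 and U5 demand different bases) follows the same scheme over A/C/G/U
frequencies.

**Multiple testing.** α′ = α/m (reported at full precision and rounded to
4 decimals, the conventional presentation).  The correlated-test
adjustment m′ = (m+1) − [1 + (m−1)R] is applied per group of correlated
tests — R = 1 for two-class positions, 0.5 for three, 0.33 for four
(the nucleotide tests) — rounded to the nearest integer per group and
summed; per-group rounding is required for the adjustment to land on
integer counts.  The plan builder derives m from the loop structure (2
tests per uridine-partner position, 3 otherwise): 28 for the 11-position
U5 junction site, 17 for the 6-position U6 site, 32 when the four
exon −3 nucleotide tests are appended.  Both the 28-cell and 32-cell
countings are exposed; nothing is hard-coded to a target.

**Determinism.** Every stochastic operation takes a seed and uses an
isolated `numpy` generator; the model front-end derives stage seeds by
fixed offsets (seed, seed+1, seed+2 for sKL / bootstrap / nucleotide) so
stages are independently reproducible; reruns are byte-identical.

## Synthetic generator

The generator emulates the study conditions: positional nucleotide
vectors approximating the human major-spliceosome consensus (exon −1
G = 0.82, intron +5 G = 0.80, exon +1 G = 0.50, intron −3 C = 0.60,
near-invariant +2U/−2A, enforced GT..AG termini, pyrimidine-rich intron
end fill), all configuration data rather than genome claims.
Dependencies use a mixture construction: the intron-side conserved
position is drawn first, then the exon-side partner position is drawn
from one of two conditional vectors whose difference on the
Watson–Crick-forming nucleotide is exactly δ, split so the marginal is
preserved (conserved branch −δ(1−w), substituted branch +δw for
conservation level w).  With δ = 0 all positions are independent.

What the generator does *not* emulate: branchpoints, splicing
regulation, dinucleotide composition, paralog structure, or any linkage
beyond the two configured dependencies.  Passing tests therefore
demonstrate that the statistical machinery is calibrated and has power
against the modelled dependency structure — not that the biological
conclusions hold for real transcripts, which requires real annotation
input through the same interfaces.

## Test-suite problem sizes

The calibration battery runs 200 replicate null experiments at the
emulated group sizes 445/1545 with 1,000 bootstrap iterations each,
asserting the empirical type-I error of the two-sided test within 3
binomial SD of α at 0.05 and 0.01 over the 2,200 independent
Watson–Crick cells.  The power battery runs 100 seeded reruns at
δ = 0.15 with ~400/1500 groups (n = 1,900 at the default 80 % +5G
level), requiring detection at exon −1 below the Dunn-adjusted threshold
(0.0025) in ≥ 95 % of reruns with the 3′-exon cells staying null.
Register-scan equivalence against the exhaustive boundary-enumeration
oracle is checked on 1,000 random windows.  Production analyses default
to 10,000 iterations.

## Known limitations

* The minor-intron rule is a motif approximation; real U12-type intron
  curation needs dedicated annotation.
* The Id3 loop default is a constrained reconstruction (see above).
* Three of the fourteen PSI measurements are not printed in the source
  text and ship as explicit NaN placeholders; tests exclude them from
  test statistics while keeping them in group membership.
* φ is reported without an uncertainty interval, matching the original
  presentation; its single-realization dispersion is discussed above.
* No thermodynamic scoring, tautomer enumeration, 3D geometry, splice
  site strength models or branchpoint prediction.
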