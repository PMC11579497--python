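# wheatdecay

mRNA decay kinetics and stability-associated RNA structural motifs in
allopolyploid wheat.

`wheatdecay` is a tested re-implementation of a transcriptome-wide mRNA
stability analysis for tetraploid (AABB) wheat: genome-wide decay rates are
estimated from cordycepin transcription-arrest time courses, correlated with
sequence/structure features of the mRNA, and mined for degenerate stem–loop
elements in 3' UTRs whose occurrence is informative of stability. Because the
original sequencing libraries are far beyond desk scale, the package ships a
first-class synthetic-data generator that reproduces the statistical
structure of each input with known ground truth, so every stage is
quantitatively testable.

## The models

**Decay kinetics.** After transcription is arrested at t = 0, the relative
abundance of each transcript is modelled as either

- constant rate: m(t) = exp(−αt), or
- decaying rate: m(t) = exp(−(α/β)(1 − e^(−βt))),

with Gaussian error on log relative abundance. Parameters are estimated per
gene by maximum likelihood; the model is chosen by the corrected Akaike
criterion AICc = −2 logL + 2k + 2k(k+1)/(n−k−1), and the half-life is
t<sub>1/2</sub> = ln(2)/α. Before fitting, profiles are corrected for
total-RNA-pool drift using *decay factor* genes (highly expressed, stable)
and scaled to their own t = 0 value.

**Motif discovery.** Stem–loop seeds (stem 4–7 nt, loop 4–9 nt, 14–20 bits
of information, 4–6 degenerate IUPAC positions) are matched against 3' UTRs
with Watson–Crick (optionally G·U) pairing and an in-vivo structure filter:
SHAPE reactivity must be low on the stem relative to the loop and to the
transcript median. Transcripts are split into 15 equal stability bins by
decay rate, and each seed's binary presence vector R is scored against the
bin assignment A by mutual information

MI(R;A) = Σ<sub>r</sub> Σ<sub>a</sub> p(r,a) log₂ [ p(r,a) / (p(r) p(a)) ],

calibrated with a Z-score from 1000 random permutations of the bin labels.
Motifs with MI > 0.001 and Z > 2 are classified sRSM (stabilizing; frequency
decreasing toward unstable bins) or uRSM (destabilizing; the opposite trend).

**Subgenome and population statistics.** Homoeologous A/B gene pairs are
classified by one-sided t-tests on replicate-level decay rates; decay and
abundance asymmetries are correlated per class; motif presence is tested for
subgenome preference with Fisher's exact test (BH-adjusted); allele-frequency
differentiation across wild emmer / domesticated emmer / durum populations is
measured with the Weir–Cockerham F<sub>ST</sub> estimator, and SNVs are
called structure-perturbing when the alternate allele breaks a stem pair or a
seed constraint so that a motif match is lost.

## Worked example

```python
import numpy as np
from wheatdecay import DecayModel, MotifDiscovery, StructureMotifSeed
from wheatdecay.motifs import enumerate_seeds
from wheatdecay.simulate import (SimulationConfig, generate_decay_counts,
                                 generate_utr_with_motifs)

table, truth = generate_decay_counts(SimulationConfig(n_genes=500, seed=7))
results = DecayModel(table).fit()
print(results.summary())

planted = StructureMotifSeed("planted", "GCAUC", "RRYY")
config = SimulationConfig(n_utrs=1500, seed=7, motif_seed=planted,
                          motif_bin_frequencies=tuple(np.linspace(0.6, 0.05, 15)))
sequences, shapes, rates, _ = generate_utr_with_motifs(config)
discovery = MotifDiscovery(sequences, rates, shapes=shapes,
                           seeds=[planted] + enumerate_seeds(budget=200, seed=1))
motifs = discovery.fit(n_shuffle=1000, seed=0)
row = motifs.stats.set_index("seed_id").loc["planted"]
print(f"planted motif: MI = {row.mi_bits:.4f} bits, Z = {row.z:.1f}, "
      f"class = {row['class']}")
```

prints

```
Decay model results
===================
genes fitted:        500 / 500
models:              const_rate, decaying_rate (scale: log)
decay-factor genes:  30
model selection:     {'const_rate': 435, 'decaying_rate': 65}
median half-life:    4.36 h
mean half-life:      11.01 h

planted motif: MI = 0.0933 bits, Z = 32.4, class = sRSM
```

The decay summary shows 500 genes fitted on the 0–480 min grid with three
replicates; most genes prefer the single-rate model, and the fitted
half-lives span minutes to days, as expected from the simulated log-normal
distribution. The motif block plants a GCAUC/RRYY stem–loop whose frequency
falls from 60% in the most stable bin to 5% in the least stable one; against
200 decoy seeds the planted element is recovered with MI = 0.093 bits and
permutation Z = 32, and its falling frequency trend classifies it as a
stabilizing motif (sRSM).

A command-line interface mirrors the library
(`wheatdecay simulate | fit-decay | features | discover-rsm | subgenome`);
`wheatdecay simulate --out ds --plant-motif` writes a complete synthetic
dataset directory (counts, UTR FASTA, SHAPE tables, GFF3 + transcript FASTA,
homoeolog pairs, SNVs, and ground-truth tables) that the other subcommands
consume.

## Layout

| module | contents |
| --- | --- |
| `wheatdecay.timecourse`, `.io`, `.annotation` | readers/writers (counts TSV, SHAPE, BPP, pairs, SNV TSV/VCF, GFF3+FASTA), RPM, intron counts, UTR partitions |
| `wheatdecay.simulate` | `SimulationConfig` and generators for every input, with ground truth |
| `wheatdecay.decay` | `DecayModel` / `DecayResults`, normalization, AICc selection, repeated-measures curve comparison |
| `wheatdecay.seqfeat` | composition, codon frequencies, CSC, cAI/tAI, feature–decay correlations |
| `wheatdecay.structure` | SHAPE/BPP region summaries and structure–decay correlations |
| `wheatdecay.motifs` | seed grammar, matching, binning, MI, permutation Z, sRSM/uRSM calls (`MotifDiscovery` / `MotifDiscoveryResults`) |
| `wheatdecay.subgenome` | homoeolog classification, asymmetry correlations, motif subgenome enrichment, F<sub>ST</sub>, SNV perturbation |

See `docs/methods.md` for the modelling assumptions, parameter defaults, and
known limitations.
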