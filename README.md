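# amidasekit

Screening analytics and substrate-specificity modelling for
amidase-signature (AS) enzymes.

AS-family hydrolases — defined by a conserved ~160-residue signature
region carrying a Ser-Ser-Lys catalytic triad and a Gly/Ser-rich motif —
include aryl acylamidases (EC 3.5.1.13) that cleave N-aryl amide bonds in
drugs, pesticides and sweeteners. Screens of such enzymes against
micropollutant panels produce two kinds of raw readout (HPLC peak areas
before/after incubation, and plate-reader OD time series against a
complete-turnover reference), anchored on a catalytically dead
triad-serine-to-alanine control. `amidasekit` turns those readouts into a
binary enzyme × substrate activity matrix, models what drives activity,
and characterizes substrate specificity. It is aimed at enzymology and
environmental-biotech groups running promiscuity screens of hydrolase
libraries.

## What it computes

* **Hit calling** (`amidasekit.hitcalling`). Relative removal
  `100·(A_t0 − A_t24)/A_t0` per replicate; control replicates are
  outlier-filtered with Tukey fences (Q1 − 1.5·IQR, Q3 + 1.5·IQR). An
  HPLC pair is a hit iff `median(removal) > median_ctrl + 1.5·IQR_ctrl`
  **and** `median(removal) > 50 %`. A colorimetric pair is a hit iff its
  mean yield (OD at a substrate-specific evaluation time over the
  complete-turnover reference) is ≥ 2 control SDs above the control
  mean, with an extra 30 % yield floor for 4-nitrophenyl esters.
* **Library design** (`amidasekit.library_design`). Homolog hits are kept
  at e-value ≤ 0.1, query cover ≥ 20 %, bitscore ≥ 50, greedily clustered
  at 60 % identity, thinned to ⌈n/2⌉ per cluster by max-min Hamming
  diversity, deduplicated per genus (cap 3), and purged of near-query
  (>90 % identity), motif-less, mispredicted (EC 6.3.5.7) and
  literature-known sequences.
* **Featurization** (`amidasekit.featurization`). The signature-region
  alignment is encoded column-wise with the first four amino-acid
  factor-analysis scores (polarity, secondary structure, molecular size,
  codon diversity); substrates get element counts, formal-charge counts,
  functional-group counts, an ANILIDE indicator, and hydrolysis-aware
  masses `MW_bond` (amide tail), `MW_ring` (aryl part) with
  `MW_bond + MW_ring + 43.03 ≈ MW` for secondary anilides.
* **Modelling** (`amidasekit.modeling`). Ten XGBoost classifiers on
  stratified 80/20 resamples; features with nonzero gain importance in
  ≥ 70 % of models form the consensus set; a final model on that set
  reports importances scaled to max 1. Leave-one-chemical-out and
  leave-one-enzyme-out validation report per-fold F1 and balanced
  accuracy with explicit single-class conventions.
* **Analytics** (`amidasekit.analytics`). Jaccard-distance dendrogram of
  enzyme profiles, Pearson correlations of substrates, centered PCA
  biplot, and promiscuity classes (≥ 8 substrates promiscuous, ≤ 2
  narrow) with per-class residue-frequency logos.
* **Synthetic studies** (`amidasekit.synthetic`). A generator that
  emulates the screen end to end — conserved-triad alignments, an
  anilide/ester/primary-amide panel, a planted logistic activity rule,
  and noisy HPLC/plate readouts with dead-enzyme controls — so every
  stage is testable without external data.

## Worked example

Run the whole pipeline on a synthetic 16-enzyme × 17-substrate study:

```python
import amidasekit as ak

cfg = ak.RunConfig(out_dir="scratch/demo", seed=7)
manifest = ak.run_pipeline(cfg)
```

The run directory then contains the activity matrix, feature table,
importances, validation reports and analytics. With seed 7 the screen
yields a 16 × 17 matrix with 136 hits, and the final consensus model
ranks:

```
            feature  scaled_importance
            MW_bond           1.000000
                 MW           0.796617
           AA151_f3           0.791001
formal_charge_count           0.637575
                n_H           0.564569
                n_O           0.561903
```

`MW_bond` (amide tail mass), `formal_charge_count` and the molecular-size
factor of alignment column 151 are exactly the three determinants the
generator planted — small amide tails and charged aryl substituents
favour turnover, and the planted surface residue modulates it per
enzyme. The classes split 11 promiscuous / 4 intermediate / 1 narrow,
and leave-one-chemical-out validation produces 17 folds with F1 between
0.0 and 1.0 depending on the substrate left out, mirroring how strongly
fold difficulty varies when whole chemicals are withheld.

The same stages are scriptable from the shell:

```bash
amidase-pipeline simulate --seed 7 --out scratch/sim
amidase-pipeline hitcall --measurements scratch/sim/measurements.csv \
    --substrates scratch/sim/substrates.tsv --out scratch/hits
amidase-pipeline run --config run.yaml
```

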