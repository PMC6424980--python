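# phosphodecode

Decoding combinatorial phosphorylation barcodes on the rhodopsin C-terminus:
how the pattern of phosphates over seven Ser/Thr sites (S334, T335, T336,
S338, T340, T342, S343) controls arrestin binding, activation and global
conformation. The package re-implements the quantitative core of that
analysis as a tested pipeline, with a synthetic-data generator standing in
for the wet-lab inputs.

## What's inside

| Module | Purpose |
|---|---|
| `phosphodecode.core` | Phosphosite/pattern types, 7-bit bitstring serialization, combinatorial enumeration, the packaged peptide panel |
| `phosphodecode.synth` | Synthetic array spots, anisotropy titrations and NMR titration peak lists with known ground truth |
| `phosphodecode.array_fit` | Exhaustive best-subset OLS over all 128 site subsets, AIC ranking, top-20 coefficient-importance matrix, threshold-robustness sweep |
| `phosphodecode.binding` | 1:1 binding-curve fitting (`r = R0 + dR·P/(Kd+P)`), censoring of weak binders at the 250 µM assay bound, exact ligand-depletion occupancy and its inverse |
| `phosphodecode.csp` | Weighted chemical-shift perturbations (`sqrt((0.2·ΔδN)² + ΔδH²)`), trajectory tracking over peptide:protein ratios, five-class binning, line-broadening flags, Sparky-like peak-list I/O |
| `phosphodecode.motifs` | Site-role map (key / inhibitory / secondary / modulator), binding / C-tail-release / ternary-complex predictions, concordance reports, a declarative motif-scanning language |

## CLI

All commands live under one entry point:

```bash
# simulate a combinatorial array and fit it
phosphodecode simulate array --theta 0,0,0,0,5,0,3 --noise-sd 0.2 \
    --seed 1 --out spots.csv
phosphodecode fit-array --input spots.csv --top 20 --thresholds 0,1,2 --out results/

# simulate and fit an anisotropy titration
phosphodecode simulate titration --kd 50 --noise-sd 0.002 --seed 1 --out curve.csv
phosphodecode fit-titration --input curve.csv

# exact fraction of protein bound with ligand depletion
phosphodecode occupancy --pt 100 --lt 1000 --kd 250

# rule-based predictions for the packaged peptide panel (+ concordance)
phosphodecode classify [--panel panel.csv] [--measured calls.csv] [--out concordance.tsv]

# evaluate a declarative motif over the panel
phosphodecode motif-scan --spec motif.yaml
# motif.yaml:  expression: "T340 AND S343 AND NOT T342"

# simulate NMR titration peak lists (ratios 0/1/4/10)
phosphodecode simulate csp --kd 50 --n-residues 60 --seed 1 --out peaks/
```

The motif language supports site names, `AND`/`OR`/`NOT`, parentheses, and
`SPACED(count, sep)` (count phosphorylated residues with exactly `sep`
residues between consecutive sites).

## File formats

Everything is plain text: array spots as CSV (`label,bitstring,rep1..repN`),
titrations as CSV (`conc_uM,anisotropy`), peak lists either Sparky-like
whitespace tables (`Assignment w1 w2 Height`, w1 = ¹⁵N ppm, w2 = ¹H ppm) or
CSV (`residue,dH,dN,intensity`), and results as TSV (`models.tsv`,
`importance_matrix.tsv`, `fits.tsv`, `csp.tsv`, `concordance.tsv`).
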