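# promspec

Spectral analysis of promoter sequences, two complementary methods in one
package:

1. **Alignment-based spectral clustering.** All-vs-all affine-gap alignment
   (EDNAFULL scoring, free end gaps, Needleman–Wunsch or Smith–Waterman),
   thresholded against a reshuffled-sequence null model, followed by
   normalized-Laplacian spectral clustering with the eigengap rule and
   k-means on the row-normalized spectral embedding.
2. **Regular-sequence detection.** Each promoter is mapped to a harmonic
   lattice model (Morse on-site wells whose depth/width depend on the
   weak/strong — A/T vs C/G — character of each site, plus nearest-neighbour
   stacking springs). Tracts that are regular in the W/S binary code
   (homogeneous, periodic, palindromic) carry *delocalized* eigenvectors of
   the chain Hessian; regions are accepted when the number of delocalized
   modes they contain matches their length within a 30% tolerance.

Downstream cataloguing covers TATA-box consensus scanning (degenerate
`HWHWWWWR`, 576 → 532 8-mers after exclusions), per-position base
composition and dinucleotide profiles, per-cluster regular-sequence
catalogues, and transposon-overlap statistics from RepeatMasker `.out` or
BED annotations. A synthetic-promoter generator produces compositional
mixtures, strand-symmetric planted elements, and regularity-free
backgrounds with planted tracts — every synthetic set ships with a ground
truth table.

## Command line

```bash
# synthetic 4-class mixture with ground truth
promspec simulate --preset human4 -n 120 -L 240 --seed 1 -o synth.fasta

# TATA / TATA-less labels
promspec tata --window -40:-19 synth.fasta > labels.tsv

# all-vs-all similarity matrix + reshuffle-null threshold
promspec align synth.fasta --mode global --gapopen 20 --gapextend 0.5 -o sim.tsv

# spectral clustering (K chosen by the eigengap unless -K is given)
promspec cluster sim.tsv --theta $(cat sim.theta.txt) --kmax 15 -o clusters.tsv

# eigenvector localization indicators / regular regions
promspec spectra synth.fasta -o indicators.tsv
promspec regular synth.fasta -o regions.bed

# repeat coverage and the full pipeline
promspec repeats synth.fasta repeats.bed
promspec run synth.fasta --repeats repeats.out -o runs/demo
```

All thresholds and model parameters live in one YAML config
(`promspec run --config config.yaml`); unknown keys are rejected. Key
defaults: GAPOPEN 20, GAPEXTEND 0.5, free end gaps; lattice parameters
k = 0.025 eV/Å², ρ = 2, D_W = 0.05 eV, D_S = 1.5·D_W, a_W = 4.2 Å⁻¹,
a_S = 6.9 Å⁻¹; delocalization threshold P ≥ 4, tail threshold ε = 0.01,
count tolerance 30%, minimum region length 7 nt.

The RepeatMasker option set used for the reference annotations (engine
abblast, default sensitivity, no simple-repeat/low-complexity masking,
E. coli IS artifact check on, no divergence cutoff) is documented here for
provenance; this package only **parses** RepeatMasker output, it never runs
the program.

## Package layout

| module | contents |
| --- | --- |
| `promspec.seqio` | FASTA I/O, coordinate conventions, W/S binary code, reverse complement |
| `promspec.composition` | degenerate-consensus expansion, TATA scan, BCA, dinucleotide profiles |
| `promspec.alignment` | scoring schemes, pairwise alignment, similarity matrices, reshuffle null |
| `promspec.spectral` | adjacency thresholding, normalized Laplacian, eigengap, spectral k-means |
| `promspec.pb` | lattice Hessian, tridiagonal eigenproblem, localization indicators |
| `promspec.regions` | regular-region detection, coverage, length histograms, motif catalogues |
| `promspec.repeats` | RepeatMasker/BED parsing, transposon coverage and overlap statistics |
| `promspec.synth` | mixture presets, regularity-free backgrounds, planted tracts, truth tables |
| `promspec.pipeline`, `promspec.cli` | orchestration, manifest, click CLI |
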