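# geneimage

Tools for studying evolutionary relatedness through *genetic images*:
fixed-length binary encodings of the two classic DNA-barcode proteins,
cytochrome b and cytochrome c oxidase subunit I (COI), recognized by small
ensembles of sigmoid neural networks and corroborated by a codon-level
transition/transversion position classifier.

The package is aimed at researchers in molecular evolution and DNA barcoding
who want to rank organisms by similarity of their barcode proteins *without*
building phylogenetic trees, and at anyone who needs a clean, seeded
implementation of the underlying primitives (5-bit sequence encoding, online
backpropagation with momentum, codon-set point-mutation analysis, codon
evolution simulation).

## The method

**Genetic images.** Each amino-acid sequence is fitted to a reference length
(the human cytochrome b and COI lengths, 380 and 513 residues, by default) by
end-padding with `-` or end-truncation, then encoded residue-by-residue with
5 bits per residue (`A` → `00001`, `B` → `00010`, …, `-` → `00000`). The
concatenated cytochrome b + COI image therefore has 5 × (380 + 513) = 4465
bits; the single-gene images have 1900 and 2565.

**Recognition.** A panel of k organisms teaches five full-synapse three-layer
sigmoid networks (n inputs, √(n·k) hidden units by the geometric pyramid
rule, k outputs, one per organism). Online backpropagation with momentum
runs until the root-mean-squared error over all samples and outputs reaches
0.01. A query image is evaluated by all five members and the activations are
averaged; organisms with average ≥ 0.01 are *recognized* — the best is the
*foreground* genetic image, the rest are *background* images.

**Uncovering.** Recognized organisms obscure more distant relatives, so they
are removed from the teaching set and the ensembles are retaught; repeating
this uncovers progressively deeper relatives. When recognition is lost, the
reference switches to the earliest foreground found so far. Runs from both
ends of the panel ("top" and "bottom" of evolution) are merged — at the
*threshold organisms*, where the homologous-position fraction versus the top
reference crosses 25% (top-down) or 50% (bottom-up) — into the *virtual line
of inheritance*.

**Semihomology.** Aligned positions are classified over the codon sets of a
genetic code: `R` (same residue), `#` (residues one *transition* apart in
some codon pair), `$` (one *transversion* apart), `-` (two or three point
mutations, or pads). Counts are reported as `[R/#/$/-]` and always sum to
the aligned length.

**Simulator.** Synthetic panels evolve from a random root by a fixed number
of single-nucleotide substitutions per branch with transition:transversion
proposal odds κ:1 and stop-codon rejection, recording exact ground truth, so
the whole pipeline is testable with no downloads.

## Worked example

```bash
python examples/recognize_relative.py
```

```
panel: ['org00', 'org01', 'org02', 'org03', 'org04', 'org05']
held out: org05 (true parent org04)

  org04: 0.9717 <- foreground
  org02: 0.0291 <- background
  org01: 0.0099
  org03: 0.0039
  org00: 0.0037

Organisms with average >= 0.01 are 'recognized'; the best one is the
foreground genetic image — here the held-out organism's direct ancestor.
```

A 6-organism ladder is simulated (30 + 40 codons, 4 substitutions per
branch, κ = 3), the tip `org05` is held out, and the ensemble taught on the
other five ranks the tip's true parent `org04` first by a wide margin — the
foreground genetic image. Its average activation 0.97 is close to the ideal
1; the grandparent `org02` clears the 0.01 threshold as a background image;
the rest are unrecognized.

Other capabilities, one script each, are in `examples/`: `encode_images.py`,
`semihomology_pairs.py`, `uncover_ladder.py`, `simulate_panel.py`. The same
stages are exposed as a thin CLI (`geneimage encode|semihomology|recognize|
uncover|virtual-line|simulate|tree-count`).

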