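# Methods

This note documents the models and procedures implemented in `geneimage`,
the parameters that matter, and the choices made where the design was
genuinely open.

## Genetic-image encoding

An organism is represented by the amino-acid sequences of two mitochondrial
DNA-barcode proteins: cytochrome b and cytochrome c oxidase subunit I (COI).
Each sequence is *fitted* to a reference length — end-padded with `-` or
end-truncated; no alignment in the bioinformatic sense is performed — and
encoded with 5 bits per residue. Codes follow alphabetic indexing: `A` = 1
(`00001`), `B` = 2, …, `Z` = 26, pad = 0 (`00000`). This covers the
ambiguity letters (`B`, `J`, `O`, `U`, `X`, `Z`) uniformly; every code fits
in 5 bits. Unknown characters (digits, `*`) are hard errors rather than
silent pads, because silent coercion would corrupt images.

Default reference lengths are the human protein lengths, 380 (cytochrome b)
and 513 (COI), giving images of 1900, 2565 and — concatenated, cytochrome b
first — 4465 bits. The lengths are configurable so synthetic panels can use
short references.

PNG rendering (one colored cell per residue) is a debugging aid only;
nothing downstream consumes it.

## Recognition by sigmoid-network ensembles

The recognizer is a full-synapse three-layer perceptron: n inputs (one per
bit), a hidden layer of round(√(n·k)) sigmoid units (the geometric pyramid
rule), and k sigmoid outputs, one per organism in the teaching set (ordered
alphabetically by Latin name, which makes output order canonical).

Training is per-sample (online) backpropagation on squared error with
momentum: each update is `dW ← η·∇ + α·dW_prev`, applied immediately. The
stopping rule is the root-mean-squared error over all samples and output
units evaluated at epoch end, target 0.01. Defaults: η = 0.3, α = 0.1 for
single-gene images; η = α = 0.07 for concatenated images. Where the
training procedure is under-determined, this implementation fixes: bias
units on both layers (needed in practice to reach RMSE 0.01 on one-hot
targets), weight initialization uniform on [−0.5, 0.5] from a seeded
generator, presentation order reshuffled each epoch with the same generator
(`shuffle_each_epoch=False` gives a strictly sequential order), and an epoch
cap of 50 000 with an explicit non-convergence error. Training one-hot
targets requires pairwise-distinct teaching images; duplicates are rejected
up front with a clear message rather than looping to the epoch cap.

The inner loop runs through a numba-compiled kernel when numba is
importable, with an arithmetically identical numpy fallback; a fixed seed
gives bit-identical weights and epoch logs across runs on one machine
within either path.

An *ensemble* is five such networks with consecutive seeds. "Recognized
five times" is implemented as five independently initialized members
evaluated once each — forward passes are deterministic, so repetition is
only meaningful across members — and the per-organism activations averaged.
Organisms with average ≥ the recognition threshold (0.01) are *recognized*,
sorted by descending average with a lexicographic tie-break; the first is
the *foreground* genetic image, the rest *background* images. The best
sub-threshold organism is always reported too, because recognition against
very distant references legitimately produces sub-threshold maxima that the
protocol may still need.

## The uncovering protocol

One step: teach ensembles on the panel minus the reference minus everything
already removed; recognize the reference's image; remove every organism the
*main recognition system* (the concatenated-image ensemble) recognized.
Single-gene ensembles can be requested and are reported, but never drive
removal — in practice they lose recognition earlier than the concatenated
system. When nothing is recognized, the run switches reference to the
earliest-recognized foreground not yet used as a reference (a FIFO queue)
and halts when that queue is empty or the teaching set is exhausted. The
teaching set strictly shrinks at every productive step, so termination is
guaranteed. Sub-threshold continuation (removing the best sub-threshold
organism when nothing passes) is enabled by default only for bottom-up
runs, where early references are so distant that all averages may sit below
0.01; it is flag-controlled.

*Threshold organisms* are detected from the homologous-position fraction
(R positions / aligned length) of each step's foreground versus the apex
reference: top-down, the last foreground still at ≥ 25% before the first
below; bottom-up, the last at ≤ 50% before the first above. The first
foreground after a reference switch is marked as well (`*`; the two
fraction-based markers are `**` and `***`).

The *virtual line of inheritance* merges the two runs: position 0 is the
top apex, then top-down foregrounds in step order up to a credibility bound
(by default the top-down threshold organism; configurable, since where
top-down contributions should end is a judgment call), then the bottom-up
foregrounds reversed from its threshold organism back to its own apex.
Background organisms ride along in brackets with their step's foreground.
Organisms that cannot be placed are reported, and conflicting placements
raise rather than being silently resolved.

`count_rooted_trees(n) = (2n−3)!!` (exact integer arithmetic) gives the
number of rooted binary topologies the tree-based alternative would have to
search over; for 32 taxa this is ≈ 1.782 × 10⁴².

## Semihomologous position classification

For two aligned residues, the classifier asks how the codon sets of a
genetic code connect them: identical standard residues are homologous
(`R`); residues whose codon sets contain a pair at Hamming distance 1 are
semihomologous, typed `#` if some distance-1 pair differs by a transition
(purine↔purine or pyrimidine↔pyrimidine) and `$` if by a transversion;
everything else — distance ≥ 2, pads, residues without codons (`X`, `B`,
`Z`, `J`, and by default the rare nonstandard `U`/`O`) — is `-`. Putting
pads in `-` keeps the counts summing to the full fitted length, which is
the invariant the `[R/#/$/-]` report format relies on.

Two decisions are exposed as flags because the canonical convention is not
fixed by the definitions alone:

- **Tie policy.** Some residue pairs (e.g. L/F) have both transition-type
  and transversion-type distance-1 codon pairs. The default prefers `#`,
  since transitions dominate several-fold in molecular evolution; a
  transversion-precedence policy is selectable. The choice moves only the
  `#`/`$` split, never `R`.
- **Code table.** The universal code (NCBI table 1) is the default; the
  vertebrate-mitochondrial code (table 2) is shipped and selectable, which
  is the natural choice for cytochrome b/COI. Again only `#`/`$`/`-` can
  shift, never `R`.

Codons are represented as RNA (`U`, not `T`); tables come from Biopython's
copy of the NCBI translation tables.

## Codon-evolution simulator

The simulator exists so every stage runs, with exact ground truth, on
panels whose ancestry is known. A root of uniformly random sense codons
evolves along a chain or complete binary tree; each branch receives a fixed
number of single-nucleotide substitutions at uniformly chosen sites. Each
proposal is the site's transition with probability κ/(κ+1), otherwise one
of its two transversions uniformly; proposals creating stop codons are
rejected and redrawn, so every node stays translatable full-length (the
equal-length premise of the encoder). Substitutions are recorded
(gene, site, bases, transition flag) and replaying them reproduces the
child exactly.

Defaults — 60+80 codons, chain of 8, 4 substitutions per branch, κ = 3 —
are the package's standing study conditions: κ = 3 is a typical
transition/transversion bias for mitochondrial protein-coding genes, and 4
substitutions on ~420 nucleotide sites (~1%) gives the small per-branch
divergence regime in which recognition of a nearest relative is meaningful.
Branches are additionally redrawn until at least one residue changed
(`min_aa_subs_per_branch=1`): panel members model distinct species, whose
barcode proteins differ by definition, and identical teaching images would
make one-hot training ill-posed. Setting it to 0 disables the redraw;
`subs_per_branch=0` ignores it and produces identical records.

What the simulator does *not* emulate: rate heterogeneity across sites and
lineages, selection, codon-usage bias, indels, and the deep divergences of
a real cross-kingdom panel. Passing tests on these panels demonstrates that
the machinery behaves as specified under controlled divergence — not that
recognition accuracy transfers quantitatively to real organisms.

## Problem sizes and numerical choices

The test suite and the acceptance script run the training-heavy checks at
simulation scale chosen as the smallest panels on which the contracts are
meaningful: the training-contract check uses the default generator panel
(8 organisms, 60+80 codons, concatenated images of 700 bits); recovery and
uncovering-order checks use 6-organism ladders with 30+40 codons over 20
and 10/6 seeded replicates respectively. Recognition thresholds (0.01),
RMSE target (0.01), and the 25%/50% homology fractions are the protocol's
own constants, not tunables of the tests.

Ties in recognition averages break lexicographically by Latin name;
`hidden_size` rounds half to even (numpy convention) with a floor of 1;
degenerate inputs (empty teaching sets, empty sample lists, unequal
sequence lengths, non-RNA bases, identical bases passed to the transition
test) raise `ValueError` with the offending item named.

## Known limitations

- Recognition activations are not calibrated probabilities; only their
  ranking and the 0.01 threshold are meaningful.
- The uncovering order can depend on seeds near the recognition threshold;
  all stochasticity funnels through one base seed and traces record enough
  to replay a run exactly.
- The virtual-line merge rule beyond the threshold organisms is a
  documented convention (configurable stops), not a uniquely determined
  procedure.
- With very high per-branch divergence the one-point-mutation classes
  saturate (`-` dominates) and the semihomology signal carries little
  information; the classifier is existence-based over codon sets and does
  not estimate substitution histories.
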