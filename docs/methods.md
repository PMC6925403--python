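# Methods

## The fluctuation scale

The package's central object is a fixed three-way partition of the 20
standard amino acids by conformational mobility: high (G, A, S, P, D),
moderate (T, E, N, K, C, Q, R, V) and weak (H, L, M, I, Y, F, W)
fluctuating residues, with integer indices −2, −1 and +2 respectively.
The classification is taken as given — it is not re-estimated from
structural B-factors or any other data — and ships as a plain TSV
(`src/prefrp/data/fluctuation_scale.tsv`) so that an alternative
grouping or index assignment is a one-file change, loadable with
`load_scale`. The asymmetry of the index (two negative mobile classes,
one positive rigid class) keeps the two signs visually separable in
profile plots and makes "index ≤ −1" a natural flexibility predicate.

## Carbon content

The physical basis of the classification is the carbon content of the
residues. The published description does not pin down a formula, so the
package adopts one convention and states it: **carbon fraction =
(number of carbon atoms) / (number of all atoms, hydrogens included) of
the residue as a chain monomer**, i.e. the free amino acid minus one
water. Glycine (monomer C2H3NO, 7 atoms) gives 2/7 ≈ 0.286; tryptophan
(C11H10N2O, 24 atoms) gives 11/24 ≈ 0.458. The atom counts live in the
same TSV as the scale and are checked in the test suite against an
independent oracle that counts atoms in the amino acids' molecular
structures (rdkit, explicit hydrogens, minus H2O). Alternative
conventions (heavy atoms only, side-chain only) would change the
numeric fractions but not the machinery; they can be supplied via
`load_carbon_table`.

## Profiles, smoothing and unknown residues

`profile_sequence` maps residue *i* to its index; profiles keep the
1-based source coordinate of every profiled residue. Non-standard codes
(X, B, Z, U, O, gaps) are governed by a policy flag:

- `skip` (default): drop the position and count it, with a warning.
  Composition denominators then count classifiable residues only.
- `zero`: keep the position with index 0, preserving length. Zero sits
  between the two signs and never satisfies a threshold of −1.
- `error`: raise, naming the first offending position.

Smoothing is an optional centred moving average with an odd window
(default 1 = unsmoothed; no window is imposed because none is inherent
to the method). At the ends the window shrinks symmetrically
(`k = min(half, i, n−1−i)`), so every smoothed value is a mean of raw
values and lies within their range — the suite asserts exactly that
bound rather than any end-effect mean-preservation, which symmetric
shrinking does not guarantee.

## Composition

`composition` pools residues across the whole record set rather than
averaging per-record fractions; fractions are counts over the pooled
total. Pooling makes the summary additive over dataset splits and
invariant under any permutation of residues within or across records,
both of which are tested. Per-record summaries are obtained by calling
it on single-record lists.

## Segment calling and agreement

`call_segments` reports maximal runs of consecutive positions whose
series value (smoothed when present, else raw) is ≤ threshold, kept iff
the run length reaches the minimum. Defaults: threshold −1 (captures
the high and moderate classes exactly on raw profiles) and minimum
length 30 residues, following the conventional definition of a long
disordered region. Both are exposed as flags, as the calling rule —
unlike the index itself — is a design choice of this package.
Coordinates are 1-based inclusive (the residue-numbering convention of
structure-facing tools); the BED-like output converts to 0-based
half-open starts. `agreement` reduces a segment call and an external
per-residue binary reference to confusion counts; sensitivity and
specificity are NaN when their denominators are empty rather than
being clamped.

## Rank-occupancy matrices

Each complete 20-value scale orders the residues from highest to lowest
property value (rank 1 = highest; an `ascending` flag serves scale
families where low means flexible). Ties break alphabetically by
one-letter code — some fixed rule is required for the matrix to be
well-defined, and alphabetical is deterministic and auditable. Scales
with missing values are rejected rather than imputed, because ranking
an incomplete alphabet breaks the matrix's defining invariant: over `k`
scales every row and every column sums to `k` (each scale places each
residue at exactly one rank). The bundled reference matrix
(`occupancy70`) aggregates 70 hydrophobicity/flexibility scales; the
identities of those 70 scales are not re-derivable, so the matrix is
shipped as data, validated against its marginal invariant and spot
cells, and is explicitly not a rebuild target. A separate curated
sample of 8 complete hydrophobicity/flexibility scales (Kyte–Doolittle,
Hopp–Woods, Eisenberg, Fauchère–Pliska, Bhaskaran–Ponnuswamy,
Grantham polarity, Karplus–Schulz, Janin), transcribed from their
original publications in AAindex1 format, exercises the builder.

## Synthetic sequences

The generator draws each residue in two steps: a fluctuation class from
the target fractions, then a residue uniformly within that class. No
within-class frequencies are inherent to the method, so uniform is the
default; a full 20-residue frequency vector can be supplied and is
renormalised within each class. Observed class fractions converge to
the targets with binomial error ≈ √(f(1−f)/n), about 0.16% at
n = 100 000 — the suite checks recovery within ±0.01 at that length.
The generator is deterministic under a fixed seed (one NumPy
`default_rng` stream). Synthetic sequences emulate composition only:
they have no positional autocorrelation, no secondary-structure
segments and no disorder grammar, so tests built on them validate the
counting and calling machinery, not biological prediction accuracy.

## Sequence I/O

FASTA reading/writing and PDB parsing delegate to Biopython. PDB
extraction prefers SEQRES (the full construct, independent of which
residues are resolved in the coordinates) and falls back to the CA
trace; `prefer_atom=True` forces the trace. Only the first model of
multi-model entries is used, and only the legacy PDB format is
supported — the package's structure needs end at sequence extraction.
The crotamine fixture is a SEQRES-only PDB file constructed from the
peptide's published 42-residue sequence (filename marks it synthetic);
the same sequence ships as FASTA so both input routes hit the same
42-residue check. The AAindex1 parser is written here (no installed
library provides one); the residue order of the two ten-value rows is
fixed by the format documentation, never inferred from the file.

## Problem sizes and numerics

The randomized suites use 1000 random sequences (composition oracle),
300 random profiles of length ≤ 200 (segment-caller oracle) and one
100 000-residue draw (generator convergence); these sizes put the
binomial error an order of magnitude below the asserted tolerances
while keeping the whole suite in a few seconds. All core quantities are
exact integer arithmetic; the only floating-point tolerances are 1e−9
on fraction sums and the ±0.01 convergence band above. Matrix TSV
round-trips are bit-exact.

## Known limitations

- The classification is fixed; residues in unusual chemical contexts
  (e.g. disulfide-bonded cysteines, as in crotamine) carry their
  standard class.
- The carbon-content convention above is one of several defensible
  choices; results that depend on the absolute fractions should state
  the convention.
- Segment calling is thresholding, not probabilistic inference; it has
  no notion of uncertainty and its defaults are conventions, not fitted
  parameters.
- mmCIF, coordinate-level analysis and B-factors are out of scope.
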