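# prefrp

Fluctuating-residue prediction from protein sequence.

Conformational flexibility of individual amino acids shapes how proteins
fold and how they bind partners: flexible residues concentrate at binding
interfaces, in chameleon sequences and in intrinsically disordered
regions. `prefrp` implements a simple, fully deterministic sequence-level
method for this: the 20 standard amino acids are partitioned into three
fluctuation classes derived from their carbon content, and each class
carries a fixed integer index,

| class    | residues               | index |
|----------|------------------------|------:|
| high     | G, A, S, P, D          | −2    |
| moderate | T, E, N, K, C, Q, R, V | −1    |
| weak     | H, L, M, I, Y, F, W    | +2    |

so a sequence becomes a per-residue series of −2/−1/+2 values. Negative
values mark mobile residues, positive values rigid ones. On top of that
the package provides:

- per-residue **profiles** with optional centred moving-average smoothing,
- pooled **class compositions** over sequence sets,
- **segment calling** — maximal runs of positions with index ≤ a threshold
  (default −1, i.e. the high + moderate classes) of at least a minimum
  length (default 30 residues, the conventional cutoff for long
  disordered regions),
- per-residue **agreement statistics** (sensitivity/specificity) against
  any external binary annotation, e.g. a disorder mask,
- **rank-occupancy matrices**: given a family of amino-acid propensity
  scales (AAindex1 format), each scale orders the residues from highest
  to lowest value; counting which rank each residue occupies across `k`
  scales yields a doubly balanced 20×20 matrix (every row and column
  sums to `k`). A reference matrix aggregated over 70
  hydrophobicity/flexibility scales ships with the package,
- a **synthetic sequence generator** with controlled class composition,
- readers for FASTA, sequence extraction from PDB files (SEQRES with an
  ATOM-trace fallback) and a parser for the AAindex1 flat-file format.

## Worked example

Crotamine (PDB 1H5O), a 42-residue cell-penetrating peptide, ships as a
bundled fixture. Its pooled class composition:

```sh
$ prefrp compose src/prefrp/data/crotamine.fasta
class	count	fraction
high	13	0.30952380952380953
moderate	19	0.4523809523809524
weak	10	0.23809523809523808
```

31% of crotamine's residues are high-fluctuating and 45% moderate — about
three quarters of the peptide is conformationally mobile, consistent with
its largely irregular, disulfide-stapled structure. Calling flexible
segments on a lightly smoothed profile:

```sh
$ prefrp segments src/prefrp/data/crotamine.fasta --min-length 5 --window 3
id	start	end	length	mean_index
crotamine_1H5O	36	42	7	-1.4285714285714286
```

finds one 7-residue flexible stretch at the C-terminus (positions 36–42,
1-based inclusive; mean index −1.43). The same operations are available
as library calls (`prefrp.composition`, `prefrp.call_segments`, ...), and
`prefrp profile`, `prefrp rankmatrix` and `prefrp synth` expose the
remaining functionality; every CLI result equals the corresponding
library call.

Querying the bundled 70-scale rank-occupancy matrix:

```pycon
>>> from prefrp import load_fixture, modal_position
>>> m = load_fixture("occupancy70")
>>> modal_position(m, "A")
ModalPosition(position=10, count=16, tied=False)
>>> modal_position(m, "D")
ModalPosition(position=19, count=12, tied=False)
```

Alanine most often sits mid-ranking (rank 10 in 16 of 70 scales) while
aspartic acid clusters near the bottom (rank 19 in 12 scales) — the
high-fluctuating residues occupy characteristic bands of the
hydrophobicity ordering.

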