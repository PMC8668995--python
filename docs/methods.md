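# Methods

## The analysis

The package implements a residue-level conservation analysis of WEE1-family
kinases against a single reference (human WEE1A). The pipeline is: align the
family; map alignment columns to reference numbering; read each sequence at a
catalog of functional sites; classify the observation; derive functionality
flags; summarize relationships as a midpoint-rooted distance tree; and, where
structures exist, superpose them and measure the catalytic-pocket access
distance. Each stage is an ordinary, well-characterized method — the value of
the package is that the stages are deterministic, parameterized, and tested
against independent oracles, so a conservation claim ("this legume duplicate
lacks the catalytic aspartate") is reproducible from the raw inputs.

## Pairwise and multiple alignment

Global alignment is Needleman–Wunsch with Gotoh's three-state affine-gap
recurrences. A gap of length *k* costs `gap_open + k·gap_extend`; end gaps
are penalized (true global alignment) because ragged ends are handled
explicitly by the trimming step instead. Defaults are BLOSUM62 with
`gap_open = 10`, `gap_extend = 0.5` — a Clustal-like parameterization; any
NCBI-format matrix can be substituted. `X` scores 0 against everything.
Traceback tie-breaks are fixed (diagonal > up > left), so identical inputs
always give identical alignments. The DP score is verified against exhaustive
enumeration of all global alignments for short sequences and against
Biopython's independent `PairwiseAligner` for realistic lengths.

The multiple aligner is a single-pass progressive method: p-distances from
pairwise alignments feed a neighbor-joining guide tree (midpoint rooted;
children visited by smallest member id), and profiles are merged in
post-order. Profile–profile column scores are the frequency-weighted average
substitution score (gap fraction contributes zero) with the same affine gap
penalties, computed as one matrix product per merge. There is no iterative
refinement — determinism is worth more here than the last few percent of
alignment quality, and the package can import externally computed alignments
(aligned FASTA or Clustal) for all downstream stages.

`trim_ends` removes the maximal prefix/suffix runs of columns whose non-gap
occupancy is below a threshold (default 0.5; there is no canonical value, so
the chosen occupancy is recorded in every report header). Interior columns
are never touched, making the operation idempotent; after trimming, the
column map keeps full-length reference numbering by offsetting the first
kept reference residue.

## Reference anchoring

Column maps are built from the reference row: numbering is 1-based over the
full-length reference, and segments never renumber. Queries at positions
trimmed out of the alignment return an explicit out-of-alignment observation
rather than raising, because "this fragment does not cover the site" is an
analysis result, not an error. Per-species positions (e.g. "the gate residue
sits at position 259 of the Arabidopsis sequence") can be derived either
from the family MSA or from a pairwise global alignment to the reference;
both modes are provided and agree on substitution-only families, where
homology is unambiguous.

## Site catalog and conservation calls

The built-in catalog records, in human numbering: E309 (G-loop gate), K328,
N376 (gatekeeper), C379, D426 (catalytic), K428, N431, D463–G465 with L/F
both accepted at the middle position (human DLG, plant DFG — the aspartate is
the function-critical atom donor), E477–D479 (EGD), D479, R481, R518, and the
catalytic-segment consensus `IVHxDLKPxNIx` anchored at 422. Catalogs
serialize to JSON so other kinase families can be annotated with the same
machinery.

A call compares the observed residue letter against the expected set:
`conserved` (member), `conservative` (same physicochemical class),
`class-change`, or `missing` (gap / outside alignment). Classes follow the
standard kinase-figure coloring: hydrophobic AILMFVW, acidic DE, basic RK,
polar QSNT, aromatic YH, and C, P, G as singletons (histidine is grouped
aromatic, not polar, following that convention). Calls use the residue
letter only, not column context, matching how such figures are read.

Functionality flags are pure functions of the calls: `catalytic-dead` when
the catalytic aspartate is absent, `ATP-binding-compromised` when the
DFG/DLG aspartate is absent (the L/F exchange never flags), plus variant
flags for EGD, R481, R518 and the gatekeeper. The consensus scanner's
relaxed mode widens hydrophobic pattern positions to the whole hydrophobic
class (AILMFVW) and is off by default; when enabled it is recorded in the
output.

## Phylogeny

Neighbor joining uses the standard Q-matrix agglomeration with two
determinism guarantees: ties are broken by the lexicographically smallest
pair of cluster labels, and negative branch-length estimates are clamped to
zero with the deficit moved to the sister branch. Midpoint rooting places
the root halfway along the longest leaf-to-leaf path (ties again
lexicographic); on an all-zero-length tree the midpoint is undefined and the
tree is rooted at its basal node with a warning. Distances default to
p-distance with an optional Poisson correction `−ln(1−p)` (p capped below 1;
flagged in the report when used). Bayesian inference is deliberately not
reimplemented — externally computed trees are imported as Newick (support
values preserved) and compared by Robinson–Foulds distance. NJ is verified
to recover random additive trees exactly (topology and branch lengths) and
cross-checked against dendropy.

## Structures

PDB input is parsed with gemmi and reduced to a flat atom table: first model
only, ATOM records only by default, altlocs resolved to the
highest-occupancy location (ties prefer 'A'), insertion codes kept in the
residue key. Superposition is Kabsch (SVD with reflection correction,
guaranteeing a proper rotation) on Cα atoms of alignment-paired residues —
Cα only, because predicted models differ from crystals mostly in side-chain
reliability. A ≥5% sequence/structure mismatch aborts the pairing.

Pocket access is measured as the minimum distance over heavy side-chain
atoms of the two gate residues (backbone N/CA/C/O excluded; glycine falls
back to Cα). Closest side-chain approach is the defensible reading of
"access" between two side chains, and since molecular-graphics measurements
rarely state their atom pair, every report names the atoms that achieved
the minimum; an `atom-pair` mode allows probing alternatives.

## Synthetic data

The generators exist to make every stage testable offline with exact truth:

* `simulate_family` evolves a reference down a random tree, i.i.d. per site,
  uniform over the 19 alternative residues — deliberately not an empirical
  substitution model, because truth bookkeeping and detectability matter
  here and realism does not. Protected positions (the catalog sites) never
  mutate stochastically and indels stay ≥2 residues away from them, so a
  planted substitution is provably the only change at a tested site; planted
  events are applied on the terminal branch and guaranteed present.
* `simulate_structure_pair` builds a smooth helix-like Cα curve (a wide
  solenoid, spread in all three dimensions so rotations about every axis are
  well-constrained; stereochemical realism is a non-goal) and a copy moved
  by a known rotation/translation plus Gaussian noise.
* `simulate_gate` constructs two residues whose minimum side-chain
  heavy-atom distance equals the requested value to 1e-6 (decoy atoms
  strictly farther), then rigidly re-orients the whole structure per seed.
* `synthetic_reference_wee1` / `synthetic_wee1_study_family` are labelled
  synthetic surrogates of the human WEE1A protein and a cross-species
  comparison set: a deterministic 646-residue sequence carrying the
  documented functional residues at the documented human coordinates (the
  background is scrubbed of chance copies of the diagnostic motifs so scans
  are unambiguous), and plant-like derivatives built by N-terminal
  truncation (placing the G-loop gate at own-positions 259/248/256),
  documented site substitutions (gate E→H/Y/N, gatekeeper N→M, R518→E, the
  monocot EGD E→D, and a degenerate legume duplicate lacking both
  aspartates), plus 3% background substitutions away from catalog sites.

Because the surrogates are constructed, passing tests demonstrate that the
*methods* (anchoring, calling, flagging, measuring) are correct and
deterministic — they do not re-validate database sequences or experimental
structures. Runs on real inputs go through exactly the same code paths via
`seqio.read_fasta` / `read_pdb` (see `scripts/fetch_ncbi.py`).

## Numerical choices and problem sizes

Scores are sums of integer matrix entries and gap-penalty multiples, so
traceback equality checks use a 1e-9 tolerance that is exact in practice.
Collinearity in Kabsch input is rejected at a 1e-8 relative singular-value
threshold. Tests and the acceptance script use families of 3–6 taxa on the
646-residue reference, trees of up to 12 leaves, and point sets of 40–100
atoms — sizes at which the exhaustive and closed-form oracles are exact and
the full suite runs in well under a minute.

## Known limitations

* The progressive aligner does not aim to reproduce any specific external
  aligner column-for-column; imported alignments should be used when an
  exact published alignment matters.
* p-distance trees are a conventions-compatible stand-in (topology, lengths,
  midpoint rooting, Newick), not a substitute for model-based inference.
* Pocket-access values depend on the chosen atom rule; comparisons across
  structures are meaningful within one mode.
* The uniform substitution model and rigid truth bookkeeping of the
  simulators trade realism for exactness by design.
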