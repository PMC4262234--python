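# Methods

This note records the models, parameter choices and numerical conventions
behind `dsloop`, and what the synthetic generators do and do not emulate.

## Loop definition and knot exclusion

A loop is a same-chain cysteine pair (i, j) with interior length
j − i − 1.  Structure mode accepts interiors of 2–9 residues and endpoint
separations up to 10 (total length ≤ 11); sequence mode, which works from
curated disulphide annotations rather than geometry, uses 2–8.  Both
bounds are configurable; the defaults reflect the slight asymmetry
between what can be measured in a structure and what is typically
annotated in sequence databases.

Cysteine-knot-like arrangements are excluded by three rules applied
simultaneously over all candidate bonds of a chain: bonds sharing a
cysteine are both dropped (a thiol cannot form two disulphides, so such
candidates are contradictory); interleaved spans i1 < i2 < j1 < j2 are
both dropped; and a bond whose interior contains another bond's cysteine
is dropped, so for cleanly nested bonds the outer goes and the inner
survives.  The rules are deliberately not iterated: exclusion is decided
on the full candidate set, which keeps the result independent of
processing order.

## Bond geometry

The canonical S–S bond length is ~2.05 Å; the detection window defaults
to [1.6, 2.5] Å (inclusive at both ends) to absorb crystallographic
coordinate error while excluding non-bonded sulphur pairs, and is
configurable.  Cysteines lacking an Sγ atom cannot be tested and are
skipped with a logged warning rather than an error, since partial side
chains are common in real structures.

## Surface area and interfaces

SASA uses Shrake–Rupley sphere sampling (Biopython's implementation)
with probe radius 1.4 Å and 960 points per atom.  960 points keeps the
per-residue quantisation error under 2%: doubling to 1920 points moves no
residue area by more than that on the test structures.  Hydrogens,
waters and hetero records are stripped at parse time; every analysis is
heavy-atom only.  A residue is "surface" when its SASA strictly exceeds
2.5 Å² ("over" is read as strict), and "interface" when any heavy atom
lies within (≤) 3 Å of a different chain.  Surface classification
defaults to assembly context (the complex as given), with single-chain
context available, since the assembly is the biologically relevant form.

Interface coverage is offered in two modes because the underlying notion
is genuinely ambiguous: `buried_area` (default) weights residues by
ΔSASA = max(0, monomer − complex), matching the idea of "interface
surface area"; `residue_count` simply counts residues.  The two agree
exactly when all ΔSASA values are equal.  Negative ΔSASA beyond a 0.1 Å²
numerical tolerance is treated as an invariant violation in tests, not
silently clipped in reporting.

Superposition RMSD pairs Cα atoms by rank order within each fragment, not
by author numbering, because de-novo models rarely share numbering with
crystal structures; the optimal rotation comes from SVD (Kabsch).

## Conservation scoring

Column conservation is the base-2 Jensen–Shannon divergence between the
column's amino-acid distribution and a background, with equal mixture
weights (λ = 0.5), which bounds the score in [0, 1] without further
normalisation.  The default background is the BLOSUM62 amino-acid
frequency vector.  Gaps and non-standard residues are excluded from the
column distribution and instead down-weight the score by
(1 − gap fraction); an all-gap column scores 0.  Windowed averaging is
available but off by default.  No pseudocounts are added: the mixture
distribution is strictly positive wherever either component is, so the
divergence is always finite.

A loop's statistic is interior mean minus flank mean.  Terminal cysteine
columns are excluded from the interior mean because disulphide cysteines
are conserved almost by definition and would dilute the signal of
interest.  Flanks take up to 4 reference positions per side — matching
the distance range examined by the positional profile — skipping
positions that fall off the sequence or inside another loop's span (those
are not "outside" any loop).  By default a loop is scored only when both
terminal cysteines align to cysteines in at least one homolog row; a flag
includes all loops.

The Mann–Whitney U implementation delegates to scipy: exact null
distribution for tie-free samples of at most 20 per group, tie-corrected
normal approximation otherwise.  The degenerate all-tied case returns
p = 0.5 (z = 0 under the normal reading).  Raw p-values are reported;
no multiplicity correction is applied by default.

## Similarity scoring

Loop interiors (flanking cysteines stripped) are aligned globally under
BLOSUM62 with gap open = extend = −12 — an effectively linear gap penalty
three times the worst substitution score, which strongly favours
equal-length ungapped alignments at these peptide lengths.  The score is
normalised by the *target* (viral) interior's self-alignment score, so
the measure is asymmetric, at most 1, and exactly 1 for identical
interiors.  Local alignment is available via `mode="local"`; the default
is global.  The reporting threshold 0.50 is strict.

The sequence-based loop predictor requires a coil interior (no residue
predicted H or E between the cysteines) and a strict exposed-majority
over the whole Cys…Cys window; exposure ties are excluded.  The
predictor's window is capped at 10 total residues ("under 11"), one less
than the structural cap — both are configurable and the discrepancy is
intentional, mirroring the two definitions' sources.

## Interaction networks

PSI-MITAB 2.5 files merge into one undirected graph keyed by protein
accession.  `uniprotkb:`-prefixed identifiers are preferred; isoform
suffixes (P04004-2) collapse to the parent accession, since interactions
are matched at protein level.  Taxid 9606 labels a node human; a taxid
from a configurable virus list, or any taxon string containing "virus",
labels it viral.  Duplicate edges merge with the union of their source
tags, making hit sets invariant to file and line order.  A mimicry hit
requires a qualifying similarity pair plus at least one shared interactor
(a triangle H–X, V–X).

## Synthetic data: what it emulates, and what it does not

The structure generator builds parallel extended chains (3.8 Å Cα
spacing) with N/CA/C/O/CB atoms at fixed offsets and explicit Sγ atoms
placed to hit each planted bond distance exactly; each plant's Sγ pair
sits on its own z-level so distinct plants can never fake a bond.
Chains are offset so the interchain closest approach equals the requested
gap by construction.  These toys satisfy or violate precisely the metric
criteria under test — distances, exposure, contacts — and nothing else:
they are not stereochemically valid proteins, carry no rotamers, and
passing tests on them says nothing about parser robustness to real PDB
idiosyncrasies beyond what the parser tests cover.

The MSA generator plants conservation directly: each row copies the
per-column consensus with probability `base_conservation` (default 0.6),
raised by `loop_boost` inside loop interiors, otherwise drawing from the
background; cys-flanked loop endpoints are invariant C.  With the default
background and 50 rows, the JS score responds approximately one-to-one to
the copy probability over the 0.6–0.9 range (numerically: mean column
score ≈ 0.40 at p = 0.6 and ≈ 0.71 at p = 0.9), which is why a planted
boost of 0.3 is recovered as a mean interior-minus-flank difference of
≈ 0.3.  That near-linearity is a property of this operating point, not of
the JS score in general; real alignments also carry phylogenetic
correlation between rows, which the row-independent generator does not
emulate, so recovery here demonstrates correctness of the scoring
machinery, not calibrated effect sizes on real orthologs.

The network generator adds the two planted edges per triangle and then
rejection-samples noise edges under the constraint that no planted
human–virus pair gains an extra shared interactor, erroring after 10×
the requested budget in attempts so the postcondition is guaranteed
rather than probabilistic.

All generators are deterministic given spec + seed, and their outputs are
plain text (PDB, aligned FASTA, PSI-MITAB, TSV).

## Problem sizes used in the test suite

The deep end-to-end checks run at sizes chosen to keep the full suite in
a couple of minutes while leaving no statistical ambiguity: 100 seeded
two-chain complexes (25 residues per chain) for detection
precision/recall and interface equality with a brute-force scan; 5
complexes for SASA convergence; one 200-loop alignment for parameter
recovery; 200 seeds of 10-loop alignments for null calibration of the
inside-vs-outside test; 50 random graphs of ≤ 50 nodes against exhaustive
triangle enumeration; and the full exhaustive alignment oracle over all
interior pairs of length ≤ 3 on a 6-letter alphabet.

## Known limitations

- The geometric detector trusts Sγ coordinates; it does not infer bonds
  from Cβ proximity when side chains are truncated.
- Redundancy removal keeps one representative per (accession, cys pair)
  by smallest structure id; no sequence-identity clustering is attempted.
- Conservation scores treat alignment rows as independent; no
  phylogenetic weighting.
- The similarity normalisation divides by the viral self-score only; a
  symmetrised variant is not provided.
- Nucleic-acid chains and modified residues are ignored wherever they
  appear.
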