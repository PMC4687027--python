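# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `solentile`. Empirical statements below are the ones the
test suite and `scripts/acceptance.py` themselves compute.

## Structure model

Everything operates on a coarse Cα/Cβ representation: per chain an ordered
list of residues with a mandatory Cα, an optional Cβ (absent for glycine;
reconstructed from backbone N/CA/C by the standard tetrahedral formula when
missing on other residues), and optional heavy atoms. Author numbering
(seq id + insertion code) is preserved for reporting only; all algorithms
address residues by a gap-free 0-based internal index with half-open
intervals, which keeps insertion-code arithmetic out of every algorithm.
Alternate locations resolve to the highest occupancy (ties: first in
file); only one model of multi-model files is read. Contact maps default
to Cβ (Cα fallback) within 8 Å at sequence separation ≥ 3 — the standard
coarse-grained convention; scheme, cutoff and separation are configurable
everywhere, and a heavy-atom minimum-distance scheme is available when
heavy atoms are present.

## Fragment alignment

`align_fragment` enumerates the distinct placements of a query fragment on
a target chain:

1. **Seeding.** Every query window of `seed_window = 8` residues is
   Kabsch-fitted at every target offset (batched SVD over all offsets at
   once). Diagonals with any window RMSD ≤ 2.5 Å survive, keyed by the
   implied placement offset.
2. **Refinement.** Each candidate diagonal is refined by iterating
   {superpose on current equivalences → re-derive equivalences} until
   stable (≤ 20 iterations). Equivalences come from a banded dynamic
   program (half-band 8) that maximizes `Σ exp(−r²/σ²)` minus affine gap
   penalties (open 0.5, extend 0.1 score units); pairs with residual
   above `distance_cap = 5 Å` are disallowed; end gaps are free.
3. **Deduplication.** Placements whose target-residue sets overlap by more
   than 50% keep only the higher score; equal scores prefer the smaller
   target start, making the output deterministic.

`σ = 3 Å` by default. The similarity kernel makes the score roughly "the
number of equivalent residues", so thresholds can be stated as fractions
of the fragment length. The empirical random background of this gap model
is worth knowing: for a 30-residue query against an unrelated compact
random coil, the best gapped placements score S ≈ 10–13 (gapless: < 10).
Downstream stages therefore accept placements only at `S ≥ 0.5·L`, far
above background.

A vectorized gapless mode (whole-fragment Kabsch at every offset, batched
3×3 SVDs) backs the tiling module, where ~10³–10⁴ (length, phase) tiles
must each be scanned against the chain; it is exactly the exhaustive
sliding-window scan, so the test suite checks the seed-and-refine path
against an independently coded plain-loop version of it.

## Tiling

Eq: `Θ = (C − L)/(N − L)`. Coverage `C` uses greedy selection of
placements by descending score, accepting a placement when its score is at
least `0.5·L` and its covered residues overlap previously covered ones by
at most `0.1·L`. A placement covers only the residues whose
post-superposition residual is within the 5 Å cap — not its whole
footprint. This matters: α-helical segments superpose on one another
regardless of register, so a footprint rule would let half-period
helix-on-helix matches claim loop residues they do not explain and
saturate Θ at spurious lengths. The whole-chain tile is Θ = 1 by the
limit convention and excluded from spectra.

The period spectrum records, per tile length, the maximum Θ over phases
and the phases within 1% of it (the tie tolerance is configurable);
peaks are local maxima with prominence ≥ 0.05, ranked by amplitude, ties
to the smaller length. Tileability `Ξ` is the plain mean of the
per-length maxima. Note an algebraic property of Θ with non-overlapping
placements: tile lengths incommensurate with the period can cover at most
about `(n−1)/n` of each placement footprint on an n-unit array, so for a
perfect 4-unit solenoid Ξ over lengths `[p−5, 2p]` sits near 0.7 — not
near 1 — while Θ is exactly 1 at the period (and its multiples). A random
coil of the same size scores Ξ ≈ 0.07 on the same range, so the contrast
remains an order of magnitude.

## Energy model and energetic phase

The internal-energy model is deliberately simple and injectable: a 20×20
contact potential plus a linear burial term (burial = within-fragment or
within-system contact count, default weight −0.2, negative = burial
favourable). The default potential is a hydrophobicity-product
quasichemical form, `ε(a,b) = −2·h_a·h_b + 0.3·q_a·q_b`, with `h` the
Kyte–Doolittle hydropathy rescaled to [0,1] and `q` unit charges (±1 for
K/R/D/E, +0.5 for H). This is the dominant one-body-product mode of
knowledge-based contact potentials; the phasing and frustration
procedures only require an energy capable of *ranking* fragments and
decoys, not force-field fidelity, and the full associative-memory/water
style force field used in the original frustration literature is outside
this package's scope. Any symmetric 20×20 matrix can be supplied instead.

Relative foldability compares each period-length fragment's internal
energy to the sample mean and sample (n−1) standard deviation of all
*other* same-length fragments: `Θ_fold = (⟨E⟩ − E_frag)/(δE·N)` with `N`
the comparison-set size. The sign convention is fixed so higher = more
foldable; a z-score variant (no `1/N`) is available behind a flag. All
fragments equal in energy → the statistic is undefined and an error is
raised. The best fragment's start, modulo the period, is the energetic
phase; phase offsets are reported against a bundled 33-position consensus
profile (a consensus sequence with the canonical GxTPLHLA motif and a
0.6-match log-odds table), replacing any external HMM dependency. An
external HMMER hook (`hmmalign` on PATH, via the exported Stockholm MSA)
can substitute the bundled profile but is never required.

## Repeat annotation and the structure-based MSA

Repeat detection places a period-length query greedily (best score first,
non-overlapping up to 10% of the period) and sorts accepted placements by
position; each becomes a repeat unit whose residues get canonical
positions 1..period from the alignment equivalences. Unaligned target
residues inside a unit are insertions at the preceding canonical
position; unaligned query positions are deletions; unaligned residues
*between* consecutive units attach to the preceding unit as a trailing
insertion after the last canonical position. Units classify positionally:
first = N-terminal, last = C-terminal, rest internal; a single-unit array
is N-terminal by convention, with a logged warning.

The MSA over all detected repeats is built on a global canonical frame:
one column per canonical position plus, after each position, an insertion
block as wide as the longest insertion observed there in any unit. This
realizes the transitive merge of the pairwise structure-based alignments
with its two guarantees — every gap inserted into a query row appears in
its paired target row (all query rows are identical), and deleting the
gaps from any row returns its source subsequence exactly. The merge order
is deterministic (by target position). Export is FASTA or Stockholm with
'-' gaps, round-trip checked, suitable for `hmmbuild`.

## Frustration

All indices are z-scores of the native energy against a decoy ensemble,
`F = (⟨E_decoy⟩ − E_native)/δE_decoy`, positive = native better than
decoys. A contact's energy includes its pair term and the burial terms of
both partners. Mutational decoys resample the two identities from the
chain's empirical composition (geometry and burial fixed); EXHAUSTIVE
mode enumerates the 400 ordered identity pairs, composition-weighted.
Configurational decoys additionally re-draw both burial values from the
chain's empirical burial distribution, so with the burial term off the
two flavours coincide. Single-residue decoys are the 19 exhaustive
substitutions, with the energy integrating all of the residue's contacts
plus its burial term. Zero decoy variance flags the record undefined
(classified neutral, marked). Classification thresholds are the
frustratometer literature's standard cut-points, minimal at `F ≥ 0.78`
and high at `F ≤ −1.0`, configurable. Sampled modes default to 1000
decoys and are fully seeded.

For complexes, the bound state is the full multi-chain system (cross-chain
contacts count toward burial and the decoy environment distributions); the
unbound state is the rigid monomer with partners removed — the same
coordinates, no relaxation. The frustration delta of each native
intra-chain contact uses matched decoy seeds in both states, so a
single-chain "complex" gives exactly zero everywhere. Interface residues
are those with any atom (heavy, else Cβ/Cα) within 5 Å (configurable) of a
partner chain; binding residues classify as canonical, insertion, or
non-repetitive against the repeat annotation. The released fraction is
reported both per contact and per residue, since either convention is
defensible.

## Information content

`R = H_max − H_obs` in bits. Sequence IC uses 20 states and
`H_max = log₂20`; gaps are excluded from the counts rather than treated
as a 21st state. Frustration IC uses 3 states with `H_max = log₂3` under
the uniform default, or the entropy of a supplied 3-state background — in
which case R can be negative when the observation is more uncertain than
the background, which is reported as-is. Schneider's small-sample
correction `e(n) ≈ (M−1)/(2·ln2·n)` is implemented but off by default.

Contact-level conservation maps the contacts of every consecutive pair of
internal repeats into a 2-period canonical frame (both intra blocks and
the inter block). Cell frequency is the exact fraction `k/n_pairs` of
repeat pairs exhibiting the contact; the cell's frustration IC is
computed over the observed class labels and weighted by that frequency;
the most-informative state is the argmax of the per-state contribution
`R·P(state)`, ties resolved to neutral (the conservative call). The
conserved network keeps cells whose weighted IC strictly exceeds the
highest value among neutral-dominant cells; with no neutral-dominant cell
the threshold is zero, with a warning. On perfectly regular synthetic
families some contacts are conserved in the *neutral* state at the
maximal IC, which saturates this threshold — an artifact of idealized
geometry that real, noisier families do not show; the contact map itself
still ranks the minimally-frustrated conserved cells correctly.

## The synthetic generator

The generator emulates the statistical structure of an ankyrin-like
family, not its physics. A unit is a parametric Cα trace: two ideal
α-helical segments (1.5 Å rise/residue, 2.3 Å radius, 100°/residue) of
*unequal* length (n±2 residues — real solenoid units pair a shorter inner
with a longer outer helix; equal lengths would give the unit an internal
near-symmetry under which half-period tiles tessellate), joined by a
4-residue arc, with a tail that runs back along the side of the unit's
own first helix turn before handing over to the next unit. That capping
tail gives the unit energetic identity: windows in register with the
construction keep the cap's intra-unit contacts (including a
first-to-last-residue contact), while any shifted window severs several
of them, so the construction phase is recoverable from the energy with a
margin of ~4 energy units on the default consensus. Units stack by a
screw transformation (default twist 4°, rise 11 Å about/along z — chosen
for a gently curved, clash-free stack, not fitted to real ankyrin
geometry). Pseudo-Cβ atoms sit 1.5 Å outward from the local chain
midpoint.

Sequences are drawn per position from a bundled 33-residue consensus
(carrying the GxTPLHLA motif, hydrophobic helix cores, and hydrophobic
cap residues at the unit boundaries) with a scalar or per-position
mutation rate; default rate 0.1 approximates the divergence of natural
repeat units, and the default coordinate noise of 0.3 Å Gaussian per
coordinate approximates coordinate uncertainty. Insertions splice an
outward loop bulge of loop-like residues (G/S/T/N/D/P/A) after a
canonical position; deletions remove a canonical span; both are recorded
in the ground truth together with unit boundaries, canonical maps, the
construction phase, and the per-position mutation profile. A non-zero
construction phase trims the head of the chain so it starts mid-unit.
Identical spec + seed yields byte-identical PDB output.

What passing on these constructs does and does not show: the generator's
loops are smooth interpolating arcs with irregular Cα spacing, there is
no side-chain packing, no real curvature statistics, and sequence and
geometry are independent except where stated. Recovery results therefore
demonstrate the correctness and determinism of the algorithms under
realistic noise and divergence levels — not performance on crystal
structures, which additionally show variable unit geometry, missing
residues and non-repetitive decorations.

## Problem sizes and numerical choices

The seeded batteries use 20 replicates each: period recovery on 4-unit
solenoids with periods 20–40 at 0.5 Å noise and 10% mutations; phase
recovery on 6-unit solenoids at 0.3 Å noise and 5% mutations; indel
recovery on 6-unit solenoids with 1–3 indels of lengths 1–5 at 0.3 Å
noise and 10% mutations. These sizes keep the full suite and the
acceptance script to a few minutes on one CPU while leaving every
recovery margin comfortably measured. Tie-breaks are deterministic
throughout (smaller index/length/offset wins); every stochastic stage
takes an explicit seed; degenerate inputs (zero decoy variance, equal
fragment energies, empty labels, single-unit arrays) are flagged or
raised rather than silently absorbed.

## Known limitations

- The aligner is sequential and rigid: no topology-crossing equivalences,
  no flexible/hinged alignment, no database-scale search.
- The energy model is a ranking device; absolute energies and frustration
  indices are not comparable to force-field-based implementations,
  though the z-score structure and classification logic are the same.
- Interface analysis treats the unbound state as the rigid monomer;
  conformational change on binding is out of scope.
- The canonical contact map requires consecutive *internal* repeats, so
  arrays with fewer than four units contribute nothing to it.
- PDB writing is limited to Cα/Cβ records and 9999 residues per chain.
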