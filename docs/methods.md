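# Methods

This note records the models implemented in `cidkit`, the parameters
that matter, the choices made where the design was genuinely open, and
what the synthetic generators do and do not establish.

## Conservation scoring

Column conservation is scored as `C(i) = 1 − S(i)/ln(m)` from the
Shannon entropy `S(i) = −Σ_j P_j(i) ln P_j(i)` of the column's
amino-acid composition, in nats (natural log throughout).

- **Gap handling.** `P_j(i)` uses the non-gap denominator: gaps are not
  an amino-acid type. Gapped columns are handled by a separate rule:
  any column with *more than one* gap is declared non-conserved and its
  score forced to 0 (bin `gap_zeroed`), *after* scoring. A single gap
  is tolerated.
- **The alphabet size m.** `C(i)` needs the number of amino-acid types
  considered. The default is the full alphabet, `m = 20`; per-column
  observed type counts are available via `entropy_m="observed"` (with a
  floor of 2 so the score stays defined for invariant columns). The
  default was chosen because it makes scores comparable across columns
  of one alignment; the observed-types variant rescales every column by
  its own ceiling.
- **Bin boundaries.** high: `C ≥ 0.45`; moderate: `0.35 ≤ C < 0.45`;
  low: `C < 0.35`. The closed/half-open convention is used because it
  partitions [0, 1] with no gaps; descriptions in prose ("greater
  than", "between") are ambiguous exactly at the boundary values, and a
  partition is the only self-consistent reading.

## Hydropathy and physicochemical classification

Column hydropathy is `Σ_j n_j·h_j` over the observed residues, with
`h_j` from the Nozaki–Tanford transfer-free-energy scale (kcal/mol, the
widely used digitised form in which residues without a measured value
are assigned 0; range 0 for Gly to 3.4 for Trp). Both the literal sum
and the per-residue mean are reported; classification uses the mean so
it is independent of alignment depth.

Classification of conserved (high/moderate) columns, in order:

1. **neutral** if Gly+Ala+Pro together reach ≥ 0.5 of observed
   residues (`neutral_majority`). These small residues recur in turns
   and flexible regions for structural rather than chemical reasons, so
   they are separated before the hydropathy test.
2. **hydrophobic** if the mean hydropathy ≥ `hydrophobic_cut`, else
   **hydrophilic** if ≤ `hydrophilic_cut`. Both cuts default to the
   scale midpoint (1.7 kcal/mol for Nozaki–Tanford), i.e. a single
   threshold, so every non-neutral conserved column is classified.

Caveat of the default single threshold: moderately hydrophobic residues
(Val 1.5, Met 1.3) fall on the hydrophilic side of the Nozaki–Tanford
midpoint; columns dominated by them need a lowered `hydrophobic_cut`.
The synthetic tests therefore plant unambiguous compositions (Ile/Leu/
Phe/Trp/Tyr for hydrophobic columns, zero-valued residues for
hydrophilic ones). An alternative majority-residue route
(`classify_by="majority"`) classifies by the most common residue's own
scale value instead of the column mean. Low and gap-zeroed columns are
never classified.

## Motif scanning

Motifs are consensus column patterns, not per-sequence regular
expressions: slot *s* at anchor *a* matches when the fraction of
non-gap residues at column `a + offset_s` belonging to the allowed set
reaches `min_occupancy` **and** that column is conserved (high or
moderate bin). The default `min_occupancy = 0.5` reflects that the
CID's motifs are conserved-position patterns tolerant of individual
substitutions (e.g. a serine standing in the [V/I] slot in one
bacterial chitinase); no published threshold exists, so 0.5 (simple
majority) was fixed once and exposed in config. Wildcard columns are
unconstrained by default; `require_gap_free_x` additionally demands a
gap-free majority there. Anchors whose span passes the alignment end
are skipped.

## Contact detection

All detectors are purely geometric, on PDB coordinates as deposited (no
symmetry expansion, first model, first/blank altloc). Published contact
analyses rarely state their criteria, so every cutoff is explicit
config with conventional defaults:

| criterion | default | note |
|---|---|---|
| hbond donor–acceptor | ≤ 3.5 Å | protein N/O/S vs ligand N/O, element-based |
| hbond angle | ≥ 90° | applied only when explicit hydrogens exist |
| hydrophobic C–C | ≤ 2·1.70 + 0.5 Å | vdW radius sum + tolerance |
| salt bridge | ≤ 4.0 Å | Asp/Glu carboxylate O vs Arg/Lys/His side-chain N |
| pi-cation | ≤ 6.0 Å | ring centroid vs cation-group centroid |
| water bridge | ≤ 3.5 Å | both legs, protein polar – HOH O – ligand polar |

Donor/acceptor typing is element-based without hydrogen placement,
because crystal structures mostly lack hydrogens; when hydrogens are
present the X–H···Y angle filter is applied over hydrogens covalently
close (≤ 1.25 Å) to either partner. Sugar subsite labels (−n…+n along
the cleft) are user input attached to the ligand selection; scissile-
bond inference is out of scope. Matching against published contact
lists should be read as set-inclusion at the chosen criteria, not as a
bit-exact reproduction, since the generating software's cutoffs are
unknown.

## Phylogeny

- **p-distance** with pairwise deletion (only mutually ungapped
  columns), the convention of classic alignment-based tree programs.
  Zero comparable columns is an error, not a silent 0.
- **Kimura protein correction** `d = −ln(1 − p − p²/5)` optional; at
  saturation (p ≳ 0.854) the distance is capped at 10 with a warning.
- **Neighbour joining** per Saitou & Nei with the Q-criterion
  `Q(i,j) = (n−2)d(i,j) − r_i − r_j`, the standard split formula for
  branch lengths, and reduction
  `d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2`. Ties in Q are broken on the
  smallest active index pair, making the output deterministic on
  degenerate inputs. Negative branch lengths (possible on non-additive
  matrices) are clamped to 0 and flagged on the returned tree
  (`clamped`). On additive matrices the algorithm is exact: recovered
  path lengths equal the input distances (verified to 1e-9 in tests).
  The unrooted tree is represented as a trifurcation at the root and
  serialised to Newick via scikit-bio.

## Synthetic data: what it emulates, what it does not

- `gen_alignment` realises **exact** per-column compositions (not
  i.i.d. draws), so class-count recovery tests are deterministic; truth
  labels are computed from the spec composition, never from the
  generated data. `twin_alignment` plants a 27-sequence alignment with
  9/5/5/2/5/6 hydrophobic/hydrophilic/neutral × high/moderate conserved
  columns (32 positions), low-conservation filler and gap-zeroed
  columns — the statistical shape of a curated CID alignment. It does
  **not** emulate phylogenetic correlation between columns, realistic
  residue co-occurrence, or alignment error, so a green recovery test
  establishes correctness of the scoring arithmetic and thresholds, not
  robustness to real alignment noise.
- `gen_complex` builds chemically simplified sugar rings (hexagonal
  heavy-atom rings plus one exocyclic oxygen) and minimal protein
  residues, placed so that planted interactions sit inside the default
  cutoffs and everything else sits outside with a margin; a brute-force
  all-pairs scan validates feasibility at generation time and rejects
  infeasible specs. Decoy atoms are placed > 20 Å away. Realism beyond
  cutoff geometry (stereochemistry, B-factors, occupancy) is a
  non-goal.
- `evolve_on_tree` uses a uniform-rate 20-state model: along a branch
  of length *b* (expected substitutions/site) each site differs from
  its parent with probability `(19/20)(1 − e^(−20b/19))`, the new
  residue uniform over the other 19. This is a Jukes–Cantor-style
  idealisation — no rate heterogeneity, no realistic exchangeabilities
  (BLOSUM/WAG), no indels — sufficient for testing distance/NJ
  machinery, not for simulating real protein families.

All generators are deterministic under a fixed seed (byte-identical
outputs).

## Numerical and I/O conventions

- Columns are 1-based and inclusive everywhere user-facing.
- Ambiguity codes (B, Z, X, J, U, O) are rejected on read by default;
  an opt-in maps them to gaps, since the entropy statistic is defined
  over amino-acid types only.
- Report TSVs format floats at 6 significant digits for stable diffs;
  the run manifest keeps full precision. Two runs with identical config
  and inputs produce byte-identical reports.
- Pipeline exit codes: 0 ok, 2 config error, 3 stage error.

## Known limitations

- Domain boundaries within full-length chitinase alignments must be
  supplied by the user (columns or residue ranges); structure-guided
  boundary detection is out of scope.
- PDB format only (no mmCIF); first model; no symmetry mates.
- Contact detection is distance-geometric, not energetic; reproducing
  a specific published contact list may require tuning cutoffs, and
  near-miss distances can be read off the TSV report for calibration.
- The exact distance model behind published CID trees is unknown, so
  topology agreement with any particular published figure is not a
  correctness criterion; NJ correctness is established on additive and
  simulated data instead.
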