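# cidkit

Sequence and structure analysis of the **chitinase insertion domain (CID)**,
the small α+β module inserted into the TIM-barrel catalytic domain of
subfamily A family 18 chitinases, where it deepens the substrate-binding
cleft. The package is for computational biologists who want to score
conservation and hydropathy across a protein multiple alignment, locate
conserved column motifs (such as the CID's YxR and [E/D]xx[V/I] motifs),
detect protein–oligosaccharide contacts in holo crystal structures, and
build distance-based phylogenies — each stage independently testable on
synthetic inputs with known ground truth.

## The statistics at the core

**Conservation.** For alignment column *i*, with `P_j(i)` the fractional
occurrence of amino-acid type *j* among the non-gap residues, the Shannon
entropy and conservation score are

    S(i) = − Σ_j P_j(i) ln P_j(i)          C(i) = 1 − S(i) / ln(m)

with *m* the number of amino-acid types considered (20 by default).
Columns are binned as highly conserved (`C ≥ 0.45`), moderately conserved
(`0.35 ≤ C < 0.45`) or less conserved; columns with more than one gap are
treated as non-conserved (score forced to 0).

**Hydropathy.** Column hydropathy is the sum over residues of their
Nozaki–Tanford side-chain transfer free energies (kcal/mol), reported as
both the raw sum and the per-residue mean. Conserved columns are
classified as neutral (mostly Gly/Ala/Pro), hydrophobic, or hydrophilic.

**Motifs.** A motif is a set of constrained slots at fixed column offsets
(YxR = {0: Y, 2: R}; [E/D]xx[V/I] = {0: E/D, 3: V/I}). A hit requires every
slot column to be conserved and to reach a consensus occupancy threshold
(default 0.5), which tolerates individual substitutions.

**Contacts.** Hydrogen bonds (polar–polar ≤ 3.5 Å), hydrophobic C–C
contacts (≤ vdW sum + 0.5 Å), salt bridges (≤ 4.0 Å), pi-cation pairs
(ring/charge centroids ≤ 6.0 Å) and water-mediated hydrogen bonds, each
cutoff configurable, attributed to sugar subsites (−n…+n).

**Phylogeny.** p-distances with pairwise gap deletion, optional Kimura
correction `d = −ln(1 − p − p²/5)`, and Saitou–Nei neighbour joining
(exact on additive matrices), serialised to Newick.

## Worked example

```bash
# a 27-sequence synthetic CID-like alignment with a planted conservation
# structure, then profile it and build its NJ tree
cidkit simulate alignment --seed 1 --out twin.fasta
cidkit profile twin.fasta --out profile.tsv
cidkit tree twin.fasta --out tree.nwk
```

prints

```
27 sequences x 44 columns, 32 planted conserved positions
44 columns: 19 high, 13 moderate, 8 low, 4 gap-zeroed
27 leaves -> tree.nwk
```

The 32 conserved positions break down as 9 hydrophobic-high,
5 hydrophobic-moderate, 5 hydrophilic-high, 2 hydrophilic-moderate,
5 neutral-high and 6 neutral-moderate columns — exactly the composition
the generator planted; `profile.tsv` holds the per-column entropy, score,
bin, hydropathy and class. Motif scanning with structure numbering works
the same way:

```bash
cidkit simulate complex --seed 1 --out complex.pdb
cidkit contacts complex.pdb --subsites=-1,-2,-3 --out contacts.tsv
```

```
5 planted contacts -> complex.pdb
2 hbond, 1 hydrophobic, 1 pi_cation, 1 salt_bridge
```

Python API, same computation:

```python
from cidkit.synthetic import twin_alignment
from cidkit.profiles import profile_alignment

aln, truth = twin_alignment(seed=1)
result = profile_alignment(aln)
print(result.class_counts())       # {('high', 'hydrophobic'): 9, ...}
```

## Acceptance script

`scripts/acceptance.py` re-runs the whole pipeline from scratch on
seeded synthetic inputs — twin-alignment profiling, planted-motif
scanning with residue mapping, planted-contact detection on a generated
PDB complex, and NJ recovery of a known 8-taxon tree from sequences
evolved on it — and writes its results JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/cidkit/alignment.py` — aligned-FASTA I/O, region extraction, residue maps
- `src/cidkit/profiles.py` — entropy/conservation and hydropathy profiling
- `src/cidkit/motifs.py` — motif definitions and occupancy-based scanning
- `src/cidkit/contacts.py` — PDB parsing and geometric contact detection
- `src/cidkit/phylogeny.py` — distances, neighbour joining, Newick
- `src/cidkit/synthetic.py` — ground-truth generators for all stages
- `src/cidkit/pipeline.py`, `src/cidkit/cli.py` — orchestration and CLI

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
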