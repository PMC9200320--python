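# flexidock

Flexible protein–protein docking with temperature replica-exchange Monte
Carlo (T-REMC). Each trajectory runs parallel replicas at three inverse
temperatures (1/1.5, 1/3, 1/5 kcal⁻¹·mol by default); every Monte Carlo
trial is either a rigid-body perturbation of the ligand or an induced-fit
backrub of a contiguous interface fragment (rotation of the segment between
two pivot Cα atoms). Configurations are exchanged between adjacent replicas
every 1,000 trials under the standard Metropolis swap criterion, and a
snapshot of the coldest replica is stored per round with a successful swap.
Candidates are then quenched with fine rigid moves, ranked by interface
score, and evaluated with standard docking quality metrics (fnat, I-RMSD,
L-RMSD, Cα RMSD, quality ranks) and the bootstrap expected-N5 success
statistic.

The low-resolution energy is a weighted composite of:

- an inter-chain **residue-pair-transform** term: a binned 6-D
  (translation + rotation) knowledge-based score with a trainable table
  (`score.build_pair_table`) and a smooth analytic surrogate well as the
  no-download default;
- split **Lennard-Jones** repulsive/attractive terms over the coarse atoms
  (backbone + CB + sidechain centroid), intra- and inter-chain;
- backbone **torsion statistics**: phi/psi propensity surfaces per residue
  class (general / glycine / proline / pre-proline), an omega planarity
  penalty, and an amino-acid-given-torsion propensity.

Structures are handled in a reduced representation; the ligand placement is
carried by a rigid "jump" transform so rigid-body moves never touch residue
internals. Everything needed for testing is generated synthetically
(`flexidock.fixtures`): ideal helices built by internal-coordinate
extension, toy complexes with a controllable unbound-to-bound loop motion,
decoy sets with tunable score/quality association, and a funnel-shaped
energy for end-to-end sampling tests — no downloads required.

## CLI

```bash
# write a synthetic unbound/bound fixture pair
flexidock fixtures --out fx/

# local docking (unbound monomers superposed onto the native, moved apart
# 15 A with a 45 deg spin, slid back into contact, then T-REMC)
flexidock local --receptor fx/unbound.pdb --ligand fx/unbound.pdb \
    --native fx/bound.pdb --chains A_B --flex 8 \
    --trajectories 8 --trials 250000 --seed 17 --out run/

# blind global docking from randomized orientations
flexidock global --receptor R.pdb --ligand L.pdb --chains A_B --out run/

# evaluate a candidate directory against the native complex
flexidock eval --pred run/ --native fx/bound.pdb --stage lowres
```

Flexibility scopes (`--flex`): `5.5`, `8` (interface patches by distance to
the partner, recomputed on the fly), `5.5+loops`, `8+loops` (patch plus all
loop residues of the monomers), and `directed` with `--mobile-list` (lines
of `chain:seq` or `chain:start-end`).

Outputs: numbered candidate PDBs, a `candidates.tsv` score/provenance
table, and a `diagnostics.json` with per-pair exchange acceptance rates and
energy-histogram overlaps.

## Layout

| module | contents |
| --- | --- |
| `structmodel` | residues, coarse pose + jump, PDB I/O, dihedrals, secondary structure |
| `geom` | rigid transforms, Kabsch, residue frames, pair transforms, backrub |
| `score` | LJ split, torsion statistics, pair-transform table, composite energy |
| `sample` | mobile-residue selection, move set, pose initializers |
| `remc` | replica ladder, Metropolis/swap criteria, trajectory scheduler |
| `refine` | zero-temperature quench, jump minimization, ranking |
| `evalx` | fnat / RMSD metrics, quality ranks, enrichment, bootstrap N5 |
| `fixtures` | synthetic helices, toy complexes, decoy sets, funnel energy |

Scope notes: the refinement stage replaces all-atom packing with a coarse
clash-relief quench (documented in `refine`); the genuine database-mined
pair-transform table is not shipped — the machinery, a builder, and an
analytic surrogate are.
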