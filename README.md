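# quadbind

Trajectory analysis for small-molecule binding to G-quadruplex and duplex
DNA: stable-complex detection, binding-mode clustering and classification,
binding-pathway order parameters, backbone-torsion / base-flip analysis, and
an MM-GBSA binding-energy decomposition — plus a synthetic-data generator
that builds idealized quadruplex/duplex/ligand structures and scripted
binding trajectories with exact ground truth.

## Who it is for and what it does

Free-ligand binding simulations of G-quadruplex stabilizers (planar
polycyclic cations such as the tri-substituted acridines) produce long
trajectories in which the ligand samples end-stacking poses on the terminal
G-tetrads, groove poses along the flanks, and unbound excursions.  `quadbind`
turns such trajectories into the standard summary:

- **Binding modes.** A frame is a *stable complex* when receptor and ligand
  share more than 10 atom contacts at 3.0 Å.  Stable poses are aligned on the
  receptor backbone, clustered with the Daura algorithm at a 2 Å pairwise
  ligand-RMSD cutoff (no ligand fit), filtered at 1% population, and merged
  into **top** / **bottom** / **groove** modes by a geometric rule on each
  cluster centroid.
- **Order parameters**, per frame: hydrogen bonds per G-tetrad (3.5 Å / 120°
  criteria; a complete Hoogsteen tetrad shows 8), the ligand-plane/tetrad-
  plane angle, receptor and ligand RMSD, the centre-to-centre distance R,
  and the channel K⁺–K⁺ distance; backbone torsions α…ζ and χ with
  histograms, and base-flip intervals from radial base displacement.
- **Energetics.**  A from-scratch MM-GBSA engine:

      ΔE = E_complex − E_DNA,free − E_lig,free
         = ΔE_vdw + ΔE_sur + ΔE_GBELE + ΔE_conformation

  with 12-6 Lennard-Jones and Coulomb molecular-mechanics terms,
  Hawkins–Cramer–Truhlar generalized-Born polar solvation (0.15 M salt,
  mBondi-convention radii, Still pairwise expression), and a Shrake–Rupley
  surface term at 0.0072 kcal/(mol·Å²).  Modes are ranked by
  ΔΔG = ΔE_mode − min ΔE.

Everything is deterministic, every threshold lives in one config object, and
all intermediates are written as fingerprinted TSV files.

## Worked example

```python
import quadbind.synthetic_data as sd
import quadbind.binding_modes as bm
import quadbind.energetics as en

receptor = sd.build_quadruplex()          # 22-mer, 3 tetrads, 2 channel K+
ligand = sd.build_ligand()                # planar tricyclic cation, +3 e
script = sd.TrajectoryScript(
    segments=[(20, "unbound", 0.3), (10, "approach", 0.3),
              (90, "groove", 0.3), (60, "top", 0.3)],
    flips=[(5, 50, 120)], seed=11)        # flip T6 out at 50, back at 120
traj, truth, flips = sd.generate_trajectory(receptor, ligand, script)

result = bm.analyze_binding_modes(traj)
print(f"stable frames: {result.n_stable}/{len(traj)}")
for fam in result.families:
    print(f"family centroid frame {fam.centroid:4d}  "
          f"population {fam.population:.3f}  mode {fam.mode}")

from quadbind.order_parameters import detect_base_flips
intervals, _ = detect_base_flips(traj, residue=5)
print("flip intervals:", intervals)
```

prints

```
stable frames: 151/180
family centroid frame   29  population 0.603  mode groove
family centroid frame  120  population 0.397  mode top
flip intervals: [(52, 118)]
```

The 180-frame script planted 90 groove and 60 top frames among 30
unbound/approach frames: the pipeline recovers the 60/40 split of the bound
population and the scripted flip interval (50, 120) within two frames.
Ranking published per-mode MM-GBSA means reproduces the relative binding
energies of the four receptor systems:

```python
table = en.delta_delta_g({"parallel_top": -62.3, "duplex_groove": -61.7,
                          "antiparallel_bottom": -53.9, "hybrid_top": -40.5})
print(table.to_string(index=False))
```

```
               mode    dE  ddG
       parallel_top -62.3  0.0
      duplex_groove -61.7  0.6
antiparallel_bottom -53.9  8.4
         hybrid_top -40.5 21.8
```

ΔΔG = 0 marks the most favourable binding (top stacking on the parallel
quadruplex); the duplex groove mode trails by only 0.6 kcal/mol, the
antiparallel bottom mode by 8.4 and the hybrid top mode by 21.8.

## Command line

```bash
quadbind synth trajectory --frames 300 --seed 7 --out run     # frames/params/annot/truth
quadbind modes --traj run_frames.pdb --params run_params.txt \
               --annot run_annot.yaml --out modes.tsv
quadbind orderparams --traj run_frames.pdb --annot run_annot.yaml --out op.tsv
quadbind gbsa --complex run_frames.pdb --params run_params.txt \
              --annot run_annot.yaml --window 0.6:1.0 --out energy.tsv
quadbind run --config run.yaml                                # full pipeline
```

Trajectories are multi-model PDB (bonds as CONECT records), parameters a
whitespace-delimited sidecar table keyed by residue/atom name, annotations a
small YAML file naming roles, G-tetrads, channel ions and the ligand core.

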