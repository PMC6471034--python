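# Methods

`quadbind` analyses ligand binding to G-quadruplex and duplex DNA from
trajectories of coordinate frames.  This note records the models and
procedures it implements, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical choices made where the
design was genuinely open.

## Binding-mode analysis

**Stable complexes.**  A frame is a *stable complex* when the receptor and the
ligand share more than 10 atom contacts, an atom-to-atom pair within 3.0 Å
(`contact_cutoff`).  The strict inequality matters: exactly 10 contacts is not
stable.  Contacts are counted over all atoms, hydrogens included.

**Pose clustering.**  Every frame is superposed onto the first frame of the
trajectory by a least-squares (Kabsch/SVD) fit of the receptor sugar-phosphate
backbone (P, OP1, OP2, O5', C5', C4', C3', O3').  The pairwise ligand RMSD —
with no further ligand fit — feeds the Daura greedy clustering at a 2.0 Å
cutoff: the frame with the most neighbours within the cutoff becomes a
centroid, its cluster is removed, and the scan repeats.  Ties in neighbour
count break to the lowest frame index, which makes the procedure fully
deterministic; the original algorithm leaves this open.  Family populations
are fractions of the *stable* frames; families under 1% are dropped and the
survivors are *not* renormalised, so reported populations need not sum to 1.

**Mode classification.**  Visual inspection is replaced by a geometric rule on
each family's centroid pose.  The stack axis runs from the centroid of tetrad
1 (nearest the 5' terminus) to the centroid of the last tetrad.  The
ligand-core centroid is projected onto this axis: beyond the tetrad-1 plane
and inside the axial cylinder (maximum tetrad radial extent + 3 Å) is `top`;
beyond the last tetrad plane is `bottom`; otherwise, within 6 Å of a receptor
heavy atom is `groove`.  A pose with zero receptor contacts is `unbound` and
is refused a mode label.  For duplexes the terminal base pairs are annotated
as two-residue pseudo-tetrads and the same rule applies, so `top` means
stacking on the pair nearest chain A's 5' end.

## Order parameters

Five per-frame observables characterise a binding pathway:

1. Hydrogen bonds per annotated tetrad.  A bond is a donor/hydrogen/acceptor
   triple with donor-acceptor distance ≤ 3.5 Å and donor-H-acceptor angle
   ≥ 120°.  Tetrad counting restricts to the Hoogsteen atoms (donors N1-H1
   and N2-H2x, acceptors O6 and N7) and to inter-guanine triples; a complete
   tetrad presents 8 bonds (two per adjacent pair around the cycle).  General
   donor/acceptor assignment comes from per-residue templates (standard
   nucleic-acid base atoms plus the ligand's amine/ring nitrogens), since no
   universal list exists.
2. The angle between the ligand ring plane and the nearest tetrad plane, from
   total-least-squares plane fits, folded to [0°, 90°] (a plane-plane angle is
   orientation-free; published per-trajectory plots use an unstated
   convention, so the folded angle is this package's reporting surface).
3. Receptor backbone RMSD against the initial structure (fit and measure on
   the backbone), so frame 0 reads exactly 0.
4. Ligand RMSD against the first frame after the receptor-backbone fit, with
   no ligand fit.
5. The centre-to-centre distance R (unweighted heavy-atom centroids of
   receptor and ligand — hydrogens excluded, a choice this package fixes
   because the source analyses leave it open) and the K+-K+ channel-ion
   distance.

**Backbone torsions** follow the standard definitions (α:
O3'(i−1)-P-O5'-C5' … ζ: C3'-O3'-P(i+1)-O5'(i+1); χ: O4'-C1'-N9-C4 for
purines, O4'-C1'-N1-C2 for pyrimidines) in the IUPAC sign convention with
values in (−180°, 180°].  Terminal residues leave α/β (5') or ε/ζ (3')
undefined; they are reported as missing, not errors.  Histograms bin
(−180°, 180°] at 10° by default and accept a trailing frame window.

**Base flips.**  Because flips express themselves across several torsions at
once, the detector uses a single geometric criterion instead: the radial
distance of the base-ring centroid from the stack axis, thresholded at the
groove radius (frame-0 maximum radial extent of the tetrad nucleotides' heavy
atoms) plus 2 Å, smoothed by a centred 5-frame majority filter.  Torsion
histograms remain the reporting surface for characterising individual events.

## MM-GBSA energetics

The binding energy of an ensemble is the end-point estimate

    dE      = E_complex − E_DNA_free − E_lig_free
    dE      = dE_vdw + dE_sur + dE_gbele + dE_conformation
    dE_x    = E_x(complex) − E_x(DNA in complex) − E_x(ligand in complex)
    dE_conf = <E(DNA from complex)> + <E(lig from complex)>
              − <E(DNA free)> − <E(lig free)>

with x ∈ {vdw, sur, gbele}.  GBELE combines vacuum Coulomb and the
generalized-Born polar term; SUR is surface tension × SASA.  Entropy is
deliberately not estimated: the estimate ranks poses of one ligand under the
assumption of comparable entropic terms.  When the "free" trajectories are the
in-complex sub-frames (single-trajectory protocol) the conformation term
cancels identically and the code asserts so.  Ions and any other
non-receptor/non-ligand atoms are stripped before energetics; the channel K+
ions are retained only for the ion-ion order parameter.

Component terms:

- **LJ**: 12-6 over non-excluded pairs, AMBER combination (rmin = rmin_i/2 +
  rmin_j/2, ε geometric mean), 1-4 pairs × 1/2, no cutoff.  Exclusions are
  1-2/1-3 pairs by shortest bond path; 1-4 pairs are at path length 3.
- **Coulomb**: k_e Σ q_i q_j / r_ij with k_e = 332.0637 kcal·Å/(mol·e²),
  1-4 pairs × 1/1.2, no cutoff.
- **GB polar**: the Hawkins-Cramer-Truhlar pairwise-descreening model (the
  classic "GB1" lineage).  Effective radii come from 1/R_i = 1/ρ̃_i − Σ_j I,
  where ρ̃ is the intrinsic (mBondi-convention) radius minus a 0.09 Å offset
  and I is the closed-form descreening integral including the overlapping and
  engulfed-atom cases; radii are floored at 0.1 Å.  The energy is the Still
  expression E = −(k_e/2) Σ_ij (1/ε_in − exp(−0.73 κ f_ij)/ε_out) q_i q_j /
  f_ij with f_ij = sqrt(r² + R_i R_j exp(−r²/4R_iR_j)), self-terms included
  (f_ii = R_i).  κ is the Debye constant computed from physical constants at
  the configured salt concentration (default 0.15 M) and temperature
  (298.15 K); ε_in = 1, ε_out = 78.5.  Note the salt factor *deepens* the
  polar term (exp(−0.73κf) < 1 adds ionic to dielectric screening); a single
  ion's energy is bounded between the salt-free Born value and −k_e q²/2a.
- **SASA**: Shrake-Rupley sphere sampling with a deterministic golden-spiral
  point set (960 points/atom by default; doubling changes totals by < 0.2%),
  probe 1.4 Å.  Atomic radii are the LJ rmin/2 values — one self-consistent
  radius set rather than a second table.  Surface energy = 0.0072 kcal/(mol
  Å²) × SASA.

Averaging uses a configurable frame window (default the last 40% of the
trajectory, since equilibrated-pose windows are system-specific), with means
± standard deviations per component.  `delta_delta_g` ranks modes by mean dE;
the best mode defines ddG = 0, and ties order alphabetically.

## Synthetic data

The generator produces every input with exact ground truth.  Its defaults are
the study conditions the analysis assumes; they are geometric emulations, not
force-field models.

- **Quadruplex**: the 22-mer d(AGGGTTAGGGTTAGGGTTAGGG) folded into three
  stacked G-tetrads (rise 3.4 Å, inter-tetrad twist 30°) with two K+ ions on
  the axis midway between adjacent planes.  The in-plane tetrad arrangement is
  solved once by least squares so the Hoogsteen cycle presents N1···O6 and
  N2···N7 pairs at 2.90 Å with donor-H-acceptor angles near 160° and the
  amine-carbonyl distance held off the 3.5 Å cutoff — each tetrad yields
  exactly 8 detected bonds, by construction and by test.  Topology labels
  (parallel / antiparallel / hybrid) set the strand polarity pattern, i.e.
  which G-run residues occupy which tetrad and the direction the backbone
  propagates; the tetrad hydrogen-bond network is identical across
  topologies.  Loop (TTA) and terminal residues sit just outside the G-core
  at mid-height; their final placement comes from a deterministic rigid-body
  relaxation that removes steric clashes against the core while a soft wall
  keeps each base-ring centroid inside the flip-detection annulus.
- **Duplex**: idealized B-form d([GC]10)2, rise 3.38 Å, twist 36°/bp.  Base
  pairs are generated with the standard-reference-frame Watson-Crick flip, so
  every G·C pair presents its three hydrogen bonds.  Terminal pairs are
  annotated as pseudo-tetrads.
- **Nucleotides**: bases use the standard planar reference-frame coordinates
  with geometrically placed hydrogens; the deoxyribose/phosphate unit is
  built from internal coordinates (C2'-endo-like pucker, χ = −102°, γ = 38°,
  β = 136°, δ = 140°) so canonical-B torsion checks hold exactly for every
  residue.
- **Ligand**: a planar, linearly fused tricyclic core of 13 carbons and one
  ring nitrogen (protonated), an anilino-like arm, and two cationic
  side chains — 46 atoms, net charge exactly +3.  The core is coplanar to
  numerical precision.  Exact substituent chemistry is not reproduced; the
  analysis-relevant features (planar core, core nitrogen facing the channel,
  three arms, +3 charge) are.
- **Parameters**: element-level Lennard-Jones, partial-charge and Born
  parameters with plausible magnitudes, keyed by (residue, atom) name.  The
  LJ radii are deliberately compact (C rmin/2 = 1.45 Å) so that packing at
  the 3.0 Å contact criterion is attractive rather than repulsive; polar
  hydrogens get small LJ radii (0.6 Å) and enlarged Born radii (1.3 Å), the
  usual convention that keeps hydrogen-bonded contacts from reading as
  clashes.
- **Trajectories**: rigid-body ligand paths through scripted segments
  (unbound → approach → top/bottom/groove) with i.i.d. Gaussian positional
  noise of scripted amplitude (0.3 Å in the standard plant) on every atom,
  plus optional base-flip events that displace a designated base radially by
  6 Å over 10-frame ramps lying inside the scripted interval.  Bound poses
  are solved at build time: the ligand slides along the approach direction
  until it is contact-rich, then settles by rigid-body minimisation of the
  receptor-ligand LJ energy under soft walls that pin the pose to the
  intended site.  The unbound point lies on the ray through the DNA centre,
  so R decreases monotonically during approach segments.  Everything is
  deterministic in the script seed; the same seed reproduces files
  byte-for-byte.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: internal receptor dynamics beyond the scripted flips,
correlated thermal motion (noise is isotropic and independent per atom, which
inflates the frame-to-frame variance of stiff terms such as LJ), solvent,
sequence-specific groove geometry, and force-field-quality parameters.  The
acceptance surface is pipeline correctness against planted ground truth, not
crystallographic or thermodynamic fidelity, which is also why absolute
MM-GBSA values for the synthetic systems are not comparable to published
per-mode means (those derive from microsecond explicit-solvent ensembles).

## Numerical choices and degenerate inputs

- Superposition uses the SVD closed form with reflection correction
  (determinant forced to +1); fewer than 3 non-collinear points is an error.
- Plane fits are total-least-squares via SVD; the normal's sign follows the
  5'→3' stack axis when one is supplied.
- A trajectory with zero stable frames is a legitimate outcome: the pipeline
  emits empty mode/energy tables with an explicit flag and exit code 0.
- Pairwise ligand-RMSD matrices over zero selected frames return an empty
  matrix, not an exception.
- Missing torsion atoms mark the angle as missing (NaN) with a logged
  warning; a malformed donor/hydrogen pairing is a hard error.
- File formats: multi-model PDB (fixed width, MODEL/ENDMDL, CONECT records
  carry the bond list), a whitespace-delimited parameter table keyed by
  (residue, atom) name, and a YAML annotation file (roles, tetrads, channel
  ions, ligand-core atoms; 1-based in files, 0-based in memory).  Structure
  round-trips preserve coordinates to the PDB's 10⁻³ Å precision and atom
  order exactly.
- Every pipeline output file is stamped with a 12-hex-digit SHA-256
  fingerprint of the run configuration, and per-frame energy components are
  persisted so every table entry is reproducible from intermediates.

## Problem sizes

The standard planted-recovery experiment uses 2000 frames (10% unbound, 3%
approach, 60% groove, 27% top of the total; 66.7%/33.3% of bound frames) at
0.3 Å noise; per-mode MM-GBSA in the pipeline averages an evenly spaced
subsample (default 20 frames per mode).  These sizes give sub-minute
pipeline runs while leaving the recovery tolerances (±5 population points,
±5 frames on flip boundaries) comfortably non-trivial.
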