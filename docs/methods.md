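# Methods

This note documents the models implemented in `xdc`, their assumptions,
the defaults that matter, and the places where a design choice was
genuinely open.

## Structure model and conventions

Structures are read with gemmi (PDB v3.3 and mmCIF) into a single-model,
single-conformer representation. Alternate locations are resolved at read
time: the highest-occupancy conformer wins, ties broken alphabetically by
altloc id. This makes every downstream geometric quantity a deterministic
function of the file. Hydrogens are dropped by default — the crystal
structures this pipeline targets rarely contain them — with a flag to keep
them. Waters and heteroatoms are kept but flagged, and excluded from
residue-range selections.

Author residue numbering is the coordinate convention throughout; ranges
are 1-based inclusive (a selection `A:10-99` means residues 10 through 99
as the depositors numbered them). Residue pairing between structures is by
author number, never by sequence alignment: the intended comparisons are
between identical constructs, where alignment would only add a failure
mode. Missing residues inside a requested range are skipped pairwise and
reported, not fatal.

Van der Waals radii are assigned per element from a YAML table shipped
with the package (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å, plus common
ions). Overlap volumes depend on this table, so it is explicit and
swappable (`--radii` / `radii=`) rather than hard-coded.

## Superposition, RMSD, rotation angles

Superposition is the Kabsch least-squares fit via SVD, with the reflection
corrected so the rotation is always proper (det = +1). Degenerate inputs
(fewer than three points, collinear clouds) raise rather than return a
garbage frame. The test suite checks the fit against an independent
quaternion-parameterized numerical minimizer and against scipy's
`Rotation.align_vectors`, to 10⁻⁶ Å.

RMSD between structures is reported two ways: the scalar over all selected
atoms, and mean ± SD over per-residue main-chain deviations. The second
form exists because structural papers conventionally quote "x ± y Å" for a
comparison, and a single scalar RMSD cannot carry a spread; we interpret
the ± as the SD over residues. Both numbers are emitted so either
convention can be compared against.

The inter-domain rotation angle between two structures is computed
frame-based: superpose both structures on the reference domain (domain A),
fit the second domain (domain B) of the aligned structure onto domain B of
the template, and report the angle of that fitting rotation,
θ = arccos((tr R − 1)/2) ∈ [0°, 180°]. This is a deliberate simplification
of full dynamic-domain (hinge) analysis: it answers "by how much has
domain B rotated relative to domain A" without attempting hinge-axis
decomposition, which is out of scope.

## Template-guided assembly

`build_hypothetical_assembly` superposes the antigen domain of an
antibody–antigen complex onto each protomer of a dimer template
(main-chain atoms, default residue range configurable; 10–99 is the
EC1 window used in the deposited-structure analyses) and applies each
fitting transform to the whole complex. Invariants enforced and tested:
the template never moves; each placed copy is an exact rigid transform of
the input complex (internal distances preserved to < 10⁻⁶ Å); the
construction is equivariant under rigid motion of the template. A fit RMSD
above a sanity bound (default 5 Å) warns but does not fail — a bad
placement is visible in the report, and hard-failing would hide *why* it
was bad. Which template chain plays protomer A is always explicit input,
never inferred.

## Point mutation

`mutate_residue` swaps one side chain for an idealized replacement built
by NeRF (natural-extension reference frame) from a shipped
internal-coordinate table with one fixed, common rotamer per residue type
(e.g. arginine extended: χ₁ ≈ −67°, χ₂–χ₄ trans). The main chain is
untouched; an existing CB is inherited when both residue types have one.
There is no refinement, repacking or clash relief — determinism is the
point. The overlap change the design screen reports is therefore an
*estimate* whose value lies in its sign and ranking, not in rotamer
realism; a mutation whose effect depends on a specific non-modal rotamer
will be mis-scored, and users screening such cases should inspect the
clash-pair table rather than trust the single number.

## Overlap volume and signed clearance

Overlap between two bodies is defined on van der Waals envelopes (union of
element-radius spheres), not on a solvent-excluded molecular surface. The
volume is integrated on a regular grid anchored at the corner of the
intersection of the two padded bounding boxes — no randomness, repeated
runs are bit-identical. Default spacing is 0.5 Å; reported values state
the spacing used. The discretization error on protein-scale clash volumes
is a few per cent at 0.5 Å and below 1 % at 0.2 Å on the analytic
two-sphere fixtures; volumes comparable to a single grid cell
(≲ spacing³ × 10) are below the method's resolution. The choice of vdW
envelopes over a molecular-surface construction trades a small systematic
difference in absolute volume for full reproducibility from first
principles; comparisons against molecular-surface-derived numbers should
allow for that method dependence.

The signed clearance extends the score into the non-clashing regime for
design work: positive = raw overlap volume (clash); otherwise −(overlap
volume with all radii inflated by a probe, default 1.4 Å), a "how close to
clashing" margin; −0 with a far-apart flag when even the inflated
envelopes are disjoint. Molecular-surface programs can emit negative
"overlap" values for nearly-touching bodies without documenting their
meaning; our negative branch is an explicit, defined stand-in, and reports
flag it as method-divergent. Note the score is monotone in separation
within each regime but jumps from negative to positive at first contact by
construction.

Clash pairs list atom pairs with center distance below the radius sum plus
a configurable slack (default 0.0 Å), sorted by interpenetration depth.

## SASA and BSA

Shrake–Rupley with test points from a deterministic golden-section spiral
(default 960 per atom — single-atom SASA agrees with 4π(r+probe)² to well
under 1 %; the count is the accuracy/cost dial). Probe radius 1.4 Å.
BSA = SASA(A) + SASA(B) − SASA(AB) on the complex's own coordinates; it is
symmetric in its arguments by construction and non-negative up to
point-sampling noise. Cross-checked in tests against biotite's
implementation with identical radii and against analytic two-sphere cases.

## ITC one-site model

Cumulative heat after reaching cell concentrations (Mt, Xt):

    Q = n·Mt·ΔH·V0/2 · [A − √(A² − 4·Xt/(n·Mt))],
    A = 1 + Xt/(n·Mt) + 1/(n·K·Mt)

Per-injection heats are differences of Q with the standard perfusion-cell
displaced-volume correction ΔQᵢ = Qᵢ − Qᵢ₋₁ + (dVᵢ/V0)(Qᵢ + Qᵢ₋₁)/2, and
active concentrations are diluted by (1 − dV/V0) at every injection —
stated explicitly because calorimetry software differs silently on this
bookkeeping, and simulator and fitter must share one convention. A
constant per-injection offset is fitted as a baseline/dilution-heat
nuisance parameter. The first injection is excluded by default (syringe-tip
diffusion), with a flag to keep it.

The fit is trust-region nonlinear least squares on (n, log₁₀K, ΔH,
offset), multi-started from n ∈ {0.5, 1, 1.5, 2} with K seeded from the
transition width of the isotherm (the 25→75 % saturation width in molar
ratio shrinks like 1/c with c = n·K·Mt); ties broken by residual norm,
then by lower n. One-site fits are multimodal at low c-value, hence the
multi-start. Standard errors come from the Jacobian at the optimum.
Default simulated layout: 20 µM cell, 250 µM syringe, 20 × 2 µL
injections into a 200 µL cell at 15 °C — the concentration regime of the
titrations this pipeline models.

## SPR 1:1 kinetics

Pseudo-first-order Langmuir: association
R(t) = Req(1 − e^−(C·kon+koff)t) with Req = C·kon·Rmax/(C·kon+koff);
dissociation R(t) = R_end·e^−koff(t−t_a). One shared (kon, koff, Rmax) is
fitted across all concentrations (global fit); K_D = koff/kon by identity.
No mass-transport or bivalent-analyte terms — the model is a plain global
1:1, which also means avidity effects on dimeric analytes fold into the
apparent constants rather than being modelled. Default simulated series:
1.25–20 nM (dimer-analyte regime) or 6.25–100 nM (monomer regime),
120 s association, 300 s dissociation, 1 Hz, noise in RU.

## Epitope calling

A mutant set marks its mutated positions as epitope for an antibody when
its binding level falls strictly below the threshold fraction of WT
(default 0.20 — "below 20 %", so exactly 0.20 is *not* called). The
epitope is the union over such mutant sets; mutants that knock out more
than one antibody are flagged as possible fold disruptions but still
counted, since excluding them silently would bias calls toward clean
single-antibody epitopes. Lowering the threshold can only shrink an
epitope (tested as a property), and calls are independent of panel row
order.

## Synthetic data

The generators produce every input the pipeline consumes, with ground
truth serialized next to the files. The toy structural system emulates the
blocking-antibody geometry: a ~20-residue idealized helix "antigen" (four
main-chain atoms per residue, written as legal PDB so the reader is
exercised), a single-sphere "antibody" body rigidly attached 8 Å from the
antigen centroid, and a two-protomer template whose protomer separation
sets the placed antibody–antibody distance exactly — so the expected
overlap has a closed-form two-sphere lens value. Close (3 Å) and wide
(60–200 Å) separations give the clash and no-clash regimes. The ITC/SPR
fixtures use the concentration regimes above with planted (n, K, ΔH) and
(kon, koff, Rmax); the epitope panels plant three pairwise-disjoint
epitopes across nine mutant sets, knock-out levels at 5 ± 3 % of WT and
bystanders at 95 ± 5 %.

What the toys do *not* emulate: side-chain packing, the shape complexity
of an scFv, solvent, disorder, or correlated experimental noise. Passing
on them demonstrates the correctness of the geometric and statistical
machinery, not the biology of any particular antibody; the
deposited-structure tests exist precisely to close that gap and require
the archive coordinates to run.

Every generator takes one seed, surfaces it in the output metadata, and is
bit-reproducible.

## Problem sizes and numerical defaults

The self-contained test and acceptance runs use the sizes above (20-seed
to 50-seed simulation studies, 10⁶-sample Monte-Carlo volume oracles,
0.2–0.3 Å grids on sphere fixtures), chosen to pin the statistics well
below the tolerances being asserted while keeping a full run in well under
a minute. Tolerances in tests: 10⁻⁶ Å against superposition oracles, 2 %
against analytic/Monte-Carlo volumes and surfaces at the stated grids and
point counts, 0.05 on median fitted stoichiometry at 1 % heat noise, 10 %
on median fitted K_D at 1 RU noise.

## Known limitations

- Overlap volumes are vdW-envelope, not solvent-excluded-surface, values;
  absolute comparisons across methods carry that definitional offset.
- Single-rotamer mutation without relief can over- or under-estimate a
  designed clash; the screen's ranking is the robust output.
- The frame-based rotation angle does not locate hinges.
- The SPR model omits mass transport; fits to transport-limited data will
  bias kon low.
- Residue pairing by author number requires consistent numbering between
  compared structures.
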