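# xdc — steric compatibility of antibody-decorated cadherin dimers

`xdc` is a pipeline for asking a structural question that comes up when an
antibody blocks a protein–protein assembly without touching its interface:
*can two copies of the antibody–antigen complex coexist on the two
protomers of a dimer?* The motivating system is an scFv against the
cell-adhesive EC1 domain of human P-cadherin, which abolishes the
dimerization intermediate (the X-dimer) not by covering the dimer
interface but because the two antibody molecules, placed on both halves of
the dimer, collide with each other.

The package is aimed at structural biologists and antibody engineers who
want that argument as a reproducible computation instead of a one-off
modelling session: build the hypothetical assembly, score the clash,
screen point mutations that *introduce* a clash, and back the structural
verdict with solution-state binding models.

## What it computes

**Template-guided assembly.** Given an antibody–antigen complex and a
dimer template, the antigen domain of the complex is superposed (Kabsch,
main-chain atoms) onto each protomer of the template; the two placed
copies are exact rigid transforms of the complex, and the template never
moves.

**Overlap volume and signed clearance.** The steric score between the two
placed antibody bodies is the intersection volume of their van der Waals
envelopes, integrated on a deterministic grid:

    V_overlap = #{cells inside both envelopes} × spacing³   (ų)

A positive volume means clash. When the raw envelopes are disjoint, a
*signed clearance* reports −(overlap of probe-inflated envelopes), i.e.
how close the bodies are to clashing; this is the score a design screen
ranks when engineering a clash (e.g. swapping a small serine for a bulky
arginine across the two-fold axis).

**Geometry.** Kabsch superposition with per-residue deviations
(mean ± SD, the "x ± y Å" convention), pairwise main-chain RMSD, and
frame-based inter-domain rotation angles θ = arccos((tr R − 1)/2).

**Surface areas.** Shrake–Rupley SASA on a deterministic spiral point set,
and buried surface area BSA = SASA(A) + SASA(B) − SASA(AB).

**Binding models.** One-site ITC isotherms (closed-form cumulative heat,
per-injection differences with displaced-volume correction) fitted for
(n, K, ΔH) — the stoichiometry n distinguishes one-antibody-per-dimer
(n ≈ 1.5 per antibody in the cell) from equimolar binding (n ≈ 0.7–0.8) —
and 1:1 Langmuir SPR kinetics fitted globally for (kon, koff, Rmax) with
K_D = koff/kon.

**Epitope calling.** From a panel of mutant binding levels relative to
wild type, an antibody's epitope is the union of mutated positions of the
mutants whose binding drops strictly below 20 % of the WT signal.

## Worked example

`xdc demo` generates a toy complex (a helical "antigen" domain with a
rigidly attached single-sphere "antibody" body), two dimer templates —
one with closely spaced protomers, one wide — runs the full pipeline, and
asserts every planted ground truth:

```bash
$ xdc demo --seed 1
{
 "elapsed_s": 0.2,
 "epitopes_recovered": true,
 "itc_n": 1.4999999999999838,
 "overlap_close_A3": 22.784000000000006,
 "overlap_wide_A3": 0.0,
 "spr_KD_nM": 1.0,
 "verdict_close": "clash",
 "verdict_wide": "no-clash"
}
```

Reading the output: on the close template the two placed antibody spheres
overlap by 22.8 ų (the analytic lens value is 22.9 ų — the grid is 0.2 Å)
and the verdict is *clash*; on the wide template the overlap is 0 and the
verdict *no-clash* — the dichotomy that explains why an antibody can kill
one dimeric state and tolerate another. The ITC fit recovers the planted
stoichiometry n = 1.5 (one antibody per locked dimer), the SPR global fit
the planted K_D of 1 nM, and the three planted epitopes are recovered
exactly by the below-20 % rule.

The same stages are available individually (`xdc rmsd`, `xdc rotation`,
`xdc assemble`, `xdc mutate`, `xdc overlap`, `xdc sasa`, `xdc bsa`,
`xdc fit-itc`, `xdc fit-spr`, `xdc call-epitopes`, `xdc simulate ...`),
and as end-to-end analyses with JSON reports:

```bash
xdc run xdimer complex.pdb xdimer.pdb swapdimer.pdb \
    --antigen A:10-99 --protomer-a A:10-99 --protomer-b B:10-99 \
    --antibody H -o report.json
xdc run design complex.pdb swapdimer.pdb --mutation H:77:ARG \
    --antigen A:10-99 --protomer-a A:10-99 --protomer-b B:10-99 --antibody H
```

Every report records all parameters (selections, grid spacing, probe,
radii provenance), so re-running from a report reproduces the numbers
bit-identically.

## Layout

```
src/xdc/structure.py   PDB/mmCIF model, selections, vdW radii (gemmi-backed)
src/xdc/geometry.py    Kabsch, RMSD, domain rotation
src/xdc/assembly.py    template-guided assembly, deterministic mutation
src/xdc/sterics.py     overlap volume, signed clearance, SASA/BSA
src/xdc/binding.py     ITC + SPR simulation and fitting
src/xdc/epitope.py     mutant-panel epitope calling
src/xdc/synthetic.py   seeded fixtures with ground truth
src/xdc/reporting.py   end-to-end analyses, JSON reports
src/xdc/cli.py         the `xdc` command
docs/methods.md        models, assumptions, numerical choices
```
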