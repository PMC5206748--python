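"""Seed-deterministic synthetic fixtures with serialized ground truth.

Everything the pipeline consumes — structures, dimer templates, calorimetry
isotherms, sensorgrams, mutant panels — can be generated here with known
ground truth, so the full analysis runs and is tested without downloading
any deposited coordinates.

The toy structural system emulates the geometry of the antibody-blocking
experiment: an "antigen" domain (a short idealized helix with N/CA/C/O
main-chain atoms, written as legal PDB so the reader is exercised rather
than bypassed) carries a rigidly attached "antibody" body.  A two-protomer
template built from the same antigen controls, through its protomer
separation, whether the two placed antibody bodies clash — a close
template reproduces the clash regime, a wide one the clash-free regime.
The antibody body is a single heavy atom, so the expected overlap of the
two placed copies has a closed-form two-sphere lens value.

What these fixtures do *not* emulate: real side-chain packing, solvent,
crystallographic disorder, or the shape complexity of an scFv.  Passing on
them demonstrates the correctness of the geometry/scoring machinery, not
the biology of any particular antibody.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import binding
from .epitope import MutantPanel
from .geometry import axis_angle_rotation, kabsch_superpose, rmsd_between
from .structure import (
    MAIN_CHAIN,
    Atom,
    Chain,
    Residue,
    Selection,
    Structure,
    load_radii,
    radius_for,
    resolve_selection,
    write_pdb,
)

#: element used for the single-atom antibody body; its table radius is the
#: sphere radius entering the analytic ground-truth overlap.
ANTIBODY_ELEMENT = "K"


@dataclass
class GroundTruth:
    """Planted truth serialized alongside every generated fixture."""

    seed: int | None = None
    transforms: dict = field(default_factory=dict)  # name → {rotation, translation}
    overlap_expected: bool | None = None
    analytic_overlap_volume: float | None = None  # ų, None if not sphere-approximable
    antibody_center_distance: float | None = None  # Å
    antibody_sphere_radius: float | None = None  # Å
    binding_parameters: dict = field(default_factory=dict)
    epitopes: dict = field(default_factory=dict)  # antibody → sorted positions

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Toy structures


def make_toy_domain(
    n_residues: int = 20,
    *,
    chain_id: str = "A",
    shape: str = "helix",
    seed: int = 0,
    start_resseq: int = 1,
) -> Structure:
    """An idealized protein-like domain with N/CA/C/O atoms per residue.

    ``shape='helix'`` traces an ideal α-helix (rise 1.5 Å, 100°/residue,
    radius 2.3 Å); ``shape='cluster'`` draws a seeded globular Gaussian
    blob of residues.  Same seed → bit-identical structure.
    """
    rng = np.random.default_rng(seed)
    if shape == "helix":
        i = np.arange(n_residues + 2)
        theta = np.radians(100.0) * i
        ca = np.column_stack(
            (2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i)
        )
    elif shape == "cluster":
        ca = rng.normal(0.0, 0.35 * n_residues ** (1 / 3) * 3.0, size=(n_residues + 2, 3))
    else:
        raise ValueError(f"unknown shape {shape!r}")
    radii = load_radii()
    chain = Chain(chain_id=chain_id)
    serial = 0
    for k in range(1, n_residues + 1):
        resseq = start_resseq + k - 1
        d = ca[k + 1] - ca[k - 1]
        d = d / max(np.linalg.norm(d), 1e-9)
        radial = ca[k] - ca[k].mean()
        perp = np.cross(d, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(d, [0.0, 1.0, 0.0])
        perp = perp / np.linalg.norm(perp)
        positions = {
            "N": ca[k] - 1.46 * d + 0.4 * perp,
            "CA": ca[k],
            "C": ca[k] + 1.52 * d + 0.4 * perp,
            "O": ca[k] + 1.52 * d + 0.4 * perp + 1.23 * np.cross(d, perp),
        }
        res = Residue(name="ALA", resseq=resseq)
        for name in ("N", "CA", "C", "O"):
            serial += 1
            elem = name[0]
            res.atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=elem,
                    altloc="",
                    occupancy=1.0,
                    coords=positions[name],
                    vdw_radius=radius_for(elem, radii),
                    chain_id=chain_id,
                    resseq=resseq,
                    resname="ALA",
                )
            )
        chain.residues[res.seqid] = res
    st = Structure(entry_id=f"toy-{shape}-{seed}")
    st.chains[chain_id] = chain
    return st


def _attach_antibody_sphere(
    structure: Structure, offset: np.ndarray, chain_id: str = "H"
) -> Structure:
    """Attach a single-atom 'antibody' body at antigen centroid + offset."""
    out = structure.copy()
    center = out.coords().mean(axis=0) + np.asarray(offset, float)
    radii = load_radii()
    serial = max(a.serial for a in out.iter_atoms()) + 1
    res = Residue(name="ABD", resseq=1, is_hetero=True)
    res.atoms.append(
        Atom(
            serial=serial,
            name=ANTIBODY_ELEMENT,
            element=ANTIBODY_ELEMENT,
            altloc="",
            occupancy=1.0,
            coords=center,
            vdw_radius=radius_for(ANTIBODY_ELEMENT, radii),
            chain_id=chain_id,
            resseq=1,
            resname="ABD",
        )
    )
    chain = Chain(chain_id=chain_id)
    chain.residues[res.seqid] = res
    out.chains[chain_id] = chain
    return out


def make_toy_complex_and_template(
    *,
    protomer_separation: float = 3.0,
    antibody_offset: tuple[float, float, float] = (8.0, 0.0, 0.0),
    n_residues: int = 20,
    protomer_rotation_deg: float = 180.0,
    seed: int = 0,
) -> tuple[Structure, Structure, GroundTruth]:
    """Toy antibody–antigen complex plus a two-protomer dimer template.

    The template's protomer A is the antigen in place (chain A); protomer B
    is the antigen rotated by ``protomer_rotation_deg`` about the x axis
    through the antigen centroid and shifted by ``protomer_separation``
    along x (chain B).  With the antibody offset also along x, the two
    placed antibody centers are exactly ``protomer_separation`` apart, so
    the single-sphere antibody body gives the ground truth an analytic
    lens volume for the placed pair.
    """
    antigen = make_toy_domain(n_residues, chain_id="G", seed=seed)
    complex_structure = _attach_antibody_sphere(antigen, antibody_offset, chain_id="H")

    centroid = antigen.coords().mean(axis=0)
    R = axis_angle_rotation(np.array([1.0, 0.0, 0.0]), protomer_rotation_deg)
    t = centroid - R @ centroid + np.array([protomer_separation, 0.0, 0.0])

    template = Structure(entry_id="toy-template")
    protA = antigen.copy()
    chainA = protA.chains["G"]
    chainA.chain_id = "A"
    for res in chainA:
        for a in res.atoms:
            a.chain_id = "A"
    template.chains["A"] = chainA
    protB_struct = antigen.apply_transform(R, t)
    chainB = protB_struct.chains["G"]
    chainB.chain_id = "B"
    for res in chainB:
        for a in res.atoms:
            a.chain_id = "B"
    template.chains["B"] = chainB

    ab_center = complex_structure.chains["H"].residues[(1, "")].atoms[0].coords
    ab_radius = complex_structure.chains["H"].residues[(1, "")].atoms[0].vdw_radius
    centerA = ab_center  # protomer A placement is the identity
    centerB = R @ ab_center + t
    d = float(np.linalg.norm(centerA - centerB))
    from .sterics import sphere_overlap_volume

    lens = sphere_overlap_volume(ab_radius, ab_radius, d)
    truth = GroundTruth(
        seed=seed,
        transforms={
            "protomerA": {"rotation": np.eye(3).tolist(), "translation": [0.0, 0.0, 0.0]},
            "protomerB": {"rotation": R.tolist(), "translation": t.tolist()},
        },
        overlap_expected=lens > 0.0,
        analytic_overlap_volume=float(lens),
        antibody_center_distance=d,
        antibody_sphere_radius=float(ab_radius),
    )
    return complex_structure, template, truth


def perturb_structure(
    structure: Structure, target_rmsd: float, seed: int = 0
) -> Structure:
    """Copy with Gaussian coordinate noise rescaled so that the no-fit
    main-chain RMSD to the original equals ``target_rmsd`` exactly."""
    if target_rmsd < 0:
        raise ValueError("target_rmsd must be >= 0")
    out = structure.copy()
    if target_rmsd == 0:
        return out
    rng = np.random.default_rng(seed)
    atoms = list(out.iter_atoms())
    noise = rng.normal(0.0, 1.0, size=(len(atoms), 3))
    for a, dx in zip(atoms, noise):
        a.coords = a.coords + dx
    sel = Selection(tuple(out.chains), None, MAIN_CHAIN)
    realized = rmsd_between(structure, out, sel, fit=False).rmsd
    scale = target_rmsd / realized
    for a, dx in zip(atoms, noise):
        a.coords = a.coords + (scale - 1.0) * dx
    return out


# ---------------------------------------------------------------------------
# File-level fixture factories (PDB/CSV/YAML + ground_truth.json)


def make_structure_fixture(outdir: str | Path, *, seed: int = 0, close: bool = True) -> GroundTruth:
    """Write complex.pdb, template.pdb and ground_truth.json.

    ``close=True`` yields an overlap-positive ("X-dimer-like") template;
    ``close=False`` a wide, clash-free ("strand-swap-like") one.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sep = 3.0 if close else 60.0
    complex_structure, template, truth = make_toy_complex_and_template(
        protomer_separation=sep, seed=seed
    )
    write_pdb(complex_structure, outdir / "complex.pdb")
    write_pdb(template, outdir / "template.pdb")
    truth.to_json(outdir / "ground_truth.json")
    return truth


def make_itc_fixture(
    outdir: str | Path,
    *,
    n: float = 1.5,
    K: float = 1e8,
    dH: float = -1e4,
    noise_sd: float = 0.0,
    seed: int = 0,
    cell_concentration: float = 20e-6,
    syringe_concentration: float = 250e-6,
) -> GroundTruth:
    """Write exp.yaml + heats.csv + ground_truth.json for a one-site titration.

    Defaults mirror the experimental regime of the mapping study: ~20 μM
    antibody in the cell titrated with ~250 μM cadherin construct.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exp = binding.simulate_itc(
        n,
        K,
        dH,
        cell_concentration=cell_concentration,
        syringe_concentration=syringe_concentration,
        noise_sd=noise_sd,
        seed=seed,
    )
    binding.save_itc(exp, outdir / "exp.yaml", outdir / "heats.csv")
    truth = GroundTruth(
        seed=seed,
        binding_parameters={"n": n, "K_M^-1": K, "dH_cal_mol": dH, "noise_sd_ucal": noise_sd},
    )
    truth.to_json(outdir / "ground_truth.json")
    return truth


def make_spr_fixture(
    outdir: str | Path,
    *,
    kon: float = 1e6,
    koff: float = 1e-3,
    Rmax: float = 100.0,
    concentrations: tuple[float, ...] = (1.25e-9, 2.5e-9, 5e-9, 10e-9, 20e-9),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> GroundTruth:
    """Write sensorgrams.csv + ground_truth.json for a 1:1 kinetic series.

    The default concentration ladder covers 1.25–20 nM (the dimer-analyte
    regime of the affinity comparison); association 120 s, dissociation
    300 s, 1 Hz sampling.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exp = binding.simulate_sensorgram(
        kon, koff, Rmax, list(concentrations), noise_sd=noise_sd, seed=seed
    )
    binding.save_spr(exp, outdir / "sensorgrams.csv")
    truth = GroundTruth(
        seed=seed,
        binding_parameters={
            "kon_M^-1s^-1": kon,
            "koff_s^-1": koff,
            "Rmax_RU": Rmax,
            "KD_M": koff / kon,
            "noise_sd_RU": noise_sd,
        },
    )
    truth.to_json(outdir / "ground_truth.json")
    return truth


def make_epitope_panel(
    *,
    n_antibodies: int = 3,
    n_mutants: int = 9,
    positions_per_mutant: int = 3,
    seed: int = 0,
    hit_level: tuple[float, float] = (0.05, 0.03),
    miss_level: tuple[float, float] = (0.95, 0.05),
) -> tuple[MutantPanel, GroundTruth]:
    """Panel with planted, pairwise-disjoint epitopes.

    Mutant sets are assigned round-robin to antibodies; a set belonging to
    antibody k knocks out binding to k only (level ~ ``hit_level``) and
    leaves the others near WT (~ ``miss_level``).  Defaults: 9 mutant sets
    × 3 antibodies, knock-out at 5 ± 3 % of WT, bystanders at 95 ± 5 %.
    """
    rng = np.random.default_rng(seed)
    import pandas as pd

    antibodies = [f"Ab{k + 1}" for k in range(n_antibodies)]
    positions: dict[str, list[int]] = {"WT": []}
    true_epitopes: dict[str, set[int]] = {ab: set() for ab in antibodies}
    rows = {"WT": {ab: 1.0 for ab in antibodies}}
    next_pos = 10
    for m in range(n_mutants):
        mid = f"M{m + 1}"
        pos = list(range(next_pos, next_pos + positions_per_mutant))
        next_pos += positions_per_mutant + 1
        positions[mid] = pos
        owner = antibodies[m % n_antibodies]
        true_epitopes[owner].update(pos)
        row = {}
        for ab in antibodies:
            mu, sd = hit_level if ab == owner else miss_level
            row[ab] = float(max(rng.normal(mu, sd), 0.0))
        rows[mid] = row
    levels = pd.DataFrame.from_dict(rows, orient="index")[antibodies]
    panel = MutantPanel(levels, positions)
    truth = GroundTruth(
        seed=seed, epitopes={ab: sorted(s) for ab, s in true_epitopes.items()}
    )
    return panel, truth


def make_epitope_fixture(outdir: str | Path, *, seed: int = 0, **kwargs) -> GroundTruth:
    """Write panel.csv + ground_truth.json for a planted-epitope panel."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel, truth = make_epitope_panel(seed=seed, **kwargs)
    df = panel.levels.copy()
    df.columns = [f"level_{c}" for c in df.columns]
    df.insert(0, "positions", [";".join(map(str, panel.positions[m])) for m in df.index])
    df.index.name = "mutant_id"
    df.to_csv(outdir / "panel.csv")
    truth.to_json(outdir / "ground_truth.json")
    return truth
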