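"""Template-guided assembly building and deterministic point mutation.

The central construction here mirrors how crystallographers probe whether
an antibody is compatible with a dimeric state of its antigen: take the
experimentally determined antibody–antigen complex, superpose its antigen
domain onto each protomer of a dimer template, and ask whether the two
placed antibody copies can coexist.  The template never moves; each placed
copy is an exact rigid transform of the input complex, so all internal
geometry is preserved and any inter-copy clash is attributable to the
dimer architecture alone.

``mutate_residue`` swaps a side chain for an idealized single-rotamer
replacement (NeRF construction from a shipped internal-coordinate table)
without touching the main chain and without any refinement — deterministic
by design, since the downstream overlap score is an estimate whose value
lies in its sign and magnitude, not in rotamer realism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

from .errors import PairingError, XdcError
from .geometry import SuperpositionResult, kabsch_superpose, pair_atoms_by_residue
from .structure import (
    MAIN_CHAIN,
    Atom,
    Selection,
    Structure,
    load_radii,
    radius_for,
    resolve_selection,
)

DEFAULT_FIT_SANITY_RMSD = 5.0  # Å; above this the placement is suspect


@dataclass
class AssemblyModel:
    """A dimer template plus the complex placed onto each protomer."""

    template: Structure
    placed_copies: tuple[Structure, Structure]
    mappings: tuple[Selection, Selection]
    fit_rmsds: tuple[float, float]

    @property
    def copyA(self) -> Structure:
        return self.placed_copies[0]

    @property
    def copyB(self) -> Structure:
        return self.placed_copies[1]


def build_hypothetical_assembly(
    complex_structure: Structure,
    template: Structure,
    protomerA: Selection,
    protomerB: Selection,
    antigen: Selection,
    *,
    atom_names: frozenset[str] = MAIN_CHAIN,
    fit_sanity_rmsd: float = DEFAULT_FIT_SANITY_RMSD,
) -> AssemblyModel:
    """Place the complex onto both protomers of a dimer template.

    The antigen selection of the complex is superposed (main-chain atoms by
    default) onto each protomer selection of the template; the resulting
    rigid transform is applied to the *whole* complex.  Fit RMSDs above
    ``fit_sanity_rmsd`` raise a warning, not an error.
    """
    antigen = _with_atoms(antigen, atom_names)
    placed: list[Structure] = []
    rmsds: list[float] = []
    for prot in (protomerA, protomerB):
        prot_sel = _with_atoms(prot, atom_names)
        try:
            mob, ref = pair_atoms_by_residue(
                resolve_selection(complex_structure, antigen),
                resolve_selection(template, prot_sel),
            )
        except PairingError as exc:
            raise PairingError(f"antigen/protomer pairing failed for {prot}: {exc}")
        n_res = len({a.residue_id for a in mob})
        if n_res < 3:
            raise PairingError(
                f"antigen and protomer {prot} share only {n_res} residues (need >= 3)"
            )
        fit: SuperpositionResult = kabsch_superpose(mob, ref)
        if fit.rmsd > fit_sanity_rmsd:
            warnings.warn(
                f"placement fit RMSD {fit.rmsd:.2f} Å exceeds sanity bound "
                f"{fit_sanity_rmsd} Å for protomer {prot}",
                stacklevel=2,
            )
        placed.append(
            complex_structure.apply_transform(
                fit.transform.rotation, fit.transform.translation
            )
        )
        rmsds.append(fit.rmsd)
    return AssemblyModel(
        template=template,
        placed_copies=(placed[0], placed[1]),
        mappings=(protomerA, protomerB),
        fit_rmsds=(rmsds[0], rmsds[1]),
    )


# ---------------------------------------------------------------------------
# Point mutation


def _load_rotamers() -> dict[str, list]:
    text = resources.files("xdc.data").joinpath("rotamers.yaml").read_text()
    return yaml.safe_load(text)


_ROTAMERS: dict[str, list] | None = None

_BACKBONE = {"N", "CA", "C", "O", "OXT"}


def supported_residues() -> set[str]:
    global _ROTAMERS
    if _ROTAMERS is None:
        _ROTAMERS = _load_rotamers()
    return set(_ROTAMERS)


def nerf_place(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, dihedral: float
) -> np.ndarray:
    """Place atom D from reference atoms A, B, C (natural-extension frame).

    ``angle`` = ∠(B, C, D) and ``dihedral`` = torsion(A, B, C, D), degrees.
    """
    ang = np.radians(angle)
    tor = np.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-10:
        raise XdcError("collinear reference atoms in NeRF placement")
    n /= norm
    m = np.cross(n, bc)
    # sign convention chosen so the reproduced torsion(A,B,C,D) follows IUPAC
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            -bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _element_of(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def mutate_residue(
    structure: Structure,
    chain_id: str,
    resseq: int,
    new_residue: str,
    *,
    icode: str = "",
    radii: Mapping[str, float] | None = None,
) -> Structure:
    """Return a copy with one residue's side chain replaced.

    The main chain (N, CA, C, O) is untouched; the existing CB is inherited
    when both residues have one, and the remaining side-chain atoms are
    built from the idealized internal-coordinate table.  Rotamer choice is
    fixed (one entry per residue type), so the operation is deterministic.
    """
    new_residue = new_residue.upper()
    if new_residue not in supported_residues():
        raise XdcError(
            f"unsupported target residue {new_residue!r}; "
            f"supported: {sorted(supported_residues())}"
        )
    out = structure.copy()
    try:
        res = out.chains[chain_id].residues[(resseq, icode)]
    except KeyError:
        raise XdcError(f"residue {chain_id}:{resseq}{icode} not found")
    for name in ("N", "CA", "C"):
        if not res.has_atom(name):
            raise XdcError(
                f"residue {chain_id}:{resseq} lacks backbone atom {name}; cannot mutate"
            )
    radii = radii if radii is not None else load_radii()
    recipe = _ROTAMERS[new_residue]
    recipe_names = {row[0] for row in recipe}
    keep = [a for a in res.atoms if a.name in _BACKBONE]
    cb = next((a for a in res.atoms if a.name == "CB"), None)
    if cb is not None and "CB" in recipe_names:
        keep.append(cb)
    placed: dict[str, np.ndarray] = {a.name: a.coords for a in keep}
    max_serial = max((a.serial for a in structure.iter_atoms()), default=0)
    new_atoms: list[Atom] = []
    for row in recipe:
        name, ra, rb, rc, bond, angle, dihedral = row
        if name in placed:
            continue
        for ref in (ra, rb, rc):
            if ref not in placed:
                raise XdcError(
                    f"cannot place {name}: reference atom {ref} missing in "
                    f"{chain_id}:{resseq}"
                )
        pos = nerf_place(placed[ra], placed[rb], placed[rc], bond, angle, dihedral)
        placed[name] = pos
        elem = _element_of(name)
        max_serial += 1
        new_atoms.append(
            Atom(
                serial=max_serial,
                name=name,
                element=elem,
                altloc="",
                occupancy=1.0,
                coords=pos,
                vdw_radius=radius_for(elem, radii),
                chain_id=chain_id,
                resseq=resseq,
                icode=icode,
                resname=new_residue,
            )
        )
    res.name = new_residue
    for a in keep:
        a.resname = new_residue
    res.atoms = keep + new_atoms
    return out


def _with_atoms(sel: Selection, names: frozenset[str]) -> Selection:
    if sel.atom_names is not None:
        return sel
    return Selection(sel.chain_ids, sel.residue_range, names)
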