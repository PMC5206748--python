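"""Rigid-body superposition, RMSD and relative domain rotation.

The superposition is the classic Kabsch least-squares fit (SVD with a
reflection correction so the returned rotation is always proper).  RMSD
between two structures is reported both as the scalar over all selected
atoms and as mean ± SD over per-residue main-chain deviations, since
structural papers conventionally quote the latter as "x ± y Å".

The relative rotation between two domains is the angle of the composed
rotation R_B · R_A⁻¹ between the fitting transforms of the two domains
after a common reference superposition — a frame-based reading of the
domain-rotation angle usually attributed to hinge-analysis tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import IllPosedError, PairingError
from .structure import (
    MAIN_CHAIN,
    Atom,
    ResolvedSelection,
    Selection,
    Structure,
    atom_name_sort_key,
    resolve_selection,
)


@dataclass
class RigidTransform:
    """Proper rigid motion x → R·x + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, float)
        self.translation = np.asarray(self.translation, float)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise IllPosedError("rotation matrix is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise IllPosedError("improper rotation (det = -1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def angle_degrees(self) -> float:
        """Rotation angle of R in [0°, 180°]."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_atoms: int
    #: per-residue mean main-chain deviation after the fit
    per_residue_deviation: list[tuple[tuple[str, int, str], float]] = field(default_factory=list)

    @property
    def per_residue_mean_sd(self) -> tuple[float, float]:
        """Mean ± SD over per-residue deviations (the "x ± y Å" convention)."""
        if not self.per_residue_deviation:
            return (self.rmsd, 0.0)
        d = np.array([v for _, v in self.per_residue_deviation])
        return (float(d.mean()), float(d.std(ddof=0)))


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Least-squares proper rotation + translation mapping mobile → reference."""
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise IllPosedError("point sets must be equal-length (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise IllPosedError(f"need at least 3 points, got {n}")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    # degenerate (collinear / coincident) clouds leave the fit underdetermined
    if n > 3 and S[1] < 1e-10 * max(S[0], 1e-300):
        raise IllPosedError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    return RigidTransform(R, t)


def kabsch_superpose(
    mobile_atoms: list[Atom] | np.ndarray,
    reference_atoms: list[Atom] | np.ndarray,
) -> SuperpositionResult:
    """Superpose correspondence-ordered atom (or point) lists.

    Returns the optimal transform, the post-fit scalar RMSD, and — when the
    inputs are atoms — per-residue mean deviations.
    """
    mob_atoms = mobile_atoms if _is_atoms(mobile_atoms) else None
    P = _coords(mobile_atoms)
    Q = _coords(reference_atoms)
    if len(P) != len(Q):
        raise IllPosedError(f"length mismatch: {len(P)} vs {len(Q)}")
    tr = kabsch(P, Q)
    moved = tr.apply(P)
    dev = np.linalg.norm(moved - Q, axis=1)
    rmsd = float(np.sqrt(np.mean(dev**2)))
    per_res: list[tuple[tuple[str, int, str], float]] = []
    if mob_atoms is not None:
        acc: dict[tuple[str, int, str], list[float]] = {}
        for atom, d in zip(mob_atoms, dev):
            acc.setdefault(atom.residue_id, []).append(float(d))
        per_res = [(rid, float(np.mean(v))) for rid, v in acc.items()]
    return SuperpositionResult(tr, rmsd, len(P), per_res)


def pair_atoms_by_residue(
    selA: ResolvedSelection, selB: ResolvedSelection
) -> tuple[list[Atom], list[Atom]]:
    """Pair atoms by (residue number, insertion code, atom name) per chain.

    Chains are paired positionally (first selected chain of A with first of
    B, ...), residues by author number; anything unmatched is dropped
    pairwise.
    """
    chainsA = _group_by_chain(selA)
    chainsB = _group_by_chain(selB)
    if len(chainsA) != len(chainsB):
        raise PairingError(
            f"selection spans {len(chainsA)} vs {len(chainsB)} chains; cannot pair"
        )
    outA: list[Atom] = []
    outB: list[Atom] = []
    for ca, cb in zip(chainsA.values(), chainsB.values()):
        keysA = {(a.resseq, a.icode, a.name): a for a in ca}
        keysB = {(a.resseq, a.icode, a.name): a for a in cb}
        shared = sorted(
            keysA.keys() & keysB.keys(),
            key=lambda k: (k[0], k[1], atom_name_sort_key(k[2])),
        )
        outA.extend(keysA[k] for k in shared)
        outB.extend(keysB[k] for k in shared)
    return outA, outB


def rmsd_between(
    structA: Structure,
    structB: Structure,
    selectionA: Selection,
    selectionB: Selection | None = None,
    *,
    fit: bool = True,
) -> SuperpositionResult:
    """RMSD between two structures over a selection (main-chain by default).

    With ``fit=True`` (default) the structures are first superposed on the
    selection; with ``fit=False`` the deviation is measured in place.
    Residues are paired by author number; gaps are dropped pairwise.
    """
    selectionB = selectionB if selectionB is not None else selectionA
    atomsA, atomsB = pair_atoms_by_residue(
        resolve_selection(structA, selectionA), resolve_selection(structB, selectionB)
    )
    n_res = len({a.residue_id for a in atomsA})
    if n_res < 3:
        raise PairingError(f"only {n_res} paired residues; need >= 3")
    if fit:
        return kabsch_superpose(atomsA, atomsB)
    P, Q = _coords(atomsA), _coords(atomsB)
    dev = np.linalg.norm(P - Q, axis=1)
    rmsd = float(np.sqrt(np.mean(dev**2)))
    acc: dict[tuple[str, int, str], list[float]] = {}
    for atom, d in zip(atomsA, dev):
        acc.setdefault(atom.residue_id, []).append(float(d))
    per_res = [(rid, float(np.mean(v))) for rid, v in acc.items()]
    return SuperpositionResult(RigidTransform.identity(), rmsd, len(P), per_res)


def relative_rotation_angle(
    transformA: RigidTransform, transformB: RigidTransform
) -> float:
    """Angle (degrees, in [0, 180]) of R_B · R_A⁻¹."""
    return transformB.compose(transformA.inverse()).angle_degrees()


def domain_rotation(
    structure: Structure,
    template: Structure,
    domainA: Selection,
    domainB: Selection,
) -> float:
    """Relative rotation of domain B between two structures, after aligning
    both on domain A.

    Procedure: superpose ``structure`` onto ``template`` using domain A
    (the reference domain); then fit domain B of the aligned structure onto
    domain B of the template; the angle of that fitting rotation is the
    inter-domain rotation.
    """
    a1, a2 = pair_atoms_by_residue(
        resolve_selection(structure, domainA), resolve_selection(template, domainA)
    )
    refFit = kabsch_superpose(a1, a2)
    moved = structure.apply_transform(
        refFit.transform.rotation, refFit.transform.translation
    )
    b1, b2 = pair_atoms_by_residue(
        resolve_selection(moved, domainB), resolve_selection(template, domainB)
    )
    bFit = kabsch_superpose(b1, b2)
    return bFit.transform.angle_degrees()


def axis_angle_rotation(axis: np.ndarray, degrees: float) -> np.ndarray:
    """Rotation matrix about ``axis`` by ``degrees`` (Rodrigues)."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    th = np.radians(degrees)
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def _is_atoms(x) -> bool:
    return len(x) > 0 and isinstance(x[0], Atom)


def _coords(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return np.asarray(x, float)
    if isinstance(x, ResolvedSelection):
        return x.coords()
    return np.array([a.coords for a in x], float).reshape(-1, 3)


def _group_by_chain(sel: ResolvedSelection) -> dict[str, list[Atom]]:
    out: dict[str, list[Atom]] = {}
    for a in sel.atoms:
        out.setdefault(a.chain_id, []).append(a)
    return out
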