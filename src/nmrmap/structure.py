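"""Rigid-body superposition (Kabsch) and RMSD between coordinate models."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .io_formats import StructureModel


@dataclass
class Superposition:
    rotation: np.ndarray      # 3x3 proper rotation applied to model a
    translation: np.ndarray   # applied after rotation
    rmsd: float
    n_atoms: int
    residues: list[int]


def _paired_coords(a: StructureModel, b: StructureModel,
                   residues: Optional[range], atom_name: str):
    ca = dict(a.coords(residues, atom_name))
    cb = dict(b.coords(residues, atom_name))
    common = sorted(set(ca) & set(cb))
    A = np.array([ca[n] for n in common], dtype=float)
    B = np.array([cb[n] for n in common], dtype=float)
    return A, B, common


def kabsch(P: np.ndarray, Q: np.ndarray):
    """Optimal proper rotation/translation mapping P onto Q, plus the RMSD.

    Closed-form least squares via SVD of the covariance matrix, with the
    determinant sign corrected so the rotation is proper (no reflection).
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValidationError("coordinate sets must be matching (n, 3) arrays")
    if len(P) < 3:
        raise ValidationError(f"need >= 3 paired atoms, got {len(P)}")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = (P0 @ R.T) - Q0
    rmsd = float(np.sqrt((diff * diff).sum() / len(P)))
    return R, t, rmsd


def kabsch_superpose(a: StructureModel, b: StructureModel,
                     residues: Optional[range] = None,
                     atom_name: str = "CA") -> Superposition:
    """Superpose the selected atoms of model ``a`` onto model ``b``.

    Only residues present in both models (with the named atom) are paired,
    ordered by residue number. The RMSD is reported on the same selection the
    fit used.
    """
    A, B, common = _paired_coords(a, b, residues, atom_name)
    if len(common) < 3:
        raise ValidationError(
            f"only {len(common)} common {atom_name} atoms in the selection"
        )
    R, t, rmsd = kabsch(A, B)
    return Superposition(rotation=R, translation=t, rmsd=rmsd,
                         n_atoms=len(common), residues=common)


def ensemble_rmsd(ensemble: Sequence[StructureModel], reference: StructureModel,
                  residues: Optional[range] = None, atom_name: str = "CA"):
    """Superpose each ensemble member independently on the reference.

    Returns ``(per_model_rmsds, mean, sd)``; sd is 0 for a single model.
    """
    if not ensemble:
        raise ValidationError("empty ensemble")
    rmsds = [kabsch_superpose(m, reference, residues, atom_name).rmsd
             for m in ensemble]
    arr = np.asarray(rmsds)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return rmsds, float(arr.mean()), sd


def rmsd_grid(models_a: Sequence[StructureModel], models_b: Sequence[StructureModel],
              model_indices: Sequence[tuple[int, int]],
              residue_ranges: Sequence[tuple[int, int]],
              atom_name: str = "CA") -> dict:
    """RMSD over a grid of model-pair and residue-range choices.

    Useful when the representative model and superposition range of a
    published comparison are unstated: every (model_a, model_b, start, end)
    combination is evaluated and returned as
    {(ia, ib, start, end): rmsd}. Index pairs are 0-based into the lists.
    """
    out = {}
    for ia, ib in model_indices:
        for start, end in residue_ranges:
            sup = kabsch_superpose(models_a[ia], models_b[ib],
                                   residues=range(start, end + 1),
                                   atom_name=atom_name)
            out[(ia, ib, start, end)] = sup.rmsd
    return out
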