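"""File formats: curve/window CSVs, multi-page TIFF image sets, PDB structures.

Conventions
-----------
* force curves: CSV with columns ``indentation_nm,force_nN`` (one file per
  curve) or long format with a leading ``curve_id`` column;
* FRET image sets: multi-page TIFF in page order donor, acceptor, FRET;
  ROI masks as single-page integer label TIFF;
* umbrella windows: long CSV with columns ``center_nm,k_kJ_mol_nm2,sample_nm``;
* PMF profiles: CSV ``xi_nm,free_energy_kJ_mol,error_kJ_mol`` plus a JSON
  summary with the well depth and convergence diagnostics;
* structures: PDB via biotite.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .contacts import Residue, Structure, three_letter
from .fret import FretImageSet
from .nanoindentation import ForceCurve
from .pmf import BindingEnergy, PmfProfile, UmbrellaWindow

__all__ = [
    "write_force_curve_csv",
    "read_force_curve_csv",
    "read_force_curves_long",
    "write_imageset_tiff",
    "read_imageset_tiff",
    "write_mask_tiff",
    "read_mask_tiff",
    "write_umbrella_csv",
    "read_umbrella_csv",
    "write_profile_csv",
    "write_pmf_summary_json",
    "read_structure_pdb",
    "write_structure_pdb",
]


# -- force curves -----------------------------------------------------------


def write_force_curve_csv(curve: ForceCurve, path) -> None:
    pd.DataFrame(
        {"indentation_nm": curve.indentation_nm, "force_nN": curve.force_nn}
    ).to_csv(path, index=False)


def read_force_curve_csv(path, **curve_kwargs) -> ForceCurve:
    frame = pd.read_csv(path)
    return ForceCurve(
        indentation_nm=frame["indentation_nm"].to_numpy(),
        force_nn=frame["force_nN"].to_numpy(),
        curve_id=Path(path).stem,
        **curve_kwargs,
    )


def read_force_curves_long(path, **curve_kwargs) -> list[ForceCurve]:
    """Read a long-format CSV with columns ``curve_id,indentation_nm,force_nN``."""
    frame = pd.read_csv(path)
    curves = []
    for curve_id, sub in frame.groupby("curve_id", sort=False):
        curves.append(
            ForceCurve(
                indentation_nm=sub["indentation_nm"].to_numpy(),
                force_nn=sub["force_nN"].to_numpy(),
                curve_id=str(curve_id),
                **curve_kwargs,
            )
        )
    return curves


# -- FRET images ------------------------------------------------------------


def write_imageset_tiff(images: FretImageSet, path) -> None:
    stack = np.stack([images.donor, images.acceptor, images.fret]).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack")


def read_imageset_tiff(path) -> FretImageSet:
    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] != 3:
        raise ValueError("expected a 3-page TIFF (donor, acceptor, FRET)")
    return FretImageSet(donor=stack[0], acceptor=stack[1], fret=stack[2])


def write_mask_tiff(mask: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(mask).astype(np.int32))


def read_mask_tiff(path) -> np.ndarray:
    return tifffile.imread(path).astype(int)


# -- umbrella windows -------------------------------------------------------


def write_umbrella_csv(windows: list[UmbrellaWindow], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "center_nm": w.center_nm,
                "k_kJ_mol_nm2": w.force_constant,
                "sample_nm": w.samples_nm,
            }
        )
        for w in windows
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_umbrella_csv(path) -> list[UmbrellaWindow]:
    frame = pd.read_csv(path)
    windows = []
    for (center, k), sub in frame.groupby(["center_nm", "k_kJ_mol_nm2"], sort=True):
        windows.append(
            UmbrellaWindow(
                center_nm=float(center),
                force_constant=float(k),
                samples_nm=sub["sample_nm"].to_numpy(),
            )
        )
    return windows


# -- PMF profiles -----------------------------------------------------------


def write_profile_csv(profile: PmfProfile, path) -> None:
    error = (
        profile.error_kj_mol
        if profile.error_kj_mol is not None
        else np.full_like(profile.grid_nm, np.nan)
    )
    pd.DataFrame(
        {
            "xi_nm": profile.grid_nm,
            "free_energy_kJ_mol": profile.free_energy_kj_mol,
            "error_kJ_mol": error,
        }
    ).to_csv(path, index=False)


def write_pmf_summary_json(
    profile: PmfProfile, energy: BindingEnergy, path
) -> None:
    summary = {
        "delta_g_kJ_mol": energy.delta_g_kj_mol,
        "delta_g_error_kJ_mol": energy.error_kj_mol,
        "xi_min_nm": energy.xi_min_nm,
        "minimum_at_edge": energy.minimum_at_edge,
        "converged": profile.converged,
        "n_iterations": profile.n_iterations,
        "reference": profile.reference,
    }
    Path(path).write_text(json.dumps(summary, indent=2))


# -- structures -------------------------------------------------------------


def read_structure_pdb(path) -> Structure:
    """Read the first model of a PDB file into a residue-level Structure."""
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    atoms = pdb_file.get_structure(model=1)
    residues = []
    # group atoms by (chain, residue id) preserving file order
    seen: dict[tuple[str, int], int] = {}
    order: list[tuple[str, int]] = []
    coords: dict[tuple[str, int], list] = {}
    names: dict[tuple[str, int], str] = {}
    for i in range(atoms.array_length()):
        key = (str(atoms.chain_id[i]), int(atoms.res_id[i]))
        if key not in seen:
            seen[key] = len(order)
            order.append(key)
            coords[key] = []
            names[key] = str(atoms.res_name[i])
        coords[key].append(atoms.coord[i])
    for key in order:
        chain, res_id = key
        residues.append(
            Residue(
                chain=chain,
                index=res_id,
                name=names[key],
                atoms=np.array(coords[key]),
            )
        )
    return Structure(residues=tuple(residues))


def write_structure_pdb(structure: Structure, path) -> None:
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n_atoms = sum(r.atoms.shape[0] for r in structure.residues)
    array = struc.AtomArray(n_atoms)
    idx = 0
    for residue in structure.residues:
        for a in range(residue.atoms.shape[0]):
            array.chain_id[idx] = residue.chain
            array.res_id[idx] = residue.index
            array.res_name[idx] = three_letter(residue.name)
            array.atom_name[idx] = "CA" if a == 0 else f"X{a}"
            array.element[idx] = "C"
            array.coord[idx] = residue.atoms[a]
            idx += 1
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(array)
    pdb_file.write(str(path))
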