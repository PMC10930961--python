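"""Residue-level contact analysis of peptide-domain complexes.

Contacts are registered between residue centers of geometry (COG, the
unweighted mean of a residue's atom coordinates) using a distance cutoff,
6.5 A by default with an inclusive boundary.  Peptide residues are labelled
backwards from the C-terminus (``C-1`` is the last residue), the convention
used for PDZ-binding motifs whose recognition is anchored at the free
carboxylate.  The module also provides hydropathy classification on the
PARCH scale (0-10, values < 1 hydrophobic) and the water-contact counting
primitive used by annealing-based hydropathy protocols (water oxygens within
0.315 nm of any residue atom).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "Residue",
    "Structure",
    "ContactMap",
    "residue_cog",
    "contact_map",
    "summarize_contact_table",
    "classify_hydropathy",
    "count_water_contacts",
    "one_letter",
]

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}

NM_PER_ANGSTROM = 0.1


def one_letter(name: str) -> str:
    """One-letter code for a residue name (three-letter or already one-letter)."""
    name = name.upper()
    if len(name) == 1:
        return name
    return _THREE_TO_ONE.get(name, "X")


def three_letter(code: str) -> str:
    code = code.upper()
    if len(code) == 3:
        return code
    return _ONE_TO_THREE.get(code, "UNK")


@dataclass(frozen=True)
class Residue:
    """One residue: chain label, sequence index, name, atom coordinates (A)."""

    chain: str
    index: int
    name: str
    atoms: np.ndarray

    def __post_init__(self) -> None:
        atoms = np.atleast_2d(np.asarray(self.atoms, dtype=float))
        object.__setattr__(self, "atoms", atoms)
        if atoms.ndim != 2 or atoms.shape[1] != 3 or atoms.shape[0] < 1:
            raise ValueError("atoms must be an (n, 3) array with n >= 1")
        if not np.all(np.isfinite(atoms)):
            raise ValueError("atom coordinates must be finite")

    @property
    def label(self) -> str:
        """Compact label, e.g. ``L321``."""
        return f"{one_letter(self.name)}{self.index}"


@dataclass(frozen=True)
class Structure:
    """Ordered list of residues with coordinates in Angstrom."""

    residues: tuple[Residue, ...]

    def __post_init__(self) -> None:
        residues = tuple(self.residues)
        object.__setattr__(self, "residues", residues)
        if len(residues) < 1:
            raise ValueError("structure needs >= 1 residue")

    def __len__(self) -> int:
        return len(self.residues)

    def cogs(self) -> np.ndarray:
        """(n_residues, 3) array of residue centers of geometry."""
        return np.array([residue_cog(r) for r in self.residues])

    @classmethod
    def from_pdb(cls, path) -> "Structure":
        """Read a structure from a PDB file (first model)."""
        from .io import read_structure_pdb

        return read_structure_pdb(path)

    def to_pdb(self, path) -> None:
        from .io import write_structure_pdb

        write_structure_pdb(self, path)


@dataclass(frozen=True)
class ContactMap:
    """Peptide-position -> domain-residue-label contact listing.

    ``pairs`` maps the backwards peptide position label (``C-1`` ... ``C-n``)
    to the set of contacting domain residue labels; ``index_pairs`` holds the
    same contacts as 0-based (peptide_index, domain_index) tuples.
    """

    pairs: dict[str, frozenset[str]]
    index_pairs: frozenset[tuple[int, int]]
    cutoff_angstrom: float

    def __post_init__(self) -> None:
        if self.cutoff_angstrom <= 0:
            raise ValueError("cutoff must be > 0")


def residue_cog(residue: Residue) -> np.ndarray:
    """Center of geometry: unweighted mean of the residue's atom coordinates."""
    return residue.atoms.mean(axis=0)


def peptide_position_label(index: int, n_peptide: int) -> str:
    """Backwards-from-C-terminus label for 0-based residue ``index``."""
    return f"C-{n_peptide - index}"


def contact_map(
    peptide: Structure,
    domain: Structure,
    cutoff_angstrom: float = 6.5,
) -> ContactMap:
    """All peptide-domain residue pairs with COG distance <= cutoff.

    Neighbor search uses a KD-tree over domain COGs; the boundary is
    inclusive, so a pair at exactly the cutoff distance is a contact.
    """
    if cutoff_angstrom <= 0:
        raise ValueError("cutoff must be > 0")
    pep_cogs = peptide.cogs()
    dom_cogs = domain.cogs()
    tree = cKDTree(dom_cogs)
    n_pep = len(peptide)
    neighbor_lists = tree.query_ball_point(pep_cogs, r=cutoff_angstrom)

    pairs: dict[str, frozenset[str]] = {}
    index_pairs: set[tuple[int, int]] = set()
    for p_idx in range(n_pep):
        hits = sorted(neighbor_lists[p_idx])
        label = peptide_position_label(p_idx, n_pep)
        pairs[label] = frozenset(domain.residues[d].label for d in hits)
        index_pairs.update((p_idx, d) for d in hits)
    return ContactMap(
        pairs=pairs,
        index_pairs=frozenset(index_pairs),
        cutoff_angstrom=float(cutoff_angstrom),
    )


def summarize_contact_table(
    cmap_or_pairs,
    n_peptide: int,
    peptide_residues: list[str] | None = None,
    parch: dict[str, float] | None = None,
) -> dict:
    """Contacting-residue count and a tidy per-position contact listing.

    Accepts a :class:`ContactMap` or a plain ``{position label: iterable of
    domain labels}`` mapping (e.g. a transcribed published table).  Positions
    without contacts are listed with ``"-"``.

    Returns ``{"contacting_residues": int, "table": DataFrame}`` where the
    table has columns ``position, residue, parch, contacts``.
    """
    pairs = cmap_or_pairs.pairs if isinstance(cmap_or_pairs, ContactMap) else cmap_or_pairs
    referenced = [int(key.split("-")[1]) for key in pairs]
    if referenced and n_peptide < max(referenced):
        raise ValueError("n_peptide smaller than largest referenced position")

    rows = []
    n_contacting = 0
    for k in range(1, n_peptide + 1):
        label = f"C-{k}"
        contacts = sorted(pairs.get(label, ()))
        if contacts:
            n_contacting += 1
        residue = ""
        if peptide_residues is not None:
            # peptide_residues is N->C ordered; position C-k is the k-th from the end
            residue = one_letter(peptide_residues[n_peptide - k])
        rows.append(
            {
                "position": label,
                "residue": residue,
                "parch": parch.get(label, np.nan) if parch else np.nan,
                "contacts": " ".join(contacts) if contacts else "-",
            }
        )
    table = pd.DataFrame(rows, columns=["position", "residue", "parch", "contacts"])
    return {"contacting_residues": n_contacting, "table": table}


def classify_hydropathy(
    parch: dict[str, float], threshold: float = 1.0
) -> dict[str, str]:
    """Classify residues on the PARCH scale: value < threshold -> hydrophobic.

    The boundary is strict, so a value exactly at the threshold is
    hydrophilic.  Values must lie on the 0-10 scale.
    """
    out = {}
    for key, value in parch.items():
        if not (0.0 <= value <= 10.0):
            raise ValueError(f"parch value for {key} outside [0, 10]: {value}")
        out[key] = "hydrophobic" if value < threshold else "hydrophilic"
    return out


def count_water_contacts(
    structure: Structure,
    water_oxygens_angstrom: np.ndarray,
    cutoff_nm: float = 0.315,
    mode: str = "atom",
) -> np.ndarray:
    """Number of water oxygens contacting each residue.

    A water contacts a residue when it lies within ``cutoff_nm`` (converted
    internally to Angstrom) of any residue atom (``mode='atom'``, the
    minimum-atom-distance criterion) or of the residue COG
    (``mode='cog'``).  Returns an int array over residues in order.
    """
    waters = np.asarray(water_oxygens_angstrom, dtype=float)
    if waters.size == 0:
        return np.zeros(len(structure), dtype=int)
    waters = np.atleast_2d(waters)
    if not np.all(np.isfinite(waters)):
        raise ValueError("water coordinates must be finite")
    cutoff_angstrom = cutoff_nm / NM_PER_ANGSTROM  # single unit-conversion site
    tree = cKDTree(waters)
    counts = np.zeros(len(structure), dtype=int)
    for i, residue in enumerate(structure.residues):
        if mode == "atom":
            hits: set[int] = set()
            for hit_list in tree.query_ball_point(residue.atoms, r=cutoff_angstrom):
                hits.update(hit_list)
            counts[i] = len(hits)
        elif mode == "cog":
            counts[i] = len(tree.query_ball_point(residue_cog(residue), r=cutoff_angstrom))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return counts
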