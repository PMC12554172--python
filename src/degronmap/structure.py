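"""Static-structure contact detection by van der Waals overlap.

Given an all-atom structure of a two-chain (or multi-chain) complex, two
atoms on different chains are in contact when their van der Waals overlap

    overlap = r_i + r_j - d_ij

meets a threshold (default -0.40 Å, i.e. surfaces may be separated by up
to 0.4 Å and still count).  Residue pairs are reported whenever any of
their atom pairs qualifies.  Static-structure math is in ångströms, the
native unit of PDB/mmCIF files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

#: Van der Waals radii in Å (Bondi 1964; metals from Mantina et al. 2009).
VDW_RADII_A: dict[str, float] = {
    "H": 1.10,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "B": 1.92,
    "NA": 2.27,
    "MG": 1.73,
    "K": 2.75,
    "CA": 2.31,
    "MN": 2.05,
    "FE": 2.04,
    "CO": 2.00,
    "NI": 1.97,
    "CU": 1.96,
    "ZN": 1.39,
}

#: Overlap (Å) above which two atoms are reported as clashing.
CLASH_OVERLAP_A = 0.6


class MissingRadiusError(KeyError):
    """No van der Waals radius is available for an element."""


@dataclass
class StaticStructure:
    """All-atom structure: elements, coordinates (Å), chain and residue ids."""

    elements: np.ndarray
    coords: np.ndarray
    chains: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray

    def __post_init__(self) -> None:
        self.elements = np.asarray([str(e).upper() for e in self.elements])
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        n = len(self.elements)
        for name in ("chains", "resids", "resnames"):
            arr = np.asarray(getattr(self, name))
            setattr(self, name, arr)
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n} atoms")

    @classmethod
    def from_atom_array(cls, atoms) -> "StaticStructure":
        """Build from a ``biotite.structure.AtomArray``."""
        return cls(
            elements=atoms.element,
            coords=atoms.coord,
            chains=atoms.chain_id,
            resids=atoms.res_id,
            resnames=atoms.res_name,
        )

    @classmethod
    def from_file(cls, path: str) -> "StaticStructure":
        """Read a PDB or mmCIF file (first model)."""
        path = str(path)
        if path.endswith((".cif", ".mmcif", ".pdbx")):
            from biotite.structure.io.pdbx import CIFFile, get_structure

            atoms = get_structure(CIFFile.read(path), model=1)
        else:
            from biotite.structure.io.pdb import PDBFile

            atoms = PDBFile.read(path).get_structure(model=1)
        return cls.from_atom_array(atoms)

    def radii(self, table: dict[str, float] | None = None) -> np.ndarray:
        table = table or VDW_RADII_A
        missing = sorted({e for e in self.elements if e not in table})
        if missing:
            raise MissingRadiusError(f"no van der Waals radius for element(s): {missing}")
        return np.array([table[e] for e in self.elements])


def static_contacts(
    structure: StaticStructure,
    overlap_cutoff: float = -0.40,
    radii: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Cross-chain residue contacts by van der Waals overlap.

    Atoms i, j on different chains are in contact iff
    ``r_i + r_j - d_ij >= overlap_cutoff`` (Å).  Returns one row per
    contacting residue pair with columns ``chain_a, resid_a, resname_a,
    chain_b, resid_b, resname_b, max_overlap_A, n_atom_pairs``, sorted by
    descending maximum overlap.  Atom pairs whose overlap exceeds
    ``0.6 Å`` additionally trigger a clash warning.
    """
    r = structure.radii(radii)
    max_search = 2.0 * r.max() - min(overlap_cutoff, 0.0)
    tree = cKDTree(structure.coords)
    pairs = tree.query_pairs(max_search, output_type="ndarray")
    if len(pairs):
        cross = structure.chains[pairs[:, 0]] != structure.chains[pairs[:, 1]]
        pairs = pairs[cross]
    records: dict[tuple, dict] = {}
    n_clashes = 0
    for i, j in pairs:
        d = float(np.linalg.norm(structure.coords[i] - structure.coords[j]))
        overlap = r[i] + r[j] - d
        if overlap < overlap_cutoff:
            continue
        if overlap >= CLASH_OVERLAP_A:
            n_clashes += 1
        a, b = (i, j) if str(structure.chains[i]) <= str(structure.chains[j]) else (j, i)
        key = (
            str(structure.chains[a]),
            int(structure.resids[a]),
            str(structure.chains[b]),
            int(structure.resids[b]),
        )
        rec = records.setdefault(
            key,
            {
                "chain_a": key[0],
                "resid_a": key[1],
                "resname_a": str(structure.resnames[a]),
                "chain_b": key[2],
                "resid_b": key[3],
                "resname_b": str(structure.resnames[b]),
                "max_overlap_A": -np.inf,
                "n_atom_pairs": 0,
            },
        )
        rec["max_overlap_A"] = max(rec["max_overlap_A"], overlap)
        rec["n_atom_pairs"] += 1
    if n_clashes:
        warnings.warn(
            f"{n_clashes} atom pair(s) overlap by >= {CLASH_OVERLAP_A} Å (steric clash)",
            UserWarning,
            stacklevel=2,
        )
    columns = [
        "chain_a",
        "resid_a",
        "resname_a",
        "chain_b",
        "resid_b",
        "resname_b",
        "max_overlap_A",
        "n_atom_pairs",
    ]
    if not records:
        return pd.DataFrame(columns=columns)
    return (
        pd.DataFrame(list(records.values()), columns=columns)
        .sort_values("max_overlap_A", ascending=False)
        .reset_index(drop=True)
    )
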