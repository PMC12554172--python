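"""Plain-text readers and writers for the pipeline's datasets.

TSV is the contract of record for tabular data (array signals, isotherms,
chase courses, contact maps, RMSD series); trajectories additionally round-
trip through a plain per-frame coordinate table and multi-model PDB (one
MODEL per frame, chain A = receptor, chain B = peptide, one Cα per
residue).  PDB files are in Å; the in-memory trajectory unit is nm.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .arrays import ArrayDesign, NormalizedMatrix, SubstitutionArrayDataset
from .binding import BindingIsotherm
from .trajectory import ContactMap, RMSDSeries, TrajectoryEnsemble
from .turnover import DecayCourse

NM_PER_ANGSTROM = 0.1
ANGSTROM_PER_NM = 10.0


# ---------------------------------------------------------------- arrays


def write_array_tsv(dataset: SubstitutionArrayDataset, path: str) -> None:
    dataset.signals.to_csv(path, sep="\t", index=False)


def read_array_tsv(path: str, design: ArrayDesign) -> SubstitutionArrayDataset:
    df = pd.read_csv(path, sep="\t")
    for col in ("position", "trunc_last"):
        if col in df:
            df[col] = df[col].astype("Int64")
    return SubstitutionArrayDataset(design=design, signals=df)


def write_normalized_matrix(matrix: NormalizedMatrix, prefix: str) -> None:
    """Write ``<prefix>_mean.tsv``, ``<prefix>_sd.tsv`` and ``<prefix>_n.tsv``."""
    matrix.mean_pct.to_csv(f"{prefix}_mean.tsv", sep="\t")
    matrix.sd_pct.to_csv(f"{prefix}_sd.tsv", sep="\t")
    matrix.n.to_csv(f"{prefix}_n.tsv", sep="\t")


# ---------------------------------------------------------- trajectories


def write_coordinate_table(ensemble: TrajectoryEnsemble, path: str) -> None:
    """Per-frame coordinate table: pose, trial, frame, chain, residue_number, x/y/z in nm."""
    frames = []
    for (pose, trial), traj in sorted(ensemble.coords.items()):
        n_frames, n_atoms, _ = traj.shape
        frames.append(
            pd.DataFrame(
                {
                    "pose": np.repeat(pose, n_frames * n_atoms),
                    "trial": np.repeat(trial, n_frames * n_atoms),
                    "frame": np.repeat(np.arange(n_frames), n_atoms),
                    "chain": np.tile(ensemble.chains, n_frames),
                    "residue_number": np.tile(ensemble.resids, n_frames),
                    "x_nm": traj[:, :, 0].ravel(),
                    "y_nm": traj[:, :, 1].ravel(),
                    "z_nm": traj[:, :, 2].ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_coordinate_table(path: str, frame_spacing_ps: float = 10.0) -> TrajectoryEnsemble:
    df = pd.read_csv(path, sep="\t")
    first = df[(df["pose"] == df["pose"].iloc[0]) & (df["trial"] == df["trial"].iloc[0])]
    first_frame = first[first["frame"] == first["frame"].iloc[0]]
    chains = first_frame["chain"].to_numpy()
    resids = first_frame["residue_number"].to_numpy()
    n_atoms = len(resids)
    coords = {}
    for (pose, trial), grp in df.groupby(["pose", "trial"]):
        grp = grp.sort_values(["frame"], kind="stable")
        n_frames = grp["frame"].nunique()
        xyz = grp[["x_nm", "y_nm", "z_nm"]].to_numpy().reshape(n_frames, n_atoms, 3)
        coords[(int(pose), int(trial))] = xyz
    return TrajectoryEnsemble(
        coords=coords, chains=chains, resids=resids, frame_spacing_ps=frame_spacing_ps
    )


def write_multimodel_pdb(
    ensemble: TrajectoryEnsemble, pose: int, trial: int, path: str
) -> None:
    """Write one trial as a multi-model PDB, one MODEL per frame, Cα only."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    traj = ensemble.coords[(pose, trial)]
    n_atoms = traj.shape[1]
    template = struc.AtomArray(n_atoms)
    template.chain_id = ensemble.chains.astype("U4")
    template.res_id = ensemble.resids.astype(int)
    template.res_name = np.full(n_atoms, "GLY", dtype="U5")
    template.atom_name = np.full(n_atoms, "CA", dtype="U6")
    template.element = np.full(n_atoms, "C", dtype="U2")
    stack = struc.AtomArrayStack(traj.shape[0], n_atoms)
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = traj * ANGSTROM_PER_NM
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(path)


def read_multimodel_pdb(
    path: str, pose: int = 1, trial: int = 0, frame_spacing_ps: float = 10.0
) -> TrajectoryEnsemble:
    """Read a multi-model Cα PDB back into a single-trial ensemble (nm)."""
    from biotite.structure.io.pdb import PDBFile

    stack = PDBFile.read(path).get_structure()
    return TrajectoryEnsemble(
        coords={(pose, trial): stack.coord * NM_PER_ANGSTROM},
        chains=np.asarray(stack.chain_id),
        resids=np.asarray(stack.res_id),
        frame_spacing_ps=frame_spacing_ps,
    )


def write_contact_map(cmap: ContactMap, path: str) -> None:
    cmap.freq.to_csv(path, sep="\t")


def write_rmsd_series(series_list: list[RMSDSeries], path: str) -> None:
    rows = []
    for s in series_list:
        for i, v in enumerate(s.values):
            rows.append(
                {
                    "pose": s.pose,
                    "trial": s.trial,
                    "selection": s.selection,
                    "frame": i,
                    "time_ps": i * s.frame_spacing_ps,
                    "rmsd_nm": v,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------ isotherm / chase


def write_isotherm_tsv(isotherm: BindingIsotherm, path: str) -> None:
    isotherm.data.to_csv(path, sep="\t", index=False)


def read_isotherm_tsv(path: str) -> BindingIsotherm:
    return BindingIsotherm(pd.read_csv(path, sep="\t"))


def write_chase_tsv(course: DecayCourse, path: str) -> None:
    course.data.to_csv(path, sep="\t", index=False)


def read_chase_tsv(path: str, condition: str = "") -> DecayCourse:
    return DecayCourse(pd.read_csv(path, sep="\t"), condition=condition)
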