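"""Plain-text I/O for assay and trajectory data.

All tabular formats are tab-separated text with a comment-prefixed (#)
metadata block, readable by any spreadsheet or pandas.  Trajectories can
also be exchanged as multi-frame PDB (MODEL/ENDMDL records) with the sulfur
roles encoded in residue names: GSF = free GS- sulfur, CYX = active-site
cysteine sulfur, GSM = glutathione-moiety sulfur.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import ProgressCurve, AssayConditions
from .dalziel import RateGrid
from .pka import ResidualActivityProfile
from .rogfp2 import Well, PlateRun
from .trajectory import GsTrajectory, TrajectoryReplicate, DensityGrid

__all__ = [
    "write_progress_curve", "read_progress_curve",
    "write_rate_grid", "read_rate_grid",
    "write_pka_profile", "read_pka_profile",
    "write_plate_run", "read_plate_run",
    "write_trajectory_tsv", "read_trajectory_tsv",
    "write_trajectory_pdb", "read_trajectory_pdb",
    "write_density_grid", "read_density_grid",
]


def _write_with_meta(path, df: pd.DataFrame, meta: dict) -> None:
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_with_meta(path):
    meta = {}
    lines = Path(path).read_text().splitlines(keepends=True)
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            body_start = i + 1
            stripped = line.lstrip("#").strip()
            if ":" in stripped:
                key, _, value = stripped.partition(":")
                meta[key.strip()] = value.strip()
        else:
            break
    df = pd.read_csv(_io.StringIO("".join(lines[body_start:])), sep="\t")
    return df, meta


# -- progress curves --------------------------------------------------------

def write_progress_curve(path, curve: ProgressCurve) -> None:
    c = curve.meta
    meta = {
        "enzyme0_M": c.enzyme0, "gssr0_M": c.gssr0, "gsh0_M": c.gsh0,
        "nadph0_M": c.nadph0, "epsilon_nadph": c.epsilon_nadph,
        "path_length_cm": c.path_length_cm, "baseline_s": c.baseline_s,
        "temperature_C": c.temperature_C, "gr_activity": c.gr_activity,
        "nadph_exhausted": curve.nadph_exhausted,
    }
    df = pd.DataFrame({"time_s": curve.time, "a340": curve.a340})
    _write_with_meta(path, df, meta)


def read_progress_curve(path) -> ProgressCurve:
    df, meta = _read_with_meta(path)
    cond = AssayConditions(
        enzyme0=float(meta["enzyme0_M"]), gssr0=float(meta["gssr0_M"]),
        gsh0=float(meta["gsh0_M"]), nadph0=float(meta["nadph0_M"]),
        epsilon_nadph=float(meta["epsilon_nadph"]),
        path_length_cm=float(meta["path_length_cm"]),
        baseline_s=float(meta["baseline_s"]),
        temperature_C=float(meta.get("temperature_C", 25.0)),
        gr_activity=float(meta.get("gr_activity", 1.0)),
    )
    return ProgressCurve(
        time=df["time_s"].to_numpy(), a340=df["a340"].to_numpy(), meta=cond,
        nadph_exhausted=meta.get("nadph_exhausted", "False") == "True",
    )


# -- rate grids --------------------------------------------------------------

def write_rate_grid(path, grid: RateGrid) -> None:
    df = grid.data.copy()
    df.insert(0, "variant", grid.variant_label)
    df.insert(1, "substrate_label", grid.substrate_label)
    _write_with_meta(path, df, dict(grid.meta))


def read_rate_grid(path) -> RateGrid:
    df, meta = _read_with_meta(path)
    variant = str(df["variant"].iloc[0]) if "variant" in df else "WT"
    substrate = (str(df["substrate_label"].iloc[0])
                 if "substrate_label" in df else "GSSCys")
    data = df.drop(columns=[c for c in ("variant", "substrate_label")
                            if c in df.columns])
    return RateGrid(data, substrate_label=substrate, variant_label=variant,
                    meta=meta)


# -- pKa profiles -------------------------------------------------------------

def write_pka_profile(path, profile: ResidualActivityProfile) -> None:
    df = pd.DataFrame({
        "ph": profile.ph, "residual_pct": profile.residual_pct,
        "replicate": profile.replicate, "variant": profile.variant_label,
    })
    _write_with_meta(path, df, dict(profile.meta))


def read_pka_profile(path) -> ResidualActivityProfile:
    df, meta = _read_with_meta(path)
    return ResidualActivityProfile(
        ph=df["ph"].to_numpy(), residual_pct=df["residual_pct"].to_numpy(),
        variant_label=str(df["variant"].iloc[0]) if "variant" in df else "WT",
        replicate=int(df["replicate"].iloc[0]) if "replicate" in df else 0,
        meta=meta,
    )


# -- plate runs ---------------------------------------------------------------

def write_plate_run(path, run: PlateRun) -> None:
    rows = []
    for w in run.wells:
        for t, a, b in zip(w.time, w.i400, w.i480):
            rows.append({
                "well": w.well_id, "role": w.role, "construct": w.construct_label,
                "dose_M": w.dose_h2o2, "replicate": w.replicate,
                "time_s": t, "i400": a, "i480": b,
            })
    _write_with_meta(path, pd.DataFrame(rows), dict(run.meta))


def read_plate_run(path) -> PlateRun:
    df, meta = _read_with_meta(path)
    wells = []
    for (well_id, role), sub in df.groupby(["well", "role"], sort=False):
        sub = sub.sort_values("time_s")
        wells.append(Well(
            well_id=str(well_id), role=str(role),
            time=sub["time_s"].to_numpy(), i400=sub["i400"].to_numpy(),
            i480=sub["i480"].to_numpy(), dose_h2o2=float(sub["dose_M"].iloc[0]),
            construct_label=str(sub["construct"].iloc[0]),
            replicate=int(sub["replicate"].iloc[0]),
        ))
    return PlateRun(wells, meta=meta)


# -- trajectories -------------------------------------------------------------

_ROLE_GS = "gs_s"
_ROLE_CYS = "cys_s"
_ROLE_MOIETY = "moiety_s"


def write_trajectory_tsv(path, traj: GsTrajectory) -> None:
    rows = []
    for rep in traj.replicates:
        for f in range(rep.n_frames):
            for role, xyz, mol in (
                (_ROLE_CYS, rep.disulfide_xyz[f, 0], 0),
                (_ROLE_MOIETY, rep.disulfide_xyz[f, 1], 0),
            ):
                rows.append((rep.replicate, f, mol, role, *xyz))
            for g in range(rep.n_gs):
                rows.append((rep.replicate, f, g + 1, _ROLE_GS,
                             *rep.gs_xyz[f, g]))
    df = pd.DataFrame(rows, columns=[
        "replicate", "frame", "molecule_id", "atom_role", "x", "y", "z",
    ])
    meta = dict(traj.meta)
    meta["frame_interval_ps"] = traj.replicates[0].frame_interval_ps
    _write_with_meta(path, df, meta)


def read_trajectory_tsv(path) -> GsTrajectory:
    df, meta = _read_with_meta(path)
    interval = float(meta.pop("frame_interval_ps", 20.0))
    reps = []
    for rep_id, sub in df.groupby("replicate"):
        n_frames = int(sub["frame"].max()) + 1
        gs_ids = sorted(sub.loc[sub["atom_role"] == _ROLE_GS,
                                "molecule_id"].unique())
        gs_xyz = np.empty((n_frames, len(gs_ids), 3))
        dis = np.empty((n_frames, 2, 3))
        cys = sub[sub["atom_role"] == _ROLE_CYS].sort_values("frame")
        moi = sub[sub["atom_role"] == _ROLE_MOIETY].sort_values("frame")
        dis[:, 0] = cys[["x", "y", "z"]].to_numpy()
        dis[:, 1] = moi[["x", "y", "z"]].to_numpy()
        gs = sub[sub["atom_role"] == _ROLE_GS]
        for j, gid in enumerate(gs_ids):
            block = gs[gs["molecule_id"] == gid].sort_values("frame")
            gs_xyz[:, j] = block[["x", "y", "z"]].to_numpy()
        reps.append(TrajectoryReplicate(
            gs_xyz=gs_xyz, disulfide_xyz=dis, frame_interval_ps=interval,
            replicate=int(rep_id),
        ))
    return GsTrajectory(reps, meta=meta)


def write_trajectory_pdb(path, traj: GsTrajectory) -> None:
    """Multi-frame PDB (one replicate's frames concatenated as MODELs).

    Replicates are concatenated in order; the replicate boundaries are
    recorded in a REMARK-free companion convention: all frames of replicate
    r precede those of replicate r+1.  Residue names encode the roles (CYX,
    GSM, GSF).
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_gs = traj.replicates[0].n_gs
    n_atoms = 2 + n_gs
    template = struc.AtomArray(n_atoms)
    template.atom_name = np.array(["SG"] * n_atoms)
    template.element = np.array(["S"] * n_atoms)
    template.res_name = np.array(["CYX", "GSM"] + ["GSF"] * n_gs)
    template.res_id = np.arange(1, n_atoms + 1)
    template.chain_id = np.array(["A"] * n_atoms)
    frames = []
    for rep in traj.replicates:
        coords = np.concatenate(
            [rep.disulfide_xyz, rep.gs_xyz], axis=1
        )  # (n_frames, n_atoms, 3)
        frames.append(coords)
    all_coords = np.concatenate(frames, axis=0)
    stack = struc.from_template(template, all_coords.astype(np.float32))
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_trajectory_pdb(path, n_replicates: int = 1,
                        frame_interval_ps: float = 20.0) -> GsTrajectory:
    """Read a multi-frame PDB written by ``write_trajectory_pdb``.

    Frames are split evenly into ``n_replicates`` consecutive blocks.
    """
    import biotite.structure as struc  # noqa: F401
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()
    res_names = stack.res_name
    cys_idx = np.nonzero(res_names == "CYX")[0]
    moi_idx = np.nonzero(res_names == "GSM")[0]
    gs_idx = np.nonzero(res_names == "GSF")[0]
    if len(cys_idx) != 1 or len(moi_idx) != 1:
        raise ValueError("PDB must contain exactly one CYX and one GSM sulfur")
    coords = stack.coord  # (n_models, n_atoms, 3)
    n_total = coords.shape[0]
    if n_total % n_replicates:
        raise ValueError("frame count not divisible by n_replicates")
    per = n_total // n_replicates
    reps = []
    for r in range(n_replicates):
        block = coords[r * per:(r + 1) * per]
        dis = np.stack([block[:, cys_idx[0]], block[:, moi_idx[0]]], axis=1)
        reps.append(TrajectoryReplicate(
            gs_xyz=block[:, gs_idx].astype(float),
            disulfide_xyz=dis.astype(float),
            frame_interval_ps=frame_interval_ps, replicate=r,
        ))
    return GsTrajectory(reps)


# -- density grids ------------------------------------------------------------

def write_density_grid(path, grid: DensityGrid) -> None:
    with open(path, "w") as fh:
        fh.write(f"# origin: {grid.origin[0]} {grid.origin[1]} {grid.origin[2]}\n")
        fh.write(f"# spacing: {grid.spacing}\n")
        fh.write(f"# dims: {grid.counts.shape[0]} {grid.counts.shape[1]} "
                 f"{grid.counts.shape[2]}\n")
        fh.write(f"# n_samples: {grid.n_samples}\n")
        flat = grid.counts.reshape(-1)
        nz = np.nonzero(flat)[0]
        fh.write("index\tcount\n")
        for i in nz:
            fh.write(f"{i}\t{flat[i]:g}\n")


def read_density_grid(path) -> DensityGrid:
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line.lstrip("#").strip().partition(":")
                meta[key.strip()] = value.strip()
            elif line.strip() and not line.startswith("index"):
                i, c = line.split("\t")
                rows.append((int(i), float(c)))
    dims = tuple(int(x) for x in meta["dims"].split())
    counts = np.zeros(int(np.prod(dims)))
    for i, c in rows:
        counts[i] = c
    return DensityGrid(
        origin=np.array([float(x) for x in meta["origin"].split()]),
        spacing=float(meta["spacing"]),
        counts=counts.reshape(dims),
        n_samples=int(meta["n_samples"]),
    )
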