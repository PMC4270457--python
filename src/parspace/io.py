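"""Readers and writers for the package's tabular and image formats.

Canonical tabular format is tab-separated text with a header row and
units in the column names; values are written with 6 significant digits
so every writer/reader pair round-trips at that precision.  Intensity
stacks are exchanged either as multi-page TIFF (one page per z section)
or as long-format TSV (cell, channel, z, x_um, intensity).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .localization import IntensityStack
from .trajectories import MSDCurve, SubdiffusionFit, TrajectorySet

__all__ = [
    "write_tracks", "read_tracks",
    "write_msd", "read_msd",
    "write_fit", "write_table",
    "write_stack_tsv", "read_stack_tsv",
    "write_stack_tiff", "read_stack_tiff",
    "write_kymograph", "write_config",
]

_FLOAT_FMT = "%.6g"


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_tracks(tracks: TrajectorySet, path) -> None:
    write_table(tracks.records, path)


def read_tracks(path, frame_interval: float | None = None,
                pixel: float = 0.066) -> TrajectorySet:
    df = pd.read_csv(path, sep="\t")
    if frame_interval is None:
        # smallest positive time difference within any focus
        diffs = (df.sort_values("t_s").groupby(["cell", "focus"])["t_s"]
                 .diff().dropna())
        frame_interval = float(diffs[diffs > 0].min()) if len(diffs) else 1.0
    return TrajectorySet(df, frame_interval=frame_interval, pixel=pixel)


def write_msd(msd: MSDCurve, path) -> None:
    write_table(pd.DataFrame({
        "lag_s": msd.lags, "msd_um2": msd.msd,
        "sem_um2": msd.sem, "n": msd.n,
    }), path)


def read_msd(path) -> MSDCurve:
    df = pd.read_csv(path, sep="\t")
    return MSDCurve(df["lag_s"].to_numpy(), df["msd_um2"].to_numpy(),
                    df["sem_um2"].to_numpy(), df["n"].to_numpy())


def write_fit(fit: SubdiffusionFit, path) -> None:
    write_table(pd.DataFrame([{
        "alpha": fit.alpha, "alpha_se": fit.alpha_se,
        "D_um2_s_alpha": fit.D, "D_se": fit.D_se,
        "beta_um2": fit.beta, "beta_se": fit.beta_se,
        "r_squared": fit.r_squared,
    }]), path)


def write_stack_tsv(stack: IntensityStack, path, cell: str = "cell0",
                    channel: str = "ch0") -> None:
    z_idx, x_idx = np.meshgrid(np.arange(stack.n_planes),
                               np.arange(len(stack.x)), indexing="ij")
    write_table(pd.DataFrame({
        "cell": cell, "channel": channel, "z": z_idx.ravel(),
        "x_um": stack.x[x_idx.ravel()], "intensity": stack.I.ravel(),
    }), path)


def read_stack_tsv(path, cell: str | None = None, channel: str | None = None,
                   dz: float = 0.1) -> IntensityStack:
    df = pd.read_csv(path, sep="\t")
    if cell is not None:
        df = df[df["cell"] == cell]
    if channel is not None:
        df = df[df["channel"] == channel]
    if df.empty:
        raise ValueError("no rows match the requested cell/channel")
    piv = df.pivot_table(index="z", columns="x_um", values="intensity")
    return IntensityStack(x=piv.columns.to_numpy(dtype=float),
                          I=piv.to_numpy(), dz=dz)


def write_stack_tiff(stack: IntensityStack, path) -> None:
    import tifffile
    tifffile.imwrite(path, stack.I.astype(np.float32))


def read_stack_tiff(path, dx: float = 0.0625, dz: float = 0.1) -> IntensityStack:
    """Read an I(z, x) grid stored as a (possibly multi-page) TIFF."""
    import tifffile
    data = np.asarray(tifffile.imread(path), dtype=float)
    if data.ndim == 1:
        data = data[None]
    if data.ndim != 2:
        # multi-page stacks of 1-row pages collapse to (n_z, n_x)
        data = data.reshape(data.shape[0], -1)
    return IntensityStack(x=np.arange(data.shape[1]) * dx, I=data, dz=dz)


def write_kymograph(times, values, dx, path, species: str = "parA") -> None:
    """Long-format kymograph table (t_s, site, species, count)."""
    rows = []
    values = np.asarray(values)
    for k, t in enumerate(times):
        row = values[k]
        nz = np.flatnonzero(row)
        for i in nz:
            rows.append((t, int(i), species, int(row[i])))
    write_table(pd.DataFrame(rows, columns=["t_s", "site", "species", "count"]),
                path)


def write_gradient_profile(solution, path, n_points: int = 500) -> None:
    """Steady-state ParA-ATP profile as two-column (x_um, A_per_um) text."""
    x = np.linspace(0.0, solution.params.L, n_points)
    write_table(pd.DataFrame({"x_um": x, "A_per_um": solution.profile(x)}),
                path)


def write_gradient_fluxes(solution, path) -> None:
    """Per-plasmid arrival fluxes as (plasmid, J_minus, J_plus) text."""
    n = len(solution.fluxes)
    write_table(pd.DataFrame({
        "plasmid": np.arange(1, n + 1),
        "J_minus": solution.fluxes[:, 0],
        "J_plus": solution.fluxes[:, 1],
    }), path)


def write_config(config: dict, path) -> None:
    """Write the fully resolved run configuration next to the outputs."""
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        return str(o)

    Path(path).write_text(json.dumps(config, indent=2, default=default,
                                     sort_keys=True) + "\n")
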