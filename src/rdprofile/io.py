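"""Readers and writers for image series, profiles and fit reports.

Image series travel either as a multi-page TIFF (one page per time point,
pixels raster-ordered row-major) with a JSON sidecar holding times, layout
and the noisy flag, or as a single NPZ container (lossless float64
round-trip), or as a long-format CSV.  Reports are JSON; profile traces are
CSV.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import tifffile

from .errors import FormatError
from .observation import ImageSeries, PixelLayout
from .profiling import LocalApproximation, ProfileResult

_SIDECAR_SUFFIX = ".json"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + _SIDECAR_SUFFIX)


def write_image_series(series: ImageSeries, path) -> Path:
    """Write an image series; the format is chosen by the file suffix
    (.npz, .tif/.tiff with JSON sidecar, or .csv).  Returns the path."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".npz":
        np.savez(
            path,
            times=series.times,
            values=series.values,
            rows=series.layout.rows,
            cols=series.layout.cols,
            extent=series.layout.extent,
            noisy=series.noisy,
        )
    elif suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, series.as_images().astype(np.float64))
        meta = {
            "times": series.times.tolist(),
            "rows": series.layout.rows,
            "cols": series.layout.cols,
            "extent": series.layout.extent,
            "noisy": series.noisy,
        }
        _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    elif suffix == ".csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time", "pixel_row", "pixel_col", "value",
                        f"# rows={series.layout.rows} cols={series.layout.cols} "
                        f"extent={series.layout.extent!r} noisy={int(series.noisy)}"])
            imgs = series.as_images()
            for k, t in enumerate(series.times):
                for r in range(series.layout.rows):
                    for c in range(series.layout.cols):
                        w.writerow([repr(float(t)), r, c, repr(float(imgs[k, r, c]))])
    else:
        raise FormatError(f"unsupported image-series format {suffix!r}")
    return path


def _build_series(times, values, rows, cols, extent, noisy) -> ImageSeries:
    layout = PixelLayout(rows=int(rows), cols=int(cols), extent=float(extent))
    return ImageSeries(times=np.asarray(times, dtype=float),
                       values=np.asarray(values, dtype=float).reshape(len(times), layout.M),
                       layout=layout, noisy=bool(noisy))


def read_image_series(path) -> ImageSeries:
    """Read an image series written by :func:`write_image_series`.

    ``read(write(x))`` is the identity on times, values and layout (bit
    identical in NPZ mode).  Malformed files raise :class:`FormatError`
    naming the offending field.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if suffix == ".npz":
        with np.load(path) as z:
            for key in ("times", "values", "rows", "cols", "extent", "noisy"):
                if key not in z:
                    raise FormatError(f"NPZ container missing field {key!r}")
            return _build_series(z["times"], z["values"], z["rows"], z["cols"],
                                 z["extent"], z["noisy"])
    if suffix in (".tif", ".tiff"):
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FormatError(f"missing JSON sidecar {sidecar} for TIFF series")
        meta = json.loads(sidecar.read_text())
        for key in ("times", "rows", "cols", "extent", "noisy"):
            if key not in meta:
                raise FormatError(f"sidecar missing field {key!r}")
        values = np.asarray(tifffile.imread(path), dtype=float)
        if values.ndim == 2:  # single-page stack
            values = values[None, ...]
        if values.shape != (len(meta["times"]), meta["rows"], meta["cols"]):
            raise FormatError(
                f"TIFF stack shape {values.shape} does not match sidecar "
                f"(N={len(meta['times'])}, rows={meta['rows']}, cols={meta['cols']})"
            )
        return _build_series(meta["times"], values, meta["rows"], meta["cols"],
                             meta["extent"], meta["noisy"])
    if suffix == ".csv":
        with open(path, newline="") as fh:
            rows_iter = list(csv.reader(fh))
        header = rows_iter[0]
        try:
            tag = dict(item.split("=") for item in header[4].lstrip("# ").split())
            rows, cols = int(tag["rows"]), int(tag["cols"])
            extent, noisy = float(tag["extent"]), bool(int(tag["noisy"]))
        except (IndexError, KeyError, ValueError) as exc:
            raise FormatError(f"CSV header missing layout metadata: {exc}") from exc
        data: dict[float, np.ndarray] = {}
        for rec in rows_iter[1:]:
            t, r, c, v = float(rec[0]), int(rec[1]), int(rec[2]), float(rec[3])
            data.setdefault(t, np.full((rows, cols), np.nan))[r, c] = v
        times = sorted(data)
        values = np.stack([data[t] for t in times])
        if np.any(np.isnan(values)):
            raise FormatError("CSV series has missing pixel values")
        return _build_series(times, values, rows, cols, extent, noisy)
    raise FormatError(f"unsupported image-series format {suffix!r}")


def write_trajectory(traj, path) -> Path:
    """Write a state trajectory as an NPZ container (times, p, s, c plus
    grid metadata)."""
    path = Path(path)
    if path.suffix.lower() != ".npz":
        raise FormatError(f"trajectory export supports .npz, got {path.suffix!r}")
    np.savez(path, times=traj.times, p=traj.p, s=traj.s, c=traj.c,
             nx=traj.grid.nx, extent=traj.grid.extent, s0=traj.s0)
    return path


def read_trajectory(path):
    """Read a trajectory written by :func:`write_trajectory`."""
    from .grid import DomainGrid
    from .model import StateTrajectory

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with np.load(path) as z:
        for key in ("times", "p", "s", "c", "nx", "extent", "s0"):
            if key not in z:
                raise FormatError(f"trajectory container missing field {key!r}")
        grid = DomainGrid(nx=int(z["nx"]), extent=float(z["extent"]))
        return StateTrajectory(times=z["times"], p=z["p"], s=z["s"], c=z["c"],
                               grid=grid, s0=float(z["s0"]))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return repr(obj)
    return obj


def save_json(obj, path) -> Path:
    """Write a JSON report deterministically (sorted keys, no timestamps)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(obj), indent=1, sort_keys=True) + "\n")
    return path


def profile_to_csv(profile: ProfileResult, path) -> Path:
    """Write a profile trace (log10 θ, θ, J, ratio) as CSV."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["log10_theta", "theta", "nll", "ratio"])
        for g, j, r in zip(profile.grid, profile.nll_profile, profile.ratio):
            w.writerow([repr(float(g)), repr(float(10.0**g)), repr(float(j)), repr(float(r))])
    return path


def profile_summary(profile: ProfileResult) -> dict:
    ci = profile.ci
    return {
        "parameter": profile.parameter,
        "alpha": profile.alpha,
        "delta": profile.delta,
        "mle_log10": profile.xi_hat,
        "mle": 10.0**profile.xi_hat,
        "ci_lower": ci.lower if ci else None,
        "ci_upper": ci.upper if ci else None,
        "ci_lower_open": ci.lower_open if ci else None,
        "ci_upper_open": ci.upper_open if ci else None,
        "verdict": profile.verdict,
        "n_points": int(profile.grid.size),
        "n_failed": profile.n_failed,
    }


def plot_profiles(profiles: dict[str, ProfileResult],
                  local: LocalApproximation | None, path) -> Path:
    """One panel per parameter: profile likelihood ratio in red, quadratic
    (Hessian) approximation in blue, threshold as a dashed line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(profiles)
    fig, axes = plt.subplots(1, len(names), figsize=(3.2 * len(names), 3.0), squeeze=False)
    for ax, name in zip(axes[0], names):
        prof = profiles[name]
        ax.plot(prof.grid, prof.ratio, "r.-", label="profile likelihood")
        if local is not None:
            idx = local.parameters.index(name)
            xs = np.linspace(prof.grid.min(), prof.grid.max(), 200)
            ax.plot(xs, local.quadratic_ratio(idx, xs), "b-", lw=1,
                    label="quadratic approx.")
        ax.axhline(np.exp(-0.5 * prof.delta), ls="--", c="k", lw=0.8)
        ax.set_xlabel(f"log10 {name}")
        ax.set_ylim(0, 1.05)
        ax.set_title(f"{name}: {prof.verdict}", fontsize=9)
    axes[0][0].set_ylabel("likelihood ratio R")
    axes[0][-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
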