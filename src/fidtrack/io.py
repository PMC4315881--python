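"""Plain-text readers and writers for directions, projections, peak lists
and marker models."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .localizer import ProjectionPeaks
from .peak_processing import Peak, Projection1D
from .pose_registration import MarkerModel


def write_directions(path, directions, level: int | None = None) -> None:
    """One row per direction, three float columns, '#'-prefixed header."""
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    header = f"# projection directions ({len(directions)} lines"
    header += f", {level}-neighbourhood)" if level is not None else ")"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for row in directions:
            fh.write(f"{row[0]:.17g} {row[1]:.17g} {row[2]:.17g}\n")


def read_directions(path) -> np.ndarray:
    return np.loadtxt(path, comments="#", ndmin=2)


def write_projection(path, proj: Projection1D) -> None:
    """Header lines '#direction x y z', '#fov_mm', '#n_samples', then one
    magnitude per line."""
    d = proj.direction
    with open(path, "w") as fh:
        fh.write(f"#direction {d[0]:.17g} {d[1]:.17g} {d[2]:.17g}\n")
        fh.write(f"#fov_mm {proj.fov:.17g}\n")
        fh.write(f"#n_samples {proj.n_samples}\n")
        for v in proj.samples:
            fh.write(f"{v:.17g}\n")


def read_projection(path) -> Projection1D:
    direction = None
    fov = None
    n_samples = None
    samples = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#direction"):
                direction = np.array([float(x) for x in line.split()[1:4]])
            elif line.startswith("#fov_mm"):
                fov = float(line.split()[1])
            elif line.startswith("#n_samples"):
                n_samples = int(line.split()[1])
            elif not line.startswith("#"):
                samples.append(float(line))
    if direction is None or fov is None:
        raise ValueError(f"{path}: missing '#direction' or '#fov_mm' header")
    samples = np.array(samples)
    if n_samples is not None and n_samples != len(samples):
        raise ValueError(f"{path}: header announces {n_samples} samples, found {len(samples)}")
    return Projection1D(direction=direction, samples=samples, fov=fov)


def write_peaks_csv(path, peaksets_or_rows) -> None:
    """Peak list CSV with columns projection_id, position_mm, amplitude, snr.

    Accepts either a list of ``(projection_id, peaks, snrs)`` tuples (with
    :class:`~fidtrack.peak_processing.Peak` objects) or a ready DataFrame.
    """
    if isinstance(peaksets_or_rows, pd.DataFrame):
        peaksets_or_rows.to_csv(path, index=False)
        return
    rows = []
    for projection_id, peaks, snrs in peaksets_or_rows:
        for peak, ratio in zip(peaks, snrs):
            rows.append(
                {
                    "projection_id": projection_id,
                    "position_mm": peak.position,
                    "amplitude": peak.amplitude,
                    "snr": ratio,
                }
            )
    pd.DataFrame(rows, columns=["projection_id", "position_mm", "amplitude", "snr"]).to_csv(path, index=False)


def read_peaks_csv(path, directions, pixel_size: float) -> list[ProjectionPeaks]:
    """Peak-list CSV back into per-projection peak sets.

    ``projection_id`` values index rows of ``directions``.  Projections
    without any row yield an empty peak set (zero detected peaks).
    """
    df = pd.read_csv(path)
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    out = []
    for i, direction in enumerate(directions):
        positions = df.loc[df["projection_id"] == i, "position_mm"].to_numpy()
        out.append(ProjectionPeaks(direction=direction, positions=positions, pixel_size=pixel_size))
    return out


def write_marker_model(path, model: MarkerModel) -> None:
    """Marker model CSV with columns label, x_mm, y_mm, z_mm."""
    df = pd.DataFrame(
        {
            "label": list(model.labels),
            "x_mm": model.points[:, 0],
            "y_mm": model.points[:, 1],
            "z_mm": model.points[:, 2],
        }
    )
    df.to_csv(path, index=False)


def read_marker_model(path) -> MarkerModel:
    df = pd.read_csv(path)
    return MarkerModel(points=df[["x_mm", "y_mm", "z_mm"]].to_numpy(float), labels=df["label"].tolist())
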