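"""Delimited-text readers and writers.

The canonical interchange format is CSV.  The matrix dialect has a header
row holding the ascending m/z axis, one row per spectrum, and the spectrum
id in the first column; the same layout serves intensity matrices ``X`` and
persistence matrices ``Z``.  Labels and groups travel in a three-column file
``spectrum_id,label,group``.  Reduced features are written long-format with
``spectrum_id,mz,persistence`` — two payload values per retained feature.

All format errors name the offending row or column; malformed input is
never silently coerced.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import IntensityMatrix, PersistenceMatrix
from .simulate import MSImage

__all__ = [
    "read_intensity_matrix",
    "read_imzml",
    "write_matrix",
    "read_labels",
    "write_reduced_features",
    "write_cv_report",
    "save_image_bundle",
    "load_image_bundle",
]


class FormatError(ValueError):
    """Malformed input file."""


def read_intensity_matrix(path) -> IntensityMatrix:
    """Read a CSV matrix: header = m/z axis, first column = spectrum id."""
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] < 1 or df.shape[0] < 1:
        raise FormatError(f"{path}: matrix must have at least one row and column")
    try:
        mz = df.columns.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: m/z header is not numeric") from exc
    if mz.size > 1 and not np.all(np.diff(mz) > 0):
        j = int(np.flatnonzero(np.diff(mz) <= 0)[0]) + 1
        raise FormatError(f"{path}: m/z not ascending at column {j + 1}")
    values = df.to_numpy(dtype=float)
    bad = np.flatnonzero(np.any(~np.isfinite(values) | (values < 0), axis=1))
    if bad.size:
        raise FormatError(
            f"{path}: negative or non-finite intensity in row "
            f"{df.index[bad[0]]!r}"
        )
    return IntensityMatrix(
        mz_axis=mz, values=values, spectrum_ids=df.index.to_numpy(dtype=str)
    )


def read_imzml(path) -> IntensityMatrix:
    """Read a continuous-mode imzML file onto a shared m/z axis.

    Optional: requires the ``pyimzml`` extra.  Every spectrum must share
    the common m/z axis (continuous mode); spectrum ids encode the pixel
    coordinates.
    """
    try:
        from pyimzml.ImzMLParser import ImzMLParser
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "imzML support needs pyimzml; install with 'pip install topoms[imzml]'"
        ) from exc
    parser = ImzMLParser(str(path))
    mz_ref, _ = parser.getspectrum(0)
    rows, ids = [], []
    for i, (x, y, *_rest) in enumerate(parser.coordinates):
        mz, intensities = parser.getspectrum(i)
        if mz.shape != mz_ref.shape or not np.array_equal(mz, mz_ref):
            raise FormatError(
                f"{path}: spectrum {i} is not on the shared m/z axis "
                "(processed-mode imzML is not supported)"
            )
        rows.append(intensities)
        ids.append(f"px_{x}_{y}")
    return IntensityMatrix(
        mz_axis=np.asarray(mz_ref, dtype=float),
        values=np.asarray(rows, dtype=float),
        spectrum_ids=np.asarray(ids),
    )


def write_matrix(matrix, path) -> None:
    """Write an intensity or persistence matrix in the CSV matrix dialect."""
    df = pd.DataFrame(
        matrix.values,
        index=pd.Index(matrix.spectrum_ids, name="spectrum_id"),
        columns=[format(v, "g") for v in matrix.mz_axis],
    )
    df.to_csv(path)


def read_labels(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read ``spectrum_id,label,group`` CSV; returns (ids, labels, groups)."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"spectrum_id", "label", "group"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    labels = df["label"].to_numpy()
    if not np.isin(labels, [0, 1]).all():
        bad = df.index[~np.isin(labels, [0, 1])][0]
        raise FormatError(f"{path}: non-binary label in row {bad + 2}")
    return (
        df["spectrum_id"].to_numpy(dtype=str),
        labels.astype(int),
        df["group"].to_numpy(),
    )


def write_reduced_features(features_per_spectrum, spectrum_ids, path) -> None:
    """Write retained reduced features long-format.

    ``features_per_spectrum`` is an iterable of structured arrays with
    ``position`` and ``persistence`` fields, one per spectrum.
    """
    rows = []
    for sid, feats in zip(spectrum_ids, features_per_spectrum):
        for f in feats:
            rows.append((sid, float(f["position"]), float(f["persistence"])))
    df = pd.DataFrame(rows, columns=["spectrum_id", "mz", "persistence"])
    df.to_csv(path, index=False)


def write_cv_report(result, path=None) -> str:
    """Render a CV result as fold rows plus the five summary rows."""
    lines = ["fold,balanced_accuracy"]
    for fid, score in zip(result.fold_ids, result.per_fold):
        lines.append(f"{fid},{score:.6f}")
    for stat, value in result.summary().items():
        lines.append(f"{stat},{value:.6f}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def save_image_bundle(image: MSImage, directory) -> None:
    """Save an MS image as plain text: pixel spectra CSV + JSON ground truth."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    height, width, n_bins = image.data.shape
    ids = [f"px_{r}_{c}" for r in range(height) for c in range(width)]
    flat = IntensityMatrix(
        mz_axis=image.mz_axis,
        values=image.data.reshape(height * width, n_bins),
        spectrum_ids=np.asarray(ids),
    )
    write_matrix(flat, directory / "spectra.csv")
    meta = {
        "height": height,
        "width": width,
        "baseline": image.baseline,
        "truth_peaks": [
            {"bin": int(p["bin"]), "region": str(p["region"]),
             "amplitude": float(p["amplitude"])}
            for p in image.truth_peaks
        ],
        "region_masks": {
            name: np.flatnonzero(mask.ravel()).tolist()
            for name, mask in image.region_masks.items()
        },
    }
    (directory / "truth.json").write_text(json.dumps(meta))


def load_image_bundle(directory) -> MSImage:
    """Load an MS image saved by :func:`save_image_bundle`."""
    from .simulate import TRUTH_DTYPE

    directory = Path(directory)
    flat = read_intensity_matrix(directory / "spectra.csv")
    meta = json.loads((directory / "truth.json").read_text())
    height, width = meta["height"], meta["width"]
    if flat.n != height * width:
        raise FormatError(
            f"{directory}: {flat.n} spectra do not fill a "
            f"{height}x{width} pixel grid"
        )
    truth = np.array(
        [(p["bin"], p["region"], p["amplitude"]) for p in meta["truth_peaks"]],
        dtype=TRUTH_DTYPE,
    )
    masks = {}
    for name, idx in meta["region_masks"].items():
        mask = np.zeros(height * width, dtype=bool)
        mask[np.asarray(idx, dtype=int)] = True
        masks[name] = mask.reshape(height, width)
    return MSImage(
        mz_axis=flat.mz_axis,
        data=flat.values.reshape(height, width, flat.q),
        truth_peaks=truth,
        region_masks=masks,
        baseline=float(meta["baseline"]),
    )
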