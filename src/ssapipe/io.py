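"""File formats: multi-page TIFF movies, manifests, ground truth, masks.

Movies are stored as 16-bit unsigned multi-page TIFFs with the float scale
factor and acquisition timing recorded in a JSON sidecar next to each file;
loading reverses the scaling exactly.  The experiment manifest is a CSV with
one row per trial; ground truth is a JSON mapping trial_id -> injected
amplitudes.  ROI masks round-trip as single-page 0/255 TIFFs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .exceptions import DataError
from .synth import GroundTruth, Movie, TrialRecord

MANIFEST_NAME = "manifest.csv"
TRUTH_NAME = "ground_truth.json"


def write_movie_tiff(movie: Movie, path) -> None:
    path = Path(path)
    peak = float(movie.frames.max())
    scale = 65535.0 / peak if peak > 0 else 1.0
    data = np.round(movie.frames * scale).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    sidecar = {"scale": scale, "fps": movie.fps, "t0_s": movie.t0_s}
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_movie_tiff(path) -> Movie:
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except Exception as exc:
        raise DataError(f"cannot read TIFF movie {path}: {exc}") from exc
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise DataError(f"missing metadata sidecar for {path}")
    meta = json.loads(sidecar_path.read_text())
    frames = np.asarray(data, dtype=float) / meta["scale"]
    return Movie(frames, meta["fps"], meta["t0_s"])


def write_mask_tiff(mask: np.ndarray, path) -> None:
    tifffile.imwrite(Path(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def read_mask_tiff(path) -> np.ndarray:
    try:
        data = tifffile.imread(Path(path))
    except Exception as exc:
        raise DataError(f"cannot read mask TIFF {path}: {exc}") from exc
    return np.asarray(data) > 0


def write_experiment(records, outdir) -> Path:
    """Write TIFFs, manifest and ground truth for a simulated experiment."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    truth = {}
    for rec in records:
        tiff_path = outdir / f"{rec.trial_id}.tif"
        write_movie_tiff(rec.movie, tiff_path)
        rows.append(
            {
                "trial_id": rec.trial_id,
                "rate_hz": rec.rate_hz,
                "condition": rec.condition,
                "seed": rec.seed,
                "inter_trial_gap_s": rec.inter_trial_gap_s,
                "tiff_path": tiff_path.name,
            }
        )
        truth[rec.trial_id] = {
            "amp_sequence": rec.truth.amp_sequence.tolist(),
            "condition": rec.truth.condition,
            "rate_hz": rec.truth.rate_hz,
            "seed": rec.truth.seed,
        }
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / MANIFEST_NAME, index=False)
    (outdir / TRUTH_NAME).write_text(json.dumps(truth, indent=1))
    return outdir / MANIFEST_NAME


def read_manifest(expdir) -> pd.DataFrame:
    path = Path(expdir) / MANIFEST_NAME
    if not path.exists():
        raise DataError(f"no manifest found at {path}")
    return pd.read_csv(path)


def load_trial_movie(expdir, row) -> Movie:
    return read_movie_tiff(Path(expdir) / row["tiff_path"])


def read_ground_truth(expdir) -> dict:
    path = Path(expdir) / TRUTH_NAME
    if not path.exists():
        raise DataError(f"no ground truth found at {path}")
    raw = json.loads(path.read_text())
    return {
        tid: GroundTruth(
            np.asarray(v["amp_sequence"]), v["condition"], v["rate_hz"], v["seed"]
        )
        for tid, v in raw.items()
    }
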