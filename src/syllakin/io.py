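"""File formats: DeepLabCut-dialect CSV, HDF5 keypoints, labels, models.

Also exposes the published per-syllable reference tables (velocity, usage
and p values for the 6-OHDA, mitoPark and l-DOPA cohorts) that ship with the
package as TSV data files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from importlib import resources
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from syllakin.segmentation import ARHMMHyper, ARHMMModel, SyllableSequence
from syllakin.synthetic import GroundTruth, KeypointRecording

logger = logging.getLogger(__name__)

__all__ = [
    "read_dlc_csv",
    "write_dlc_csv",
    "read_keypoints_h5",
    "write_keypoints_h5",
    "write_ground_truth",
    "read_ground_truth",
    "write_labels_csv",
    "read_labels_csv",
    "save_model",
    "load_model",
    "load_reference_table",
]

_SCORER = "syllakin"


def write_dlc_csv(rec: KeypointRecording, path) -> None:
    """Write a recording as DLC-style CSV (scorer / bodyparts / coords header)."""
    cols = pd.MultiIndex.from_tuples(
        [(_SCORER, part, coord) for part in rec.body_parts for coord in ("x", "y", "likelihood")],
        names=["scorer", "bodyparts", "coords"],
    )
    n = rec.n_frames
    data = np.empty((n, len(cols)))
    for p in range(len(rec.body_parts)):
        data[:, 3 * p] = rec.coords[:, p, 0]
        data[:, 3 * p + 1] = rec.coords[:, p, 1]
        data[:, 3 * p + 2] = rec.likelihood[:, p]
    pd.DataFrame(data, columns=cols).to_csv(path, index_label="frame")


def read_dlc_csv(path, fps: float = 30.0, arena_size: float = 400.0) -> KeypointRecording:
    """Read a DLC-dialect CSV (3 header rows: scorer / bodyparts / coords).

    Missing likelihood columns are accepted (filled with 1.0, with a
    warning); an inconsistent coordinate set per part is a hard error; any
    non-numeric cell is an error naming the data row.
    """
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except Exception as exc:  # malformed header / truncation
        raise ValueError(f"{path}: not a DLC-dialect CSV ({exc})") from exc
    if df.columns.nlevels != 3:
        raise ValueError(f"{path}: expected 3 header rows (scorer/bodyparts/coords)")

    parts = list(dict.fromkeys(df.columns.get_level_values(1)))
    per_part = {}
    for part in parts:
        sub = df.xs(part, axis=1, level=1)
        coords_present = set(sub.columns.get_level_values(-1))
        if not {"x", "y"} <= coords_present:
            raise ValueError(f"{path}: body part {part!r} lacks x/y columns")
        per_part[part] = sub

    ref_coords = None
    for part, sub in per_part.items():
        present = frozenset(sub.columns.get_level_values(-1))
        if ref_coords is None:
            ref_coords = present
        elif present != ref_coords:
            raise ValueError(f"{path}: inconsistent coordinate sets across body parts")

    n = len(df)
    coords = np.empty((n, len(parts), 2))
    lik = np.ones((n, len(parts)))
    has_lik = "likelihood" in ref_coords
    if not has_lik:
        warnings.warn(f"{path}: no likelihood columns; assuming confidence 1.0", stacklevel=2)
    for p, part in enumerate(parts):
        sub = per_part[part]
        for c, name in enumerate(("x", "y")):
            col = pd.to_numeric(sub.xs(name, axis=1, level=-1).iloc[:, 0], errors="coerce")
            bad = col.isna() & sub.xs(name, axis=1, level=-1).iloc[:, 0].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(f"{path}: malformed {part}/{name} cell at data row {row}")
            coords[:, p, c] = col.to_numpy()
        if has_lik:
            lik[:, p] = pd.to_numeric(
                sub.xs("likelihood", axis=1, level=-1).iloc[:, 0], errors="coerce"
            ).fillna(0.0).to_numpy()
    return KeypointRecording(
        body_parts=tuple(parts), coords=coords, likelihood=lik, fps=fps, arena_size=arena_size
    )


def write_keypoints_h5(rec: KeypointRecording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("coords", data=rec.coords)
        f.create_dataset("likelihood", data=rec.likelihood)
        f.attrs["fps"] = rec.fps
        f.attrs["arena_size"] = rec.arena_size
        f.attrs["body_parts"] = [p.encode() for p in rec.body_parts]


def read_keypoints_h5(path) -> KeypointRecording:
    with h5py.File(path, "r") as f:
        return KeypointRecording(
            body_parts=tuple(p.decode() if isinstance(p, bytes) else str(p)
                             for p in f.attrs["body_parts"]),
            coords=f["coords"][...],
            likelihood=f["likelihood"][...],
            fps=float(f.attrs["fps"]),
            arena_size=float(f.attrs["arena_size"]),
        )


def write_ground_truth(truth: GroundTruth, csv_path, json_path) -> None:
    pd.DataFrame({"frame": np.arange(truth.labels.size), "label": truth.labels}).to_csv(
        csv_path, index=False
    )
    with open(json_path, "w") as f:
        json.dump(
            {
                "transition_matrix": truth.transition_matrix.tolist(),
                "speeds": truth.speeds.tolist(),
                "seed": int(truth.seed),
            },
            f,
            indent=1,
        )


def read_ground_truth(csv_path, json_path) -> GroundTruth:
    labels = pd.read_csv(csv_path)["label"].to_numpy(dtype=np.int64)
    with open(json_path) as f:
        meta = json.load(f)
    return GroundTruth(
        labels=labels,
        transition_matrix=np.asarray(meta["transition_matrix"], dtype=float),
        speeds=np.asarray(meta["speeds"], dtype=float),
        seed=int(meta["seed"]),
    )


def write_labels_csv(sequences, path) -> None:
    frames = []
    for seq in sequences:
        frames.append(
            pd.DataFrame(
                {
                    "session": seq.session_id,
                    "frame": np.arange(seq.n_frames),
                    "label": seq.labels,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_labels_csv(path, fps: float = 30.0):
    df = pd.read_csv(path)
    return [
        SyllableSequence(labels=g["label"].to_numpy(), fps=fps, session_id=str(sid))
        for sid, g in df.groupby("session", sort=True)
    ]


def save_model(model: ARHMMModel, json_path, h5_path) -> None:
    """Model = JSON (hyperparameters, shapes) + HDF5 (parameter arrays)."""
    with open(json_path, "w") as f:
        json.dump(
            {
                "hyper": dataclasses.asdict(model.hyper),
                "n_states": model.n_states,
                "latent_dim": model.latent_dim,
                "arrays": str(Path(h5_path).name),
            },
            f,
            indent=1,
        )
    with h5py.File(h5_path, "w") as f:
        f.create_dataset("ar_weights", data=model.ar_weights)
        f.create_dataset("innovation_cov", data=model.innovation_cov)
        f.create_dataset("transitions", data=model.transitions)
        f.create_dataset("state_usage", data=model.state_usage)


def load_model(json_path, h5_path=None) -> ARHMMModel:
    with open(json_path) as f:
        meta = json.load(f)
    if h5_path is None:
        h5_path = Path(json_path).parent / meta["arrays"]
    hyper = ARHMMHyper(**meta["hyper"])
    with h5py.File(h5_path, "r") as f:
        return ARHMMModel(
            ar_weights=f["ar_weights"][...],
            innovation_cov=f["innovation_cov"][...],
            transitions=f["transitions"][...],
            hyper=hyper,
            state_usage=f["state_usage"][...],
        )


def load_deposited_sequences(directory) -> dict:
    """Best-effort adapter for deposited per-animal syllable sequences.

    Expects a directory of per-animal CSV files named ``<group>_<id>.csv``
    whose rows are per-frame records with a ``label`` (or ``syllable``)
    column; the archived tabular-data schema is not formally documented, so
    this loader is an adapter, not a contract. Returns
    ``{group: [label arrays]}``.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"deposited data directory not found: {directory}")
    out: dict = {}
    for path in sorted(directory.glob("*.csv")):
        df = pd.read_csv(path)
        col = "label" if "label" in df.columns else "syllable" if "syllable" in df.columns else None
        if col is None:
            logger.warning("skipping %s: no label/syllable column", path.name)
            continue
        group = path.stem.rsplit("_", 1)[0]
        out.setdefault(group, []).append(df[col].to_numpy(dtype=np.int64))
    if not out:
        raise ValueError(f"no usable sequence files under {directory}")
    return out


def load_reference_table(name: str) -> pd.DataFrame:
    """Load a published per-syllable reference table shipped with the package.

    Names: ``"6ohda"`` (control vs 6-OHDA), ``"mitopark"`` (control vs
    mitoPark at 8/14/24 weeks; has an ``age_weeks`` column), ``"ldopa"``
    (saline control vs mitoPark vs mitoPark + l-DOPA). Velocities are mm/s
    (group mean), usages are time fractions; ``*_p`` columns hold the
    published between-group p values.
    """
    fname = {"6ohda": "cohort_6ohda.tsv", "mitopark": "cohort_mitopark.tsv",
             "ldopa": "cohort_ldopa.tsv"}.get(name)
    if fname is None:
        raise ValueError(f"unknown reference table {name!r}")
    with resources.files("syllakin.data").joinpath(fname).open() as f:
        return pd.read_csv(f, sep="\t")
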