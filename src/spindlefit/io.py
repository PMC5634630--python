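"""Dataset readers and writers.

On disk a dataset is a JSON manifest plus, per trial, a CSV of the sampled
channels (header ``time_s,length_mm,force_N``) and a plain-text spike file
(one spike time per line, seconds).  Floats are written with 17 significant
digits so that write(read(x)) reproduces the files byte-for-byte.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np

from .exceptions import InvalidInput
from .signals import TrialRecord
from .simulate import GroundTruthSpindle, SyntheticDataset

__all__ = ["write_dataset", "read_dataset", "write_trial", "read_trial",
           "read_truths"]

_FMT = "%.17g"

_META_FIELDS = ("stretch_type", "peak_length_mm", "peak_velocity_mm_s",
                "peak_accel_mm_s2", "ramp_end_time_s", "hold_end_time_s",
                "exclude")


def write_trial(trial: TrialRecord, directory: Path) -> dict:
    """Write one trial's CSV + spike file; return its manifest entry."""
    directory = Path(directory)
    csv_name = f"{trial.trial_id}.csv"
    spk_name = f"{trial.trial_id}.spikes.txt"
    with open(directory / csv_name, "w") as fh:
        fh.write("time_s,length_mm,force_N\n")
        for t, l, f in zip(trial.t, trial.length, trial.force):
            fh.write(f"{t:.17g},{l:.17g},{f:.17g}\n")
    with open(directory / spk_name, "w") as fh:
        for s in trial.spike_times:
            fh.write(f"{s:.17g}\n")
    entry = {"trial_id": trial.trial_id, "afferent_id": trial.afferent_id,
             "fs": trial.fs, "csv": csv_name, "spikes": spk_name}
    for name in _META_FIELDS:
        val = getattr(trial, name)
        entry[name] = val if not isinstance(val, float) or np.isfinite(val) else None
    return entry


def read_trial(entry: dict, directory: Path) -> TrialRecord:
    directory = Path(directory)
    csv_path = directory / entry["csv"]
    spk_path = directory / entry["spikes"]
    for p in (csv_path, spk_path):
        if not p.exists():
            raise InvalidInput(f"missing trial file: {p}")
    with open(csv_path) as fh:
        header = fh.readline().strip()
        if header != "time_s,length_mm,force_N":
            raise InvalidInput(f"{csv_path}: unexpected header {header!r}")
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    if data.shape[1] != 3:
        raise InvalidInput(f"{csv_path}: expected 3 columns")
    spikes = np.loadtxt(spk_path, ndmin=1) if spk_path.stat().st_size else np.empty(0)
    kwargs = {}
    for name in _META_FIELDS:
        val = entry.get(name)
        if val is None and name != "exclude":
            val = float("nan")
        if val is not None:
            kwargs[name] = val
    return TrialRecord(
        trial_id=entry["trial_id"], afferent_id=entry["afferent_id"],
        fs=float(entry["fs"]), t=data[:, 0], length=data[:, 1],
        force=data[:, 2], spike_times=spikes, **kwargs)


def write_dataset(dataset: SyntheticDataset | dict, out_dir: str | Path,
                  truths: Optional[dict] = None) -> Path:
    """Write a dataset directory; returns the manifest path.

    Accepts either a SyntheticDataset or a plain ``{afferent_id: [trials]}``
    mapping.  Ground truths, when present, go to ``truth.json`` beside the
    manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(dataset, SyntheticDataset):
        afferents = dataset.afferents
        truths = truths if truths is not None else dataset.truths
    else:
        afferents = dataset
    manifest = {"afferents": {}}
    for aff_id in sorted(afferents):
        entries = [write_trial(tr, out_dir) for tr in afferents[aff_id]]
        manifest["afferents"][aff_id] = entries
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if truths:
        with open(out_dir / "truth.json", "w") as fh:
            json.dump({a: t.to_dict() for a, t in sorted(truths.items())},
                      fh, indent=2, sort_keys=True)
            fh.write("\n")
    return manifest_path


def read_dataset(manifest_path: str | Path) -> dict:
    """Load a dataset directory -> ``{afferent_id: [TrialRecord, ...]}``."""
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.json"
    if not manifest_path.exists():
        raise InvalidInput(f"missing manifest: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    if "afferents" not in manifest:
        raise InvalidInput(f"{manifest_path}: no 'afferents' key")
    directory = manifest_path.parent
    out = {}
    for aff_id, entries in manifest["afferents"].items():
        out[aff_id] = [read_trial(e, directory) for e in entries]
    return out


def read_truths(dataset_dir: str | Path) -> dict:
    path = Path(dataset_dir) / "truth.json"
    if not path.exists():
        raise InvalidInput(f"missing truth file: {path}")
    with open(path) as fh:
        raw = json.load(fh)
    return {a: GroundTruthSpindle.from_dict(d) for a, d in raw.items()}
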