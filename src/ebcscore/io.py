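"""Dataset storage: JSON manifest + NumPy ``.npz`` trace container.

No standard bioinformatics format fits trial-wise EMG, so the layout is
explicit: ``manifest.json`` holds the design, seed, format version and
one record per trial (ids, block, type, ITI, stimulus times, sampling
metadata, ground truth when synthetic); ``traces.npz`` maps each
``trial_id`` to its float64 sample array.  Round trips are lossless,
including bit-identical floating-point samples.  All times are ms
relative to CS onset.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from .design import DesignParams, StimulusTiming, TrialSpec
from .errors import DatasetError
from .preprocess import RawTrace
from .synth import GroundTruth, SimTrial

FORMAT_VERSION = 1
MANIFEST_NAME = "manifest.json"
TRACES_NAME = "traces.npz"


@dataclass
class Dataset:
    """In-memory dataset: manifest dict + per-trial raw traces."""

    manifest: dict
    traces: Dict[str, RawTrace]

    @property
    def trial_records(self) -> List[dict]:
        return self.manifest["trials"]

    def trial_ids(self) -> List[str]:
        return [r["trial_id"] for r in self.trial_records]

    def iter_trials(self):
        """Yield SimTrial objects reconstructed from records + traces."""
        for rec in self.trial_records:
            yield sim_trial_from_record(rec, self.traces[rec["trial_id"]])


def _timing_to_dict(t: StimulusTiming) -> dict:
    return dict(cs_duration_ms=t.cs_duration_ms, us_onset_ms=t.us_onset_ms,
                us_duration_ms=t.us_duration_ms)


def _timing_from_dict(d: dict) -> StimulusTiming:
    return StimulusTiming(**d)


def design_to_dict(p: DesignParams) -> dict:
    d = dataclasses.asdict(p)
    d["iti_range_s"] = list(p.iti_range_s)
    return d


def design_from_dict(d: dict) -> DesignParams:
    d = dict(d)
    d["iti_range_s"] = tuple(d["iti_range_s"])
    d["timing"] = _timing_from_dict(d["timing"])
    return DesignParams(**d)


def trial_record(trial: SimTrial) -> dict:
    spec, raw = trial.spec, trial.raw
    tid = f"{trial.subject or 'subj'}_s{trial.session or 0}_t{spec.index:03d}"
    truth = dataclasses.asdict(trial.truth)
    truth["spont_times_ms"] = list(truth["spont_times_ms"])
    return dict(trial_id=tid, subject=trial.subject, group=trial.group,
                session=trial.session, index=spec.index, block=spec.block,
                trial_type=spec.trial_type, iti_s=spec.iti_s,
                timing=_timing_to_dict(spec.timing),
                fs=raw.fs, t0_ms=raw.t0_ms, n_samples=int(raw.samples.size),
                truth=truth)


def sim_trial_from_record(rec: dict, raw: RawTrace) -> SimTrial:
    spec = TrialSpec(index=rec["index"], block=rec["block"],
                     trial_type=rec["trial_type"], iti_s=rec["iti_s"],
                     timing=_timing_from_dict(rec["timing"]))
    truth_d = dict(rec["truth"])
    truth_d["spont_times_ms"] = tuple(truth_d["spont_times_ms"])
    return SimTrial(spec=spec, raw=raw, truth=GroundTruth(**truth_d),
                    group=rec["group"], session=rec["session"],
                    subject=rec["subject"])


def dataset_from_trials(trials: Sequence[SimTrial], design: DesignParams,
                        seed: Optional[int] = None,
                        config_hash: Optional[str] = None) -> Dataset:
    records, traces = [], {}
    for t in trials:
        rec = trial_record(t)
        if rec["trial_id"] in traces:
            raise DatasetError(f"duplicate trial_id {rec['trial_id']!r}")
        records.append(rec)
        traces[rec["trial_id"]] = t.raw
    manifest = dict(format_version=FORMAT_VERSION, seed=seed,
                    config_hash=config_hash, design=design_to_dict(design),
                    trials=records)
    return Dataset(manifest=manifest, traces=traces)


def write_dataset(dataset: Dataset, path) -> None:
    """Store a dataset under a directory (manifest.json + traces.npz)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / MANIFEST_NAME, "w") as fh:
        json.dump(dataset.manifest, fh, indent=1)
    np.savez(path / TRACES_NAME,
             **{tid: tr.samples for tid, tr in dataset.traces.items()})


def read_dataset(path) -> Dataset:
    """Load a stored dataset, validating manifest/trace consistency."""
    path = Path(path)
    mpath = path / MANIFEST_NAME
    if not mpath.exists():
        raise DatasetError(f"missing manifest: {mpath}")
    try:
        with open(mpath) as fh:
            manifest = json.load(fh)
    except json.JSONDecodeError as e:
        raise DatasetError(f"malformed manifest {mpath}: {e}") from e
    version = manifest.get("format_version")
    if version != FORMAT_VERSION:
        raise DatasetError(f"unsupported dataset format version {version!r}")
    try:
        npz = np.load(path / TRACES_NAME)
    except FileNotFoundError as e:
        raise DatasetError(f"missing trace container: {path / TRACES_NAME}") from e
    traces = {}
    for rec in manifest.get("trials", []):
        tid = rec["trial_id"]
        if tid not in npz.files:
            raise DatasetError(f"manifest references missing trace for trial_id {tid!r}")
        arr = npz[tid]
        if arr.size != rec["n_samples"]:
            raise DatasetError(f"trace length mismatch for trial_id {tid!r}")
        traces[tid] = RawTrace(arr, fs=rec["fs"], t0_ms=rec["t0_ms"])
    return Dataset(manifest=manifest, traces=traces)
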