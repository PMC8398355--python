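"""HDF5 / CSV persistence for trial datasets.

Layout: ``/subject_{id}/class_{id}/trial_{k}`` each a float dataset of
shape [channels x samples] with attributes ``fs``, ``class``, ``subject``,
``seed``, ``preprocessed``.  Datasets are written with ``track_times=False``
so a fixed generator seed yields a byte-identical file.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synthetic import AcquisitionSpec, Dataset, NoiseSpec, Trial

__all__ = ["save_dataset", "load_dataset", "trial_to_csv", "trial_from_csv"]


def save_dataset(dataset: Dataset, path: str | Path) -> None:
    counters: dict[tuple[int, int], int] = {}
    with h5py.File(path, "w", track_order=True) as f:
        f.attrs["manifest"] = dataset.manifest_json()
        for trial in dataset.trials:
            key = (trial.subject_id, trial.class_id)
            k = counters.get(key, 0)
            counters[key] = k + 1
            grp = f.require_group(f"subject_{trial.subject_id}/class_{trial.class_id}")
            ds = grp.create_dataset(
                f"trial_{k}", data=trial.data, track_times=False
            )
            ds.attrs["fs"] = trial.acquisition.sampling_rate
            ds.attrs["class"] = trial.class_id
            ds.attrs["subject"] = trial.subject_id
            ds.attrs["seed"] = -1 if trial.seed is None else trial.seed
            ds.attrs["preprocessed"] = trial.preprocessed


def load_dataset(path: str | Path) -> Dataset:
    trials: list[Trial] = []
    with h5py.File(path, "r") as f:
        manifest = json.loads(f.attrs["manifest"])
        a = manifest["acquisition"]
        acq = AcquisitionSpec(
            sampling_rate=a["sampling_rate"],
            duration=a["duration"],
            n_channels=a["n_channels"],
            n_classes=a["n_classes"],
            trials_per_class_per_subject=a["trials_per_class_per_subject"],
            n_subjects=a["n_subjects"],
        )
        noise = NoiseSpec(**manifest["noise"])
        for sname in f:
            for cname in f[sname]:
                grp = f[sname][cname]
                for tname in grp:
                    ds = grp[tname]
                    seed = int(ds.attrs["seed"])
                    trials.append(
                        Trial(
                            data=np.asarray(ds),
                            class_id=int(ds.attrs["class"]),
                            subject_id=int(ds.attrs["subject"]),
                            acquisition=acq,
                            preprocessed=bool(ds.attrs["preprocessed"]),
                            seed=None if seed < 0 else seed,
                        )
                    )
    return Dataset(trials=trials, acquisition=acq, noise=noise, manifest=manifest)


def trial_to_csv(trial: Trial, path: str | Path) -> None:
    """One column per channel, header CH1..CHn."""
    cols = {f"CH{i + 1}": trial.data[i] for i in range(trial.data.shape[0])}
    pd.DataFrame(cols).to_csv(path, index=False)


def trial_from_csv(
    path: str | Path, class_id: int, subject_id: int, acq: AcquisitionSpec
) -> Trial:
    df = pd.read_csv(path)
    data = df[[f"CH{i + 1}" for i in range(acq.n_channels)]].to_numpy().T
    return Trial(data=data, class_id=class_id, subject_id=subject_id, acquisition=acq)
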