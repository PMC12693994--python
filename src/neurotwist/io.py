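"""On-disk formats: CSV/TSV matrices, JSON metadata, optional HDF5.

A :class:`~neurotwist.decoding.PopulationDataset` round-trips either as a
directory of per-condition ``neurons × time`` CSVs plus a JSON sidecar,
or as a single HDF5 file.  Rule tables are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .decoding import PopulationDataset

__all__ = [
    "save_dataset_csv",
    "load_dataset_csv",
    "save_dataset_hdf5",
    "load_dataset_hdf5",
    "rules_table",
]


def save_dataset_csv(data: PopulationDataset, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "time_ms": data.time_ms.tolist(),
        "condition_vertices": data.condition_vertices.tolist(),
        "coherence": None if data.coherence is None else np.asarray(data.coherence).tolist(),
        "outcome": None if data.outcome is None else np.asarray(data.outcome).tolist(),
    }
    (directory / "meta.json").write_text(json.dumps(meta))
    for ci in range(data.activity.shape[0]):
        # neurons x time, one file per condition
        np.savetxt(directory / f"condition_{ci:03d}.csv", data.activity[ci].T, delimiter=",")


def load_dataset_csv(directory) -> PopulationDataset:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    mats = []
    for ci in range(len(meta["condition_vertices"])):
        m = np.loadtxt(directory / f"condition_{ci:03d}.csv", delimiter=",", ndmin=2)
        mats.append(m.T)  # back to time x neurons
    return PopulationDataset(
        np.array(mats),
        np.array(meta["time_ms"]),
        np.array(meta["condition_vertices"]),
        None if meta["coherence"] is None else np.array(meta["coherence"]),
        None if meta["outcome"] is None else np.array(meta["outcome"]),
    )


def save_dataset_hdf5(data: PopulationDataset, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("activity", data=data.activity)
        f.create_dataset("time_ms", data=data.time_ms)
        f.create_dataset("condition_vertices", data=data.condition_vertices)
        if data.coherence is not None:
            f.create_dataset("coherence", data=np.asarray(data.coherence))
        if data.outcome is not None:
            f.create_dataset("outcome", data=np.asarray(data.outcome))


def load_dataset_hdf5(path) -> PopulationDataset:
    import h5py

    with h5py.File(path, "r") as f:
        return PopulationDataset(
            f["activity"][...],
            f["time_ms"][...],
            f["condition_vertices"][...],
            f["coherence"][...] if "coherence" in f else None,
            f["outcome"][...] if "outcome" in f else None,
        )


def rules_table() -> pd.DataFrame:
    """All 256 rules with 3D/7D separability and a witness subspace."""
    from .separability import separable_rule_ids_3d
    from .stimulus_space import enumerate_rules
    from .twist_algebra import subspace_coverage

    sep3 = separable_rule_ids_3d()
    witnesses, _ = subspace_coverage(inseparable_only=False)
    rows = []
    for rule in enumerate_rules():
        hits = witnesses.get(rule.rule_id, [])
        rows.append(
            {
                "rule_id": rule.rule_id,
                "positive_set": "".join(str(i) for i in sorted(rule.positive_set)),
                "separable_3d": rule.rule_id in sep3,
                "separable_7d": bool(hits),
                "n_witness_subspaces": len(hits),
                "witness_subspace": "".join(hits[0]) if hits else "",
            }
        )
    return pd.DataFrame(rows)
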