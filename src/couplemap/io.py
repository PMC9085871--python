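"""Delimited-text I/O for parcel maps and matrices used by the CLI."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["read_map", "write_map", "read_matrix", "write_matrix"]


def write_map(path, values, parcel_ids=None) -> None:
    values = np.asarray(values, dtype=float)
    if parcel_ids is None:
        parcel_ids = [f"parcel_{i:04d}" for i in range(values.size)]
    pd.DataFrame({"parcel_id": parcel_ids, "value": values}).to_csv(path, index=False)


def read_map(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, dtype={"parcel_id": str})
    return df["value"].to_numpy(dtype=float), df["parcel_id"].to_numpy()


def write_matrix(path, values, parcel_ids=None) -> None:
    values = np.asarray(values, dtype=float)
    if parcel_ids is None:
        parcel_ids = [f"parcel_{i:04d}" for i in range(values.shape[0])]
    pd.DataFrame(values, index=parcel_ids, columns=parcel_ids).to_csv(path, sep="\t")


def read_matrix(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), df.index.to_numpy(dtype=str)
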