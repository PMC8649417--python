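"""Plain-text serialisation of item tables, response data and results.

Item parameter tables are CSV with columns ``item, V, a, b_1..b_4``
(trailing thresholds blank for shorter items).  Response tables are wide
CSV with a blank missing sentinel, or long CSV with one row per observed
response.  Provenance sidecars are JSON.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .model import MISSING, ItemParameters
from .simulate import SimulatedDataset

_MAX_THRESHOLDS = 4


def items_to_frame(items) -> pd.DataFrame:
    rows = []
    for j, it in enumerate(items):
        row = {"item": j, "V": it.n_categories, "a": it.discrimination}
        for k in range(_MAX_THRESHOLDS):
            row[f"b_{k + 1}"] = (
                it.thresholds[k] if k < len(it.thresholds) else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_items(frame: pd.DataFrame) -> list[ItemParameters]:
    items = []
    for _, row in frame.sort_values("item").iterrows():
        V = int(row["V"])
        b = [row[f"b_{k + 1}"] for k in range(V - 1)]
        items.append(ItemParameters(V, float(row["a"]), np.asarray(b, dtype=float)))
    return items


def write_items(items, path) -> None:
    items_to_frame(items).to_csv(path, index=False)


def read_items(path) -> list[ItemParameters]:
    return frame_to_items(pd.read_csv(path))


def responses_to_frame(
    resp_ref: np.ndarray, resp_focal: np.ndarray
) -> pd.DataFrame:
    """Wide table: person id, group label, one column per item; missing
    cells are left blank."""
    def block(resp, label, offset):
        df = pd.DataFrame(
            resp.astype(float),
            columns=[f"item_{j}" for j in range(resp.shape[1])],
        )
        df = df.where(df >= 0)  # MISSING -> NaN -> blank in CSV
        df.insert(0, "group", label)
        df.insert(0, "person", np.arange(len(resp)) + offset)
        return df

    return pd.concat(
        [block(resp_ref, "reference", 0),
         block(resp_focal, "focal", len(resp_ref))],
        ignore_index=True,
    )


def frame_to_responses(frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    cols = [c for c in frame.columns if c.startswith("item_")]
    out = []
    for label in ("reference", "focal"):
        sub = frame.loc[frame["group"] == label, cols]
        arr = sub.to_numpy(dtype=float)
        arr = np.where(np.isnan(arr), MISSING, arr)
        out.append(arr.astype(int))
    return out[0], out[1]


def write_dataset(dataset: SimulatedDataset, path) -> None:
    responses_to_frame(dataset.resp_ref, dataset.resp_focal).to_csv(
        path, index=False
    )


def responses_to_long(resp: np.ndarray, group: str) -> pd.DataFrame:
    """Long table of observed responses only."""
    persons, items = np.nonzero(resp >= 0)
    return pd.DataFrame(
        {
            "person": persons,
            "group": group,
            "item": items,
            "response": resp[persons, items],
        }
    )


def write_provenance(record_dicts, path) -> None:
    with open(path, "w") as fh:
        json.dump(record_dicts, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
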