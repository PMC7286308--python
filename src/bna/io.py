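"""Text-format I/O: TSV matrices and time series, JSON sidecars and manifests.

Time series are stored frames-as-rows with a header of region labels;
connectomes are square TSVs with an optional header row.  Every artifact
written by the command-line tools gets a JSON run manifest beside it
(version, configuration, seed, input hashes) so outputs are reproducible
from their manifests alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectome import StructuralNetwork
from .preprocess import ROITimeSeries

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_connectome",
    "write_connectome",
    "write_manifest",
    "save_model",
    "load_model",
]


class FormatError(ValueError):
    """Malformed input file, with row/column diagnostics where possible."""


def _read_numeric_tsv(path: str | Path) -> tuple[np.ndarray, list[str] | None]:
    path = Path(path)
    try:
        first = pd.read_csv(path, sep="\t", header=None, nrows=1)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: cannot parse TSV: {exc}") from exc
    has_header = first.iloc[0].map(
        lambda v: isinstance(v, str) and not _is_number(v)
    ).any()
    df = pd.read_csv(path, sep="\t", header=0 if has_header else None)
    labels = [str(c) for c in df.columns] if has_header else None
    arr = df.to_numpy()
    if arr.dtype == object or not np.issubdtype(arr.dtype, np.number):
        coerced = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
        bad = np.argwhere(np.isnan(coerced) & ~df.isna().to_numpy())
        if bad.size:
            r, c = bad[0]
            row = int(r) + (2 if has_header else 1)
            raise FormatError(
                f"{path}: non-numeric value at row {row}, column {int(c) + 1}"
            )
        arr = coerced
    arr = arr.astype(float)
    if np.isnan(arr).any():
        r, c = np.argwhere(np.isnan(arr))[0]
        row = int(r) + (2 if has_header else 1)
        raise FormatError(f"{path}: missing value at row {row}, column {int(c) + 1}")
    return arr, labels


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def read_timeseries(path: str | Path, tr_s: float | None = None) -> ROITimeSeries:
    """Read a T x M TSV time series; TR comes from the sidecar unless given."""
    arr, labels = _read_numeric_tsv(path)
    side = Path(str(path) + ".json")
    meta = json.loads(side.read_text()) if side.exists() else {}
    if tr_s is None:
        tr_s = float(meta.get("tr_s", 0.72))
    return ROITimeSeries(
        data=arr,
        tr_s=tr_s,
        roi_labels=labels or meta.get("roi_labels", []),
        provenance=[f"read[{path}]"],
    )


def write_timeseries(ts: ROITimeSeries, path: str | Path, **meta) -> None:
    path = Path(path)
    pd.DataFrame(ts.data, columns=ts.roi_labels).to_csv(path, sep="\t", index=False)
    sidecar = {"tr_s": ts.tr_s, "provenance": ts.provenance, **meta}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def read_connectome(path: str | Path) -> StructuralNetwork:
    arr, labels = _read_numeric_tsv(path)
    side = Path(str(path) + ".json")
    meta = json.loads(side.read_text()) if side.exists() else {}
    return StructuralNetwork(
        weights=arr,
        roi_labels=labels or meta.get("roi_labels", []),
        spectrally_normalized=bool(meta.get("normalized", False)),
    )


def write_connectome(sn: StructuralNetwork, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(sn.weights, columns=sn.roi_labels).to_csv(path, sep="\t", index=False)
    Path(str(path) + ".json").write_text(
        json.dumps(
            {"roi_labels": sn.roi_labels, "normalized": sn.spectrally_normalized},
            indent=2,
        )
    )


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_path: str | Path, config: dict, inputs: list[str | Path]) -> None:
    manifest = {
        "version": __version__,
        "config": config,
        "input_hashes": {
            str(p): sha256_file(p) for p in inputs if Path(p).is_file()
        },
    }
    Path(str(out_path) + ".manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def save_model(model, path: str | Path) -> None:
    """Serialize a trained autoencoder: weights as npz + JSON manifest."""
    from .autoencoder import BrainNetworkAutoencoder  # local import, avoid cycle

    assert isinstance(model, BrainNetworkAutoencoder)
    path = Path(path)
    with open(path, "wb") as fh:
        np.savez(fh, **model.core_.params, __connectome__=model.connectome.weights)
    manifest = {
        "kind": model.kind,
        "k": model.k,
        "dt": model.dt,
        "n_layers": model.n_layers,
        "units": model.units,
        "dropout": model.dropout,
        "segment_len": model.segment_len,
        "std_floor": model.std_floor,
        "random_state": model.random_state,
        "connectome_sha256": hashlib.sha256(
            model.connectome.weights.tobytes()
        ).hexdigest(),
        "roi_labels": model.connectome.roi_labels,
        "loss_final": model.loss_history_[-1] if getattr(model, "loss_history_", None) else None,
    }
    Path(str(path) + ".json").write_text(json.dumps(manifest, indent=2))


def load_model(path: str | Path):
    from .autoencoder import BrainNetworkAutoencoder

    path = Path(path)
    manifest = json.loads(Path(str(path) + ".json").read_text())
    with np.load(path) as data:
        arrays = {k: data[k] for k in data.files}
    weights = arrays.pop("__connectome__")
    sn = StructuralNetwork(
        weights=weights,
        roi_labels=manifest.get("roi_labels", []),
        spectrally_normalized=True,
    )
    model = BrainNetworkAutoencoder(
        connectome=sn,
        kind=manifest["kind"],
        k=manifest["k"],
        dt=manifest["dt"],
        n_layers=manifest["n_layers"],
        units=manifest["units"],
        dropout=manifest["dropout"],
        segment_len=manifest["segment_len"],
        std_floor=manifest["std_floor"],
        random_state=manifest["random_state"],
    )
    model.initialize()
    for k, v in arrays.items():
        model.core_.params[k] = v
    return model
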