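"""Plain-text file round-tripping for signals, features, labels and results.

All files are delimited numeric text (inspectable, diff-able): raw signals
are rows-of-channels matrices, feature files carry a header naming channel
and band per column, labels are one integer per line, and run results are
JSON with the configuration echoed verbatim.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .boosting import BoostResult
from .domains import LabeledDomain
from .features import N_BAND_FEATURES, band_feature_names

__all__ = [
    "read_signal",
    "read_features",
    "write_features",
    "read_labels",
    "write_labels",
    "read_domain",
    "write_domain",
    "write_result",
    "read_result",
]


def read_signal(path: str | Path) -> np.ndarray:
    """Read a (channels x samples) delimited numeric matrix."""
    arr = np.loadtxt(path, ndmin=2)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{path}: non-finite values in signal")
    return arr


def write_features(path: str | Path, X: np.ndarray) -> None:
    """Write a feature matrix as TSV with channel/band column names."""
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    if X.shape[1] % N_BAND_FEATURES == 0:
        columns = band_feature_names(X.shape[1] // N_BAND_FEATURES)
    else:
        columns = [f"f{i}" for i in range(X.shape[1])]
    # %.17g round-trips float64 exactly
    pd.DataFrame(X, columns=columns).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_features(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    X = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError(f"{path}: non-finite feature values")
    return X


def write_labels(path: str | Path, y: np.ndarray) -> None:
    np.savetxt(path, np.asarray(y, dtype=int), fmt="%d")


def read_labels(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, dtype=int, ndmin=1)


def _label_path(feature_path: str | Path) -> Path:
    p = Path(feature_path)
    return p.with_suffix(".labels" + p.suffix)


def write_domain(feature_path: str | Path, domain: LabeledDomain) -> None:
    """Feature TSV plus a ``.labels`` sidecar when the domain is labeled."""
    write_features(feature_path, domain.X)
    if domain.y is not None:
        write_labels(_label_path(feature_path), domain.y)


def read_domain(feature_path: str | Path) -> LabeledDomain:
    X = read_features(feature_path)
    label_file = _label_path(feature_path)
    y = read_labels(label_file) if label_file.exists() else None
    return LabeledDomain(X, y)


def write_result(path: str | Path, result: BoostResult) -> None:
    """Serialize a boosting run: labels, per-iteration history, config echo."""
    payload = {
        "config": result.config,
        "labels": result.hf.tolist(),
        "test_indices": result.idx_test.tolist(),
        "borrow_indices": result.idx_borrow.tolist(),
        "eps_history": result.eps_history.tolist(),
        "beta_t_history": result.beta_t_history.tolist(),
        "beta": result.beta,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_result(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
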