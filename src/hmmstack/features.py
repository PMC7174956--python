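"""AATP feature encoding of profile-HMM emissions.

A protein's normalized ``L x 20`` emission matrix ``h`` is summarized by

* AAC (amino-acid composition, 20 features): the column means
  ``x_j = (1/L) * sum_i h[i, j]`` — the average probability of observing
  amino-acid type ``j`` across match states; and
* TPC (transition probability composition, 400 features): for each ordered
  amino-acid pair ``(i, j)`` the co-occurrence of type ``i`` at one position
  and type ``j`` at the next,
  ``y[i, j] = sum_k h[k, i] * h[k+1, j]``, normalized per row ``i`` so each
  row sums to 1 (rows with a zero denominator are left all-zero).  TPC
  injects first-order sequence-order information that AAC discards.

Their concatenation — AAC first, then TPC flattened row-major — is the
420-dimensional feature vector used by the classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .hhm_io import LabeledDataset, NormalizedProfile

__all__ = [
    "N_FEATURES",
    "AACVector",
    "TPCMatrix",
    "FeatureVector",
    "FeatureMatrix",
    "compute_aac",
    "compute_tpc",
    "encode_aatp",
    "batch_encode",
    "feature_names",
    "write_feature_csv",
    "read_feature_csv",
]

N_FEATURES = 420  # 20 AAC + 400 TPC


@dataclass
class AACVector:
    values: np.ndarray  # shape (20,)
    alphabet: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (20,):
            raise ValueError("AAC must have exactly 20 components")


@dataclass
class TPCMatrix:
    values: np.ndarray  # shape (20, 20), rows sum to 1 or are all-zero
    alphabet: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (20, 20):
            raise ValueError("TPC must be a 20 x 20 matrix")


@dataclass
class FeatureVector:
    protein_id: str
    values: np.ndarray  # shape (420,)
    alphabet: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"feature vector must have {N_FEATURES} components")
        if not np.isfinite(self.values).all():
            raise ValueError("feature vector contains non-finite values")


@dataclass
class FeatureMatrix:
    """A labeled batch of feature vectors (rows aligned with ``ids``)."""

    ids: list[str]
    X: np.ndarray
    y: Optional[np.ndarray] = None
    names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if len(self.ids) != self.X.shape[0]:
            raise ValueError("row count of X must equal number of ids")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=np.int64)
            if self.y.shape != (self.X.shape[0],):
                raise ValueError("y length must equal number of rows")
        if not self.names:
            self.names = [f"f{i}" for i in range(self.X.shape[1])]
        if len(self.names) != self.X.shape[1]:
            raise ValueError("names length must equal number of columns")

    def __len__(self) -> int:
        return self.X.shape[0]


def compute_aac(profile: NormalizedProfile) -> AACVector:
    """Column means of the normalized emission matrix (20 features)."""
    if profile.length < 1:
        raise ValueError("AAC requires a non-empty profile")
    return AACVector(values=profile.matrix.mean(axis=0), alphabet=profile.alphabet)


def compute_tpc(profile: NormalizedProfile) -> TPCMatrix:
    """Row-normalized adjacent-position co-emission matrix (20 x 20).

    ``numerator[i, j] = sum_{k=1..L-1} h[k, i] * h[k+1, j]`` and each row is
    divided by its own sum over ``j``.  Rows whose denominator is zero are
    left all-zero (no evidence for transitions out of type ``i``).
    Requires ``L >= 2``.
    """
    h = profile.matrix
    if profile.length < 2:
        raise ValueError(
            f"TPC requires a profile of length >= 2, got L={profile.length}"
        )
    num = h[:-1].T @ h[1:]  # (20, 20); entry (i, j) sums h[k,i]*h[k+1,j]
    denom = num.sum(axis=1)
    tpc = np.zeros_like(num)
    nz = denom > 0
    tpc[nz] = num[nz] / denom[nz, None]
    return TPCMatrix(values=tpc, alphabet=profile.alphabet)


def encode_aatp(profile: NormalizedProfile) -> FeatureVector:
    """Concatenate AAC (20) and row-major TPC (400) into one 420-vector."""
    aac = compute_aac(profile)
    tpc = compute_tpc(profile)
    return FeatureVector(
        protein_id=profile.protein_id,
        values=np.concatenate([aac.values, tpc.values.ravel()]),
        alphabet=profile.alphabet,
    )


def feature_names(alphabet: str) -> list[str]:
    """Deterministic column names: AAC_<aa>, then TPC_<aa_i>_<aa_j> row-major."""
    names = [f"AAC_{a}" for a in alphabet]
    names += [f"TPC_{a}_{b}" for a in alphabet for b in alphabet]
    return names


def batch_encode(dataset: LabeledDataset) -> FeatureMatrix:
    """Encode every dataset entry; row order follows the dataset order."""
    if len(dataset) == 0:
        raise ValueError("cannot encode an empty dataset")
    alphabet = dataset.entries[0][1].alphabet
    rows, ids, labels = [], [], []
    for pid, prof, label in dataset:
        if prof.alphabet != alphabet:
            raise ValueError(
                f"profile {pid!r} uses alphabet {prof.alphabet!r}, "
                f"expected {alphabet!r}"
            )
        try:
            rows.append(encode_aatp(prof).values)
        except ValueError as exc:
            raise ValueError(f"encoding failed for {pid!r}: {exc}") from exc
        ids.append(pid)
        labels.append(label)
    return FeatureMatrix(
        ids=ids,
        X=np.vstack(rows),
        y=np.array(labels, dtype=np.int64),
        names=feature_names(alphabet),
    )


def write_feature_csv(matrix: FeatureMatrix, sink: Union[str, Path]) -> None:
    """Write a feature matrix as CSV: id column, 420 features, optional label."""
    df = pd.DataFrame(matrix.X, columns=matrix.names)
    df.insert(0, "id", matrix.ids)
    if matrix.y is not None:
        df["label"] = matrix.y
    df.to_csv(sink, index=False, float_format="%.17g")


def read_feature_csv(source: Union[str, Path]) -> FeatureMatrix:
    """Read a feature CSV written by :func:`write_feature_csv`.

    Validates the header (id column, 420 feature columns, optional trailing
    label column) and that every feature cell is numeric.
    """
    df = pd.read_csv(source, float_precision="round_trip")
    cols = list(df.columns)
    if not cols or cols[0] != "id":
        raise ValueError("first column must be 'id'")
    has_label = cols[-1] == "label"
    feat_cols = cols[1:-1] if has_label else cols[1:]
    if len(feat_cols) != N_FEATURES:
        raise ValueError(
            f"expected {N_FEATURES} feature columns, found {len(feat_cols)}"
        )
    X = df[feat_cols].to_numpy()
    if not np.issubdtype(X.dtype, np.number) or not np.isfinite(X).all():
        raise ValueError("feature columns contain non-numeric or non-finite cells")
    y = None
    if has_label:
        y_raw = df["label"].to_numpy()
        if not np.isin(y_raw, (0, 1)).all():
            raise ValueError("label column must contain only 0/1")
        y = y_raw.astype(np.int64)
    return FeatureMatrix(
        ids=[str(i) for i in df["id"]], X=X.astype(np.float64), y=y, names=feat_cols
    )
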