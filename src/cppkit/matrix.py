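"""The feature matrix: the single in-memory currency between pipeline stages.

A :class:`FeatureMatrix` is a thin, validated wrapper around a float array
with row ids, an ordered feature-name list, and an optional binary label
vector.  Column order is significant everywhere in the package: models refuse
matrices whose columns differ in name or order from the ones they were
trained on, so no silent re-alignment ever happens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ColumnMismatchError, MissingFeatureError


@dataclass
class FeatureMatrix:
    ids: list[str]
    names: list[str]
    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ColumnMismatchError("values must be a 2-D array")
        n, d = self.values.shape
        if len(self.ids) != n:
            raise ColumnMismatchError(f"{len(self.ids)} ids for {n} rows")
        if len(self.names) != d:
            raise ColumnMismatchError(f"{len(self.names)} names for {d} columns")
        if len(set(self.names)) != d:
            raise ColumnMismatchError("feature names are not unique")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ColumnMismatchError("label vector length differs from row count")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.names.index(name)
        except ValueError:
            raise MissingFeatureError(f"feature {name!r} not in matrix") from None
        return self.values[:, j]

    def subset(self, names: list[str]) -> "FeatureMatrix":
        """Return a copy restricted to ``names``, in exactly that order."""
        missing = [n for n in names if n not in set(self.names)]
        if missing:
            raise MissingFeatureError(f"features absent from matrix: {missing[:5]}")
        index = {n: j for j, n in enumerate(self.names)}
        cols = [index[n] for n in names]
        return FeatureMatrix(
            ids=list(self.ids),
            names=list(names),
            values=self.values[:, cols].copy(),
            labels=None if self.labels is None else self.labels.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.names)
        frame.insert(0, "id", self.ids)
        if self.labels is not None:
            frame["label"] = self.labels
        return frame

    def equals(self, other: "FeatureMatrix", rtol: float = 1e-12) -> bool:
        if self.ids != other.ids or self.names != other.names:
            return False
        if (self.labels is None) != (other.labels is None):
            return False
        if self.labels is not None and not np.array_equal(self.labels, other.labels):
            return False
        return np.allclose(self.values, other.values, rtol=rtol, atol=0.0)
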