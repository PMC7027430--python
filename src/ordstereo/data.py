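"""Ordinal datasets and delimited-text I/O.

An :class:`OrdinalDataset` is the universal input of the package: an
integer-coded ordinal response ``y`` with levels ``1..q`` plus a real
covariate matrix ``X``.  CSV reading assigns the 1-based codes either from
an explicit ``level_order`` or from the ascending sorted unique values of
the response column, and records the mapping so every run is reproducible
from its logged configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["OrdinalDataset", "read_ordinal_csv", "write_ordinal_csv"]


@dataclass
class OrdinalDataset:
    """Ordinal response vector plus covariate matrix.

    Parameters
    ----------
    y
        Integer response codes, each in ``{1, ..., q}``; the first level is
        the baseline category of every multinomial-logit family.
    X
        ``(n, p)`` real covariate matrix (continuous or 0/1 binary columns).
    q
        Number of ordinal levels, at least 2.
    column_names
        Covariate labels; defaults to ``x1..xp``.
    """

    y: np.ndarray
    X: np.ndarray
    q: int
    column_names: list[str] | None = None
    warnings: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != self.y.shape[0] and self.X.shape[1] == self.y.shape[0]:
            self.X = self.X.T
        if self.q < 2:
            raise ValueError("an ordinal response needs q >= 2 levels")
        if self.y.ndim != 1:
            raise ValueError("y must be a vector")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but y has {self.y.shape[0]} entries"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite entries")
        if self.y.min() < 1 or self.y.max() > self.q:
            raise ValueError(f"response codes must lie in 1..{self.q}")
        counts = np.bincount(self.y, minlength=self.q + 1)[1:]
        empty = np.flatnonzero(counts == 0) + 1
        if empty.size:
            self.warnings.append(
                f"levels {empty.tolist()} have no observations; their intercepts "
                "are weakly identified"
            )
        if self.column_names is None:
            self.column_names = [f"x{j + 1}" for j in range(self.p)]
        if len(self.column_names) != self.p:
            raise ValueError("column_names length does not match X columns")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def level_counts(self) -> np.ndarray:
        """Observation count per ordinal level (length ``q``)."""
        return np.bincount(self.y, minlength=self.q + 1)[1:]

    def to_frame(self, response_column: str = "y") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.column_names)
        df.insert(0, response_column, self.y)
        return df

    def with_interaction(self, col1: int = 0, col2: int = 1) -> "OrdinalDataset":
        """Return a copy whose design gains the product column ``x1:x2``."""
        name = f"{self.column_names[col1]}:{self.column_names[col2]}"
        X = np.column_stack([self.X, self.X[:, col1] * self.X[:, col2]])
        return OrdinalDataset(
            y=self.y.copy(), X=X, q=self.q,
            column_names=list(self.column_names) + [name],
            metadata=dict(self.metadata),
        )

    def drop_column(self, name: str) -> "OrdinalDataset":
        if name not in self.column_names:
            raise KeyError(f"no covariate named {name!r}")
        j = self.column_names.index(name)
        keep = [c for c in range(self.p) if c != j]
        return OrdinalDataset(
            y=self.y.copy(), X=self.X[:, keep], q=self.q,
            column_names=[self.column_names[c] for c in keep],
            metadata=dict(self.metadata),
        )


def read_ordinal_csv(
    path,
    response_column: str,
    level_order: list | None = None,
    covariates: list[str] | None = None,
) -> OrdinalDataset:
    """Read an ordinal dataset from delimited text.

    The response is mapped to integer codes ``1..q`` by ``level_order`` when
    given, otherwise by the ascending sort of its unique values.  String
    covariates with exactly two levels are auto-coded 0/1; the mappings are
    stored in ``dataset.metadata``.
    """
    df = pd.read_csv(path)
    if response_column not in df.columns:
        raise KeyError(f"response column {response_column!r} not found in {path}")
    resp = df[response_column]
    if level_order is None:
        levels = sorted(resp.dropna().unique().tolist())
    else:
        levels = list(level_order)
        unseen = set(resp.dropna().unique()) - set(levels)
        if unseen:
            raise ValueError(f"response values {sorted(map(str, unseen))} not in level_order")
    mapping = {lev: k + 1 for k, lev in enumerate(levels)}
    y = resp.map(mapping)
    if y.isna().any():
        raise ValueError("response column contains missing values")
    y = y.to_numpy(dtype=int)

    cov_cols = covariates if covariates is not None else [
        c for c in df.columns if c != response_column
    ]
    cov_maps: dict[str, dict] = {}
    X_cols = []
    for c in cov_cols:
        col = df[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            uniq = sorted(col.dropna().unique().tolist())
            if len(uniq) != 2:
                raise ValueError(
                    f"covariate {c!r} is non-numeric with {len(uniq)} levels; "
                    "provide a numeric coding"
                )
            cmap = {uniq[0]: 0.0, uniq[1]: 1.0}
            cov_maps[c] = cmap
            X_cols.append(col.map(cmap).to_numpy(dtype=float))
        else:
            X_cols.append(col.to_numpy(dtype=float))
    X = np.column_stack(X_cols) if X_cols else np.empty((len(y), 0))
    return OrdinalDataset(
        y=y, X=X, q=len(levels), column_names=list(cov_cols),
        metadata={
            "response_column": response_column,
            "level_mapping": {str(k): v for k, v in mapping.items()},
            "covariate_codings": {k: {str(a): b for a, b in v.items()}
                                  for k, v in cov_maps.items()},
            "source": str(path),
        },
    )


def write_ordinal_csv(data: OrdinalDataset, path, response_column: str = "y") -> None:
    """Write the dataset back to CSV (round-trips with :func:`read_ordinal_csv`)."""
    data.to_frame(response_column).to_csv(path, index=False)
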