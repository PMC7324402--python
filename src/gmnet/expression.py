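"""Gene-by-position expression matrices.

The container is a thin, validated wrapper around a pandas DataFrame with
genes as rows (unique IDs) and ordered positions along the tissue axis as
columns.  Values are non-negative FPKM-like floats.  Column order is
explicit metadata -- positions are never reordered by label sorting.

On disk the format is TSV: first row position labels, first column gene
IDs.  Lines starting with ``#`` are treated as comments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError


@dataclass
class ExpressionMatrix:
    values: pd.DataFrame
    batch_label: str = ""

    def __post_init__(self) -> None:
        df = self.values
        if not isinstance(df, pd.DataFrame):
            df = pd.DataFrame(df)
            self.values = df
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise InvalidParameterError(f"duplicate gene IDs: {dups}")
        if df.shape[1] < 2:
            raise InvalidParameterError("need at least 2 positions")
        arr = df.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise InvalidParameterError("expression values contain NaN")
        if (arr < 0).any():
            raise InvalidParameterError("expression values must be >= 0")
        self.values = df.astype(float)

    # -- basic introspection -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def position_labels(self) -> list[str]:
        return [str(p) for p in self.values.columns]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_positions(self) -> int:
        return self.values.shape[1]

    def subset(self, genes: Iterable[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` (kept in the given order)."""
        genes = list(genes)
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise InvalidParameterError(
                f"genes missing from batch {self.batch_label!r}: {missing}"
            )
        return ExpressionMatrix(self.values.loc[genes], self.batch_label)

    def select_positions(
        self, labels: Sequence[str], batch_label: str | None = None
    ) -> "ExpressionMatrix":
        missing = [p for p in labels if p not in self.values.columns]
        if missing:
            raise InvalidParameterError(f"unknown positions: {missing}")
        return ExpressionMatrix(
            self.values.loc[:, list(labels)],
            self.batch_label if batch_label is None else batch_label,
        )

    # -- IO ------------------------------------------------------------------
    def to_tsv(self, path: str | Path, comment: str | None = None) -> None:
        path = Path(path)
        with path.open("w") as fh:
            if comment:
                for line in comment.splitlines():
                    fh.write(f"# {line}\n")
            self.values.to_csv(fh, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path, batch_label: str = "") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(df, batch_label)
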