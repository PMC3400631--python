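"""Gene expression matrix container (genes × conditions)."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """A genes × conditions real-valued expression matrix.

    Values must be finite (imputation or row dropping happens at I/O time,
    see :mod:`dbomm.io`); identifiers must be unique.
    """

    values: np.ndarray
    gene_ids: list[str]
    condition_ids: list[str]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.condition_ids = [str(c) for c in self.condition_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError("gene_ids length must equal the number of rows")
        if len(self.condition_ids) != self.values.shape[1]:
            raise ValueError("condition_ids length must equal the number of columns")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if len(set(self.condition_ids)) != len(self.condition_ids):
            raise ValueError("condition_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (impute at load time)")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    def row(self, gene_id: str) -> np.ndarray:
        """Expression profile of one gene across all conditions."""
        try:
            return self.values[self._index[gene_id]]
        except KeyError:
            raise KeyError(f"unknown gene id: {gene_id!r}") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.condition_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            values=frame.to_numpy(dtype=np.float64),
            gene_ids=[str(i) for i in frame.index],
            condition_ids=[str(c) for c in frame.columns],
        )
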