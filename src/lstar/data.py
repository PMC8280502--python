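"""Wide-format panel data container and CSV I/O.

One row per dyad; columns named ``indicator<i>_rater<k>_t<l>`` in the
canonical rater-major, occasion-next, indicator-last order.  Missing cells
are NaN; rows that are entirely missing are dropped (and counted) because
they carry no likelihood information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spec import ModelSpec

__all__ = ["PanelData", "read_panel_csv", "write_panel_csv"]

log = logging.getLogger("lstar")


@dataclass
class PanelData:
    """Observed dyadic panel: values (NaN = missing), mask, dyad ids."""

    values: np.ndarray  # (n, p) float, NaN where missing
    missing_mask: np.ndarray  # (n, p) bool, True where missing
    dyad_id: np.ndarray  # (n,)
    column_names: list = field(default_factory=list)
    n_dropped: int = 0  # all-missing rows removed on construction

    @classmethod
    def from_array(cls, values, dyad_id=None, column_names=None) -> "PanelData":
        values = np.array(values, dtype=float, copy=True)
        if values.ndim != 2:
            raise ValueError("panel values must be 2-dimensional")
        mask = np.isnan(values)
        keep = ~mask.all(axis=1)
        n_dropped = int((~keep).sum())
        if n_dropped:
            log.info("dropping %d rows with no observed values", n_dropped)
        if dyad_id is None:
            dyad_id = np.arange(values.shape[0])
        dyad_id = np.asarray(dyad_id)
        if column_names is None:
            column_names = [f"col{j+1}" for j in range(values.shape[1])]
        return cls(
            values=values[keep],
            missing_mask=mask[keep],
            dyad_id=dyad_id[keep],
            column_names=list(column_names),
            n_dropped=n_dropped,
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, spec: ModelSpec | None = None,
                   id_column: str = "dyad_id") -> "PanelData":
        frame = frame.copy()
        ids = frame.pop(id_column).to_numpy() if id_column in frame else None
        if spec is not None:
            cols = spec.column_names()
            missing = [c for c in cols if c not in frame.columns]
            if missing:
                raise ValueError(f"data lacks expected columns: {missing}")
            frame = frame[cols]
        return cls.from_array(frame.to_numpy(dtype=float), dyad_id=ids,
                              column_names=list(frame.columns))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def check_spec(self, spec: ModelSpec) -> None:
        if self.n_columns != spec.n_observed:
            raise ValueError(
                f"data has {self.n_columns} columns but the spec implies "
                f"{spec.n_observed}"
            )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.column_names)
        frame.insert(0, "dyad_id", self.dyad_id)
        return frame

    def subsample(self, rows: np.ndarray) -> "PanelData":
        """Row-indexed view copy (used by the dyad bootstrap)."""
        return PanelData(
            values=self.values[rows],
            missing_mask=self.missing_mask[rows],
            dyad_id=self.dyad_id[rows],
            column_names=self.column_names,
        )


def read_panel_csv(path, spec: ModelSpec | None = None) -> PanelData:
    """Read wide CSV; empty fields or ``NA`` are missing values."""
    frame = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    return PanelData.from_frame(frame, spec=spec)


def write_panel_csv(path, data: PanelData) -> None:
    data.to_frame().to_csv(path, index=False, na_rep="NA")
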