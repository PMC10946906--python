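"""In-memory containers shared across the pipeline stages.

Expression data are held as a genes x samples :class:`pandas.DataFrame`
paired with a sample design (group or dose label per sample); screening-plate
data are held as tidy frames of wells, per-well per-gene measurements, and
compound annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "PlateLibrary", "ROLES"]

ROLES = ("compound", "positive_control", "vehicle")


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of normalized, non-negative expression values.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    design
        Series mapping sample id -> group label (e.g. ``treated``/``vehicle``)
        or dose label; must cover every sample column.
    """

    values: pd.DataFrame
    design: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        missing = self.values.columns.difference(self.design.index)
        if len(missing):
            raise ValueError(f"sample missing from design: {missing[0]!r}")
        # keep design aligned to the column order, dropping unused entries
        self.design = self.design.loc[self.values.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def group_columns(self, label: str) -> pd.Index:
        """Sample ids carrying the given design label."""
        return self.design.index[self.design == label]

    def group_values(self, label: str) -> np.ndarray:
        """Genes x samples array restricted to one design group."""
        return self.values.loc[:, self.group_columns(label)].to_numpy()

    def labels(self) -> list[str]:
        """Distinct design labels in order of first appearance."""
        return list(dict.fromkeys(self.design))


@dataclass
class PlateLibrary:
    """A plate-structured compound screen.

    ``wells`` has columns ``plate_id, well_id, role, compound_id`` (compound_id
    empty for control wells); ``measurements`` has
    ``plate_id, well_id, gene, value``; ``annotations`` has
    ``compound_id, name, approved, withdrawn, black_box``.
    """

    wells: pd.DataFrame
    measurements: pd.DataFrame
    annotations: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["compound_id", "name", "approved", "withdrawn", "black_box"]))

    def __post_init__(self) -> None:
        bad = set(self.wells["role"]) - set(ROLES)
        if bad:
            raise ValueError(f"unknown well role(s): {sorted(bad)}")
        is_compound = self.wells["role"] == "compound"
        cid = self.wells["compound_id"].fillna("")
        if (is_compound & (cid == "")).any():
            raise ValueError("compound well without a compound_id")
        if (~is_compound & (cid != "")).any():
            raise ValueError("control well carries a compound_id")
        for plate, sub in self.wells.groupby("plate_id"):
            roles = set(sub["role"])
            if "vehicle" not in roles or "positive_control" not in roles:
                raise ValueError(
                    f"plate {plate!r} lacks vehicle or positive-control wells")

    @property
    def plate_ids(self) -> list[str]:
        return sorted(self.wells["plate_id"].unique())

    @property
    def compound_ids(self) -> list[str]:
        ids = self.wells.loc[self.wells["role"] == "compound", "compound_id"]
        return sorted(ids.unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.measurements["gene"].unique())

    def plate_measurements(self, plate_id: str) -> pd.DataFrame:
        """Measurements of one plate joined with the well roles."""
        m = self.measurements[self.measurements["plate_id"] == plate_id]
        w = self.wells[self.wells["plate_id"] == plate_id]
        return m.merge(w[["well_id", "role", "compound_id"]], on="well_id")
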