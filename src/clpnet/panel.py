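"""Two-wave wide-format panel data container.

A panel holds one row per participant and, for each construct (node), one
column per wave named ``<node>_t1`` and ``<node>_t2``, plus covariate columns
(e.g. ``age``) and an optional grouping column (e.g. ``gender``). Missingness
is tracked in an explicit boolean mask aligned with the value table so that
downstream stages (imputation, estimation) never have to guess which cells
were observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

WAVES = ("t1", "t2")


class ClpnetError(Exception):
    """Base class for errors raised by this package."""


class InputError(ClpnetError):
    """Invalid user input: malformed files, bad schemas, out-of-range options."""


def node_column(node: str, wave: str) -> str:
    if wave not in WAVES:
        raise InputError(f"unknown wave {wave!r}; expected one of {WAVES}")
    return f"{node}_{wave}"


@dataclass
class PanelDataset:
    """Participant-by-variable table for two waves with covariates.

    Parameters
    ----------
    frame:
        Wide-format table; construct columns are ``<node>_t1`` / ``<node>_t2``.
    node_names:
        Construct labels, one per node of the network.
    covariates:
        Names of covariate columns (continuous or 0/1-coded categorical).
    group_col:
        Optional grouping column (must be complete if present).
    mask:
        Boolean frame, same shape/index/columns as ``frame``; ``True`` marks a
        missing cell. Built from NA cells when not supplied.
    """

    frame: pd.DataFrame
    node_names: list[str]
    covariates: list[str] = field(default_factory=list)
    group_col: str | None = None
    mask: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.node_names = list(self.node_names)
        self.covariates = list(self.covariates)
        missing_cols = [c for c in self.required_columns() if c not in self.frame.columns]
        if missing_cols:
            raise InputError(f"panel is missing required columns: {missing_cols}")
        dup = self.frame.columns[self.frame.columns.duplicated()].tolist()
        if dup:
            raise InputError(f"duplicate columns in panel: {dup}")
        if self.mask is None:
            self.mask = self.frame.isna()
        else:
            if self.mask.shape != self.frame.shape:
                raise InputError(
                    f"mask shape {self.mask.shape} does not match values {self.frame.shape}"
                )
            self.mask = self.mask.astype(bool)
            self.mask.index = self.frame.index
        if self.group_col is not None:
            if self.group_col not in self.frame.columns:
                raise InputError(f"group column {self.group_col!r} not in panel")
            if self.frame[self.group_col].isna().any():
                raise InputError(f"group column {self.group_col!r} has missing labels")

    # -- schema helpers -----------------------------------------------------

    def required_columns(self) -> list[str]:
        cols = [node_column(n, w) for n in self.node_names for w in WAVES]
        return cols + self.covariates

    def node_columns(self, wave: str | None = None) -> list[str]:
        waves = WAVES if wave is None else (wave,)
        return [node_column(n, w) for w in waves for n in self.node_names]

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def p(self) -> int:
        return len(self.node_names)

    def groups(self) -> list:
        if self.group_col is None:
            return []
        return sorted(self.frame[self.group_col].unique().tolist())

    def has_missing(self) -> bool:
        return bool(self.mask[self.node_columns()].to_numpy().any())

    # -- transforms ---------------------------------------------------------

    def copy(self) -> "PanelDataset":
        return PanelDataset(
            frame=self.frame.copy(),
            node_names=list(self.node_names),
            covariates=list(self.covariates),
            group_col=self.group_col,
            mask=self.mask.copy(),
        )

    def subset(self, row_mask: np.ndarray) -> "PanelDataset":
        """Row subset (boolean or integer indexer), preserving the mask."""
        return PanelDataset(
            frame=self.frame.iloc[row_mask].reset_index(drop=True),
            node_names=list(self.node_names),
            covariates=list(self.covariates),
            group_col=self.group_col,
            mask=self.mask.iloc[row_mask].reset_index(drop=True),
        )

    def group_subset(self, level) -> "PanelDataset":
        if self.group_col is None:
            raise InputError("panel has no group column")
        sel = (self.frame[self.group_col] == level).to_numpy()
        if not sel.any():
            raise InputError(f"group level {level!r} not present")
        return self.subset(sel)
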