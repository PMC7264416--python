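"""Core in-memory containers shared across the pipeline.

An :class:`OmicsMatrix` holds one omics layer as a features x samples
table with a value-domain contract per omics type; a :class:`SurvivalTable`
holds per-sample overall survival, the event flag and clinical covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

OMICS_TYPES = ("gene", "exon", "methylation", "mutation")

#: columns every survival table must carry
SURVIVAL_COLUMNS = ("os_days", "event")


class DomainError(ValueError):
    """A matrix value violates the declared omics value domain."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()][0]
        raise ValueError(f"duplicate {what} id: {dup!r}")


def check_domain(values: pd.DataFrame, omics_type: str) -> None:
    """Raise :class:`DomainError` naming the offending cell if any value
    falls outside the omics type's domain (methylation beta in [0,1],
    mutation in {0,1}, expression layers non-negative)."""
    arr = values.to_numpy(dtype=float)
    if np.isnan(arr).any():
        r, c = np.argwhere(np.isnan(arr))[0]
        raise DomainError(
            f"missing value at feature {values.index[r]!r}, sample {values.columns[c]!r}"
        )
    if omics_type == "methylation":
        bad = (arr < 0) | (arr > 1)
    elif omics_type == "mutation":
        bad = (arr != 0) & (arr != 1)
    else:  # gene / exon expression: non-negative
        bad = arr < 0
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise DomainError(
            f"{omics_type} value {arr[r, c]!r} out of domain at feature "
            f"{values.index[r]!r}, sample {values.columns[c]!r}"
        )


@dataclass
class OmicsMatrix:
    """One omics layer: features (rows) x samples (columns).

    Parameters
    ----------
    omics_type
        One of ``gene``, ``exon``, ``methylation``, ``mutation``.
    data
        Feature-by-sample numeric table. Feature and sample ids must be
        unique; values must satisfy the omics type's domain.
    """

    omics_type: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.omics_type not in OMICS_TYPES:
            raise ValueError(
                f"unknown omics_type {self.omics_type!r}; expected one of {OMICS_TYPES}"
            )
        _check_unique(self.data.index, "feature")
        _check_unique(self.data.columns, "sample")
        check_domain(self.data, self.omics_type)

    @property
    def feature_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    def restrict_samples(self, sample_ids) -> "OmicsMatrix":
        return OmicsMatrix(self.omics_type, self.data.loc[:, list(sample_ids)])


@dataclass
class SurvivalTable:
    """Per-sample survival outcome plus optional clinical covariates.

    ``data`` is indexed by sample id and carries at least ``os_days``
    (non-negative) and ``event`` (1 = death observed, 0 = censored).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        for col in SURVIVAL_COLUMNS:
            if col not in self.data.columns:
                raise ValueError(f"survival table lacks required column {col!r}")
        os_days = self.data["os_days"].to_numpy(dtype=float)
        if np.isnan(os_days).any() or (os_days < 0).any():
            raise ValueError("os_days must be non-negative and non-missing")
        ev = self.data["event"].to_numpy(dtype=float)
        if not np.isin(ev, (0, 1)).all():
            raise ValueError("event flag must be 0/1")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def os_days(self) -> pd.Series:
        return self.data["os_days"].astype(float)

    @property
    def event(self) -> pd.Series:
        return self.data["event"].astype(int)

    @property
    def covariates(self) -> list:
        return [c for c in self.data.columns if c not in SURVIVAL_COLUMNS]

    def restrict_samples(self, sample_ids) -> "SurvivalTable":
        return SurvivalTable(self.data.loc[list(sample_ids)])
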