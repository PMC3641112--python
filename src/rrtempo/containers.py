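"""Core in-memory containers shared by every pipeline stage.

The study design is fixed: three practice groups (N1 novices, N2 the same
subjects after short-term training, M independent long-term practitioners)
sampled at three timepoints (T0 before, T1 immediately after, T2 fifteen
minutes after a single 20-minute session). An :class:`ExpressionMatrix`
carries log-scale expression (genes x samples) together with per-sample
(subject, group, timepoint) metadata; :class:`GeneSetCollection` holds named
gene sets; molecular-interaction networks are plain :class:`networkx.Graph`
objects (simple, undirected).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

GROUPS = ("N1", "N2", "M")
TIMEPOINTS = ("T0", "T1", "T2")

#: canonical condition order used for 9-point temporal profiles
CONDITIONS = tuple((g, t) for g in GROUPS for t in TIMEPOINTS)

META_COLUMNS = ("subject", "group", "timepoint")


class ValidationError(ValueError):
    """Raised when a container or parsed file violates its invariants."""


@dataclass
class ExpressionMatrix:
    """Log-intensity grid (genes x samples) plus per-sample design metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier with one column per sample.
    samples
        DataFrame indexed by sample identifier with columns
        ``subject``, ``group`` (N1/N2/M) and ``timepoint`` (T0/T1/T2).
        May be ``None`` for a bare matrix (e.g. straight from a GCT file
        before a design table is attached); stages that need the design
        will refuse to run without it.
    """

    values: pd.DataFrame
    samples: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValidationError(f"duplicate gene identifier: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValidationError(f"duplicate sample identifier: {dup!r}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr.astype(float)).all():
            raise ValidationError("expression values must be finite")
        if self.samples is not None:
            self._check_design()

    def _check_design(self) -> None:
        meta = self.samples
        missing = [c for c in META_COLUMNS if c not in meta.columns]
        if missing:
            raise ValidationError(f"sample metadata missing columns: {missing}")
        if set(meta.index) != set(self.values.columns):
            raise ValidationError(
                "sample metadata does not cover exactly the matrix samples"
            )
        if meta[list(META_COLUMNS)].isna().any().any():
            raise ValidationError("incomplete sample metadata")
        bad_g = set(meta["group"]) - set(GROUPS)
        if bad_g:
            raise ValidationError(f"unknown group labels: {sorted(bad_g)}")
        bad_t = set(meta["timepoint"]) - set(TIMEPOINTS)
        if bad_t:
            raise ValidationError(f"unknown timepoints: {sorted(bad_t)}")
        # keep metadata in matrix column order
        self.samples = meta.loc[self.values.columns]

    # -- convenience accessors -------------------------------------------

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def require_design(self) -> pd.DataFrame:
        if self.samples is None:
            raise ValidationError("this operation needs sample metadata")
        return self.samples

    def select_samples(self, group: str | None = None,
                       timepoint: str | None = None) -> list[str]:
        """Sample ids in a design cell, in matrix column order."""
        meta = self.require_design()
        mask = pd.Series(True, index=meta.index)
        if group is not None:
            mask &= meta["group"] == group
        if timepoint is not None:
            mask &= meta["timepoint"] == timepoint
        return list(meta.index[mask])

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.samples)

    def attach_design(self, design: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values, design)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


class GeneSetCollection:
    """Ordered collection of uniquely named gene sets (GMT semantics)."""

    def __init__(self, sets: Iterable[GeneSet]):
        self._sets: list[GeneSet] = list(sets)
        names = [s.name for s in self._sets]
        if len(set(names)) != len(names):
            dup = next(n for i, n in enumerate(names) if n in names[:i])
            raise ValidationError(f"duplicate gene set name: {dup!r}")
        self._by_name = {s.name: s for s in self._sets}

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [s.name for s in self._sets]

    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self._sets:
            out |= s.genes
        return frozenset(out)
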