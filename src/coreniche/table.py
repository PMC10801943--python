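"""Core in-memory containers: abundance table, sample metadata, taxonomy.

The canonical orientation everywhere in the package is samples x taxa.
Detection for presence/absence is ``count > 0`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RANKS = ("Kingdom", "Phylum", "Class", "Order", "Family", "Genus", "Species")


class TableError(ValueError):
    """Raised when a table violates its structural invariants."""


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise TableError(f"duplicate {what}: {dups}")


@dataclass
class AbundanceTable:
    """Non-negative integer counts for taxa across samples.

    Parameters
    ----------
    counts : array-like, shape (n_samples, n_taxa)
        Non-negative integer counts, samples as rows.
    sample_ids : sequence of str
        Unique, ordered sample identifiers (row labels).
    taxon_ids : sequence of str
        Unique, ordered taxon identifiers (column labels).
    """

    counts: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    taxon_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise TableError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.rint(self.counts)
            if not np.allclose(self.counts, as_int, atol=0, rtol=0):
                raise TableError("counts contain non-integral values")
            self.counts = as_int.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise TableError("counts contain negative entries")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.taxon_ids, "taxon ids")
        if self.counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise TableError(
                f"shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )

    # -- basic views ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.taxon_ids,
        )

    def depths(self) -> pd.Series:
        """Total read count per sample."""
        return pd.Series(self.counts.sum(axis=1), index=self.sample_ids, name="depth")

    def relative_abundance(self) -> np.ndarray:
        """Per-sample relative abundances; zero-depth samples stay all-zero."""
        tot = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(tot > 0, self.counts / tot, 0.0)
        return rel

    def presence(self) -> np.ndarray:
        return self.counts > 0

    # -- subsetting ----------------------------------------------------

    def select_samples(self, keep) -> "AbundanceTable":
        idx = [self.sample_ids.index(s) for s in keep]
        return AbundanceTable(self.counts[idx, :], list(keep), list(self.taxon_ids))

    def select_taxa(self, keep) -> "AbundanceTable":
        pos = {t: j for j, t in enumerate(self.taxon_ids)}
        idx = [pos[t] for t in keep]
        return AbundanceTable(self.counts[:, idx], list(self.sample_ids), list(keep))

    def __eq__(self, other) -> bool:
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.taxon_ids == other.taxon_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class SampleMetadata:
    """Categorical covariates per sample plus a negative-control flag."""

    data: pd.DataFrame
    control_column: str = "is_negative_control"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise TableError("duplicate sample ids in metadata")
        self.data = self.data.copy()
        self.data.index = self.data.index.astype(str)
        if self.control_column in self.data.columns:
            col = self.data[self.control_column]
            if col.dtype != bool:
                self.data[self.control_column] = (
                    col.astype(str).str.strip().str.lower()
                    .isin({"true", "1", "yes", "t", "y"})
                )
        else:
            self.data[self.control_column] = False

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.data.columns if c != self.control_column]

    def is_control(self) -> pd.Series:
        return self.data[self.control_column].astype(bool)

    def control_ids(self) -> list[str]:
        return list(self.data.index[self.is_control()])

    def levels(self, covariate: str) -> list[str]:
        if covariate not in self.data.columns:
            raise KeyError(f"unknown covariate {covariate!r}")
        return sorted(self.data[covariate].dropna().astype(str).unique())

    def groups(self, covariate: str, samples=None) -> pd.Series:
        """Group label per sample, restricted to ``samples`` if given."""
        if covariate not in self.data.columns:
            raise KeyError(f"unknown covariate {covariate!r}")
        s = self.data[covariate].astype(str)
        if samples is not None:
            missing = [x for x in samples if x not in self.data.index]
            if missing:
                raise KeyError(f"samples missing from metadata: {missing}")
            s = s.loc[list(samples)]
        return s

    def subset(self, samples) -> "SampleMetadata":
        return SampleMetadata(self.data.loc[list(samples)], self.control_column)


@dataclass
class TaxonomyTable:
    """7-rank lineages per taxon; unknown ranks stored as empty strings."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.data.columns]
        if missing:
            raise TableError(f"taxonomy missing ranks: {missing}")
        self.data = self.data[list(RANKS)].fillna("").astype(str).copy()
        self.data.index = self.data.index.astype(str)
        if self.data.index.has_duplicates:
            raise TableError("duplicate taxon ids in taxonomy")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    def lineage(self, taxon_id: str) -> dict[str, str]:
        return self.data.loc[taxon_id].to_dict()

    def rank_values(self, rank: str) -> pd.Series:
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}; valid ranks: {RANKS}")
        return self.data[rank]

    def fully_unassigned(self) -> pd.Series:
        return (self.data == "").all(axis=1)
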