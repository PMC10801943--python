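"""Reading, writing and filtering of abundance tables, metadata and taxonomy.

Filtering order used by the pipeline: lineage exclusions, then
prevalence-based contaminant removal, then the low-yield sample filter.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .table import RANKS, AbundanceTable, SampleMetadata, TableError, TaxonomyTable

_SILVA_PREFIX = re.compile(r"^\s*[dkpcofgs]__\s*")


@dataclass
class FilterReport:
    """What a filtering step removed and why."""

    removed_samples: pd.DataFrame = field(default_factory=pd.DataFrame)
    removed_taxa: list[str] = field(default_factory=list)
    reason: str = ""
    total_before: int = 0
    total_after: int = 0

    @property
    def total_removed(self) -> int:
        return self.total_before - self.total_after


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_abundance_table(path, format: str = "tsv",
                         samples_as_rows: bool = True) -> AbundanceTable:
    """Read an abundance table from TSV or BIOM 2.x.

    TSV tables are a header row plus one labelled row per sample
    (``samples_as_rows=True``, default) or per taxon
    (``samples_as_rows=False``); either orientation yields the canonical
    samples x taxa table.  BIOM files follow the format's taxa-as-rows
    convention and are transposed on read.
    """
    if format == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        if len(set(header)) != len(header):
            dups = sorted({h for h in header if header.count(h) > 1})
            raise TableError(f"duplicate column ids in {path}: {dups}")
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        df.index = df.index.astype(str)
        mat = np.empty(df.shape, dtype=float)
        for j, col in enumerate(df.columns):
            try:
                mat[:, j] = pd.to_numeric(df[col], errors="raise")
            except (ValueError, TypeError) as exc:
                bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
                raise TableError(
                    f"non-numeric value in column {col!r}, row(s) {list(bad)}"
                ) from exc
        if not samples_as_rows:
            mat = mat.T
            samples, taxa = list(df.columns), list(df.index)
        else:
            samples, taxa = list(df.index), list(df.columns)
        return AbundanceTable(mat, samples, taxa)
    if format == "biom":
        import biom

        bt = biom.load_table(str(path))  # biom stores taxa (observations) as rows
        mat = np.asarray(bt.matrix_data.todense()).T
        return AbundanceTable(mat, [str(s) for s in bt.ids("sample")],
                              [str(t) for t in bt.ids("observation")])
    raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'biom'")


def write_abundance_table(table: AbundanceTable, path, format: str = "tsv") -> None:
    if format == "tsv":
        df = table.to_dataframe()
        df.to_csv(path, sep="\t")
        return
    if format == "biom":
        import biom

        bt = biom.Table(table.counts.T, observation_ids=table.taxon_ids,
                        sample_ids=table.sample_ids)
        with biom.util.biom_open(str(path), "w") as fh:
            bt.to_hdf5(fh, "coreniche")
        return
    raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'biom'")


def read_metadata(path, control_column: str = "is_negative_control") -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return SampleMetadata(df, control_column=control_column)


def write_metadata(metadata: SampleMetadata, path) -> None:
    metadata.data.to_csv(path, sep="\t")


def read_taxonomy(path) -> TaxonomyTable:
    """Read taxon_id + semicolon-delimited lineage TSV (SILVA prefixes stripped)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    lineage_col = df.columns[0]
    rows = {}
    for taxon, lineage in df[lineage_col].fillna("").items():
        parts = [_SILVA_PREFIX.sub("", p).strip() for p in lineage.split(";")]
        parts = [("" if p.lower() in {"", "na", "unassigned"} else p) for p in parts]
        parts = (parts + [""] * len(RANKS))[: len(RANKS)]
        rows[str(taxon)] = dict(zip(RANKS, parts))
    return TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index"))


def write_taxonomy(taxonomy: TaxonomyTable, path) -> None:
    lineages = taxonomy.data.apply(lambda r: ";".join(r.values), axis=1)
    pd.DataFrame({"Taxonomy": lineages}).rename_axis("taxon_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_low_yield_samples(table: AbundanceTable, min_reads: int = 2000
                             ) -> tuple[AbundanceTable, FilterReport]:
    """Drop samples whose total count is strictly below ``min_reads``.

    A sample at exactly ``min_reads`` is retained (the threshold is an
    exclusive lower bound on what gets removed).
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    depths = table.depths()
    keep = depths.index[depths >= min_reads].tolist()
    if not keep:
        raise TableError(
            f"all {table.n_samples} samples fall below {min_reads} reads"
        )
    removed = depths[depths < min_reads]
    out = table.select_samples(keep)
    report = FilterReport(
        removed_samples=removed.rename("depth").to_frame(),
        reason=f"total reads < {min_reads}",
        total_before=int(depths.sum()),
        total_after=int(out.counts.sum()),
    )
    return out, report


def filter_taxa_by_lineage(table: AbundanceTable, taxonomy: TaxonomyTable,
                           exclude_terms=(), drop_fully_unassigned: bool = False
                           ) -> tuple[AbundanceTable, FilterReport]:
    """Remove taxa whose lineage matches any ``rank=value`` rule.

    ``exclude_terms`` is an iterable of ``(rank, value)`` pairs; matching is
    case-insensitive and exact at the named rank.  With
    ``drop_fully_unassigned`` taxa whose every rank is empty are removed too.
    Taxa missing from the taxonomy are treated as fully unassigned.
    """
    rules = [(str(r), str(v)) for r, v in exclude_terms]
    for rank, _ in rules:
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}; valid ranks: {RANKS}")

    known = set(taxonomy.taxon_ids)
    drop: set[str] = set()
    for rank, value in rules:
        vals = taxonomy.rank_values(rank).str.lower()
        drop.update(vals.index[vals == value.lower()])
    if drop_fully_unassigned:
        unassigned = taxonomy.fully_unassigned()
        drop.update(unassigned.index[unassigned])
        drop.update(t for t in table.taxon_ids if t not in known)
    keep = [t for t in table.taxon_ids if t not in drop]
    removed = [t for t in table.taxon_ids if t in drop]
    out = table.select_taxa(keep)
    report = FilterReport(
        removed_taxa=removed,
        reason="lineage exclusion",
        total_before=int(table.counts.sum()),
        total_after=int(out.counts.sum()),
    )
    return out, report


def identify_contaminants_prevalence(table: AbundanceTable,
                                     metadata: SampleMetadata,
                                     threshold: float = 0.1) -> pd.DataFrame:
    """Flag likely contaminants from prevalence in negative controls.

    For each taxon a 2x2 presence/absence table (control vs true sample) is
    scored with the one-sided hypergeometric tail probability of seeing at
    least the observed number of control detections under independence;
    taxa with score < ``threshold`` are flagged.

    Returns a DataFrame indexed by taxon_id with columns ``score``,
    ``prev_control``, ``prev_true`` and boolean ``contaminant``.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    ctrl_mask = np.array([metadata.is_control().get(s, False)
                          for s in table.sample_ids])
    n_ctrl = int(ctrl_mask.sum())
    n_true = int((~ctrl_mask).sum())
    if n_ctrl == 0:
        raise TableError(
            "no negative-control samples present; skip contaminant "
            "identification or flag controls in the metadata"
        )
    if n_true == 0:
        raise TableError("no true (non-control) samples present")

    present = table.presence()
    k_ctrl = present[ctrl_mask, :].sum(axis=0)
    k_true = present[~ctrl_mask, :].sum(axis=0)
    k_tot = k_ctrl + k_true
    # P(X >= k_ctrl), X ~ Hypergeom(M=n_ctrl+n_true, K=k_tot, n=n_ctrl)
    scores = stats.hypergeom.sf(k_ctrl - 1, n_ctrl + n_true, k_tot, n_ctrl)
    out = pd.DataFrame(
        {
            "score": scores,
            "prev_control": k_ctrl / n_ctrl,
            "prev_true": k_true / n_true,
            "contaminant": scores < threshold,
        },
        index=pd.Index(table.taxon_ids, name="taxon_id"),
    )
    return out


def remove_contaminants(table: AbundanceTable, metadata: SampleMetadata,
                        threshold: float = 0.1
                        ) -> tuple[AbundanceTable, FilterReport]:
    """Drop taxa flagged by :func:`identify_contaminants_prevalence`."""
    flagged = identify_contaminants_prevalence(table, metadata, threshold)
    drop = set(flagged.index[flagged["contaminant"]])
    keep = [t for t in table.taxon_ids if t not in drop]
    out = table.select_taxa(keep)
    report = FilterReport(
        removed_taxa=[t for t in table.taxon_ids if t in drop],
        reason=f"prevalence-method contaminant (score < {threshold})",
        total_before=int(table.counts.sum()),
        total_after=int(out.counts.sum()),
    )
    return out, report


def drop_control_samples(table: AbundanceTable, metadata: SampleMetadata
                         ) -> AbundanceTable:
    keep = [s for s in table.sample_ids
            if not metadata.is_control().get(s, False)]
    return table.select_samples(keep)
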