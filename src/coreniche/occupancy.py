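"""Occupancy/consistency ranking of taxa and core-set selection.

Taxa are ranked by an index combining per-group occupancy with replicate
consistency (being detected in every sample of a group).  The ranked list is
turned into a cumulative Bray-Curtis contribution curve; two stopping rules
(a last-2%-relative-gain rule and an elbow rule on segment slopes) pick the
prefix that forms the core set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .table import AbundanceTable, SampleMetadata, TaxonomyTable


def group_occupancy(table: AbundanceTable, metadata: SampleMetadata | None = None,
                    grouping: str = "none") -> pd.DataFrame:
    """Per-taxon detection proportion within each group.

    With ``grouping="none"`` all samples form a single group ``"all"``.
    Returns a taxa x groups DataFrame of proportions in [0, 1].
    """
    present = table.presence()
    if grouping == "none":
        labels = pd.Series("all", index=table.sample_ids)
    else:
        if metadata is None:
            raise ValueError("metadata required when grouping != 'none'")
        labels = metadata.groups(grouping, table.sample_ids)
        if labels.isna().any():
            missing = list(labels.index[labels.isna()])
            raise ValueError(f"samples without a {grouping!r} label: {missing}")
    out = {}
    for g, idx in labels.groupby(labels).groups.items():
        rows = [table.sample_ids.index(s) for s in idx]
        if not rows:
            raise ValueError(f"empty group {g!r}")
        out[g] = present[rows, :].mean(axis=0)
    df = pd.DataFrame(out, index=pd.Index(table.taxon_ids, name="taxon_id"))
    return df[sorted(df.columns)]


def ranking_index(occupancies: pd.DataFrame,
                  mean_relabund: pd.Series | None = None) -> pd.DataFrame:
    """Composite ranking index from per-group occupancies.

    index = (sum of group occupancies + number of fully-occupied groups)
    / (2 * n_groups).  Ties are broken by mean relative abundance
    (descending) then taxon_id (ascending).  Returns a DataFrame sorted by
    rank with columns sum_freq, sum_full, index, mean_relabund, rank.
    """
    n_groups = occupancies.shape[1]
    if n_groups < 1:
        raise ValueError("at least one group required")
    sum_freq = occupancies.sum(axis=1)
    sum_full = (occupancies == 1.0).sum(axis=1).astype(float)
    index = (sum_freq + sum_full) / (2.0 * n_groups)
    if mean_relabund is None:
        mean_relabund = pd.Series(0.0, index=occupancies.index)
    df = pd.DataFrame(
        {
            "sum_freq": sum_freq,
            "sum_full": sum_full,
            "index": index,
            "mean_relabund": mean_relabund.reindex(occupancies.index).fillna(0.0),
        }
    )
    df.index = df.index.rename("taxon_id")
    df = df.sort_values(
        by=["index", "mean_relabund", "taxon_id"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def rank_taxa(table: AbundanceTable, metadata: SampleMetadata | None = None,
              grouping: str = "none") -> pd.DataFrame:
    """Full ranking table: occupancy per group, overall occupancy, index, rank."""
    occ = group_occupancy(table, metadata, grouping)
    overall = pd.Series(table.presence().mean(axis=0), index=table.taxon_ids)
    mra = pd.Series(table.relative_abundance().mean(axis=0), index=table.taxon_ids)
    ranked = ranking_index(occ, mra)
    ranked.insert(0, "overall_occupancy", overall.reindex(ranked.index))
    return ranked


# ---------------------------------------------------------------------------
# Bray-Curtis contribution curve
# ---------------------------------------------------------------------------

def bc_contribution_curve(table: AbundanceTable, ranked_taxa,
                          max_rank: int | None = None,
                          relative: bool = True) -> np.ndarray:
    """Mean per-pair share of Bray-Curtis structure explained by top-k taxa.

    For each rank k the non-core taxa are zeroed in the numerator while each
    pair's denominator comes from the full table, so BC_core(pair, k) =
    sum_{i in top k} |x_i - y_i| / sum_all (x_i + y_i); the curve value is
    the mean over pairs of BC_core / BC_all.  Pairs with BC_all = 0
    (identical samples) are excluded from the mean.

    Returns an array of length max_rank; entry k-1 is the contribution of
    the top-k prefix.  The value at k = n_taxa is exactly 1.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    order = [table.taxon_ids.index(t) for t in ranked_taxa]
    if max_rank is None:
        max_rank = len(order)
    if max_rank > table.n_taxa:
        raise ValueError("max_rank exceeds number of taxa")

    x = table.relative_abundance() if relative else table.counts.astype(float)
    pairs = list(combinations(range(table.n_samples), 2))
    # per-pair |x - y| per taxon, ordered by rank
    diffs = np.stack([np.abs(x[i] - x[j])[order] for i, j in pairs])  # pairs x taxa
    denom = np.array([(x[i] + x[j]).sum() for i, j in pairs])
    all_num = np.stack([np.abs(x[i] - x[j]) for i, j in pairs]).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        bc_all = np.where(denom > 0, all_num / denom, 0.0)
    valid = bc_all > 0
    if not valid.any():
        raise ValueError("all sample pairs are identical (BC_all = 0)")

    cum = np.cumsum(diffs[valid, :max_rank], axis=1)  # pairs x ranks
    ratios = cum / (denom[valid, None] * bc_all[valid, None])
    return ratios.mean(axis=0)


def select_core_last2pct(contribution_curve) -> int:
    """Prefix length under the last->=2%-relative-gain stopping rule.

    Ranks are included through the last rank k whose contribution grows by
    at least 2% relative to rank k-1 (ratio >= 1.02).  Ranks with zero
    contribution at k-1 are always included up to the first strictly
    positive contribution.  Returns K >= 1.
    """
    curve = np.asarray(contribution_curve, dtype=float)
    if curve.size == 0:
        raise ValueError("empty contribution curve")
    first_pos = int(np.argmax(curve > 0)) if (curve > 0).any() else len(curve) - 1
    best = first_pos + 1  # ranks are 1-based
    for k in range(max(first_pos, 1), len(curve)):
        if curve[k - 1] > 0 and curve[k] / curve[k - 1] >= 1.02:
            best = k + 1
    return best


def select_core_elbow(contribution_curve) -> int:
    """Prefix length at the elbow of the contribution curve.

    For each candidate split i the difference between the average rate of
    change of the left segment, (curve(i) - curve(1)) / i, and of the right
    segment, (curve(n) - curve(i)) / (n - i), is computed; the elbow is the
    i maximising this difference (smallest i on ties).
    """
    curve = np.asarray(contribution_curve, dtype=float)
    n = curve.size
    if n < 3:
        raise ValueError("elbow criterion needs a curve of length >= 3")
    i = np.arange(1, n)  # 1-based candidate ranks 1..n-1
    fo_diff = (curve[i - 1] - curve[0]) / i - (curve[-1] - curve[i - 1]) / (n - i)
    return int(i[np.argmax(fo_diff)])


@dataclass
class CoreSelection:
    """Ranked order, contribution curve and core membership per stopping rule."""

    ranking: pd.DataFrame
    contribution_curve: np.ndarray
    k_last2pct: int
    k_elbow: int | None
    grouping: str = "none"

    @property
    def ranked_taxa(self) -> list[str]:
        return list(self.ranking.index)

    @property
    def core_last2pct(self) -> list[str]:
        return self.ranked_taxa[: self.k_last2pct]

    @property
    def core_elbow(self) -> list[str]:
        if self.k_elbow is None:
            return []
        return self.ranked_taxa[: self.k_elbow]

    def min_core_occupancy(self, criterion: str = "last2pct") -> float:
        """Minimum overall occupancy among core members."""
        core = self.core_last2pct if criterion == "last2pct" else self.core_elbow
        return float(self.ranking.loc[core, "overall_occupancy"].min())

    def to_frame(self, taxonomy: TaxonomyTable | None = None) -> pd.DataFrame:
        df = self.ranking.copy()
        df["contribution"] = np.concatenate(
            [self.contribution_curve,
             np.full(len(df) - len(self.contribution_curve), np.nan)]
        )
        df["in_core_last2pct"] = df["rank"] <= self.k_last2pct
        df["in_core_elbow"] = (
            df["rank"] <= self.k_elbow if self.k_elbow is not None else False
        )
        if taxonomy is not None:
            phyla = taxonomy.rank_values("Phylum").reindex(df.index).fillna("")
            df["phylum"] = phyla.replace("", "Unknown")
        return df


def select_core(table: AbundanceTable, metadata: SampleMetadata | None = None,
                grouping: str = "none", max_rank: int | None = None,
                relative: bool = True) -> CoreSelection:
    """Rank taxa, build the contribution curve and apply both stopping rules."""
    ranking = rank_taxa(table, metadata, grouping)
    curve = bc_contribution_curve(table, ranking.index, max_rank, relative)
    k2 = select_core_last2pct(curve)
    ke = select_core_elbow(curve) if len(curve) >= 3 else None
    return CoreSelection(ranking, curve, k2, ke, grouping)


def core_phylum_composition(core_taxa, taxonomy: TaxonomyTable) -> dict[str, int]:
    """Count core taxa per phylum; phylum-less taxa fall under ``Unknown``."""
    out: dict[str, int] = {}
    phyla = taxonomy.rank_values("Phylum")
    for t in core_taxa:
        p = phyla.get(t, "")
        p = p if p else "Unknown"
        out[p] = out.get(p, 0) + 1
    return out
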