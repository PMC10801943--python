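"""Alpha diversity, Bray-Curtis distances, PCoA and PERMANOVA."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln
from skbio.stats.distance import DistanceMatrix

from .table import AbundanceTable, SampleMetadata


def shannon_entropy(counts) -> float:
    """Shannon entropy in nats, H = -sum p ln p over nonzero proportions."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def rarefied_richness(counts, depth: int) -> float:
    """Expected number of taxa in a random subsample of ``depth`` reads.

    Hypergeometric expectation: E[S_n] = sum_i [1 - C(N-N_i, n)/C(N, n)]
    with N the total count and N_i each taxon's count.
    """
    c = np.asarray(counts, dtype=np.int64)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    N = int(c.sum())
    if depth > N:
        raise ValueError(f"rarefaction depth {depth} exceeds total count {N}")
    if depth < 0:
        raise ValueError("depth must be non-negative")
    c = c[c > 0]

    def log_choose(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    # P(taxon absent from subsample) = C(N - N_i, n) / C(N, n)
    absent = np.where(
        N - c >= depth,
        np.exp(log_choose(N - c, depth) - log_choose(N, depth)),
        0.0,
    )
    return float((1.0 - absent).sum())


def alpha_diversity(table: AbundanceTable, rarefaction_depth: int | None = None
                    ) -> pd.DataFrame:
    """Per-sample Shannon entropy and rarefied richness.

    Rarefaction depth defaults to the minimum sample depth.
    """
    depths = table.depths()
    if rarefaction_depth is None:
        rarefaction_depth = int(depths.min())
    rows = {}
    for i, s in enumerate(table.sample_ids):
        c = table.counts[i]
        rows[s] = {
            "depth": int(depths[s]),
            "shannon": shannon_entropy(c),
            "rarefied_richness": rarefied_richness(c, rarefaction_depth),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


def bray_curtis_matrix(table: AbundanceTable, relative: bool = True
                       ) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities, BC = sum|x-y| / sum(x+y)."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if (table.counts.sum(axis=1) == 0).any():
        bad = [s for s, d in table.depths().items() if d == 0]
        raise ValueError(f"samples with zero total count: {bad}")
    x = table.relative_abundance() if relative else table.counts.astype(float)
    dm = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(dm, ids=table.sample_ids)


def pcoa(dist: DistanceMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical scaling of a distance matrix.

    Double-centres the squared distances and eigendecomposes the Gram
    matrix.  Axes are ordered by decreasing eigenvalue; negative eigenvalues
    are reported as-is and their axes excluded from the coordinates.

    Returns (coordinates DataFrame indexed by sample, all eigenvalues).
    """
    d = dist.data
    n = d.shape[0]
    gram = -0.5 * d ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    gram = centering @ gram @ centering
    eigvals, eigvecs = np.linalg.eigh(gram)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-12
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=list(dist.ids), columns=cols), eigvals


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    statistic: float  # pseudo-F
    r_squared: float
    p_value: float
    n_permutations: int
    n_groups: int


def _ss_decomposition(d2: np.ndarray, codes: np.ndarray, n_groups: int
                      ) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and integer group codes."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    return ss_total, ss_within


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int
              ) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total, ss_within = _ss_decomposition(d2, codes, n_groups)
    ss_between = ss_total - ss_within
    df_between = n_groups - 1
    df_within = n - n_groups
    if df_within <= 0 or ss_within <= 0:
        return np.inf, ss_between / ss_total if ss_total > 0 else np.nan
    f = (ss_between / df_between) / (ss_within / df_within)
    r2 = ss_between / ss_total if ss_total > 0 else np.nan
    return f, r2


def _distinct_label_permutations(codes: np.ndarray):
    """All distinct arrangements of a label multiset (small n only)."""
    from sympy.utilities.iterables import multiset_permutations

    for perm in multiset_permutations(codes.tolist()):
        yield np.asarray(perm)


def permanova(dist: DistanceMatrix, grouping, n_permutations: int = 999,
              seed: int | None = None) -> PermanovaResult:
    """One-factor PERMANOVA with seeded label permutations.

    ``grouping`` maps each sample id of ``dist`` to a group label (mapping,
    Series, or sequence aligned with ``dist.ids``).  With
    ``n_permutations="exhaustive"`` every distinct label arrangement is
    evaluated and p is the exact fraction with F >= F_observed (the observed
    arrangement included); otherwise p uses the +1-corrected Monte-Carlo
    estimate.
    """
    ids = list(dist.ids)
    if isinstance(grouping, (dict, pd.Series)):
        labels = [grouping[s] for s in ids]
    else:
        labels = list(grouping)
        if len(labels) != len(ids):
            raise ValueError("grouping length does not match distance matrix")
    uniq = sorted(set(map(str, labels)))
    if len(uniq) < 2:
        raise ValueError("PERMANOVA requires at least 2 groups")
    code_of = {g: i for i, g in enumerate(uniq)}
    codes = np.array([code_of[str(g)] for g in labels])
    sizes = np.bincount(codes, minlength=len(uniq))
    if (sizes < 2).any():
        small = [uniq[i] for i in np.flatnonzero(sizes < 2)]
        raise ValueError(f"groups with fewer than 2 samples: {small}")

    d2 = dist.data ** 2
    f_obs, r2 = _pseudo_f(d2, codes, len(uniq))

    if n_permutations == "exhaustive":
        fs = np.array([_pseudo_f(d2, perm, len(uniq))[0]
                       for perm in _distinct_label_permutations(codes)])
        p = float(np.mean(fs >= f_obs))
        n_perm = len(fs)
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(int(n_permutations)):
            perm = rng.permutation(codes)
            if _pseudo_f(d2, perm, len(uniq))[0] >= f_obs:
                count += 1
        p = (1 + count) / (1 + int(n_permutations))
        n_perm = int(n_permutations)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm, len(uniq))


def permanova_by_covariates(table: AbundanceTable, metadata: SampleMetadata,
                            covariates, n_permutations: int = 999,
                            seed: int | None = None) -> pd.DataFrame:
    """Single-factor PERMANOVA per covariate on the Bray-Curtis matrix."""
    dm = bray_curtis_matrix(table)
    rows = []
    for i, cov in enumerate(covariates):
        labels = metadata.groups(cov, table.sample_ids)
        res = permanova(dm, labels, n_permutations,
                        None if seed is None else seed + i)
        rows.append({"covariate": cov, "F": res.statistic,
                     "R2": res.r_squared, "p": res.p_value,
                     "n_permutations": res.n_permutations})
    return pd.DataFrame(rows)
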