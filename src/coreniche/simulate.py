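"""Synthetic multi-site community generator with known ground truth.

Neutral counts are drawn from the same stationary Beta law the fitting stage
assumes (local relative abundance ~ Beta(N*m*p, N*m*(1-p)), then multinomial
sampling at each sample's depth), so parameter-recovery tests are exact
self-consistency checks rather than independent ecological simulation.
Non-neutral taxa are planted afterwards: "selected" taxa are forced present
almost everywhere at low abundance, "dispersal-limited" taxa are confined to
a subset of sites.  A questionnaire covariate with a configurable planted
association against health status supports the contingency analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .table import AbundanceTable, SampleMetadata

PROVINCES = ("Punjab", "Sindh", "Balochistan", "KPK", "ICT", "AJK")
GENDERS = ("male", "female")


@dataclass
class SyntheticConfig:
    n_sites: int = 6
    samples_per_site: int = 8  # per gender x province cell
    n_taxa: int = 300
    lognormal_mean: float = 0.0
    lognormal_sd: float = 2.0
    m: float = 0.1
    depth_mean: float = 20_000.0
    depth_sd_log: float = 0.15
    depth_min: int = 13_000
    depth_max: int = 37_000
    n_selected: int = 10
    selected_relabund: float = 2e-4
    n_dispersal_limited: int = 10
    dispersal_boost: float = 0.02  # within-site relative abundance of planted taxa
    allowed_sites: tuple[int, ...] = (0, 1)
    n_patchy: int = 0  # generalists at intermediate prevalence in every site
    patchy_occupancy: float = 0.5
    patchy_relabund: float = 0.008
    n_negative_controls: int = 0
    contaminant_taxa: tuple[str, ...] = ()
    health_association_odds: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_sites > len(PROVINCES):
            raise ValueError(f"n_sites must be in [1, {len(PROVINCES)}]")
        if self.n_selected + self.n_dispersal_limited + self.n_patchy > self.n_taxa:
            raise ValueError("injected taxa exceed n_taxa")
        if self.n_dispersal_limited > 0 and not self.allowed_sites:
            raise ValueError("allowed_sites must be non-empty")

    @property
    def sites(self) -> tuple[str, ...]:
        return PROVINCES[: self.n_sites]

    @property
    def n_samples(self) -> int:
        return self.n_sites * len(GENDERS) * self.samples_per_site


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated dataset."""

    taxon_class: pd.Series  # neutral | selected | dispersal_limited | contaminant
    m: float
    metacommunity: pd.Series
    allowed_sites: tuple[str, ...] = ()
    planted_level: str = ""
    sample_labels: pd.DataFrame = field(default_factory=pd.DataFrame)

    def taxa_of(self, cls: str) -> list[str]:
        return list(self.taxon_class.index[self.taxon_class == cls])


def generate_metacommunity(config: SyntheticConfig) -> np.ndarray:
    """Log-normal metacommunity relative abundances, normalised to sum 1."""
    if config.n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    rng = np.random.default_rng(config.seed)
    raw = rng.lognormal(config.lognormal_mean, config.lognormal_sd, config.n_taxa)
    return raw / raw.sum()


def draw_depths(config: SyntheticConfig, rng: np.random.Generator,
                n: int) -> np.ndarray:
    """Log-normal read depths around the target mean, clipped to range."""
    mu = np.log(config.depth_mean) - config.depth_sd_log ** 2 / 2
    depths = rng.lognormal(mu, config.depth_sd_log, n)
    return np.clip(np.round(depths), config.depth_min, config.depth_max
                   ).astype(np.int64)


def simulate_neutral_counts(p: np.ndarray, m: float, depths: np.ndarray,
                            seed: int | None = None,
                            sample_ids=None, taxon_ids=None) -> AbundanceTable:
    """Sample counts from the stationary Sloan law.

    Per sample, local relative abundances are drawn
    Beta(N*m*p_i, N*m*(1-p_i)) with N the mean depth, renormalised, then
    counts are multinomial at the sample's depth; column sums equal depths
    exactly.
    """
    if m <= 0:
        raise ValueError("m must be positive")
    depths = np.asarray(depths, dtype=np.int64)
    if (depths <= 0).any():
        raise ValueError("depths must be positive")
    p = np.asarray(p, dtype=float)
    rng = np.random.default_rng(seed)
    N = float(depths.mean())
    alpha = N * m * p
    beta = N * m * (1.0 - p)
    n_samples, n_taxa = len(depths), len(p)
    counts = np.zeros((n_samples, n_taxa), dtype=np.int64)
    for i in range(n_samples):
        local = rng.beta(alpha, beta)
        local = np.nan_to_num(local, nan=0.0)
        tot = local.sum()
        local = local / tot if tot > 0 else np.full(n_taxa, 1.0 / n_taxa)
        counts[i] = rng.multinomial(depths[i], local)
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    if taxon_ids is None:
        taxon_ids = [f"ASV_{j:04d}" for j in range(n_taxa)]
    return AbundanceTable(counts, list(sample_ids), list(taxon_ids))


def inject_non_neutral_taxa(table: AbundanceTable, truth: SyntheticTruth,
                            config: SyntheticConfig,
                            site_of_sample: pd.Series,
                            seed: int | None = None
                            ) -> tuple[AbundanceTable, SyntheticTruth]:
    """Plant host-selected and dispersal-limited taxa into a neutral table.

    Selected taxa are forced present (small positive count) in >= 95% of
    samples so their occupancy exceeds the neutral expectation at their
    (low) abundance.  Dispersal-limited taxa are zeroed outside their
    allowed sites and boosted within.  Depths are restored to the original
    per-sample totals by adjusting the most abundant unplanted taxon.
    """
    rng = np.random.default_rng(seed)
    counts = table.counts.copy()
    depths = counts.sum(axis=1)
    n_samples = table.n_samples
    classes = truth.taxon_class.copy()
    taxa = table.taxon_ids

    n_inject = config.n_selected + config.n_dispersal_limited + config.n_patchy
    sel_idx = rng.choice(table.n_taxa, n_inject, replace=False)
    selected = sel_idx[: config.n_selected]
    limited = sel_idx[config.n_selected:
                      config.n_selected + config.n_dispersal_limited]
    patchy = sel_idx[config.n_selected + config.n_dispersal_limited:]
    allowed = {config.sites[i] for i in config.allowed_sites}
    sites = np.asarray([site_of_sample[s] for s in table.sample_ids])

    for j in selected:
        target = max(1, int(round(config.selected_relabund * depths.mean())))
        n_present = max(1, int(np.ceil(0.98 * n_samples)))
        present = np.zeros(n_samples, dtype=bool)
        present[rng.choice(n_samples, n_present, replace=False)] = True
        col = np.where(present, rng.poisson(target, n_samples) + 1, 0)
        counts[:, j] = col
        classes.iloc[j] = "selected"
    for j in limited:
        inside = np.isin(sites, list(allowed))
        boost = np.zeros(n_samples, dtype=np.int64)
        # high abundance inside the allowed sites, hard zero outside
        boost[inside] = rng.poisson(
            config.dispersal_boost * depths[inside]).astype(np.int64)
        counts[:, j] = boost
        classes.iloc[j] = "dispersal_limited"
    for j in patchy:
        # balanced design: the same fraction of samples within every site,
        # never a full site, so ranking places them between full-occupancy
        # taxa and site-restricted ones under both occupancy models
        col = np.zeros(n_samples, dtype=np.int64)
        for site_name in pd.unique(sites):
            in_site = np.flatnonzero(sites == site_name)
            k = max(1, min(len(in_site) - 1,
                           int(round(config.patchy_occupancy * len(in_site)))))
            chosen = rng.choice(in_site, k, replace=False)
            col[chosen] = rng.poisson(
                config.patchy_relabund * depths[chosen]) + 1
        counts[:, j] = col
        classes.iloc[j] = "patchy"

    # restore configured depths via the deepest untouched taxon per sample
    untouched = np.setdiff1d(np.arange(table.n_taxa), sel_idx)
    for i in range(n_samples):
        delta = depths[i] - counts[i].sum()
        j = untouched[np.argmax(counts[i, untouched])]
        counts[i, j] = max(0, counts[i, j] + delta)

    new_truth = SyntheticTruth(
        taxon_class=classes, m=truth.m, metacommunity=truth.metacommunity,
        allowed_sites=tuple(sorted(allowed)), planted_level=truth.planted_level,
        sample_labels=truth.sample_labels,
    )
    return AbundanceTable(counts, list(table.sample_ids), list(taxa)), new_truth


def generate_metadata(config: SyntheticConfig, rng: np.random.Generator,
                      sample_ids, site_of_sample: pd.Series,
                      gender_of_sample: pd.Series) -> tuple[SampleMetadata, str]:
    """Questionnaire-style metadata with an optional planted association.

    Generates health_status in {poor, moderate, good} and a binary exposure
    covariate whose "yes" level multiplies the odds of "poor" health by
    ``health_association_odds``.  Returns (metadata, planted level name).
    """
    exposure = rng.random(len(sample_ids)) < 0.5
    base = np.array([0.2, 0.4, 0.4])  # poor, moderate, good
    odds = config.health_association_odds
    health = []
    for e in exposure:
        w = base.copy()
        if e:
            w[0] *= odds
        w /= w.sum()
        health.append(rng.choice(["poor", "moderate", "good"], p=w))
    df = pd.DataFrame(
        {
            "province_of_residence": [site_of_sample[s] for s in sample_ids],
            "gender": [gender_of_sample[s] for s in sample_ids],
            "exposure": np.where(exposure, "yes", "no"),
            "health_status": health,
            "is_negative_control": False,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return SampleMetadata(df), "yes"


def generate_dataset(config: SyntheticConfig
                     ) -> tuple[AbundanceTable, SampleMetadata, SyntheticTruth]:
    """Full generator: neutral table + injections + metadata + controls."""
    rng = np.random.default_rng(config.seed)
    p = generate_metacommunity(config)

    sample_ids, site, gender = [], {}, {}
    for prov in config.sites:
        for g in GENDERS:
            for r in range(config.samples_per_site):
                sid = f"{prov[:3]}_{g[0]}_{r:02d}"
                sample_ids.append(sid)
                site[sid], gender[sid] = prov, g
    site = pd.Series(site)
    gender = pd.Series(gender)

    depths = draw_depths(config, rng, len(sample_ids))
    table = simulate_neutral_counts(
        p, config.m, depths, seed=rng.integers(2**31), sample_ids=sample_ids
    )
    truth = SyntheticTruth(
        taxon_class=pd.Series("neutral", index=table.taxon_ids,
                              name="taxon_class"),
        m=config.m,
        metacommunity=pd.Series(p, index=table.taxon_ids, name="p"),
    )
    if config.n_selected or config.n_dispersal_limited or config.n_patchy:
        table, truth = inject_non_neutral_taxa(
            table, truth, config, site, seed=rng.integers(2**31)
        )

    metadata, planted = generate_metadata(config, rng, sample_ids, site, gender)

    if config.n_negative_controls > 0:
        ctrl_ids = [f"NEG_{i:02d}" for i in range(config.n_negative_controls)]
        ctrl_counts = np.zeros((len(ctrl_ids), table.n_taxa), dtype=np.int64)
        contam = [t for t in config.contaminant_taxa if t in table.taxon_ids]
        classes = truth.taxon_class.copy()
        true_counts = table.counts.copy()
        for t in contam:
            j = table.taxon_ids.index(t)
            ctrl_counts[:, j] = rng.poisson(50, len(ctrl_ids)) + 1
            # contaminants are reagent-borne: strip them from true samples,
            # repaying the removed reads to each sample's deepest taxon
            removed = true_counts[:, j].copy()
            true_counts[:, j] = 0
            top = np.argmax(true_counts, axis=1)
            true_counts[np.arange(len(removed)), top] += removed
            classes.loc[t] = "contaminant"
        # sprinkle a little cross-talk so controls are not all-zero elsewhere
        ctrl_counts += rng.poisson(0.02, ctrl_counts.shape)
        table = AbundanceTable(
            np.vstack([true_counts, ctrl_counts]),
            list(table.sample_ids) + ctrl_ids, list(table.taxon_ids),
        )
        ctrl_meta = pd.DataFrame(
            {c: "" for c in metadata.covariates} | {"is_negative_control": True},
            index=pd.Index(ctrl_ids, name="sample_id"),
        )
        metadata = SampleMetadata(pd.concat([metadata.data, ctrl_meta]))
        truth = SyntheticTruth(classes, truth.m, truth.metacommunity,
                               truth.allowed_sites, planted,
                               truth.sample_labels)

    labels = pd.DataFrame({"site": site, "gender": gender})
    truth = SyntheticTruth(truth.taxon_class, truth.m, truth.metacommunity,
                           truth.allowed_sites, planted, labels)
    return table, metadata, truth
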