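"""Sloan neutral community model: fit, envelope and taxon partition.

Under the model a taxon with metacommunity relative abundance p has local
relative abundance X ~ Beta(N*m*p, N*m*(1-p)) at stationarity, where N is
the local community size and m the migration rate.  Its expected occupancy
can be predicted two ways:

* ``detection="threshold"``: P(X > d) with a fixed detection limit d = 1/N
  (the classic occupancy curve);
* ``detection="sampling"`` (default): P(count > 0) when reads are sampled
  from X, i.e. 1 - E[(1 - X)^n_reads] - the beta-binomial zero-probability
  complement.  On count data the threshold curve is systematically biased
  (it ignores sampling noise in detection), so the sampling form is the
  default for fitting.

Taxa whose observed occupancy falls outside a confidence envelope around
the prediction are labelled "above" (selected by the host environment) or
"below" (dispersal limited); the rest are "neutral".  The default envelope
is the exact binomial quantile band; a Wilson score band is available but
degenerates for predictions near 0 or 1 (it can exclude the observed
occupancies 0 and 1 themselves, grossly inflating the non-neutral rate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import betaln

M_BOUNDS = (1e-6, 10.0)
M_STARTS = (0.01, 0.1, 1.0)


def sloan_predicted_occupancy(p, N: float, m: float, d: float) -> np.ndarray:
    """P(local relative abundance > d) under the stationary Beta law.

    Vectorised over ``p``.  Boundary conventions: p = 0 -> 0, p = 1 -> 1.
    """
    if N <= 0 or m <= 0:
        raise ValueError("N and m must be positive")
    if not 0 < d < 1:
        raise ValueError("detection limit d must lie in (0, 1)")
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p must lie in [0, 1]")
    alpha = N * m * p
    beta = N * m * (1.0 - p)
    with np.errstate(invalid="ignore"):
        occ = stats.beta.sf(d, alpha, beta)
    occ = np.where(p <= 0, 0.0, occ)
    occ = np.where(p >= 1, 1.0, occ)
    return occ if occ.ndim else float(occ)


def sampling_predicted_occupancy(p, N: float, m: float,
                                 n_reads: float) -> np.ndarray:
    """P(taxon observed in >= 1 of ``n_reads`` reads) under the Beta law.

    E[(1-X)^n] for X ~ Beta(a, b) is B(a, b+n)/B(a, b); the detection
    probability is its complement.  p = 0 -> 0, p = 1 -> 1.
    """
    if N <= 0 or m <= 0 or n_reads <= 0:
        raise ValueError("N, m and n_reads must be positive")
    p = np.asarray(p, dtype=float)
    alpha = N * m * p
    beta = N * m * (1.0 - p)
    with np.errstate(invalid="ignore", divide="ignore"):
        occ = 1.0 - np.exp(betaln(alpha, beta + n_reads) - betaln(alpha, beta))
    occ = np.where(p <= 0, 0.0, occ)
    occ = np.where(p >= 1, 1.0, occ)
    return occ if occ.ndim else float(occ)


def wilson_interval(p_hat, n: int, confidence: float = 0.95):
    """Wilson score interval for a proportion ``p_hat`` observed over n trials."""
    if not 0 <= confidence < 1:
        raise ValueError("confidence must lie in [0, 1)")
    p_hat = np.asarray(p_hat, dtype=float)
    z = stats.norm.ppf(0.5 + confidence / 2.0) if confidence > 0 else 0.0
    if z == 0.0:
        return p_hat.copy(), p_hat.copy()
    denom = 1.0 + z * z / n
    centre = (p_hat + z * z / (2 * n)) / denom
    half = (z / denom) * np.sqrt(p_hat * (1 - p_hat) / n + z * z / (4 * n * n))
    return np.clip(centre - half, 0.0, 1.0), np.clip(centre + half, 0.0, 1.0)


def binomial_envelope(pred, n: int, confidence: float = 0.95):
    """Exact two-sided binomial quantile band for an observed proportion.

    Bounds are quantiles of Binomial(n, pred)/n, so an observation drawn
    from the predicted law falls inside with probability >= ``confidence``.
    """
    if not 0 <= confidence < 1:
        raise ValueError("confidence must lie in [0, 1)")
    pred = np.clip(np.asarray(pred, dtype=float), 0.0, 1.0)
    tail = (1.0 - confidence) / 2.0
    lower = stats.binom.ppf(tail, n, pred) / n
    upper = stats.binom.ppf(1.0 - tail, n, pred) / n
    # discrete quantiles can exclude the prediction itself at the extremes;
    # widen so the band always contains it (coverage only increases)
    return np.minimum(lower, pred), np.maximum(upper, pred)


@dataclass
class NeutralFit:
    """Fitted migration rate plus per-taxon predictions and partition."""

    m: float
    N: float
    d: float
    r_squared: float
    taxa: pd.DataFrame  # p, occupancy, predicted, lower, upper, label
    n_samples: int
    detection: str = "sampling"

    def summary(self) -> dict:
        counts = self.taxa["label"].value_counts().to_dict()
        return {
            "m": self.m,
            "N": self.N,
            "d": self.d,
            "r_squared": self.r_squared,
            "detection": self.detection,
            "n_taxa": int(len(self.taxa)),
            "n_above": int(counts.get("above", 0)),
            "n_neutral": int(counts.get("neutral", 0)),
            "n_below": int(counts.get("below", 0)),
        }


def _predict(p, N: float, m: float, detection: str) -> np.ndarray:
    if detection == "sampling":
        return sampling_predicted_occupancy(p, N, m, N)
    if detection == "threshold":
        return sloan_predicted_occupancy(p, N, m, 1.0 / N)
    raise ValueError(f"unknown detection mode {detection!r}")


def fit_migration(table, community_size: str = "mean",
                  confidence: float = 0.95, detection: str = "sampling",
                  envelope: str = "binomial") -> NeutralFit:
    """Least-squares fit of the migration rate m to occupancy-abundance data.

    N is the mean (or median, per ``community_size``) sample depth, the
    detection limit is 1/N, and p is each taxon's mean relative abundance.
    Taxa never detected are excluded.  m is optimised from multiple starts
    within ``M_BOUNDS``; r^2 = 1 - SSE/SST.
    """
    if table.n_samples < 5:
        raise ValueError("need at least 5 samples to fit")
    depths = table.depths().to_numpy(dtype=float)
    N = float(np.mean(depths) if community_size == "mean" else np.median(depths))
    d = 1.0 / N
    p_all = table.relative_abundance().mean(axis=0)
    occ_all = table.presence().mean(axis=0)
    mask = occ_all > 0
    if mask.sum() < 10:
        raise ValueError("need at least 10 taxa with nonzero occupancy")
    taxa = [t for t, keep in zip(table.taxon_ids, mask) if keep]
    p = p_all[mask]
    occ = occ_all[mask]

    def sse(m_arr):
        pred = _predict(p, N, float(m_arr[0]), detection)
        return float(np.sum((occ - pred) ** 2))

    best = None
    diagnostics = []
    for start in M_STARTS:
        res = optimize.minimize(sse, x0=[start], bounds=[M_BOUNDS],
                                method="L-BFGS-B")
        diagnostics.append((start, res.success, float(res.fun)))
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(f"migration-rate fit failed at all starts: {diagnostics}")

    m_hat = float(best.x[0])
    pred = _predict(p, N, m_hat, detection)
    sse_val = float(np.sum((occ - pred) ** 2))
    sst = float(np.sum((occ - occ.mean()) ** 2))
    r2 = 1.0 - sse_val / sst if sst > 0 else (1.0 if sse_val == 0 else 0.0)

    if envelope == "binomial":
        lower, upper = binomial_envelope(pred, table.n_samples, confidence)
    elif envelope == "wilson":
        lower, upper = wilson_interval(pred, table.n_samples, confidence)
    else:
        raise ValueError(f"unknown envelope {envelope!r}")
    df = pd.DataFrame(
        {"p": p, "occupancy": occ, "predicted": pred,
         "lower": lower, "upper": upper},
        index=pd.Index(taxa, name="taxon_id"),
    )
    df["label"] = partition_labels(df["occupancy"], df["lower"], df["upper"])
    return NeutralFit(m_hat, N, d, r2, df, table.n_samples, detection)


def partition_labels(observed, lower, upper) -> pd.Series:
    """"above" if observed > upper, "below" if < lower, else "neutral".

    Equality with either bound resolves to "neutral" (conservative with
    respect to claiming selection).
    """
    idx = getattr(observed, "index", None)
    obs = np.asarray(observed, dtype=float)
    labels = np.full(obs.shape, "neutral", dtype=object)
    labels[obs > np.asarray(upper, dtype=float)] = "above"
    labels[obs < np.asarray(lower, dtype=float)] = "below"
    return pd.Series(labels, index=idx)


def confidence_envelope(fit: NeutralFit, confidence: float = 0.95,
                        method: str = "binomial") -> pd.DataFrame:
    """Recompute the envelope of a fit at another confidence level."""
    pred = fit.taxa["predicted"].to_numpy()
    if method == "binomial":
        lower, upper = binomial_envelope(pred, fit.n_samples, confidence)
    elif method == "wilson":
        lower, upper = wilson_interval(pred, fit.n_samples, confidence)
    else:
        raise ValueError(f"unknown envelope method {method!r}")
    out = fit.taxa.copy()
    out["lower"], out["upper"] = lower, upper
    out["label"] = partition_labels(out["occupancy"], lower, upper)
    return out


def partition_taxa(fit: NeutralFit) -> pd.Series:
    """Per-taxon partition label from the fitted envelope."""
    return fit.taxa["label"].copy()
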