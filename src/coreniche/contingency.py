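"""Chi-square independence tests, Pearson residual maps and Poisson
log-linear incidence-rate ratios for categorical questionnaire covariates."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class SmallExpectedCountWarning(UserWarning):
    """Emitted when any expected cell count is below 5."""


def crosstab(metadata_df: pd.DataFrame, a: str, b: str) -> pd.DataFrame:
    """Observed contingency table between two categorical covariates."""
    for c in (a, b):
        if c not in metadata_df.columns:
            raise KeyError(f"unknown covariate {c!r}")
    sub = metadata_df[[a, b]].dropna().astype(str)
    return pd.crosstab(sub[a], sub[b])


def _validate_table(obs: np.ndarray) -> None:
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be 2-D with >= 2 levels per margin")
    if (obs < 0).any():
        raise ValueError("negative cell counts")
    if obs.sum() == 0:
        raise ValueError("zero grand total")
    rows, cols = obs.sum(axis=1), obs.sum(axis=0)
    if (rows == 0).any():
        raise ValueError(f"zero row margin at level index {np.flatnonzero(rows == 0)}")
    if (cols == 0).any():
        raise ValueError(
            f"zero column margin at level index {np.flatnonzero(cols == 0)}"
        )


def expected_table(obs: np.ndarray) -> np.ndarray:
    """Independence expectation E = row * col / total."""
    obs = np.asarray(obs, dtype=float)
    return np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()


def chi2_independence(table) -> tuple[float, int, float]:
    """Chi-square test of independence; Yates correction on 2x2 tables only.

    Returns (statistic, dof, p).  Warns when any expected count is < 5.
    """
    obs = np.asarray(table, dtype=float)
    _validate_table(obs)
    expected = expected_table(obs)
    if (expected < 5).any():
        warnings.warn(
            f"{int((expected < 5).sum())} expected cell count(s) below 5; "
            "chi-square approximation may be poor",
            SmallExpectedCountWarning,
            stacklevel=2,
        )
    correction = obs.shape == (2, 2)
    stat, p, dof, _ = stats.chi2_contingency(obs, correction=correction)
    return float(stat), int(dof), float(p)


def pearson_residuals(table) -> pd.DataFrame:
    """Uncorrected Pearson residuals (O - E)/sqrt(E) per cell."""
    obs = np.asarray(table, dtype=float)
    _validate_table(obs)
    expected = expected_table(obs)
    resid = (obs - expected) / np.sqrt(expected)
    if isinstance(table, pd.DataFrame):
        return pd.DataFrame(resid, index=table.index, columns=table.columns)
    return pd.DataFrame(resid)


def poisson_loglinear_irr(table) -> pd.DataFrame:
    """Incidence-rate ratios from the main-effects log-linear model.

    Fits cell frequency ~ rowfactor + colfactor with a Poisson GLM and a log
    link; each non-reference level's IRR is the exponentiated coefficient
    with a 95% Wald CI.  The reference is the first level of each factor in
    declared order.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.DataFrame(np.asarray(table))
        df.index = [f"r{i}" for i in range(df.shape[0])]
        df.columns = [f"c{j}" for j in range(df.shape[1])]
    _validate_table(df.to_numpy(dtype=float))

    long = df.stack().rename("Freq").reset_index()
    long.columns = ["A", "B", "Freq"]
    a_levels = [str(x) for x in df.index]
    b_levels = [str(x) for x in df.columns]
    long["A"] = pd.Categorical(long["A"].astype(str), categories=a_levels)
    long["B"] = pd.Categorical(long["B"].astype(str), categories=b_levels)
    model = smf.glm("Freq ~ A + B", data=long, family=sm.families.Poisson())
    fit = model.fit()
    if not fit.converged:
        raise RuntimeError("Poisson log-linear model did not converge")

    ci = fit.conf_int()
    rows = []
    for name in fit.params.index:
        if name == "Intercept":
            continue
        factor, level = ("A", name) if name.startswith("A[") else ("B", name)
        level = name.split("[T.", 1)[1].rstrip("]")
        rows.append({
            "factor": factor,
            "level": level,
            "reference": a_levels[0] if factor == "A" else b_levels[0],
            "irr": float(np.exp(fit.params[name])),
            "ci_lower": float(np.exp(ci.loc[name, 0])),
            "ci_upper": float(np.exp(ci.loc[name, 1])),
        })
    out = pd.DataFrame(rows)
    out.attrs["fitted_cells"] = pd.DataFrame(
        fit.fittedvalues.to_numpy().reshape(df.shape),
        index=df.index, columns=df.columns,
    )
    return out


@dataclass
class ContingencyResult:
    """Full result of one covariate-pair test."""

    covariate_a: str
    covariate_b: str
    observed: pd.DataFrame
    expected: pd.DataFrame = field(default=None)
    chi2: float = np.nan
    dof: int = 0
    p_value: float = np.nan
    residuals: pd.DataFrame = field(default=None)

    @classmethod
    def from_metadata(cls, metadata_df: pd.DataFrame, a: str, b: str
                      ) -> "ContingencyResult":
        obs = crosstab(metadata_df, a, b)
        stat, dof, p = chi2_independence(obs)
        exp = pd.DataFrame(expected_table(obs.to_numpy(dtype=float)),
                           index=obs.index, columns=obs.columns)
        return cls(a, b, obs, exp, stat, dof, p, pearson_residuals(obs))

    def strongest_attractor(self, anchor_level: str) -> tuple[str, float]:
        """(level of B, residual) with the largest positive residual for
        the given anchor (row) level."""
        row = self.residuals.loc[anchor_level]
        return str(row.idxmax()), float(row.max())


def attractor_summary(results, anchor: str, alpha: float = 0.05,
                      bh_correction: bool = False) -> pd.DataFrame:
    """Strongest positive attractor per anchor level across significant pairs.

    ``results`` is an iterable of ContingencyResult whose covariate_a is the
    anchor.  Pairs with p >= alpha are excluded (after optional
    Benjamini-Hochberg adjustment across pairs).  For each anchor level the
    covariate/level with the maximal positive residual is reported.
    """
    results = [r for r in results if r.covariate_a == anchor]
    if not results:
        return pd.DataFrame(
            columns=["anchor_level", "covariate", "level", "residual", "p"]
        )
    pvals = np.array([r.p_value for r in results])
    if bh_correction and len(pvals):
        from statsmodels.stats.multitest import multipletests

        keep_mask = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    else:
        keep_mask = pvals < alpha
    significant = [r for r, k in zip(results, keep_mask) if k]

    best: dict[str, dict] = {}
    for r in significant:
        for lvl in r.residuals.index:
            col, val = r.strongest_attractor(str(lvl))
            if val <= 0:
                continue
            cur = best.get(str(lvl))
            if cur is None or val > cur["residual"]:
                best[str(lvl)] = {
                    "anchor_level": str(lvl), "covariate": r.covariate_b,
                    "level": col, "residual": val, "p": r.p_value,
                }
    out = pd.DataFrame(list(best.values()),
                       columns=["anchor_level", "covariate", "level",
                                "residual", "p"])
    return out.sort_values("anchor_level").reset_index(drop=True)
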