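"""Study-level statistics for clustered optical-mapping outcomes.

Covers three layers:

* descriptive summaries of the shortest-captured S2 table (mean +/- sample
  SD per animal and per pacing position, rounded to integers);
* a linear mixed-effects model (REML) of each outcome with animal as a
  random intercept and class, train, position, class x train and
  class x position fixed effects (9 predictor terms), with adjusted
  (marginal) means and mean-centered Wald contrasts;
* the intraclass correlation, the design effect
  D_eff = 1 + (m - 1) * ICC for average cluster size m, and the effective
  sample size n_obs / D_eff for judging overfitting risk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

__all__ = [
    "ModelFit",
    "DesignEffectResult",
    "summarize_s2",
    "fit_mixed",
    "estimate_icc",
    "design_effect",
    "effective_sample_size",
    "design_effect_report",
]

MIXED_FORMULA = (
    "value ~ C(cls, Treatment('control')) + C(train) + C(position)"
    " + C(cls, Treatment('control')):C(train)"
    " + C(cls, Treatment('control')):C(position)"
)


def _round_half_up(x) -> int:
    return int(np.floor(x + 0.5))


def summarize_s2(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Summarize a shortest-captured-S2 table (ms) by animal and position.

    ``table`` is wide: one row per animal, one column per pacing position,
    NaN for missing cells.  Means and sample standard deviations (n-1
    denominator) are rounded half-up to integers, matching how such tables
    are reported.  Groups with fewer than two values get an undefined SD
    and are flagged.
    """
    if table.empty:
        raise ValueError("empty S2 table")

    def summarize_axis(df: pd.DataFrame) -> pd.DataFrame:
        n = df.notna().sum(axis=1)
        mean = df.mean(axis=1, skipna=True)
        sd = df.std(axis=1, ddof=1, skipna=True)
        out = pd.DataFrame(
            {
                "n": n,
                "mean": [None if not nn else _round_half_up(m) for nn, m in zip(n, mean)],
                "sd": [
                    None if nn < 2 else _round_half_up(s) for nn, s in zip(n, sd)
                ],
                "sd_defined": n >= 2,
            },
            index=df.index,
        )
        return out

    return {
        "by_animal": summarize_axis(table),
        "by_position": summarize_axis(table.T),
    }


@dataclass
class ModelFit:
    """Mixed-model results: fixed effects, variance components, ICC,
    adjusted means and mean-centered Wald contrasts."""

    fe_params: pd.Series
    fe_se: pd.Series
    fe_cov: pd.DataFrame
    animal_var: float
    resid_var: float
    icc: float
    n_obs: int
    n_groups: int
    n_predictors: int
    marginal_means: dict = field(default_factory=dict)
    contrasts: dict = field(default_factory=dict)
    converged: bool = True
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "fixed_effects": {
                k: {"estimate": float(v), "se": float(self.fe_se[k])}
                for k, v in self.fe_params.items()
            },
            "animal_var": self.animal_var,
            "resid_var": self.resid_var,
            "icc": self.icc,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "n_predictors": self.n_predictors,
            "marginal_means": self.marginal_means,
            "contrasts": self.contrasts,
            "converged": self.converged,
            "note": self.note,
        }


def _exog_for(design_info, df: pd.DataFrame) -> np.ndarray:
    from patsy import dmatrix

    return np.asarray(dmatrix(design_info, df, return_type="dataframe"))


def _mean_row(design_info, df: pd.DataFrame, **overrides) -> np.ndarray:
    """Average design row with some factors pinned to fixed levels.

    Averaging the rebuilt design matrix over the observed rows holds every
    non-pinned covariate at its sample mean — the mean-centering used for
    adjusted (marginal) means.
    """
    work = df.copy()
    for col, level in overrides.items():
        work[col] = level
    return _exog_for(design_info, work).mean(axis=0)


def fit_mixed(table: pd.DataFrame, outcome: str) -> ModelFit:
    """REML fit of one outcome with animal as a random intercept.

    Fixed effects: class, train, position, class x train, class x position
    (9 predictor terms plus the intercept).  Adjusted means per factor
    level are computed by averaging the design matrix with that factor
    pinned; contrasts (class, train overall and within class, position
    joint test) are Wald z-tests on those linear combinations.

    A singular fit (zero animal variance) is returned with ICC 0 and a
    convergence note rather than raising.
    """
    df = table[table["outcome"] == outcome].copy() if "outcome" in table else table.copy()
    if df.empty:
        raise ValueError(f"outcome {outcome!r} not present in table")
    for col in ("animal", "cls", "position", "train", "value"):
        if col not in df:
            raise ValueError(f"study table lacks column {col!r}")
    if df.duplicated(["animal", "position", "train"]).any():
        raise ValueError("duplicate (animal, position, train) cells")
    by_animal = df.groupby("animal")["cls"].nunique()
    if (by_animal > 1).any():
        raise ValueError("class must be constant within animal")
    if df.groupby("cls")["animal"].nunique().min() < 2 or df["animal"].nunique() < 2:
        raise ValueError("need at least 2 animals per class to identify the random effect")

    note = ""
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(MIXED_FORMULA, df, groups=df["animal"])
        try:
            res = model.fit(reml=True)
        except Exception:
            res = model.fit(reml=True, method="powell")
    animal_var = float(np.squeeze(res.cov_re))
    resid_var = float(res.scale)
    if animal_var <= 1e-10 * max(resid_var, 1.0):
        animal_var = 0.0
        note = "singular fit: animal variance estimated at zero"
        converged = bool(res.converged)
    icc = animal_var / (animal_var + resid_var) if animal_var + resid_var > 0 else 0.0

    k = model.k_fe
    fe = res.fe_params
    cov = pd.DataFrame(
        np.asarray(res.cov_params())[:k, :k], index=fe.index, columns=fe.index
    )
    design_info = model.data.design_info

    def lin(lvec):
        est = float(lvec @ fe.values)
        se = float(np.sqrt(lvec @ cov.values @ lvec))
        return est, se

    marginal: dict[str, dict[str, dict]] = {}
    for factor, levels in (
        ("cls", sorted(df["cls"].unique())),
        ("train", sorted(df["train"].unique())),
        ("position", sorted(df["position"].unique())),
    ):
        marginal[factor] = {}
        for level in levels:
            row = _mean_row(design_info, df, **{factor: level})
            est, se = lin(row)
            marginal[factor][level] = {"mean": est, "se": se}

    def wald(l1, l2):
        d = l1 - l2
        est, se = lin(d)
        z = est / se if se > 0 else 0.0
        p = float(2.0 * sps.norm.sf(abs(z)))
        return {"estimate": est, "se": se, "z": z, "p": p}

    contrasts: dict[str, dict] = {}
    classes = sorted(df["cls"].unique())
    trains = sorted(df["train"].unique())
    if len(classes) == 2:
        rows = {c: _mean_row(design_info, df, cls=c) for c in classes}
        other = [c for c in classes if c != "control"][0] if "control" in classes else classes[1]
        base = "control" if "control" in classes else classes[0]
        contrasts["class"] = wald(rows[other], rows[base])
    if len(trains) == 2:
        r1 = _mean_row(design_info, df, train=trains[1])
        r0 = _mean_row(design_info, df, train=trains[0])
        contrasts[f"train_{trains[1]}_vs_{trains[0]}"] = wald(r1, r0)
        for c in classes:
            r1c = _mean_row(design_info, df, cls=c, train=trains[1])
            r0c = _mean_row(design_info, df, cls=c, train=trains[0])
            contrasts[f"train_within_{c}"] = wald(r1c, r0c)
    positions = sorted(df["position"].unique())
    if len(positions) > 1:
        base_row = _mean_row(design_info, df, position=positions[0])
        lmat = np.stack(
            [_mean_row(design_info, df, position=p) - base_row for p in positions[1:]]
        )
        est = lmat @ fe.values
        vmat = lmat @ cov.values @ lmat.T
        try:
            chi2 = float(est @ np.linalg.solve(vmat, est))
            dof = len(est)
            contrasts["position_joint"] = {
                "chi2": chi2,
                "df": dof,
                "p": float(sps.chi2.sf(chi2, dof)),
            }
        except np.linalg.LinAlgError:
            contrasts["position_joint"] = {"chi2": float("nan"), "df": len(est), "p": float("nan")}

    return ModelFit(
        fe_params=fe,
        fe_se=pd.Series(np.sqrt(np.diag(cov.values)), index=fe.index),
        fe_cov=cov,
        animal_var=animal_var,
        resid_var=resid_var,
        icc=float(icc),
        n_obs=len(df),
        n_groups=df["animal"].nunique(),
        n_predictors=k - 1,
        marginal_means=marginal,
        contrasts=contrasts,
        converged=converged,
        note=note,
    )


def estimate_icc(table: pd.DataFrame, outcome: str) -> float:
    """Intraclass correlation of one outcome via the mixed model."""
    return fit_mixed(table, outcome).icc


def design_effect(avg_cluster_size: float, icc: float) -> float:
    """Design effect D_eff = 1 + (m - 1) * ICC for average cluster size m."""
    if avg_cluster_size < 1:
        raise ValueError("average cluster size must be >= 1")
    if not 0 <= icc <= 1:
        raise ValueError("ICC must lie in [0, 1]")
    return 1.0 + (avg_cluster_size - 1.0) * icc


def effective_sample_size(n_obs: int, d_eff: float, rounding: str = "nearest") -> int:
    """Effective number of independent observations, n_obs / D_eff.

    ``rounding`` is "nearest" (half-up, the default), "floor" or "ceil".
    """
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    if d_eff < 1:
        raise ValueError("design effect must be >= 1")
    raw = n_obs / d_eff
    if rounding == "nearest":
        return _round_half_up(raw)
    if rounding == "floor":
        return int(np.floor(raw))
    if rounding == "ceil":
        return int(np.ceil(raw))
    raise ValueError("rounding must be 'nearest', 'floor' or 'ceil'")


@dataclass
class DesignEffectResult:
    """Clustering summary: D_eff and the effective sample size."""

    avg_cluster_size: float
    icc: float
    d_eff: float
    n_obs: int
    n_effective: int

    def to_dict(self) -> dict:
        return {
            "avg_cluster_size": self.avg_cluster_size,
            "icc": self.icc,
            "d_eff": self.d_eff,
            "n_obs": self.n_obs,
            "n_effective": self.n_effective,
        }


def design_effect_report(
    table: pd.DataFrame, outcome: str, rounding: str = "nearest"
) -> DesignEffectResult:
    """ICC, design effect and effective sample size for one outcome."""
    df = table[table["outcome"] == outcome] if "outcome" in table else table
    icc = estimate_icc(table, outcome)
    n_obs = len(df)
    m = df.groupby("animal").size().mean()
    d_eff = design_effect(m, icc)
    return DesignEffectResult(
        avg_cluster_size=float(m),
        icc=icc,
        d_eff=d_eff,
        n_obs=n_obs,
        n_effective=effective_sample_size(n_obs, d_eff, rounding),
    )
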