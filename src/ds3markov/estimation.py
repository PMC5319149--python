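"""Refitting the two regressions from longitudinal panel data.

Two models parameterize the projection framework and both can be
re-estimated here from a state panel / utility panel with the same layout
as the original study data:

* annual health-state transitions — proportional-odds (ordered logistic)
  maximum likelihood on the 9 ranked states, with cluster-robust (by
  patient) sandwich standard errors;
* health-state utilities — Gaussian GEE with identity link and an
  independence working correlation (point estimates coincide with OLS;
  the cluster-robust covariance supplies the within-patient correlation
  adjustment).

Panel schemas
-------------
State panel: columns ``patient, year, state, prev_state, years_on_tx,
baseline_d, spleen`` — one row per patient-year, ``state``/``prev_state``
ranks 1..9, ``years_on_tx`` in {"1","2","3plus"}, ``baseline_d`` in
{"mild","moderate","marked","severe"}, ``spleen`` in
{"intact","splenectomized"}.

Utility panel: columns ``patient, state, utility, female, age_at_init``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .params import TransitionCoefficients, UtilityCoefficients
from .states import STATES, HealthState

__all__ = [
    "fit_transition_model",
    "fit_utility_model",
    "ordered_logit_loglike",
    "TRANSITION_TERM_ORDER",
    "UTILITY_TERM_ORDER",
]

_SLOPE_TERMS = [f"prev_{s.label.lower().replace('+', '_')}" for s in STATES[1:]] + [
    "tx_two_years",
    "tx_three_plus_years",
    "baseline_moderate",
    "baseline_marked",
    "baseline_severe",
    "not_splenectomized",
]
TRANSITION_TERM_ORDER = _SLOPE_TERMS + [f"cutpoint_{k}" for k in range(1, 9)]
UTILITY_TERM_ORDER = [
    "constant",
    "d_moderate",
    "d_marked",
    "d_severe",
    "bone_pain",
    "ssc",
    "female",
    "age_at_init",
]


def _transition_design(panel: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(index=panel.index)
    prev = panel["prev_state"].astype(int)
    for term, rank in zip(_SLOPE_TERMS[:8], range(2, 10)):
        X[term] = (prev == rank).astype(float)
    tx = panel["years_on_tx"].astype(str)
    X["tx_two_years"] = (tx == "2").astype(float)
    X["tx_three_plus_years"] = (tx == "3plus").astype(float)
    base = panel["baseline_d"].astype(str)
    for sev in ("moderate", "marked", "severe"):
        X[f"baseline_{sev}"] = (base == sev).astype(float)
    X["not_splenectomized"] = (panel["spleen"].astype(str) == "intact").astype(float)
    return X


def _cluster_sandwich(
    model, params: np.ndarray, groups: np.ndarray
) -> np.ndarray:
    """Cluster-robust covariance H^-1 (sum_g s_g s_g') H^-1 with a G/(G-1) factor."""
    scores = model.score_obs(params)
    hess = model.hessian(params)
    bread = np.linalg.inv(-hess)
    codes = pd.factorize(groups)[0]
    n_groups = codes.max() + 1
    meat = np.zeros((scores.shape[1], scores.shape[1]))
    group_scores = np.zeros((n_groups, scores.shape[1]))
    np.add.at(group_scores, codes, scores)
    meat = group_scores.T @ group_scores
    factor = n_groups / (n_groups - 1)
    return factor * bread @ meat @ bread


def fit_transition_model(
    panel: pd.DataFrame,
) -> tuple[TransitionCoefficients, dict[str, float]]:
    """Proportional-odds ML fit of annual transitions with cluster-robust SEs.

    Returns the fitted coefficients in the same layout as the packaged
    defaults, plus a term -> robust-SE mapping (cutpoint SEs by the delta
    method from the optimizer's increment parameterization).

    Raises
    ------
    ValueError
        If fewer than two outcome categories are present or the optimizer
        fails to converge.
    """
    observed = sorted(panel["state"].astype(int).unique())
    if len(observed) < 2:
        raise ValueError(
            f"ordered logit needs >= 2 outcome categories, got {observed}"
        )
    endog = pd.Categorical(
        panel["state"].astype(int), categories=observed, ordered=True
    )
    X = _transition_design(panel)
    model = OrderedModel(endog, X, distr="logit")
    res = model.fit(method="lbfgs", maxiter=2000, disp=False)
    if not np.all(np.isfinite(res.params)):
        raise ValueError("ordered-logit fit did not converge (non-finite parameters)")

    k = X.shape[1]
    n_cats = len(observed)
    slopes = np.asarray(res.params[:k], dtype=float)
    # optimizer parameterization: first threshold, then log-increments
    thresh = model.transform_threshold_params(res.params)[1:-1]  # drop +-inf
    if n_cats != 9:
        raise ValueError(
            f"transition fit requires all 9 states observed, got {n_cats} categories"
        )

    cov_internal = _cluster_sandwich(model, res.params, panel["patient"].to_numpy())
    # delta method: th_j = t_1 + sum_{i<j} exp(d_i)
    n_th = n_cats - 1
    J = np.zeros((k + n_th, k + n_th))
    J[:k, :k] = np.eye(k)
    internal_th = np.asarray(res.params[k:], dtype=float)
    for j in range(n_th):
        J[k + j, k] = 1.0
        for i in range(1, j + 1):
            J[k + j, k + i] = np.exp(internal_th[i])
    cov = J @ cov_internal @ J.T
    se = np.sqrt(np.diag(cov))

    values = dict(zip(_SLOPE_TERMS, slopes))
    for j in range(8):
        values[f"cutpoint_{j + 1}"] = float(thresh[j])
    ses = dict(zip(TRANSITION_TERM_ORDER, se))
    return TransitionCoefficients.from_dict(values), ses


def ordered_logit_loglike(
    panel: pd.DataFrame, coefs: TransitionCoefficients
) -> float:
    """Proportional-odds log-likelihood of a state panel at given coefficients.

    Exposed so the fitted likelihood can be verified against an independent
    hand computation on small panels.
    """
    X = _transition_design(panel).to_numpy()
    slopes = np.array(
        [coefs.to_dict()[t] for t in _SLOPE_TERMS], dtype=float
    )
    lp = X @ slopes
    cuts = np.asarray(coefs.cutpoints, dtype=float)
    cum = np.concatenate(
        [np.zeros((len(lp), 1)), 1 / (1 + np.exp(-(cuts[None, :] - lp[:, None]))), np.ones((len(lp), 1))],
        axis=1,
    )
    ranks = panel["state"].astype(int).to_numpy()
    probs = cum[np.arange(len(lp)), ranks] - cum[np.arange(len(lp)), ranks - 1]
    return float(np.log(probs).sum())


def _utility_design(panel: pd.DataFrame) -> pd.DataFrame:
    states = [HealthState.from_rank(int(r)) for r in panel["state"]]
    X = pd.DataFrame(index=panel.index)
    X["constant"] = 1.0
    X["d_moderate"] = [float(s.severity.value == "moderate") for s in states]
    X["d_marked"] = [float(s.severity.value == "marked") for s in states]
    X["d_severe"] = [float(s.severity.value == "severe") for s in states]
    X["bone_pain"] = [float(s.has_bp or s.has_ssc) for s in states]
    X["ssc"] = [float(s.has_ssc) for s in states]
    X["female"] = panel["female"].astype(float)
    X["age_at_init"] = panel["age_at_init"].astype(float)
    return X


def fit_utility_model(
    panel: pd.DataFrame,
) -> tuple[UtilityCoefficients, dict[str, float]]:
    """Gaussian GEE (identity link, independence working correlation) utility fit.

    Sample means of ``female`` and ``age_at_init`` are stored on the
    returned object so recycled predictions can be formed directly.

    Raises
    ------
    ValueError
        If fewer than two patients are present or the design is collinear.
    """
    if panel["patient"].nunique() < 2:
        raise ValueError("utility GEE needs >= 2 patients")
    X = _utility_design(panel)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"collinear utility design: rank {rank} < {X.shape[1]} columns "
            "(some health states or covariates are unobserved or confounded)"
        )
    model = sm.GEE(
        panel["utility"].astype(float),
        X,
        groups=panel["patient"],
        family=sm.families.Gaussian(),
        cov_struct=sm.cov_struct.Independence(),
    )
    res = model.fit()
    values = {term: float(res.params[term]) for term in UTILITY_TERM_ORDER}
    ses = {term: float(res.bse[term]) for term in UTILITY_TERM_ORDER}
    coefs = UtilityCoefficients(
        **values,
        mean_female=float(panel["female"].mean()),
        mean_age=float(panel["age_at_init"].mean()),
    )
    return coefs, ses
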