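"""Candidate regression models on histometric co-predictors + eigenvectors.

Each candidate model regresses one blood-cell response on an intercept, at
most one log-histometric co-predictor, and a forward-selected subset of
phylogenetic eigenvectors.  The comparison grid holds four models (one per
co-predictor plus a phylogeny-only model); the grid's overall-F p-values are
adjusted with the step-down Holm-Sidak procedure and the best model is the
one with the highest R^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .pem_core import PEMBasis

__all__ = [
    "PREDICTORS",
    "RESPONSES",
    "CandidateModel",
    "FittedCandidateModel",
    "FitError",
    "candidate_model_grid",
    "aicc",
    "forward_select_eigenvectors",
    "fit_candidate_model",
    "holm_sidak_adjust",
    "model_comparison_table",
]

PREDICTORS = ("lnOsteo_volume", "lnCan_harmean", "lnCan_min")
RESPONSES = ("RBC_width", "RBC_area", "RBC_length")

#: Condition-number threshold beyond which a design is rejected as collinear.
COLLINEARITY_THRESHOLD = 1e10


class FitError(ValueError):
    """Unusable design matrix or insufficient data for a fit."""


@dataclass(frozen=True)
class CandidateModel:
    """One cell of the model-comparison grid."""

    response: str
    co_predictors: tuple[str, ...] = ()
    use_phylogeny: bool = True
    log_response: bool = True

    def __post_init__(self):
        if self.response not in RESPONSES:
            raise ValueError(f"unknown response {self.response!r}")
        for p in self.co_predictors:
            if p not in PREDICTORS:
                raise ValueError(f"unknown co-predictor {p!r}")

    @property
    def model_id(self) -> str:
        parts = list(self.co_predictors)
        if self.use_phylogeny:
            parts.append("phylogeny")
        return " + ".join(parts) if parts else "intercept-only"


def candidate_model_grid(response: str, log_response: bool = True) -> list[CandidateModel]:
    """The four-model grid: each single co-predictor + phylogeny, and
    phylogeny alone."""
    grid = [
        CandidateModel(response, (p,), True, log_response) for p in PREDICTORS
    ]
    grid.append(CandidateModel(response, (), True, log_response))
    return grid


@dataclass
class FittedCandidateModel:
    spec: CandidateModel
    intercept: float
    coef: dict[str, float]            # co-predictor and eigenvector terms
    selected: list[int]               # eigenvector column indices
    r2: float
    p_value: float
    aicc: float
    resid_var: float
    training_taxa: list[str]
    p_adjusted: float | None = None
    column_names: list[str] = field(default_factory=list)


def aicc(sse: float, n: int, n_params: int) -> float:
    """Small-sample corrected AIC for a Gaussian OLS fit.

    ``n_params`` counts the regression coefficients (including the
    intercept); one more parameter is charged for the residual variance.
    Returns ``inf`` when the correction denominator is non-positive.
    """
    k = n_params + 1
    if n - k - 1 <= 0:
        return np.inf
    with np.errstate(divide="ignore"):
        loglik = -0.5 * n * (np.log(2.0 * np.pi) + np.log(sse / n) + 1.0)
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _sse(design: np.ndarray, y: np.ndarray) -> float:
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(resid @ resid)


def forward_select_eigenvectors(
    U: np.ndarray,
    y: np.ndarray,
    Z: np.ndarray | None = None,
    max_k: int | None = None,
    criterion: str = "aicc",
) -> list[int]:
    """Greedy forward selection of eigenvector columns.

    Starting from intercept (+ co-predictors ``Z``), repeatedly add the
    eigenvector whose inclusion gives the lowest AICc, stopping when no
    addition improves it or ``max_k`` columns are selected.  Ties are broken
    by the lowest column index.  With ``criterion="r2"`` the stopping rule is
    dropped and the greedy path runs to ``max_k`` (the best single addition
    by residual sum of squares at each step).
    """
    if criterion not in ("aicc", "r2"):
        raise ValueError(f"unknown selection criterion {criterion!r}")
    U = np.asarray(U, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    base = [np.ones((n, 1))]
    if Z is not None and np.size(Z):
        base.append(np.asarray(Z, dtype=float).reshape(n, -1))
    base_design = np.hstack(base)
    if max_k is None:
        max_k = U.shape[1]
    max_k = min(max_k, U.shape[1])

    selected: list[int] = []
    current_design = base_design
    current_crit = aicc(_sse(current_design, y), n, current_design.shape[1])
    while len(selected) < max_k:
        n_params = current_design.shape[1] + 1
        if criterion == "aicc" and n - (n_params + 1) - 1 <= 0:
            break  # AICc undefined at the next size: stop here
        best_j, best_crit, best_sse = None, np.inf, np.inf
        for j in range(U.shape[1]):
            if j in selected:
                continue
            design = np.hstack([current_design, U[:, [j]]])
            sse = _sse(design, y)
            crit = aicc(sse, n, n_params) if criterion == "aicc" else sse
            if crit < best_crit - 0.0:
                best_j, best_crit, best_sse = j, crit, sse
        if best_j is None:
            break
        if criterion == "aicc" and best_crit >= current_crit:
            break
        selected.append(best_j)
        current_design = np.hstack([current_design, U[:, [best_j]]])
        current_crit = best_crit
        if criterion == "aicc" and best_sse == 0.0:
            break  # perfect fit; nothing left to explain
    return selected


def _check_collinearity(design: np.ndarray, names: list[str]) -> None:
    cond = np.linalg.cond(design)
    if cond > COLLINEARITY_THRESHOLD:
        # Identify columns that do not increase the design rank when added.
        offenders = []
        rank = 0
        for j in range(design.shape[1]):
            new_rank = np.linalg.matrix_rank(design[:, : j + 1])
            if new_rank == rank:
                offenders.append(names[j])
            rank = new_rank
        raise FitError(
            f"collinear design (condition number {cond:.3g}); "
            f"dependent columns: {offenders or names}"
        )


def fit_candidate_model(
    table: pd.DataFrame,
    basis: PEMBasis,
    spec: CandidateModel,
    max_k: int | None = None,
    criterion: str = "aicc",
) -> FittedCandidateModel:
    """Fit one candidate model by OLS on the training (basis) taxa.

    The response is modelled on the natural-log scale when
    ``spec.log_response`` is set; R^2 and the overall-F p-value are those of
    the full fitted model against intercept-only.
    """
    rows = table.set_index("taxon").loc[basis.tip_labels]
    y_raw = rows[spec.response].to_numpy(dtype=float)
    if np.isnan(y_raw).any():
        bad = [t for t, v in zip(basis.tip_labels, y_raw) if np.isnan(v)]
        raise FitError(f"missing response {spec.response} for training taxa {bad}")
    if len(y_raw) < 5:
        raise FitError(f"need >=5 training taxa, got {len(y_raw)}")
    if spec.log_response:
        if np.any(y_raw <= 0):
            raise FitError("non-positive response values cannot be log-modelled")
        y = np.log(y_raw)
    else:
        y = y_raw

    Z = rows[list(spec.co_predictors)].to_numpy(dtype=float) if spec.co_predictors else None
    n = len(y)
    if max_k is None:
        max_k = max(0, n - len(spec.co_predictors) - 3)

    selected: list[int] = []
    if spec.use_phylogeny:
        selected = forward_select_eigenvectors(basis.U, y, Z, max_k, criterion)

    names = ["intercept", *spec.co_predictors, *[f"V{j + 1}" for j in selected]]
    cols = [np.ones((n, 1))]
    if Z is not None:
        cols.append(Z)
    if selected:
        cols.append(basis.U[:, selected])
    design = np.hstack(cols)
    _check_collinearity(design, names)

    fit = sm.OLS(y, design).fit()
    sse = float(fit.ssr)
    p_value = float(fit.f_pvalue) if design.shape[1] > 1 else 1.0
    return FittedCandidateModel(
        spec=spec,
        intercept=float(fit.params[0]),
        coef=dict(zip(names[1:], (float(b) for b in fit.params[1:]))),
        selected=selected,
        r2=float(fit.rsquared),
        p_value=p_value,
        aicc=aicc(sse, n, design.shape[1]),
        resid_var=sse / max(1, n - design.shape[1]),
        training_taxa=list(basis.tip_labels),
        column_names=names,
    )


def holm_sidak_adjust(p_values) -> np.ndarray:
    """Step-down Holm-Sidak adjustment.

    Sorting ascending, the i-th adjusted value is the running maximum of
    ``1 - (1 - p_(j)) ** (m - j)`` over j <= i (0-based j), restored to input
    order and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    stepwise = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adjusted_sorted = np.minimum(np.maximum.accumulate(stepwise), 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def model_comparison_table(
    table: pd.DataFrame,
    basis: PEMBasis,
    response: str,
    log_response: bool = True,
    max_k: int | None = None,
    criterion: str = "aicc",
) -> tuple[pd.DataFrame, dict[str, FittedCandidateModel]]:
    """Fit the four-model grid and rank it.

    Returns the comparison table (one row per candidate, flagging the best
    fit by highest R^2) and the fitted models keyed by model id.  A row whose
    fit fails is kept, flagged with the error message.
    """
    fits: dict[str, FittedCandidateModel] = {}
    records = []
    for spec in candidate_model_grid(response, log_response):
        try:
            fitted = fit_candidate_model(table, basis, spec, max_k, criterion)
        except FitError as exc:
            records.append(
                {"model": spec.model_id, "r2": np.nan, "p_value": np.nan,
                 "aicc": np.nan, "n_eigenvectors": 0, "error": str(exc)}
            )
            continue
        fits[spec.model_id] = fitted
        records.append(
            {"model": spec.model_id, "r2": fitted.r2, "p_value": fitted.p_value,
             "aicc": fitted.aicc, "n_eigenvectors": len(fitted.selected),
             "error": ""}
        )
    out = pd.DataFrame.from_records(records)
    ok = out["p_value"].notna()
    adjusted = np.full(len(out), np.nan)
    if ok.any():
        adjusted[ok.to_numpy()] = holm_sidak_adjust(out.loc[ok, "p_value"])
    out["p_holm_sidak"] = adjusted
    for model_id, fitted in fits.items():
        fitted.p_adjusted = float(
            out.loc[out["model"] == model_id, "p_holm_sidak"].iloc[0]
        )
    out["best"] = False
    if ok.any():
        out.loc[out["r2"].idxmax(), "best"] = True
    out = out[
        ["model", "r2", "p_value", "p_holm_sidak", "aicc",
         "n_eigenvectors", "best", "error"]
    ]
    return out, fits
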