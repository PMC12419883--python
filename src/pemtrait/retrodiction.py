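"""Predict responses at held-out tips and orchestrate the full pipeline."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .pem_core import EdgeWeighting, PEMBasis, build_pem, estimate_steepness, location_scores
from .phylo_graph import (
    InfluenceMatrix,
    PhyloTree,
    TipLocation,
    influence_matrix,
    locate_targets,
    parse_newick,
)
from .trait_model import FittedCandidateModel, model_comparison_table

__all__ = [
    "ReconciliationError",
    "PipelineConfig",
    "PipelineResult",
    "retrodict_traits",
    "run_pipeline",
]

log = logging.getLogger(__name__)


class ReconciliationError(ValueError):
    """Tree tips and character-matrix taxa do not match."""


def retrodict_traits(
    fitted: FittedCandidateModel,
    basis: PEMBasis,
    locations: list[TipLocation],
    table: pd.DataFrame,
) -> pd.DataFrame:
    """Predict the fitted model's response at each target location.

    For every target the eigenvector scores at its attachment point replace
    the training eigenvectors in the linear predictor; co-predictor values
    come from the character table.  Predictions made on the log scale are
    back-transformed by plain exponentiation.  A target missing a required
    co-predictor yields an error row; the others are still predicted.
    """
    rows = table.set_index("taxon")
    spec = fitted.spec
    records = []
    for loc in locations:
        record = {
            "taxon": loc.label,
            "response": spec.response,
            "model_id": spec.model_id,
            "ln_prediction": np.nan,
            "prediction": np.nan,
            "error": "",
        }
        try:
            if loc.label not in rows.index:
                raise KeyError(f"taxon {loc.label!r} absent from character table")
            eta = fitted.intercept
            for name in spec.co_predictors:
                value = float(rows.at[loc.label, name])
                if np.isnan(value):
                    raise ValueError(f"missing predictor {name} for {loc.label!r}")
                eta += fitted.coef[name] * value
            scores = location_scores(basis, loc)
            for idx in fitted.selected:
                eta += fitted.coef[f"V{idx + 1}"] * scores[idx]
            if spec.log_response:
                record["ln_prediction"] = eta
                record["prediction"] = float(np.exp(eta))
            else:
                record["prediction"] = eta
        except (KeyError, ValueError) as exc:
            record["error"] = str(exc)
        records.append(record)
    return pd.DataFrame.from_records(
        records,
        columns=["taxon", "response", "ln_prediction", "prediction", "model_id", "error"],
    )


@dataclass
class PipelineConfig:
    """Resolved settings for one end-to-end run."""

    tree_path: str
    matrix_path: str
    responses: tuple[str, ...] = ("RBC_area",)
    steepness: float = 0.0
    rate: float = 1.0
    estimate_steepness: bool = False
    log_response: bool = True
    criterion: str = "aicc"
    max_k: int | None = None
    out_dir: str | None = None
    allow_drop: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    model_tables: dict[str, pd.DataFrame]
    fits: dict[str, dict[str, FittedCandidateModel]]
    best_models: dict[str, str]
    retrodictions: pd.DataFrame
    provenance: dict
    basis: dict[str, PEMBasis] = field(default_factory=dict)


def _sha256(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _reconcile(tree: PhyloTree, table: pd.DataFrame, allow_drop: bool):
    tree_tips = set(tree.tip_labels())
    taxa = set(table["taxon"])
    only_tree = sorted(tree_tips - taxa)
    only_table = sorted(taxa - tree_tips)
    if only_tree or only_table:
        message = (
            f"taxon mismatch between tree and character matrix; "
            f"tree-only: {only_tree}; matrix-only: {only_table}"
        )
        if not allow_drop:
            raise ReconciliationError(message)
        log.warning("%s (dropping to the intersection)", message)
        table = table[table["taxon"].isin(tree_tips)].reset_index(drop=True)
    return table, only_tree, only_table


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute tree -> basis -> model comparison -> retrodiction.

    Training taxa are those with the response observed; everything else
    (fossils, and extant taxa with a missing response) is held out, located
    on the training tree and predicted with the best candidate model.
    Reruns on identical inputs are bit-identical.
    """
    from .cli_io import read_character_matrix, write_outputs

    tree = parse_newick(Path(config.tree_path).read_text())
    table = read_character_matrix(config.matrix_path)
    table, only_tree, only_table = _reconcile(tree, table, config.allow_drop)
    if config.allow_drop and only_tree:
        from .phylo_graph import prune_to

        tree = prune_to(tree, [t for t in tree.tip_labels() if t in set(table["taxon"])]).tree

    model_tables: dict[str, pd.DataFrame] = {}
    all_fits: dict[str, dict[str, FittedCandidateModel]] = {}
    best_models: dict[str, str] = {}
    bases: dict[str, PEMBasis] = {}
    prediction_frames = []
    steepness_used: dict[str, float] = {}

    for response in config.responses:
        observed = table.loc[table[response].notna(), "taxon"].tolist()
        # keep tree tip order for reproducible row order
        training = [t for t in tree.tip_labels() if t in set(observed)]
        infl = influence_matrix(tree, training)
        a = config.steepness
        if config.estimate_steepness:
            y = table.set_index("taxon").loc[infl.tip_labels, response].to_numpy(dtype=float)
            if config.log_response:
                y = np.log(y)
            a = estimate_steepness(infl, y, psi=config.rate)
        steepness_used[response] = a
        basis = build_pem(infl, EdgeWeighting(a=a, psi=config.rate))
        bases[response] = basis

        comparison, fits = model_comparison_table(
            table, basis, response,
            log_response=config.log_response,
            max_k=config.max_k,
            criterion=config.criterion,
        )
        model_tables[response] = comparison
        all_fits[response] = fits
        best_id = comparison.loc[comparison["best"], "model"].iloc[0]
        best_models[response] = best_id

        locations = locate_targets(tree, training)
        prediction_frames.append(
            retrodict_traits(fits[best_id], basis, locations, table)
        )
        log.info(
            "%s: %d training taxa, %d targets, best model %r",
            response, len(training), len(locations), best_id,
        )

    retrodictions = (
        pd.concat(prediction_frames, ignore_index=True)
        if prediction_frames
        else pd.DataFrame()
    )

    provenance = {
        "package": "pemtrait",
        "version": __version__,
        "config": config.to_dict(),
        "inputs": {
            "tree": {"path": str(config.tree_path), "sha256": _sha256(config.tree_path)},
            "matrix": {"path": str(config.matrix_path), "sha256": _sha256(config.matrix_path)},
        },
        "steepness_used": steepness_used,
        "n_taxa": int(len(table)),
        "n_fossil": int((table["status"] == "fossil").sum()),
        "dropped": {"tree_only": only_tree, "matrix_only": only_table},
        "best_models": best_models,
        "library_versions": _library_versions(),
    }

    result = PipelineResult(
        model_tables=model_tables,
        fits=all_fits,
        best_models=best_models,
        retrodictions=retrodictions,
        provenance=provenance,
        basis=bases,
    )
    if config.out_dir is not None:
        write_outputs(result, config.out_dir)
    return result


def _library_versions() -> dict[str, str]:
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }
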