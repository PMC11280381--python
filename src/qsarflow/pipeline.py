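"""End-to-end orchestration: data -> split -> selection -> fit -> validate
-> applicability domain -> screening, with deterministic report emission.

All randomness flows from three named seeds in the configuration (data
synthesis, train/test split, y-scrambling), so identical configurations
produce byte-identical JSON reports.  Descriptor correlations for the
selection stage are computed on training records only, which is why the
split precedes selection here.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic_data
from .applicability_domain import (
    classify_domain,
    leverage_threshold,
    leverages,
    standardized_residuals,
    williams_table,
)
from .dataset_io import Dataset, read_compound_table, split_dataset
from .descriptor_selection import SelectionConfig, prune_descriptors, select_descriptors
from .errors import ConfigurationError
from .mlr_core import MLRModel, fit_mlr
from .screening import ScreeningConfig, screen_candidates
from .validation import GateThresholds, validate_model

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "load_config"]


@dataclass
class InputConfig:
    path: str | None = None
    format: str = "csv"
    activity_column: str = "pIC50"
    activity_kind: str = "pic50"
    ic50_unit: str | None = None
    id_column: str = "id"


@dataclass
class SyntheticConfig:
    seed: int = 0
    overrides: dict = field(default_factory=dict)  # SyntheticSpec field overrides


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    output_dir: str
    input: InputConfig | None = None
    synthetic: SyntheticConfig | None = None
    candidates_path: str | None = None
    split_fraction: float = 0.8
    split_seed: int = 42
    require_external: bool = True
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    n_perm: int = 100
    perm_seed: int = 7
    h_star_override: float | None = None
    residual_limit: float = 3.0
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    gate: GateThresholds = field(default_factory=GateThresholds)

    def __post_init__(self):
        if (self.input is None) == (self.synthetic is None):
            raise ConfigurationError(
                "exactly one of 'input' and 'synthetic' must be configured"
            )


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "input" in kwargs and kwargs["input"] is not None:
        kwargs["input"] = InputConfig(**kwargs["input"])
    if "synthetic" in kwargs and kwargs["synthetic"] is not None:
        kwargs["synthetic"] = SyntheticConfig(**kwargs["synthetic"])
    if "selection" in kwargs:
        kwargs["selection"] = SelectionConfig(**kwargs["selection"])
    if "screening" in kwargs:
        kwargs["screening"] = ScreeningConfig(**kwargs["screening"])
    if "gate" in kwargs:
        kwargs["gate"] = GateThresholds(**kwargs["gate"])
    try:
        return RunConfig(**kwargs)
    except TypeError as exc:
        raise ConfigurationError(f"bad configuration: {exc}") from None


@dataclass
class PipelineResult:
    model: MLRModel
    selected_descriptors: list[str]
    validation: object
    ad_report: object
    screening: object
    artifacts: dict[str, str]


def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    return obj


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(_jsonify(payload), indent=2, sort_keys=True) + "\n")


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute all stages and write every report under ``cfg.output_dir``.

    Artifacts: model.json, validation.json, validation.csv, williams.csv,
    screening.csv and run_log.json (every threshold actually applied,
    the selected descriptors, and the h* used).
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage: data
    if cfg.synthetic is not None:
        spec = synthetic_data.default_paperlike_spec(seed=cfg.synthetic.seed)
        spec = dataclasses.replace(spec, **cfg.synthetic.overrides)
        ds = synthetic_data.generate_dataset(spec)
        data_source = f"synthetic(seed={cfg.synthetic.seed})"
    else:
        ds = read_compound_table(
            cfg.input.path,
            format=cfg.input.format,
            activity_column=cfg.input.activity_column,
            activity_kind=cfg.input.activity_kind,
            ic50_unit=cfg.input.ic50_unit,
            id_column=cfg.input.id_column,
        )
        data_source = str(cfg.input.path)

    candidates = None
    if cfg.candidates_path is not None:
        candidates = read_compound_table(
            cfg.candidates_path,
            activity_column=cfg.input.activity_column if cfg.input else "pIC50",
        )
    elif any(lab == "candidate" for lab in ds.role_labels):
        candidates = ds

    # --- stage: split (before selection so correlations see training rows only)
    ds = split_dataset(ds, cfg.split_fraction, cfg.split_seed, require_test=cfg.require_external)

    # --- stage: descriptor selection
    pruned, removal_log = prune_descriptors(ds, cfg.selection)
    selected = select_descriptors(pruned, cfg.selection)
    ds_model = ds.with_descriptors(selected)

    # --- stage: MLR fit
    X_train, y_train = ds_model.X("train"), ds_model.y("train")
    X_test, y_test = ds_model.X("test"), ds_model.y("test")
    model = fit_mlr(X_train, y_train)

    # --- stage: validation
    report = validate_model(
        model, X_train, y_train, X_test, y_test,
        n_perm=cfg.n_perm, seed=cfg.perm_seed, thresholds=cfg.gate,
    )

    # --- stage: applicability domain
    h_star = (
        cfg.h_star_override
        if cfg.h_star_override is not None
        else leverage_threshold(model.k, model.n_train)
    )
    lev = leverages(X_train)
    lev.update(leverages(X_train, X_test))
    sdr = standardized_residuals(model, X_train, y_train)
    sdr.update(standardized_residuals(model, X_test, y_test))
    roles = {cid: "train" for cid in X_train.index}
    roles.update({cid: "test" for cid in X_test.index})
    if candidates is not None:
        cand = candidates.subset("candidate").with_descriptors(selected)
        cand_X = cand.X()
        lev.update(leverages(X_train, cand_X))
        roles.update({cid: "candidate" for cid in cand_X.index})
    ad = classify_domain(lev, sdr, h_star, cfg.residual_limit)

    # --- stage: screening
    if candidates is not None:
        screening = screen_candidates(
            model, candidates.subset("candidate").with_descriptors(selected),
            cfg.screening, ad,
        )
    else:
        screening = screen_candidates(model, Dataset([], selected), cfg.screening, ad)

    # --- reports
    artifacts = {}
    model_payload = {
        "intercept": model.intercept,
        "coefficients": model.coefficients,
        "standardized_coefficients": model.standardized_coefficients,
        "n_train": model.n_train,
        "k": model.k,
        "r2": model.r2,
        "rmse": model.rmse,
        "residual_sd": model.residual_sd,
        "f_stat": model.f_stat,
        "f_pvalue": model.f_pvalue,
    }
    _write_json(out / "model.json", model_payload)
    artifacts["model"] = str(out / "model.json")

    _write_json(out / "validation.json", report)
    artifacts["validation"] = str(out / "validation.json")
    val_rows = {
        "q2_cv": report.q2_cv,
        "r2_test": report.r2_test,
        "rmse_test": report.rmse_test,
        "r2_pred": report.r2_pred,
        "n_ext": report.n_ext,
        "r2_minus_q2": report.r2_minus_q2,
        "f_pvalue": report.f_pvalue,
        "mean_r2_rand": report.randomization.mean_r2_rand,
        "mean_q2_rand": report.randomization.mean_q2_rand,
        "crp2": report.randomization.crp2,
    }
    pd.DataFrame([val_rows]).to_csv(out / "validation.csv", index=False)
    artifacts["validation_csv"] = str(out / "validation.csv")

    williams_table(ad, roles).to_csv(out / "williams.csv", index=False)
    artifacts["williams"] = str(out / "williams.csv")

    screening.table.to_csv(out / "screening.csv", index=False)
    artifacts["screening"] = str(out / "screening.csv")

    log = {
        "data_source": data_source,
        "n_records": len(ds),
        "split": {
            "fraction": cfg.split_fraction,
            "seed": cfg.split_seed,
            "n_train": int(sum(l == "train" for l in ds.role_labels)),
            "n_test": int(sum(l == "test" for l in ds.role_labels)),
        },
        "pruning_removed": [
            {"descriptor": e.descriptor, "rule": e.rule, "detail": e.detail}
            for e in removal_log
        ],
        "selection_config": cfg.selection,
        "selected_descriptors": selected,
        "gate_thresholds": cfg.gate,
        "randomization": {"n_perm": cfg.n_perm, "seed": cfg.perm_seed},
        "h_star": h_star,
        "h_star_source": "override" if cfg.h_star_override is not None else "3(K+1)/n",
        "residual_limit": cfg.residual_limit,
        "screening_config": cfg.screening,
    }
    _write_json(out / "run_log.json", log)
    artifacts["run_log"] = str(out / "run_log.json")

    return PipelineResult(
        model=model,
        selected_descriptors=selected,
        validation=report,
        ad_report=ad,
        screening=screening,
        artifacts=artifacts,
    )
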