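"""End-to-end pipeline: classify, profile disturbance, score diversity,
run uncertainty scenarios, prioritize, and emit a machine-readable report.

Every number written to ``report.json`` is recomputed by calling the module
operations; the pipeline adds no math of its own.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import BankfullWidthModel, HydrologyClassifier, LayerModels, classify_all_layers
from .core import ClassThresholds, LAYERS, StreamNetwork
from .disturbance import (
    association_stats,
    class_disturbance_frequency,
    disturbance_cascade,
    disturbance_profile,
)
from .io import write_annotations
from .prioritize import PrioritizationParams, prioritize_all
from .typology import (
    assemble_typologies,
    combination_scan,
    filter_min_length,
    select_combination,
    summarize_classes,
)
from .uncertainty import run_scenarios

DEFAULT_BANDS = {"size": 0.0, "gradient": 0.0, "temperature": 0.0, "substrate": 0.0}


def fit_models(training: dict, seed: int = 0) -> LayerModels:
    """Fit the hydrology and bankfull predictors from training tables (as
    emitted by the synthetic generator or assembled from observations)."""
    models = LayerModels()
    if "hydrology" in training and len(training["hydrology"]):
        tab = training["hydrology"]
        # classes observed fewer than 5 times cannot be cross-validated and
        # are dropped from training (they stay predictable as their nearest
        # well-sampled neighbour, mirroring how rarely gauged flow classes
        # behave in practice)
        counts = tab["hydrology_class"].value_counts()
        tab = tab[tab["hydrology_class"].isin(counts[counts >= 5].index)]
        feats = tuple(c for c in tab.columns if c.startswith("hydro_cov_"))
        clf = HydrologyClassifier(random_state=seed)
        clf.fit(tab[list(feats)].to_numpy(float), tab["hydrology_class"].to_numpy())
        models.hydrology = clf
        models.hydrology_features = feats
    if "bankfull" in training and len(training["bankfull"]):
        tab = training["bankfull"]
        reg = BankfullWidthModel(random_state=seed)
        reg.fit(
            tab[["cum_area_km2", "precip_mm"]].to_numpy(float),
            tab["bankfull_width_m"].to_numpy(float),
        )
        models.bankfull = reg
    return models


def run_pipeline(
    network: StreamNetwork,
    dams: pd.DataFrame,
    biosamples: pd.DataFrame,
    thresholds: ClassThresholds | None = None,
    models: LayerModels | None = None,
    params: PrioritizationParams | None = None,
    bands: dict | None = None,
    layer_subset=None,
    excluded_layers=("substrate",),
    out_dir=None,
    seed: int = 0,
) -> dict:
    """Run the full reach-classification and prioritization pipeline.

    Returns a dict with all artifact frames and the JSON-serializable run
    report; writes CSV/JSON artifacts when ``out_dir`` is given.
    """
    t = thresholds or ClassThresholds()
    params = params or PrioritizationParams()
    bands = dict(DEFAULT_BANDS, **(bands or {}))

    classified = classify_all_layers(network, t, models)
    lengths = network.lengths_km

    scan = combination_scan(classified)
    if layer_subset is None:
        layer_subset = select_combination(scan, excluded_layers)
    subset = [l for l in LAYERS if l in layer_subset]

    typologies = assemble_typologies(classified, subset)
    table = summarize_classes(typologies, lengths, t.rarity_percentile)
    table_kept = filter_min_length(table, t.min_class_length_km)

    profiles = disturbance_cascade(disturbance_profile(network, dams), t)
    freq = class_disturbance_frequency(typologies, profiles["disturbed"], lengths)

    # restrict prioritization to classes surviving the minimum-length filter
    kept_codes = set(table_kept["code"])
    kept_typologies = typologies.where(typologies.isin(kept_codes), None)
    prior = prioritize_all(
        table_kept, kept_typologies, profiles["disturbed"], freq, biosamples, lengths, params
    )

    scenarios = run_scenarios(classified, bands, lengths, subset, t)

    associations = {}
    for layer in LAYERS:
        cls = classified[layer]
        if cls.notna().any() and cls.dropna().nunique() >= 2:
            associations[layer] = association_stats(cls, profiles["dominant_class"]).as_dict()

    six = scan[scan["n_layers"] == 6].iloc[0]
    subset_row = scan[scan["layers"] == "-".join(subset)].iloc[0]
    report = {
        "schema_version": 1,
        "package_version": __version__,
        "seed": seed,
        "n_reaches": len(network),
        "total_length_km": float(lengths.sum()),
        "layer_subset": subset,
        "diversity": {
            "all_layers": {"C": int(six["C"]), "C_hat": int(six["C_hat"]), "score": float(six["score"])},
            "selected_subset": {
                "C": int(subset_row["C"]),
                "C_hat": int(subset_row["C_hat"]),
                "score": float(subset_row["score"]),
            },
            "scan": scan.to_dict(orient="records"),
        },
        "typologies": {
            "total": int(len(table)),
            "min_length_retained": int(len(table_kept)),
            "rare": int(table_kept["rare_flag"].sum()),
        },
        "disturbance": {
            "pct_disturbed_length": float(
                100.0 * lengths[profiles["disturbed"].to_numpy()].sum() / lengths.sum()
            ),
            "dominant_class_counts": profiles["dominant_class"].value_counts().to_dict(),
            "pct_connected": float(100.0 * profiles["connected"].mean()),
        },
        "associations": associations,
        "uncertainty_scenarios": scenarios.to_dict(orient="records"),
        "prioritization": {
            "x0": prior["x0"],
            "params": asdict(params),
            "summary": prior["summary"],
        },
    }

    artifacts = {
        "classified": classified,
        "typologies": typologies,
        "typology_summary": table_kept,
        "scan": scan,
        "disturbance": profiles,
        "scenarios": scenarios,
        "prioritization": prior,
        "report": report,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_annotations(out / "classified.csv", classified.reset_index(drop=True))
        write_annotations(out / "typology_summary.csv", table_kept)
        write_annotations(out / "scan.csv", scan)
        write_annotations(out / "disturbance.csv", profiles.reset_index(drop=True))
        prior_rows = []
        for name, idx in prior["selections"].items():
            for rid in idx:
                prior_rows.append({"reach_id": rid, "scenario": name, "class_code": typologies.loc[rid]})
        write_annotations(out / "priorities.csv", pd.DataFrame(prior_rows, columns=["reach_id", "scenario", "class_code"]))
        (out / "report.json").write_text(json.dumps(report, indent=2, default=_json_default))
    return artifacts


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, (np.ndarray, tuple, set)):
        return list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
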