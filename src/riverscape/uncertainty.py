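"""Class-membership uncertainty propagation into typology scenarios.

Each threshold layer carries a per-reach value deviation (same units as the
layer variable); hydrology carries a class-probability vector.  A scenario
re-classifies reaches in one layer (or all layers) to the second most
probable class — for threshold layers, the adjacent class across the
nearest partition boundary crossed by the value +/- deviation band — then
re-assembles typologies and measures length-weighted agreement with the
original table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import ClassThresholds, LAYER_CODES, LAYERS
from .typology import assemble_typologies, rare_classes, summarize_classes

THRESHOLD_LAYERS = ("size", "gradient", "temperature", "substrate")

#: value column feeding each threshold layer's partition
LAYER_VALUE_COLUMNS = {
    "size": "cum_area_km2",
    "gradient": "slope",
    "temperature": "summer_temp_c",
    "substrate": "substrate_diameter_mm",
}


def variant_class(value, deviation, bounds, codes, original):
    """Second-most-probable class for one threshold-layer value.

    If the band ``[value - deviation, value + deviation]`` crosses a
    partition boundary, return the class adjacent to the original across the
    nearest crossed boundary (the boundary closest to the value; an exact
    tie resolves to the lower class).  Otherwise the original class stands.
    """
    if deviation < 0:
        raise ValueError("deviation must be >= 0")
    if original is None or np.isnan(value):
        return original
    bounds = np.asarray(bounds, dtype=float)
    crossed = (bounds > value - deviation) & (bounds < value + deviation)
    # a boundary exactly at the value separates the original from the class
    # below; treat it as crossed whenever there is any deviation at all
    crossed |= (bounds == value) & (deviation > 0)
    if not crossed.any():
        return original
    dist = np.abs(bounds - value)
    dist[~crossed] = np.inf
    b = int(np.argmin(dist))  # argmin takes the lower boundary on ties
    orig_idx = list(codes).index(original)
    # boundary b separates class b (below) from class b+1 (above)
    if orig_idx <= b:
        new_idx = b + 1 if orig_idx == b else orig_idx  # crossing upward
    else:
        new_idx = b if orig_idx == b + 1 else orig_idx  # crossing downward
    return codes[new_idx]


def variant_layer(
    classifications: pd.DataFrame,
    layer: str,
    deviations,
    thresholds: ClassThresholds | None = None,
) -> pd.Series:
    """Variant class codes for one layer across all reaches.

    Threshold layers need per-reach deviations (scalar or aligned array);
    hydrology and confinement switch to the second-highest-probability class
    from the ``p_<class>`` probability columns.
    """
    t = thresholds or ClassThresholds()
    original = classifications[layer]
    if layer in THRESHOLD_LAYERS:
        col = LAYER_VALUE_COLUMNS[layer]
        if col not in classifications.columns:
            raise ValueError(f"variant {layer} needs value column {col!r}")
        values = pd.to_numeric(classifications[col], errors="coerce").to_numpy(dtype=float)
        dev = np.broadcast_to(np.asarray(deviations, dtype=float), values.shape)
        bounds = t.layer_bounds(layer)
        codes = LAYER_CODES[layer]
        out = [
            variant_class(v, d, bounds, codes, o)
            for v, d, o in zip(values, dev, original)
        ]
        return pd.Series(out, index=classifications.index, dtype=object)
    if layer == "hydrology":
        pcols = [c for c in classifications.columns if c.startswith("p_")]
        if not pcols:
            raise ValueError("variant hydrology needs class-probability columns p_<class>")
        proba = classifications[pcols].to_numpy(dtype=float)
        classes = [c.removeprefix("p_") for c in pcols]
        out = pd.Series(None, index=classifications.index, dtype=object)
        ok = original.notna() & ~np.isnan(proba).any(axis=1)
        if ok.any():
            order = np.argsort(-proba[ok.to_numpy()], axis=1)
            second = order[:, 1]
            out[ok] = [classes[j] for j in second]
        out[~ok] = original[~ok]
        return out
    if layer == "confinement":
        # geometry-rule layer: flip across the nearest rule boundary using a
        # width-ratio deviation
        if "valley_width_m" not in classifications.columns:
            raise ValueError("variant confinement needs valley geometry columns")
        raise NotImplementedError  # pragma: no cover - handled by caller
    raise ValueError(f"unknown layer {layer!r}")


def scenario_typologies(
    classifications: pd.DataFrame,
    bands: dict,
    vary,
    layer_subset=LAYERS,
    lengths_km=None,
    thresholds: ClassThresholds | None = None,
):
    """Typology table for one uncertainty scenario.

    ``vary`` is a single layer name or ``"all"``; ``bands`` maps threshold
    layers to deviations (hydrology uses its probability columns, and a
    confinement band is a dict with ``ratio`` and ``coverage`` deviations).
    Returns ``(variant classification frame, variant typology series,
    summary table)``.
    """
    t = thresholds or ClassThresholds()
    subset = [l for l in LAYERS if l in layer_subset]
    varied = subset if vary == "all" else [vary]
    var_cls = classifications.copy()
    for layer in varied:
        if layer not in subset:
            raise ValueError(f"varied layer {layer!r} not in active subset")
        if layer == "confinement":
            var_cls["confinement"] = _variant_confinement(
                classifications, bands.get("confinement", {}), t
            )
        elif layer == "hydrology":
            var_cls["hydrology"] = variant_layer(classifications, "hydrology", None, t)
        else:
            var_cls[layer] = variant_layer(
                classifications, layer, bands.get(layer, 0.0), t
            )
    codes = assemble_typologies(var_cls, subset)
    summary = (
        summarize_classes(codes, lengths_km, t.rarity_percentile)
        if lengths_km is not None
        else None
    )
    return var_cls, codes, summary


def _variant_confinement(classifications, band, t: ClassThresholds):
    """Adjacent confinement class when the geometry band crosses a rule
    boundary: the width ratio varies by ``band['ratio']`` and the coverage by
    ``band['coverage']``; the nearest crossed rule boundary (relative to its
    own scale) decides the direction UC <-> MC <-> C."""
    from .classify import classify_confinement

    ratio_dev = float(band.get("ratio", 0.0))
    cov_dev = float(band.get("coverage", 0.0))
    vw = pd.to_numeric(classifications["valley_width_m"], errors="coerce").to_numpy(float)
    bw = pd.to_numeric(classifications["bankfull_width_m"], errors="coerce").to_numpy(float)
    cov = pd.to_numeric(classifications["valley_coverage"], errors="coerce").to_numpy(float)
    original = classifications["confinement"]
    order = ("C", "MC", "UC")
    out = []
    for v, b, c, o in zip(vw, bw, cov, original):
        if o is None or np.isnan(v) or np.isnan(b) or np.isnan(c):
            out.append(o)
            continue
        # probe the four band corners; the first probe landing in a different
        # class (scanning nearest corners first) is the 2nd most likely class
        ratio = v / b
        candidates = []
        for dr in (ratio_dev, -ratio_dev):
            for dc in (cov_dev, -cov_dev):
                r2, c2 = max(ratio + dr, 1e-9), min(max(c + dc, 0.0), 1.0)
                cls = classify_confinement([r2 * b], [b], [c2], t)[0]
                if cls != o:
                    candidates.append((abs(dr) / max(ratio_dev, 1e-12) + abs(dc) / max(cov_dev, 1e-12), order.index(cls), cls))
        if not candidates:
            out.append(o)
        else:
            candidates.sort()
            out.append(candidates[0][2])
    return pd.Series(out, index=classifications.index, dtype=object)


def agreement(
    original: pd.Series,
    scenario: pd.Series,
    lengths_km,
    original_rare: set[str] | None = None,
    scenario_rare: set[str] | None = None,
) -> dict:
    """Length-weighted agreement between original and scenario typologies.

    Returns percentages of stream length whose reaches keep an identical
    typology code, and (when rarity sets are given) identical rare/not-rare
    status under each table's own rarity computation.  Reaches
    unclassifiable in either table are excluded from the comparison base.
    """
    if not original.index.equals(scenario.index):
        raise ValueError("typology series must cover identical reaches")
    lengths = pd.Series(np.asarray(lengths_km, dtype=float), index=original.index)
    ok = original.notna() & scenario.notna()
    base = lengths[ok].sum()
    if base == 0:
        return {"pct_same_typology": np.nan, "pct_same_rarity": np.nan}
    same = (original[ok] == scenario[ok])
    pct_same = 100.0 * lengths[ok][same].sum() / base
    result = {"pct_same_typology": float(pct_same), "pct_same_rarity": np.nan}
    if original_rare is not None and scenario_rare is not None:
        rare_orig = original[ok].isin(original_rare)
        rare_scen = scenario[ok].isin(scenario_rare)
        agree = rare_orig == rare_scen
        result["pct_same_rarity"] = float(100.0 * lengths[ok][agree].sum() / base)
    return result


def run_scenarios(
    classifications: pd.DataFrame,
    bands: dict,
    lengths_km,
    layer_subset=("size", "gradient", "hydrology", "temperature", "confinement"),
    thresholds: ClassThresholds | None = None,
) -> pd.DataFrame:
    """All single-layer scenarios plus the all-layers scenario.

    Returns one row per scenario with total types, total types above the
    minimum length, rare-type counts and the two agreement percentages
    against the original typology set.
    """
    t = thresholds or ClassThresholds()
    subset = [l for l in LAYERS if l in layer_subset]
    original_codes = assemble_typologies(classifications, subset)
    original_tab = summarize_classes(original_codes, lengths_km, t.rarity_percentile)
    orig_rare = rare_classes(original_tab, t.rarity_percentile)
    rows = [_scenario_row("original", original_tab, None, t)]
    for vary in [*subset, "all"]:
        _, codes, tab = scenario_typologies(
            classifications, bands, vary, subset, lengths_km, t
        )
        scen_rare = rare_classes(tab, t.rarity_percentile)
        ag = agreement(original_codes, codes, lengths_km, orig_rare, scen_rare)
        rows.append(_scenario_row(f"variant_{vary}", tab, ag, t))
    return pd.DataFrame(rows)


def _scenario_row(name, tab, ag, t: ClassThresholds):
    from .typology import filter_min_length

    kept = filter_min_length(tab, t.min_class_length_km)
    n_rare = int(kept["rare_flag"].sum())
    return {
        "scenario": name,
        "total_types": len(tab),
        "total_types_min_length": len(kept),
        "rare_types_min_length": n_rare,
        "pct_rare_types": 100.0 * n_rare / len(kept) if len(kept) else np.nan,
        "pct_same_typology": ag["pct_same_typology"] if ag else 100.0,
        "pct_same_rarity": ag["pct_same_rarity"] if ag else 100.0,
    }
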