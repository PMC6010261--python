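"""Conservation, restoration and biological-monitoring prioritization.

Selections couple each typology's abundance rank with its disturbance
frequency through an inverse-logistic disturbance threshold::

    D(X_r) = L + d / (1 + exp(s * (X_r - X0)))

where X_r is the class abundance rank (1 = rarest), L the acceptable
disturbance frequency for the rarest classes, L + d the limit for the most
abundant, s (< 0) the steepness, and X0 the inflection rank.  With the
defaults L = 0.4, d = 0.5, s = -0.0125, rare classes tolerate no more than
40% disturbed length and abundant ones 90%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PrioritizationParams:
    """Parameters of the inverse-logistic disturbance threshold."""

    L: float = 0.4
    d: float = 0.5
    s: float = -0.0125
    x0: float | None = None  # derived from the typology table when None
    x0_quantile: float = 0.90
    bio_cutoff_year: int = 1990

    def __post_init__(self):
        if not (0.0 <= self.L <= self.L + self.d <= 1.0):
            raise ValueError("need 0 <= L <= L + d <= 1")


def disturbance_threshold(rank, params: PrioritizationParams, x0: float | None = None):
    """Acceptable disturbance frequency D for classes at abundance rank(s).

    Non-decreasing in rank for s < 0, asymptoting to L at the rare end and
    L + d at the abundant end.
    """
    x0 = x0 if x0 is not None else params.x0
    if x0 is None:
        raise ValueError("x0 must be given or set in params")
    x = np.asarray(rank, dtype=float)
    out = params.L + params.d / (1.0 + np.exp(params.s * (x - x0)))
    return float(out) if out.ndim == 0 else out


def auto_inflection(table: pd.DataFrame, quantile: float = 0.90) -> int:
    """Inflection rank from the cumulative length distribution.

    The largest rank x0 such that the classes more abundant than x0 jointly
    hold at least ``quantile`` of total stream length; equivalently the rank
    at which the abundant side crosses the critical cumulative-length
    threshold.  x0 = 0 when the quantile is 1 (every class abundant side).
    """
    tab = table.sort_values("rank")
    total = tab["total_length_km"].sum()
    if total <= 0:
        raise ValueError("typology table has no stream length")
    cum = tab["total_length_km"].cumsum().to_numpy()
    ranks = tab["rank"].to_numpy()
    # abundant-side length above rank r is total - cum(r)
    ok = (total - cum) >= quantile * total - 1e-9 * total
    return int(ranks[ok].max()) if ok.any() else 0


def _class_lookup(table: pd.DataFrame):
    return table.set_index("code")


def select_conservation(
    table: pd.DataFrame, typologies: pd.Series, disturbed: pd.Series
) -> pd.Index:
    """Reaches in rare typologies that are individually not disturbed."""
    rare = set(table.loc[table["rare_flag"], "code"])
    mask = typologies.isin(rare) & ~disturbed.astype(bool)
    return typologies.index[mask]


def select_restoration(
    table: pd.DataFrame,
    typologies: pd.Series,
    disturbed: pd.Series,
    class_frequency: pd.Series,
    biosamples: pd.DataFrame,
    params: PrioritizationParams,
    x0: float | None = None,
) -> pd.Index:
    """Reaches in classes whose disturbance frequency surpasses D, that are
    individually disturbed and have at least one biological sample at or
    after the cutoff year."""
    exceed = _classes_exceeding_d(table, class_frequency, params, x0)
    sampled = _sampled_reaches(biosamples, params.bio_cutoff_year)
    mask = (
        typologies.isin(exceed)
        & disturbed.astype(bool)
        & typologies.index.to_series().isin(sampled)
    )
    return typologies.index[mask]


def select_monitoring(
    table: pd.DataFrame,
    typologies: pd.Series,
    class_frequency: pd.Series,
    biosamples: pd.DataFrame,
    params: PrioritizationParams,
    x0: float | None = None,
) -> pd.Index:
    """Reaches in classes whose disturbance frequency surpasses D and whose
    entire class is unsampled since the cutoff year — the biological
    information gap."""
    exceed = _classes_exceeding_d(table, class_frequency, params, x0)
    sampled = _sampled_reaches(biosamples, params.bio_cutoff_year)
    sampled_classes = set(typologies[typologies.index.to_series().isin(sampled)].dropna())
    target = exceed - sampled_classes
    return typologies.index[typologies.isin(target)]


def _classes_exceeding_d(table, class_frequency, params, x0) -> set[str]:
    if x0 is None and params.x0 is None:
        x0 = auto_inflection(table, params.x0_quantile)
    d_vals = disturbance_threshold(table["rank"].to_numpy(), params, x0)
    freq = table["code"].map(class_frequency).to_numpy(dtype=float)
    return set(table.loc[freq > d_vals, "code"])


def _sampled_reaches(biosamples: pd.DataFrame, cutoff_year: int) -> set[str]:
    if biosamples is None or len(biosamples) == 0:
        return set()
    recent = biosamples[pd.to_numeric(biosamples["year"]) >= cutoff_year]
    return set(recent["reach_id"].astype(str))


def prioritize_all(
    table: pd.DataFrame,
    typologies: pd.Series,
    disturbed: pd.Series,
    class_frequency: pd.Series,
    biosamples: pd.DataFrame,
    lengths_km,
    params: PrioritizationParams | None = None,
) -> dict:
    """Run all three scenarios; returns reach sets plus a summary with
    per-scenario class counts, reach counts, total length, and shares of
    physical diversity and stream length (union double-counting removed in
    the "all" row)."""
    params = params or PrioritizationParams()
    x0 = params.x0 if params.x0 is not None else auto_inflection(table, params.x0_quantile)
    lengths = pd.Series(np.asarray(lengths_km, dtype=float), index=typologies.index)
    sets = {
        "conservation": select_conservation(table, typologies, disturbed),
        "restoration": select_restoration(
            table, typologies, disturbed, class_frequency, biosamples, params, x0
        ),
        "monitoring": select_monitoring(
            table, typologies, class_frequency, biosamples, params, x0
        ),
    }
    total_classes = len(table)
    total_length = float(lengths[typologies.notna()].sum())
    rows = {}
    union = typologies.index[[False] * len(typologies)]
    for name, idx in sets.items():
        union = union.union(idx)
        rows[name] = _scenario_summary(idx, typologies, lengths, total_classes, total_length)
    rows["all"] = _scenario_summary(union, typologies, lengths, total_classes, total_length)
    return {"params": params, "x0": x0, "selections": sets, "summary": rows}


def _scenario_summary(idx, typologies, lengths, total_classes, total_length):
    codes = typologies.loc[idx].dropna()
    length = float(lengths.loc[idx].sum())
    return {
        "classes": int(codes.nunique()),
        "reaches": int(len(idx)),
        "length_km": length,
        "pct_physical_diversity": 100.0 * codes.nunique() / total_classes if total_classes else np.nan,
        "pct_stream_length": 100.0 * length / total_length if total_length else np.nan,
    }
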