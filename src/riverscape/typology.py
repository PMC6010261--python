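"""Typology assembly, diversity scoring, rarity ranking and subset scans.

A typology is the hyphen-joined combination of one class code per active
habitat layer, in the fixed order size-gradient-hydrology-temperature-
confinement-substrate (e.g. ``CK-M-PR2-CD-UC-LB``).  With K_i classes in
layer i, a fully independent set of layers could realize
``C_hat = prod(K_i)`` typologies; the observed count C is far smaller when
layers are physically interrelated, and the diversity score ``C / C_hat``
measures that redundancy.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import ceil, prod

import numpy as np
import pandas as pd

from .core import LAYER_CODES, LAYERS


def assemble_typologies(classifications: pd.DataFrame, layer_subset=LAYERS) -> pd.Series:
    """Hyphen-joined typology code per reach for the active layer subset.

    Layers always join in the canonical order regardless of the order given.
    Reaches unclassifiable in any active layer get ``None``.
    """
    subset = [l for l in LAYERS if l in layer_subset]
    if not subset:
        raise ValueError("layer subset must not be empty")
    missing = [l for l in subset if l not in classifications.columns]
    if missing:
        raise ValueError(f"layers not classified: {missing}")
    parts = classifications[subset]
    ok = parts.notna().all(axis=1)
    codes = pd.Series(None, index=classifications.index, dtype=object)
    if ok.any():
        codes[ok] = parts[ok].agg("-".join, axis=1)
    return codes


def theoretical_class_count(cardinalities) -> int:
    """Factorial-combination class count C_hat = prod(K_i)."""
    ks = [int(k) for k in cardinalities]
    if any(k < 1 for k in ks):
        raise ValueError("layer cardinalities must be >= 1")
    return prod(ks)


def diversity_score(observed: int, theoretical: int) -> float:
    """Diversity score C / C_hat in (0, 1]; low values indicate redundancy
    among habitat layers."""
    if not 0 < observed <= theoretical:
        raise ValueError("need 0 < C <= C_hat")
    return observed / theoretical


def layer_cardinalities(layer_subset=LAYERS, classifications: pd.DataFrame | None = None):
    """Class count per layer: the full published code sets by default, or
    realized counts when a classification table is given."""
    subset = [l for l in LAYERS if l in layer_subset]
    if classifications is None:
        return [len(LAYER_CODES[l]) for l in subset]
    return [int(classifications[l].dropna().nunique()) for l in subset]


def summarize_classes(typologies: pd.Series, lengths_km, rare_percentile: float = 10.0) -> pd.DataFrame:
    """Per-typology summary table: reach count, total length, abundance rank,
    cumulative length fraction and rarity flag.

    Rank 1 is the rarest (smallest total length) class, rank N the most
    abundant; ties break lexicographically by code for determinism.  The
    cumulative length fraction accumulates from rank 1 upward, reaching 1 at
    rank N.  A class is rare when its total length does not exceed the
    nearest-rank ``rare_percentile`` value of the class length distribution.
    """
    lengths = pd.Series(np.asarray(lengths_km, dtype=float), index=typologies.index)
    ok = typologies.notna()
    df = pd.DataFrame({"code": typologies[ok], "length_km": lengths[ok]})
    tab = (
        df.groupby("code", sort=True)
        .agg(n_reaches=("code", "size"), total_length_km=("length_km", "sum"))
        .reset_index()
    )
    tab = tab.sort_values(["total_length_km", "code"], kind="stable").reset_index(drop=True)
    tab["rank"] = np.arange(1, len(tab) + 1)
    total = tab["total_length_km"].sum()
    tab["cumulative_length_fraction"] = tab["total_length_km"].cumsum() / total if total > 0 else np.nan
    cutoff = nearest_rank_percentile(tab["total_length_km"].to_numpy(), rare_percentile)
    tab["rare_flag"] = tab["total_length_km"] <= cutoff
    return tab


def nearest_rank_percentile(values: np.ndarray, percentile: float) -> float:
    """Nearest-rank percentile: the ceil(p/100 * N)-th smallest value."""
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) == 0:
        return np.nan
    k = max(1, ceil(percentile / 100.0 * len(v)))
    return float(v[k - 1])


def filter_min_length(table: pd.DataFrame, min_length_km: float = 1.0) -> pd.DataFrame:
    """Drop typologies whose cumulative length falls below the minimum —
    classes that thin are plausibly artifacts of coarse predictor data.
    Ranks, cumulative fractions and rarity flags are recomputed on the
    retained classes."""
    keep = table[table["total_length_km"] >= min_length_km].copy()
    keep = keep.sort_values(["total_length_km", "code"], kind="stable").reset_index(drop=True)
    keep["rank"] = np.arange(1, len(keep) + 1)
    total = keep["total_length_km"].sum()
    keep["cumulative_length_fraction"] = keep["total_length_km"].cumsum() / total if total > 0 else np.nan
    cutoff = nearest_rank_percentile(keep["total_length_km"].to_numpy(), 10.0)
    keep["rare_flag"] = keep["total_length_km"] <= cutoff
    return keep


def rare_classes(table: pd.DataFrame, percentile: float = 10.0) -> set[str]:
    """Codes of classes whose total length sits in the lowest ``percentile``
    of the class length distribution (nearest-rank)."""
    cutoff = nearest_rank_percentile(table["total_length_km"].to_numpy(), percentile)
    return set(table.loc[table["total_length_km"] <= cutoff, "code"])


@dataclass
class DiversityResult:
    layer_subset: tuple[str, ...]
    observed: int
    theoretical: int

    @property
    def score(self) -> float:
        return diversity_score(self.observed, self.theoretical)


def combination_scan(
    classifications: pd.DataFrame,
    sizes=(6, 5, 4),
    cardinalities: str = "published",
) -> pd.DataFrame:
    """Diversity scan over habitat-layer subsets.

    Evaluates the full six-layer set plus every five- and four-layer subset
    (22 subsets), reporting observed classes C, theoretical classes C_hat
    and the diversity score per subset.  ``cardinalities`` chooses whether
    C_hat multiplies the published per-layer class counts ("published") or
    the class counts realized in this network ("observed").
    """
    rows = []
    for size in sizes:
        for subset in combinations(LAYERS, size):
            codes = assemble_typologies(classifications, subset)
            observed = int(codes.dropna().nunique())
            if cardinalities == "published":
                ks = layer_cardinalities(subset)
            elif cardinalities == "observed":
                ks = layer_cardinalities(subset, classifications)
            else:
                raise ValueError("cardinalities must be 'published' or 'observed'")
            theoretical = theoretical_class_count(ks)
            rows.append(
                {
                    "layers": "-".join(subset),
                    "n_layers": size,
                    "C": observed,
                    "C_hat": theoretical,
                    "score": observed / theoretical if observed else np.nan,
                }
            )
    return pd.DataFrame(rows)


def select_combination(scan: pd.DataFrame, excluded_layers=("substrate",)) -> tuple[str, ...]:
    """Pick the layer subset minimizing the diversity score after dropping
    subsets that include any explicitly excluded layer (substrate by
    default, mirroring the final simplified typology).  Ties break toward
    more layers, then lexicographically."""
    mask = ~scan["layers"].str.split("-").apply(lambda ls: any(l in excluded_layers for l in ls))
    cand = scan[mask & scan["score"].notna()]
    if cand.empty:
        raise ValueError("no subset left after exclusions")
    cand = cand.sort_values(["score", "n_layers", "layers"], ascending=[True, False, True], kind="stable")
    return tuple(cand.iloc[0]["layers"].split("-"))


def match_typology(classifications: pd.DataFrame, pattern: dict, lengths_km=None):
    """Reaches whose classification matches all layer codes in ``pattern``.

    ``pattern`` maps layer name -> code (or collection of accepted codes),
    e.g. ``{"size": "HW", "gradient": "M"}``.  Returns ``(index, total
    length)``; total length is NaN when no lengths are supplied.  Chaining
    calls with nested patterns performs the sequential narrowing used to
    find reference-stream analogs.
    """
    mask = pd.Series(True, index=classifications.index)
    for layer, wanted in pattern.items():
        if layer not in classifications.columns:
            raise ValueError(f"layer {layer!r} not classified")
        accepted = {wanted} if isinstance(wanted, str) else set(wanted)
        mask &= classifications[layer].isin(accepted)
    idx = classifications.index[mask]
    if lengths_km is None:
        return idx, float("nan")
    lengths = pd.Series(np.asarray(lengths_km, dtype=float), index=classifications.index)
    return idx, float(lengths[mask].sum())
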