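"""Anthropogenic disturbance profiling and class-disturbance associations.

Four disturbance pathways are assessed per reach — impoundment, dam
regulation (DOR), upstream fragmentation (DCI), and cumulative landscape
alteration (an ordinal index) — and combined by an ordered cascade from
highest to lowest hypothesized intensity.  The first matching condition
labels the reach with its dominant disturbance class; a reach matching none
is "not disturbed".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .core import ClassThresholds, NFHP_LEVELS, StreamNetwork
from .netops import accumulate, connected_to_terminus, dci, dor

DISTURBANCE_CLASSES = (
    "impoundment",
    "dam_regulation",
    "dam_fragmentation",
    "landscape_alteration",
    "none",
)

#: NFHP cumulative-index levels that fire the landscape-alteration condition.
NFHP_DISTURBED_LEVELS = ("moderate", "high", "very_high")


def disturbance_profile(
    network: StreamNetwork,
    dams: pd.DataFrame,
    runoff_column: str = "runoff_mm_yr",
    urban_column: str = "pct_urban_local",
    agric_column: str = "pct_agric_local",
    nfhp_column: str = "nfhp_category",
) -> pd.DataFrame:
    """Per-reach disturbance metrics prior to the cascade.

    Upstream landcover percentages are area-weighted means of the local
    catchment percentages over the focal and all upstream reaches, which
    equals the percentage of upstream cumulative area under that landcover
    when local percentages are area-consistent.
    """
    out = pd.DataFrame(index=network.df.index)
    out["reach_id"] = network.df["reach_id"]
    out["pct_urban_upstream"] = accumulate(
        network, network.column(urban_column), "area_weighted_mean"
    )
    out["pct_agric_upstream"] = accumulate(
        network, network.column(agric_column), "area_weighted_mean"
    )
    out["dor_percent"] = dor(network, dams, runoff_column)
    out["dci_percent"] = dci(network, dams)
    connected, terminus = connected_to_terminus(network, dams)
    out["connected"] = connected
    out["terminus_type"] = terminus
    out["is_impounded"] = network.df["is_impounded"].astype(bool)
    if nfhp_column in network.df.columns:
        out["nfhp_category"] = network.df[nfhp_column]
    else:
        out["nfhp_category"] = None
    return out


def disturbance_cascade(
    profiles: pd.DataFrame, thresholds: ClassThresholds | None = None
) -> pd.DataFrame:
    """Apply the ordered disturbed/not-disturbed cascade to reach profiles.

    Conditions in order of hypothesized influence: (1) the reach is
    impounded; (2) noticeable dam regulation, DOR >= 4%; (3) fragmented
    upstream watershed, DCI < 75%; (4) landscape alteration, cumulative
    disturbance index at moderate or worse.  Returns the profile frame with
    ``disturbed`` and ``dominant_class`` columns appended.
    """
    t = thresholds or ClassThresholds()
    n = len(profiles)
    dominant = np.full(n, "none", dtype=object)
    nfhp = profiles["nfhp_category"].astype(object)
    unknown = set(nfhp.dropna()) - set(NFHP_LEVELS)
    if unknown:
        raise ValueError(f"unknown NFHP categories: {sorted(unknown)}")
    conds = [
        ("impoundment", profiles["is_impounded"].astype(bool).to_numpy()),
        ("dam_regulation", profiles["dor_percent"].to_numpy(dtype=float) >= t.dor_cutoff_percent),
        ("dam_fragmentation", profiles["dci_percent"].to_numpy(dtype=float) < t.dci_cutoff_percent),
        ("landscape_alteration", nfhp.isin(NFHP_DISTURBED_LEVELS).to_numpy()),
    ]
    for name, mask in conds[::-1]:  # apply low->high so high overwrites
        dominant[mask] = name
    out = profiles.copy()
    out["dominant_class"] = dominant
    out["disturbed"] = dominant != "none"
    return out


def class_disturbance_frequency(
    typologies: pd.Series, disturbed: pd.Series, lengths_km
) -> pd.Series:
    """Length-weighted fraction of each typology's stream length that is
    disturbed, indexed by typology code."""
    lengths = pd.Series(np.asarray(lengths_km, dtype=float), index=typologies.index)
    ok = typologies.notna()
    df = pd.DataFrame(
        {
            "code": typologies[ok],
            "length": lengths[ok],
            "dist_length": lengths[ok] * disturbed[ok].astype(float),
        }
    )
    g = df.groupby("code").sum(numeric_only=True)
    return g["dist_length"] / g["length"]


@dataclass
class AssociationResult:
    """Chi-square association between a habitat layer and the dominant
    disturbance classes, with the classical strength measures."""

    chi2: float
    df: int
    n: int
    g_statistic: float
    phi: float
    contingency_coefficient: float
    cramers_v: float

    def as_dict(self) -> dict:
        return {
            "chi2": self.chi2,
            "df": self.df,
            "n": self.n,
            "g_statistic": self.g_statistic,
            "phi": self.phi,
            "contingency_coefficient": self.contingency_coefficient,
            "cramers_v": self.cramers_v,
        }


def association_stats(layer_classes: pd.Series, disturbance_classes: pd.Series) -> AssociationResult:
    """Association between layer class and dominant disturbance class.

    Builds the r x c contingency table of reach counts (empty rows/columns
    dropped), computes the Pearson chi-square without continuity correction
    and the likelihood-ratio G statistic, and derives phi = sqrt(chi2/n),
    the contingency coefficient sqrt(chi2/(chi2+n)) and Cramer's V =
    sqrt(chi2 / (n * min(r-1, c-1))).
    """
    df = pd.DataFrame({"layer": layer_classes, "disturbance": disturbance_classes}).dropna()
    table = pd.crosstab(df["layer"], df["disturbance"])
    table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    r, c = table.shape
    if r < 2 or c < 2:
        raise ValueError("both factors need at least two non-empty levels")
    n = int(table.to_numpy().sum())
    if (table.to_numpy().sum(axis=1) == 0).any():  # pragma: no cover
        raise ValueError("empty contingency row")
    chi2 = float(chi2_contingency(table, correction=False).statistic)
    g = float(chi2_contingency(table, correction=False, lambda_="log-likelihood").statistic)
    phi = float(np.sqrt(chi2 / n))
    contingency = float(np.sqrt(chi2 / (chi2 + n)))
    cramers_v = float(np.sqrt(chi2 / (n * min(r - 1, c - 1))))
    return AssociationResult(
        chi2=chi2,
        df=(r - 1) * (c - 1),
        n=n,
        g_statistic=g,
        phi=phi,
        contingency_coefficient=contingency,
        cramers_v=cramers_v,
    )
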