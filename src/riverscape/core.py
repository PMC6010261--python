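"""Domain types for dendritic stream networks.

A riverscape is modelled as a forest of in-trees: every reach drains to at
most one downstream reach, terminal reaches drain to an ocean, a Great Lake,
or an interior sink.  All spatial structure used by the pipeline is carried
by the ``reach_id -> downstream_id`` edge list; no geometry is stored.

Units are fixed throughout the package: km for reach length, km^2 for
catchment area, dimensionless rise/run for slope, degrees C for summer
temperature, mm for substrate grain size, m for channel/valley widths,
m^3 for impoundment storage and mm/yr for runoff depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TERMINUS_TYPES = ("ocean", "great_lake", "interior")
TAXA = ("fish", "mussel", "crayfish")
NFHP_LEVELS = ("very_low", "low", "moderate", "high", "very_high")

#: Columns every reach table must provide; everything else is a covariate.
MANDATORY_REACH_COLUMNS = (
    "reach_id",
    "downstream_id",
    "length_km",
    "local_area_km2",
    "slope",
)

LAYERS = ("size", "gradient", "hydrology", "temperature", "confinement", "substrate")

SIZE_CODES = ("HW", "CK", "SR", "MR", "MS", "LR", "GR")
GRADIENT_CODES = ("VL", "L", "M", "MH", "H", "S")
HYDROLOGY_CODES = ("IF1", "IF2", "LTR", "PR1", "PR2", "SNM2", "SHBF", "SSGW", "PF")
TEMPERATURE_CODES = ("CD", "CC", "CL", "CW", "W")
CONFINEMENT_CODES = ("UC", "MC", "C")
SUBSTRATE_CODES = ("SG", "CG", "SC", "LC", "SB", "LB", "LBB")

LAYER_CODES: dict[str, tuple[str, ...]] = {
    "size": SIZE_CODES,
    "gradient": GRADIENT_CODES,
    "hydrology": HYDROLOGY_CODES,
    "temperature": TEMPERATURE_CODES,
    "confinement": CONFINEMENT_CODES,
    "substrate": SUBSTRATE_CODES,
}

#: Representative diameters (mm) of the substrate composition categories.
SUBSTRATE_CATEGORY_DIAMETERS_MM = {
    "fines": 0.03,
    "sand": 1.0,
    "gravel": 33.0,
    "big_rock": 1055.0,
    "bedrock": 2056.0,
}


@dataclass(frozen=True)
class ClassThresholds:
    """Partition boundaries and rule parameters for all habitat layers.

    Threshold layers use left-closed right-open intervals; the first and last
    intervals are open-ended so every finite value receives a class.  The
    defaults reproduce the published size / gradient / temperature / substrate
    partitions and the confinement, regulation, fragmentation, minimum-length
    and rarity rule parameters.
    """

    size_bounds: tuple[float, ...] = (10.0, 100.0, 500.0, 2500.0, 10000.0, 25000.0)
    gradient_bounds: tuple[float, ...] = (0.001, 0.005, 0.02, 0.04, 0.1)
    temperature_bounds: tuple[float, ...] = (19.0, 21.0, 23.0, 25.0)
    substrate_bounds: tuple[float, ...] = (16.0, 64.0, 150.0, 300.0, 600.0, 1000.0)
    # confinement rule: width ratio = valley bottom width / bankfull width
    confinement_ratio_unconfined: float = 4.0
    confinement_ratio_moderate: float = 2.0
    confinement_coverage_high: float = 0.50
    confinement_coverage_low: float = 0.25
    # disturbance cascade cutoffs
    dor_cutoff_percent: float = 4.0
    dci_cutoff_percent: float = 75.0
    # typology bookkeeping
    min_class_length_km: float = 1.0
    rarity_percentile: float = 10.0

    def __post_init__(self) -> None:
        for name in ("size_bounds", "gradient_bounds", "temperature_bounds", "substrate_bounds"):
            b = np.asarray(getattr(self, name), dtype=float)
            if b.ndim != 1 or len(b) < 1 or np.any(np.diff(b) <= 0):
                raise ValueError(f"{name} must be strictly increasing")

    def layer_bounds(self, layer: str) -> np.ndarray:
        return np.asarray(getattr(self, f"{layer}_bounds"), dtype=float)


@dataclass
class ValidationReport:
    """Outcome of structural validation of a reach table."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def __str__(self) -> str:  # pragma: no cover - convenience
        lines = [f"ERROR: {e}" for e in self.errors] + [f"WARNING: {w}" for w in self.warnings]
        return "\n".join(lines) if lines else "OK"


def validate_network(reaches: pd.DataFrame) -> ValidationReport:
    """Structurally validate a reach table.

    Fatal errors: duplicate ids, downstream references to missing reaches,
    cycles, nonpositive lengths, negative areas or slopes.  Warnings: isolated
    reaches (no upstream and no downstream neighbour), the analog of braided
    or artificial channels with no usable topological connection.
    """
    report = ValidationReport()
    ids = reaches["reach_id"].astype(str)
    dup = ids[ids.duplicated()].unique()
    if len(dup):
        report.errors.append(f"duplicate reach ids: {sorted(dup)[:5]}")
        return report

    idx = {r: i for i, r in enumerate(ids)}
    down = reaches["downstream_id"].fillna("").astype(str).to_numpy()
    dangling = [d for d in down if d and d not in idx]
    if dangling:
        report.errors.append(f"dangling downstream references: {sorted(set(dangling))[:5]}")

    bad_len = reaches.loc[pd.to_numeric(reaches["length_km"], errors="coerce") <= 0, "reach_id"]
    if len(bad_len):
        report.errors.append(f"nonpositive length_km on reaches: {list(bad_len.astype(str))[:5]}")
    for col in ("local_area_km2", "slope"):
        bad = reaches.loc[pd.to_numeric(reaches[col], errors="coerce") < 0, "reach_id"]
        if len(bad):
            report.errors.append(f"negative {col} on reaches: {list(bad.astype(str))[:5]}")

    if not dangling:
        # cycle check by pointer-chasing with visitation colouring
        n = len(ids)
        down_i = np.full(n, -1, dtype=np.int64)
        for i, d in enumerate(down):
            if d:
                down_i[i] = idx[d]
        color = np.zeros(n, dtype=np.int8)  # 0 unseen, 1 in progress, 2 done
        for start in range(n):
            if color[start]:
                continue
            path = []
            node = start
            while node != -1 and color[node] == 0:
                color[node] = 1
                path.append(node)
                node = down_i[node]
            if node != -1 and color[node] == 1:
                report.errors.append(f"cycle detected through reach {ids.iloc[node]}")
                for p in path:
                    color[p] = 2
                break
            for p in path:
                color[p] = 2

        has_upstream = set(d for d in down if d)
        isolated = [
            r for r, d in zip(ids, down) if not d and r not in has_upstream
        ]
        # a lone reach network (n == 1) is legitimately a single terminal reach
        if len(ids) > 1 and isolated:
            report.warnings.append(
                f"{len(isolated)} isolated reach(es) with no topological connection: "
                f"{isolated[:5]}"
            )
    return report


class StreamNetwork:
    """A forest of stream reaches with single-downstream topology.

    Wraps a reach attribute table (one row per reach, indexed by ``reach_id``)
    and precomputes the integer topology arrays used by the accumulation and
    connectivity operations.  Construction validates the table and raises
    ``ValueError`` on any fatal structural error.
    """

    def __init__(self, reaches: pd.DataFrame):
        reaches = reaches.copy()
        reaches["reach_id"] = reaches["reach_id"].astype(str)
        if "downstream_id" not in reaches:
            reaches["downstream_id"] = ""
        reaches["downstream_id"] = reaches["downstream_id"].fillna("").astype(str)
        if "terminus_type" not in reaches:
            reaches["terminus_type"] = "interior"
        if "is_impounded" not in reaches:
            reaches["is_impounded"] = False
        missing = [c for c in MANDATORY_REACH_COLUMNS if c not in reaches.columns]
        if missing:
            raise ValueError(f"reach table missing mandatory columns: {missing}")
        report = validate_network(reaches)
        if not report.ok:
            raise ValueError("invalid network:\n" + str(report))
        self.validation = report

        self.df = reaches.set_index("reach_id", drop=False)
        self.ids: list[str] = list(self.df.index)
        self._idx: dict[str, int] = {r: i for i, r in enumerate(self.ids)}
        n = len(self.ids)
        self.downstream_index = np.full(n, -1, dtype=np.int64)
        for i, d in enumerate(self.df["downstream_id"].to_numpy()):
            if d:
                self.downstream_index[i] = self._idx[d]
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i, d in enumerate(self.downstream_index):
            if d >= 0:
                self.children[d].append(i)
        self._topo_order: np.ndarray | None = None

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, reach_id: str) -> bool:
        return str(reach_id) in self._idx

    def index_of(self, reach_id: str) -> int:
        return self._idx[str(reach_id)]

    @property
    def lengths_km(self) -> np.ndarray:
        return self.df["length_km"].to_numpy(dtype=float)

    @property
    def local_areas_km2(self) -> np.ndarray:
        return self.df["local_area_km2"].to_numpy(dtype=float)

    def column(self, name: str) -> np.ndarray:
        """Numeric covariate column as a float array (NaN where missing)."""
        if name not in self.df.columns:
            raise KeyError(f"network has no covariate column {name!r}")
        return pd.to_numeric(self.df[name], errors="coerce").to_numpy(dtype=float)

    def terminal_mask(self) -> np.ndarray:
        return self.downstream_index < 0

    def covariate_columns(self) -> list[str]:
        reserved = set(MANDATORY_REACH_COLUMNS) | {"terminus_type", "is_impounded"}
        return [c for c in self.df.columns if c not in reserved]


def validate_dams(dams: pd.DataFrame, network: StreamNetwork) -> ValidationReport:
    report = ValidationReport()
    unknown = [r for r in dams["reach_id"].astype(str) if r not in network]
    if unknown:
        report.errors.append(f"dams on unknown reaches: {sorted(set(unknown))[:5]}")
    if (pd.to_numeric(dams["storage_m3"], errors="coerce") < 0).any():
        report.errors.append("negative storage_m3")
    return report


def validate_biosamples(samples: pd.DataFrame, network: StreamNetwork) -> ValidationReport:
    report = ValidationReport()
    unknown = [r for r in samples["reach_id"].astype(str) if r not in network]
    if unknown:
        report.warnings.append(f"biosamples on unknown reaches: {sorted(set(unknown))[:5]}")
    bad_taxon = set(samples["taxon"]) - set(TAXA)
    if bad_taxon:
        report.errors.append(f"unknown taxa: {sorted(bad_taxon)}")
    years = pd.to_numeric(samples["year"], errors="coerce")
    if ((years < 1800) | (years > 2100)).any():
        report.errors.append("implausible sample years (outside 1800-2100)")
    return report
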