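"""Synthetic riverscape generator.

Emulates the inputs the classification pipeline consumes in the field —
dendritic reach networks with covarying physical attributes, impoundments,
landcover pressure, a cumulative disturbance index and biological sampling
records — so every stage is testable end to end without geospatial data.

The generative couplings are the standard monotone relationships of fluvial
geomorphology: slope decays as a power of drainage area, summer temperature
warms downstream and cools with elevation, valley bottoms widen (and
confinement relaxes) where slopes are gentle, substrate fines downstream of
steep reaches, bankfull width follows downstream hydraulic geometry
``w = a A^b P^c``, and dams preferentially sit on larger rivers.  Everything
is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import StreamNetwork, TAXA
from .netops import cumulative_area, topological_order


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic riverscape; defaults give a mid-size dendritic
    network with realistic covariation and moderate disturbance."""

    n_reaches: int = 500
    n_outlets: int = 3
    branching_prob: float = 0.5
    seed: int = 0

    # reach geometry
    length_median_km: float = 1.0
    length_sigma: float = 0.5
    area_median_km2: float = 2.0
    area_sigma: float = 0.7

    # slope = slope_coeff * A_cum^-theta * lognormal(noise)
    slope_coeff: float = 0.02
    slope_theta: float = 0.45
    slope_noise_sigma: float = 0.6

    # temperature field (degrees C)
    temp_baseline_c: float = 16.0
    temp_area_warming: float = 1.3      # per log10 km^2 of cumulative area
    temp_elevation_cooling: float = 4.0  # per km of elevation
    temp_latitude_range: float = 4.0     # spread across subnetworks
    temp_noise_sigma: float = 0.8

    # latent hydrology classes
    hydrology_k: int = 5
    hydrology_switch_prob: float = 0.1
    hydrology_n_covariates: int = 5
    hydrology_separation_sd: float = 2.0
    hydrology_covariate_sigma: float = 1.0

    # valley geometry / confinement coupling
    valley_width_scale: float = 120.0
    valley_slope_coupling: float = 0.6
    valley_noise_sigma: float = 0.4

    # bankfull width w = a * A^b * P^c * lognormal(noise)
    bankfull_a: float = 1.2
    bankfull_b: float = 0.42
    bankfull_c: float = 0.5
    bankfull_noise_sigma: float = 0.1

    # substrate Dirichlet concentrations by slope band (gentle -> steep)
    substrate_concentration: float = 8.0

    # dams
    dam_rate: float = 0.08               # network-average placement probability
    dam_storage_median_m3: float = 5e5
    dam_storage_sigma: float = 1.5
    backwater_length_km: float = 2.0

    # landcover and runoff
    landcover_autocorr: float = 0.8
    urban_scale: float = 8.0
    agric_scale: float = 25.0
    runoff_median_mm: float = 400.0
    runoff_sigma: float = 0.2
    precip_median_mm: float = 1100.0
    precip_sigma: float = 0.15

    # biological sampling
    sampling_fraction: float = 0.15
    year_range: tuple[int, int] = (1970, 2017)

    # training tables
    training_fraction: float = 0.4

    def __post_init__(self):
        if self.n_reaches < 1:
            raise ValueError("n_reaches must be >= 1")
        for p in ("branching_prob", "sampling_fraction", "training_fraction", "landcover_autocorr", "hydrology_switch_prob"):
            if not 0.0 <= getattr(self, p) <= 1.0:
                raise ValueError(f"{p} must lie in [0, 1]")
        for p in (
            "length_sigma", "area_sigma", "slope_noise_sigma", "temp_noise_sigma",
            "valley_noise_sigma", "bankfull_noise_sigma", "dam_storage_sigma",
            "runoff_sigma", "precip_sigma", "hydrology_covariate_sigma",
        ):
            if getattr(self, p) < 0:
                raise ValueError(f"{p} must be >= 0")


HYDRO_CLASS_NAMES = ("IF2", "LTR", "PR1", "PR2", "SNM2", "SHBF", "SSGW", "PF", "IF1")


def generate_network(config: SimulationConfig) -> pd.DataFrame:
    """Grow a dendritic reach table (topology only).

    Growth by random upstream attachment: starting from the outlet reaches,
    each step attaches a new reach upstream of an existing one chosen
    uniformly from the eligible pool.  With probability ``branching_prob``
    the pool is reaches that already have one upstream neighbour (creating a
    confluence, capped at two); otherwise it is current tips.  The result is
    always a valid forest with reach counts decaying with stream order.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reaches
    n_out = min(config.n_outlets, n)
    downstream = [-1] * n_out
    n_children = [0] * n_out
    for i in range(n_out, n):
        tips = [j for j in range(i) if n_children[j] == 0]
        once = [j for j in range(i) if n_children[j] == 1]
        if once and (not tips or rng.random() < config.branching_prob):
            parent = once[rng.integers(len(once))]
        else:
            parent = tips[rng.integers(len(tips))]
        downstream.append(parent)
        n_children[parent] += 1
        n_children.append(0)
    ids = [f"r{i:05d}" for i in range(n)]
    terminus = rng.choice(["ocean", "great_lake", "interior"], size=n_out, p=[0.4, 0.2, 0.4])
    df = pd.DataFrame(
        {
            "reach_id": ids,
            "downstream_id": ["" if d < 0 else ids[d] for d in downstream],
            "length_km": 1.0,
            "local_area_km2": 1.0,
            "slope": 0.01,
            "terminus_type": ["interior"] * n,
        }
    )
    for k in range(n_out):
        df.loc[k, "terminus_type"] = terminus[k]
    df["is_impounded"] = False
    return df


def generate_attributes(reaches: pd.DataFrame, config: SimulationConfig):
    """Attach covarying physical attributes to a topology table.

    Returns ``(annotated reach table, truth/training tables dict)``.  The
    training tables are random reach subsets carrying the latent labels
    (hydrology class, noiseless bankfull width target) used to exercise the
    predictive-model interfaces with known ground truth.
    """
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31 - 1) + 1)
    df = reaches.copy()
    n = len(df)
    df["length_km"] = np.exp(rng.normal(np.log(config.length_median_km), config.length_sigma, n))
    df["local_area_km2"] = np.exp(rng.normal(np.log(config.area_median_km2), config.area_sigma, n))

    net = StreamNetwork(df)
    order = topological_order(net)
    a_cum = cumulative_area(net)

    # distance (km) from each reach down to its outlet; elevation grows with it
    dist_out = np.zeros(n)
    for i in order[::-1]:
        d = net.downstream_index[i]
        dist_out[i] = 0.0 if d < 0 else dist_out[d] + df["length_km"].iloc[int(d)]
    elevation_km = 0.02 * dist_out + 0.05
    df["elevation_m"] = elevation_km * 1000.0

    slope_noise = np.exp(rng.normal(0.0, config.slope_noise_sigma, n))
    df["slope"] = config.slope_coeff * a_cum ** (-config.slope_theta) * slope_noise

    # subnetwork root (outlet) of each reach -> pseudo-latitude
    root = np.arange(n)
    for i in order[::-1]:
        d = net.downstream_index[i]
        if d >= 0:
            root[i] = root[d]
    outlets = np.unique(root)
    lat = {o: v for o, v in zip(outlets, rng.uniform(-0.5, 0.5, len(outlets)))}
    lat_effect = np.array([lat[r] for r in root]) * config.temp_latitude_range

    df["summer_temp_c"] = (
        config.temp_baseline_c
        + config.temp_area_warming * np.log10(a_cum + 1.0)
        - config.temp_elevation_cooling * elevation_km
        + lat_effect
        + rng.normal(0.0, config.temp_noise_sigma, n)
    )

    # latent hydrology class: one draw per subnetwork root, inherited
    # upstream with a small switching probability (regional coherence)
    k = config.hydrology_k
    class_names = HYDRO_CLASS_NAMES[:k]
    hydro = np.zeros(n, dtype=np.int64)
    for o in outlets:
        hydro[o] = rng.integers(k)
    for i in order[::-1]:
        d = net.downstream_index[i]
        if d >= 0:
            hydro[i] = rng.integers(k) if rng.random() < config.hydrology_switch_prob else hydro[d]
    df["hydrology_class_true"] = [class_names[h] for h in hydro]
    # class-conditional covariates: class means on a linear arrangement,
    # adjacent classes separated by separation_sd * sigma on every
    # informative covariate, isotropic Gaussian noise — so misclassification
    # concentrates among generatively adjacent classes
    m = config.hydrology_n_covariates
    sep = config.hydrology_separation_sd * config.hydrology_covariate_sigma
    grid = (np.arange(k) - (k - 1) / 2.0) * sep
    signs = np.where(np.arange(m) % 2 == 0, 1.0, -1.0)  # vary direction per covariate
    means = grid[:, None] * signs[None, :]
    X = means[hydro] + rng.normal(0.0, config.hydrology_covariate_sigma, (n, m))
    for j in range(m):
        df[f"hydro_cov_{j + 1}"] = X[:, j]

    # precipitation and runoff depth fields (lognormal, mildly regional)
    reg = np.array([lat[r] for r in root])
    df["precip_mm"] = np.exp(
        rng.normal(np.log(config.precip_median_mm), config.precip_sigma, n) + 0.1 * reg
    )
    df["runoff_mm_yr"] = np.exp(
        rng.normal(np.log(config.runoff_median_mm), config.runoff_sigma, n) + 0.1 * reg
    )

    # bankfull width via downstream hydraulic geometry
    w_true = (
        config.bankfull_a
        * a_cum ** config.bankfull_b
        * (df["precip_mm"].to_numpy() / 1000.0) ** config.bankfull_c
    )
    df["bankfull_width_m"] = w_true * np.exp(rng.normal(0.0, config.bankfull_noise_sigma, n))

    # valley geometry: gentler slopes -> wider, better-covered valley bottoms
    slope_rank = pd.Series(df["slope"]).rank(pct=True).to_numpy()
    width_factor = np.exp(
        -config.valley_slope_coupling * 3.0 * slope_rank
        + rng.normal(0.0, config.valley_noise_sigma, n)
    )
    df["valley_width_m"] = config.valley_width_scale * width_factor * (a_cum / 10.0) ** 0.2
    df["valley_coverage"] = np.clip(
        1.0 - config.valley_slope_coupling * slope_rank + rng.normal(0.0, 0.15, n), 0.0, 1.0
    )

    # substrate composition: steeper reaches skew coarse (Dirichlet)
    base = np.array([0.25, 0.25, 0.25, 0.2, 0.05])
    coarse = np.array([0.02, 0.05, 0.18, 0.45, 0.30])
    frac = np.empty((n, 5))
    for i in range(n):
        mean = base * (1.0 - slope_rank[i]) + coarse * slope_rank[i]
        frac[i] = rng.dirichlet(mean * config.substrate_concentration)
    for j, cat in enumerate(("fines", "sand", "gravel", "big_rock", "bedrock")):
        df[f"frac_{cat}"] = frac[:, j]

    # training tables with known truth
    n_train = max(2, int(round(config.training_fraction * n)))
    train_idx = rng.choice(n, size=n_train, replace=False)
    hydro_cols = [f"hydro_cov_{j + 1}" for j in range(m)]
    training = {
        "hydrology": df.iloc[train_idx][["reach_id", *hydro_cols, "hydrology_class_true"]]
        .rename(columns={"hydrology_class_true": "hydrology_class"})
        .reset_index(drop=True),
        "bankfull": pd.DataFrame(
            {
                "reach_id": df["reach_id"].iloc[train_idx].to_numpy(),
                "cum_area_km2": a_cum[train_idx],
                "precip_mm": df["precip_mm"].iloc[train_idx].to_numpy(),
                "bankfull_width_m": df["bankfull_width_m"].iloc[train_idx].to_numpy(),
            }
        ),
    }
    return df, training


def generate_disturbances(reaches: pd.DataFrame, config: SimulationConfig):
    """Dams, landcover pressure, cumulative-index ordinal and biosamples.

    Dam placement probability increases with cumulative drainage area;
    reaches within a dam's backwater (upstream path length within
    ``backwater_length_km``) are flagged impounded.  Landcover percentages
    are network-autocorrelated (inherited downstream-to-upstream with AR
    mixing).  The cumulative disturbance ordinal is monotone in combined
    landcover pressure.  Returns ``(annotated reaches, dams, biosamples)``.
    """
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31 - 1) + 2)
    df = reaches.copy()
    n = len(df)
    net = StreamNetwork(df)
    order = topological_order(net)
    a_cum = cumulative_area(net)

    # dams: probability scaled so the network average matches dam_rate
    raw = np.sqrt(a_cum)
    p = config.dam_rate * raw * n / raw.sum() if config.dam_rate > 0 else np.zeros(n)
    dam_mask = rng.random(n) < np.clip(p, 0.0, 1.0)
    dam_rows = []
    for i in np.flatnonzero(dam_mask):
        dam_rows.append(
            {
                "dam_id": f"d{len(dam_rows):04d}",
                "reach_id": df["reach_id"].iloc[i],
                "storage_m3": float(
                    np.exp(rng.normal(np.log(config.dam_storage_median_m3), config.dam_storage_sigma))
                ),
            }
        )
    dams = pd.DataFrame(dam_rows, columns=["dam_id", "reach_id", "storage_m3"])

    # backwater: impound the dam reach plus upstream reaches within the
    # configured cumulative path length
    impounded = np.zeros(n, dtype=bool)
    lengths = df["length_km"].to_numpy(dtype=float)
    for i in np.flatnonzero(dam_mask):
        stack = [(int(i), 0.0)]
        while stack:
            j, dist = stack.pop()
            impounded[j] = True
            for c in net.children[j]:
                nd = dist + lengths[c]
                if nd <= config.backwater_length_km:
                    stack.append((int(c), nd))
    df["is_impounded"] = impounded

    # landcover: draw at outlets, inherit upstream with AR(1)-style mixing
    rho = config.landcover_autocorr
    urban = np.zeros(n)
    agric = np.zeros(n)
    for i in order[::-1]:
        d = net.downstream_index[i]
        if d < 0:
            urban[i] = rng.exponential(config.urban_scale)
            agric[i] = rng.exponential(config.agric_scale)
        else:
            urban[i] = rho * urban[d] + (1 - rho) * rng.exponential(config.urban_scale)
            agric[i] = rho * agric[d] + (1 - rho) * rng.exponential(config.agric_scale)
    df["pct_urban_local"] = np.clip(urban, 0.0, 100.0)
    df["pct_agric_local"] = np.clip(agric, 0.0, 100.0)

    # cumulative disturbance ordinal, monotone in landcover pressure
    pressure = df["pct_urban_local"] + 0.5 * df["pct_agric_local"]
    bins = np.quantile(pressure, [0.3, 0.55, 0.75, 0.9])
    level = np.searchsorted(bins, pressure, side="right")
    levels = np.array(["very_low", "low", "moderate", "high", "very_high"], dtype=object)
    df["nfhp_category"] = levels[level]

    # biological samples
    n_samp = int(round(config.sampling_fraction * n))
    rows = []
    if n_samp:
        picks = rng.choice(n, size=n_samp, replace=False)
        y0, y1 = config.year_range
        for i in picks:
            rows.append(
                {
                    "reach_id": df["reach_id"].iloc[int(i)],
                    "taxon": TAXA[rng.integers(len(TAXA))],
                    "year": int(rng.integers(y0, y1 + 1)),
                }
            )
    biosamples = pd.DataFrame(rows, columns=["reach_id", "taxon", "year"])
    return df, dams, biosamples


def simulate_riverscape(config: SimulationConfig | None = None):
    """Full synthetic riverscape: network, attribute covariates, training
    tables, dams and biological samples.

    Returns a dict with keys ``network`` (a validated StreamNetwork),
    ``reaches`` (its table), ``dams``, ``biosamples`` and ``training``.
    """
    config = config or SimulationConfig()
    topo = generate_network(config)
    reaches, training = generate_attributes(topo, config)
    reaches, dams, biosamples = generate_disturbances(reaches, config)
    return {
        "config": config,
        "network": StreamNetwork(reaches),
        "reaches": reaches,
        "dams": dams,
        "biosamples": biosamples,
        "training": training,
    }
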