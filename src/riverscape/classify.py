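"""Per-reach habitat layer classification.

Six habitat layers are classified per reach: size (cumulative drainage
area), gradient (channel slope), hydrology (flow-regime class predicted
from catchment covariates), temperature (mean July-August water
temperature), valley confinement (valley-bottom width relative to bankfull
width and coverage), and substrate (weighted mean particle diameter on a
modified Wentworth scale).

Threshold layers use left-closed right-open intervals with open ends, so
the partition is total, exclusive and monotone.  The two empirically
extrapolated layers (hydrology, bankfull width for confinement) are served
by sklearn-compatible estimators; any model exposing the same surface can
be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import cross_val_score, train_test_split
from sklearn.utils.validation import check_is_fitted

from .core import (
    ClassThresholds,
    LAYER_CODES,
    LAYERS,
    StreamNetwork,
    SUBSTRATE_CATEGORY_DIAMETERS_MM,
)
from .netops import cumulative_area


# ---------------------------------------------------------------------------
# threshold layers
# ---------------------------------------------------------------------------

def _classify_interval(values, bounds: np.ndarray, codes) -> np.ndarray:
    """Left-closed right-open interval classification with open end classes.

    ``bounds`` are the interior boundaries; ``codes`` has ``len(bounds)+1``
    entries.  NaN maps to None (unclassifiable).
    """
    x = np.asarray(values, dtype=float)
    idx = np.searchsorted(bounds, x, side="right")
    out = np.empty(x.shape, dtype=object)
    valid = ~np.isnan(x)
    codes_arr = np.asarray(codes, dtype=object)
    out[valid] = codes_arr[idx[valid]]
    out[~valid] = None
    return out


def classify_size(cumulative_area_km2, thresholds: ClassThresholds | None = None):
    """Size class from cumulative upstream drainage area (km^2)."""
    t = thresholds or ClassThresholds()
    x = np.asarray(cumulative_area_km2, dtype=float)
    if np.nanmin(x, initial=0.0) < 0:
        raise ValueError("negative drainage area")
    return _classify_interval(x, t.layer_bounds("size"), LAYER_CODES["size"])


def classify_gradient(slope, thresholds: ClassThresholds | None = None):
    """Gradient class from dimensionless channel slope (rise/run)."""
    t = thresholds or ClassThresholds()
    x = np.asarray(slope, dtype=float)
    if np.nanmin(x, initial=0.0) < 0:
        raise ValueError("negative slope")
    return _classify_interval(x, t.layer_bounds("gradient"), LAYER_CODES["gradient"])


def classify_temperature(mean_summer_temp_c, thresholds: ClassThresholds | None = None):
    """Temperature class from mean July-August temperature (degrees C).

    Values outside the calibrated 12-30 degree span clamp into the end
    classes rather than erroring: extrapolated temperatures can exceed the
    span the partition was derived on.
    """
    t = thresholds or ClassThresholds()
    return _classify_interval(
        mean_summer_temp_c, t.layer_bounds("temperature"), LAYER_CODES["temperature"]
    )


def classify_substrate(diameter_mm, thresholds: ClassThresholds | None = None):
    """Substrate class from weighted mean particle diameter (mm); diameters
    above the top boundary clamp into the coarsest (boulder-bedrock) class."""
    t = thresholds or ClassThresholds()
    x = np.asarray(diameter_mm, dtype=float)
    if np.nanmin(x, initial=0.0) < 0:
        raise ValueError("negative diameter")
    return _classify_interval(x, t.layer_bounds("substrate"), LAYER_CODES["substrate"])


def weighted_mean_diameter(composition) -> np.ndarray | float:
    """Weighted mean substrate diameter (mm) from category fractions.

    ``composition`` maps the categories fines / sand / gravel / big_rock /
    bedrock to fractions on the unit simplex (a mapping, or a DataFrame with
    one column per category).  Representative diameters: fines 0.03 mm,
    sand 1 mm, gravel 33 mm, big rock 1055 mm, bedrock 2056 mm.
    """
    cats = list(SUBSTRATE_CATEGORY_DIAMETERS_MM)
    diam = np.array([SUBSTRATE_CATEGORY_DIAMETERS_MM[c] for c in cats])
    if isinstance(composition, pd.DataFrame):
        frac = composition[cats].to_numpy(dtype=float)
    else:
        frac = np.array([composition[c] for c in cats], dtype=float).T
    frac = np.atleast_2d(frac)
    if (frac < 0).any() or not np.allclose(frac.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("substrate fractions must be nonnegative and sum to 1")
    out = frac @ diam
    return out if out.size > 1 else float(out[0])


def classify_confinement(
    valley_width_m, bankfull_width_m, coverage, thresholds: ClassThresholds | None = None
):
    """Valley confinement class from the valley-bottom geometry of a reach.

    With ratio = valley-bottom width / bankfull width and coverage the
    fraction of reach length with a valley bottom present:

    - unconfined (UC): ratio >= 4 and coverage >= 0.5;
    - moderately confined (MC): ratio >= 4 with coverage in [0.25, 0.5), or
      ratio in [2, 4) with coverage >= 0.5;
    - confined (C): everything else.
    """
    t = thresholds or ClassThresholds()
    vw = np.asarray(valley_width_m, dtype=float)
    bw = np.asarray(bankfull_width_m, dtype=float)
    cov = np.asarray(coverage, dtype=float)
    if np.nanmin(bw, initial=1.0) <= 0 or np.nanmin(vw, initial=1.0) <= 0:
        raise ValueError("widths must be positive")
    if np.nanmin(cov, initial=0.0) < 0 or np.nanmax(cov, initial=0.0) > 1:
        raise ValueError("coverage must lie in [0, 1]")
    ratio = vw / bw
    out = np.full(ratio.shape, "C", dtype=object)
    wide = ratio >= t.confinement_ratio_unconfined
    mid = (ratio >= t.confinement_ratio_moderate) & ~wide
    hi_cov = cov >= t.confinement_coverage_high
    lo_cov = (cov >= t.confinement_coverage_low) & ~hi_cov
    out[wide & hi_cov] = "UC"
    out[(wide & lo_cov) | (mid & hi_cov)] = "MC"
    out[np.isnan(ratio) | np.isnan(cov)] = None
    return out


# ---------------------------------------------------------------------------
# temperature partition derivation
# ---------------------------------------------------------------------------

def derive_temperature_partitions(
    values,
    k_min: int = 2,
    k_max: int = 15,
    elbow_fraction: float = 0.10,
    random_state: int = 0,
):
    """Derive temperature class boundaries by 1-D k-means.

    Runs k-means for k in [k_min, k_max] on the reach temperature values and
    picks the most parsimonious k by an elbow rule: the k with the largest
    relative drop in within-group sum of squared distances over k-1.  On
    well-separated groups the drop spikes at the true group count; on
    unstructured data the drop decays smoothly and the minimum k wins.
    Drops below ``elbow_fraction`` never count, so a flat SSD profile falls
    back to ``k_min``.  Boundaries are midpoints between adjacent sorted
    cluster centers.

    Returns ``(k_star, boundaries)`` with ``len(boundaries) == k_star - 1``.
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    x = x[~np.isnan(x[:, 0])]
    if len(np.unique(x)) < k_max:
        raise ValueError(f"need at least k_max={k_max} distinct values")
    ssd = {}
    centers = {}
    for k in range(k_min - 1 if k_min > 1 else k_min, k_max + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=random_state).fit(x)
        ssd[k] = km.inertia_
        centers[k] = np.sort(km.cluster_centers_[:, 0])
    k_star, best_drop = k_min, 0.0
    for k in range(k_min, k_max + 1):
        prev = ssd[k - 1]
        if prev <= 0:
            break
        drop = (prev - ssd[k]) / prev
        if drop > elbow_fraction and drop > best_drop:
            k_star, best_drop = k, drop
    c = centers[k_star]
    boundaries = (c[:-1] + c[1:]) / 2.0
    return k_star, boundaries


# ---------------------------------------------------------------------------
# predictive models for the empirically extrapolated layers
# ---------------------------------------------------------------------------

class HydrologyClassifier(ClassifierMixin, BaseEstimator):
    """Flow-regime class predictor over catchment covariates.

    A thin sklearn-compatible wrapper (default: random forest) that reports a
    cross-validated held-out accuracy at fit time and exposes per-reach class
    probability vectors, which downstream feed the membership-uncertainty
    scenarios.

    Parameters
    ----------
    n_estimators : trees in the default forest.
    cv : folds for the held-out accuracy estimate.
    random_state : seed for the forest and the CV shuffle.
    model : optional externally constructed classifier implementing
        fit/predict/predict_proba; overrides the default forest.
    """

    def __init__(self, n_estimators: int = 200, cv: int = 5, random_state: int = 0, model=None):
        self.n_estimators = n_estimators
        self.cv = cv
        self.random_state = random_state
        self.model = model

    def _make_model(self):
        if self.model is not None:
            return self.model
        return RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=self.random_state, oob_score=False
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("training set must contain at least two classes")
        if counts.min() < 5:
            raise ValueError("every class needs at least 5 training samples")
        self.model_ = self._make_model()
        cv = min(self.cv, int(counts.min()))
        self.holdout_accuracy_ = float(
            np.mean(cross_val_score(self._make_model(), X, y, cv=cv, scoring="accuracy"))
        )
        self.model_.fit(X, y)
        self.classes_ = self.model_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(np.asarray(X, dtype=float))


class BankfullWidthModel(RegressorMixin, BaseEstimator):
    """Bankfull width predictor from drainage area and precipitation.

    Downstream hydraulic geometry treats bankfull width as a power law of
    drainage area (and here precipitation), ``w = a * A^b * P^c``, so the
    default model is an ordinary least-squares fit in log-log space, which
    guarantees strictly positive predictions.  A held-out R^2 (on the width
    scale) is computed at fit time.  Any regressor operating on the
    log-transformed design can be substituted via ``model``.
    """

    def __init__(self, test_size: float = 0.25, random_state: int = 0, model=None):
        self.test_size = test_size
        self.random_state = random_state
        self.model = model

    def _make_model(self):
        return self.model if self.model is not None else LinearRegression()

    @staticmethod
    def _design(X):
        X = np.asarray(X, dtype=float)
        if (X <= 0).any():
            raise ValueError("features must be strictly positive for the log design")
        return np.log(X)

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        if (y <= 0).any():
            raise ValueError("bankfull widths must be positive")
        Z = self._design(X)
        if len(y) < 8:
            raise ValueError("too few training rows")
        Ztr, Zte, ytr, yte = train_test_split(
            Z, np.log(y), test_size=self.test_size, random_state=self.random_state
        )
        probe = self._make_model().fit(Ztr, ytr)
        pred = np.exp(probe.predict(Zte))
        truth = np.exp(yte)
        ss_res = float(np.sum((truth - pred) ** 2))
        ss_tot = float(np.sum((truth - truth.mean()) ** 2))
        self.holdout_r2_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        self.model_ = self._make_model().fit(Z, np.log(y))
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return np.exp(self.model_.predict(self._design(X)))


# ---------------------------------------------------------------------------
# whole-network classification
# ---------------------------------------------------------------------------

@dataclass
class LayerModels:
    """Fitted predictive models for the empirically extrapolated layers."""

    hydrology: HydrologyClassifier | None = None
    hydrology_features: tuple[str, ...] = ()
    bankfull: BankfullWidthModel | None = None
    bankfull_features: tuple[str, ...] = ("cum_area_km2", "precip_mm")


SUBSTRATE_FRACTION_COLUMNS = ("frac_fines", "frac_sand", "frac_gravel", "frac_big_rock", "frac_bedrock")


def classify_all_layers(
    network: StreamNetwork,
    thresholds: ClassThresholds | None = None,
    models: LayerModels | None = None,
    layers=LAYERS,
) -> pd.DataFrame:
    """Classify every reach of a network in all requested habitat layers.

    Returns a frame indexed like the network with one code column per layer
    (None where the reach lacks the covariates for that layer), the derived
    quantities (cumulative area, weighted mean substrate diameter, bankfull
    width used), and, when hydrology is predicted from a model, per-class
    probability columns ``p_<class>``.
    """
    t = thresholds or ClassThresholds()
    m = models or LayerModels()
    df = network.df
    out = pd.DataFrame(index=df.index)
    out["reach_id"] = df["reach_id"]

    if "size" in layers:
        out["cum_area_km2"] = cumulative_area(network)
        out["size"] = classify_size(out["cum_area_km2"], t)
    if "gradient" in layers:
        out["slope"] = df["slope"]
        out["gradient"] = classify_gradient(df["slope"], t)
    if "temperature" in layers:
        if "summer_temp_c" in df.columns:
            out["summer_temp_c"] = network.column("summer_temp_c")
            out["temperature"] = classify_temperature(out["summer_temp_c"], t)
        else:
            out["temperature"] = None
    if "hydrology" in layers:
        if m.hydrology is not None and all(c in df.columns for c in m.hydrology_features):
            X = df[list(m.hydrology_features)].to_numpy(dtype=float)
            ok = ~np.isnan(X).any(axis=1)
            codes = np.full(len(df), None, dtype=object)
            proba = np.full((len(df), len(m.hydrology.classes_)), np.nan)
            if ok.any():
                codes[ok] = m.hydrology.predict(X[ok])
                proba[ok] = m.hydrology.predict_proba(X[ok])
            out["hydrology"] = codes
            for j, cls in enumerate(m.hydrology.classes_):
                out[f"p_{cls}"] = proba[:, j]
        elif "hydrology_class" in df.columns:
            out["hydrology"] = df["hydrology_class"].where(df["hydrology_class"].notna(), None)
        else:
            out["hydrology"] = None
    if "confinement" in layers:
        if "bankfull_width_m" in df.columns:
            bw = network.column("bankfull_width_m")
        elif m.bankfull is not None and all(c in set(df.columns) | set(out.columns) for c in m.bankfull_features):
            feats = pd.concat([df, out], axis=1)
            X = feats.loc[:, ~feats.columns.duplicated()][list(m.bankfull_features)].to_numpy(dtype=float)
            bw = m.bankfull.predict(X)
            out["bankfull_width_m"] = bw
        else:
            bw = np.full(len(df), np.nan)
        if "valley_width_m" in df.columns and "valley_coverage" in df.columns:
            out["valley_width_m"] = network.column("valley_width_m")
            out["valley_coverage"] = network.column("valley_coverage")
            out["bankfull_width_m"] = bw
            out["confinement"] = classify_confinement(
                out["valley_width_m"], bw, out["valley_coverage"], t
            )
        else:
            out["confinement"] = None
    if "substrate" in layers:
        if all(c in df.columns for c in SUBSTRATE_FRACTION_COLUMNS):
            comp = df[list(SUBSTRATE_FRACTION_COLUMNS)].to_numpy(dtype=float)
            ok = ~np.isnan(comp).any(axis=1)
            dmm = np.full(len(df), np.nan)
            if ok.any():
                comp_df = pd.DataFrame(
                    comp[ok], columns=[c.removeprefix("frac_") for c in SUBSTRATE_FRACTION_COLUMNS]
                )
                dmm[ok] = np.atleast_1d(weighted_mean_diameter(comp_df))
            out["substrate_diameter_mm"] = dmm
            out["substrate"] = classify_substrate(dmm, t)
        elif "substrate_diameter_mm" in df.columns:
            out["substrate_diameter_mm"] = network.column("substrate_diameter_mm")
            out["substrate"] = classify_substrate(out["substrate_diameter_mm"], t)
        else:
            out["substrate"] = None
    return out
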