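"""Group-behavior phenotyping: AL/AD/SL/SD features, PCA, clustering, stats.

Each animal is summarised by four features:

* ``AL`` / ``AD`` -- normalized locomotor activity averaged over light /
  dark time points.  Activity in each 2-h bin is first normalized to the
  animal's maximum bin over the whole recording (x100), bins at the same
  time of day are averaged across days, and the day-averaged profile is
  then averaged over the light (resp. dark) slots.
* ``SL`` / ``SD`` -- sociability: the animal's per-partner-averaged CCR
  over pooled light / dark seconds.

These features feed a PCA (z-scored by default) and k-means clustering;
the cluster count is chosen as the k with maximal mean silhouette over a
candidate range, with the inertia curve reported for elbow inspection.

Statistical helpers: Pearson chi-square on pooled category-seconds
contingencies (light/dark x four proximity categories, or groups x
categories), the step-down Holm-Sidak adjustment for families of
per-comparison p-values, and the coefficient of variation used for
behavioral-variability comparisons.  Omnibus two-way ANOVAs are
delegated to standard statistical software via the tidy exports; only
the adjustment layer is implemented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

logger = logging.getLogger("cagetrack.phenotype")

__all__ = [
    "FEATURE_NAMES",
    "extract_features",
    "PCAResult",
    "pca_embed",
    "ClusteringReport",
    "select_k",
    "coefficient_of_variation",
    "chi_square_light_dark",
    "holm_sidak_adjust",
]

FEATURE_NAMES = ("AL", "AD", "SL", "SD")


def extract_features(
    activity: pd.DataFrame,
    phase_ccr_per_animal: pd.DataFrame,
    labels: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-animal (AL, AD, SL, SD) feature table.

    Parameters
    ----------
    activity:
        Normalized long activity table (from
        :func:`cagetrack.locomotion.normalize_activity`) with columns
        ``tag_id, window_start, phase, relative_activity``; 2-h bins over
        the full recording.
    phase_ccr_per_animal:
        Per-animal CCR by phase: columns ``tag_id, phase, ccr_pct`` with
        phase in {"light", "dark"} (e.g. per-animal means of
        :func:`cagetrack.proximity.phase_pooled_ccr`).
    labels:
        Optional per-animal grouping labels (indexed or keyed by
        ``tag_id``) appended to the output.

    Animals missing an entire phase are excluded with a warning.
    """
    act = activity[activity["phase"].isin(["light", "dark"])].copy()
    act["slot"] = pd.to_datetime(act["window_start"]).dt.strftime("%H:%M")
    # average across days at each time-of-day slot, then across slots per phase
    day_avg = (
        act.groupby(["tag_id", "phase", "slot"], sort=False)["relative_activity"]
        .mean()
        .reset_index()
    )
    phase_avg = (
        day_avg.groupby(["tag_id", "phase"], sort=False)["relative_activity"]
        .mean()
        .unstack("phase")
    )
    soc = phase_ccr_per_animal.pivot(index="tag_id", columns="phase", values="ccr_pct")

    rows = []
    for tag in phase_avg.index:
        vals = {
            "AL": phase_avg.at[tag, "light"] if "light" in phase_avg else np.nan,
            "AD": phase_avg.at[tag, "dark"] if "dark" in phase_avg else np.nan,
            "SL": soc.at[tag, "light"] if tag in soc.index and "light" in soc else np.nan,
            "SD": soc.at[tag, "dark"] if tag in soc.index and "dark" in soc else np.nan,
        }
        if any(pd.isna(v) for v in vals.values()):
            logger.warning("tag %r missing a full phase; excluded from features", tag)
            continue
        rows.append({"tag_id": tag, **vals})
    feats = pd.DataFrame(rows, columns=["tag_id", *FEATURE_NAMES])
    if labels is not None:
        lab = labels.set_index("tag_id") if "tag_id" in labels.columns else labels
        feats = feats.join(lab, on="tag_id")
    return feats


@dataclass
class PCAResult:
    """PC scores and loadings for the four-feature space."""

    scores: pd.DataFrame            # tag_id x PC columns, zero column means
    loadings: pd.DataFrame          # feature x PC, orthonormal rows of V^T
    explained_variance_ratio: np.ndarray
    feature_means: np.ndarray
    feature_scales: np.ndarray


def _feature_matrix(features: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols = [c for c in FEATURE_NAMES if c in features.columns]
    if len(cols) != len(FEATURE_NAMES):
        missing = set(FEATURE_NAMES) - set(cols)
        raise ValueError(f"feature table missing columns {sorted(missing)}")
    x = features[list(FEATURE_NAMES)].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("feature matrix contains missing values")
    return x, list(FEATURE_NAMES)


def pca_embed(
    features: pd.DataFrame, n_components: int = 2, standardize: bool = True
) -> PCAResult:
    """PCA of the per-animal feature table.

    Features are z-scored by default.  The sign of each component is
    fixed so its largest-magnitude loading is positive, making results
    deterministic up to that convention.  Raises on zero-variance
    features (they carry no information and break standardization).
    """
    x, names = _feature_matrix(features)
    if x.shape[0] < 3:
        raise ValueError("PCA needs at least three animals")
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    zero_var = np.where(sd == 0)[0]
    if zero_var.size:
        raise ValueError(
            f"zero-variance feature(s): {[names[i] for i in zero_var]}"
        )
    scale = sd if standardize else np.ones_like(sd)
    z = (x - mu) / scale
    n_components = min(n_components, x.shape[1], x.shape[0])
    p = PCA(n_components=n_components, svd_solver="full")
    scores = p.fit_transform(z)
    load = p.components_  # (n_comp, n_feat)
    for k in range(load.shape[0]):
        i = np.argmax(np.abs(load[k]))
        if load[k, i] < 0:
            load[k] = -load[k]
            scores[:, k] = -scores[:, k]
    pc_cols = [f"PC{k + 1}" for k in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=features["tag_id"], columns=pc_cols),
        loadings=pd.DataFrame(load.T, index=names, columns=pc_cols),
        explained_variance_ratio=p.explained_variance_ratio_,
        feature_means=mu,
        feature_scales=scale,
    )


@dataclass
class ClusteringReport:
    """K-means model selection over a candidate range of cluster counts."""

    k: int
    inertia: dict[int, float]
    silhouette: dict[int, float]
    labels: np.ndarray              # 1-based cluster labels at the chosen k
    pca: PCAResult
    seed: int = 0
    tag_ids: list[str] = field(default_factory=list)


def select_k(
    features: pd.DataFrame,
    k_range: range | list[int] = range(2, 7),
    seed: int = 0,
    n_restarts: int = 50,
    standardize: bool = True,
    n_components: int = 2,
) -> ClusteringReport:
    """Choose the cluster count by maximal mean silhouette on PC scores.

    K-means (``n_restarts`` restarts, fixed seed) is run on the leading
    PC scores for each candidate k; the inertia curve is reported for
    elbow inspection and the k with the highest mean silhouette is
    selected.  Reproducible bit-for-bit for a fixed seed.
    """
    ks = sorted(set(int(k) for k in k_range))
    pca = pca_embed(features, n_components=n_components, standardize=standardize)
    z = pca.scores.to_numpy()
    n = z.shape[0]
    if np.allclose(z, z[0]):
        raise ValueError("all animals identical in feature space; clustering degenerate")
    if not ks or ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}] for {n} animals")
    inertia: dict[int, float] = {}
    sil: dict[int, float] = {}
    models = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        lab = km.fit_predict(z)
        inertia[k] = float(km.inertia_)
        sil[k] = float(silhouette_score(z, lab))
        models[k] = lab
    best = max(ks, key=lambda k: sil[k])
    return ClusteringReport(
        k=best,
        inertia=inertia,
        silhouette=sil,
        labels=models[best] + 1,
        pca=pca,
        seed=seed,
        tag_ids=list(features["tag_id"]),
    )


def coefficient_of_variation(values) -> float:
    """Sample coefficient of variation: sd (ddof=1) / mean.

    Returns NaN (with a warning) when the mean is zero; dimensionless and
    invariant under positive rescaling.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least two values")
    m = v.mean()
    if m == 0:
        logger.warning("zero mean; coefficient of variation undefined")
        return float("nan")
    return float(v.std(ddof=1) / m)


def chi_square_light_dark(counts) -> tuple[float, float, int]:
    """Pearson chi-square on a category-seconds contingency table.

    ``counts`` is a 2-D table, e.g. light/dark x {Same, Close,
    Intermediate, Away} (df = 3) or group-size x categories.  Returns
    ``(statistic, p_value, dof)``.  Zero rows or columns are an error
    (expected counts must be positive).
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero row or column")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue), int(res.dof)


def holm_sidak_adjust(p_values) -> np.ndarray:
    """Step-down Holm-Sidak adjustment of a family of p-values.

    Sort ascending; the i-th smallest (1-based) becomes
    ``1 - (1 - p_i)**(m - i + 1)``; enforce monotone non-decreasing down
    the sorted list; cap at 1; return in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out
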