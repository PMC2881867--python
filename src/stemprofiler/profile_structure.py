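"""PCA co-clustering on focused gene lists and exponential-trendline
relatedness between score tables.

Samples are embedded on the first principal components of a
probe-subsetted, per-probe mean-centered matrix (no unit-variance scaling
by default, preserving magnitude structure). Co-clustering is quantified
by the mean silhouette width in component space — a numeric stand-in for
the visual "clusters circled on the plot" reading, and labeled as such.

Relatedness between two per-sample score tables is measured the way
spreadsheet "exponential trendlines" do: ordinary least squares of
``ln y`` on ``x``, i.e. ``y = a * exp(b * x)``, optionally after a median
split of the cohort on the x-axis scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples

from .expr_io import ExpressionMatrix, GeneSet, subset_matrix
from .stemness import median_split

log = logging.getLogger(__name__)


@dataclass
class PCAEmbedding:
    """Sample coordinates on the leading principal components."""

    coordinates: pd.DataFrame  # index: sample_id, columns: PC1..PCk
    explained_variance_fraction: np.ndarray

    def __post_init__(self) -> None:
        evf = np.asarray(self.explained_variance_fraction, dtype=float)
        if np.any(np.diff(evf) > 1e-12) or np.any(evf < -1e-12) or evf.sum() > 1 + 1e-9:
            raise ValueError("explained variance fractions must be non-increasing in [0, 1]")
        self.explained_variance_fraction = evf


@dataclass
class TrendFit:
    """Log-linear exponential fit y = a * exp(b * x)."""

    a: float
    b: float
    r_fit: float  # Pearson r of (x, ln y)
    n: int

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("multiplier a must be positive")
        if self.n < 3:
            raise ValueError("fit needs >= 3 points")
        if not -1.0 <= self.r_fit <= 1.0:
            raise ValueError("r_fit out of [-1, 1]")


def pca_embed(
    matrix: ExpressionMatrix,
    gene_set: Optional[GeneSet] = None,
    n_components: int = 3,
    transform: str = "linear",
    scale_unit_variance: bool = False,
) -> PCAEmbedding:
    """Embed samples on the top principal components of a gene-list view.

    Probes are mean-centered; unit-variance scaling is off by default.
    The per-component sign is fixed by convention: the largest-magnitude
    probe loading is made positive, so output is deterministic.
    """
    m = subset_matrix(matrix, gene_set) if gene_set is not None else matrix
    if m.shape[0] < n_components:
        raise ValueError(
            f"only {m.shape[0]} probes available for {n_components} components"
        )
    if m.shape[1] < n_components + 1:
        raise ValueError(
            f"need >= {n_components + 1} samples for {n_components} components"
        )
    X = m.values.to_numpy(dtype=float).T  # samples x probes
    if transform == "log2":
        X = np.log2(X + 1.0)
    elif transform != "linear":
        raise ValueError(f"transform must be 'linear' or 'log2', got {transform!r}")
    if scale_unit_variance:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = X / sd

    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    loadings = pca.components_
    for k in range(n_components):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            coords[:, k] = -coords[:, k]
    cols = [f"PC{k + 1}" for k in range(n_components)]
    return PCAEmbedding(
        coordinates=pd.DataFrame(coords, index=m.sample_ids, columns=cols),
        explained_variance_fraction=pca.explained_variance_ratio_,
    )


def cluster_separation(embedding: PCAEmbedding, labels: pd.Series) -> dict:
    """Mean silhouette width of the labeled samples in component space.

    Labels with a single sample are excluded with a warning; if everything
    is a singleton (or only one label survives) that's an error. Returns
    the overall mean and per-label means.
    """
    labels = labels.reindex(embedding.coordinates.index)
    if labels.isna().any():
        missing = embedding.coordinates.index[labels.isna()].tolist()
        raise ValueError(f"samples without labels: {missing}")
    counts = labels.value_counts()
    singletons = counts[counts < 2].index.tolist()
    if singletons:
        log.warning("excluding singleton labels from silhouette: %s", singletons)
    keep = ~labels.isin(singletons)
    kept_labels = labels[keep]
    if kept_labels.nunique() < 2:
        raise ValueError("need >= 2 labels with >= 2 samples each for silhouette")
    X = embedding.coordinates.loc[keep].to_numpy(dtype=float)
    widths = silhouette_samples(X, kept_labels.to_numpy())
    per_label = {
        lab: float(widths[(kept_labels == lab).to_numpy()].mean())
        for lab in sorted(kept_labels.unique())
    }
    return {
        "mean_silhouette": float(widths.mean()),
        "per_label_silhouette": per_label,
        "n_samples_used": int(keep.sum()),
        "excluded_singletons": singletons,
    }


def fit_exponential_trend(x_values, y_values) -> TrendFit:
    """Fit y = a * exp(b * x) by OLS on (x, ln y).

    This is the spreadsheet trendline convention; ``r_fit`` is the Pearson
    correlation of x with ln y. Non-positive y or constant x is an error.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if len(x) < 3:
        raise ValueError(f"fit needs >= 3 points, got {len(x)}")
    bad = np.flatnonzero(y <= 0)
    if bad.size:
        raise ValueError(
            f"y must be positive for an exponential fit; point {bad[0]} has y={y[bad[0]]}"
        )
    if np.ptp(x) == 0:
        raise ValueError("x is constant; trend undefined")
    ln_y = np.log(y)
    if np.ptp(ln_y) == 0:  # flat y: slope 0, correlation defined as 0
        return TrendFit(a=float(y[0]), b=0.0, r_fit=0.0, n=len(x))
    fit = stats.linregress(x, ln_y)
    return TrendFit(
        a=float(np.exp(fit.intercept)),
        b=float(fit.slope),
        r_fit=float(fit.rvalue),
        n=len(x),
    )


def relatedness_analysis(
    scores_ref: pd.DataFrame,
    scores_treatment: pd.DataFrame,
    split: str = "none",
) -> dict[str, TrendFit]:
    """Exponential-trendline relatedness of treatment-profile similarity
    (y) to reference-profile similarity (x), optionally per median-split
    subgroup of the x scores.

    Both tables must cover the same samples. Returns ``{"all": fit}`` or
    ``{"low": fit, "high": fit}``.
    """
    if split not in ("none", "median"):
        raise ValueError(f"split must be 'none' or 'median', got {split!r}")
    xs = scores_ref.set_index("sample_id")["r"]
    ys = scores_treatment.set_index("sample_id")["r"]
    asym = sorted(set(xs.index).symmetric_difference(ys.index))
    if asym:
        raise ValueError(f"sample sets differ between score tables: {asym}")
    ys = ys.reindex(xs.index)

    if split == "none":
        return {"all": fit_exponential_trend(xs.to_numpy(), ys.to_numpy())}
    labels = median_split(scores_ref)
    out: dict[str, TrendFit] = {}
    for lab in ("low", "high"):
        ids = labels.index[labels == lab]
        out[lab] = fit_exponential_trend(
            xs.loc[ids].to_numpy(), ys.loc[ids].to_numpy()
        )
    return out
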