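"""Reference-profile stemness scoring and score-based sample grouping.

The central statistic: each sample's Pearson correlation, across all
measured transcripts, with the arithmetic-mean expression profile of a
designated set of cancer-stem-cell reference samples. Higher correlation
means a more stem-like global expression program. Scores feed a median
split (low/high stemness subgroups), an ordered stratification into
score-ascending groups, and a discrimination report comparing the score
against a single marker probe.

Missing values are handled by pairwise-complete exclusion per sample, with
the number of probes actually used recorded alongside each coefficient.
Scoring can run on values as provided (``transform="linear"``, the default,
matching MAS5-scale inputs) or on ``log2(x + 1)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expr_io import ExpressionMatrix

log = logging.getLogger(__name__)

MIN_PROBES = 3


@dataclass
class ReferenceProfile:
    """Per-probe arithmetic mean over the reference (stem-cell) samples.

    Probes with any missing reference value carry NaN as a missing marker.
    """

    mean_values: pd.Series  # index: probe_ids
    n_reference: int

    def __post_init__(self) -> None:
        if self.n_reference < 1:
            raise ValueError("n_reference must be >= 1")

    @property
    def probe_ids(self) -> pd.Index:
        return self.mean_values.index


@dataclass
class SeparationReport:
    """Rank-based two-group separation of a per-sample statistic.

    ``auc`` is the probability that a random stem-line sample exceeds a
    random bulk sample (ties count 1/2); 1.0 with disjoint ranges means
    full separation. ``p_value`` is a Welch two-sample t-test.
    """

    auc: float
    p_value: float
    fully_separated: bool
    n_stem: int
    n_bulk: int


def build_reference_profile(
    matrix: ExpressionMatrix, reference_sample_ids: list[str]
) -> ReferenceProfile:
    """Average the reference sample columns probe-by-probe."""
    if not reference_sample_ids:
        raise ValueError("reference_sample_ids is empty")
    unknown = [s for s in reference_sample_ids if s not in matrix.sample_ids]
    if unknown:
        raise ValueError(f"unknown reference sample IDs: {unknown}")
    cols = matrix.values[list(reference_sample_ids)]
    # skipna=False: any missing reference value marks the probe as missing
    mean = cols.mean(axis=1, skipna=False)
    n_missing = int(mean.isna().sum())
    if n_missing:
        log.warning("%d probes carry a missing marker in the reference profile", n_missing)
    return ReferenceProfile(mean_values=mean, n_reference=len(reference_sample_ids))


def _transform(values: np.ndarray, transform: str) -> np.ndarray:
    if transform == "linear":
        return values
    if transform == "log2":
        return np.log2(values + 1.0)
    raise ValueError(f"transform must be 'linear' or 'log2', got {transform!r}")


def score_samples(
    matrix: ExpressionMatrix,
    profile: ReferenceProfile,
    transform: str = "linear",
) -> pd.DataFrame:
    """Pearson-correlate every sample column with the reference profile.

    Probes are aligned by ID (inner join; mismatched order is re-aligned),
    the optional ``log2(x + 1)`` transform is applied to both sides, and
    each coefficient uses the probes where both the sample and the profile
    are present (pairwise-complete).

    Returns a DataFrame with columns ``sample_id``, ``r``,
    ``n_probes_used``; the transform used is recorded in ``.attrs``.
    """
    common = matrix.probe_ids.intersection(profile.probe_ids)
    if len(common) < MIN_PROBES:
        raise ValueError(
            f"only {len(common)} probes shared between matrix and profile "
            f"(need >= {MIN_PROBES})"
        )
    sample_vals = _transform(matrix.values.loc[common].to_numpy(dtype=float), transform)
    prof_vals = _transform(
        profile.mean_values.loc[common].to_numpy(dtype=float), transform
    )

    rows = []
    for j, sample in enumerate(matrix.sample_ids):
        x = sample_vals[:, j]
        mask = ~np.isnan(x) & ~np.isnan(prof_vals)
        n_used = int(mask.sum())
        if n_used < MIN_PROBES:
            raise ValueError(
                f"sample {sample!r}: only {n_used} usable probes (need >= {MIN_PROBES})"
            )
        xm = x[mask] - x[mask].mean()
        pm = prof_vals[mask] - prof_vals[mask].mean()
        sx = float(np.sqrt(np.dot(xm, xm)))
        sp = float(np.sqrt(np.dot(pm, pm)))
        if sx == 0.0:
            raise ValueError(f"zero variance on the sample side for {sample!r}")
        if sp == 0.0:
            raise ValueError("zero variance on the profile side")
        r = float(np.dot(xm, pm) / (sx * sp))
        rows.append((sample, min(1.0, max(-1.0, r)), n_used))

    out = pd.DataFrame(rows, columns=["sample_id", "r", "n_probes_used"])
    out.attrs["transform"] = transform
    out.attrs["n_reference"] = profile.n_reference
    return out


def _rank_auc(stem: np.ndarray, bulk: np.ndarray) -> float:
    """P(random stem > random bulk), ties counted 1/2 (midrank formula)."""
    pooled = np.concatenate([stem, bulk])
    ranks = stats.rankdata(pooled)
    n1, n2 = len(stem), len(bulk)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def discriminate_score_vs_marker(
    scores: pd.DataFrame,
    marker: pd.Series,
    labels: pd.Series,
) -> dict[str, SeparationReport]:
    """Compare the stemness score against a single marker probe as a
    discriminator of stem-line versus bulk samples.

    Parameters
    ----------
    scores
        Score table from :func:`score_samples`.
    marker
        Expression of one marker probe, indexed by sample ID.
    labels
        Per-sample labels, values ``"stem_line"`` or ``"bulk"``.

    Returns a report per metric (keys ``"score"`` and ``"marker"``).
    """
    score_series = scores.set_index("sample_id")["r"]
    reports: dict[str, SeparationReport] = {}
    for key, series in (("score", score_series), ("marker", marker)):
        stem_ids = labels.index[labels == "stem_line"]
        bulk_ids = labels.index[labels == "bulk"]
        if len(stem_ids) < 2 or len(bulk_ids) < 2:
            raise ValueError("each label class needs >= 2 samples")
        stem = series.loc[stem_ids].to_numpy(dtype=float)
        bulk = series.loc[bulk_ids].to_numpy(dtype=float)
        auc = _rank_auc(stem, bulk)
        p = float(stats.ttest_ind(stem, bulk, equal_var=False).pvalue)
        fully = bool(auc == 1.0 and stem.min() > bulk.max())
        reports[key] = SeparationReport(
            auc=auc, p_value=p, fully_separated=fully,
            n_stem=len(stem), n_bulk=len(bulk),
        )
    return reports


def median_split(scores: pd.DataFrame) -> pd.Series:
    """Label samples ``low`` (score <= median) or ``high`` (score > median).

    Ties at the median break toward ``low``; deterministic by construction.
    """
    if len(scores) < 2:
        raise ValueError("median split needs >= 2 samples")
    med = float(scores["r"].median())
    labels = np.where(scores["r"] <= med, "low", "high")
    return pd.Series(labels, index=scores["sample_id"].tolist(), name="split")


def stratify_by_score(scores: pd.DataFrame, n_groups: int) -> list[list[str]]:
    """Partition samples into score-ascending groups.

    The first ``n_groups - 1`` groups take ``ceil(n / n_groups)`` samples
    each (when that leaves at least one sample over); the final, most
    stem-like group absorbs the remainder and may be smaller — matching
    e.g. 200 samples -> ten groups of 20, and 23 samples -> (5, 5, 5, 5, 3)
    with the smallest group most stem-like. If front-loading full-sized
    groups would exhaust the cohort early, sizes fall back to the balanced
    partition with larger groups first.
    """
    n = len(scores)
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if n_groups > n:
        raise ValueError(f"n_groups={n_groups} exceeds the {n} samples available")
    ordered = scores.sort_values("r", kind="mergesort")["sample_id"].tolist()

    q, r = divmod(n, n_groups)
    if r == 0:
        sizes = [q] * n_groups
    elif q + r >= n_groups:
        head = q + 1
        sizes = [head] * (n_groups - 1) + [n - head * (n_groups - 1)]
    else:  # too few samples to front-load ceil-sized groups
        sizes = [q + 1] * r + [q] * (n_groups - r)

    groups: list[list[str]] = []
    pos = 0
    for size in sizes:
        groups.append(ordered[pos:pos + size])
        pos += size
    return groups
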