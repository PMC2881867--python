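"""Score-stratified, gene-universe-compartmentalized heterogeneity.

For each score-ascending stratum of samples, every within-stratum sample
pair is Pearson-correlated twice: across all transcripts, and across a
named gene universe (progenitor/differentiation genes). Lower intra-group
pairwise correlation means higher heterogeneity; heterogeneity confined to
the named universe while the all-transcript similarity stays high is
"compartmentalized". The universe effect is tested per stratum and pooled
by one-way ANOVA between the two coefficient collections, exactly as the
coefficients-as-observations convention does — with the caveat (appended
to every report) that pairs sharing a sample are not independent.

Summaries use the upper-triangle off-diagonal coefficients only (each
pair counted once); SEM = sd / sqrt(n_pairs) with n_pairs = k(k-1)/2 for a
stratum of k samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expr_io import ExpressionMatrix, GeneSet, subset_matrix
from .stemness import stratify_by_score

log = logging.getLogger(__name__)

DEPENDENCE_CAVEAT = (
    "pairwise coefficients sharing a sample are dependent; the ANOVA "
    "treats them as independent observations"
)

ALL_TRANSCRIPTS = "all_transcripts"


@dataclass
class PairwiseSimilarityMatrix:
    """Symmetric unit-diagonal Pearson matrix over one gene universe."""

    values: pd.DataFrame  # square, index == columns == sample ids
    universe_label: str

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("similarity matrix must be symmetric")
        finite = v[~np.isnan(v)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("coefficients must lie in [-1, 1]")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    def upper_triangle(self) -> np.ndarray:
        """Off-diagonal upper-triangle coefficients, NaN pairs dropped."""
        v = self.values.to_numpy(dtype=float)
        iu = np.triu_indices(v.shape[0], k=1)
        coeffs = v[iu]
        n_bad = int(np.isnan(coeffs).sum())
        if n_bad:
            log.warning("%d degenerate pairs excluded from summaries", n_bad)
        return coeffs[~np.isnan(coeffs)]


def pairwise_similarity(
    matrix: ExpressionMatrix,
    sample_subset: Sequence[str],
    universe: Optional[GeneSet] = None,
    transform: str = "linear",
) -> PairwiseSimilarityMatrix:
    """All pairwise Pearson coefficients among a sample subset.

    ``universe=None`` means all transcripts; a GeneSet restricts to its
    probes (>= 3 overlapping required). The transform and pairwise-complete
    missing-value policy match stemness scoring. A zero-variance sample
    yields NaN for its pairs, which are flagged and excluded downstream.
    """
    samples = list(sample_subset)
    if len(samples) < 2:
        raise ValueError("need >= 2 samples for pairwise similarity")
    unknown = [s for s in samples if s not in matrix.sample_ids]
    if unknown:
        raise ValueError(f"unknown sample IDs: {unknown}")
    if universe is not None:
        m = subset_matrix(matrix, universe)
        if m.shape[0] < 3:
            raise ValueError(
                f"universe {universe.name!r} overlaps only {m.shape[0]} probes (need >= 3)"
            )
        label = universe.name
    else:
        m = matrix
        label = ALL_TRANSCRIPTS
    vals = m.values[samples]
    if transform == "log2":
        vals = np.log2(vals + 1.0)
    elif transform != "linear":
        raise ValueError(f"transform must be 'linear' or 'log2', got {transform!r}")
    # pandas corr: pairwise-complete Pearson, NaN on zero variance
    corr = vals.corr(method="pearson", min_periods=3)
    np.fill_diagonal(corr.values, 1.0)
    if corr.isna().to_numpy().any():
        log.warning("degenerate zero-variance sample(s) produced NaN coefficients")
    return PairwiseSimilarityMatrix(values=corr, universe_label=label)


def compare_universes(coeffs_all, coeffs_subset) -> dict:
    """One-way ANOVA between two collections of pairwise coefficients.

    Returns F, p, the difference of means (subset minus all-transcripts)
    and its sign, plus the dependence caveat. Identical-mean lists give
    F = 0, p = 1; distinct means with zero within-group variance give
    F = inf, p = 0.
    """
    a = np.asarray(coeffs_all, dtype=float)
    b = np.asarray(coeffs_subset, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both coefficient lists must be non-empty")
    if a.size + b.size < 2:
        raise ValueError("need >= 2 coefficients in total")
    diff = float(b.mean() - a.mean())
    grand = np.concatenate([a, b]).mean()
    ss_between = a.size * (a.mean() - grand) ** 2 + b.size * (b.mean() - grand) ** 2
    ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    if ss_between <= 1e-300:
        f_stat, p = 0.0, 1.0
    elif ss_within == 0.0:
        f_stat, p = math.inf, 0.0
    else:
        res = stats.f_oneway(a, b)
        f_stat, p = float(res.statistic), float(res.pvalue)
    return {
        "F": f_stat,
        "p_value": p,
        "mean_difference": diff,
        "direction": "subset_lower" if diff < 0 else "subset_higher_or_equal",
        "n_all": int(a.size),
        "n_subset": int(b.size),
        "caveat": DEPENDENCE_CAVEAT,
    }


def _mean_pairwise_r(x: np.ndarray) -> float:
    """Mean off-diagonal pairwise Pearson r of the columns of ``x``."""
    xc = x - x.mean(axis=0)
    norms = np.sqrt((xc * xc).sum(axis=0))
    ok = norms > 0
    xc, norms = xc[:, ok], norms[ok]
    k = xc.shape[1]
    if k < 2:
        return float("nan")
    r = (xc.T @ xc) / np.outer(norms, norms)
    iu = np.triu_indices(k, k=1)
    return float(r[iu].mean())


def universe_permutation_test(
    matrix: ExpressionMatrix,
    group_members: Sequence[Sequence[str]],
    subset: GeneSet,
    n_resamples: int = 199,
    seed: int = 0,
    transform: str = "linear",
) -> dict:
    """Probe-resampling null for the universe effect.

    The coefficient-level ANOVA treats pairwise coefficients as independent,
    which is anticonservative: any finite gene universe carries a shared
    sampling offset in all its coefficients. This test is calibrated by
    construction against the hypothesis that the subset behaves like a
    random probe universe of the same size: the observed statistic (pooled
    mean subset-universe coefficient minus pooled mean all-transcript
    coefficient, averaged over groups) is ranked within the null
    distribution obtained from random equal-size probe subsets.

    Returns observed difference, two-sided permutation p-value
    ``(1 + #extreme) / (n_resamples + 1)``, and the resample count.
    """
    vals = matrix.values
    if transform == "log2":
        vals = np.log2(vals + 1.0)
    elif transform != "linear":
        raise ValueError(f"transform must be 'linear' or 'log2', got {transform!r}")
    subset_idx = np.flatnonzero(matrix.probe_ids.isin(subset.members))
    if subset_idx.size < 3:
        raise ValueError(f"universe {subset.name!r} overlaps < 3 probes")
    group_arrays = [vals[list(members)].to_numpy(dtype=float)
                    for members in group_members]

    def pooled_diff(idx: np.ndarray) -> float:
        diffs = [_mean_pairwise_r(x[idx]) - _mean_pairwise_r(x)
                 for x in group_arrays]
        return float(np.nanmean(diffs))

    observed = pooled_diff(subset_idx)
    rng = np.random.default_rng(seed)
    n_probes = matrix.shape[0]
    null = np.array([
        pooled_diff(rng.choice(n_probes, size=subset_idx.size, replace=False))
        for _ in range(n_resamples)
    ])
    n_extreme = int((np.abs(null) >= abs(observed)).sum())
    return {
        "observed_difference": observed,
        "p_value": (1 + n_extreme) / (n_resamples + 1),
        "n_resamples": n_resamples,
        "subset_size": int(subset_idx.size),
    }


@dataclass
class HeterogeneitySummary:
    """Per (stratum, universe) coefficient summaries plus universe tests."""

    table: pd.DataFrame  # columns: group, universe, n_pairs, mean, sem
    coefficients: dict[tuple[str, str], np.ndarray]
    per_group_tests: dict[str, dict]
    pooled_test: dict
    group_members: dict[str, list[str]]
    pooled_permutation_test: Optional[dict] = None


def heterogeneity_profile(
    matrix: ExpressionMatrix,
    scores: pd.DataFrame,
    n_groups: int,
    universes: Optional[dict[str, Optional[GeneSet]]] = None,
    subset: Optional[GeneSet] = None,
    transform: str = "linear",
    fisher_z: bool = False,
    permutation_null: bool = False,
    n_resamples: int = 199,
    permutation_seed: int = 0,
) -> HeterogeneitySummary:
    """Stratify by ascending stemness score and profile intra-group
    similarity in two gene universes (by default all transcripts versus a
    gene subset such as progenitor/differentiation genes).

    ``universes`` maps exactly two labels to a GeneSet or None (None = all
    transcripts); passing ``subset`` alone is shorthand for
    ``{all_transcripts: None, subset.name: subset}``. The universe-effect
    ANOVA compares the second universe against the first, per group and
    pooled. Group names run G01 (least stem-like) upward. ``fisher_z``
    applies arctanh to the coefficients before summarizing and testing
    (summaries are then on the z scale). ``permutation_null=True``
    additionally runs the calibrated probe-resampling universe test
    (see :func:`universe_permutation_test`); the coefficient-level pooled
    ANOVA is always reported for fidelity, with its dependence caveat.
    """
    if universes is None:
        if subset is None:
            raise ValueError("provide either a universes mapping or a subset gene set")
        universes = {ALL_TRANSCRIPTS: None, subset.name: subset}
    if len(universes) != 2:
        raise ValueError(f"exactly 2 universes required, got {len(universes)}")
    groups = stratify_by_score(scores, n_groups)
    sizes = [len(g) for g in groups]
    if min(sizes) < 2:
        raise ValueError(
            f"a stratum of size {min(sizes)} has no sample pairs; use fewer groups"
        )
    rows = []
    coeffs: dict[tuple[str, str], np.ndarray] = {}
    group_members: dict[str, list[str]] = {}
    for gi, members in enumerate(groups, start=1):
        gname = f"G{gi:02d}"
        group_members[gname] = members
        for label, uni in universes.items():
            psm = pairwise_similarity(matrix, members, universe=uni, transform=transform)
            c = psm.upper_triangle()
            if fisher_z:
                c = np.arctanh(np.clip(c, -1 + 1e-15, 1 - 1e-15))
            coeffs[(gname, label)] = c
            sem = float(c.std(ddof=1) / np.sqrt(c.size)) if c.size > 1 else float("nan")
            rows.append(
                {
                    "group": gname,
                    "universe": label,
                    "n_samples": len(members),
                    "n_pairs": int(c.size),
                    "mean": float(c.mean()),
                    "sem": sem,
                }
            )
    table = pd.DataFrame(rows)

    base_label, other_label = list(universes)
    per_group_tests = {
        gname: compare_universes(coeffs[(gname, base_label)], coeffs[(gname, other_label)])
        for gname in group_members
    }
    pooled_base = np.concatenate([coeffs[(g, base_label)] for g in group_members])
    pooled_other = np.concatenate([coeffs[(g, other_label)] for g in group_members])
    pooled_test = compare_universes(pooled_base, pooled_other)

    perm_test = None
    if permutation_null:
        other_set = universes[other_label]
        if universes[base_label] is not None or other_set is None:
            raise ValueError(
                "permutation_null needs universes of the form "
                "{all transcripts: None, subset: GeneSet}"
            )
        perm_test = universe_permutation_test(
            matrix, list(group_members.values()), other_set,
            n_resamples=n_resamples, seed=permutation_seed,
            transform=transform,
        )

    return HeterogeneitySummary(
        table=table,
        coefficients=coeffs,
        per_group_tests=per_group_tests,
        pooled_test=pooled_test,
        group_members=group_members,
        pooled_permutation_test=perm_test,
    )
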