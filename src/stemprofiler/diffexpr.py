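"""Treatment-altered gene lists by a joint fold-change / p-value filter.

A probe passes when its linear-scale fold change exceeds the threshold in
either direction (``max(fc, 1/fc) > fc_threshold``) AND its test p-value is
below ``p_threshold``. Fold change is the ratio of group means on the
linear scale; tests run on ``log2(x + 1)`` values. The historical defaults
are fc > 1.3 with p < 0.05 for the human pre/post-vaccine comparison and
fc > 1.5 for the mouse host comparison.

No multiple-testing correction is applied by default (matching the
original raw-p filtering); a Benjamini-Hochberg mode is available and the
result records which mode ran.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expr_io import ExpressionMatrix, GeneSet, SampleAnnotation

log = logging.getLogger(__name__)

TESTS = ("t_one_tailed", "t_two_tailed", "anova")


def _paired_columns(
    annotation: SampleAnnotation, group_a: str, group_b: str
) -> tuple[list[str], list[str]]:
    """Order group columns so position k holds the same pair in A and B."""
    tab = annotation.table
    a = tab[tab["group_label"] == group_a].set_index("pair_id")["sample_id"]
    b = tab[tab["group_label"] == group_b].set_index("pair_id")["sample_id"]
    orphans = sorted(set(a.index).symmetric_difference(b.index))
    if orphans or a.index.hasnans or b.index.hasnans:
        raise ValueError(f"unmatched pair IDs between groups: {orphans}")
    pairs = list(a.index)
    return [a[p] for p in pairs], [b[p] for p in pairs]


def altered_gene_list(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    group_a: str,
    group_b: str,
    fc_threshold: float = 1.3,
    p_threshold: float = 0.05,
    paired: bool = False,
    test: str = "t_two_tailed",
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-probe fold change, p-value and pass/fail for B versus A.

    ``fold_change = mean(group_b) / mean(group_a)`` on the linear scale;
    p-values come from the selected test on log2(x + 1) values (the paired
    test uses within-pair differences). One-tailed means the tail chosen by
    the observed fold-change direction per probe, i.e. half the two-sided p.

    Returns a DataFrame indexed by probe (matrix row order) with columns
    ``fold_change``, ``p_value``, ``direction``, ``passes``; filter settings
    are recorded in ``.attrs``.
    """
    if test not in TESTS:
        raise ValueError(f"test must be one of {TESTS}, got {test!r}")
    if paired:
        cols_a, cols_b = _paired_columns(annotation, group_a, group_b)
    else:
        cols_a = annotation.samples_in_group(group_a)
        cols_b = annotation.samples_in_group(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs >= 2 samples")

    va = matrix.values[cols_a].to_numpy(dtype=float)
    vb = matrix.values[cols_b].to_numpy(dtype=float)

    mean_a = va.mean(axis=1)
    mean_b = vb.mean(axis=1)
    zero = np.flatnonzero((mean_a == 0) | (mean_b == 0))
    if zero.size:
        raise ValueError(
            f"zero group mean at probe {matrix.probe_ids[zero[0]]!r}; "
            "fold change undefined"
        )
    fc = mean_b / mean_a

    la = np.log2(va + 1.0)
    lb = np.log2(vb + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        if paired:
            res = stats.ttest_rel(lb, la, axis=1)
        elif test == "anova":
            res = stats.f_oneway(lb, la, axis=1)
        else:
            res = stats.ttest_ind(lb, la, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    if test == "t_one_tailed":
        p = p / 2.0
    # a probe with zero variance and zero difference carries no evidence
    p = np.where(np.isnan(p), 1.0, p)

    p_effective = p
    if bh_correct:
        p_effective = multipletests(p, method="fdr_bh")[1]

    direction = np.where(fc >= 1.0, "up", "down")
    magnitude = np.maximum(fc, 1.0 / fc)
    passes = (magnitude > fc_threshold) & (p_effective < p_threshold)

    out = pd.DataFrame(
        {
            "fold_change": fc,
            "p_value": p,
            "direction": direction,
            "passes": passes,
        },
        index=matrix.probe_ids,
    )
    if bh_correct:
        out["p_adjusted"] = p_effective
    out.attrs.update(
        fc_threshold=fc_threshold,
        p_threshold=p_threshold,
        paired=paired,
        test=test,
        correction="benjamini-hochberg" if bh_correct else "none",
        group_a=group_a,
        group_b=group_b,
    )
    return out


def summarize_list(
    de_result: pd.DataFrame,
    set_name: str = "treatment_altered",
) -> dict:
    """Tally the passing probes and export them as a gene set.

    Returns a dict with ``n_up``, ``n_down``, ``n_passing``,
    ``passing_probe_ids`` and ``gene_set`` (None, with a warning, when
    nothing passes).
    """
    passing = de_result[de_result["passes"]]
    n_up = int((passing["direction"] == "up").sum())
    n_down = int((passing["direction"] == "down").sum())
    probe_ids = passing.index.tolist()
    gene_set: Optional[GeneSet] = None
    if probe_ids:
        gene_set = GeneSet(
            name=set_name,
            description=(
                f"fc>{de_result.attrs.get('fc_threshold')} "
                f"p<{de_result.attrs.get('p_threshold')} "
                f"({de_result.attrs.get('correction', 'none')} correction)"
            ),
            members=frozenset(probe_ids),
        )
    else:
        log.warning("no probes pass the joint filter; empty gene list")
    return {
        "n_up": n_up,
        "n_down": n_down,
        "n_passing": len(probe_ids),
        "passing_probe_ids": probe_ids,
        "gene_set": gene_set,
    }
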