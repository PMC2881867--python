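"""Synthetic microarray cohorts with a planted stemness axis and ground truth.

The generator emulates the statistical structure the downstream analyses
assume: a cohort of tumor samples whose expression is coupled to a latent
stemness value in [0, 1], a designated reference subgroup of stem-cell-line
samples pinned at stemness 1, a named "progenitor/differentiation" probe
subset whose residual variance can be inflated in low-stemness samples
(compartmentalized heterogeneity), and matched pre/post-treatment pairs
with planted log2 fold-change shifts in designated probes.

Generative model (log2 scale, exponentiated to linear on output):

    x_gi = b_g + l_g * s_i + eps_gi

with probe baseline b_g ~ N(baseline_mean, baseline_sd), loading
l_g ~ N(0, signal_sd) on a ``stemness_loading_fraction`` of probes (0
elsewhere), latent stemness s_i ~ U(0, 1) (reference samples forced to 1),
and noise eps_gi ~ N(0, noise_sd * m_gi) where the multiplier m_gi equals
``inflation_factor`` for subset probes in designated low-stemness samples
and 1 otherwise.

All randomness flows from one integer seed through named
``numpy.random.SeedSequence`` sub-streams (PCG64), so output is
bit-identical across platforms and adding probes does not perturb the
sample-level draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .expr_io import ExpressionMatrix, GeneSet, SampleAnnotation

# fixed order of named sub-streams; append only, never reorder
_STREAMS = (
    "baseline",
    "loading_choice",
    "loading",
    "latent",
    "noise",
    "subset_choice",
    "altered_choice",
    "pair_effect",
)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort generator (log2-scale units).

    Defaults describe a mid-sized glioma-like cohort: 2,000 probes,
    60 samples of which 6 are stem-cell-line references, 40% of probes
    coupled to the stemness axis with loading sd 1.0 against residual
    noise sd 0.5 (signal-to-noise 2), baselines N(7, 1.5), a 200-probe
    progenitor/differentiation subset whose noise is doubled in the
    lowest-stemness 40% of tumor samples, and 100 treatment-altered
    probes shifted by 1 log2 unit in the paired design.
    """

    n_probes: int = 2000
    n_samples: int = 60
    n_reference: int = 6
    stemness_loading_fraction: float = 0.4
    signal_sd: float = 1.0
    noise_sd: float = 0.5
    subset_name: str = "progenitor_differentiation"
    subset_size: int = 200
    inflation_factor: float = 2.0
    inflated_quantile: float = 0.4
    n_altered: int = 100
    effect_log2fc: float = 1.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    pair_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_probes", "n_samples", "n_reference", "subset_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_altered < 0:
            raise ValueError("n_altered must be >= 0")
        if self.subset_size > self.n_probes:
            raise ValueError("subset_size exceeds n_probes")
        if self.n_altered > self.n_probes:
            raise ValueError("n_altered exceeds n_probes")
        if self.n_reference >= self.n_samples:
            raise ValueError("n_reference must be smaller than n_samples")
        if self.inflation_factor < 1:
            raise ValueError("inflation_factor must be >= 1")
        if not 0 <= self.inflated_quantile <= 1:
            raise ValueError("inflated_quantile must lie in [0, 1]")
        if not 0 <= self.stemness_loading_fraction <= 1:
            raise ValueError("stemness_loading_fraction must lie in [0, 1]")
        for name in ("baseline_sd",):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("signal_sd", "noise_sd", "pair_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SyntheticTruth:
    """Planted latent parameters a recovery test can compare against."""

    latent_stemness: dict[str, float]
    reference_ids: list[str]
    altered_probe_ids: list[str]
    subset_probe_ids: list[str]
    inflated_sample_ids: list[str]
    seed: int

    def subset_gene_set(self, name: str = "progenitor_differentiation") -> GeneSet:
        return GeneSet(
            name=name,
            description="planted variable-heterogeneity probe subset",
            members=frozenset(self.subset_probe_ids),
        )

    def altered_gene_set(self, name: str = "treatment_altered") -> GeneSet:
        return GeneSet(
            name=name,
            description="planted treatment-shifted probes",
            members=frozenset(self.altered_probe_ids),
        )

    def to_dict(self) -> dict:
        return asdict(self)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.Generator(np.random.PCG64(child))
            for name, child in zip(_STREAMS, children)}


def _probe_ids(n: int) -> list[str]:
    return [f"P{i:06d}" for i in range(1, n + 1)]


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, SampleAnnotation, SyntheticTruth]:
    """Generate a tumor cohort with a latent stemness axis and references.

    Reference samples (stem-cell lines) are pinned at latent stemness 1;
    tumor samples draw s ~ U(0, 1). Returns the linear-scale matrix, the
    sample annotation (group labels ``reference_GSC`` / ``bulk``) and the
    planted truth.
    """
    config.validate()
    rng = _streams(config.seed)
    G, N, R = config.n_probes, config.n_samples, config.n_reference

    probes = _probe_ids(G)
    ref_ids = [f"REF{i:02d}" for i in range(1, R + 1)]
    bulk_ids = [f"T{i:03d}" for i in range(1, N - R + 1)]
    samples = ref_ids + bulk_ids

    b = rng["baseline"].normal(config.baseline_mean, config.baseline_sd, size=G)
    n_loaded = int(round(config.stemness_loading_fraction * G))
    loaded_idx = rng["loading_choice"].choice(G, size=n_loaded, replace=False)
    loadings = np.zeros(G)
    loadings[loaded_idx] = rng["loading"].normal(0.0, config.signal_sd, size=n_loaded)

    s = np.empty(N)
    s[:R] = 1.0
    s[R:] = rng["latent"].uniform(0.0, 1.0, size=N - R)

    subset_idx = np.sort(
        rng["subset_choice"].choice(G, size=config.subset_size, replace=False)
    )
    subset_probes = [probes[i] for i in subset_idx]

    # designate the lowest-stemness tumor samples for variance inflation
    bulk_s = s[R:]
    n_inflated = int(round(config.inflated_quantile * (N - R)))
    order = np.argsort(bulk_s, kind="stable")
    inflated_bulk_pos = order[:n_inflated]
    inflated_cols = np.array([R + i for i in inflated_bulk_pos], dtype=int)

    sd = np.full((G, N), config.noise_sd)
    if config.inflation_factor > 1 and inflated_cols.size:
        sd[np.ix_(subset_idx, inflated_cols)] *= config.inflation_factor
    eps = rng["noise"].standard_normal((G, N)) * sd

    x = b[:, None] + loadings[:, None] * s[None, :] + eps
    values = pd.DataFrame(np.exp2(x), index=probes, columns=samples)
    matrix = ExpressionMatrix(values=values, scale="linear")

    annotation = SampleAnnotation(
        table=pd.DataFrame(
            {
                "sample_id": samples,
                "group_label": ["reference_GSC"] * R + ["bulk"] * (N - R),
                "pair_id": [pd.NA] * N,
            }
        )
    )
    inflated_ids = (
        [samples[c] for c in sorted(inflated_cols)]
        if config.inflation_factor > 1
        else []
    )
    truth = SyntheticTruth(
        latent_stemness={sid: float(v) for sid, v in zip(samples, s)},
        reference_ids=ref_ids,
        altered_probe_ids=[],
        subset_probe_ids=subset_probes,
        inflated_sample_ids=inflated_ids,
        seed=config.seed,
    )
    return matrix, annotation, truth


def generate_paired_cohort(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, SampleAnnotation, SyntheticTruth]:
    """Generate matched pre/post-treatment pairs with planted shifts.

    ``n_samples`` must be even; each of the ``n_samples / 2`` pairs shares
    its probe baselines and a per-pair random effect (sd ``pair_sd``), and
    post samples add ``effect_log2fc`` to ``n_altered`` designated probes.
    """
    config.validate()
    if config.n_samples % 2:
        raise ValueError(f"paired design needs an even n_samples, got {config.n_samples}")
    rng = _streams(config.seed)
    G = config.n_probes
    n_pairs = config.n_samples // 2

    probes = _probe_ids(G)
    pair_ids = [f"PT{k:02d}" for k in range(1, n_pairs + 1)]
    pre_ids = [f"{p}_pre" for p in pair_ids]
    post_ids = [f"{p}_post" for p in pair_ids]
    samples = pre_ids + post_ids

    b = rng["baseline"].normal(config.baseline_mean, config.baseline_sd, size=G)
    altered_idx = np.sort(
        rng["altered_choice"].choice(G, size=config.n_altered, replace=False)
    ) if config.n_altered else np.array([], dtype=int)
    altered_probes = [probes[i] for i in altered_idx]

    u = rng["pair_effect"].normal(0.0, config.pair_sd, size=(G, n_pairs))
    eps = rng["noise"].standard_normal((G, 2 * n_pairs)) * config.noise_sd

    shift = np.zeros(G)
    shift[altered_idx] = config.effect_log2fc
    pre = b[:, None] + u + eps[:, :n_pairs]
    post = b[:, None] + u + shift[:, None] + eps[:, n_pairs:]
    x = np.concatenate([pre, post], axis=1)

    values = pd.DataFrame(np.exp2(x), index=probes, columns=samples)
    matrix = ExpressionMatrix(values=values, scale="linear")
    annotation = SampleAnnotation(
        table=pd.DataFrame(
            {
                "sample_id": samples,
                "group_label": ["pre"] * n_pairs + ["post"] * n_pairs,
                "pair_id": pair_ids + pair_ids,
            }
        )
    )
    truth = SyntheticTruth(
        latent_stemness={},
        reference_ids=[],
        altered_probe_ids=altered_probes,
        subset_probe_ids=[],
        inflated_sample_ids=[],
        seed=config.seed,
    )
    return matrix, annotation, truth
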