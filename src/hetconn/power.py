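"""Repeated-subsampling power analysis with set-matching TPR/FDR metrics.

A fitted rank-one model classifies parcels into two sets (same-side
coefficients: positively correlated in the contrast; opposite sides:
negatively) plus an undecided remainder.  Because the set labels are not
identified, predicted sets are compared to the truth over both possible
matchings: true positives take the better (max) matching,

    TP = max(|P1 ∩ T1| + |P2 ∩ T2|, |P1 ∩ T2| + |P2 ∩ T1|),

and false positives the more charitable (min) one,

    FP = min(|P1 \\ T1| + |P2 \\ T2|, |P1 \\ T2| + |P2 \\ T1|),

with TPR = TP / (|T1| + |T2|) and FDR = FP / (TP + FP) (zero when nothing
is predicted).  ``run_power`` repeatedly subsamples a subject population
preserving its group ratio, thins to the study-wide effective sample size,
fits the model and averages the metrics per (sample size, alpha).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._mcmc import SamplerConfig
from .data_io import DesignMatrix, TimeseriesMatrix, build_design, center_columns
from .ess import study_ess, thin
from .lowdim import align_signs, fit_lowdim, summarize_coefficients

__all__ = [
    "ParcelSets",
    "true_positive_count",
    "false_positive_count",
    "tpr_fdr",
    "parcel_sets_from_summary",
    "run_power",
]


@dataclass(frozen=True)
class ParcelSets:
    """Disjoint parcel sets (0-based indices); the complement is undecided."""

    set1: frozenset[int]
    set2: frozenset[int]
    p: int

    def __post_init__(self) -> None:
        s1, s2 = frozenset(self.set1), frozenset(self.set2)
        if s1 & s2:
            raise ValueError("set1 and set2 must be disjoint")
        if any(not 0 <= j < self.p for j in s1 | s2):
            raise ValueError("parcel indices must lie in [0, p)")
        object.__setattr__(self, "set1", s1)
        object.__setattr__(self, "set2", s2)

    @property
    def undecided(self) -> frozenset[int]:
        return frozenset(range(self.p)) - self.set1 - self.set2

    @property
    def n_assigned(self) -> int:
        return len(self.set1) + len(self.set2)


def true_positive_count(pred: ParcelSets, truth: ParcelSets) -> int:
    """Correctly predicted parcels under the better of the two matchings."""
    straight = len(pred.set1 & truth.set1) + len(pred.set2 & truth.set2)
    crossed = len(pred.set1 & truth.set2) + len(pred.set2 & truth.set1)
    return max(straight, crossed)


def false_positive_count(pred: ParcelSets, truth: ParcelSets) -> int:
    """Falsely predicted parcels under the more charitable matching."""
    straight = len(pred.set1 - truth.set1) + len(pred.set2 - truth.set2)
    crossed = len(pred.set1 - truth.set2) + len(pred.set2 - truth.set1)
    return min(straight, crossed)


def tpr_fdr(pred: ParcelSets, truth: ParcelSets) -> tuple[float, float]:
    """True positive rate and false discovery rate of a set prediction."""
    total_true = truth.n_assigned
    if total_true == 0:
        raise ValueError("truth must assign at least one parcel")
    tp = true_positive_count(pred, truth)
    fp = false_positive_count(pred, truth)
    tpr = tp / total_true
    fdr = fp / (tp + fp) if (tp + fp) > 0 else 0.0
    return tpr, fdr


def parcel_sets_from_summary(summary: pd.DataFrame) -> ParcelSets:
    """Convert a coefficient summary's ``set`` column into ParcelSets."""
    assignment = summary["set"].to_numpy()
    return ParcelSets(
        set1=frozenset(int(i) for i in np.nonzero(assignment == "set1")[0]),
        set2=frozenset(int(i) for i in np.nonzero(assignment == "set2")[0]),
        p=len(summary),
    )


def _stratified_sample(
    subjects: pd.DataFrame, size: int, reference_group: str, rng: np.random.Generator
) -> np.ndarray:
    """Indices of a group-ratio-preserving subsample without replacement."""
    n_total = len(subjects)
    if size > n_total:
        raise ValueError(f"sample size {size} exceeds population {n_total}")
    groups = subjects["group"].astype(str).to_numpy()
    nonref_mask = groups != reference_group
    n_nonref = int(round(size * nonref_mask.sum() / n_total))
    n_nonref = min(max(n_nonref, 0), size)
    n_ref = size - n_nonref
    ref_idx = np.nonzero(~nonref_mask)[0]
    nonref_idx = np.nonzero(nonref_mask)[0]
    chosen = np.concatenate(
        [
            rng.choice(ref_idx, size=n_ref, replace=False),
            rng.choice(nonref_idx, size=n_nonref, replace=False),
        ]
    )
    return np.sort(chosen)


def _fit_seed(seed: int, size: int, rep: int) -> int:
    seq = np.random.SeedSequence(entropy=seed, spawn_key=(size, rep))
    return int(seq.generate_state(1)[0] % (2**31))


def run_power(
    series: Sequence[TimeseriesMatrix],
    subjects: pd.DataFrame,
    truth: ParcelSets,
    sample_sizes: Sequence[int],
    alphas: Sequence[float],
    n_replicates: int,
    seed: int,
    reference_group: str,
    chains: int = 2,
    iterations: int = 250,
    burnin: int = 250,
    max_lag: int | None = None,
    bonferroni_m: int | None = None,
) -> pd.DataFrame:
    """Average TPR/FDR of the rank-one model over repeated subsamples.

    For every sample size and replicate: draw a stratified subsample with
    the population's group ratio, thin every subject's centered series to
    the subsample's study-wide ESS, stack the thinned rows, fit the model,
    sign-align, and classify parcels at each Bonferroni-corrected level
    alpha; metrics are scored against ``truth`` and averaged over
    replicates.  One fit serves all alpha levels, since alpha only moves
    the summary quantiles.
    """
    if len(series) != len(subjects):
        raise ValueError("one timeseries per subjects-table row is required")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    centered = [center_columns(ts) for ts in series]
    records = []
    for size in sample_sizes:
        scores: dict[float, list[tuple[float, float]]] = {a: [] for a in alphas}
        for rep in range(n_replicates):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(size, rep, 1))
            )
            idx = _stratified_sample(subjects, size, reference_group, rng)
            sub_series = [centered[i] for i in idx]
            sub_table = subjects.iloc[idx].reset_index(drop=True)
            n_eff = study_ess(sub_series, max_lag=max_lag)
            thinned = [thin(ts, n_eff) for ts in sub_series]
            Y = np.vstack([ts.values for ts in thinned])
            design = build_design(sub_table, reference_group)
            X_rows = np.repeat(design.values, [ts.n_timepoints for ts in thinned], axis=0)
            X = DesignMatrix(values=X_rows, column_names=design.column_names)
            config = SamplerConfig(
                seed=_fit_seed(seed, size, rep),
                chains=chains,
                iterations=iterations,
                burnin=burnin,
            )
            posterior = align_signs(fit_lowdim(Y, X, config))
            for alpha in alphas:
                summary = summarize_coefficients(
                    posterior, column=1, alpha=alpha, m=bonferroni_m
                )
                pred = parcel_sets_from_summary(summary)
                scores[alpha].append(tpr_fdr(pred, truth))
        for alpha in alphas:
            vals = np.asarray(scores[alpha], dtype=float)
            records.append(
                {
                    "sample_size": int(size),
                    "alpha": float(alpha),
                    "tpr": float(vals[:, 0].mean()),
                    "fdr": float(vals[:, 1].mean()),
                    "n_replicates": int(n_replicates),
                }
            )
    return pd.DataFrame(records)
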