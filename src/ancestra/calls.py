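"""Ancestry calling from bootstrap ensembles.

Bootstrap replicates of the Q matrix give, per individual and component, a
mean, a standard error, and a normal-approximation 95% confidence interval.
Proportions whose CI includes 0 are zeroed and the survivors renormalized to
sum to 1; sample-level proportions combine individuals by inverse-variance
weights with a DerSimonian-Laird between-individual variance component, and
the same zeroing rule is applied to the weighted sample means.  Counts of
nonzero called components per individual/sample summarize mixed ancestry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .admixture import BootstrapEnsemble

__all__ = [
    "CalledAncestry",
    "individual_intervals",
    "zero_and_renormalize",
    "sample_average_ancestry",
    "designate_exemplars",
    "mixed_ancestry_stats",
    "call_ancestry",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


def individual_intervals(ens: BootstrapEnsemble):
    """Per-(individual, component) bootstrap mean, SE, and 95% CI.

    SE is the replicate standard deviation (ddof=1); the CI is
    mean +/- 1.96*SE truncated to [0, 1].
    """
    if ens.B < 2:
        raise ValueError("need >= 2 bootstrap replicates")
    means = ens.Q_reps.mean(axis=0)
    ses = ens.Q_reps.std(axis=0, ddof=1)
    lo = np.clip(means - _Z95 * ses, 0.0, 1.0)
    hi = np.clip(means + _Z95 * ses, 0.0, 1.0)
    return means, ses, np.stack([lo, hi], axis=-1)


def zero_and_renormalize(means: np.ndarray, cis: np.ndarray):
    """Zero cells whose CI lower bound is <= 0 and renormalize rows.

    A proportion is called absent when its 95% CI includes 0 (lower bound
    <= 0 after truncation, i.e. exactly 0).  Rows where every cell would be
    zeroed are kept as the unzeroed means and flagged degenerate.
    """
    means = np.asarray(means, dtype=float)
    keep = cis[..., 0] > 0.0
    out = np.where(keep, means, 0.0)
    sums = out.sum(axis=-1, keepdims=True)
    degenerate = (sums.squeeze(-1) == 0.0)
    if np.any(degenerate):
        warnings.warn(f"{int(np.sum(degenerate))} row(s) zeroed everywhere; kept unzeroed")
        out[degenerate] = means[degenerate]
        sums = out.sum(axis=-1, keepdims=True)
    return out / sums, degenerate


def _dl_tau2(y: np.ndarray, v: np.ndarray) -> float:
    """DerSimonian-Laird between-unit variance (moment estimator, floored at 0)."""
    w = 1.0 / np.maximum(v, 1e-300)
    ybar = (w * y).sum() / w.sum()
    Qstat = (w * (y - ybar) ** 2).sum()
    df = len(y) - 1
    denom = w.sum() - (w**2).sum() / w.sum()
    if denom <= 0:
        return 0.0
    return float(max(0.0, (Qstat - df) / denom))


def sample_average_ancestry(ens: BootstrapEnsemble, sample_map: dict[str, str]):
    """Inverse-variance-weighted sample ancestry proportions.

    Per sample and component, the weighted mean of individual bootstrap
    means with weights 1/(SE_i^2 + tau^2), tau^2 the DerSimonian-Laird
    between-individual variance.  Returns (sample_props DataFrame,
    combined-SE DataFrame) with one row per sample.
    """
    means, ses, _ = individual_intervals(ens)
    ids = ens.reference.model.individual_ids
    for iid in ids:
        if iid not in sample_map:
            raise KeyError(f"individual {iid!r} not in sample map")
    K = means.shape[1]
    samples = sorted(set(sample_map[i] for i in ids))
    props = np.empty((len(samples), K))
    comb_se = np.empty((len(samples), K))
    idx_of = {iid: i for i, iid in enumerate(ids)}
    for s_i, s in enumerate(samples):
        rows = [idx_of[i] for i in ids if sample_map[i] == s]
        if not rows:
            raise ValueError(f"sample {s!r} has no individuals")
        y = means[rows]
        v = ses[rows] ** 2
        for k in range(K):
            yk, vk = y[:, k], v[:, k]
            if np.all(vk == 0):
                # degenerate bootstrap: no within-individual variance
                props[s_i, k] = yk.mean()
                comb_se[s_i, k] = 0.0
                continue
            tau2 = _dl_tau2(yk, vk) if len(yk) > 1 else 0.0
            w = 1.0 / (vk + tau2 + 1e-300)
            props[s_i, k] = (w * yk).sum() / w.sum()
            comb_se[s_i, k] = np.sqrt(1.0 / w.sum())
    cols = [f"comp{k + 1}" for k in range(K)]
    return (
        pd.DataFrame(props, index=samples, columns=cols),
        pd.DataFrame(comb_se, index=samples, columns=cols),
    )


def designate_exemplars(sample_props: pd.DataFrame, log=None) -> dict[str, str]:
    """Per component, the sample with the highest proportion of it.

    Ties break to the lexicographically first sample label.
    """
    if sample_props.empty:
        raise ValueError("no samples")
    out: dict[str, str] = {}
    for comp in sample_props.columns:
        col = sample_props[comp]
        best = col.max()
        winners = sorted(col.index[col == best])
        if len(winners) > 1 and log is not None:
            log(f"exemplar tie for {comp}: {winners}; chose {winners[0]}")
        out[comp] = winners[0]
    return out


@dataclass
class CalledAncestry:
    """Called ancestry proportions and mixed-ancestry summaries."""

    individual_props: pd.DataFrame  # renormalized means, zeroed cells exactly 0
    individual_cis: np.ndarray  # n x K x 2 bounds
    sample_props: pd.DataFrame
    degenerate_individuals: np.ndarray

    def write(self, prefix) -> None:
        ind = self.individual_props.copy()
        for k, comp in enumerate(self.individual_props.columns):
            ind[f"{comp}_lo"] = self.individual_cis[:, k, 0]
            ind[f"{comp}_hi"] = self.individual_cis[:, k, 1]
        ind["n_ancestries"] = (self.individual_props.values > 0).sum(axis=1)
        ind.to_csv(f"{prefix}.individuals.tsv", sep="\t")
        samp = self.sample_props.copy()
        samp["n_ancestries"] = (self.sample_props.values > 0).sum(axis=1)
        samp.to_csv(f"{prefix}.samples.tsv", sep="\t")


def call_ancestry(ens: BootstrapEnsemble, sample_map: dict[str, str]) -> CalledAncestry:
    """Full calling pipeline: intervals -> zeroing -> sample averaging.

    Sample-level proportions average the unzeroed individual means with
    inverse-variance weights, then apply the same CI-zeroing rule using the
    combined SE of the weighted mean.
    """
    means, _, cis = individual_intervals(ens)
    ind_props, degen = zero_and_renormalize(means, cis)
    samp_means, samp_se = sample_average_ancestry(ens, sample_map)
    s_lo = np.clip(samp_means.values - _Z95 * samp_se.values, 0.0, 1.0)
    s_hi = np.clip(samp_means.values + _Z95 * samp_se.values, 0.0, 1.0)
    samp_props, _ = zero_and_renormalize(samp_means.values, np.stack([s_lo, s_hi], axis=-1))
    ids = ens.reference.model.individual_ids
    cols = [f"comp{k + 1}" for k in range(means.shape[1])]
    return CalledAncestry(
        pd.DataFrame(ind_props, index=ids, columns=cols),
        cis,
        pd.DataFrame(samp_props, index=samp_means.index, columns=cols),
        degen,
    )


def mixed_ancestry_stats(called: CalledAncestry) -> dict:
    """Mixed-ancestry summary at individual and sample level.

    An individual (sample) is mixed when more than one called component is
    nonzero.  The interval on counts is the 2.5th-97.5th percentile range of
    the integer count distribution.
    """
    ind_counts = (called.individual_props.values > 0).sum(axis=1)
    samp_counts = (called.sample_props.values > 0).sum(axis=1)

    def pct_interval(c):
        lo, hi = np.percentile(c, [2.5, 97.5], method="closest_observation")
        return int(lo), int(hi)

    return {
        "pct_mixed_individuals": 100.0 * float((ind_counts > 1).mean()),
        "median_ancestries_per_individual": float(np.median(ind_counts)),
        "individual_count_interval": pct_interval(ind_counts),
        "pct_mixed_samples": 100.0 * float((samp_counts > 1).mean()),
        "median_ancestries_per_sample": float(np.median(samp_counts)),
        "sample_count_interval": pct_interval(samp_counts),
        "individual_counts": ind_counts,
        "sample_counts": samp_counts,
    }
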