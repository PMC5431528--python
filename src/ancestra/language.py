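"""Ancestry-language correlation: point-biserial r, t-tests, batteries.

Each hypothesis pairs one ancestry's sample-level proportions with a binary
indicator built from language annotations (1 when a sample is annotated by
any family or branch in the tested grouping).  The point-biserial
correlation is the Pearson correlation of proportions with the 0/1 vector;
significance comes from the usual t-test with n-2 degrees of freedom, and
p-values are not corrected for multiple comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LanguageAnnotation",
    "CorrelationResult",
    "build_indicator",
    "point_biserial",
    "correlation_t_test",
    "run_hypothesis_battery",
    "battery_frame",
]


@dataclass
class LanguageAnnotation:
    """Sample -> language annotations (one or more families/branches each)."""

    families: dict[str, set[str]]

    @classmethod
    def from_map(cls, mapping: dict[str, str]) -> "LanguageAnnotation":
        return cls({s: {f} for s, f in mapping.items()})

    @classmethod
    def read_tsv(cls, path) -> "LanguageAnnotation":
        df = pd.read_csv(path, sep="\t", header=None, names=["sample", "family"], dtype=str)
        out: dict[str, set[str]] = {}
        for s, f in zip(df["sample"], df["family"]):
            out.setdefault(s, set()).add(f)
        return cls(out)

    def annotated(self, samples) -> list[str]:
        return [s for s in samples if s in self.families]


def build_indicator(
    ann: LanguageAnnotation, grouping: set[str], samples: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Binary indicator over annotated samples for a language grouping.

    Returns (indicator, used_samples); samples without annotation are
    excluded.  A grouping matching no sample (or all samples) yields a
    constant vector and is refused.
    """
    if not samples:
        raise ValueError("empty sample list")
    used = ann.annotated(samples)
    y = np.array([1 if ann.families[s] & set(grouping) else 0 for s in used])
    if len(used) and (y.all() or not y.any()):
        raise ValueError("grouping yields a constant indicator")
    return y, used


def point_biserial(x: np.ndarray, y: np.ndarray) -> float:
    """Point-biserial correlation (Pearson r of a proportion with a 0/1 vector)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    return float(np.corrcoef(x, y)[0, 1])


def correlation_t_test(r: float, n: int) -> tuple[float, int, float]:
    """(t, df, two-sided p) for H0: rho = 0 given a sample correlation.

    t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.  A perfect
    correlation has no finite t; p is reported as 0 with t = inf.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    df = n - 2
    if abs(r) >= 1:
        return float(np.inf) * np.sign(r), df, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


@dataclass
class CorrelationResult:
    """One ancestry-language hypothesis outcome."""

    ancestry: str
    grouping: tuple[str, ...]
    r: float
    n: int
    t: float
    df: int
    p: float
    error: str | None = None


def run_hypothesis_battery(
    sample_props: pd.DataFrame,
    ann: LanguageAnnotation,
    hypotheses: list[tuple[str, set[str]]],
) -> list[CorrelationResult]:
    """Run every (ancestry, grouping) hypothesis on annotated samples.

    Individual failures (constant indicators, missing ancestries) are
    recorded per row and the battery continues.  No multiplicity
    correction is applied.
    """
    if not hypotheses:
        raise ValueError("empty hypothesis list")
    samples = list(sample_props.index)
    out = []
    for ancestry, grouping in hypotheses:
        grouping = tuple(sorted(grouping))
        try:
            if ancestry not in sample_props.columns:
                raise KeyError(f"unknown ancestry {ancestry!r}")
            y, used = build_indicator(ann, set(grouping), samples)
            x = sample_props.loc[used, ancestry].to_numpy()
            r = point_biserial(x, y)
            t, df, p = correlation_t_test(r, len(used))
            out.append(CorrelationResult(ancestry, grouping, r, len(used), t, df, p))
        except Exception as exc:  # noqa: BLE001 - per-row failure is data
            out.append(
                CorrelationResult(ancestry, grouping, np.nan, 0, np.nan, 0, np.nan, str(exc))
            )
    return out


def battery_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ancestry": c.ancestry,
                "grouping": "+".join(c.grouping),
                "r": c.r,
                "n": c.n,
                "t": c.t,
                "df": c.df,
                "p": c.p,
                "error": c.error or "",
            }
            for c in results
        ]
    )
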