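"""F_ST estimation, matrix-comparison statistics, and power analysis.

Two estimators: a Hudson-type ratio-of-sums over loci on component
(parameter) allele frequencies, and the Weir & Cockerham (1984)
two-population theta on sample genotypes.  Matrix comparisons cover the
ascertainment check (median difference with percentile interval), Mantel
correlation tests with Fisher-z parametric bounds plus permutation, and a
block-bootstrap test of F_ST = 0.  The power analysis converts a
detectability threshold on F_ST into a divergence time in generations and
years.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import child_rng
from .genotype_io import GenotypeMatrix

__all__ = [
    "FstMatrix",
    "PowerResult",
    "component_fst",
    "hudson_fst",
    "weir_cockerham_theta",
    "pairwise_sample_fst",
    "compare_fst_matrices",
    "mantel_test",
    "fst_zero_test",
    "detectability_threshold",
    "divergence_time",
    "generations_to_years",
    "power_analysis",
]


@dataclass
class FstMatrix:
    """Labelled symmetric matrix of pairwise F_ST values."""

    labels: list[str]
    values: np.ndarray
    estimator: str  # "component" | "weir-cockerham"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        self.values = v

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def hudson_fst(fa: np.ndarray, fb: np.ndarray) -> float:
    """Hudson-type F_ST between two parameter frequency vectors.

    Ratio of sums across loci: sum (fa-fb)^2 over sum [fa(1-fb)+fb(1-fa)].
    Defined as 0 when both vectors are identically fixed everywhere.
    """
    fa = np.asarray(fa, dtype=float)
    fb = np.asarray(fb, dtype=float)
    num = ((fa - fb) ** 2).sum()
    den = (fa * (1 - fb) + fb * (1 - fa)).sum()
    if den == 0.0:
        return 0.0
    return float(num / den)


def component_fst(F: np.ndarray, labels: list[str] | None = None) -> FstMatrix:
    """Pairwise Hudson-type F_ST between component frequency rows."""
    F = np.asarray(F, dtype=float)
    if np.any((F < 0) | (F > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    K = F.shape[0]
    labels = labels or [f"comp{k + 1}" for k in range(K)]
    out = np.zeros((K, K))
    for a in range(K):
        for b in range(a + 1, K):
            out[a, b] = out[b, a] = hudson_fst(F[a], F[b])
    return FstMatrix(labels, out, "component")


# -- Weir & Cockerham --------------------------------------------------------

def _wc_components(d1: np.ndarray, d2: np.ndarray):
    """Per-locus Weir-Cockerham (1984) variance components a, b, c for r=2.

    ``d1``/``d2`` are dosage matrices (individuals x loci) with NaN for
    missing.  Returns (a, b, c) arrays over loci; loci with fewer than two
    usable individuals in either group come back NaN.
    """
    r = 2
    n1 = np.sum(~np.isnan(d1), axis=0).astype(float)
    n2 = np.sum(~np.isnan(d2), axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.nansum(d1, axis=0) / (2 * n1)
        p2 = np.nansum(d2, axis=0) / (2 * n2)
        # NaN == 1 is False, so divide by the non-missing count explicitly
        h1 = np.sum(d1 == 1, axis=0) / n1
        h2 = np.sum(d2 == 1, axis=0) / n2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    usable = (n1 >= 2) & (n2 >= 2)
    for arr in (a, b, c):
        arr[~usable] = np.nan
    return a, b, c


def weir_cockerham_theta(d1: np.ndarray, d2: np.ndarray) -> float:
    """Weir-Cockerham two-population theta, ratio of sums across loci.

    Loci monomorphic across both groups (or unusable) are skipped.
    """
    a, b, c = _wc_components(np.asarray(d1, float), np.asarray(d2, float))
    tot = a + b + c
    use = np.isfinite(tot) & (tot != 0.0)
    if not use.any():
        raise ValueError("no usable polymorphic loci")
    return float(np.sum(a[use]) / np.sum(tot[use]))


def pairwise_sample_fst(G: GenotypeMatrix, sample_map: dict[str, str]) -> FstMatrix:
    """Pairwise Weir-Cockerham theta between all samples in the map."""
    d = G.dosages_float()
    groups = sorted(set(sample_map.values()))
    rows = {
        g: [i for i, iid in enumerate(G.individual_ids) if sample_map.get(iid) == g]
        for g in groups
    }
    for g, idx in rows.items():
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 individuals")
    K = len(groups)
    out = np.zeros((K, K))
    for a in range(K):
        for b in range(a + 1, K):
            out[a, b] = out[b, a] = weir_cockerham_theta(d[rows[groups[a]]], d[rows[groups[b]]])
    return FstMatrix(groups, out, "weir-cockerham")


# -- matrix comparisons ------------------------------------------------------

def compare_fst_matrices(A: FstMatrix, B: FstMatrix):
    """Median and 2.5/97.5 percentile interval of elementwise differences.

    Differences are taken over upper-triangle entries (B - A).
    """
    if A.labels != B.labels:
        raise ValueError("label mismatch between matrices")
    diff = B.upper_triangle() - A.upper_triangle()
    lo, hi = np.percentile(diff, [2.5, 97.5])
    return float(np.median(diff)), (float(lo), float(hi))


def mantel_test(
    A: FstMatrix,
    B: FstMatrix,
    rho0: float = 0.0,
    n_perm: int = 9999,
    seed: int = 0,
):
    """Mantel correlation between two distance matrices.

    Returns (r, (p_N, p_pairs), p_permutation).  The parametric p is a
    Fisher-z chi-square(1) test of rho = rho0 computed twice, once with
    effective sample size N (the matrix dimension) and once with N(N-1)/2
    (the number of off-diagonal pairs), reported as a bound pair.  The
    permutation p permutes rows/columns of B jointly and is valid for
    rho0 = 0; for |rho0| = 1 the parametric construction diverges and only
    the permutation p is returned.
    """
    if A.values.shape != B.values.shape:
        raise ValueError("matrices differ in shape")
    if not -1 <= rho0 <= 1:
        raise ValueError("rho0 must lie in [-1, 1]")
    x = A.upper_triangle()
    y = B.upper_triangle()
    r = float(np.corrcoef(x, y)[0, 1])
    N = len(A.labels)
    if abs(rho0) == 1:
        warnings.warn("|rho0| = 1: parametric Fisher-z p undefined; permutation only")
        p_param = (np.nan, np.nan)
    else:
        ps = []
        for n_eff in (N, N * (N - 1) // 2):
            z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15)) - np.arctanh(rho0)
            chi2 = max(n_eff - 3, 1) * z**2
            ps.append(float(stats.chi2.sf(chi2, df=1)))
        p_param = (min(ps), max(ps))
    rng = child_rng(seed, "mantel")
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(N)
        yp = B.values[np.ix_(perm, perm)][np.triu_indices(N, k=1)]
        if abs(np.corrcoef(x, yp)[0, 1]) >= abs(r) - 1e-12:
            count += 1
    p_perm = (count + 1) / (n_perm + 1)
    return r, p_param, float(p_perm)


def fst_zero_test(
    f_prev: np.ndarray,
    f_curr: np.ndarray,
    n_blocks: int = 1000,
    block_size: int = 100,
    seed: int = 0,
):
    """Test F_ST = 0 between two frequency vectors for the same markers.

    Point estimate by the Hudson-type component estimator; SE by block
    bootstrap over contiguous locus blocks (``n_blocks`` resamples); one-
    sided p from z = fst/se against 0.
    """
    f_prev = np.asarray(f_prev, float)
    f_curr = np.asarray(f_curr, float)
    if f_prev.shape != f_curr.shape:
        raise ValueError("frequency vectors differ in length")
    m = len(f_prev)
    if m < 10:
        raise ValueError("need at least 10 loci for a block-bootstrap SE")
    fst = hudson_fst(f_prev, f_curr)
    bs = max(1, min(block_size, m // 2))
    starts = np.arange(0, m, bs)
    blocks = [np.arange(s, min(s + bs, m)) for s in starts]
    rng = child_rng(seed, "fst-zero")
    reps = np.empty(n_blocks)
    for i in range(n_blocks):
        chosen = rng.integers(len(blocks), size=len(blocks))
        idx = np.concatenate([blocks[c] for c in chosen])
        reps[i] = hudson_fst(f_prev[idx], f_curr[idx])
    se = float(reps.std(ddof=1))
    if se == 0.0:
        p = 1.0 if fst == 0.0 else 0.0
    else:
        p = float(stats.norm.sf(fst / se))
    return fst, se, p


# -- power analysis ----------------------------------------------------------

@dataclass
class PowerResult:
    """Detectability threshold and its divergence-time interpretation."""

    m: int
    n1_eff: float
    n2_eff: float
    fst_threshold: float
    Ne: float
    t_generations: float
    generation_years: tuple[float, float]
    years: tuple[float, float]

    def to_json(self, path=None) -> str:
        d = {
            "m": self.m,
            "n1_eff": self.n1_eff,
            "n2_eff": self.n2_eff,
            "fst_threshold": self.fst_threshold,
            "Ne": self.Ne,
            "t_generations": self.t_generations,
            "generation_years": list(self.generation_years),
            "years": list(self.years),
        }
        text = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def detectability_threshold(n1_eff: float, n2_eff: float, m: int) -> float:
    """F_ST threshold above which structure is always detectable.

    The phase-transition result gives detectability at F_ST of order
    1/sqrt(n m); with unequal effective sizes the harmonic mean of the two
    is used: threshold = 1/sqrt(m * harmonic_mean(n1, n2)).
    """
    if n1_eff <= 0 or n2_eff <= 0 or m <= 0:
        raise ValueError("inputs must be positive")
    n_tilde = 2.0 / (1.0 / n1_eff + 1.0 / n2_eff)
    return float(1.0 / np.sqrt(m * n_tilde))


def divergence_time(fst: float, Ne: float) -> float:
    """Divergence time in generations: t = ln(1-F_ST)/ln(1-1/(2 Ne))."""
    if not 0 <= fst < 1:
        raise ValueError("fst must lie in [0, 1)")
    if Ne <= 0:
        raise ValueError("Ne must be positive")
    if fst == 0:
        return 0.0
    return float(np.log1p(-fst) / np.log1p(-1.0 / (2.0 * Ne)))


def generations_to_years(
    t: float, gen_years_low: float, gen_years_high: float, round_to: int | None = None
):
    """Convert generations to a (low, high) range of years.

    ``round_to`` (e.g. 100) rounds both endpoints for report formatting.
    """
    if t < 0 or gen_years_low <= 0 or gen_years_high <= 0:
        raise ValueError("inputs must be positive")
    lo, hi = t * gen_years_low, t * gen_years_high
    if round_to:
        lo = round(lo / round_to) * round_to
        hi = round(hi / round_to) * round_to
    return float(lo), float(hi)


def power_analysis(
    Q: np.ndarray,
    m: int,
    Ne: float = 20000.0,
    gen_years: tuple[float, float] = (25.0, 30.0),
) -> PowerResult:
    """Full power analysis from a fitted Q matrix.

    Effective per-ancestry sample sizes are the Q column sums; the two
    smallest drive the detectability threshold.
    """
    n_eff = np.sort(np.asarray(Q).sum(axis=0))
    n1, n2 = float(n_eff[0]), float(n_eff[1] if len(n_eff) > 1 else n_eff[0])
    thr = detectability_threshold(n1, n2, m)
    t = divergence_time(thr, Ne)
    years = generations_to_years(t, *gen_years)
    return PowerResult(m, n1, n2, thr, Ne, t, gen_years, years)
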