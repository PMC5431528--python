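"""Unsupervised admixture model: binomial likelihood, EM fitting, K selection.

The model: individual i carries ancestry proportions q_i (summing to 1 over
K latent components) and component k carries allele frequencies f_k.  The
dosage g_ij at a diallelic marker is Binomial(2, p_ij) with
p_ij = sum_k q_ik f_kj.  Constant binomial coefficients are dropped from the
log-likelihood; missing genotypes contribute nothing.

``AdmixtureModel`` follows the statsmodels convention: construct from data,
``fit`` returns an ``AdmixtureResults`` carrying Q, F, the log-likelihood
and diagnostics; cross-validation, K selection and marker-bootstrap
ensembles hang off the model/results pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import xlogy

from ._util import child_rng, child_seed
from .genotype_io import GenotypeMatrix

__all__ = [
    "AdmixtureModel",
    "AdmixtureResults",
    "BootstrapEnsemble",
    "CVTable",
    "loglikelihood",
    "em_step",
    "fit_admixture",
    "cross_validation_error",
    "select_K",
    "bootstrap_fit",
    "align_components",
]

_EPS = 1e-9  # clamp for F to keep the log-likelihood finite


def _as_arrays(G) -> tuple[np.ndarray, np.ndarray]:
    """(dosage float array with 0 at missing, observation mask)."""
    if isinstance(G, GenotypeMatrix):
        miss = G.missing_mask
        g = G.dosages.astype(np.float64)
    else:
        g = np.asarray(G, dtype=np.float64)
        miss = np.isnan(g) | (g < 0)
        g = g.copy()
    g[miss] = 0.0
    return g, (~miss).astype(np.float64)


def loglikelihood(G, Q: np.ndarray, F: np.ndarray) -> float:
    """Binomial admixture log-likelihood (binomial coefficients dropped).

    Returns -inf (with a warning) if some observed genotype has probability
    exactly 0 under (Q, F).
    """
    g, mask = _as_arrays(G)
    P = Q @ F
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = mask * (g * np.log(P) + (2.0 - g) * np.log1p(-P))
    # 0 * log 0 at an unobserved or irrelevant boundary is 0, not NaN
    terms = np.where(mask * (g != 0) * (P == 0), -np.inf, np.where(np.isnan(terms), 0.0, terms))
    terms = np.where(mask * (g != 2) * (P == 1), -np.inf, terms)
    ll = float(terms.sum())
    if not np.isfinite(ll):
        warnings.warn("degenerate p_ij: observed genotype with probability 0")
    return ll


def em_step(G, Q: np.ndarray, F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One EM update; ascends the log-likelihood.

    q'_ik averages, over the individual's non-missing markers, the posterior
    expected number of gene copies from component k; f'_kj is the posterior
    ratio of alternate to total copies attributed to k at marker j.
    """
    g, mask = _as_arrays(G)
    F = np.clip(F, _EPS, 1.0 - _EPS)
    P = Q @ F
    R = mask * g / P  # n x m
    S = mask * (2.0 - g) / (1.0 - P)
    # Q update
    M = mask.sum(axis=1)  # non-missing markers per individual
    Qnew = Q * (R @ F.T + S @ (1.0 - F).T)
    Qnew /= np.maximum(2.0 * M, 1.0)[:, None]
    Qnew /= Qnew.sum(axis=1, keepdims=True)
    # F update
    A = F * (Q.T @ R)
    B = (1.0 - F) * (Q.T @ S)
    with np.errstate(invalid="ignore"):
        Fnew = A / (A + B)
    Fnew = np.where(np.isnan(Fnew), F, Fnew)
    return Qnew, np.clip(Fnew, _EPS, 1.0 - _EPS)


@dataclass
class AdmixtureResults:
    """Fit of the admixture model: proportions Q, frequencies F, diagnostics."""

    model: "AdmixtureModel"
    Q: np.ndarray
    F: np.ndarray
    loglik: float
    K: int
    iterations: int
    converged: bool
    seed: int

    def summary(self) -> str:
        lines = [
            "Admixture model fit",
            "===================",
            f"individuals:      {self.Q.shape[0]}",
            f"markers:          {self.F.shape[1]}",
            f"components (K):   {self.K}",
            f"log-likelihood:   {self.loglik:.4f}",
            f"EM iterations:    {self.iterations}",
            f"converged:        {self.converged}",
            "",
            "mean ancestry proportions per component:",
        ]
        for k, v in enumerate(self.Q.mean(axis=0)):
            lines.append(f"  comp{k + 1}: {v:.4f}")
        return "\n".join(lines)

    def q_frame(self) -> pd.DataFrame:
        cols = [f"comp{k + 1}" for k in range(self.K)]
        return pd.DataFrame(self.Q, index=self.model.individual_ids, columns=cols)

    def component_fst(self):
        from .fst import component_fst

        return component_fst(self.F, labels=[f"comp{k + 1}" for k in range(self.K)])

    def bootstrap(self, B: int = 200, seed: int = 0) -> "BootstrapEnsemble":
        return bootstrap_fit(self.model.G, self.K, B=B, seed=seed, reference=self)

    def write(self, prefix) -> None:
        """Write Q (individuals x K) and P-style F (markers x K) text files."""
        np.savetxt(f"{prefix}.Q", self.Q, fmt="%.6f")
        np.savetxt(f"{prefix}.P", self.F.T, fmt="%.6f")


class AdmixtureModel:
    """Binomial admixture model over a genotype matrix.

    Parameters
    ----------
    G : GenotypeMatrix or array of dosages (NaN / negative = missing)
    K : number of ancestral components
    """

    def __init__(self, G, K: int):
        if K < 1:
            raise ValueError("K must be >= 1")
        self.G = G
        self.K = int(K)
        g, mask = _as_arrays(G)
        self._g, self._mask = g, mask
        self.n, self.m = g.shape
        if isinstance(G, GenotypeMatrix):
            self.individual_ids = list(G.individual_ids)
            self.marker_ids = list(G.marker_ids)
        else:
            self.individual_ids = [f"ind{i + 1}" for i in range(self.n)]
            self.marker_ids = [f"snp{j + 1}" for j in range(self.m)]

    # -- fitting ------------------------------------------------------------

    def _init_params(self, rng) -> tuple[np.ndarray, np.ndarray]:
        Q = rng.dirichlet(np.ones(self.K), size=self.n)
        F = rng.uniform(0.05, 0.95, size=(self.K, self.m))
        return Q, F

    def fit(
        self,
        seed: int = 0,
        tol: float = 1e-6,
        max_iter: int = 2000,
        start: tuple[np.ndarray, np.ndarray] | None = None,
    ) -> AdmixtureResults:
        """Run EM to convergence (log-likelihood gain < ``tol``)."""
        if self.K == 1:
            # closed form: f_j = mean dosage / 2, q = 1
            with np.errstate(invalid="ignore"):
                f = self._g.sum(axis=0) / np.maximum(2.0 * self._mask.sum(axis=0), 1.0)
            F = np.clip(f[None, :], _EPS, 1.0 - _EPS)
            Q = np.ones((self.n, 1))
            return AdmixtureResults(self, Q, F, loglikelihood(self.G, Q, F), 1, 0, True, seed)
        rng = child_rng(seed, "admixture-init")
        Q, F = self._init_params(rng) if start is None else (start[0].copy(), start[1].copy())
        F = np.clip(F, _EPS, 1.0 - _EPS)
        g, mask = self._g, self._mask
        gm = g * mask
        g2m = (2.0 - g) * mask
        inv2M = 1.0 / np.maximum(2.0 * mask.sum(axis=1), 1.0)[:, None]

        def ll_of(Qx, Fx):
            P = Qx @ Fx
            return float((gm * np.log(P) + g2m * np.log1p(-P)).sum())

        def em(Qx, Fx):
            P = Qx @ Fx
            R = gm / P
            S = g2m / (1.0 - P)
            Qn = Qx * (R @ Fx.T + S @ (1.0 - Fx).T) * inv2M
            Qn /= Qn.sum(axis=1, keepdims=True)
            A = Fx * (Qx.T @ R)
            B = (1.0 - Fx) * (Qx.T @ S)
            Fn = np.clip(A / np.maximum(A + B, 1e-300), _EPS, 1.0 - _EPS)
            return Qn, Fn

        # Monotone SQUAREM acceleration over the EM map: the extrapolated
        # step is accepted only when it does not lower the likelihood, so
        # the EM ascent property is preserved along the trajectory.
        ll = ll_of(Q, F)
        converged = False
        it = 0
        while it < max_iter:
            Q1, F1 = em(Q, F)
            Q2, F2 = em(Q1, F1)
            it += 2
            rQ, rF = Q1 - Q, F1 - F
            vQ, vF = (Q2 - Q1) - rQ, (F2 - F1) - rF
            vnorm = np.sqrt((vQ**2).sum() + (vF**2).sum())
            accepted = False
            if vnorm > 0:
                alpha = -np.sqrt(((rQ**2).sum() + (rF**2).sum())) / vnorm
                alpha = min(alpha, -1.0)
                Qc = Q - 2 * alpha * rQ + alpha**2 * vQ
                Fc = F - 2 * alpha * rF + alpha**2 * vF
                Qc = np.clip(Qc, 1e-12, None)
                Qc /= Qc.sum(axis=1, keepdims=True)
                Fc = np.clip(Fc, _EPS, 1.0 - _EPS)
                # stabilizing EM step after extrapolation
                Qc, Fc = em(Qc, Fc)
                it += 1
                ll_c = ll_of(Qc, Fc)
                if np.isfinite(ll_c) and ll_c >= ll_of(Q2, F2):
                    Q, F, ll_new = Qc, Fc, ll_c
                    accepted = True
            if not accepted:
                Q, F = Q2, F2
                ll_new = ll_of(Q, F)
            if ll_new - ll < tol:
                ll = ll_new
                converged = True
                break
            ll = ll_new
        if not converged:
            warnings.warn(f"EM did not converge in {max_iter} iterations")
        return AdmixtureResults(self, Q, F, ll, self.K, it, converged, seed)

    # -- cross-validation ---------------------------------------------------

    def cv_error(self, folds: int = 5, seed: int = 0, tol: float = 1e-4,
                 max_iter: int = 500) -> float:
        """Masked-entry cross-validation error (mean held-out binomial deviance).

        Non-missing genotype entries are partitioned at random into ``folds``
        groups; each group is masked in turn, the model refit, and the
        held-out entries scored by binomial deviance under the predicted
        p_ij.  Returns the mean over folds.
        """
        if folds < 2:
            raise ValueError("folds must be >= 2")
        rng = child_rng(seed, "cv-folds")
        obs_i, obs_j = np.nonzero(self._mask)
        assignment = rng.integers(folds, size=len(obs_i))
        errors = []
        for fold in range(folds):
            hold = assignment == fold
            hi, hj = obs_i[hold], obs_j[hold]
            mask = self._mask.copy()
            mask[hi, hj] = 0.0
            if (mask.sum(axis=1) == 0).any() or (mask.sum(axis=0) == 0).any():
                raise ValueError(
                    "a CV fold empties an individual or marker; "
                    "use fewer folds or more data"
                )
            masked = np.where(mask.astype(bool), self._g, np.nan)
            sub = AdmixtureModel(masked, self.K)
            res = sub.fit(seed=child_seed(seed, f"cv-fit-{fold}"), tol=tol, max_iter=max_iter)
            P = np.clip(res.Q @ res.F, _EPS, 1 - _EPS)
            p = P[hi, hj]
            g = self._g[hi, hj]
            # xlogy handles the 0 * log 0 saturated-model terms at g = 0, 2
            d = xlogy(g, g / (2 * p)) + xlogy(2 - g, (2 - g) / (2 * (1 - p)))
            errors.append(float(2 * d.mean()))
        return float(np.mean(errors))


# module-level functional surface -------------------------------------------

def fit_admixture(G, K: int, seed: int = 0, tol: float = 1e-6,
                  max_iter: int = 2000) -> AdmixtureResults:
    return AdmixtureModel(G, K).fit(seed=seed, tol=tol, max_iter=max_iter)


def cross_validation_error(G, K: int, folds: int = 5, seed: int = 0, **kw) -> float:
    return AdmixtureModel(G, K).cv_error(folds=folds, seed=seed, **kw)


@dataclass
class CVTable:
    """Cross-validation errors per (K, replicate)."""

    rows: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["K", "replicate", "cv_error"])
    )

    def add(self, K: int, replicate: int, cv_error: float) -> None:
        if ((self.rows["K"] == K) & (self.rows["replicate"] == replicate)).any():
            raise ValueError(f"duplicate (K={K}, replicate={replicate})")
        if cv_error < 0:
            raise ValueError("cv_error must be >= 0")
        self.rows.loc[len(self.rows)] = [K, replicate, cv_error]

    def averaged(self) -> pd.Series:
        return self.rows.groupby("K")["cv_error"].mean()

    def per_run_argmin(self) -> list[int]:
        """Minimizing K within each replicate (run)."""
        out = []
        for _, grp in self.rows.groupby("replicate"):
            grp = grp.sort_values("K")
            out.append(int(grp.loc[grp["cv_error"].idxmin(), "K"]))
        return out

    def write(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def select_K(cv: CVTable, mode_runs: CVTable | None = None):
    """Model-order selection from cross-validation error tables.

    posterior-mean analog: the K minimizing the replicate-averaged CV error
    (ties go to the smaller K).  posterior-mode analog: the most frequent
    per-run minimizing K across the ``mode_runs`` table.  The HPD analog is
    the [min, max] range of distinct per-run minima.
    """
    avg = cv.averaged().sort_index()
    post_mean = int(avg.index[np.argmin(avg.values)])  # argmin; first = smaller K on ties
    runs = (mode_runs or cv).per_run_argmin()
    counts = pd.Series(runs).value_counts()
    top = counts[counts == counts.max()].index
    post_mode = int(min(top))
    hpd = (int(min(runs)), int(max(runs)))
    return post_mean, post_mode, hpd


# -- bootstrap ---------------------------------------------------------------

def align_components(F_ref: np.ndarray, F_new: np.ndarray) -> np.ndarray:
    """Permutation aligning components of ``F_new`` to ``F_ref``.

    Maximum-total-correlation one-to-one assignment between frequency rows
    (Hungarian algorithm).  Returns ``perm`` such that ``F_new[perm]``
    matches ``F_ref`` row for row.
    """
    K = F_ref.shape[0]
    C = np.empty((K, K))
    for a in range(K):
        for b in range(K):
            sa = F_ref[a] - F_ref[a].mean()
            sb = F_new[b] - F_new[b].mean()
            denom = np.sqrt((sa**2).sum() * (sb**2).sum())
            C[a, b] = (sa * sb).sum() / denom if denom > 0 else 0.0
    _, perm = linear_sum_assignment(-C)
    return perm


@dataclass
class BootstrapEnsemble:
    """Marker-bootstrap replicates of Q, aligned to a reference fit."""

    Q_reps: np.ndarray  # B x n x K
    reference: AdmixtureResults

    @property
    def B(self) -> int:
        return self.Q_reps.shape[0]


def bootstrap_fit(
    G,
    K: int,
    B: int = 200,
    seed: int = 0,
    reference: AdmixtureResults | None = None,
    tol: float = 1e-4,
    max_iter: int = 500,
    warm_start: bool = False,
) -> BootstrapEnsemble:
    """Marker bootstrap conditioned on K.

    Each replicate resamples markers with replacement, refits by EM, and
    aligns its components to the reference fit by maximum-correlation
    assignment of frequency rows.  Replicates start from fresh random
    initialisations by default: warm-starting every replicate at the
    reference solution (``warm_start=True``, cheaper) keeps all replicates
    in the reference's basin of attraction and demonstrably understates the
    sampling spread, so the resulting intervals under-cover the truth.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    model = AdmixtureModel(G, K)
    if reference is None:
        reference = model.fit(seed=child_seed(seed, "bootstrap-ref"))
    g, mask = model._g, model._mask
    m = model.m
    rng = child_rng(seed, "bootstrap")
    reps = np.empty((B, model.n, K))
    for b in range(B):
        idx = rng.integers(m, size=m)
        gb = np.where(mask[:, idx].astype(bool), g[:, idx], np.nan)
        sub = AdmixtureModel(gb, K)
        res = sub.fit(
            seed=child_seed(seed, f"bootstrap-{b}"),
            tol=tol,
            max_iter=max_iter,
            start=(reference.Q, reference.F[:, idx]) if warm_start else None,
        )
        perm = align_components(reference.F[:, idx], res.F)
        reps[b] = res.Q[:, perm]
    return BootstrapEnsemble(reps, reference)
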