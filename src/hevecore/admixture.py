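"""Maximum-likelihood admixture model and Evanno ΔK model selection.

Each individual ``i`` carries ancestry proportions ``q_i`` over ``K``
source populations with allele frequencies ``p_l`` per locus; the two
allele draws of a diploid genotype are independent Bernoulli with
success probability ``f_il = sum_k q_ik p_lk``.  The log-likelihood over
called genotypes ``g`` in {0, 1, 2} is

    L = sum_{i,l} [ g log f_il + (2 - g) log(1 - f_il) ].

The model is fitted by expectation–maximization from a seeded random
start; the updates are the standard frequency-model EM and increase the
likelihood monotonically.  Model choice across K follows the ad hoc ΔK
statistic of Evanno et al.: the absolute second difference of the mean
model-fit score over replicate runs, normalized by the replicate
standard deviation, peaks at the number of subpopulations.  Here the
maximized log-likelihood of each EM run plays the role of the per-run
model-fit score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypePanel

P_EPS = 1e-9


@dataclass
class AdmixtureFit:
    """One converged (or iteration-capped) EM run."""

    K: int
    Q: np.ndarray  # samples x K, rows sum to 1
    P: np.ndarray  # loci x K allele frequencies
    loglik: float
    seed: int
    n_iter: int
    converged: bool
    loglik_path: list[float] = field(default_factory=list)


def admixture_loglik(panel: GenotypePanel, Q: np.ndarray, P: np.ndarray) -> float:
    """Log-likelihood of the admixture model; missing genotypes are skipped."""
    G = panel.G
    if Q.shape != (panel.n_samples, P.shape[1]) or P.shape[0] != panel.n_loci:
        raise ValueError("dimension mismatch between panel, Q and P")
    called = G != MISSING
    g = np.where(called, G, 0).astype(float)
    r = np.where(called, 2 - G, 0).astype(float)
    F = np.clip(Q @ P.T, P_EPS, 1.0 - P_EPS)
    return float(np.sum(g * np.log(F) + r * np.log1p(-F)))


def fit_admixture(
    panel: GenotypePanel,
    K: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> AdmixtureFit:
    """Fit the K-population admixture model by EM from a seeded random start.

    Q rows start Dirichlet(1), P uniform on (0.05, 0.95).  Iteration stops
    when the log-likelihood improves by less than ``tol`` or after
    ``max_iter`` sweeps.  K = 1 converges in a single sweep to the
    observed frequencies.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > panel.n_samples:
        raise ValueError("K cannot exceed the number of samples")
    rng = np.random.default_rng(seed)
    n, m = panel.n_samples, panel.n_loci
    G = panel.G
    called = G != MISSING
    g = np.where(called, G, 0).astype(float)
    r = np.where(called, 2 - G, 0).astype(float)
    n_called = called.sum(axis=1)  # loci called per sample
    # samples with no calls keep a flat Q row
    safe_n_called = np.maximum(n_called, 1)

    Q = rng.dirichlet(np.ones(K), size=n)
    P = rng.uniform(0.05, 0.95, size=(m, K))

    path: list[float] = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        F = np.clip(Q @ P.T, P_EPS, 1.0 - P_EPS)
        A = g / F            # n x m, zero where missing
        B = r / (1.0 - F)
        # E-step expected allele assignments folded into closed-form M-step
        alt_scores = (A @ P) * Q            # n x K: expected alt alleles from k
        ref_scores = (B @ (1.0 - P)) * Q    # n x K: expected ref alleles from k
        Q_new = (alt_scores + ref_scores) / (2.0 * safe_n_called)[:, None]
        row_sums = Q_new.sum(axis=1, keepdims=True)
        Q_new = np.where(row_sums > 0, Q_new / np.maximum(row_sums, P_EPS), 1.0 / K)
        num = P * (A.T @ Q)                 # m x K expected alt allele counts
        den = num + (1.0 - P) * (B.T @ Q)
        P_new = np.where(den > 0, num / np.maximum(den, P_EPS), P)
        P_new = np.clip(P_new, P_EPS, 1.0 - P_EPS)
        Q, P = Q_new, P_new
        ll = admixture_loglik(panel, Q, P)
        path.append(ll)
        if abs(ll - prev) < tol:
            converged = True
            break
        prev = ll
    return AdmixtureFit(K, Q, P, path[-1], seed, it, converged, path)


def run_k_grid(
    panel: GenotypePanel,
    k_min: int = 1,
    k_max: int = 10,
    n_replicates: int = 5,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> dict[int, list[AdmixtureFit]]:
    """Replicate EM fits over a consecutive K grid.

    Replicate seeds are spawned deterministically from the master seed so
    each (K, replicate) cell is independently reproducible.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn((k_max - k_min + 1) * n_replicates)
    fits: dict[int, list[AdmixtureFit]] = {}
    i = 0
    for K in range(k_min, k_max + 1):
        fits[K] = []
        for _ in range(n_replicates):
            rep_seed = int(children[i].generate_state(1)[0] % (2**31))
            i += 1
            fits[K].append(fit_admixture(panel, K, rep_seed, max_iter, tol))
    return fits


def evanno_delta_k(logliks: dict[int, list[float]]) -> pd.DataFrame:
    """Evanno ΔK table from replicate model-fit scores per K.

    Returns one row per K with ``mean_L``, ``sd_L``, ``L1`` (first
    difference), ``abs_L2`` (absolute second difference) and ``delta_k``;
    ΔK is defined only for interior K.  The table carries a ``best_k``
    attribute (argmax ΔK, or None when no interior K has positive,
    defined ΔK).
    """
    ks = sorted(logliks)
    if len(ks) < 3:
        raise ValueError("Evanno ΔK needs at least three consecutive K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K grid must be consecutive")
    for k in ks[1:-1]:
        if len(logliks[k]) < 2:
            raise ValueError(f"interior K={k} needs >= 2 replicates")
    mean = {k: float(np.mean(logliks[k])) for k in ks}
    sd = {k: float(np.std(logliks[k], ddof=1)) if len(logliks[k]) > 1 else np.nan
          for k in ks}
    rows = []
    for k in ks:
        l1 = mean[k] - mean[k - 1] if k - 1 in mean else np.nan
        l2 = np.nan
        dk = np.nan
        if k - 1 in mean and k + 1 in mean:
            l2 = abs((mean[k + 1] - mean[k]) - (mean[k] - mean[k - 1]))
            if sd[k] == 0:
                warnings.warn(
                    f"replicate sd is zero at K={k}; ΔK undefined", UserWarning,
                    stacklevel=2,
                )
            else:
                dk = l2 / sd[k]
        rows.append(
            {
                "K": k,
                "n_replicates": len(logliks[k]),
                "mean_L": mean[k],
                "sd_L": sd[k],
                "L1": l1,
                "abs_L2": l2,
                "delta_k": dk,
            }
        )
    table = pd.DataFrame(rows)
    interior = table.dropna(subset=["delta_k"])
    if len(interior) and interior["delta_k"].max() > 0:
        best_k = int(interior.loc[interior["delta_k"].idxmax(), "K"])
    else:
        best_k = None
    table.attrs["best_k"] = best_k
    return table


def delta_k_from_fits(fits: dict[int, list[AdmixtureFit]]) -> pd.DataFrame:
    return evanno_delta_k({k: [f.loglik for f in v] for k, v in fits.items()})


def structure_report(fit: AdmixtureFit, sample_ids: list[str]) -> pd.DataFrame:
    """Per-sample ancestry table sorted for barplot display.

    Columns: sample, q1..qK, group (argmax ancestry) and max_q; rows are
    sorted by group then by descending membership.  Every reported
    quantity is invariant to column permutations of Q up to group
    relabelling.
    """
    if len(sample_ids) != fit.Q.shape[0]:
        raise ValueError("sample_ids do not match Q")
    out = pd.DataFrame(fit.Q, columns=[f"q{j + 1}" for j in range(fit.K)])
    out.insert(0, "sample", sample_ids)
    out["group"] = fit.Q.argmax(axis=1)
    out["max_q"] = fit.Q.max(axis=1)
    out = out.sort_values(
        ["group", "max_q", "sample"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return out
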