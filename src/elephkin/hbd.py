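"""Multi-class homozygosity-by-descent (HBD) hidden Markov model.

The genome of each individual is partitioned among nine HBD classes plus a
non-HBD class.  Class k's segment lengths are exponential with rate R_k
per Morgan, so R_k indexes the age of the common ancestor (~R_k/2
generations back): small rates mean long segments and recent inbreeding.
Default rates are the doubling series (2, 4, ..., 512) with the non-HBD
rate tied to the largest HBD rate.

Transitions between markers at genetic distance d: stay on the current
segment with probability exp(-R_k * d); otherwise a new segment starts and
belongs to class j with mixing probability M_j.  Emissions: non-HBD sites
are Hardy-Weinberg in the population allele frequency; HBD sites are
homozygous (p, 0, q) up to a genotyping-error mass eps spread as
Hardy-Weinberg.  Genetic positions come from bp at a constant 1 cM/Mb.

Inference is exact per chromosome (scaled forward-backward); the mixing
vector is estimated per individual by maximising the log-likelihood over
the simplex through an unconstrained softmax reparameterisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import minimize

from .core import MISSING, GenotypeMatrix

DEFAULT_RATES = (2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0, 256.0, 512.0, 512.0)

CLASS_NAMES = tuple(f"hbd_{int(r)}" for r in DEFAULT_RATES[:-1]) + ("non_hbd",)


@dataclass
class HbdModel:
    """Layered HBD model: per-class rates (1/Morgan), mixing simplex,
    genotyping-error mass."""

    rates: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_RATES))
    mixing: np.ndarray = None
    error: float = 0.001

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        k = len(self.rates)
        if self.mixing is None:
            self.mixing = np.full(k, 1.0 / k)
        self.mixing = np.asarray(self.mixing, dtype=float)
        if len(self.mixing) != k:
            raise ValueError("mixing length != number of classes")
        if np.any(self.rates <= 0):
            raise ValueError("rates must be strictly positive")
        if np.any(np.diff(self.rates[:-1]) < 0):
            raise ValueError("HBD class rates must be non-decreasing")
        if self.mixing.min() < -1e-12 or abs(self.mixing.sum() - 1) > 1e-8:
            raise ValueError("mixing must be a simplex")
        if not (0 <= self.error < 0.5):
            raise ValueError("error must be in [0, 0.5)")

    @property
    def n_states(self) -> int:
        return len(self.rates)

    def with_mixing(self, mixing) -> "HbdModel":
        return HbdModel(self.rates.copy(), np.asarray(mixing, float), self.error)


@dataclass
class HbdPosterior:
    """Per-marker state posteriors, total log-likelihood and the per-class
    genome fractions (unweighted marker average of the posteriors)."""

    gamma: np.ndarray  # (n_markers, n_states)
    loglik: float
    class_fractions: np.ndarray  # (n_states,)


def bp_to_morgans(pos_bp, cM_per_Mb: float = 1.0) -> np.ndarray:
    """Physical to genetic position under a constant recombination rate."""
    return np.asarray(pos_bp, dtype=float) * cM_per_Mb * 1e-8


def emission_prob(dosage: int, alt_freq: float, state: int, model: HbdModel) -> float:
    """Emission probability of one dosage under one state."""
    e = emission_matrix(np.array([dosage]), np.array([alt_freq]), model)
    return float(e[0, state])


def emission_matrix(dosages, freqs, model: HbdModel) -> np.ndarray:
    """(n_markers, n_states) emission probabilities; MISSING rows emit 1."""
    q = np.asarray(freqs, dtype=float)
    if np.any(q < 0) or np.any(q > 1):
        raise ValueError("allele frequencies outside [0, 1]")
    d = np.asarray(dosages)
    p = 1.0 - q
    hw = np.stack([p * p, 2 * p * q, q * q], axis=1)  # (m, 3)
    auto = (1 - model.error) * np.stack(
        [p, np.zeros_like(p), q], axis=1
    ) + model.error * hw
    m = len(q)
    k = model.n_states
    out = np.ones((m, k))
    obs = d != MISSING
    di = np.clip(d, 0, 2).astype(int)
    out[obs, : k - 1] = auto[obs, di[obs]][:, None]
    out[obs, k - 1] = hw[obs, di[obs]]
    return out


@njit(cache=True)
def _forward_core(em, stay, new_chain, M):
    """Scaled forward pass; returns loglik.  `stay` is exp(-R*d) per step
    (row t applies between markers t-1 and t); `new_chain[t]` marks the
    first marker of a chromosome (chain restarts there)."""
    m, k = em.shape
    loglik = 0.0
    alpha = np.empty(k)
    for t in range(m):
        if new_chain[t]:
            for j in range(k):
                alpha[j] = M[j] * em[t, j]
        else:
            leave = 0.0
            for j in range(k):
                leave += alpha[j] * (1.0 - stay[t, j])
            for j in range(k):
                alpha[j] = alpha[j] * stay[t, j] + leave * M[j]
            for j in range(k):
                alpha[j] *= em[t, j]
        s = 0.0
        for j in range(k):
            s += alpha[j]
        if s <= 0.0:
            return -np.inf
        loglik += np.log(s)
        for j in range(k):
            alpha[j] /= s
    return loglik


def _chain_geometry(model: HbdModel, chrom, pos_bp, cM_per_Mb: float):
    pos = bp_to_morgans(pos_bp, cM_per_Mb)
    chrom = np.asarray(chrom)
    m = len(pos)
    new_chain = np.zeros(m, dtype=np.bool_)
    new_chain[0] = True
    new_chain[1:] = chrom[1:] != chrom[:-1]
    d = np.zeros(m)
    d[1:] = pos[1:] - pos[:-1]
    d[new_chain] = 0.0
    stay = np.exp(-np.outer(d, model.rates))
    return stay, new_chain


def forward_backward(
    model: HbdModel,
    dosages,
    freqs,
    chrom,
    pos_bp,
    cM_per_Mb: float = 1.0,
) -> HbdPosterior:
    """Exact scaled forward-backward for one individual.

    Chromosomes are independent chains; each restarts from the mixing
    distribution.  Posteriors at each marker sum to one.
    """
    em = emission_matrix(dosages, freqs, model)
    if len(em) == 0:
        raise ValueError("zero markers")
    stay, new_chain = _chain_geometry(model, chrom, pos_bp, cM_per_Mb)
    M = model.mixing
    m, k = em.shape

    alpha = np.empty((m, k))
    scale = np.empty(m)
    for t in range(m):
        if new_chain[t]:
            a = M * em[t]
        else:
            leave = float(alpha[t - 1] @ (1.0 - stay[t]))
            a = (alpha[t - 1] * stay[t] + leave * M) * em[t]
        s = a.sum()
        if s <= 0:
            raise FloatingPointError("vanishing forward mass (emission bug?)")
        alpha[t] = a / s
        scale[t] = s
    loglik = float(np.log(scale).sum())

    beta = np.empty((m, k))
    beta[m - 1] = 1.0
    for t in range(m - 2, -1, -1):
        if new_chain[t + 1]:
            beta[t] = 1.0
        else:
            eb = em[t + 1] * beta[t + 1]
            common = float(M @ eb)
            beta[t] = (stay[t + 1] * eb + (1.0 - stay[t + 1]) * common) / scale[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return HbdPosterior(gamma, loglik, gamma.mean(axis=0))


def loglik_brute_force(
    model: HbdModel, dosages, freqs, chrom, pos_bp, cM_per_Mb: float = 1.0
) -> float:
    """Path-enumeration log-likelihood over all n_states**L paths (oracle
    for small L; single chromosome only)."""
    em = emission_matrix(dosages, freqs, model)
    stay, new_chain = _chain_geometry(model, chrom, pos_bp, cM_per_Mb)
    if new_chain.sum() != 1:
        raise ValueError("brute force expects a single chromosome")
    m, k = em.shape
    M = model.mixing
    # weights over all k**t path prefixes, tracked with each prefix's end state
    weights = (M * em[0]).astype(float)
    last = np.arange(k)
    for t in range(1, m):
        trans = (
            stay[t][:, None] * np.eye(k) + (1.0 - stay[t])[:, None] * M[None, :]
        )  # (from, to)
        weights = (weights[:, None] * trans[last] * em[t][None, :]).ravel()
        last = np.tile(np.arange(k), len(last))
    return float(np.log(weights.sum()))


def fit_mixing(
    model: HbdModel,
    dosages,
    freqs,
    chrom,
    pos_bp,
    cM_per_Mb: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 1000,
):
    """Maximum-likelihood mixing vector for one individual.

    Optimises the log-likelihood over the simplex via softmax logits with
    L-BFGS-B; rates and error stay fixed.  Returns (fitted HbdModel,
    log-likelihood trace over accepted iterations).
    """
    em = emission_matrix(dosages, freqs, model)
    stay, new_chain = _chain_geometry(model, chrom, pos_bp, cM_per_Mb)
    k = model.n_states
    trace: list[float] = []

    def neg_loglik(z):
        z = z - z.max()
        M = np.exp(z)
        M /= M.sum()
        ll = _forward_core(em, stay, new_chain, M)
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite likelihood during fit")
        return -ll

    def cb(z):
        trace.append(-neg_loglik(z))

    z0 = np.zeros(k)
    trace.append(-neg_loglik(z0))
    res = minimize(
        neg_loglik,
        z0,
        method="L-BFGS-B",
        callback=cb,
        options={"ftol": tol, "maxiter": max_iter},
    )
    z = res.x - res.x.max()
    M = np.exp(z)
    M /= M.sum()
    trace.append(float(-res.fun))
    return model.with_mixing(M), np.array(trace)


def partition_autozygosity(posterior: HbdPosterior) -> np.ndarray:
    """Per-class genome fractions (stacked-bar-ready): unweighted marker
    average of the state posteriors; sums to 1."""
    return posterior.class_fractions


def plot_partition(table: pd.DataFrame, path) -> None:
    """Stacked-bar figure of per-sample genome fractions by class
    (recent classes at the bottom, non-HBD on top)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cols = [c for c in CLASS_NAMES if c in table.columns]
    frac = table[cols].to_numpy()
    fig, ax = plt.subplots(figsize=(max(6, 0.04 * len(table)), 3.5))
    bottom = np.zeros(len(table))
    cmap = plt.get_cmap("viridis")
    for j, name in enumerate(cols):
        color = "lightgrey" if name == "non_hbd" else cmap(j / max(len(cols) - 2, 1))
        ax.bar(np.arange(len(table)), frac[:, j], bottom=bottom, width=1.0,
               color=color, label=name)
        bottom += frac[:, j]
    ax.set_xlim(-0.5, len(table) - 0.5)
    ax.set_ylim(0, 1)
    ax.set_xlabel("individual")
    ax.set_ylabel("genome fraction")
    ax.legend(fontsize=6, ncol=2, loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def fit_samples(
    G: GenotypeMatrix,
    freqs,
    model: Optional[HbdModel] = None,
    cM_per_Mb: float = 1.0,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Fit mixing and report genome partition for every sample.

    Returns a table with one row per sample: the 10 class fractions (from
    the posterior under the fitted mixing) plus the fitted log-likelihood.
    """
    model = model or HbdModel()
    rows = []
    chrom, pos = G.markers.chrom, G.markers.pos
    for i, sid in enumerate(G.sample_ids):
        fitted, trace = fit_mixing(
            model, G.calls[i], freqs, chrom, pos, cM_per_Mb, tol=tol
        )
        post = forward_backward(fitted, G.calls[i], freqs, chrom, pos, cM_per_Mb)
        row = {"sample_id": sid, "loglik": post.loglik}
        for name, frac in zip(CLASS_NAMES, post.class_fractions):
            row[name] = frac
        rows.append(row)
    return pd.DataFrame(rows)
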