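"""Bayesian admixture-model clustering of multilocus genotypes.

Model
-----
Each accession *i* carries a membership vector Q_i on the K-simplex; each
cluster *k* has allele frequencies P_k at every locus.  Every gene copy
independently picks an ancestral cluster from Q_i and then an allele from
that cluster's frequencies.  Two allele-frequency priors are available:

* ``independent``: P_k,l ~ Dirichlet(lambda) independently per cluster;
* ``correlated`` (default, the F-model): P_k,l ~ Dirichlet(p_A,l (1-F_k)/F_k)
  around a shared ancestral frequency vector p_A,l, with per-cluster drift
  F_k in (0, 0.5).

Inference is by Gibbs sampling: cluster-of-origin indicators, P, and Q all
have conjugate full conditionals; F_k and p_A,l (correlated model) are
updated by Metropolis steps.  The symmetric Dirichlet parameter alpha of
the Q prior is itself inferred by a Metropolis random walk (uniform prior
on (0, 10]): for panels of nearly pure accessions alpha collapses toward 0
and sharpens the memberships, while a fixed alpha = 1 (``infer_alpha=False``)
leaves them visibly smoothed toward 1/K.

Dominant markers scored as pseudo-homozygotes (1/1 band present, 0/0 band
absent) enter the likelihood exactly as coded, i.e. as two identical gene
copies; dominance is not modelled.

Model-size selection uses the log data probability lnP(D), estimated per
run as mean(lnL) - var(lnL)/2 over collected sweeps, and the second-order
rate-of-change statistic

    deltaK(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd L(K)

computed across replicate runs, which typically peaks at the uppermost
level of genuine structure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numba
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln

from .data_model import MISSING, DataError, GenotypeMatrix

__all__ = [
    "AdmixtureConfig",
    "AdmixtureRun",
    "gibbs_run",
    "run_structure",
    "delta_k",
    "align_runs",
    "assign_populations",
]

_F_MIN, _F_MAX = 1e-4, 0.5 - 1e-4
_F_STEP = 0.05
_PA_CONC = 50.0
_EPS = 1e-12
_ALPHA_MIN, _ALPHA_MAX = 1e-3, 10.0
_ALPHA_STEP = 0.3  # sd of the log-scale alpha random walk


@dataclass(frozen=True)
class AdmixtureConfig:
    """Sampler settings; defaults mirror a typical germplasm survey protocol
    (5000 burn-in, 5000 collected sweeps, 20 runs per K)."""

    K: int
    burn_in: int = 5000
    iterations: int = 5000
    n_runs: int = 20
    frequency_model: str = "correlated"
    seed: int = 0
    alpha: float = 1.0  # initial (or fixed) Dirichlet parameter for Q
    infer_alpha: bool = True
    lambda_: float = 1.0  # Dirichlet parameter for P (independent model)
    init: str = "kmeans"  # warm start near a mode; "random" for a flat start

    def __post_init__(self) -> None:
        if self.K < 1:
            raise DataError(f"K must be >= 1, got {self.K}")
        if self.burn_in <= 0 or self.iterations <= 0:
            raise DataError("burn_in and iterations must be positive")
        if self.frequency_model not in ("correlated", "independent"):
            raise DataError(f"unknown frequency model {self.frequency_model!r}")
        if self.init not in ("kmeans", "random"):
            raise DataError(f"unknown init {self.init!r}")


@dataclass
class AdmixtureRun:
    """Posterior-mean estimates from one Gibbs chain."""

    Q: np.ndarray  # (N, K) membership, rows sum to 1
    P: np.ndarray  # (K, L, J) allele frequencies (0 on invalid allele slots)
    lnPD: float
    seed: int
    K: int
    accessions: list[str]


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------


@dataclass
class _Encoded:
    """Flat allele-slot layout: locus l owns slots offsets[l] .. offsets[l]+counts[l)."""

    N: int
    L: int
    A: int  # total allele slots over all loci
    J: int  # max alleles at any locus (for the padded public P array)
    copy_acc: np.ndarray  # (M,) accession index per gene copy
    copy_slot: np.ndarray  # (M,) global allele-slot index per gene copy
    offsets: np.ndarray  # (L,) first slot of each locus
    counts: np.ndarray  # (L,) alleles per locus
    slot_loc: np.ndarray  # (A,) locus of each slot


def _encode(g: GenotypeMatrix) -> _Encoded:
    N, L = g.n_accessions, g.n_markers
    allele_maps: list[dict[int, int]] = []
    for j, mk in enumerate(g.markers):
        if mk.is_dominant:
            codes = [0, 1]
        elif mk.allele_labels:
            codes = sorted(int(a) for a in mk.allele_labels)
        else:
            observed = g.calls[:, j, :]
            codes = sorted(set(observed[observed != MISSING].tolist()))
            if not codes:
                codes = [0]
        allele_maps.append({c: d for d, c in enumerate(codes)})
    counts = np.array([len(m) for m in allele_maps], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(counts)[:-1]]).astype(np.int64)
    A = int(counts.sum())
    slot_loc = np.repeat(np.arange(L, dtype=np.int64), counts)

    acc_list, slot_list = [], []
    nonmissing_per_acc = np.zeros(N, dtype=int)
    for l in range(L):
        amap = allele_maps[l]
        col = g.calls[:, l, :]
        for i in range(N):
            a, b = col[i]
            if a == MISSING:
                continue
            for code in (a, b):
                acc_list.append(i)
                slot_list.append(offsets[l] + amap[int(code)])
            nonmissing_per_acc[i] += 1
    if (nonmissing_per_acc == 0).any():
        bad = [g.accessions[i] for i in np.flatnonzero(nonmissing_per_acc == 0)]
        raise DataError(f"accessions with all-missing genotypes: {bad}")
    return _Encoded(
        N=N,
        L=L,
        A=A,
        J=int(counts.max()),
        copy_acc=np.asarray(acc_list, dtype=np.int64),
        copy_slot=np.asarray(slot_list, dtype=np.int64),
        offsets=offsets,
        counts=counts,
        slot_loc=slot_loc,
    )


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------


@numba.njit(cache=False)
def _z_step(Q, P, alpha, ca, cs, u, z, nk, m):  # pragma: no cover - jit
    """Collapsed (Polya-urn) resampling of the cluster of origin per copy.

    Q is integrated out of the update: each copy is drawn from its full
    conditional given all other copies, pr_k ∝ (alpha + m[i,k]) * P[k,slot],
    with the accession's count vector m updated in place.  This mixes far
    better than conditioning on a sampled Q, whose corner states a short
    chain essentially never reaches.  ``u`` supplies one uniform per copy so
    the draw stream stays tied to the caller's numpy Generator.

    Returns the data log-likelihood sum(log Σ_k Q[i,k] P[k,slot]) evaluated
    at the supplied (reporting) Q, for the lnP(D) estimator.
    """
    M = ca.shape[0]
    K = Q.shape[1]
    lnl = 0.0
    pr = np.empty(K)
    for i in range(M):
        a, s = ca[i], cs[i]
        m[a, z[i]] -= 1.0
        tot = 0.0
        lik = 0.0
        for k in range(K):
            pr[k] = (alpha + m[a, k]) * P[k, s]
            tot += pr[k]
            lik += Q[a, k] * P[k, s]
        lnl += np.log(lik)
        target = u[i] * tot
        acc = 0.0
        knew = K - 1
        for k in range(K - 1):
            acc += pr[k]
            if target < acc:
                knew = k
                break
        z[i] = knew
        m[a, knew] += 1.0
        nk[knew, s] += 1.0
    return lnl


def _sample_dirichlet(
    rng: np.random.Generator, shape: np.ndarray, enc: _Encoded
) -> np.ndarray:
    """Per-locus Dirichlet draws over the flat allele slots (last axis)."""
    gam = rng.gamma(shape) + _EPS
    sums = np.add.reduceat(gam, enc.offsets, axis=-1)
    return gam / np.repeat(sums, enc.counts, axis=-1)


def _log_dirichlet_pdf(x: np.ndarray, conc: np.ndarray, enc: _Encoded) -> np.ndarray:
    """Per-locus log Dirichlet(conc) density at x; returns (..., L)."""
    terms = (conc - 1.0) * np.log(np.maximum(x, _EPS)) - gammaln(conc)
    return gammaln(np.add.reduceat(conc, enc.offsets, axis=-1)) + np.add.reduceat(
        terms, enc.offsets, axis=-1
    )


def _kmeans_partition(enc: _Encoded, K: int, rng: np.random.Generator) -> np.ndarray:
    """Hard K-partition of accessions on one-hot allele dosages (warm start)."""
    from sklearn.cluster import KMeans

    x = np.zeros((enc.N, enc.A))
    np.add.at(x, (enc.copy_acc, enc.copy_slot), 0.5)
    seed = int(rng.integers(2**31 - 1))
    km = KMeans(n_clusters=K, n_init=4, random_state=seed)
    return km.fit_predict(x)


def gibbs_run(g: GenotypeMatrix, cfg: AdmixtureConfig) -> AdmixtureRun:
    """One Gibbs chain; returns posterior-mean Q and P plus estimated lnP(D)."""
    if cfg.K > g.n_accessions:
        raise DataError(
            f"K = {cfg.K} exceeds the number of accessions ({g.n_accessions})"
        )
    enc = _encode(g)
    rng = np.random.default_rng(cfg.seed)
    K, N, L, A = cfg.K, enc.N, enc.L, enc.A
    correlated = cfg.frequency_model == "correlated"
    ca, cs = enc.copy_acc, enc.copy_slot
    M = ca.size

    # initial state; the k-means warm start places the chain near a mode of
    # the sharply multimodal posterior, which short chains cannot reach from
    # a flat start (the Z<->Q coupling sharpens only incrementally per sweep)
    if cfg.init == "kmeans" and K > 1:
        hard = _kmeans_partition(enc, K, rng)
        Q = np.full((N, K), 0.2 / max(K - 1, 1))
        Q[np.arange(N), hard] = 0.8
        z = hard[ca].astype(np.int64)
    else:
        Q = np.full((N, K), 1.0 / K)
        cum = np.cumsum(Q[ca, :], axis=1)
        z = np.minimum(
            (cum < (rng.random(M) * cum[:, -1])[:, None]).sum(axis=1), K - 1
        ).astype(np.int64)
    m = np.bincount(ca * K + z, minlength=N * K).reshape(N, K).astype(float)

    # ancestral frequencies start at the pooled observed frequencies, and P
    # at its conditional given the initial origin assignments, so every run
    # spends its burn-in refining the same mode rather than finding one
    pooled = np.bincount(cs, minlength=A).astype(float) + 0.5
    pA = pooled / np.repeat(
        np.add.reduceat(pooled, enc.offsets), enc.counts
    )
    F = np.full(K, 0.05)
    alpha = float(cfg.alpha)
    if correlated:
        prior = pA[None, :] * ((1.0 - F) / F)[:, None]
    else:
        prior = np.full((K, A), cfg.lambda_)
    nk0 = np.zeros((K, A))
    np.add.at(nk0, (z, cs), 1.0)
    P = _sample_dirichlet(rng, prior + nk0, enc)

    total = cfg.burn_in + cfg.iterations
    lnls = np.empty(cfg.iterations)
    q_sum = np.zeros_like(Q)
    p_sum = np.zeros_like(P)
    nk = np.empty((K, A))

    for t in range(total):
        # (a)+(b) collapsed origin resampling plus count accumulation
        nk[:] = 0.0
        lnl = _z_step(Q, P, alpha, ca, cs, rng.random(M), z, nk, m)

        # (c) allele frequencies P
        if correlated:
            prior = pA[None, :] * ((1.0 - F) / F)[:, None]
        P = _sample_dirichlet(rng, prior + nk, enc)

        if correlated:
            logdens_cur = _log_dirichlet_pdf(P, prior, enc).sum(axis=1)  # (K,)

            # (d) Metropolis update of per-cluster drift F_k, uniform prior
            f_prop = F + rng.normal(0.0, _F_STEP, size=K)
            f_prop = np.where(f_prop < _F_MIN, 2 * _F_MIN - f_prop, f_prop)
            f_prop = np.where(f_prop > _F_MAX, 2 * _F_MAX - f_prop, f_prop)
            f_prop = np.clip(f_prop, _F_MIN, _F_MAX)
            conc_prop = pA[None, :] * ((1.0 - f_prop) / f_prop)[:, None]
            logdens_prop = _log_dirichlet_pdf(P, conc_prop, enc).sum(axis=1)
            accept = np.log(rng.random(K)) < (logdens_prop - logdens_cur)
            F = np.where(accept, f_prop, F)

            # (e) Metropolis update of ancestral frequencies p_A per locus
            ratio = (1.0 - F) / F  # (K,)
            conc_q = _PA_CONC * np.maximum(pA, _EPS) + 0.5
            pa_prop = _sample_dirichlet(rng, conc_q, enc)
            loglik_cur = _log_dirichlet_pdf(P, pA[None, :] * ratio[:, None], enc).sum(axis=0)
            loglik_new = _log_dirichlet_pdf(P, pa_prop[None, :] * ratio[:, None], enc).sum(axis=0)
            conc_q_rev = _PA_CONC * np.maximum(pa_prop, _EPS) + 0.5
            log_q_fwd = _log_dirichlet_pdf(pa_prop, conc_q, enc)  # (L,)
            log_q_rev = _log_dirichlet_pdf(pA, conc_q_rev, enc)
            log_ratio = loglik_new - loglik_cur + log_q_rev - log_q_fwd
            accept_l = np.log(rng.random(L)) < log_ratio
            pA = np.where(np.repeat(accept_l, enc.counts), pa_prop, pA)

        # (f) memberships Q
        gam = rng.gamma(alpha + m) + _EPS
        Q = gam / gam.sum(axis=1, keepdims=True)

        # (g) Metropolis update of the symmetric Q-Dirichlet alpha.
        # Log-scale random walk so alpha can traverse orders of magnitude
        # within short chains; the log(a'/a) term is the proposal Jacobian.
        if cfg.infer_alpha:
            a_prop = alpha * float(np.exp(rng.normal(0.0, _ALPHA_STEP)))
            if _ALPHA_MIN <= a_prop <= _ALPHA_MAX:
                sum_log_q = float(np.log(np.maximum(Q, _EPS)).sum())

                def _alpha_logpost(a: float) -> float:
                    return N * (gammaln(K * a) - K * gammaln(a)) + (a - 1.0) * sum_log_q

                log_ratio = (
                    _alpha_logpost(a_prop)
                    - _alpha_logpost(alpha)
                    + np.log(a_prop / alpha)
                )
                if np.log(rng.random()) < log_ratio:
                    alpha = a_prop

        if t >= cfg.burn_in:
            s = t - cfg.burn_in
            lnls[s] = lnl
            q_sum += Q
            p_sum += P

    q_hat = q_sum / cfg.iterations
    # repack flat posterior-mean P into the padded (K, L, J) public layout
    p_flat = p_sum / cfg.iterations
    p_hat = np.zeros((K, L, enc.J))
    pos = np.arange(A) - enc.offsets[enc.slot_loc]
    p_hat[:, enc.slot_loc, pos] = p_flat
    ln_pd = float(lnls.mean() - 0.5 * lnls.var())
    return AdmixtureRun(
        Q=q_hat,
        P=p_hat,
        lnPD=ln_pd,
        seed=int(cfg.seed),
        K=K,
        accessions=list(g.accessions),
    )


def run_structure(
    g: GenotypeMatrix,
    k_values: Sequence[int],
    base_config: AdmixtureConfig | None = None,
    master_seed: int = 0,
) -> dict[int, list[AdmixtureRun]]:
    """Replicate chains over a range of K; per-run seeds expand from one
    master seed deterministically."""
    if base_config is None:
        base_config = AdmixtureConfig(K=1)
    runs: dict[int, list[AdmixtureRun]] = {}
    for k in k_values:
        runs[k] = []
        for r in range(base_config.n_runs):
            ss = np.random.SeedSequence([int(master_seed), int(k), int(r)])
            seed = int(ss.generate_state(1)[0] & 0x7FFFFFFF)
            cfg = replace(base_config, K=int(k), seed=seed)
            runs[k].append(gibbs_run(g, cfg))
    return runs


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------


def delta_k(runs: Mapping[int, Iterable[AdmixtureRun]] | Iterable[AdmixtureRun]) -> pd.DataFrame:
    """Second-order rate-of-change table across K.

    Accepts either a {K: runs} mapping or a flat run list.  Requires at
    least 3 consecutive K values with >= 2 runs each; deltaK is undefined
    (NaN) at the endpoints and +inf where the lnP(D) spread is zero.
    """
    if not isinstance(runs, Mapping):
        grouped: dict[int, list[AdmixtureRun]] = {}
        for r in runs:
            grouped.setdefault(r.K, []).append(r)
    else:
        grouped = {k: list(v) for k, v in runs.items()}
    ks = sorted(grouped)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise DataError("deltaK needs >= 3 consecutive K values")
    for k in ks:
        if len(grouped[k]) < 2:
            raise DataError(f"deltaK needs >= 2 runs per K (K={k})")
    mean_l = {k: float(np.mean([r.lnPD for r in grouped[k]])) for k in ks}
    sd_l = {k: float(np.std([r.lnPD for r in grouped[k]], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        lp = mean_l[k] - mean_l[k - 1] if (k - 1) in mean_l else np.nan
        if (k - 1) in mean_l and (k + 1) in mean_l:
            lpp = abs(mean_l[k + 1] - 2.0 * mean_l[k] + mean_l[k - 1])
            dk = lpp / sd_l[k] if sd_l[k] > 0 else np.inf
        else:
            lpp, dk = np.nan, np.nan
        rows.append(
            {
                "K": k,
                "n_runs": len(grouped[k]),
                "mean_lnPD": mean_l[k],
                "sd_lnPD": sd_l[k],
                "L_prime": lp,
                "L_doubleprime": lpp,
                "delta_K": dk,
            }
        )
    return pd.DataFrame(rows).set_index("K")


# ---------------------------------------------------------------------------
# run alignment (label switching across runs)
# ---------------------------------------------------------------------------


def _best_permutation(q: np.ndarray, ref: np.ndarray, K: int) -> tuple[int, ...]:
    """Column permutation of ``q`` minimizing ||q[:, perm] - ref||²_F.

    The objective decomposes per column, so the Hungarian assignment is the
    exact optimum — identical to exhaustive search over the K! permutations
    (which is what a brute-force check in the tests uses).
    """
    cost = np.empty((K, K))
    for a in range(K):
        diff = q[:, a][:, None] - ref
        cost[a] = (diff**2).sum(axis=0)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(K, dtype=int)
    perm[cols] = rows
    return tuple(int(p) for p in perm)


def align_runs(
    runs: Sequence[AdmixtureRun], K: int | None = None
) -> tuple[list[AdmixtureRun], pd.DataFrame]:
    """Resolve label switching across replicate runs.

    The run with the highest lnP(D) anchors the reference; remaining runs
    are permuted one at a time to best match the incrementally updated mean,
    mirroring the greedy full-search strategy of CLUMPP-style aligners.
    Returns (aligned runs, consensus Q as a DataFrame).
    """
    runs = list(runs)
    if not runs:
        raise DataError("no runs to align")
    if K is None:
        K = runs[0].K
    for r in runs:
        if r.K != K:
            raise DataError(f"run has K={r.K}, expected {K}")
        if r.accessions != runs[0].accessions:
            raise DataError("runs disagree on accession sets/order")

    order = sorted(range(len(runs)), key=lambda i: runs[i].lnPD, reverse=True)
    ref_sum = runs[order[0]].Q.copy()
    aligned: dict[int, AdmixtureRun] = {order[0]: runs[order[0]]}
    for count, i in enumerate(order[1:], start=1):
        ref = ref_sum / count
        perm = _best_permutation(runs[i].Q, ref, K)
        permuted = replace(
            runs[i], Q=runs[i].Q[:, perm].copy(), P=runs[i].P[list(perm), :, :].copy()
        )
        aligned[i] = permuted
        ref_sum += permuted.Q
    out = [aligned[i] for i in range(len(runs))]
    consensus = np.mean([r.Q for r in out], axis=0)
    consensus = consensus / consensus.sum(axis=1, keepdims=True)
    cols = [f"Pop{k + 1}" for k in range(K)]
    return out, pd.DataFrame(consensus, index=runs[0].accessions, columns=cols)


def assign_populations(q: pd.DataFrame | np.ndarray, threshold: float = 0.6) -> pd.Series:
    """Assign each accession to a population or an admixed class.

    Memberships strictly above ``threshold`` give "PopX"; otherwise the two
    largest components name an admixed class "PopX/Y" (descending
    membership, ties broken by population number).
    """
    if not 0.5 < threshold <= 1.0:
        raise DataError(f"threshold must be in (0.5, 1], got {threshold}")
    if isinstance(q, pd.DataFrame):
        index = q.index
        arr = q.to_numpy(dtype=float)
    else:
        arr = np.asarray(q, dtype=float)
        index = pd.RangeIndex(arr.shape[0])
    if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-6):
        raise DataError("Q rows must sum to 1")
    labels = []
    for row in arr:
        top = np.argsort(-row, kind="stable")
        if row[top[0]] > threshold:
            labels.append(f"Pop{top[0] + 1}")
        else:
            a, b = sorted((top[0] + 1, top[1] + 1)) if np.isclose(
                row[top[0]], row[top[1]]
            ) else (top[0] + 1, top[1] + 1)
            labels.append(f"Pop{a}/{b}")
    return pd.Series(labels, index=index, name="population")
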