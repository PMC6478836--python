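"""Multivariate hidden Markov chromatin-state segmentation.

Genome bins carry several count tracks (histone marks, RNA) modelled with
negative-binomial emissions, plus an optional methylation track of
(methylated, total) read pairs modelled with a binomial emission; tracks are
conditionally independent given the hidden state.  Fitting is Baum-Welch EM
with exact M-steps (the NB size parameter is profiled by bounded 1-D
optimization), so the log-likelihood is non-decreasing.  Bins are annotated
with the maximum-posterior state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from sklearn.cluster import KMeans

from .core_io import BinnedTrack, GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "HMMModel",
    "Segmentation",
    "hmm_fit",
    "posterior_decode",
    "model_scan",
    "state_enrichment",
    "state_transition_overlap",
    "detect_dual_mark_state",
    "distance_stratified_fc",
]

_R_MIN, _R_MAX = 1e-3, 1e4


@dataclass
class HMMModel:
    K: int
    A: np.ndarray  # K x K transitions
    pi: np.ndarray  # initial distribution
    nb_mu: np.ndarray  # K x n_tracks NB means
    nb_r: np.ndarray  # K x n_tracks NB size (dispersion) parameters
    meth_beta: np.ndarray | None  # K methylation rates, or None
    track_names: list[str] = field(default_factory=list)
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = False

    def __post_init__(self) -> None:
        if not np.allclose(self.A.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-10):
            raise ValueError("initial distribution must sum to 1")


@dataclass
class Segmentation:
    labels: np.ndarray  # per-bin argmax-posterior state
    posteriors: np.ndarray  # T x K
    state_nucleotides: np.ndarray  # genomic nt per state

    @property
    def K(self) -> int:
        return self.posteriors.shape[1]


def _as_count_matrix(tracks) -> tuple[np.ndarray, list[str]]:
    if isinstance(tracks, np.ndarray):
        return np.atleast_2d(tracks.T).T, [f"track{j}" for j in range(np.atleast_2d(tracks.T).T.shape[1])]
    cols, names = [], []
    for j, t in enumerate(tracks):
        if isinstance(t, BinnedTrack):
            cols.append(np.asarray(t.counts, dtype=np.int64))
            names.append(t.mark)
        else:
            cols.append(np.asarray(t, dtype=np.int64))
            names.append(f"track{j}")
    X = np.stack(cols, axis=1)
    return X, names


def _nb_logpmf_table(u: np.ndarray, mu: float, r: float) -> np.ndarray:
    """log NB pmf at counts u in the (mean, size) parametrization."""
    mu = max(mu, 1e-9)
    p_log = np.log(r) - np.log(r + mu)
    q_log = np.log(mu) - np.log(r + mu)
    return gammaln(u + r) - gammaln(r) - gammaln(u + 1) + r * p_log + u * q_log


def _emission_loglik(
    X: np.ndarray,
    uniq: list[np.ndarray],
    inv: list[np.ndarray],
    nb_mu: np.ndarray,
    nb_r: np.ndarray,
    meth: np.ndarray | None,
    beta: np.ndarray | None,
) -> np.ndarray:
    T, n_tracks = X.shape
    K = nb_mu.shape[0]
    logB = np.zeros((T, K))
    for j in range(n_tracks):
        for k in range(K):
            table = _nb_logpmf_table(uniq[j], nb_mu[k, j], nb_r[k, j])
            logB[:, k] += table[inv[j]]
    if meth is not None and beta is not None:
        m, n = meth[:, 0].astype(float), meth[:, 1].astype(float)
        const = gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1)
        for k in range(K):
            bk = min(max(beta[k], 1e-9), 1 - 1e-9)
            logB[:, k] += const + m * np.log(bk) + (n - m) * np.log1p(-bk)
    return logB


def _forward_backward(logB: np.ndarray, A: np.ndarray, pi: np.ndarray):
    """Scaled forward-backward.  Returns (loglik, gamma, xi_sum)."""
    T, K = logB.shape
    shift = logB.max(axis=1, keepdims=True)
    B = np.exp(logB - shift)
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = pi * B[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    w = B[1:] * beta[1:] / c[1:, None]
    xi_sum = A * (alpha[:-1].T @ w)
    loglik = float(np.log(c).sum() + shift.sum())
    return loglik, gamma, xi_sum


def _weighted_nb_mle(u: np.ndarray, w: np.ndarray, r_prev: float) -> tuple[float, float]:
    """Exact weighted NB M-step on compressed counts: mu is the weighted mean;
    r is profiled by bounded 1-D likelihood maximization, never worse than the
    previous iterate (keeps EM monotone)."""
    wsum = w.sum()
    mu = float((w * u).sum() / wsum)
    if mu <= 0:
        return 1e-6, _R_MAX

    def neg_ll(log_r: float) -> float:
        r = np.exp(log_r)
        return -float((w * _nb_logpmf_table(u, mu, r)).sum())

    res = minimize_scalar(neg_ll, bounds=(np.log(_R_MIN), np.log(_R_MAX)), method="bounded")
    r_new = float(np.exp(res.x))
    if neg_ll(np.log(np.clip(r_prev, _R_MIN, _R_MAX))) < res.fun:
        r_new = float(np.clip(r_prev, _R_MIN, _R_MAX))
    return mu, r_new


def hmm_fit(
    tracks,
    K: int,
    meth: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-4,
    seed: int = 0,
) -> HMMModel:
    """Baum-Welch fit of the multivariate NB(/binomial) HMM.

    ``tracks`` is a list of :class:`BinnedTrack` (or count vectors) aligned on
    the same bins; ``meth`` an optional (T, 2) array of (methylated, total)
    read counts.  Initialization is k-means on the log1p count matrix.
    ``tol`` is the absolute log-likelihood improvement per iteration at which
    EM stops.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    X, names = _as_count_matrix(tracks)
    nonzero = X.sum(axis=0) > 0
    if not nonzero.all():
        dropped = [names[j] for j in np.flatnonzero(~nonzero)]
        logger.warning("hmm_fit: dropping all-zero tracks %s", dropped)
        X = X[:, nonzero]
        names = [n for n, ok in zip(names, nonzero) if ok]
    T, n_tracks = X.shape
    uniq, inv = [], []
    for j in range(n_tracks):
        u, iv = np.unique(X[:, j], return_inverse=True)
        uniq.append(u.astype(float))
        inv.append(iv)

    # --- initialization: k-means on log1p counts (+ meth rate) -------------
    feats = [np.log1p(X.astype(float))]
    if meth is not None:
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(meth[:, 1] > 0, meth[:, 0] / np.maximum(meth[:, 1], 1), 0.5)
        feats.append(rate[:, None])
    F = np.concatenate(feats, axis=1)
    F = (F - F.mean(axis=0)) / np.maximum(F.std(axis=0), 1e-9)
    km = KMeans(n_clusters=K, n_init=5, random_state=seed)
    labels = km.fit_predict(F)

    gamma = np.zeros((T, K))
    gamma[np.arange(T), labels] = 1.0
    A = np.full((K, K), 1.0)
    for t in range(1, T):
        A[labels[t - 1], labels[t]] += 1
    A /= A.sum(axis=1, keepdims=True)
    pi = np.bincount(labels, minlength=K).astype(float) + 1.0
    pi /= pi.sum()

    nb_mu = np.empty((K, n_tracks))
    nb_r = np.full((K, n_tracks), 10.0)
    beta = np.full(K, 0.5) if meth is not None else None

    def m_step(g: np.ndarray) -> None:
        for k in range(K):
            w_k = g[:, k]
            if w_k.sum() < 1e-8:
                w_k = np.full(T, 1e-8)
            for j in range(n_tracks):
                w_u = np.bincount(inv[j], weights=w_k, minlength=len(uniq[j]))
                nb_mu[k, j], nb_r[k, j] = _weighted_nb_mle(uniq[j], w_u, nb_r[k, j])
            if meth is not None:
                num = float((w_k * meth[:, 0]).sum())
                den = float((w_k * meth[:, 1]).sum())
                beta[k] = min(max(num / den if den > 0 else 0.5, 1e-6), 1 - 1e-6)

    m_step(gamma)  # initial emissions from the hard k-means assignment
    loglik_trace: list[float] = []
    converged = False
    for iteration in range(max_iter):
        logB = _emission_loglik(X, uniq, inv, nb_mu, nb_r, meth, beta)
        loglik, gamma, xi_sum = _forward_backward(logB, A, pi)
        loglik_trace.append(loglik)
        if len(loglik_trace) > 1 and loglik < loglik_trace[-2] - 1e-6 * max(abs(loglik), 1.0):
            logger.warning("hmm_fit: log-likelihood decreased at iteration %d", iteration)
        if len(loglik_trace) > 1 and abs(loglik - loglik_trace[-2]) < tol:
            converged = True
            break
        # M-step: all parameters from the same posterior (standard Baum-Welch)
        A = xi_sum + 1e-12
        A /= A.sum(axis=1, keepdims=True)
        pi = gamma[0] + 1e-12
        pi /= pi.sum()
        m_step(gamma)

    return HMMModel(
        K=K,
        A=A,
        pi=pi,
        nb_mu=nb_mu.copy(),
        nb_r=nb_r.copy(),
        meth_beta=beta.copy() if beta is not None else None,
        track_names=names,
        loglik_trace=loglik_trace,
        converged=converged,
    )


def posterior_decode(model: HMMModel, tracks, meth: np.ndarray | None = None) -> Segmentation:
    """Forward-backward posteriors under a fitted model; per-bin label is the
    argmax posterior with ties broken toward the lower state index."""
    X, _ = _as_count_matrix(tracks)
    uniq, inv = [], []
    for j in range(X.shape[1]):
        u, iv = np.unique(X[:, j], return_inverse=True)
        uniq.append(u.astype(float))
        inv.append(iv)
    logB = _emission_loglik(X, uniq, inv, model.nb_mu, model.nb_r, meth, model.meth_beta)
    _, gamma, _ = _forward_backward(logB, model.A, model.pi)
    labels = np.argmax(gamma, axis=1)
    return Segmentation(
        labels=labels,
        posteriors=gamma,
        state_nucleotides=np.bincount(labels, minlength=model.K).astype(float),
    )


def model_scan(
    tracks,
    K_range=range(5, 26),
    meth: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-4,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit one model per state count K (shared seed policy) and report
    log-likelihood and BIC; model choice is left to the user."""
    X, _ = _as_count_matrix(tracks)
    T, n_tracks = X.shape
    rows = []
    for K in K_range:
        model = hmm_fit(tracks, K, meth=meth, max_iter=max_iter, tol=tol, seed=seed)
        ll = model.loglik_trace[-1]
        n_params = (K - 1) + K * (K - 1) + 2 * K * n_tracks + (K if meth is not None else 0)
        rows.append({"K": K, "loglik": ll, "n_params": n_params, "bic": -2 * ll + n_params * np.log(T)})
    return pd.DataFrame(rows)


def state_enrichment(
    labels: np.ndarray,
    bins: list[GenomicInterval],
    features: list[GenomicInterval],
) -> np.ndarray:
    """Fold enrichment of each state inside a feature set.

    enrichment_k = (state-k nt inside features / state-k nt genome-wide)
    divided by (feature nt / genome nt).  Empty states yield NaN.
    """
    from .core_io import _merge_intervals

    merged = _merge_intervals(features) if features else {}
    K = int(labels.max()) + 1
    bin_len = np.array([len(b) for b in bins], dtype=float)
    bin_feature_nt = np.zeros(len(bins))
    for i, b in enumerate(bins):
        arr = merged.get(b.chrom)
        if arr is None:
            continue
        ov = np.minimum(arr[:, 1], b.end) - np.maximum(arr[:, 0], b.start)
        bin_feature_nt[i] = ov[ov > 0].sum()
    genome_nt = bin_len.sum()
    feature_nt = bin_feature_nt.sum()
    if feature_nt == 0:
        raise ValueError("features do not overlap the binned genome")
    enr = np.full(K, np.nan)
    for k in range(K):
        mask = labels == k
        state_nt = bin_len[mask].sum()
        if state_nt == 0:
            continue
        inside = bin_feature_nt[mask].sum()
        enr[k] = (inside / state_nt) / (feature_nt / genome_nt)
    return enr


def state_transition_overlap(
    labels_a: np.ndarray,
    labels_b: np.ndarray,
    K_a: int | None = None,
    K_b: int | None = None,
) -> np.ndarray:
    """Row-normalized K_a x K_b matrix: fraction of condition-A state-k bins
    assigned to each condition-B state.  Empty A states give NaN rows."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("segmentations must cover identical bins")
    K_a = K_a or int(labels_a.max()) + 1
    K_b = K_b or int(labels_b.max()) + 1
    mat = np.zeros((K_a, K_b))
    np.add.at(mat, (labels_a, labels_b), 1)
    totals = mat.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        out = mat / totals
    out[totals[:, 0] == 0] = np.nan
    return out


def detect_dual_mark_state(
    model: HMMModel,
    mark_pair: tuple[str, str] = ("H3K27ac", "H3K27me3"),
    threshold: str = "median",
) -> list[int]:
    """States whose NB emission means exceed the across-state median (or mean)
    for BOTH marks of ``mark_pair`` — candidate bivalent/dual-mark states."""
    ids = []
    for mark in mark_pair:
        if mark not in model.track_names:
            raise ValueError(f"mark {mark!r} not among model tracks {model.track_names}")
        ids.append(model.track_names.index(mark))
    agg = np.median if threshold == "median" else np.mean
    cut = [agg(model.nb_mu[:, j]) for j in ids]
    out = [
        k
        for k in range(model.K)
        if all(model.nb_mu[k, j] > cut[i] for i, j in enumerate(ids))
    ]
    return out


def distance_stratified_fc(
    gene_expr_a: pd.Series,
    gene_expr_b: pd.Series,
    tss_table: pd.DataFrame,
    regions: list[GenomicInterval],
    edges: tuple = (0, 10_000, 50_000, 250_000, np.inf),
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene log2 fold-change (A over B) stratified by TSS distance to the
    nearest region edge, with a monotone-trend test (Spearman of distance vs
    fold-change) attached in ``.attrs``."""
    if not regions:
        raise ValueError("no regions supplied")
    genes = gene_expr_a.index.intersection(gene_expr_b.index).intersection(
        pd.Index(tss_table["gene"]) if "gene" in tss_table else tss_table.index
    )
    if len(genes) == 0:
        raise ValueError("empty gene set")
    tss = tss_table.set_index("gene") if "gene" in tss_table else tss_table
    by_chrom: dict[str, np.ndarray] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, [])
    for r in regions:
        by_chrom[r.chrom].append((r.start, r.end))
    by_chrom = {c: np.array(v) for c, v in by_chrom.items()}

    dist = np.empty(len(genes))
    for i, g in enumerate(genes):
        chrom, pos = tss.loc[g, "chrom"], tss.loc[g, "tss"]
        arr = by_chrom.get(chrom)
        if arr is None:
            dist[i] = np.inf
            continue
        inside = (arr[:, 0] <= pos) & (pos < arr[:, 1])
        d = 0.0 if inside.any() else np.minimum(np.abs(arr[:, 0] - pos), np.abs(arr[:, 1] - 1 - pos)).min()
        dist[i] = d
    lfc = np.log2(gene_expr_a.loc[genes].to_numpy() + pseudocount) - np.log2(
        gene_expr_b.loc[genes].to_numpy() + pseudocount
    )
    bin_idx = np.digitize(dist, edges[1:-1])
    rows = []
    for b in range(len(edges) - 1):
        mask = bin_idx == b
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "n_genes": int(mask.sum()),
                "median_log2fc": float(np.median(lfc[mask])) if mask.any() else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    from scipy import stats as _stats

    finite = np.isfinite(dist)
    if finite.sum() > 2 and len(np.unique(dist[finite])) > 1:
        rho, p = _stats.spearmanr(dist[finite], lfc[finite])
        out.attrs["trend_rho"], out.attrs["trend_p"] = float(rho), float(p)
    return out
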