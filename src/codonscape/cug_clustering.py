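"""Clustering genes into codon-usage groups (CUGs).

Genes are clustered by their synonymous codon usage distributions with a
multinomial mixture conditioned on each gene's amino-acid sequence: a
cluster s is a set of within-family codon frequency vectors theta_s, and a
gene's log-likelihood under s is sum_c count(c) * log theta_s(c | family).
The mixture is fit by expectation-maximization with restarts.

Model selection follows a self-consistency argument.  bg(s), the
posterior probability that gene g belongs to its assigned cluster,
measures per-gene assignment quality.  The dataset-level score B(S) is a
stability measure: the S-cluster model is refit on random subsamples of
the genes and B(S) is the geometric mean over genes of the subsample
model's posterior for each gene's full-data cluster (after label
matching) — reproducible structure scores near 1, clusters that merely
fit sampling noise do not reappear in subsample refits and drag B toward
0.  The same score on artificial data drawn from the pooled genome-wide
family frequencies (each gene keeping its amino-acid composition, no
cluster structure) gives B_random(S), and the retained cluster count
maximizes Delta(S) = B(S) - B_random(S).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .bias_metrics import CodonCounts, centered_usage
from .genetic_code import (
    CODON_TO_AA,
    DEGENERACY,
    DEGENERATE_AAS,
    DEGENERATE_CODONS,
    FAMILIES,
    SENSE_CODONS,
)

_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
#: column index blocks per degenerate family
_FAMILY_COLS = {
    aa: np.array([_CODON_INDEX[c] for c in FAMILIES[aa]]) for aa in DEGENERATE_AAS
}


@dataclass
class ClusterModel:
    """Fitted mixture over synonymous codon usage."""

    S: int
    theta: np.ndarray  # (S, 61) within-family normalized
    weights: np.ndarray  # (S,)
    assignments: dict[str, int]
    selfcons: dict[str, float]  # bg(s) per gene
    log_likelihood: float
    converged: bool = True
    ll_trace: list[float] = field(default_factory=list)

    @property
    def B(self) -> float:
        bg = np.array(list(self.selfcons.values()))
        return float(np.exp(np.mean(np.log(bg))))


@dataclass
class ModelSelection:
    """Per-S self-consistency records and the retained cluster count."""

    records: pd.DataFrame  # columns S, B, B_random, B_random_se, Delta
    chosen_S: int
    models: dict[int, ClusterModel] = field(default_factory=dict)


def counts_matrix(genes: Iterable[CodonCounts]) -> tuple[np.ndarray, list[str]]:
    """(genes x 61) sense-codon count matrix plus gene ids."""
    gene_list = list(genes)
    X = np.zeros((len(gene_list), len(SENSE_CODONS)))
    for i, g in enumerate(gene_list):
        for c, k in g.counts.items():
            X[i, _CODON_INDEX[c]] = k
    return X, [g.gene_id for g in gene_list]


def _normalize_theta(raw: np.ndarray) -> np.ndarray:
    """Normalize each cluster's rates within every synonymous family."""
    theta = raw.copy()
    for cols in _FAMILY_COLS.values():
        theta[:, cols] /= theta[:, cols].sum(axis=1, keepdims=True)
    # nondegenerate codons contribute a constant; give them probability 1
    nondeg = [
        _CODON_INDEX[c] for c in SENSE_CODONS if DEGENERACY[CODON_TO_AA[c]] == 1
    ]
    theta[:, nondeg] = 1.0
    return theta


def _log_theta(theta: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.where(theta > 0, np.log(theta), -np.inf)


def _freq_rows(X: np.ndarray) -> np.ndarray:
    """Within-family frequency vectors (equal usage imputed when absent)."""
    F = np.zeros_like(X)
    for aa, cols in _FAMILY_COLS.items():
        tot = X[:, cols].sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            F[:, cols] = np.where(tot > 0, X[:, cols] / tot, 1.0 / len(cols))
    return F


def _kmeanspp_seeds(F: np.ndarray, S: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seed gene indices on frequency rows."""
    n = F.shape[0]
    seeds = [int(rng.integers(n))]
    for _ in range(1, S):
        d2 = np.min(
            [((F - F[s]) ** 2).sum(axis=1) for s in seeds], axis=0
        )
        if d2.sum() <= 0:
            seeds.append(int(rng.integers(n)))
        else:
            seeds.append(int(rng.choice(n, p=d2 / d2.sum())))
    return np.array(seeds)


def _em_once(
    X: np.ndarray,
    S: int,
    rng: np.random.Generator,
    pseudocount: float,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool, list[float]]:
    n = X.shape[0]
    F = _freq_rows(X)
    seeds = _kmeanspp_seeds(F, S, rng)
    theta = _normalize_theta(X[seeds] + pseudocount)
    w = np.full(S, 1.0 / S)
    deg_cols = np.concatenate(list(_FAMILY_COLS.values()))
    prev_obj = -np.inf
    trace: list[float] = []
    converged = False
    resp = np.full((n, S), 1.0 / S)
    ll = -np.inf
    for _ in range(max_iter):
        log_theta = _log_theta(theta)
        logpost = np.log(w)[None, :] + X @ log_theta.T
        norm = logsumexp(logpost, axis=1)
        ll = float(norm.sum())
        # the pseudocount makes the M-step a Dirichlet-MAP update, so the
        # EM ascent guarantee applies to the penalized objective
        obj = ll + pseudocount * float(log_theta[:, deg_cols].sum())
        assert obj >= prev_obj - 1e-7 * max(1.0, abs(prev_obj)), (
            "EM objective decreased"
        )
        trace.append(ll)
        resp = np.exp(logpost - norm[:, None])
        if abs(obj - prev_obj) < tol * max(1.0, abs(obj)):
            converged = True
            break
        prev_obj = obj
        # reseed clusters that lost all effective membership; this breaks
        # the ascent locally, so the monotonicity baseline is reset
        occupancy = resp.sum(axis=0)
        empty = np.flatnonzero(occupancy < 1e-8)
        if empty.size:
            for s in empty:
                worst = int(np.argmin(norm))
                resp[worst] = 0.0
                resp[worst, s] = 1.0
            occupancy = resp.sum(axis=0)
            prev_obj = -np.inf
        theta = _normalize_theta(resp.T @ X + pseudocount)
        w = occupancy / occupancy.sum()
    return theta, w, resp, ll, converged, trace


def fit_clusters(
    genes: Iterable[CodonCounts] | np.ndarray,
    S: int,
    seed: int,
    gene_ids: Sequence[str] | None = None,
    n_restarts: int = 10,
    pseudocount: float = 0.5,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> ClusterModel:
    """Fit an S-cluster multinomial mixture of synonymous codon usage.

    Deterministic given ``seed``; the best of ``n_restarts`` EM runs (by
    final log-likelihood) is kept, with hard maximum-posterior assignment.
    """
    if isinstance(genes, np.ndarray):
        X = genes
        ids = list(gene_ids) if gene_ids is not None else [str(i) for i in range(len(X))]
    else:
        X, ids = counts_matrix(genes)
    if S < 1 or X.shape[0] < S:
        raise ValueError("need at least S genes and S >= 1")
    rng = np.random.default_rng(seed)
    best = None
    restarts = 1 if S == 1 else n_restarts
    for _ in range(restarts):
        res = _em_once(X, S, rng, pseudocount, max_iter, tol)
        if best is None or res[3] > best[3]:
            best = res
    theta, w, resp, ll, converged, trace = best
    if not converged:
        warnings.warn(f"EM did not converge in {max_iter} iterations (S={S})")
    hard = resp.argmax(axis=1)
    bg = resp[np.arange(len(ids)), hard]
    return ClusterModel(
        S=S,
        theta=theta,
        weights=w,
        assignments=dict(zip(ids, hard.tolist())),
        selfcons=dict(zip(ids, bg.tolist())),
        log_likelihood=ll,
        converged=converged,
        ll_trace=trace,
    )


def self_consistency(
    model: ClusterModel, genes: Iterable[CodonCounts] | np.ndarray,
    gene_ids: Sequence[str] | None = None,
) -> tuple[np.ndarray, float]:
    """Recompute bg(s) per gene and B = geometric mean, under a model."""
    if isinstance(genes, np.ndarray):
        X = genes
        ids = list(gene_ids) if gene_ids is not None else [str(i) for i in range(len(X))]
    else:
        X, ids = counts_matrix(genes)
    logpost = np.log(model.weights)[None, :] + X @ _log_theta(model.theta).T
    resp = np.exp(logpost - logsumexp(logpost, axis=1)[:, None])
    hard = np.array([model.assignments[g] for g in ids])
    bg = resp[np.arange(len(ids)), hard]
    return bg, float(np.exp(np.mean(np.log(np.maximum(bg, 1e-300)))))


def pooled_family_frequencies(X: np.ndarray) -> np.ndarray:
    """Genome-pooled within-family codon frequencies (length 61)."""
    pooled = X.sum(axis=0, keepdims=True)
    return _normalize_theta(pooled + 1e-12)[0]


def resample_null_counts(
    X: np.ndarray, pooled: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Artificial counts: same per-gene family totals, codons drawn from the
    pooled genome-wide family frequencies (no cluster structure)."""
    Xnull = X.copy()
    for aa, cols in _FAMILY_COLS.items():
        tot = X[:, cols].sum(axis=1).astype(int)
        p = pooled[cols]
        Xnull[:, cols] = rng.multinomial(tot, p / p.sum())
    return Xnull


def simulate_from_model(
    X: np.ndarray, model: ClusterModel, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Artificial dataset drawn from a fitted model.

    Each gene keeps its amino-acid composition (per-family codon totals)
    and redraws codons from the usage distribution of its assigned
    cluster.  Returns the counts and the generating labels.
    """
    z = np.array(list(model.assignments.values()))
    Xa = X.copy()
    for cols in _FAMILY_COLS.values():
        tot = X[:, cols].sum(axis=1).astype(int)
        for s in range(model.S):
            sel = z == s
            p = model.theta[s, cols]
            Xa[np.ix_(sel, cols)] = rng.multinomial(tot[sel], p / p.sum())
    return Xa, z


def _match_labels(z_true: np.ndarray, z_fit: np.ndarray, S: int) -> np.ndarray:
    """Map fitted cluster labels onto generating labels (max overlap)."""
    from scipy.optimize import linear_sum_assignment

    overlap = np.zeros((S, S))
    for t, f in zip(z_true, z_fit):
        overlap[t, f] += 1
    rows, cols = linear_sum_assignment(-overlap)
    mapping = np.arange(S)
    mapping[cols] = rows
    return mapping


def _stability_once(
    X: np.ndarray,
    model: ClusterModel,
    rep_seed: int,
    n_restarts: int,
    subsample: float,
    **fit_kw,
) -> float:
    """One self-consistency replicate: re-cluster a random subsample of
    genes and take the geometric mean over all genes of the refit
    posterior of each gene's full-data cluster (after label matching)."""
    if model.S == 1:
        return 1.0
    rng = np.random.default_rng(rep_seed)
    n = X.shape[0]
    idx = np.sort(rng.choice(n, size=max(model.S, int(subsample * n)), replace=False))
    refit = fit_clusters(X[idx], model.S, seed=rep_seed, n_restarts=n_restarts, **fit_kw)
    z = np.array(list(model.assignments.values()))
    z_sub_fit = np.array(list(refit.assignments.values()))
    mapping = _match_labels(z[idx], z_sub_fit, model.S)
    logpost = np.log(refit.weights)[None, :] + X @ _log_theta(refit.theta).T
    resp = np.exp(logpost - logsumexp(logpost, axis=1)[:, None])
    # column j of the refit corresponds to full-data cluster mapping[j]
    inv = np.empty(model.S, dtype=int)
    inv[mapping] = np.arange(model.S)
    bg = resp[np.arange(n), inv[z]]
    return float(np.exp(np.mean(np.log(np.maximum(bg, 1e-12)))))


def stability_B(
    genes: Iterable[CodonCounts] | np.ndarray,
    S: int,
    n_reps: int = 10,
    seed: int = 0,
    n_restarts: int = 10,
    model: ClusterModel | None = None,
    subsample: float = 0.7,
    **fit_kw,
) -> tuple[float, float]:
    """Self-consistency B(S) of clustering a dataset into S groups.

    Fits the mixture, re-clusters random subsamples of the genes, and
    scores how confidently the subsample fits reproduce the full-data
    assignments.  Well-separated, identifiable structure gives B near 1;
    clusters that only fit sampling noise do not reappear in subsample
    refits and pull B toward 0.
    """
    X = genes if isinstance(genes, np.ndarray) else counts_matrix(genes)[0]
    if model is None:
        model = fit_clusters(X, S, seed=seed, n_restarts=n_restarts, **fit_kw)
    bs = []
    for r in range(n_reps):
        rep_seed = int(np.random.default_rng((seed, 511, r)).integers(2**31 - 1))
        bs.append(_stability_once(X, model, rep_seed, n_restarts, subsample, **fit_kw))
    bs = np.asarray(bs)
    se = float(bs.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else 0.0
    return float(bs.mean()), se


def null_B(
    genes: Iterable[CodonCounts] | np.ndarray,
    S: int,
    n_reps: int = 10,
    seed: int = 0,
    n_restarts: int = 10,
    **fit_kw,
) -> tuple[float, float]:
    """Mean and standard error of B(S) on structure-free artificial data.

    Each replicate rebuilds an artificial gene set matching the real
    genes' amino-acid compositions and lengths, with codons drawn from the
    pooled genome-wide family frequencies, and computes its
    self-consistency.  Replicate r uses a seed derived only from
    (seed, r), so scans over S share common random numbers, reducing the
    variance of Delta(S) comparisons.
    """
    X = genes if isinstance(genes, np.ndarray) else counts_matrix(genes)[0]
    pooled = pooled_family_frequencies(X)
    bs = []
    for r in range(n_reps):
        rep_seed = int(np.random.default_rng((seed, 9173, r)).integers(2**31 - 1))
        rng = np.random.default_rng(rep_seed)
        Xn = resample_null_counts(X, pooled, rng)
        b, _ = stability_B(
            Xn, S, n_reps=1, seed=rep_seed, n_restarts=n_restarts, **fit_kw
        )
        bs.append(b)
    bs = np.asarray(bs)
    se = float(bs.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else 0.0
    return float(bs.mean()), se


def select_S(
    genes: Iterable[CodonCounts] | np.ndarray,
    S_range: Sequence[int],
    seed: int = 0,
    n_reps: int = 10,
    n_restarts: int = 10,
    gene_ids: Sequence[str] | None = None,
    keep_models: bool = False,
    **fit_kw,
) -> ModelSelection:
    """Scan S, computing Delta(S) = B(S) - B_random(S); keep the argmax.

    An S qualifies only if its Delta exceeds twice the Monte-Carlo
    standard error of the B estimates (otherwise the apparent excess
    self-consistency is indistinguishable from noise); ties and flat
    profiles resolve toward the smaller S.
    """
    if isinstance(genes, np.ndarray):
        X = genes
        if gene_ids is None:
            gene_ids = [str(i) for i in range(len(X))]
    else:
        X, ids = counts_matrix(genes)
        gene_ids = gene_ids or ids
    rows = []
    models: dict[int, ClusterModel] = {}
    for S in S_range:
        m = fit_clusters(X, S, seed=seed, gene_ids=gene_ids, n_restarts=n_restarts, **fit_kw)
        b, b_se = stability_B(
            X, S, n_reps=n_reps, seed=seed, n_restarts=n_restarts, model=m, **fit_kw
        )
        b_rand, se = null_B(X, S, n_reps=n_reps, seed=seed, n_restarts=n_restarts, **fit_kw)
        rows.append(
            {
                "S": S,
                "B": b,
                "B_se": b_se,
                "B_random": b_rand,
                "B_random_se": se,
                "Delta": b - b_rand,
            }
        )
        if keep_models:
            models[S] = m
    df = pd.DataFrame(rows)
    # only S whose Delta clears its own Monte-Carlo noise count as showing
    # structure; a flat Delta profile falls back to the smallest scanned S
    se = np.sqrt(df["B_se"] ** 2 + df["B_random_se"] ** 2)
    qualified = df[df["Delta"] > 2.0 * se]
    if qualified.empty:
        chosen = int(df["S"].min())
    else:
        best = qualified.sort_values(["Delta", "S"], ascending=[False, True]).iloc[0]
        chosen = int(best["S"])
    return ModelSelection(records=df, chosen_S=chosen, models=models)


def centered_heatmap_matrix(model: ClusterModel) -> pd.DataFrame:
    """(59 degenerate codons x S) matrix of degeneracy-centered usage."""
    rows = {}
    for codon in DEGENERATE_CODONS:
        d = DEGENERACY[CODON_TO_AA[codon]]
        j = _CODON_INDEX[codon]
        rows[codon] = [centered_usage(model.theta[s, j], d) for s in range(model.S)]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"CUG{s}" for s in range(model.S)]
    )


def heatmap_order(mat: pd.DataFrame) -> pd.DataFrame:
    """Order rows/columns by complete-linkage hierarchy on Euclidean distance."""
    from scipy.cluster.hierarchy import complete, leaves_list
    from scipy.spatial.distance import pdist

    def order(frame: pd.DataFrame) -> list[int]:
        if frame.shape[0] < 3:
            return list(range(frame.shape[0]))
        return leaves_list(complete(pdist(frame.to_numpy()))).tolist()

    mat = mat.iloc[order(mat)]
    return mat.iloc[:, order(mat.T)]
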