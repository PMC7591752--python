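"""Expression-based miRNA-target scoring, ranking and validation.

Twelve scorers are provided, grouped the way the field groups them:

* correlation family — ``pearson``, ``spearman``, ``kendall``, distance
  correlation ``dcor``, Hoeffding's D ``hoeffding``, the randomized
  dependence coefficient ``rdc`` and plug-in mutual information ``mi``;
* penalised regression — ``lasso`` and ``elasticnet`` (one regression per
  target gene, all miRNAs as predictors, coefficient magnitude at the
  cross-validated penalty);
* causal inference — ``ida`` (PC-stable skeleton, Fisher-z tests, minimum
  absolute intervention effect over locally valid parent sets);
* knockdown emulation ``zscore`` and the probabilistic two-view
  competition model ``promise``.

All scorers emit a miRNA x target :class:`ScoreMatrix`; canonical scores
are ``|statistic|`` for the signed correlation family so that "higher is
stronger" holds uniformly.  Per-miRNA top-K rankings are compared against
an experimentally validated ground-truth interaction set: the method
predicting the most validated pairs wins.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet, ElasticNetCV, Lasso, LassoCV
from sklearn.model_selection import KFold

from .io_core import (ExpressionMatrix, InteractionSet, PipelineConfig,
                      SpongenetError, logger)

CORRELATION_METHODS = ("pearson", "spearman", "kendall", "dcor", "hoeffding",
                       "rdc", "mi")
SIGNED_METHODS = ("pearson", "spearman", "kendall")
REGRESSION_METHODS = ("lasso", "elasticnet")
ALL_METHODS = CORRELATION_METHODS + REGRESSION_METHODS + ("ida", "zscore",
                                                          "promise")


@dataclass
class ScoreMatrix:
    method_name: str
    mirna_ids: list[str]
    target_ids: list[str]
    statistics: np.ndarray          # raw statistic, miRNA x target
    flagged: np.ndarray             # degenerate pairs (constant gene etc.)
    signed: bool                    # statistic carries a sign

    def __post_init__(self) -> None:
        self.statistics = np.asarray(self.statistics, dtype=float)
        if self.statistics.shape != (len(self.mirna_ids), len(self.target_ids)):
            raise SpongenetError("score matrix shape mismatch")
        if np.isnan(self.statistics).any():
            raise SpongenetError("NaN scores must be flagged and zeroed")

    def canonical(self, rank_signed: bool = False) -> np.ndarray:
        """Scores on a higher-is-stronger scale.

        Signed statistics are ranked by magnitude by default; with
        ``rank_signed`` the most-negative-first convention is used
        (miRNAs repress their targets).
        """
        if not self.signed:
            return self.statistics
        return -self.statistics if rank_signed else np.abs(self.statistics)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.statistics, index=self.mirna_ids,
                            columns=self.target_ids)


@dataclass
class RankedTargets:
    mirna_id: str
    target_ids: list[str]
    k: int


@dataclass
class ValidationReport:
    method_name: str
    k: int
    n_predicted: int
    n_validated: int
    per_class: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_validated > self.n_predicted:
            raise SpongenetError("validated count exceeds predicted count")


# ---------------------------------------------------------------------------
# correlation family
# ---------------------------------------------------------------------------

def _standardize_rows(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row z-scores and a constant-row mask (constant rows become 0)."""
    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, keepdims=True)
    const = sd[:, 0] == 0
    sd[const] = 1.0
    Z = (M - mu) / sd
    Z[const] = 0.0
    return Z, const


def _pearson_matrix(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Zx, cx = _standardize_rows(X)
    Zy, cy = _standardize_rows(Y)
    n = X.shape[1]
    r = Zx @ Zy.T / n
    np.clip(r, -1.0, 1.0, out=r)
    flag = cx[:, None] | cy[None, :]
    r[flag] = 0.0
    return r, flag


def _rank_rows(M: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, M)


def _kendall_matrix(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised tau-b via sample-pair sign products."""
    n = X.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    Sx = np.sign(X[:, iu] - X[:, ju])
    Sy = np.sign(Y[:, iu] - Y[:, ju])
    num = Sx @ Sy.T
    nx = (Sx != 0).sum(axis=1).astype(float)   # untied pairs per miRNA
    ny = (Sy != 0).sum(axis=1).astype(float)
    denom = np.sqrt(np.outer(nx, ny))
    flag = (nx == 0)[:, None] | (ny == 0)[None, :]
    denom[flag] = 1.0
    tau = num / denom
    tau[flag] = 0.0
    np.clip(tau, -1.0, 1.0, out=tau)
    return tau, flag


def _centered_distance_rows(M: np.ndarray) -> np.ndarray:
    """Double-centred pairwise-distance matrices, one per row, flattened."""
    p, n = M.shape
    out = np.empty((p, n * n))
    for i in range(p):
        d = np.abs(M[i][:, None] - M[i][None, :])
        d = d - d.mean(axis=0, keepdims=True) - d.mean(axis=1, keepdims=True) + d.mean()
        out[i] = d.ravel()
    return out


def _dcor_matrix(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = X.shape[1]
    Ax = _centered_distance_rows(X)
    Ay = _centered_distance_rows(Y)
    n2 = float(n * n)
    cross = Ax @ Ay.T / n2                   # dCov^2
    vx = (Ax * Ax).sum(axis=1) / n2
    vy = (Ay * Ay).sum(axis=1) / n2
    denom = np.sqrt(np.outer(vx, vy))
    flag = (vx == 0)[:, None] | (vy == 0)[None, :]
    denom[flag] = 1.0
    r2 = np.clip(cross / denom, 0.0, None)
    r = np.sqrt(np.clip(r2, 0.0, 1.0))
    r[flag] = 0.0
    return r, flag


def _hoeffding_prep(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Midranks and the fractional 'less-than' indicator per row."""
    p, n = M.shape
    less = np.empty((p, n, n))
    for i in range(p):
        x = M[i]
        L = (x[None, :] < x[:, None]).astype(float)
        E = (x[None, :] == x[:, None]).astype(float)
        np.fill_diagonal(E, 0.0)
        less[i] = L + 0.5 * E
    R = 1.0 + less.sum(axis=2)
    return R, less


def hoeffding_d(x: np.ndarray, y: np.ndarray) -> float:
    """Hoeffding's D for one pair (rank formula with midrank ties)."""
    n = len(x)
    if n < 5:
        raise SpongenetError("Hoeffding's D requires n >= 5")
    Rx, Lx = _hoeffding_prep(x[None, :])
    Ry, Ly = _hoeffding_prep(y[None, :])
    return float(_hoeffding_from_prep(Rx, Lx, Ry, Ly)[0][0, 0])


def _hoeffding_from_prep(Rx, Lx, Ry, Ly) -> tuple[np.ndarray, np.ndarray]:
    p, n, _ = Lx.shape
    q = Ly.shape[0]
    D = np.empty((p, q))
    for i in range(p):
        for j in range(q):
            Q = (Lx[i] * Ly[j]).sum(axis=1)
            R, S = Rx[i], Ry[j]
            d1 = np.sum(Q * (Q - 1.0))
            d2 = np.sum((R - 1) * (R - 2) * (S - 1) * (S - 2))
            d3 = np.sum((R - 2) * (S - 2) * Q)
            D[i, j] = 30.0 * ((n - 2) * (n - 3) * d1 + d2 - 2 * (n - 2) * d3) / (
                n * (n - 1) * (n - 2) * (n - 3) * (n - 4))
    return D, np.zeros((p, q), dtype=bool)


def _hoeffding_matrix(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if X.shape[1] < 5:
        raise SpongenetError("Hoeffding's D requires at least 5 samples")
    _, cx = _standardize_rows(X)
    _, cy = _standardize_rows(Y)
    Rx, Lx = _hoeffding_prep(X)
    Ry, Ly = _hoeffding_prep(Y)
    D, _ = _hoeffding_from_prep(Rx, Lx, Ry, Ly)
    flag = cx[:, None] | cy[None, :]
    D[flag] = 0.0
    return D, flag


def _rdc_features(v: np.ndarray, k: int, scale: float,
                  rng: np.random.Generator) -> np.ndarray:
    n = len(v)
    u = np.column_stack([stats.rankdata(v) / n, np.ones(n)])
    w = rng.normal(0.0, scale, size=(2, k))
    return np.sin(u @ w)


def _max_canonical_correlation(Fx: np.ndarray, Fy: np.ndarray,
                               ridge: float = 1e-8) -> float:
    Fx = Fx - Fx.mean(axis=0)
    Fy = Fy - Fy.mean(axis=0)
    n = Fx.shape[0]
    Cxx = Fx.T @ Fx / n + ridge * np.eye(Fx.shape[1])
    Cyy = Fy.T @ Fy / n + ridge * np.eye(Fy.shape[1])
    Cxy = Fx.T @ Fy / n
    A = np.linalg.solve(Cxx, Cxy) @ np.linalg.solve(Cyy, Cxy.T)
    ev = np.linalg.eigvals(A)
    rho2 = float(np.max(ev.real)) if ev.size else 0.0
    return float(np.sqrt(np.clip(rho2, 0.0, 1.0)))


def rdc(x: np.ndarray, y: np.ndarray, k: int = 20, scale: float = 1.0 / 6.0,
        seed: int = 0) -> float:
    """Randomized dependence coefficient for one pair (seeded features)."""
    rng = np.random.default_rng(seed)
    return _max_canonical_correlation(_rdc_features(x, k, scale, rng),
                                      _rdc_features(y, k, scale, rng))


def _rdc_matrix(X: np.ndarray, Y: np.ndarray, k: int, scale: float,
                seed: int) -> tuple[np.ndarray, np.ndarray]:
    _, cx = _standardize_rows(X)
    _, cy = _standardize_rows(Y)
    # one feature draw per variable, derived deterministically from the seed
    fx = [_rdc_features(X[i], k, scale, np.random.default_rng((seed, 0, i)))
          for i in range(X.shape[0])]
    fy = [_rdc_features(Y[j], k, scale, np.random.default_rng((seed, 1, j)))
          for j in range(Y.shape[0])]
    out = np.zeros((X.shape[0], Y.shape[0]))
    for i in range(X.shape[0]):
        if cx[i]:
            continue
        for j in range(Y.shape[0]):
            if cy[j]:
                continue
            out[i, j] = _max_canonical_correlation(fx[i], fy[j])
    return out, cx[:, None] | cy[None, :]


def _equal_frequency_bins(v: np.ndarray, n_bins: int) -> np.ndarray:
    n = len(v)
    order = stats.rankdata(v, method="ordinal") - 1
    return np.minimum((order * n_bins) // n, n_bins - 1).astype(int)


def mutual_information(x: np.ndarray, y: np.ndarray,
                       n_bins: int | None = None) -> float:
    """Plug-in MI (nats) on equal-frequency bins, B = max(2, floor(sqrt(n/5)))."""
    n = len(x)
    if n_bins is None:
        n_bins = max(2, int(np.floor(np.sqrt(n / 5.0))))
    bx = _equal_frequency_bins(x, n_bins)
    by = _equal_frequency_bins(y, n_bins)
    joint = np.zeros((n_bins, n_bins))
    np.add.at(joint, (bx, by), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = joint * np.log(joint / (px * py))
    return float(np.nansum(term))


def _mi_matrix(X: np.ndarray, Y: np.ndarray,
               n_bins: int | None) -> tuple[np.ndarray, np.ndarray]:
    _, cx = _standardize_rows(X)
    _, cy = _standardize_rows(Y)
    out = np.zeros((X.shape[0], Y.shape[0]))
    for i in range(X.shape[0]):
        if cx[i]:
            continue
        for j in range(Y.shape[0]):
            if cy[j]:
                continue
            out[i, j] = mutual_information(X[i], Y[j], n_bins)
    return out, cx[:, None] | cy[None, :]


def score_correlation(method: str, X: ExpressionMatrix, Y: ExpressionMatrix,
                      config: PipelineConfig | None = None) -> ScoreMatrix:
    """Score all miRNA-target pairs with one correlation-family method."""
    if method not in CORRELATION_METHODS:
        raise SpongenetError(f"unknown correlation method {method!r}")
    config = config or PipelineConfig()
    if X.sample_ids != Y.sample_ids:
        raise SpongenetError("X and Y must share an identical sample ordering")
    Mx, My = X.values, Y.values
    n = Mx.shape[1]
    if n < 5:
        raise SpongenetError(f"{method} requires at least 5 matched samples")
    if method == "pearson":
        S, flag = _pearson_matrix(Mx, My)
    elif method == "spearman":
        S, flag = _pearson_matrix(_rank_rows(Mx), _rank_rows(My))
    elif method == "kendall":
        S, flag = _kendall_matrix(Mx, My)
    elif method == "dcor":
        S, flag = _dcor_matrix(Mx, My)
    elif method == "hoeffding":
        S, flag = _hoeffding_matrix(Mx, My)
    elif method == "rdc":
        S, flag = _rdc_matrix(Mx, My, config.rdc_features, config.rdc_scale,
                              config.rng_seed)
    else:
        S, flag = _mi_matrix(Mx, My, config.mi_bins)
    return ScoreMatrix(method, X.gene_ids, Y.gene_ids, S, flag,
                       signed=method in SIGNED_METHODS)


# ---------------------------------------------------------------------------
# penalised regression
# ---------------------------------------------------------------------------

def score_regression(method: str, X: ExpressionMatrix, Y: ExpressionMatrix,
                     config: PipelineConfig | None = None,
                     penalty: float | None = None) -> ScoreMatrix:
    """|coefficient| of each miRNA in one penalised regression per target.

    Predictors (miRNAs) are z-scored; the penalty is chosen by K-fold
    cross-validation at minimum CV error unless ``penalty`` pins it
    (``penalty=0`` falls back to ordinary least squares).
    """
    if method not in REGRESSION_METHODS:
        raise SpongenetError(f"unknown regression method {method!r}")
    config = config or PipelineConfig()
    if X.sample_ids != Y.sample_ids:
        raise SpongenetError("X and Y must share an identical sample ordering")
    Mx, const_x = _standardize_rows(X.values)
    My = Y.values
    n = Mx.shape[1]
    folds = config.cv_folds
    if n < folds:
        logger.warning("reducing CV folds from %d to %d (n=%d)", folds, n, n)
        folds = max(2, n)
    l1_ratio = 1.0 if method == "lasso" else config.enet_l1_ratio
    P = Mx.T                                   # samples x miRNAs
    scores = np.zeros((X.values.shape[0], My.shape[0]))
    flags = np.zeros_like(scores, dtype=bool)
    flags[const_x, :] = True
    for j in range(My.shape[0]):
        y = My[j]
        if y.std() == 0:
            flags[:, j] = True
            continue
        if penalty is not None:
            if penalty == 0:
                A = np.column_stack([P, np.ones(n)])
                coef = np.linalg.lstsq(A, y, rcond=None)[0][:-1]
            else:
                est = (Lasso(alpha=penalty) if method == "lasso"
                       else ElasticNet(alpha=penalty, l1_ratio=l1_ratio))
                coef = est.fit(P, y).coef_
        else:
            cv = KFold(n_splits=folds, shuffle=True,
                       random_state=config.rng_seed)
            est = (LassoCV(cv=cv, random_state=config.rng_seed, max_iter=5000)
                   if method == "lasso"
                   else ElasticNetCV(l1_ratio=l1_ratio, cv=cv,
                                     random_state=config.rng_seed,
                                     max_iter=5000))
            coef = est.fit(P, y).coef_
        scores[:, j] = np.abs(coef)
    scores[const_x, :] = 0.0
    return ScoreMatrix(method, X.gene_ids, Y.gene_ids, scores, flags,
                       signed=False)


# ---------------------------------------------------------------------------
# zscore and ProMISe
# ---------------------------------------------------------------------------

def score_zscore(X: ExpressionMatrix, Y: ExpressionMatrix) -> ScoreMatrix:
    """Knockdown-emulation z-score.

    For miRNA i the 'knockdown' sample k* is the one where the miRNA is
    lowest (ties -> smallest sample index); the score against target j is
    |y_j(k*) - mean(y_j)| / sd(y_j) with the n-1 sample standard deviation.
    """
    if X.sample_ids != Y.sample_ids:
        raise SpongenetError("X and Y must share an identical sample ordering")
    Mx, My = X.values, Y.values
    kstar = np.argmin(Mx, axis=1)              # argmin takes the first minimum
    mu = My.mean(axis=1)
    sd = My.std(axis=1, ddof=1)
    const = sd == 0
    sd_safe = np.where(const, 1.0, sd)
    dev = np.abs(My[:, kstar].T - mu[None, :]) / sd_safe[None, :]
    dev[:, const] = 0.0
    flags = np.zeros_like(dev, dtype=bool)
    flags[:, const] = True
    return ScoreMatrix("zscore", X.gene_ids, Y.gene_ids, dev, flags,
                       signed=False)


def score_promise(X: ExpressionMatrix, Y: ExpressionMatrix,
                  candidate_mask: InteractionSet | None = None,
                  tol: float = 1e-6, max_iter: int = 200
                  ) -> tuple[ScoreMatrix, bool]:
    """Two-view probabilistic competition model.

    View A lets targets compete for each miRNA (allocation proportional to
    target abundance times the current B, normalised over targets); view B
    lets miRNAs compete for each target (proportional to miRNA abundance
    times A, normalised over miRNAs).  B starts uniform on the admissible
    mask and the two views are alternated to a fixed point; the score of a
    pair is the elementwise product A*B.  Returns (scores, converged).
    """
    if X.sample_ids != Y.sample_ids:
        raise SpongenetError("X and Y must share an identical sample ordering")
    p, q = len(X.gene_ids), len(Y.gene_ids)
    z = X.values.mean(axis=1)
    x = Y.values.mean(axis=1)
    lo = min(z.min(), x.min())
    if lo <= 0:
        shift = -lo + 1e-6 * (max(z.max(), x.max()) - lo + 1.0)
        z = z + shift
        x = x + shift
    if candidate_mask is None:
        M = np.ones((q, p))
    else:
        idx_m = {m: i for i, m in enumerate(X.gene_ids)}
        idx_t = {t: j for j, t in enumerate(Y.gene_ids)}
        M = np.zeros((q, p))
        for m, t, _ in candidate_mask.pairs:
            if m in idx_m and t in idx_t:
                M[idx_t[t], idx_m[m]] = 1.0
    row = M.sum(axis=1, keepdims=True)
    B = np.divide(M, row, out=np.zeros_like(M), where=row > 0)
    A = np.zeros_like(B)
    converged = False
    for _ in range(max_iter):
        W = x[:, None] * B * M
        col = W.sum(axis=0, keepdims=True)
        A_new = np.divide(W, col, out=np.zeros_like(W), where=col > 0)
        V = z[None, :] * A_new * M
        row = V.sum(axis=1, keepdims=True)
        B_new = np.divide(V, row, out=np.zeros_like(V), where=row > 0)
        delta = max(np.abs(A_new - A).max(), np.abs(B_new - B).max())
        A, B = A_new, B_new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("promise: fixed point not reached in %d iterations",
                       max_iter)
    scores = (A * B).T                          # miRNA x target
    flags = (M.T == 0)
    sm = ScoreMatrix("promise", X.gene_ids, Y.gene_ids, scores, flags,
                     signed=False)
    return sm, converged


# ---------------------------------------------------------------------------
# IDA (PC skeleton + local intervention-effect bounds)
# ---------------------------------------------------------------------------

def _fisher_z_partial(R: np.ndarray, i: int, j: int, S: tuple[int, ...],
                      n: int) -> float:
    """p-value of the Fisher-z conditional-independence test."""
    if not S:
        r = R[i, j]
    else:
        idx = [i, j, *S]
        sub = R[np.ix_(idx, idx)]
        prec = np.linalg.pinv(sub)
        denom = np.sqrt(prec[0, 0] * prec[1, 1])
        r = -prec[0, 1] / denom if denom > 0 else 0.0
    r = float(np.clip(r, -0.999999, 0.999999))
    df = n - len(S) - 3
    if df <= 0:
        return 1.0
    z = 0.5 * np.log((1 + r) / (1 - r))
    return float(2.0 * stats.norm.sf(np.sqrt(df) * abs(z)))


def _pc_skeleton(R: np.ndarray, n: int, alpha: float, max_cond: int
                 ) -> tuple[set[frozenset[int]], dict[frozenset[int], tuple[int, ...]]]:
    """Stable PC skeleton with separation sets."""
    p = R.shape[0]
    edges = {frozenset((i, j)) for i in range(p) for j in range(i + 1, p)
             if _fisher_z_partial(R, i, j, (), n) < alpha}
    sepsets: dict[frozenset[int], tuple[int, ...]] = {
        frozenset((i, j)): () for i in range(p) for j in range(i + 1, p)
        if frozenset((i, j)) not in edges}
    for level in range(1, max_cond + 1):
        adj = {v: {u for u in range(p) if frozenset((u, v)) in edges}
               for v in range(p)}
        removed = []
        for e in sorted(edges, key=sorted):
            i, j = sorted(e)
            done = False
            for x, y in ((i, j), (j, i)):
                cands = sorted(adj[x] - {y})
                if len(cands) < level:
                    continue
                for S in itertools.combinations(cands, level):
                    if _fisher_z_partial(R, x, y, S, n) >= alpha:
                        removed.append(e)
                        sepsets[e] = S
                        done = True
                        break
                if done:
                    break
        for e in removed:
            edges.discard(e)
        if all(len(a) <= level for a in adj.values()):
            break
    return edges, sepsets


def _orient_cpdag(p: int, edges: set[frozenset[int]],
                  sepsets: dict[frozenset[int], tuple[int, ...]],
                  upstream: set[int]) -> np.ndarray:
    """CPDAG adjacency: G[i,j]=1 means i-j has an arrowhead at j.

    Undirected edges carry 1 in both directions.  ``upstream`` nodes
    (miRNAs) may not receive arrows from non-upstream nodes: the
    biological prior that targets do not regulate miRNAs.
    """
    G = np.zeros((p, p), dtype=bool)
    for e in edges:
        i, j = sorted(e)
        G[i, j] = G[j, i] = True
    # v-structures i -> k <- j for non-adjacent (i, j), k not in sepset
    for i in range(p):
        for j in range(i + 1, p):
            if G[i, j] or frozenset((i, j)) not in sepsets:
                continue
            for k in range(p):
                if k in (i, j) or not (G[i, k] and G[j, k]):
                    continue
                if k not in sepsets[frozenset((i, j))]:
                    G[k, i] = False if G[i, k] else G[k, i]
                    G[k, j] = False if G[j, k] else G[k, j]
    # background knowledge: orient every miRNA-target edge miRNA -> target
    for i in range(p):
        for j in range(p):
            if G[i, j] and G[j, i] and i in upstream and j not in upstream:
                G[j, i] = False
    changed = True
    while changed:                              # Meek rules 1-3
        changed = False
        for a in range(p):
            for b in range(p):
                if not (G[a, b] and G[b, a]):
                    continue
                # R1: c -> a - b with c, b non-adjacent  =>  a -> b
                for c in range(p):
                    if G[c, a] and not G[a, c] and not (G[c, b] or G[b, c]):
                        G[b, a] = False
                        changed = True
                        break
                if not G[b, a]:
                    continue
                # R2: a -> c -> b and a - b  =>  a -> b
                for c in range(p):
                    if G[a, c] and not G[c, a] and G[c, b] and not G[b, c]:
                        G[b, a] = False
                        changed = True
                        break
                if not G[b, a]:
                    continue
                # R3: a - c1 -> b, a - c2 -> b, c1, c2 non-adjacent => a -> b
                cs = [c for c in range(p)
                      if G[a, c] and G[c, a] and G[c, b] and not G[b, c]]
                if any(not (G[c1, c2] or G[c2, c1])
                       for c1, c2 in itertools.combinations(cs, 2)):
                    G[b, a] = False
                    changed = True
    return G


def _ida_effects(data: np.ndarray, G: np.ndarray, mirna_idx: list[int],
                 target_idx: list[int], sibling_cap: int = 10) -> np.ndarray:
    """Minimum |causal effect| over locally valid parent sets."""
    p = G.shape[0]
    adj = G | G.T
    out = np.zeros((len(mirna_idx), len(target_idx)))
    Xc = data - data.mean(axis=0)
    for a, m in enumerate(mirna_idx):
        parents = [v for v in range(p) if G[v, m] and not G[m, v]]
        sibs = [v for v in range(p) if G[v, m] and G[m, v]]
        if len(sibs) > sibling_cap:
            logger.warning("ida: capping %d siblings at %d", len(sibs),
                           sibling_cap)
            corr = [abs(np.corrcoef(data[:, m], data[:, s])[0, 1]) for s in sibs]
            sibs = [s for _, s in sorted(zip(corr, sibs), reverse=True)[:sibling_cap]]
        valid_sets = []
        for r in range(len(sibs) + 1):
            for S in itertools.combinations(sibs, r):
                ok = all(adj[s, t] for s in S for t in set(S) | set(parents)
                         if s != t)
                if ok:
                    valid_sets.append(list(S) + parents)
        for b, t in enumerate(target_idx):
            if not adj[m, t]:
                continue
            effects = []
            for cond in valid_sets:
                cols = [m] + [c for c in cond if c != t]
                A = Xc[:, cols]
                beta = np.linalg.lstsq(A, Xc[:, t], rcond=None)[0]
                effects.append(abs(beta[0]))
            out[a, b] = min(effects) if effects else 0.0
    return out


def score_ida(X: ExpressionMatrix, Y: ExpressionMatrix,
              alpha: float = 0.05,
              config: PipelineConfig | None = None) -> ScoreMatrix:
    """Lower-bound causal effects of miRNAs on targets.

    PC-stable skeleton over the joint (miRNA + target) data with Fisher-z
    tests at ``alpha``, v-structure and Meek orientation plus the prior
    that miRNAs are upstream; the score is the minimum absolute regression
    effect over locally valid parent sets.  Target sets larger than the
    variable budget are processed in chunks against all miRNAs.
    """
    config = config or PipelineConfig()
    if X.sample_ids != Y.sample_ids:
        raise SpongenetError("X and Y must share an identical sample ordering")
    p, q = len(X.gene_ids), len(Y.gene_ids)
    n = X.n_samples
    budget = max(config.ida_var_budget, p + 1)
    chunk_size = max(1, budget - p)
    scores = np.zeros((p, q))
    _, cx = _standardize_rows(X.values)
    _, cy = _standardize_rows(Y.values)
    if q + p > budget:
        logger.warning("ida: %d variables exceed budget %d; chunking targets",
                       q + p, budget)
    for start in range(0, q, chunk_size):
        t_idx = list(range(start, min(start + chunk_size, q)))
        data = np.vstack([X.values, Y.values[t_idx]]).T    # samples x vars
        keep = data.std(axis=0) > 0
        data_s = (data - data.mean(axis=0)) / np.where(keep, data.std(axis=0), 1.0)
        R = np.corrcoef(data_s.T)
        R[~keep, :] = 0.0
        R[:, ~keep] = 0.0
        np.fill_diagonal(R, 1.0)
        nv = data.shape[1]
        edges, sepsets = _pc_skeleton(R, n, alpha, config.ida_max_cond)
        G = _orient_cpdag(nv, edges, sepsets, upstream=set(range(p)))
        eff = _ida_effects(data, G, list(range(p)),
                           [p + i for i in range(len(t_idx))])
        scores[:, t_idx] = eff
    flags = cx[:, None] | cy[None, :]
    scores[flags] = 0.0
    return ScoreMatrix("ida", X.gene_ids, Y.gene_ids, scores, flags,
                      signed=False)


# ---------------------------------------------------------------------------
# ranking, validation, network assembly
# ---------------------------------------------------------------------------

def rank_targets(scores: ScoreMatrix, k: int,
                 rank_signed: bool = False) -> list[RankedTargets]:
    """Per-miRNA top-K targets by canonical score, ties broken by id.

    Flagged or zero-score pairs carry no evidence and are dropped, so a
    ranking may be shorter than K.
    """
    q = len(scores.target_ids)
    if k > q:
        logger.warning("K=%d exceeds target universe (%d); clamping", k, q)
        k = q
    canon = scores.canonical(rank_signed)
    out = []
    for i, m in enumerate(scores.mirna_ids):
        usable = [(-canon[i, j], scores.target_ids[j])
                  for j in range(q)
                  if not scores.flagged[i, j] and canon[i, j] > 0]
        usable.sort()
        out.append(RankedTargets(m, [t for _, t in usable[:k]], k))
    return out


def rank_and_validate(scores_by_class: dict[str, ScoreMatrix],
                      truth: InteractionSet, k: int,
                      rank_signed: bool = False) -> ValidationReport:
    """Count ground-truth hits among the per-miRNA top-K predictions.

    lncRNA and mRNA targets are ranked as separate universes and the
    per-class counts are reported alongside the total.
    """
    method = next(iter(scores_by_class.values())).method_name
    n_pred = n_val = 0
    per_class = {}
    truth_pairs = truth.pairs_no_class()
    for cls, sm in sorted(scores_by_class.items()):
        cls_pred = cls_val = 0
        for rt in rank_targets(sm, k, rank_signed):
            cls_pred += len(rt.target_ids)
            cls_val += sum((rt.mirna_id, t) in truth_pairs for t in rt.target_ids)
        per_class[cls] = (cls_pred, cls_val)
        n_pred += cls_pred
        n_val += cls_val
    return ValidationReport(method, k, n_pred, n_val, per_class)


def build_target_network(scores_by_class: dict[str, ScoreMatrix], k: int,
                         rank_signed: bool = False) -> InteractionSet:
    """Union over miRNAs of top-K pairs per target class (the merged
    predicted miRNA-target regulatory network)."""
    pairs = set()
    for cls, sm in scores_by_class.items():
        for rt in rank_targets(sm, k, rank_signed):
            pairs.update((rt.mirna_id, t, cls) for t in rt.target_ids)
    return InteractionSet(pairs, provenance="predicted")


def validation_table(reports: list[ValidationReport]) -> pd.DataFrame:
    rows = [{"method": r.method_name, "K": r.k, "n_predicted": r.n_predicted,
             "n_validated": r.n_validated,
             **{f"{cls}_validated": v for cls, (_, v) in r.per_class.items()}}
            for r in reports]
    return pd.DataFrame(rows).sort_values(["method", "K"]).reset_index(drop=True)


def best_method(reports: list[ValidationReport]) -> str:
    """Method with the largest summed validated count over the K list;
    ties go to the method predicting fewer pairs, then name order."""
    agg: dict[str, list[int]] = {}
    for r in reports:
        a = agg.setdefault(r.method_name, [0, 0])
        a[0] += r.n_validated
        a[1] += r.n_predicted
    ranked = sorted(agg.items(), key=lambda kv: (-kv[1][0], kv[1][1], kv[0]))
    return ranked[0][0]
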