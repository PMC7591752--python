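"""Two-group differential expression with an empirical-Bayes moderated t.

Per-gene pooled two-sample variances are shrunk toward a common prior
value ``s0^2`` with prior degrees of freedom ``d0`` estimated by moment
matching on the log sample variances (the standard scaled-inverse-chi^2
hierarchical model behind moderated t statistics).  When the observed
spread of log variances does not exceed what sampling alone explains,
moment estimation has no positive solution and the ordinary pooled
two-sample t is used instead.

P-values are two-sided from a t distribution with ``d0 + dg`` degrees of
freedom and are Benjamini–Hochberg adjusted within each gene class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io_core import ExpressionMatrix, SpongenetError


@dataclass
class DifferentialResult:
    gene_id: str
    log_fc: float          # mean(case) - mean(control) on the input scale
    t_stat: float
    p_value: float
    adj_p_value: float
    rank: int              # 1-based by (adj_p, |log_fc| desc, id)
    zero_variance: bool = False


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) on log sample variances.

    Returns ``(d0, s0_squared)``; ``d0 = 0`` signals that estimation
    failed (no excess variability: fall back to the ordinary t).
    Genes with zero sample variance are ignored during estimation.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return 0.0, float(np.mean(s2[ok])) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = np.var(e, ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        return 0.0, float(np.exp(np.mean(e)))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_sq


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (delegates to statsmodels)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def moderated_t(expr: ExpressionMatrix) -> list[DifferentialResult]:
    """Moderated two-sample t for every gene, case vs control."""
    case = expr.samples_in_group("case")
    control = expr.samples_in_group("control")
    n1, n2 = len(case), len(control)
    if n1 < 2 or n2 < 2:
        raise SpongenetError(
            f"need >= 2 samples per group, got case={n1}, control={n2}")
    X1 = expr.data[case].to_numpy(dtype=float)
    X2 = expr.data[control].to_numpy(dtype=float)
    m1, m2 = X1.mean(axis=1), X2.mean(axis=1)
    log_fc = m1 - m2
    ss1 = ((X1 - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((X2 - m2[:, None]) ** 2).sum(axis=1)
    dg = n1 + n2 - 2
    s2 = (ss1 + ss2) / dg
    zero_var = s2 == 0

    d0, s0_sq = estimate_variance_prior(s2, dg)
    if d0 > 0 and np.isfinite(d0):
        s2_tilde = (d0 * s0_sq + dg * s2) / (d0 + dg)
        df_total = d0 + dg
    else:
        # ordinary pooled t; zero-variance genes still get a shrunken
        # denominator (the mean variance) rather than a division by zero
        s2_tilde = s2.copy()
        if zero_var.any():
            fill = s0_sq if s0_sq > 0 else float(np.mean(s2[~zero_var])) if (~zero_var).any() else 1.0
            s2_tilde[zero_var] = fill
        df_total = float(dg)
    if np.any(s2_tilde <= 0):  # all genes constant
        s2_tilde = np.where(s2_tilde <= 0, 1.0, s2_tilde)
    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    t = log_fc / se
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    adj = benjamini_hochberg(p)

    order = sorted(range(len(t)),
                   key=lambda i: (adj[i], -abs(log_fc[i]), expr.gene_ids[i]))
    rank = np.empty(len(t), dtype=int)
    for r, i in enumerate(order, start=1):
        rank[i] = r
    return [
        DifferentialResult(expr.gene_ids[i], float(log_fc[i]), float(t[i]),
                           float(p[i]), float(adj[i]), int(rank[i]),
                           bool(zero_var[i]))
        for i in range(len(t))
    ]


def select_top(results: list[DifferentialResult], n: int) -> list[str]:
    """Top-n gene ids by (adj_p asc, |log_fc| desc, id asc)."""
    if n > len(results):
        raise SpongenetError(
            f"requested top {n} but only {len(results)} genes available")
    ordered = sorted(results,
                     key=lambda r: (r.adj_p_value, -abs(r.log_fc), r.gene_id))
    return [r.gene_id for r in ordered[:n]]


def results_table(results: list[DifferentialResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        {"gene_id": [r.gene_id for r in results],
         "log_fc": [r.log_fc for r in results],
         "t": [r.t_stat for r in results],
         "p": [r.p_value for r in results],
         "adj_p": [r.adj_p_value for r in results],
         "rank": [r.rank for r in results]})
    return df.sort_values("rank").reset_index(drop=True)
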