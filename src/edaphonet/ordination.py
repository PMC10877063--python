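"""Unconstrained (PCoA) and constrained (db-RDA) ordination.

PCoA eigen-decomposes the double-centered squared-distance matrix; db-RDA
regresses the principal coordinates on explanatory variables, measures the
constrained fraction of inertia, and assesses it with a permutation
pseudo-F test.  Forward selection follows the double-stopping rule: a
candidate enters only if its permutation p-value is below alpha and the
cumulative adjusted R-squared stays at or below the full model's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class OrdinationResult:
    eigenvalues: np.ndarray          # positive eigenvalues, descending
    sample_scores: pd.DataFrame      # samples x axes, scaled by sqrt(eigenvalue)
    percent_explained: np.ndarray    # % of positive-eigenvalue total
    negative_eigenvalue_mass: float  # sum of |negative eigenvalues|


@dataclass
class DbRdaResult:
    constrained_eigenvalues: np.ndarray
    unconstrained_eigenvalues: np.ndarray
    r2: float
    adj_r2: float
    permutation_p: float
    pseudo_f: float
    n_samples: int
    n_terms: int
    selected_terms: list[dict] = field(default_factory=list)


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    return (b + b.T) / 2.0


def pcoa(dist, k: int | None = None, eig_rtol: float = 1e-9) -> OrdinationResult:
    """Principal coordinate analysis of a distance matrix.

    Negative eigenvalues (from non-Euclidean dissimilarities) are reported
    via ``negative_eigenvalue_mass`` but excluded from the axes and from
    ``percent_explained``; no Lingoes/Cailliez correction is applied.
    """
    index = dist.index if isinstance(dist, pd.DataFrame) else None
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0, atol=1e-8):
        raise ValueError("distance matrix must have a zero diagonal")
    evals, evecs = np.linalg.eigh(_gower_center(d))
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = eig_rtol * max(abs(evals).max(), 1.0)
    pos = evals > tol
    neg_mass = float(-evals[evals < -tol].sum())
    evals_pos, vecs = evals[pos], evecs[:, pos]
    if k is not None:
        evals_pos, vecs = evals_pos[:k], vecs[:, :k]
    scores = vecs * np.sqrt(evals_pos)
    for a in range(scores.shape[1]):  # deterministic axis orientation
        i = np.argmax(np.abs(scores[:, a]))
        if scores[i, a] < 0:
            scores[:, a] *= -1
    cols = [f"PCo{a + 1}" for a in range(scores.shape[1])]
    total = evals[pos].sum()
    pct = 100.0 * evals_pos / total if total > 0 else np.zeros_like(evals_pos)
    return OrdinationResult(
        eigenvalues=evals_pos,
        sample_scores=pd.DataFrame(scores, index=index, columns=cols),
        percent_explained=pct,
        negative_eigenvalue_mass=neg_mass,
    )


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel's adjustment: 1 - (1 - R^2)(n - 1)/(n - m - 1)."""
    if n - m - 1 < 1:
        raise ValueError(f"adjusted R^2 undefined for n={n}, m={m}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def _as_matrix(x) -> tuple[np.ndarray, list[str]]:
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), list(x.columns)
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x, [f"x{j}" for j in range(x.shape[1])]


def _fitted(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Projection of (centered) y onto the column space of centered x.

    Uses a rank-tolerant least-squares fit so redundant predictors (e.g.
    full one-hot dummy sets) are handled gracefully.
    """
    xc = x - x.mean(axis=0)
    beta, *_ = np.linalg.lstsq(xc, y, rcond=None)
    return xc @ beta


def _fit_ss(y: np.ndarray, x: np.ndarray) -> float:
    """Sum of squares of fitted values from the centered least-squares fit."""
    return float((_fitted(y, x) ** 2).sum())


def _effective_rank(x: np.ndarray) -> int:
    xc = x - x.mean(axis=0)
    return int(np.linalg.matrix_rank(xc, tol=1e-10 * max(1.0, np.abs(xc).max())))


def dbrda(
    dist,
    x,
    n_perm: int = 999,
    seed: int | None = None,
) -> DbRdaResult:
    """Distance-based redundancy analysis with a permutation pseudo-F test.

    The positive principal coordinates of ``dist`` are regressed on the
    (centered) predictors; constrained inertia is the sum of squares of the
    fitted values.  Significance is assessed by permuting the sample rows
    of the predictor matrix; p = (#perm F >= observed F + 1)/(n_perm + 1).
    """
    xmat, _ = _as_matrix(x)
    ord_res = pcoa(dist)
    y = ord_res.sample_scores.to_numpy()
    n = y.shape[0]
    if xmat.shape[0] != n:
        raise ValueError("predictors and distance matrix are not aligned")
    m = _effective_rank(xmat)
    if m >= n - 1:
        raise ValueError(f"saturated model: rank {m} predictors for {n} samples")
    total = float((y**2).sum())
    ss_fit = _fit_ss(y, xmat)
    r2 = ss_fit / total if total > 0 else 0.0
    adj = adjusted_r2(r2, n, m)
    df_res = n - 1 - m

    def pseudo_f(ss):
        resid = max(total - ss, 0.0)
        if resid <= 1e-12 * max(total, 1.0):
            return np.inf
        return (ss / m) / (resid / df_res)

    f_obs = pseudo_f(ss_fit) if m else 0.0
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        f_p = pseudo_f(_fit_ss(y, xmat[perm]))
        if f_p >= f_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)

    # eigen-structure of the fitted and residual parts
    fitted = _fitted(y, xmat)
    resid = y - fitted
    c_eig = np.linalg.eigvalsh(fitted.T @ fitted)[::-1]
    u_eig = np.linalg.eigvalsh(resid.T @ resid)[::-1]
    return DbRdaResult(
        constrained_eigenvalues=c_eig[c_eig > 1e-10],
        unconstrained_eigenvalues=u_eig[u_eig > 1e-10],
        r2=r2,
        adj_r2=adj,
        permutation_p=p,
        pseudo_f=f_obs,
        n_samples=n,
        n_terms=m,
    )


def forward_select(
    dist,
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
    adjr2_scope: bool = True,
) -> DbRdaResult:
    """Forward selection of db-RDA terms on adjusted R-squared.

    At each step the candidate giving the largest adjusted-R2 gain is
    tested by permutation (marginal pseudo-F with the already-selected
    terms held fixed, permuting the candidate's rows); it enters only if
    p < alpha and the cumulative adjusted R2 does not exceed the
    full-model adjusted R2 (double stopping).  The adjusted-R2 scope stop
    is conservative when the remaining candidates are uninformative -- the
    submodel's and full model's adjusted R2 then estimate the same
    quantity and the comparison is a near coin flip -- so it can be
    disabled with ``adjr2_scope=False``, leaving the permutation test as
    the only stopping rule.  ``selected_terms`` records each accepted term
    with its cumulative and marginal adjusted R2 and p.
    """
    if candidates.shape[1] < 1:
        raise ValueError("need at least one candidate")
    rng = np.random.default_rng(seed)
    ord_res = pcoa(dist)
    y = ord_res.sample_scores.to_numpy()
    n = y.shape[0]
    total = float((y**2).sum())

    full_m = _effective_rank(candidates.to_numpy(dtype=float))
    full_adj = -np.inf
    if full_m < n - 1:
        full_r2 = _fit_ss(y, candidates.to_numpy(dtype=float)) / total
        full_adj = adjusted_r2(full_r2, n, full_m)
    else:
        log.warning("forward_select: full model saturated; skipping adj-R2 stop")
        full_adj = np.inf
    if not adjr2_scope:
        full_adj = np.inf

    selected: list[str] = []
    steps: list[dict] = []
    prev_adj = 0.0
    while True:
        remaining = [c for c in candidates.columns if c not in selected]
        if not remaining:
            break
        r_sel = (
            _effective_rank(candidates[selected].to_numpy(dtype=float))
            if selected
            else 0
        )
        best = None
        for term in remaining:
            cols = selected + [term]
            xmat = candidates[cols].to_numpy(dtype=float)
            m = _effective_rank(xmat)
            if m >= n - 1 or m <= r_sel:
                continue  # saturated, or adds no rank (e.g. redundant dummy)
            r2 = _fit_ss(y, xmat) / total
            adj = adjusted_r2(r2, n, m)
            if best is None or adj > best[0]:
                best = (adj, term, r2, m)
        if best is None:
            break
        adj, term, r2, m = best
        if adj > full_adj + 1e-12:
            log.info("forward_select: stop, %s would exceed full-model adj R2", term)
            break
        # marginal permutation test of `term` given `selected`
        x_sel = (
            candidates[selected].to_numpy(dtype=float)
            if selected
            else np.zeros((n, 0))
        )
        ss_sel = _fit_ss(y, x_sel) if selected else 0.0
        x_term = candidates[[term]].to_numpy(dtype=float)
        df_res = n - 1 - m
        dm = m - (_effective_rank(x_sel) if selected else 0)
        ss_both = r2 * total

        def marginal_f(ss):
            resid = max(total - ss, 0.0)
            if resid <= 1e-12 * max(total, 1.0):
                return np.inf
            return ((ss - ss_sel) / dm) / (resid / df_res)

        f_obs = marginal_f(ss_both)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            xp = np.column_stack([x_sel, x_term[perm]])
            f_p = marginal_f(_fit_ss(y, xp))
            if f_p >= f_obs - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
        if p >= alpha:
            break
        selected.append(term)
        steps.append(
            {
                "term": term,
                "adj_r2_cum": adj,
                "adj_r2_gain": adj - prev_adj,
                "r2_cum": r2,
                "p": p,
            }
        )
        prev_adj = adj
    if selected:
        result = dbrda(dist, candidates[selected], n_perm=n_perm,
                       seed=int(rng.integers(2**31 - 1)))
    else:
        result = DbRdaResult(
            constrained_eigenvalues=np.array([]),
            unconstrained_eigenvalues=np.array([]),
            r2=0.0,
            adj_r2=0.0,
            permutation_p=1.0,
            pseudo_f=0.0,
            n_samples=n,
            n_terms=0,
        )
    result.selected_terms = steps
    return result


def community_distance(css_table, log2_transform: bool = True) -> pd.DataFrame:
    """Euclidean sample distances on (optionally log2(x+1)) CSS abundances.

    The standard companion transform of CSS normalization; set
    ``log2_transform=False`` for plain Euclidean distances on CSS values.
    """
    x = css_table.counts.to_numpy(dtype=float)
    if log2_transform:
        x = np.log2(x + 1.0)
    sq = (x**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * x @ x.T
    d = np.sqrt(np.clip(d2, 0, None))
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=css_table.counts.index,
                        columns=css_table.counts.index)
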