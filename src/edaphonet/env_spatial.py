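"""Environmental variable conditioning, collinearity screens, and spatial
eigenvectors.

Covers the abiotic side of the pipeline: variable transforms with
skewness/kurtosis diagnostics, Pearson correlation and stepwise-VIF
collinearity screening, Kruskal-Wallis and pairwise Wilcoxon tests across
substrate groups, great-circle geographic distances, principal coordinates
of neighbour matrices (PCNM) as multi-scale spatial predictors, and the
PCNM <-> environment linear-model step (axis screening followed by AICc
stepwise selection).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
from scipy.sparse.csgraph import minimum_spanning_tree
from sklearn.metrics.pairwise import haversine_distances

log = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0

#: Default variable transforms: log for the right-skewed concentration-type
#: variables, square root for phosphate, none for pH.
DEFAULT_TRANSFORMS = {
    "pH": "none",
    "conductivity": "log",
    "TOC": "log",
    "TN": "log",
    "TP": "log",
    "N_NO3": "log",
    "N_NH4": "log",
    "P_PO4": "sqrt",
    "dry_weight": "log",
    "elevation": "log",
}


@dataclass
class EnvMatrix:
    """Transformed, centered and scaled environmental variables."""

    values: pd.DataFrame
    transform_of_variable: dict[str, str]
    centered_scaled: bool = True
    constant_variables: list[str] = field(default_factory=list)
    diagnostics: pd.DataFrame | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)


def transform_env(
    metadata: pd.DataFrame,
    scheme: dict[str, str] | None = None,
    variables=None,
    log_offset: str = "half_min_positive",
) -> EnvMatrix:
    """Transform, center and scale environmental variables.

    ``scheme`` maps variable -> {"log", "sqrt", "none"}; variables absent
    from the scheme are left untransformed.  Log transforms are natural log;
    a variable containing zeros uses log(x + half the smallest positive
    observed value) (disable by ``log_offset=None`` to make zeros an error).
    Skewness and kurtosis before/after are recorded in ``diagnostics``.
    """
    scheme = dict(DEFAULT_TRANSFORMS if scheme is None else scheme)
    if variables is None:
        variables = [v for v in scheme if v in metadata.columns]
    out = {}
    diag = {}
    for var in variables:
        raw = pd.to_numeric(metadata[var], errors="raise").astype(float)
        how = scheme.get(var, "none")
        x = raw.to_numpy(copy=True)
        if how == "log":
            if (x < 0).any():
                sid = raw.index[x < 0][0]
                raise ValueError(f"log transform of negative {var!r} at {sid!r}")
            if (x == 0).any():
                if log_offset is None:
                    sid = raw.index[x == 0][0]
                    raise ValueError(
                        f"log transform of zero {var!r} at sample {sid!r}"
                    )
                pos = x[x > 0]
                if pos.size == 0:
                    raise ValueError(f"variable {var!r} is all zero")
                offset = 0.5 * pos.min()
                log.info("transform_env: %s uses log(x + %g)", var, offset)
                x = x + offset
            x = np.log(x)
        elif how == "sqrt":
            if (x < 0).any():
                sid = raw.index[x < 0][0]
                raise ValueError(f"sqrt transform of negative {var!r} at {sid!r}")
            x = np.sqrt(x)
        elif how != "none":
            raise ValueError(f"unknown transform {how!r} for {var!r}")
        diag[var] = {
            "transform": how,
            "skew_before": sps.skew(raw.to_numpy()),
            "kurtosis_before": sps.kurtosis(raw.to_numpy()),
            "skew_after": sps.skew(x),
            "kurtosis_after": sps.kurtosis(x),
        }
        out[var] = x
    df = pd.DataFrame(out, index=metadata.index)
    constant = [v for v in df.columns if df[v].std(ddof=1) == 0 or df[v].isna().any()]
    scaled = df.copy()
    for v in df.columns:
        if v in constant:
            log.warning("transform_env: variable %s is constant, not scaled", v)
            continue
        scaled[v] = (df[v] - df[v].mean()) / df[v].std(ddof=1)
    return EnvMatrix(
        values=scaled,
        transform_of_variable={v: scheme.get(v, "none") for v in df.columns},
        centered_scaled=True,
        constant_variables=constant,
        diagnostics=pd.DataFrame(diag).T,
    )


# ---------------------------------------------------------------------------
# collinearity
# ---------------------------------------------------------------------------

def pearson_matrix(env: EnvMatrix) -> pd.DataFrame:
    """Pearson correlation matrix of the environmental variables."""
    return env.values.corr(method="pearson")


def _vif_one(X: np.ndarray, j: int) -> float:
    """VIF of column j regressed on the remaining columns (with intercept)."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    design = np.column_stack([np.ones(len(y)), others])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return np.inf
    r2 = 1.0 - ss_res / ss_tot
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def vif_stepwise(env: EnvMatrix, threshold: float = 10.0):
    """Stepwise removal of the max-VIF variable while any VIF >= threshold.

    Returns ``(retained, trace)`` where ``trace`` is a list of per-step VIF
    Series (one per iteration, computed before any removal in that step).
    Perfectly collinear variables have infinite VIF and are removed first.
    """
    cols = [v for v in env.variables if v not in env.constant_variables]
    if env.values.shape[0] < 3:
        raise ValueError("VIF screening requires at least 3 samples")
    trace = []
    while True:
        X = env.values[cols].to_numpy()
        if len(cols) < 2:
            trace.append(pd.Series(1.0, index=cols))
            break
        vifs = pd.Series({v: _vif_one(X, j) for j, v in enumerate(cols)})
        trace.append(vifs)
        worst = vifs.idxmax()
        if vifs[worst] < threshold:
            break
        log.info("vif_stepwise: removing %s (VIF=%.3g)", worst, vifs[worst])
        cols = [c for c in cols if c != worst]
    return cols, trace


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------

def _split_groups(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape[0] != groups.shape[0]:
        raise ValueError("values and groups must be aligned")
    labels = pd.unique(groups)
    parts = [values[groups == g] for g in labels]
    if len(parts) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(p) < 1 for p in parts):
        raise ValueError("every group needs at least one observation")
    return labels, parts


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-square p-value."""
    _, parts = _split_groups(values, groups)
    if np.ptp(np.concatenate(parts)) == 0:
        # every observation identical: H is 0 by convention
        return 0.0, 1.0
    h, p = sps.kruskal(*parts)
    return float(h), float(p)


def pairwise_wilcoxon(values, groups, correction: str = "bonferroni") -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum tests with Bonferroni correction.

    Returns a symmetric DataFrame of corrected p-values (diagonal NaN);
    each raw p is multiplied by the number of pairwise comparisons and
    capped at 1.
    """
    labels, parts = _split_groups(values, groups)
    k = len(labels)
    m = k * (k - 1) // 2
    out = pd.DataFrame(np.nan, index=labels, columns=labels)
    for (i, a), (j, b) in itertools.combinations(enumerate(labels), 2):
        _, p = sps.mannwhitneyu(parts[i], parts[j], alternative="two-sided")
        if correction == "bonferroni":
            p = min(1.0, p * m)
        elif correction not in (None, "none"):
            raise ValueError(f"unknown correction {correction!r}")
        out.loc[a, b] = out.loc[b, a] = p
    return out


# ---------------------------------------------------------------------------
# geography and PCNM
# ---------------------------------------------------------------------------

def geodesic_distance_matrix(coords: pd.DataFrame) -> pd.DataFrame:
    """Haversine great-circle distances (m) between samples.

    ``coords`` has columns ``latitude`` and ``longitude`` in decimal
    degrees, indexed by sample id.
    """
    lat = coords["latitude"].to_numpy(dtype=float)
    lon = coords["longitude"].to_numpy(dtype=float)
    if (np.abs(lat) > 90).any():
        raise ValueError("latitude outside [-90, 90]")
    if (np.abs(lon) > 180).any():
        raise ValueError("longitude outside [-180, 180]")
    rad = np.radians(np.column_stack([lat, lon]))
    d = haversine_distances(rad) * EARTH_RADIUS_M
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=coords.index, columns=coords.index)


@dataclass
class PcnmBasis:
    """Positive spatial eigenvectors of the truncated distance matrix.

    Axes are ordered by descending eigenvalue: PCNM1 captures the broadest
    spatial scale, later axes progressively finer structure.
    """

    eigenvectors: pd.DataFrame   # samples x axes, columns PCNM1..PCNMk
    eigenvalues: np.ndarray
    truncation_threshold: float


def pcnm(dist: pd.DataFrame, eig_rtol: float = 1e-10) -> PcnmBasis:
    """Principal coordinates of neighbour matrices.

    The distance matrix is truncated at the longest edge of its minimum
    spanning tree: entries above the threshold are replaced by 4x the
    threshold; the truncated matrix is double-centered (-1/2 D^2) and
    eigen-decomposed.  Axes with eigenvalue > ``eig_rtol`` x the largest
    eigenvalue are retained.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("PCNM requires at least 3 samples")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.all(d[np.triu_indices(n, 1)] == 0):
        raise ValueError("all points coincident: degenerate geometry")
    mst = minimum_spanning_tree(d).toarray()
    threshold = float(mst.max())
    trunc = d.copy()
    trunc[trunc > threshold] = 4.0 * threshold
    np.fill_diagonal(trunc, 0.0)
    b = -0.5 * trunc**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ b @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > eig_rtol * max(evals.max(), 0.0)
    if not keep.any():
        raise ValueError("no positive PCNM eigenvalues")
    evals, evecs = evals[keep], evecs[:, keep]
    # deterministic sign: largest-magnitude loading positive
    for k in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, k]))
        if evecs[i, k] < 0:
            evecs[:, k] *= -1
    cols = [f"PCNM{k + 1}" for k in range(evecs.shape[1])]
    basis = pd.DataFrame(evecs, index=dist.index, columns=cols)
    return PcnmBasis(basis, evals, threshold)


def select_pcnms(basis: PcnmBasis, env: EnvMatrix, alpha: float = 0.05) -> list[str]:
    """Axes whose Pearson correlation with any variable has p < alpha."""
    keep = []
    for axis in basis.eigenvectors.columns:
        x = basis.eigenvectors[axis].to_numpy()
        for var in env.variables:
            if var in env.constant_variables:
                continue
            r = sps.pearsonr(x, env.values.loc[basis.eigenvectors.index, var])
            if r.pvalue < alpha:
                keep.append(axis)
                break
    if not keep:
        log.info("select_pcnms: no axis passed the %.3g screen", alpha)
    return keep


# ---------------------------------------------------------------------------
# stepwise linear model (AICc, both directions)
# ---------------------------------------------------------------------------

def _aicc(y: np.ndarray, X: np.ndarray) -> float:
    n, k = X.shape  # k includes the intercept
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    if rss <= 0:
        rss = 1e-300
    n_par = k + 1  # + error variance
    aic = n * np.log(rss / n) + 2 * n_par
    denom = n - n_par - 1
    if denom <= 0:
        return np.inf
    return aic + 2 * n_par * (n_par + 1) / denom


@dataclass
class StepwiseLmResult:
    selected: list[str]
    coefficients: pd.Series
    aicc: float
    r2: float
    trace: list[tuple[str, str, float]]  # (action, term, aicc after)


def stepwise_lm(
    response, predictors: pd.DataFrame, max_steps: int = 100
) -> StepwiseLmResult:
    """Bidirectional stepwise OLS by small-sample-corrected AIC.

    Starts from the intercept-only model; at each step performs the single
    addition or removal that most decreases AICc, stopping when no move
    improves it.  Used to link a PCNM axis (response) to environmental and
    bedrock predictors.
    """
    y = np.asarray(response, dtype=float)
    n = len(y)
    selected: list[str] = []
    trace: list[tuple[str, str, float]] = []
    current = _aicc(y, np.ones((n, 1)))
    trace.append(("start", "(intercept)", current))
    for _ in range(max_steps):
        moves = []
        for term in predictors.columns:
            if term in selected:
                cand = [t for t in selected if t != term]
                action = "drop"
            else:
                cand = selected + [term]
                action = "add"
            X = np.column_stack(
                [np.ones(n)] + [predictors[t].to_numpy(dtype=float) for t in cand]
            )
            moves.append((_aicc(y, X), action, term, cand))
        moves.sort(key=lambda m: m[0])
        best_aicc, action, term, cand = moves[0]
        if best_aicc >= current - 1e-10:
            break
        current, selected = best_aicc, cand
        trace.append((action, term, current))
    X = np.column_stack(
        [np.ones(n)] + [predictors[t].to_numpy(dtype=float) for t in selected]
    )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0
    coef = pd.Series(beta, index=["(intercept)"] + selected)
    return StepwiseLmResult(selected, coef, current, r2, trace)


def substrate_dummies(metadata: pd.DataFrame) -> pd.DataFrame:
    """One-hot bedrock-type dummies (1: sampled bedrock, 0: others).

    No category is dropped, so any substrate can be selected by forward
    selection; fitting uses least squares, which tolerates the resulting
    linear dependence with an intercept.
    """
    sub = metadata["substrate"]
    return pd.get_dummies(sub, prefix="bedrock", dtype=float)
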