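"""Module abundance profiles and module-environment consensus analysis.

Each module's abundance profile is the per-sample mean of the z-scored
relative abundances of its member ASVs (standardizing removes any scale
difference between the bacterial and eukaryotic tables).  Modules are then
tested for substrate association (Kruskal-Wallis) and linked to
environmental variables by three converging lines of evidence: random-forest
permutation importance, Pearson correlation, and Spearman correlation, the
two correlation families Holm-corrected.  A variable is a consensus
predictor of a module when both correlations are Holm-significant and the
variable sits in the top random-forest ranks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
from sklearn.ensemble import RandomForestRegressor

from edaphonet.env_spatial import EnvMatrix, kruskal_wallis
from edaphonet.network import ModulePartition
from edaphonet.tables import AsvTable

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# module abundance profiles
# ---------------------------------------------------------------------------

def module_profile(
    merged: AsvTable, partition: ModulePartition
) -> pd.DataFrame:
    """Module x sample matrix of mean z-scored relative abundances.

    Each member ASV's relative abundance is z-scored across samples
    (sample standard deviation, ddof = 1); a module's profile is the mean
    of its members' z-scores.  Zero-variance ASVs cannot be standardized
    and are excluded from their module's mean (logged).
    """
    missing = [n for n in partition.module_of_node if n not in merged.counts.columns]
    if missing:
        raise KeyError(f"partition node(s) missing from table: {missing[:5]}")
    x = merged.counts
    rows = {}
    for mod in sorted(set(partition.module_of_node.values())):
        members = partition.members(mod)
        zs = []
        for asv in members:
            col = x[asv].to_numpy(dtype=float)
            sd = col.std(ddof=1)
            if sd == 0:
                log.info("module_profile: %s has zero variance, excluded", asv)
                continue
            zs.append((col - col.mean()) / sd)
        if not zs:
            raise ValueError(f"module {mod} has no ASV with variance")
        rows[mod] = np.mean(zs, axis=0)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=merged.sample_ids
    )


def substrate_test(
    profile: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Kruskal-Wallis test of each module profile across substrate types."""
    groups = metadata.loc[profile.columns, "substrate"].to_numpy()
    out = {}
    for mod in profile.index:
        h, p = kruskal_wallis(profile.loc[mod].to_numpy(), groups)
        out[mod] = {"H": h, "p": p}
    return pd.DataFrame(out).T


# ---------------------------------------------------------------------------
# random-forest variable ranking
# ---------------------------------------------------------------------------

def rf_importance(
    env: EnvMatrix,
    y,
    n_trees: int = 500,
    mtry: int | None = None,
    min_leaf: int = 5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Random-forest regression ranking of environmental variables.

    Fits a regression forest (bootstrap per tree, variance-reduction
    splits over ``mtry`` randomly drawn variables, minimum leaf size
    ``min_leaf``) and scores each variable by the mean out-of-bag increase
    in squared error when that variable's values are permuted among the
    out-of-bag samples.  Returns variables sorted by decreasing importance.
    """
    X = env.values.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 10:
        raise ValueError("random forest ranking needs at least 10 samples")
    if np.ptp(y) == 0:
        out = pd.DataFrame(
            {"importance": np.zeros(p), "rank": np.nan}, index=env.variables
        )
        out.attrs["constant_response"] = True
        log.warning("rf_importance: constant response, importances undefined")
        return out
    mtry = mtry or int(np.ceil(p / 3))
    rng = np.random.default_rng(seed)
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=mtry,
        min_samples_leaf=min_leaf,
        bootstrap=True,
        random_state=int(rng.integers(2**31 - 1)),
        n_jobs=1,
    )
    forest.fit(X, y)
    importances = np.zeros(p)
    counts = np.zeros(p)
    for tree, bootstrap_idx in zip(
        forest.estimators_, forest.estimators_samples_
    ):
        oob = np.setdiff1d(np.arange(n), bootstrap_idx)
        if len(oob) < 2:
            continue
        X_oob, y_oob = X[oob], y[oob]
        base_mse = float(((tree.predict(X_oob) - y_oob) ** 2).mean())
        for j in range(p):
            Xp = X_oob.copy()
            Xp[:, j] = Xp[rng.permutation(len(oob)), j]
            mse = float(((tree.predict(Xp) - y_oob) ** 2).mean())
            importances[j] += mse - base_mse
            counts[j] += 1
    importances = np.where(counts > 0, importances / np.maximum(counts, 1), 0.0)
    out = pd.DataFrame({"importance": importances}, index=env.variables)
    out = out.sort_values("importance", ascending=False, kind="mergesort")
    out["rank"] = np.arange(1, p + 1)
    out.attrs["constant_response"] = False
    return out


# ---------------------------------------------------------------------------
# Holm correction
# ---------------------------------------------------------------------------

def holm_correct(pvals) -> np.ndarray:
    """Holm step-down adjustment of a family of p-values.

    Sort ascending, multiply the i-th smallest by (m - i + 1), enforce
    monotone non-decreasing adjusted values, cap at 1, and return in the
    original order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="mergesort")
    m = p.size
    stepped = p[order] * (m - np.arange(m))
    stepped = np.minimum(np.maximum.accumulate(stepped), 1.0)
    out = np.empty_like(stepped)
    out[order] = stepped
    return out


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

@dataclass
class ModuleEnvReport:
    """Per-module environmental association evidence and consensus calls."""

    correlations: pd.DataFrame      # module, variable, r/rho, raw & Holm p
    rf_ranks: pd.DataFrame          # module x variable -> rank
    substrate_kw: pd.DataFrame      # module -> H, p
    consensus: pd.DataFrame         # consensus predictor rows with sign
    major_of_module: dict = field(default_factory=dict)
    alpha: float = 0.01
    rf_top: int = 3


def consensus_predictors(
    profile: pd.DataFrame,
    env: EnvMatrix,
    metadata: pd.DataFrame | None = None,
    alpha: float = 0.01,
    rf_top: int = 3,
    nonlinear_gap: float = 0.2,
    n_trees: int = 500,
    seed: int | None = None,
) -> ModuleEnvReport:
    """Identify each module's consensus environmental predictors.

    For every module x variable pair, Pearson and Spearman correlations are
    tested; p-values are Holm-corrected within each correlation family
    (all module x variable pairs of that family).  A variable is a
    consensus predictor when both corrected p-values are below ``alpha``
    and the variable lies within the top ``rf_top`` random-forest ranks for
    that module.  The top consensus variable per module (best RF rank, ties
    by |Pearson r|) is designated the module's major explanatory variable.
    Pairs where |Spearman rho| exceeds |Pearson r| by more than
    ``nonlinear_gap`` are annotated as possibly nonlinear (an automated
    stand-in for scatterplot inspection).
    """
    samples = list(profile.columns)
    envv = env.values.loc[samples]
    variables = [v for v in env.variables if v not in env.constant_variables]
    rng = np.random.default_rng(seed)

    rows = []
    for mod in profile.index:
        y = profile.loc[mod].to_numpy(dtype=float)
        for var in variables:
            x = envv[var].to_numpy(dtype=float)
            pr = sps.pearsonr(x, y)
            sr = sps.spearmanr(x, y)
            rows.append(
                {
                    "module": mod,
                    "variable": var,
                    "pearson_r": float(pr.statistic),
                    "pearson_p": float(pr.pvalue),
                    "spearman_rho": float(sr.statistic),
                    "spearman_p": float(sr.pvalue),
                }
            )
    corr = pd.DataFrame(rows)
    corr["pearson_p_holm"] = holm_correct(corr["pearson_p"].to_numpy())
    corr["spearman_p_holm"] = holm_correct(corr["spearman_p"].to_numpy())
    corr["possibly_nonlinear"] = (
        corr["spearman_rho"].abs() - corr["pearson_r"].abs() > nonlinear_gap
    )

    env_sub = EnvMatrix(
        values=envv[variables],
        transform_of_variable=env.transform_of_variable,
        centered_scaled=env.centered_scaled,
    )
    rf_rank_rows = {}
    for mod in profile.index:
        ranking = rf_importance(
            env_sub,
            profile.loc[mod].to_numpy(dtype=float),
            n_trees=n_trees,
            seed=int(rng.integers(2**31 - 1)),
        )
        rf_rank_rows[mod] = ranking["rank"]
    rf_ranks = pd.DataFrame(rf_rank_rows).T  # module x variable

    consensus_rows = []
    major = {}
    for mod in profile.index:
        sub = corr[corr["module"] == mod]
        hits = []
        for _, row in sub.iterrows():
            var = row["variable"]
            if (
                row["pearson_p_holm"] < alpha
                and row["spearman_p_holm"] < alpha
                and rf_ranks.loc[mod, var] <= rf_top
            ):
                hits.append(
                    {
                        "module": mod,
                        "variable": var,
                        "sign": int(np.sign(row["pearson_r"])),
                        "pearson_r": row["pearson_r"],
                        "spearman_rho": row["spearman_rho"],
                        "rf_rank": int(rf_ranks.loc[mod, var]),
                        "possibly_nonlinear": bool(row["possibly_nonlinear"]),
                    }
                )
        hits.sort(key=lambda h: (h["rf_rank"], -abs(h["pearson_r"])))
        consensus_rows.extend(hits)
        major[mod] = (hits[0]["variable"], hits[0]["sign"]) if hits else None

    kw = (
        substrate_test(profile, metadata)
        if metadata is not None
        else pd.DataFrame(index=profile.index, columns=["H", "p"])
    )
    consensus = pd.DataFrame(
        consensus_rows,
        columns=[
            "module", "variable", "sign", "pearson_r", "spearman_rho",
            "rf_rank", "possibly_nonlinear",
        ],
    )
    return ModuleEnvReport(
        correlations=corr,
        rf_ranks=rf_ranks,
        substrate_kw=kw,
        consensus=consensus,
        major_of_module=major,
        alpha=alpha,
        rf_top=rf_top,
    )
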