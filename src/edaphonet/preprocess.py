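"""Count-table hygiene, rare-ASV filtering, and CSS normalization.

Implements the standard preparation chain for amplicon ASV tables ahead of
co-occurrence and ordination analyses: singleton removal, removal of
organelle-derived (chloroplast / mitochondrial) and denied contaminant
lineages, control-sample removal with replicate de-duplication, the
rare-ASV prevalence/abundance filter, the relative-abundance transform, and
cumulative-sum scaling (CSS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from edaphonet.tables import AsvTable, TaxonomyTable

log = logging.getLogger(__name__)

DEFAULT_DENY_LIST = frozenset({"Chloroplast", "Mitochondria"})


def _require_raw(t: AsvTable, op: str) -> None:
    if t.kind != "raw_counts":
        raise ValueError(f"{op} expects raw counts, got kind={t.kind!r}")


def remove_singletons(t: AsvTable) -> AsvTable:
    """Drop ASVs whose total count across the whole dataset is below 2.

    A singleton is an ASV whose sequence occurs exactly once in the entire
    dataset; zero-total ASVs (possible after prior sample removal) are
    dropped as well.
    """
    _require_raw(t, "remove_singletons")
    totals = t.counts.sum(axis=0)
    keep = totals[totals >= 2].index
    log.info("remove_singletons: %d -> %d ASVs", t.n_asvs, len(keep))
    return t.select_asvs(keep)


def remove_organelles_and_contaminants(
    t: AsvTable,
    tax: TaxonomyTable,
    deny_list=DEFAULT_DENY_LIST,
    contaminant_flags=None,
) -> AsvTable:
    """Drop ASVs whose lineage matches a deny-list term or a contaminant flag.

    ``deny_list`` entries are matched as substrings of the full
    semicolon-joined lineage (case-sensitive).  ``contaminant_flags`` is an
    optional set of ASV ids identified as contaminants by an external
    procedure.
    """
    contaminant_flags = set(contaminant_flags or ())
    missing = [a for a in t.asv_ids if a not in tax.lineage_of_asv.index]
    if missing:
        raise KeyError(f"ASV(s) missing from taxonomy: {missing[:5]}")
    keep = []
    for asv in t.asv_ids:
        if asv in contaminant_flags:
            continue
        lineage = tax.lineage_string(asv)
        if any(term in lineage for term in deny_list):
            continue
        keep.append(asv)
    log.info(
        "remove_organelles_and_contaminants: %d -> %d ASVs", t.n_asvs, len(keep)
    )
    return t.select_asvs(keep)


def drop_controls_and_dedup(t: AsvTable, metadata: pd.DataFrame) -> AsvTable:
    """Remove blank/mock samples and keep one sample per replicate group.

    Replicates (sample_role ``replicate``) are grouped with the sample they
    replicate via a ``replicate_of`` metadata column (falling back to the
    ``site`` column if absent); within each group only the member with the
    largest library size is retained.  Ties are broken by lexicographically
    smallest sample id, which is logged.
    """
    missing = [s for s in t.sample_ids if s not in metadata.index]
    if missing:
        raise KeyError(f"sample(s) missing from metadata: {missing[:5]}")
    meta = metadata.loc[t.sample_ids]
    role = meta["sample_role"] if "sample_role" in meta.columns else pd.Series(
        "sample", index=meta.index
    )
    keep = [s for s in t.sample_ids if role[s] not in ("blank", "mock")]

    depths = t.counts.sum(axis=1)
    group_col = "replicate_of" if "replicate_of" in meta.columns else "site"
    groups: dict[str, list[str]] = {}
    for s in keep:
        if role[s] == "replicate":
            groups.setdefault(str(meta.loc[s, group_col]), []).append(s)
    drop = set()
    for anchor, members in groups.items():
        pool = list(members)
        if anchor in keep:
            pool.append(anchor)
        best = sorted(pool, key=lambda s: (-depths[s], s))[0]
        if sum(depths[s] == depths[best] for s in pool) > 1:
            log.info(
                "replicate group %r: depth tie, keeping %r (smallest id)",
                anchor, best,
            )
        drop.update(s for s in pool if s != best)
    keep = [s for s in keep if s not in drop]
    log.info("drop_controls_and_dedup: %d -> %d samples", t.n_samples, len(keep))
    return t.select_samples(keep)


def filter_rare(
    t: AsvTable,
    min_rel: float = 0.001,
    min_total: int = 5,
    min_prev: int = 3,
) -> AsvTable:
    """Remove rare ASVs ahead of network construction.

    Retains an ASV only if all three hold (strict inequalities):
    its maximum per-sample relative abundance exceeds ``min_rel``, its total
    count exceeds ``min_total`` reads, and it is present (count > 0) in more
    than ``min_prev`` samples.  Applied per domain, before merging.
    """
    _require_raw(t, "filter_rare")
    counts = t.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(lib > 0, counts / lib, 0.0)
    ok = (
        (rel.max(axis=0) > min_rel)
        & (counts.sum(axis=0) > min_total)
        & ((counts > 0).sum(axis=0) > min_prev)
    )
    keep = t.counts.columns[ok]
    log.info("filter_rare: %d -> %d ASVs", t.n_asvs, len(keep))
    return t.select_asvs(keep)


def to_relative(t: AsvTable) -> AsvTable:
    """Per-sample relative abundances; all-zero rows stay zero."""
    _require_raw(t, "to_relative")
    lib = t.counts.sum(axis=1)
    rel = t.counts.div(lib.replace(0, np.nan), axis=0).fillna(0.0)
    return AsvTable(rel, t.domain_of_asv, "relative")


# ---------------------------------------------------------------------------
# cumulative-sum scaling
# ---------------------------------------------------------------------------

@dataclass
class CssResult:
    """Output of CSS normalization.

    ``table`` holds the normalized values; each cell equals
    raw count / scaling factor x scale constant.
    """

    table: AsvTable
    percentile: float
    scaling_factor_of_sample: pd.Series
    scale_constant: float


def _positive_quantiles(t: AsvTable, levels: np.ndarray) -> pd.DataFrame:
    """Per-sample empirical quantiles of the positive counts (type-7)."""
    rows = {}
    for sid in t.sample_ids:
        pos = t.counts.loc[sid].to_numpy(dtype=float)
        pos = pos[pos > 0]
        if pos.size == 0:
            raise ValueError(f"sample {sid!r} has no positive counts")
        rows[sid] = np.quantile(pos, levels, method="linear")
    return pd.DataFrame.from_dict(rows, orient="index", columns=levels)


def css_percentile(t: AsvTable, rel_instability: float = 0.1) -> float:
    """Data-driven choice of the CSS quantile level.

    For each candidate level l on the grid 1/n, 2/n, ..., 1 the per-sample
    l-th quantile of positive counts is computed; the across-sample median
    of those quantiles serves as a reference, and the across-sample median
    absolute deviation from the reference measures instability at level l.
    The chosen level is the smallest one at which the relative increase of
    this instability between consecutive levels first reaches
    ``rel_instability`` (the point where sample count distributions begin
    to diverge); 0.5 is returned if the criterion is never met.
    """
    _require_raw(t, "css_percentile")
    if (t.counts.sum(axis=1) > 0).sum() < 2:
        raise ValueError("CSS requires at least 2 samples with positive counts")
    n = max(t.n_asvs, 2)
    levels = np.arange(1, n + 1) / n
    q = _positive_quantiles(t, levels).to_numpy()
    ref = np.median(q, axis=0)
    dev = np.median(np.abs(q - ref), axis=0)
    for k in range(1, len(levels)):
        if dev[k] <= 0:
            continue
        if (dev[k] - dev[k - 1]) / dev[k] >= rel_instability:
            return float(levels[k])
    return 0.5


def css_normalize(
    t: AsvTable, percentile: float | None = None, scale_constant: float = 1000.0
) -> CssResult:
    """Cumulative-sum scaling of a raw count table.

    Each sample's scaling factor is the sum of its counts that are less than
    or equal to its own ``percentile``-quantile of positive counts; the
    sample's counts are then multiplied by ``scale_constant / factor``.
    Robust to samples where a few dominant ASVs inflate the library size.
    """
    _require_raw(t, "css_normalize")
    if percentile is None:
        percentile = css_percentile(t)
    if not 0 < percentile <= 1:
        raise ValueError(f"percentile must be in (0, 1], got {percentile}")
    factors = {}
    normalized = t.counts.astype(float).copy()
    for sid in t.sample_ids:
        row = t.counts.loc[sid].to_numpy(dtype=float)
        pos = row[row > 0]
        if pos.size == 0:
            raise ValueError(f"sample {sid!r} has no positive counts")
        q = np.quantile(pos, percentile, method="linear")
        factor = row[row <= q].sum()
        if factor <= 0:
            raise ValueError(f"sample {sid!r}: non-positive CSS scaling factor")
        factors[sid] = factor
        normalized.loc[sid] = row * (scale_constant / factor)
    table = AsvTable(normalized, t.domain_of_asv, "css")
    return CssResult(
        table=table,
        percentile=float(percentile),
        scaling_factor_of_sample=pd.Series(factors),
        scale_constant=float(scale_constant),
    )
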