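"""Synthetic cross-domain ASV datasets with planted statistical structure.

Emulates the downstream-analysis situation of a multi-site mineral-soil
amplicon survey: ~100 samples spread over sites of four bedrock types
(granite, gneiss, marble, moraine), a bacterial and a eukaryotic ASV table
with overdispersed counts and variable sequencing depth, geochemical
covariates correlated with bedrock, and latent co-occurrence modules whose
activity tracks bedrock affinity and planted environmental drivers.  Each
module carries one or more hub ASVs that follow the module's mean activity
with reduced idiosyncratic noise, so hubs emerge through the same Spearman
estimator the pipeline uses rather than by editing any correlation matrix.

Counts are drawn from a gamma-Poisson (negative-binomial-type) model: per
cell a gamma intensity with shape ``dispersion`` is drawn around the
expected abundance, and the sample's counts are a multinomial draw of the
library size over those intensities, so each emitted library size lies
exactly within ``depth_range``.  In the ``dispersion -> infinity`` limit the
intensities are deterministic and the counts become Poisson-like.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from edaphonet.tables import (
    AsvTable,
    TaxonomyTable,
    SUBSTRATES,
    write_asv_table,
    write_metadata,
    write_taxonomy,
)

ENV_VARIABLES = (
    "pH", "conductivity", "TOC", "TN", "TP",
    "N_NO3", "N_NH4", "P_PO4", "dry_weight", "elevation",
)

#: Baseline mean and per-sample s.d. of each variable (units as in metadata).
_ENV_BASE = {
    "pH": (6.8, 0.5),
    "conductivity": (120.0, 30.0),
    "TOC": (0.6, 0.15),
    "TN": (0.06, 0.015),
    "TP": (0.05, 0.012),
    "N_NO3": (4.0, 1.0),
    "N_NH4": (2.5, 0.6),
    "P_PO4": (6.0, 1.5),
    "dry_weight": (97.0, 1.0),
    "elevation": (1400.0, 150.0),
}

_BACTERIAL_PHYLA = (
    "Actinomycetota", "Bacteroidota", "Acidobacteriota", "Cyanobacteriota",
    "Chloroflexota", "Pseudomonadota", "Abditibacteriota", "Deinococcota",
)
_EUKARYOTE_DIVISIONS = (
    "Chlorophyta", "Cercozoa", "Metazoa", "Ciliophora", "Ochrophyta",
    "Streptophyta",
)
_GENERA = (
    "Terricola", "Cryoseptum", "Nivicoccus", "Saxiphilus", "Petrobium",
    "Gelidimonas", "Frigoribacter", "Glacialella",
)


def _default_affinity(n_modules: int, contrast: float, base: float) -> np.ndarray:
    aff = np.full((n_modules, len(SUBSTRATES)), base)
    for m in range(n_modules):
        aff[m, m % len(SUBSTRATES)] = contrast
    return aff


def _default_env_means(n_modules: int, contrast_sd: float = 1.2) -> pd.DataFrame:
    """Substrate x variable means with driver variables shifted in the
    bedrock type their module prefers (sign alternating by module)."""
    means = pd.DataFrame(
        {v: [_ENV_BASE[v][0]] * len(SUBSTRATES) for v in ENV_VARIABLES},
        index=list(SUBSTRATES),
    )
    for m in range(n_modules):
        var = ENV_VARIABLES[m % len(ENV_VARIABLES)]
        sub = SUBSTRATES[m % len(SUBSTRATES)]
        sign = 1.0 if m % 2 == 0 else -1.0
        means.loc[sub, var] += sign * contrast_sd * _ENV_BASE[var][1]
    # mild extra substrate signature on the two non-driver variables
    means.loc["moraine", "dry_weight"] += 0.8
    means.loc["marble", "elevation"] -= 120.0
    means.loc["granite", "elevation"] += 90.0
    return means


@dataclass
class SimulationConfig:
    """Parameters of the planted-structure generator.

    The defaults define the package's reference study conditions: 8 sites
    (two per bedrock type) x 12 samples = 96 samples, 8 planted modules of
    40 ASVs each (3/4 bacterial) plus 160 background ASVs, strong
    module-bedrock affinity contrast, one signed environmental driver per
    module, and overdispersed counts at library sizes of 20-60k reads.
    """

    n_sites: int = 8
    samples_per_site: int = 12
    substrate_of_site: dict = field(default_factory=dict)
    n_modules: int = 8
    asvs_per_module: int = 40
    bacterial_fraction: float = 0.75
    n_background_asvs: int = 160
    module_substrate_affinity: np.ndarray | None = None
    affinity_contrast: float = 6.0
    affinity_base: float = 0.5
    env_means: pd.DataFrame | None = None
    env_sd: dict = field(default_factory=dict)
    env_beta: float = 1.1
    depth_range: tuple = (20_000, 60_000)
    dispersion: float = 8.0
    hub_per_module: int = 1
    module_noise_sd: float = 0.8
    member_noise_range: tuple = (0.9, 2.0)
    hub_noise_sd: float = 0.15
    background_noise_sd: float = 1.2
    n_organelle_decoys: int = 6
    include_controls: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.samples_per_site < 1:
            raise ValueError("samples_per_site must be >= 1 (every site sampled)")
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        if self.asvs_per_module < 2:
            raise ValueError("asvs_per_module must be >= 2")
        if not 0 < self.bacterial_fraction < 1:
            raise ValueError("bacterial_fraction must lie in (0, 1)")
        if self.n_background_asvs < 0:
            raise ValueError("n_background_asvs must be >= 0")
        if self.hub_per_module < 1:
            raise ValueError("hub_per_module must be >= 1")
        if self.hub_per_module >= self.asvs_per_module:
            raise ValueError("hub_per_module must be < asvs_per_module")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be > 0")
        lo, hi = self.depth_range
        if not (0 < lo <= hi):
            raise ValueError("depth_range must be positive with lo <= hi")
        nlo, nhi = self.member_noise_range
        if not (0 < nlo <= nhi):
            raise ValueError("member_noise_range must be positive with lo <= hi")
        if self.hub_noise_sd < 0:
            raise ValueError("hub_noise_sd must be >= 0")
        if not self.substrate_of_site:
            self.substrate_of_site = {
                f"site{k + 1}": SUBSTRATES[k % len(SUBSTRATES)]
                for k in range(self.n_sites)
            }
        if len(self.substrate_of_site) != self.n_sites:
            raise ValueError("substrate_of_site must cover every site")
        bad = set(self.substrate_of_site.values()) - set(SUBSTRATES)
        if bad:
            raise ValueError(f"substrate_of_site: unknown substrate(s) {sorted(bad)}")
        if self.module_substrate_affinity is None:
            self.module_substrate_affinity = _default_affinity(
                self.n_modules, self.affinity_contrast, self.affinity_base
            )
        aff = np.asarray(self.module_substrate_affinity, dtype=float)
        if aff.shape != (self.n_modules, len(SUBSTRATES)):
            raise ValueError(
                "module_substrate_affinity must be n_modules x 4 "
                f"(got {aff.shape})"
            )
        if (aff < 0).any():
            raise ValueError("module_substrate_affinity multipliers must be >= 0")
        self.module_substrate_affinity = aff
        if self.env_means is None:
            self.env_means = _default_env_means(self.n_modules)
        if not self.env_sd:
            self.env_sd = {v: _ENV_BASE[v][1] for v in ENV_VARIABLES}
        if any(sd <= 0 for sd in self.env_sd.values()):
            raise ValueError("env_sd entries must be > 0")

    @property
    def n_samples(self) -> int:
        return self.n_sites * self.samples_per_site


@dataclass
class GroundTruth:
    """Planted structure emitted next to a synthetic dataset."""

    module_of_asv: dict            # ASV -> module id (int) or "background"
    hub_asvs: set
    env_drivers: dict              # module id -> {variable: sign}
    substrate_of_sample: dict

    def __post_init__(self) -> None:
        for hub in self.hub_asvs:
            mod = self.module_of_asv.get(hub)
            if mod is None or mod == "background":
                raise ValueError(f"hub {hub!r} is not a module member")

    def to_json(self, path) -> None:
        payload = {
            "module_of_asv": {
                k: (v if isinstance(v, str) else int(v))
                for k, v in self.module_of_asv.items()
            },
            "hub_asvs": sorted(self.hub_asvs),
            "env_drivers": {
                str(m): {v: int(s) for v, s in d.items()}
                for m, d in self.env_drivers.items()
            },
            "substrate_of_sample": self.substrate_of_sample,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        return cls(
            module_of_asv={
                k: (v if v == "background" else int(v))
                for k, v in raw["module_of_asv"].items()
            },
            hub_asvs=set(raw["hub_asvs"]),
            env_drivers={
                int(m): {v: int(s) for v, s in d.items()}
                for m, d in raw["env_drivers"].items()
            },
            substrate_of_sample=raw["substrate_of_sample"],
        )


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def _draw_counts(rng, mu: np.ndarray, depth: int, dispersion: float) -> np.ndarray:
    """Gamma-Poisson counts scaled to an exact library size.

    ``mu`` are relative expected intensities for one sample; a gamma
    intensity (shape = dispersion) is drawn per ASV and ``depth`` reads are
    allocated multinomially over the intensities.
    """
    if np.isfinite(dispersion):
        w = rng.gamma(dispersion, mu / dispersion)
    else:  # Poisson limit
        w = mu.astype(float)
    total = w.sum()
    if total <= 0:
        w = np.ones_like(w)
        total = w.sum()
    return rng.multinomial(depth, w / total)


def _site_coordinates(rng, config) -> dict:
    """Site centres inside a ~100 km box in the Antarctic study region."""
    lat0, lon0 = -72.0, 23.0
    centres = {}
    for site in config.substrate_of_site:
        centres[site] = (
            lat0 + rng.uniform(-0.45, 0.45),       # +-50 km
            lon0 + rng.uniform(-1.45, 1.45),       # +-50 km at 72 deg S
        )
    return centres


def generate_dataset(config: SimulationConfig):
    """Generate paired bacterial/eukaryotic tables, taxonomy, metadata, truth.

    Returns ``(bacteria, eukaryotes, taxonomy, metadata, truth)``.
    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    substrates = list(SUBSTRATES)

    # --- samples and metadata -------------------------------------------
    sample_ids, site_of, sub_of = [], {}, {}
    for site, substrate in config.substrate_of_site.items():
        for k in range(config.samples_per_site):
            sid = f"{site}_s{k + 1:02d}"
            sample_ids.append(sid)
            site_of[sid] = site
            sub_of[sid] = substrate
    centres = _site_coordinates(rng, config)

    env = {}
    for v in ENV_VARIABLES:
        sd = config.env_sd[v]
        means = np.array(
            [config.env_means.loc[sub_of[s], v] for s in sample_ids]
        )
        vals = means + sd * rng.standard_normal(len(sample_ids))
        floor = 0.05 * _ENV_BASE[v][0]
        env[v] = np.maximum(vals, floor)
    meta = pd.DataFrame(env, index=sample_ids)
    meta["pH"] = meta["pH"].clip(0.5, 13.5)
    for pct in ("TOC", "TN", "TP", "dry_weight"):
        meta[pct] = meta[pct].clip(upper=100.0)
    meta.insert(0, "substrate", [sub_of[s] for s in sample_ids])
    meta.insert(1, "site", [site_of[s] for s in sample_ids])
    lat = np.array([centres[site_of[s]][0] for s in sample_ids])
    lon = np.array([centres[site_of[s]][1] for s in sample_ids])
    lat = lat + rng.uniform(-0.0045, 0.0045, len(sample_ids))       # <= 500 m
    lon = lon + rng.uniform(-0.0145, 0.0145, len(sample_ids))
    meta.insert(2, "latitude", lat)
    meta.insert(3, "longitude", lon)
    meta["sample_role"] = "sample"
    meta["replicate_of"] = ""

    # --- latent module activity -----------------------------------------
    n, M = len(sample_ids), config.n_modules
    zenv = np.column_stack(
        [
            (meta[v] - meta[v].mean()) / meta[v].std(ddof=1)
            for v in ENV_VARIABLES
        ]
    )
    beta = np.zeros((M, len(ENV_VARIABLES)))
    env_drivers: dict[int, dict[str, int]] = {}
    for m in range(M):
        vi = m % len(ENV_VARIABLES)
        sign = 1 if m % 2 == 0 else -1
        beta[m, vi] = sign * config.env_beta
        env_drivers[m + 1] = {ENV_VARIABLES[vi]: sign}
    sub_idx = np.array([substrates.index(sub_of[s]) for s in sample_ids])
    log_aff = np.log(
        np.maximum(config.module_substrate_affinity[:, sub_idx], 1e-12)
    )  # M x n
    delta = config.module_noise_sd * rng.standard_normal((M, n))
    log_activity = log_aff + beta @ zenv.T + delta  # M x n

    # --- ASV roster ------------------------------------------------------
    n_bac_m = int(round(config.asvs_per_module * config.bacterial_fraction))
    n_euk_m = config.asvs_per_module - n_bac_m
    module_of: dict[str, object] = {}
    hubs: set[str] = set()
    bac_ids, euk_ids = [], []
    for m in range(M):
        for k in range(n_bac_m):
            aid = f"bASV_m{m + 1:02d}_{k + 1:03d}"
            bac_ids.append(aid)
            module_of[aid] = m + 1
            if k < config.hub_per_module:
                hubs.add(aid)
        for k in range(n_euk_m):
            aid = f"eASV_m{m + 1:02d}_{k + 1:03d}"
            euk_ids.append(aid)
            module_of[aid] = m + 1
    n_bac_bg = int(round(config.n_background_asvs * config.bacterial_fraction))
    n_euk_bg = config.n_background_asvs - n_bac_bg
    for k in range(n_bac_bg):
        aid = f"bASV_bg_{k + 1:04d}"
        bac_ids.append(aid)
        module_of[aid] = "background"
    for k in range(n_euk_bg):
        aid = f"eASV_bg_{k + 1:04d}"
        euk_ids.append(aid)
        module_of[aid] = "background"
    decoy_ids = [f"bASV_org_{k + 1:02d}" for k in range(config.n_organelle_decoys)]
    for aid in decoy_ids:
        bac_ids.append(aid)
        module_of[aid] = "background"

    # --- expected abundances --------------------------------------------
    def expected_matrix(ids: list[str]) -> np.ndarray:
        mu = np.empty((n, len(ids)))
        for j, aid in enumerate(ids):
            baseline = float(np.exp(0.8 * rng.standard_normal()))
            if aid in hubs:
                baseline *= 3.0  # hubs are abundant, tightly coupled taxa
            mod = module_of[aid]
            if mod == "background":
                eps = config.background_noise_sd * rng.standard_normal(n)
                mu[:, j] = 0.5 * baseline * np.exp(eps)
            else:
                if aid in hubs:
                    sd = config.hub_noise_sd
                else:
                    # heterogeneous idiosyncratic noise: members span a
                    # range of coupling strengths to their module, so the
                    # low-noise hub tops the within-module degree ranking
                    sd = rng.uniform(*config.member_noise_range)
                eps = sd * rng.standard_normal(n)
                mu[:, j] = baseline * np.exp(log_activity[mod - 1] + eps)
        return mu

    mu_bac = expected_matrix(bac_ids)
    mu_euk = expected_matrix(euk_ids)

    # --- counts ----------------------------------------------------------
    lo, hi = config.depth_range

    def draw_table(mu: np.ndarray, ids: list[str]) -> pd.DataFrame:
        depths = rng.integers(lo, hi + 1, size=n)
        counts = np.vstack(
            [
                _draw_counts(rng, mu[j], int(depths[j]), config.dispersion)
                for j in range(n)
            ]
        )
        return pd.DataFrame(counts, index=sample_ids, columns=ids)

    bac_counts = draw_table(mu_bac, bac_ids)
    euk_counts = draw_table(mu_euk, euk_ids)

    # --- taxonomy ---------------------------------------------------------
    def lineage(aid: str) -> list[str]:
        if aid in decoy_ids:
            organelle = "Chloroplast" if int(aid[-2:]) % 3 else "Mitochondria"
            return ["Bacteria", "Cyanobacteriota", organelle,
                    organelle, f"{organelle}_sp"]
        if aid.startswith("b"):
            phylum = _BACTERIAL_PHYLA[rng.integers(len(_BACTERIAL_PHYLA))]
            dom = "Bacteria"
        else:
            phylum = _EUKARYOTE_DIVISIONS[rng.integers(len(_EUKARYOTE_DIVISIONS))]
            dom = "Eukaryota"
        genus = _GENERA[rng.integers(len(_GENERA))]
        return [dom, phylum, f"{phylum}_class", f"{genus}aceae", genus]

    tax = pd.DataFrame(
        {aid: lineage(aid) for aid in bac_ids + euk_ids},
        index=["domain", "phylum", "class", "family", "genus"],
    ).T

    # --- control samples --------------------------------------------------
    if config.include_controls:
        anchor = sample_ids[0]
        extra_meta = {}

        def add_sample(df, mu_row, sid, role, ref=""):
            depth = int(rng.integers(lo, hi + 1))
            counts = _draw_counts(rng, mu_row, depth, config.dispersion)
            df.loc[sid] = counts
            extra_meta[sid] = (role, ref)

        for df, mu, ids in ((bac_counts, mu_bac, bac_ids),
                            (euk_counts, mu_euk, euk_ids)):
            uniform = np.zeros(len(ids))
            uniform[rng.choice(len(ids), size=min(30, len(ids)), replace=False)] = 1.0
            add_sample(df, uniform * 0.5 + 1e-6, "BLANK1", "blank")
            add_sample(df, uniform * 0.5 + 1e-6, "BLANK2", "blank")
            mock = np.zeros(len(ids))
            mock[rng.choice(len(ids), size=min(20, len(ids)), replace=False)] = 1.0
            add_sample(df, mock + 1e-6, "MOCK1", "mock")
            # replicate re-draws the anchor sample's expected profile but is
            # forced below the anchor's library size so the anchor is kept
            rep_depth = int(bac_counts.loc[anchor].sum() if df is bac_counts
                            else euk_counts.loc[anchor].sum())
            rep = _draw_counts(rng, mu[0], max(lo, int(0.8 * rep_depth)),
                               config.dispersion)
            df.loc[f"{anchor}_rep"] = rep
            extra_meta[f"{anchor}_rep"] = ("replicate", anchor)
        for sid, (role, ref) in extra_meta.items():
            meta.loc[sid] = meta.loc[anchor]
            meta.loc[sid, "sample_role"] = role
            meta.loc[sid, "replicate_of"] = ref

    bacteria = AsvTable(
        bac_counts, pd.Series("bacteria", index=bac_ids), "raw_counts"
    )
    eukaryotes = AsvTable(
        euk_counts, pd.Series("eukaryote", index=euk_ids), "raw_counts"
    )
    truth = GroundTruth(
        module_of_asv=module_of,
        hub_asvs=hubs,
        env_drivers=env_drivers,
        substrate_of_sample=dict(sub_of),
    )
    return bacteria, eukaryotes, TaxonomyTable(tax), meta, truth


def write_dataset(config: SimulationConfig, outdir) -> dict:
    """Generate a dataset and write it as TSV + ground-truth JSON files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bac, euk, tax, meta, truth = generate_dataset(config)
    paths = {
        "bacteria": outdir / "bacteria.tsv",
        "eukaryotes": outdir / "eukaryotes.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "metadata": outdir / "metadata.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_asv_table(bac, paths["bacteria"])
    write_asv_table(euk, paths["eukaryotes"])
    write_taxonomy(tax, paths["taxonomy"])
    write_metadata(meta, paths["metadata"])
    truth.to_json(paths["ground_truth"])
    return {k: str(v) for k, v in paths.items()}
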