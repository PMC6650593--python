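"""Synthetic multi-site, multi-depth OTU + environment time series.

Emulates the processed layer the pipeline consumes: monthly samples from
several sites and depths, a few hundred prevalent OTUs (a small
cyanobacterial partition plus a non-cyanobacterial majority) and a panel of
environmental variables, with known ground truth: planted seasonal blooms,
lagged pairwise couplings, planted modules, and compositional (Dirichlet)
noise.  Every downstream stage — LSA, network construction, consensus
filtering, module detection, bloom labeling, function collapse — is
testable against the ground truth without any download.

Model per (site, depth) series
------------------------------
Latent log-abundance of OTU i in module m at month t:

    z_i(t) = b_i + sqrt(w) * g_m(t) + sqrt(1 - w) * h_i(t) + eps_i(t)

where ``w`` is the within-module coupling (shared-driver variance share),
``g_m`` a module-level seasonal driver, ``h_i`` a smooth OTU-specific AR(1)
process and ``eps`` white noise.  Module drivers are annual-harmonic
sinusoids (period 12/k months) taken in frequency/quadrature pairs so that
distinct module drivers are mutually near-orthogonal over the sampled
window; the designated bloom module additionally carries a summer pulse.
Planted pairwise couplings override the partner series with a lagged,
signed copy of its mate, so each planted edge is an unambiguous pairwise
signal.  Latents are exponentiated and closed to compositions, then
resampled Dirichlet-style with a configurable concentration.  Chl-a is an
affine function of the bloom OTU share, so bloom labeling is exercisable
end to end.  Spurious couplings are planted in exactly one (site, depth)
set, so the recurrence filter provably removes them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    CYANOBACTERIAL,
    ENVIRONMENTAL,
    NON_CYANOBACTERIAL,
    AbundanceTable,
    SampleKey,
    TaxonomyMap,
    ValidationError,
    write_abundance_table,
)

__all__ = ["GeneratorConfig", "GroundTruth", "generate_dataset", "write_fixture"]

_ENV_NAMES = (
    "chl_a", "temperature", "pH", "DO", "TN", "TDN", "TP", "TDP",
    "precipitation", "discharge", "turbidity",
)

_CYANO_GENERA = ("Microcystis", "Pseudanabaena", "Aphanizomenon", "Dolichospermum")
_OTHER_GENERA = (
    "Herbaspirillum", "Roseomonas", "Flavobacterium", "Sporichthya",
    "Methylophilus", "Rhodobacter", "Nitrosomonas", "Polynucleobacter",
    "Limnohabitans", "Sediminibacterium", "Phenylobacterium", "Paucimonas",
)
_OTHER_PHYLA = ("Proteobacteria", "Bacteroidetes", "Actinobacteria")


@dataclass
class GeneratorConfig:
    """Knobs of the generator; defaults mirror the 15-month, 3-site, 2-depth study design."""

    n_sites: int = 3
    n_depths: int = 2
    n_months: int = 15
    n_otus: int = 200
    n_env: int = 11
    n_modules: int = 5
    n_cyano_otus: int = 8
    within_module_coupling: float = 0.6
    planted_edges_per_module: int = 5
    n_spurious_edges: int = 10
    lag_fraction: float = 0.2
    negative_edge_fraction: float = 0.25
    noise_sd: float = 0.3
    base_log_sd: float = 1.5  # spread of per-OTU baseline log abundance
    dirichlet_concentration: float = 500.0
    bloom_otu_peak_fraction: float = 0.4
    missing_month_fraction: float = 0.2
    start_month: str = "2016-06"
    seed: int = 0

    def validate(self) -> None:
        counts = (self.n_sites, self.n_depths, self.n_months, self.n_otus,
                  self.n_env, self.n_modules)
        if any(c <= 0 for c in counts):
            raise ValidationError("all counts must be positive")
        if self.n_modules > self.n_otus:
            raise ValidationError("n_modules cannot exceed n_otus")
        if not 0 <= self.within_module_coupling <= 1:
            raise ValidationError("within_module_coupling must be in [0, 1]")
        if not 0 < self.bloom_otu_peak_fraction < 1:
            raise ValidationError("bloom_otu_peak_fraction must be in (0, 1)")
        if not 0 <= self.missing_month_fraction < 1:
            raise ValidationError("missing_month_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.dirichlet_concentration <= 0:
            raise ValidationError("dirichlet_concentration must be positive")
        if self.n_env > len(_ENV_NAMES):
            raise ValidationError(f"n_env supports at most {len(_ENV_NAMES)}")


@dataclass
class GroundTruth:
    """Planted structure of one generated dataset."""

    planted_edges: list[tuple[str, str, str, int]]  # (a, b, sign, delay)
    spurious_edges: list[tuple[str, str, str, int]]
    planted_modules: dict[str, int]
    bloom_months: list[SampleKey]
    generator_config: GeneratorConfig
    taxonomy: TaxonomyMap
    latent: dict[tuple[str, float], pd.DataFrame] = field(default_factory=dict)


def _module_driver(m: int, t: np.ndarray, bloom_pulse: np.ndarray) -> np.ndarray:
    """Annual harmonic (period 12/k) in quadrature pairs; module 0 carries the bloom pulse."""
    k = m // 2 + 1
    phase = 0.0 if m % 2 == 0 else np.pi / 2.0
    g = np.sin(2.0 * np.pi * k * t / 12.0 + phase)
    if m == 0:
        g = g + bloom_pulse
    g = g - g.mean()
    sd = g.std()
    return g / sd if sd > 0 else g


def _ar1(rng: np.random.Generator, n: int, phi: float = 0.6) -> np.ndarray:
    x = np.empty(n)
    x[0] = rng.normal()
    innov_sd = np.sqrt(1.0 - phi * phi)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + innov_sd * rng.normal()
    return x


def _lagged_copy(z: np.ndarray, delay: int, sign: int) -> np.ndarray:
    """Partner series: signed copy of its mate shifted by ``delay`` months (edge-held)."""
    n = z.size
    idx = np.clip(np.arange(n) - delay, 0, n - 1)
    return sign * z[idx]


def generate_dataset(config: GeneratorConfig) -> tuple[AbundanceTable, GroundTruth]:
    """Generate the full dataset; bit-identical output for a fixed seed."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    T = cfg.n_months
    months = pd.period_range(cfg.start_month, periods=T, freq="M")
    t = np.arange(T, dtype=float)
    summer = np.array([m.month in (6, 7, 8) for m in months])
    bloom_pulse = 2.0 * summer.astype(float)

    otu_ids = [f"OTU{i + 1:05d}" for i in range(cfg.n_otus)]
    cyano = set(otu_ids[: cfg.n_cyano_otus])
    bloom_otu = otu_ids[0]

    # planted module memberships: round-robin so every module gets members
    modules = {otu: i % cfg.n_modules for i, otu in enumerate(otu_ids)}
    modules[bloom_otu] = 0

    taxonomy = _make_taxonomy(rng, otu_ids, cyano)

    # planted couplings: a disjoint matching within each module
    planted, spurious = _plant_edges(rng, cfg, otu_ids, modules)
    partner_of = {b: (a, s, d) for a, b, s, d in planted}

    base = rng.normal(0.0, cfg.base_log_sd, size=cfg.n_otus)  # log-scale rank-abundance
    drivers = np.vstack(
        [_module_driver(m, t, bloom_pulse) for m in range(cfg.n_modules)]
    )

    w = cfg.within_module_coupling
    rows, keys = [], []
    bloom_months: list[SampleKey] = []
    latent_store: dict[tuple[str, float], pd.DataFrame] = {}
    spurious_set_assigned = False

    site_names = [f"S{i + 1}" for i in range(cfg.n_sites)]
    depths = [2.0 * i for i in range(cfg.n_depths)]  # 0 m, 2 m, ...
    set_index = 0
    for site in site_names:
        for depth in depths:
            Z = np.empty((cfg.n_otus, T))
            for i, otu in enumerate(otu_ids):
                m = modules[otu]
                h = _ar1(rng, T)
                eps = rng.normal(0.0, cfg.noise_sd, size=T)
                Z[i] = np.sqrt(w) * drivers[m] + np.sqrt(1.0 - w) * h + eps
            # planted pairwise couplings: partner mirrors its mate
            for b, (a, s, d) in partner_of.items():
                ia, ib = otu_ids.index(a), otu_ids.index(b)
                Z[ib] = _lagged_copy(Z[ia], d, +1 if s == "+" else -1) \
                    + rng.normal(0.0, cfg.noise_sd, size=T)
            # spurious couplings live in exactly the first series set
            if set_index == 0:
                for a, b, s, d in spurious:
                    ia, ib = otu_ids.index(a), otu_ids.index(b)
                    Z[ib] = _lagged_copy(Z[ia], d, +1 if s == "+" else -1) \
                        + rng.normal(0.0, cfg.noise_sd, size=T)
                spurious_set_assigned = True
            latent_store[(site, depth)] = pd.DataFrame(
                Z, index=otu_ids, columns=[str(m) for m in months]
            )

            raw = np.exp(Z + base[:, None])
            props = raw / raw.sum(axis=0, keepdims=True)
            # force the bloom OTU to its target share in summer months
            ib = otu_ids.index(bloom_otu)
            for k in np.flatnonzero(summer):
                others = props[:, k].sum() - props[ib, k]
                target = cfg.bloom_otu_peak_fraction
                props[ib, k] = target / (1.0 - target) * others
                props[:, k] /= props[:, k].sum()

            # Dirichlet closure noise
            comp = np.empty_like(props)
            for k in range(T):
                alpha = cfg.dirichlet_concentration * props[:, k]
                comp[:, k] = rng.dirichlet(np.maximum(alpha, 1e-8))

            env = _environment(rng, cfg, months, comp[ib])

            # mask missing months (keep at least the two endpoints)
            drop = rng.random(T) < cfg.missing_month_fraction
            drop[0] = drop[-1] = False
            for k in range(T):
                if drop[k]:
                    continue
                key = SampleKey(site, depth, str(months[k]))
                keys.append(key)
                rows.append(np.concatenate([comp[:, k], env[:, k]]))
                chl = env[0, k] if cfg.n_env >= 1 else np.inf
                if comp[ib, k] > 0.10 and chl > 15.0:
                    bloom_months.append(key)
            set_index += 1

    env_names = list(_ENV_NAMES[: cfg.n_env])
    columns = otu_ids + env_names
    data = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(keys, names=("site", "depth", "date")),
        columns=columns,
    )
    classes = {o: (CYANOBACTERIAL if o in cyano else NON_CYANOBACTERIAL) for o in otu_ids}
    classes.update({e: ENVIRONMENTAL for e in env_names})
    table = AbundanceTable(data, pd.Series(classes, dtype=object))

    if spurious and not spurious_set_assigned:  # pragma: no cover
        warnings.warn("no series set received the spurious couplings")
    truth = GroundTruth(
        planted_edges=planted,
        spurious_edges=spurious,
        planted_modules=modules,
        bloom_months=bloom_months,
        generator_config=cfg,
        taxonomy=taxonomy,
        latent=latent_store,
    )
    return table, truth


def _plant_edges(rng, cfg, otu_ids, modules):
    """Disjoint within-module pairs (planted) plus cross-module pairs (spurious)."""
    by_module: dict[int, list[str]] = {}
    for otu in otu_ids:
        by_module.setdefault(modules[otu], []).append(otu)
    planted = []
    used: set[str] = set()
    for m, members in sorted(by_module.items()):
        pool = [o for o in members if o not in used]
        rng.shuffle(pool)
        n_pairs = min(cfg.planted_edges_per_module, len(pool) // 2)
        for k in range(n_pairs):
            a, b = pool[2 * k], pool[2 * k + 1]
            sign = "+" if rng.random() > cfg.negative_edge_fraction else "-"
            delay = 0
            if rng.random() < cfg.lag_fraction:
                delay = int(rng.choice([-1, 1]))
            planted.append((a, b, sign, delay))
            used.update((a, b))
    spurious = []
    free = [o for o in otu_ids if o not in used]
    rng.shuffle(free)
    n_sp = min(cfg.n_spurious_edges, len(free) // 2)
    for k in range(n_sp):
        a, b = free[2 * k], free[2 * k + 1]
        if modules[a] == modules[b]:  # prefer cross-module, but not required
            pass
        spurious.append((a, b, "+", 0))
    return planted, spurious


def _environment(rng, cfg, months, bloom_share):
    """Environmental panel; chl-a is affine in the bloom OTU share."""
    T = len(months)
    t = np.arange(T, dtype=float)
    month_no = np.array([m.month for m in months], dtype=float)
    annual = np.sin(2.0 * np.pi * (month_no - 4.0) / 12.0)  # peak in July
    env = np.zeros((cfg.n_env, T))
    specs = {
        "chl_a": np.clip(2.0 + 40.0 * bloom_share + rng.normal(0, 0.5, T), 0.05, None),
        "temperature": 15.0 + 10.0 * annual + rng.normal(0, 1.0, T),
        "pH": 7.8 + 0.3 * annual + rng.normal(0, 0.1, T),
        "DO": 9.0 - 2.0 * annual + rng.normal(0, 0.5, T),
        "TN": np.exp(0.8 - 0.2 * annual + rng.normal(0, 0.2, T)),
        "TDN": np.exp(0.5 - 0.2 * annual + rng.normal(0, 0.2, T)),
        "TP": np.exp(-2.5 + 0.3 * annual + rng.normal(0, 0.2, T)),
        "TDP": np.exp(-3.0 + 0.3 * annual + rng.normal(0, 0.2, T)),
        "precipitation": np.exp(3.5 + 1.0 * annual + rng.normal(0, 0.5, T)),
        "discharge": np.exp(5.0 + 0.8 * annual + rng.normal(0, 0.5, T)),
        "turbidity": np.exp(1.5 + 0.5 * annual + rng.normal(0, 0.3, T)),
    }
    for i, name in enumerate(_ENV_NAMES[: cfg.n_env]):
        env[i] = specs[name]
    return env


def _make_taxonomy(rng, otu_ids, cyano):
    lineages = {}
    for otu in otu_ids:
        if otu in cyano:
            genus = _CYANO_GENERA[rng.integers(len(_CYANO_GENERA))]
            lineages[otu] = ("Bacteria", "Cyanobacteria", "Cyanophyceae",
                             "Nostocales", "Microcystaceae", genus)
        else:
            genus = _OTHER_GENERA[rng.integers(len(_OTHER_GENERA))]
            phylum = _OTHER_PHYLA[rng.integers(len(_OTHER_PHYLA))]
            lineages[otu] = ("Bacteria", phylum, f"{phylum}_class",
                             f"{phylum}_order", f"{genus}aceae", genus)
    return TaxonomyMap(lineages)


def write_fixture(dataset: tuple[AbundanceTable, GroundTruth], directory) -> list[Path]:
    """Write abundance, metadata, ground-truth edge and module-map TSVs.

    File contents are deterministic given the generator seed.  Returns the
    paths written (the four spec'd files plus a taxonomy table).
    """
    table, truth = dataset
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []

    p = directory / "abundance.tsv"
    write_abundance_table(table, p)
    paths.append(p)

    p = directory / "metadata.tsv"
    meta = pd.DataFrame(table.samples, columns=["site", "depth", "date"])
    meta.to_csv(p, sep="\t", index=False)
    paths.append(p)

    p = directory / "ground_truth_edges.tsv"
    rows = [(a, b, s, d, "planted") for a, b, s, d in truth.planted_edges]
    rows += [(a, b, s, d, "spurious") for a, b, s, d in truth.spurious_edges]
    pd.DataFrame(rows, columns=["feature_a", "feature_b", "sign", "delay", "kind"]) \
        .to_csv(p, sep="\t", index=False)
    paths.append(p)

    p = directory / "modules.tsv"
    pd.DataFrame(
        sorted(truth.planted_modules.items()), columns=["feature", "module"]
    ).to_csv(p, sep="\t", index=False)
    paths.append(p)

    p = directory / "taxonomy.tsv"
    pd.DataFrame(
        [(o, ";".join(l)) for o, l in sorted(truth.taxonomy.lineages.items())],
        columns=["otu_id", "lineage"],
    ).to_csv(p, sep="\t", index=False)
    paths.append(p)
    return paths
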