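"""Synthetic tumor-microbiome cohorts with planted, recoverable structure.

Real 16S data for the benign-polyp (BP) / tumor-stage (T1-T4) design this
package analyses are not publicly deposited, so this module generates
cohorts that carry the same statistical structure the downstream analyses
assume, together with the ground truth needed for parameter-recovery tests:

* group sizes, an age range with a mild age-by-stage gradient (the
  confounder the staging classifier must remove), and a male-skewed sex
  ratio;
* a log-normal baseline community dominated in expectation by Firmicutes,
  Bacteroidota and Proteobacteria;
* **age taxa** whose log relative abundance drifts linearly with host age;
* **stage taxa** with either monotone log2 fold-changes across T1→T4 or a
  single-stage spike;
* **driver taxa** that acquire a shared latent factor — hence positive
  pairwise co-occurrence — in the case group only (BP→T1 network rewiring);
* background co-occurrence *modules* (latent factors shared by blocks of
  taxa in every sample) so that per-group association networks have
  non-trivial topology rather than being edgeless;
* Dirichlet-multinomial count noise around per-sample compositions, with
  library sizes drawn from a truncated normal.

All randomness flows from a single seed through spawned generators, so a
cohort is reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .prep import GROUPS, STAGES, taxonomy_frame

# (phylum, expected mass share, richness share); the first three hold ~75%
# of community mass, mirroring the dominance structure of the human gut.
PHYLA = (
    ("Firmicutes", 0.40, 0.40),
    ("Bacteroidota", 0.22, 0.22),
    ("Proteobacteria", 0.13, 0.13),
    ("Actinobacteriota", 0.08, 0.08),
    ("Fusobacteriota", 0.05, 0.05),
    ("Verrucomicrobiota", 0.04, 0.04),
    ("Desulfobacterota", 0.03, 0.03),
    ("Campilobacterota", 0.03, 0.03),
    ("Patescibacteria", 0.02, 0.02),
)

DEFAULT_N_PER_GROUP = {"BP": 45, "T1": 9, "T2": 13, "T3": 22, "T4": 6}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate the study design the package targets: 95 subjects
    (45 BP; 9/13/22/6 across T1-T4), ages 21-89 with 70 males, ~81,710 ±
    47,466 raw reads per sample and a rarefaction depth of 14,221.
    """

    n_per_group: dict = field(default_factory=lambda: dict(DEFAULT_N_PER_GROUP))
    n_taxa: int = 2000
    age_range: tuple = (21, 89)
    male_fraction: float = 70 / 95
    n_age_taxa: int = 9
    n_stage_taxa: int = 15
    n_driver_taxa: int = 13
    stage_effect: float = 2.0      # log2 fold-change magnitude
    age_effect: float = 0.06       # log-abundance slope per year
    rewire_strength: float = 0.8   # latent-factor loading in the case group
    depth_mean: float = 81710.0
    depth_sd: float = 47466.0
    rarefy_depth: int = 14221
    overdispersion: float = 100.0  # per-taxon Dirichlet concentration scale
    baseline_sigma: float = 1.5    # log-normal spread of baseline abundances
    log_noise_sd: float = 0.8      # per-taxon, per-sample log-scale noise
    n_modules: int = 8             # background co-occurrence modules
    module_loading: float = 0.9    # correlation-scale loading within a module
    module_fraction: float = 0.7   # fraction of taxa belonging to a module
    age_stage_gap: float = 4.0     # mean-age increment per successive group
    case_group: str = "T1"         # group in which driver taxa are rewired
    seed: int = 0

    def validate(self) -> None:
        errs = []
        if set(self.n_per_group) != set(GROUPS):
            errs.append(f"n_per_group must have keys {GROUPS}")
        elif any(int(v) <= 0 for v in self.n_per_group.values()):
            errs.append("all group sizes must be > 0")
        if self.n_taxa <= 0:
            errs.append("n_taxa must be > 0")
        planted = self.n_age_taxa + self.n_stage_taxa + self.n_driver_taxa
        if planted > self.n_taxa:
            errs.append("planted taxa exceed n_taxa")
        if min(self.n_age_taxa, self.n_stage_taxa, self.n_driver_taxa) < 0:
            errs.append("planted taxon counts must be >= 0")
        lo, hi = self.age_range
        if not lo < hi:
            errs.append("age_range min must be < max")
        if not 0 <= self.male_fraction <= 1:
            errs.append("male_fraction must be in [0,1]")
        if not 0 <= self.rewire_strength <= 1:
            errs.append("rewire_strength must be in [0,1]")
        if not 0 <= self.module_loading < 1:
            errs.append("module_loading must be in [0,1)")
        if not 0 <= self.module_fraction <= 1:
            errs.append("module_fraction must be in [0,1]")
        if self.rarefy_depth <= 0 or self.depth_mean <= 0:
            errs.append("depths must be > 0")
        if self.overdispersion <= 0:
            errs.append("overdispersion must be > 0")
        if self.case_group not in GROUPS:
            errs.append(f"case_group must be one of {GROUPS}")
        if errs:
            raise ConfigurationError(errs)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class GroundTruth:
    """Which taxa carry each planted effect (the three sets are disjoint)."""

    age_taxa: frozenset
    stage_taxa: dict          # taxon id -> {group: log2 fold-change}
    driver_taxa: frozenset

    def to_dict(self) -> dict:
        return {
            "age_taxa": sorted(self.age_taxa),
            "stage_taxa": {t: fc for t, fc in sorted(self.stage_taxa.items())},
            "driver_taxa": sorted(self.driver_taxa),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            age_taxa=frozenset(d["age_taxa"]),
            stage_taxa={t: dict(fc) for t, fc in d["stage_taxa"].items()},
            driver_taxa=frozenset(d["driver_taxa"]),
        )


# ---------------------------------------------------------------------------
# planted-effect operations (act on a samples x taxa log-abundance profile)


def plant_age_effect(profile: pd.DataFrame, metadata: pd.DataFrame, taxa,
                     slope: float) -> pd.DataFrame:
    """Shift planted taxa's log abundance linearly with centred host age.

    Each planted taxon gains ``slope * (age - mean age)``; all other taxa are
    untouched.  With slope 0 the output equals the input.
    """
    taxa = list(taxa)
    missing = [t for t in taxa if t not in profile.columns]
    if missing:
        raise InputError(f"unknown taxa in age planting: {missing}")
    out = profile.copy()
    centred = (metadata["age"] - metadata["age"].mean()).reindex(profile.index)
    out.loc[:, taxa] = out.loc[:, taxa].add(slope * centred, axis=0)
    return out


def plant_network_rewiring(profile: pd.DataFrame, metadata: pd.DataFrame, taxa,
                           strength: float, case_group: str = "T1",
                           seed=None) -> pd.DataFrame:
    """Induce a shared latent factor among planted taxa in the case group.

    Within case-group samples each planted taxon's deviation from its own
    case-group mean is replaced by ``sqrt(s) * h_i + sqrt(1-s) * z_i`` with
    ``s = strength``, where ``z_i`` is the taxon's original standardized
    deviation and ``h`` is a latent Gaussian field over the planted taxa
    arranged on a ring, with correlation decaying smoothly with ring
    distance (``corr(h_i, h_j) = exp(-(d_ij / beta)^2)``, ``beta`` half the
    ring size).  Marginal means and variances are preserved; every planted
    pair acquires positive log-scale correlation ``strength *
    corr(h_i, h_j)`` in the case group only, strongest between ring
    neighbors.  The decay matters downstream: thresholding associations
    then yields an incomplete (lattice-like) subgraph in which rewired taxa
    genuinely gain intermediation, rather than a complete clique whose
    internal betweenness is identically zero.
    """
    if not 0 <= strength <= 1:
        raise InputError("rewiring strength must be in [0,1]")
    taxa = list(taxa)
    missing = [t for t in taxa if t not in profile.columns]
    if missing:
        raise InputError(f"unknown taxa in rewiring: {missing}")
    out = profile.copy()
    if strength == 0 or not taxa:
        return out
    case = metadata.index[metadata["group"] == case_group]
    case = case.intersection(profile.index)
    if len(case) < 2:
        return out
    rng = np.random.default_rng(seed)
    k = len(taxa)
    pos = np.arange(k)
    ring_d = np.minimum(np.abs(pos[:, None] - pos[None, :]),
                        k - np.abs(pos[:, None] - pos[None, :]))
    beta = max(2.0, 0.75 * k)
    corr = np.exp(-((ring_d / beta) ** 2))
    # wrapped RBF need not be PD; clip spectrum and renormalize to unit variance
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, 0.0, None)
    factor = v * np.sqrt(w)
    factor /= np.sqrt((factor**2).sum(axis=1, keepdims=True))
    h = rng.standard_normal((len(case), k)) @ factor.T
    # per-column standardization: exact preservation of case-group means and
    # variances (column scaling leaves pairwise correlations unchanged)
    h -= h.mean(axis=0)
    h /= np.where(h.std(axis=0) > 0, h.std(axis=0), 1.0)
    block = out.loc[case, taxa]
    mu = block.mean(axis=0)
    sd = block.std(axis=0, ddof=0).replace(0.0, 1.0)
    z = (block - mu) / sd
    rewired = mu + sd * (np.sqrt(strength) * h + np.sqrt(1 - strength) * z)
    out.loc[case, taxa] = rewired
    return out


# ---------------------------------------------------------------------------
# cohort generation


def _make_metadata(config: SimulationConfig, rng) -> pd.DataFrame:
    lo, hi = config.age_range
    rows = []
    centre = (lo + hi) / 2
    sd = (hi - lo) / 5
    k = 0
    for gi, group in enumerate(GROUPS):
        n = int(config.n_per_group[group])
        mean_age = centre + config.age_stage_gap * (gi - 2)
        for _ in range(n):
            age = int(np.clip(np.round(rng.normal(mean_age, sd)), lo, hi))
            gender = "male" if rng.random() < config.male_fraction else "female"
            rows.append((f"S{k:03d}", group, age, gender))
            k += 1
    meta = pd.DataFrame(rows, columns=["sample_id", "group", "age", "gender"])
    return meta.set_index("sample_id")


def _make_taxonomy(config: SimulationConfig, rng) -> tuple[pd.DataFrame, np.ndarray]:
    """Assign phyla (weighted by richness share) and synthetic lineages.

    Returns the taxonomy frame and the per-taxon phylum index.
    """
    names = [p[0] for p in PHYLA]
    richness = np.array([p[2] for p in PHYLA])
    phylum_idx = rng.choice(len(PHYLA), size=config.n_taxa, p=richness / richness.sum())
    lineages = []
    for t in range(config.n_taxa):
        p = names[phylum_idx[t]]
        abbr = p[:4]
        cls = f"{abbr}_c{rng.integers(1, 4)}"
        order = f"{abbr}_o{rng.integers(1, 6)}"
        fam = f"{abbr}_f{rng.integers(1, 10)}"
        genus = f"{abbr}_g{rng.integers(1, 30)}" if rng.random() > 0.12 else ""
        species = f"{genus}_sp{rng.integers(1, 5)}" if genus and rng.random() > 0.4 else ""
        lineages.append(
            f"d__Bacteria;p__{p};c__{cls};o__{order};f__{fam};g__{genus};s__{species}"
        )
    ids = [f"ASV{t + 1}" for t in range(config.n_taxa)]
    tax = taxonomy_frame(pd.Series(lineages, index=ids))
    return tax, phylum_idx


def _baseline_profile(config: SimulationConfig, phylum_idx, rng) -> np.ndarray:
    """Log-normal baseline abundances rescaled to target phylum mass shares."""
    base = rng.lognormal(mean=0.0, sigma=config.baseline_sigma, size=config.n_taxa)
    mass = np.array([p[1] for p in PHYLA])
    for i in range(len(PHYLA)):
        sel = phylum_idx == i
        total = base[sel].sum()
        if total > 0:
            base[sel] *= mass[i] / total
    return base / base.sum()


def generate_cohort(config: SimulationConfig):
    """Generate ``(counts, metadata, taxonomy, ground_truth)``.

    Counts are raw (pre-rarefaction) integer reads, samples x taxa; each
    sample's total equals its drawn library size.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    r_meta, r_tax, r_base, r_noise, r_counts, r_rewire = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    metadata = _make_metadata(config, r_meta)
    taxonomy, phylum_idx = _make_taxonomy(config, r_tax)
    taxa = taxonomy.index
    n_samples, n_taxa = len(metadata), config.n_taxa

    baseline = _baseline_profile(config, phylum_idx, r_base)

    # planted-taxon assignment: disjoint draw without replacement from the
    # top abundance quartile of the baseline, so planted effects act on taxa
    # that remain observable after rarefaction (as the real discriminatory
    # and driver taxa were; planting in the rare tail buries the signal in
    # count noise)
    n_planted = config.n_age_taxa + config.n_stage_taxa + config.n_driver_taxa
    by_abundance = np.argsort(baseline)[::-1]
    pool = by_abundance[: max(n_planted, n_taxa // 4)]
    planted = r_base.choice(pool, size=n_planted, replace=False)
    driver_pos = planted[: config.n_driver_taxa]
    rest = planted[config.n_driver_taxa:]
    age_ids = frozenset(taxa[rest[: config.n_age_taxa]])
    stage_pos = rest[config.n_age_taxa:]
    driver_ids = frozenset(taxa[driver_pos])

    # background modules: latent factors shared by blocks of taxa in every
    # sample; driver taxa stay module-free so their case-only factor is the
    # sole source of their co-occurrence.
    module_of = np.full(n_taxa, -1)
    eligible = np.setdiff1d(np.arange(n_taxa), driver_pos)
    in_module = eligible[r_noise.random(len(eligible)) < config.module_fraction]
    if config.n_modules > 0 and len(in_module):
        module_of[in_module] = r_noise.integers(0, config.n_modules, len(in_module))

    a = config.module_loading
    eps = r_noise.standard_normal((n_samples, n_taxa))
    z = eps.copy()
    if config.n_modules > 0:
        factors = r_noise.standard_normal((n_samples, config.n_modules))
        for m in range(config.n_modules):
            sel = module_of == m
            if sel.any():
                z[:, sel] = a * factors[:, [m]] + np.sqrt(1 - a**2) * eps[:, sel]

    log_abund = pd.DataFrame(
        np.log(baseline) + config.log_noise_sd * z,
        index=metadata.index, columns=taxa,
    )

    # age effect
    log_abund = plant_age_effect(log_abund, metadata, age_ids, config.age_effect)

    # stage effects: half monotone across T1..T4, half single-stage spikes
    stage_fc: dict = {}
    groups = metadata["group"].to_numpy()
    for j, pos in enumerate(stage_pos):
        sign = 1.0 if r_base.random() < 0.5 else -1.0
        fc = {g: 0.0 for g in GROUPS}
        if j < config.n_stage_taxa // 2:
            for k, g in enumerate(STAGES, start=1):
                fc[g] = sign * config.stage_effect * k / 4
        else:
            spike = STAGES[int(r_base.integers(0, len(STAGES)))]
            fc[spike] = sign * config.stage_effect
        stage_fc[taxa[pos]] = fc
        shift = np.array([fc[g] for g in groups]) * np.log(2)
        log_abund.iloc[:, pos] += shift

    # BP->case network rewiring of driver taxa
    log_abund = plant_network_rewiring(
        log_abund, metadata, driver_ids, config.rewire_strength,
        case_group=config.case_group, seed=r_rewire,
    )

    # compositions -> Dirichlet-multinomial counts
    logits = log_abund.to_numpy()
    logits -= logits.max(axis=1, keepdims=True)
    props = np.exp(logits)
    props /= props.sum(axis=1, keepdims=True)

    floor = 2 * config.rarefy_depth
    depths = np.maximum(
        floor, np.round(r_counts.normal(config.depth_mean, config.depth_sd, n_samples))
    ).astype(np.int64)

    # concentration scales with richness so per-taxon technical noise does
    # not depend on n_taxa: alpha_t ~= overdispersion on average
    concentration = config.overdispersion * n_taxa
    counts = np.empty((n_samples, n_taxa), dtype=np.int64)
    for i in range(n_samples):
        q = r_counts.dirichlet(concentration * props[i] + 1e-9)
        counts[i] = r_counts.multinomial(depths[i], q)

    counts = pd.DataFrame(counts, index=metadata.index, columns=taxa)
    truth = GroundTruth(age_taxa=age_ids, stage_taxa=stage_fc,
                        driver_taxa=driver_ids)
    return counts, metadata, taxonomy, truth


def write_cohort(outdir, counts, metadata, taxonomy, truth: GroundTruth,
                 config: SimulationConfig) -> None:
    """Write the cohort tables plus ground truth / config (with hash) JSON."""
    from .prep import write_tables

    outdir = Path(outdir)
    write_tables(outdir, counts, metadata, taxonomy)
    payload = {
        "config": dataclasses.asdict(config),
        "config_hash": config.hash(),
        "ground_truth": truth.to_dict(),
    }
    payload["config"]["age_range"] = list(config.age_range)
    (outdir / "ground_truth.json").write_text(json.dumps(payload, indent=2))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth.from_dict(payload["ground_truth"])
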