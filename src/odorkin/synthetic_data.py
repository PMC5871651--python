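"""Synthetic colonies and odor-profile data with plantable structure.

The generator emulates the structure of a cross-sectional skin-swab
GC-MS study of a provisioned macaque colony: ~60 adults with a strongly
female-biased sex ratio (52 F : 8 M), five social groups, one to five
swab samples per individual (about 2.2 on average, ~132 samples in
total), 21 endogenous compounds plus a set of contaminant compounds
that also appear in blank controls, and a pedigree planted with known
numbers of maternal and paternal half-sibling dyads.

Abundances follow a log-normal model with detection censoring: each
compound has a latent per-sample log-abundance assembled from a
compound baseline, compound-specific sex / group / maternal-family
effects, compound-specific age and rank slopes, an individual
deviation, and per-sample residual noise; areas are exp(latent) with
values below a detection threshold set to zero. The censoring produces
the zero-inflated presence pattern seen in real swab data (most samples
show only a subset of the compounds) without modeling chromatography.

The maternal-family effect is attached to the mother id, deliberately
mixing shared-environment and shared-gene similarity the way maternal
kin resemblance does in a female-philopatric species; there is no
separate additive-genetic term.

All randomness flows from one master seed through named substreams so
the colony, the profiles and downstream permutation tests are each
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .pedigree import PedigreeTable
from .profile_io import IndividualMetadata, PeakTable

__all__ = ["SimulationConfig", "simulate_colony", "simulate_profiles", "simulate_study"]


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Generator settings; defaults emulate the study colony."""

    n_individuals: int = 60
    n_females: int = 52
    n_groups: int = 5
    female_age_range: tuple[float, float] = (6.0, 21.0)
    male_age_range: tuple[float, float] = (6.0, 11.0)
    # P(1..5 samples); mean 2.25 -> ~135 samples for 60 individuals
    samples_per_individual_probs: tuple[float, ...] = (0.20, 0.50, 0.20, 0.05, 0.05)
    n_compounds_endogenous: int = 21
    n_compounds_contaminant: int = 10
    n_blanks: int = 5
    # effect sizes on the log-abundance scale
    baseline_mean: float = 0.9
    baseline_sd: float = 1.5
    sex_sd: float = 1.0
    group_sd: float = 0.5
    maternal_family_sd: float = 1.0
    individual_sd: float = 1.0
    residual_sd: float = 0.5
    age_slope_sd: float = 0.3
    rank_slope_sd: float = 0.3
    n_shared_mother_pairs: int = 6
    n_shared_father_pairs: int = 26
    detection_threshold: float = 1.0
    contaminant_log_mean: float = 1.0
    contaminant_log_sd: float = 0.5
    # contaminants appear in blanks at similar-or-higher concentration;
    # the boost (log-scale shift) keeps the planted truth unambiguous
    contaminant_blank_boost: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.n_females <= self.n_individuals:
            raise ConfigError("n_females must be in (0, n_individuals]")
        for name in ("baseline_sd", "sex_sd", "group_sd", "maternal_family_sd",
                     "individual_sd", "residual_sd", "age_slope_sd", "rank_slope_sd",
                     "contaminant_log_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        probs = np.asarray(self.samples_per_individual_probs)
        if probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
            raise ConfigError("samples_per_individual_probs must be a probability vector")
        if self.n_groups < 1 or self.n_compounds_endogenous < 1:
            raise ConfigError("counts must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(cfg_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg_seed, spawn_key=(stream,)))


def _sibship_sizes(n_pairs: int, max_size: int = 6) -> list[int]:
    """Decompose a dyad count into sibship sizes, greedily by C(s,2)."""
    sizes: list[int] = []
    remaining = n_pairs
    while remaining > 0:
        for s in range(max_size, 1, -1):
            pairs = s * (s - 1) // 2
            if pairs <= remaining:
                sizes.append(s)
                remaining -= pairs
                break
    return sizes


def simulate_colony(cfg: SimulationConfig) -> tuple[IndividualMetadata, PedigreeTable]:
    """Draw a colony: metadata (with sample map) and a planted pedigree.

    Maternal sibships are placed among females only (as in the study);
    paternal sibships among the remaining individuals. Members of a
    sibship get unique parents on the other side, and all other parents
    are unique, so the planted half-sib dyad counts are exactly the
    configured values and no distant relatives arise by accident.
    """
    cfg.validate()
    rng = _rng(cfg.seed, 0)

    n = cfg.n_individuals
    ids = [f"ind{i:03d}" for i in range(n)]
    sexes = np.array(["F"] * cfg.n_females + ["M"] * (n - cfg.n_females))
    groups = np.array([f"G{k % cfg.n_groups}" for k in range(n)])
    rng.shuffle(groups)

    ages = np.empty(n)
    for i in range(n):
        lo, hi = cfg.female_age_range if sexes[i] == "F" else cfg.male_age_range
        ages[i] = rng.uniform(lo, hi)
    ranks = np.where(sexes == "F", rng.uniform(0, 1, n), np.nan)

    # mothers contribute at most two offspring (as in the emulated colony);
    # fathers may sire larger sibships
    mat_sizes = _sibship_sizes(cfg.n_shared_mother_pairs, max_size=2)
    pat_sizes = _sibship_sizes(cfg.n_shared_father_pairs, max_size=6)
    n_mat = sum(mat_sizes)
    n_pat = sum(pat_sizes)
    if n_mat > cfg.n_females:
        raise ConfigError("maternal sibships need more females than available")
    if n_mat + n_pat > n:
        raise ConfigError("sibship design needs more individuals than available")

    females = [i for i in range(n) if sexes[i] == "F"]
    others = [i for i in range(n) if i not in set(females[:n_mat])]
    mothers = [f"uMo{i:03d}" for i in range(n)]
    fathers = [f"uFa{i:03d}" for i in range(n)]

    pos = 0
    for s_idx, size in enumerate(mat_sizes):
        shared = f"sMo{s_idx:02d}"
        for member in females[pos:pos + size]:
            mothers[member] = shared
        pos += size
    pos = 0
    for s_idx, size in enumerate(pat_sizes):
        shared = f"sFa{s_idx:02d}"
        for member in others[pos:pos + size]:
            fathers[member] = shared
        pos += size

    ped = PedigreeTable({ids[i]: (mothers[i], fathers[i]) for i in range(n)})

    n_samples = rng.choice(
        np.arange(1, len(cfg.samples_per_individual_probs) + 1),
        size=n, p=cfg.samples_per_individual_probs,
    )
    sample_ids, sample_inds = [], []
    for i in range(n):
        for k in range(n_samples[i]):
            sample_ids.append(f"{ids[i]}_s{k}")
            sample_inds.append(ids[i])

    individuals = pd.DataFrame(
        {"sex": sexes, "group": groups, "age": ages, "rank": ranks},
        index=pd.Index(ids, name="individual_id"),
    )
    sample_map = pd.Series(sample_inds, index=pd.Index(sample_ids, name="sample_id"),
                           name="individual_id")
    return IndividualMetadata(individuals, sample_map), ped


def simulate_profiles(
    colony: tuple[IndividualMetadata, PedigreeTable],
    cfg: SimulationConfig,
    planted_sex_compounds: int = 0,
) -> tuple[PeakTable, PeakTable]:
    """Draw sample and blank peak tables for a simulated colony.

    With `planted_sex_compounds = m > 0`, the compound-specific sex
    contrasts are concentrated on the first m endogenous compounds
    (each receiving the full sex_sd effect) instead of being drawn for
    every compound — the setting used for effect-recovery checks.
    """
    cfg.validate()
    meta, ped = colony
    rng = _rng(cfg.seed, 1)

    ids = list(meta.individuals.index)
    n_ind = len(ids)
    n_c = cfg.n_compounds_endogenous
    groups = sorted(set(meta.individuals["group"]))
    mothers = {i: ped.parents_of(i)[0] for i in ids}

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, n_c)
    if planted_sex_compounds:
        beta_sex = np.zeros(n_c)
        beta_sex[:planted_sex_compounds] = rng.choice([-1.0, 1.0], planted_sex_compounds)
    else:
        beta_sex = rng.normal(0, 1, n_c)
    gamma_group = rng.normal(0, 1, (n_c, len(groups)))
    fam_ids = sorted({m for m in mothers.values() if m is not None})
    m_fam = rng.normal(0, 1, (n_c, len(fam_ids)))
    age_slope = rng.normal(0, 1, n_c) * cfg.age_slope_sd
    rank_slope = rng.normal(0, 1, n_c) * cfg.rank_slope_sd
    ind_dev = rng.normal(0, 1, (n_c, n_ind)) * cfg.individual_sd

    ages = meta.individuals["age"].to_numpy()
    z_age = (ages - ages.mean()) / ages.std(ddof=1)
    ranks = np.nan_to_num(meta.individuals["rank"].to_numpy(dtype=float), nan=0.5)
    sex_num = np.where(meta.individuals["sex"].to_numpy() == "F", 0.5, -0.5)
    g_idx = np.array([groups.index(g) for g in meta.individuals["group"]])
    fam_idx = np.array([fam_ids.index(mothers[i]) for i in ids])

    latent_ind = (
        baseline[:, None]
        + cfg.sex_sd * beta_sex[:, None] * sex_num[None, :]
        + cfg.group_sd * gamma_group[:, g_idx]
        + cfg.maternal_family_sd * m_fam[:, fam_idx]
        + age_slope[:, None] * z_age[None, :]
        + rank_slope[:, None] * ranks[None, :]
        + ind_dev
    )  # n_c x n_ind

    compound_ids = [f"RT{20 + 0.5 * k:.2f}" for k in range(n_c)]
    contaminant_ids = [f"CONT{k:02d}" for k in range(cfg.n_compounds_contaminant)]
    all_compounds = compound_ids + contaminant_ids

    sample_ids = list(meta.sample_map.index)
    ind_of_sample = np.array([ids.index(meta.sample_map[s]) for s in sample_ids])
    n_s = len(sample_ids)

    noise = rng.normal(0, 1, (n_s, n_c)) * cfg.residual_sd
    latent = latent_ind[:, ind_of_sample].T + noise
    areas = np.exp(latent)
    areas[areas < cfg.detection_threshold] = 0.0

    cont_samples = rng.lognormal(cfg.contaminant_log_mean, cfg.contaminant_log_sd,
                                 (n_s, cfg.n_compounds_contaminant))
    full = np.hstack([areas, cont_samples])
    peaks = PeakTable(sample_ids, all_compounds, full)

    blank_ids = [f"blank{k}" for k in range(cfg.n_blanks)]
    cont_blanks = rng.lognormal(cfg.contaminant_log_mean + cfg.contaminant_blank_boost,
                                cfg.contaminant_log_sd,
                                (cfg.n_blanks, cfg.n_compounds_contaminant))
    blank_areas = np.hstack([np.zeros((cfg.n_blanks, n_c)), cont_blanks])
    blanks = PeakTable(blank_ids, all_compounds, blank_areas,
                       is_blank=np.ones(cfg.n_blanks, dtype=bool))
    return peaks, blanks


def simulate_study(cfg: SimulationConfig, planted_sex_compounds: int = 0):
    """Convenience: colony plus profiles in one call."""
    colony = simulate_colony(cfg)
    peaks, blanks = simulate_profiles(colony, cfg, planted_sex_compounds)
    return colony[0], colony[1], peaks, blanks
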