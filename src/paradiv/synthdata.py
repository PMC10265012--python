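"""Synthetic dissection datasets with the structure the pipeline assumes.

The generator emulates the shape of multi-ecosystem host-dissection
surveys: several ecosystems, each with host species drawn from four
taxonomic groups, a per-ecosystem pool of parasite morphogroups annotated
with taxon / life cycle / life stage, host-specificity sets, and a
host-size covariate.  Infection is a simple detection model — each
compatible morphogroup is detected independently in each host individual
with a per-morphogroup probability, and a positive count of
``1 + Poisson(1)`` is recorded on detection (downstream statistics use
presence only).

Scenario helpers encode the hypotheses under test:

* `null_scenario` makes every ecosystem's parasite side identical, so
  ecosystems are exchangeable up to labels — the ground truth for
  calibration of the ordered permutation test and the chi-square tests;
* `ordered_effect_scenario` scales detection probabilities and pool sizes
  monotonically along a specified ecosystem ordering, producing a true
  richness gradient of tunable strength for power studies.

Two deterministic fixtures are exposed for worked examples and tests:
`vent_composition` (a hydrothermal-vent-like community whose morphogroup
inventory is fixed by construction: 12 adult and 9 larval morphogroups)
and `survey_margins` (hosts only, with per-ecosystem species and individual
counts fixed at study scale: 28/44/28 host species).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import (
    DissectionDataset,
    HOST_GROUPS,
    LIFE_CYCLES,
    LIFE_STAGES,
    PARASITE_TAXA,
    make_dataset,
)


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class HostGroupSpec:
    """Host species of one taxonomic group within one ecosystem."""

    group: str
    n_species: int
    individuals: tuple[int, int]  # inclusive uniform range per species


@dataclass
class ParasitePoolSpec:
    """A block of morphogroups sharing taxon, life cycle and life stage.

    ``host_groups`` restricts which host groups the morphogroups can
    infect (None = any).  ``host_breadth`` is the *expected* number of
    compatible host species: each eligible species is compatible
    independently with probability ``host_breadth / n_eligible``.
    Independence across host species keeps per-species richness summaries
    i.i.d., which the stratified permutation test's exactness relies on;
    a morphogroup that draws no compatible species is assigned one
    uniformly so the compatibility invariant holds.
    """

    taxon: str
    life_cycle: str
    life_stage: str
    n_morphogroups: int
    detection_prob: float
    host_breadth: int = 3
    host_groups: tuple[str, ...] | None = None


@dataclass
class EcosystemSpec:
    name: str
    host_groups: list[HostGroupSpec]
    pool: list[ParasitePoolSpec]
    n_redundant_pairs: int = 0  # adult/larval same-taxon pairs sharing a redundancy group


@dataclass
class SimulationConfig:
    ecosystems: list[EcosystemSpec]
    length_lognormal: tuple[float, float] = (4.0, 0.6)  # mean/sd of log length (mm)
    length_richness_coef: float = 0.0  # per-sd log-length multiplier on detection logit
    seed: int = 0


def _validate_config(config: SimulationConfig) -> None:
    if not config.ecosystems:
        raise ConfigError("ecosystems: must list at least one ecosystem")
    for eco in config.ecosystems:
        if not eco.host_groups:
            raise ConfigError(f"{eco.name}.host_groups: must be non-empty")
        for hg in eco.host_groups:
            if hg.group not in HOST_GROUPS:
                raise ConfigError(f"{eco.name}.host_groups.group: unknown {hg.group!r}")
            if hg.n_species < 0:
                raise ConfigError(f"{eco.name}.{hg.group}.n_species: must be >= 0")
            lo, hi = hg.individuals
            if not (1 <= lo <= hi):
                raise ConfigError(f"{eco.name}.{hg.group}.individuals: bad range {hg.individuals}")
        groups_present = {hg.group for hg in eco.host_groups if hg.n_species > 0}
        for ps in eco.pool:
            if ps.taxon not in PARASITE_TAXA:
                raise ConfigError(f"{eco.name}.pool.taxon: unknown {ps.taxon!r}")
            if ps.life_cycle not in LIFE_CYCLES:
                raise ConfigError(f"{eco.name}.pool.life_cycle: unknown {ps.life_cycle!r}")
            if ps.life_stage not in LIFE_STAGES:
                raise ConfigError(f"{eco.name}.pool.life_stage: unknown {ps.life_stage!r}")
            if ps.life_cycle == "DLC" and ps.life_stage != "adult":
                raise ConfigError(
                    f"{eco.name}.pool: DLC morphogroups must be adult, got {ps.life_stage!r}"
                )
            if not 0.0 <= ps.detection_prob <= 1.0:
                raise ConfigError(
                    f"{eco.name}.pool.detection_prob: {ps.detection_prob} not in [0, 1]"
                )
            if ps.n_morphogroups < 0:
                raise ConfigError(f"{eco.name}.pool.n_morphogroups: must be >= 0")
            if ps.host_breadth < 1:
                raise ConfigError(f"{eco.name}.pool.host_breadth: must be >= 1")
            eligible = groups_present if ps.host_groups is None else (
                set(ps.host_groups) & groups_present
            )
            if ps.n_morphogroups > 0 and not eligible:
                raise ConfigError(
                    f"{eco.name}.pool ({ps.taxon}/{ps.life_stage}): no compatible "
                    f"host species in groups {ps.host_groups}"
                )


def simulate_dataset(config: SimulationConfig, seed: int | None = None) -> DissectionDataset:
    """Draw one dissection dataset; deterministic given the seed.

    ``seed`` overrides ``config.seed`` (convenient for replicate loops).
    """
    _validate_config(config)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    mu, sigma = config.length_lognormal

    rec_frames = []
    obs_rows: list[tuple[str, str, int]] = []
    ann_rows: list[dict] = []

    for eco in config.ecosystems:
        # --- host species and individuals -----------------------------
        species: list[dict] = []
        for hg in eco.host_groups:
            for i in range(hg.n_species):
                name = f"{eco.name}_{hg.group}_sp{i + 1:02d}"
                n_ind = int(rng.integers(hg.individuals[0], hg.individuals[1] + 1))
                log_len = rng.normal(mu, sigma)
                species.append(
                    {
                        "name": name,
                        "group": hg.group,
                        "n_ind": n_ind,
                        "log_len": log_len,
                        "ids": [f"{name}_h{j + 1:03d}" for j in range(n_ind)],
                    }
                )
        for sp in species:
            lengths = np.exp(sp["log_len"] + rng.normal(0.0, 0.1, sp["n_ind"]))
            rec_frames.append(
                pd.DataFrame(
                    {
                        "host_individual_id": sp["ids"],
                        "host_species": sp["name"],
                        "host_group": sp["group"],
                        "ecosystem": eco.name,
                        "site": f"{eco.name}_site1",
                        "collection_date": None,
                        "host_length_mm": np.round(lengths, 1),
                    }
                )
            )

        # --- parasite pool and infections -----------------------------
        by_index = {i: sp for i, sp in enumerate(species)}
        mg_by_taxon_stage: dict[tuple[str, bool], list[str]] = {}
        counter = 0
        for ps in eco.pool:
            eligible = [
                i
                for i, sp in by_index.items()
                if ps.host_groups is None or sp["group"] in ps.host_groups
            ]
            for _ in range(ps.n_morphogroups):
                counter += 1
                mid = f"{eco.name}_{ps.taxon.lower()[:4]}_{ps.life_stage}_{counter:03d}"
                ann_rows.append(
                    {
                        "morphogroup_id": mid,
                        "parasite_taxon": ps.taxon,
                        "life_cycle": ps.life_cycle,
                        "life_stage": ps.life_stage,
                        "redundancy_group": None,
                    }
                )
                mg_by_taxon_stage.setdefault(
                    (ps.taxon, ps.life_stage == "adult"), []
                ).append(mid)
                p_comp = min(1.0, ps.host_breadth / len(eligible))
                mask = rng.random(len(eligible)) < p_comp
                if not mask.any():
                    mask[rng.integers(len(eligible))] = True
                chosen = np.asarray(eligible)[mask]
                for si in chosen:
                    sp = by_index[int(si)]
                    p = ps.detection_prob
                    if config.length_richness_coef:
                        z = (sp["log_len"] - mu) / sigma
                        p = min(1.0, p * float(np.exp(config.length_richness_coef * z)))
                    hits = np.flatnonzero(rng.random(sp["n_ind"]) < p)
                    if len(hits):
                        counts = 1 + rng.poisson(1.0, len(hits))
                        obs_rows.extend(
                            (sp["ids"][j], mid, int(c)) for j, c in zip(hits, counts)
                        )

        # --- redundancy pairs (adult + larval stage of one taxon) ------
        paired = 0
        for taxon in sorted({t for (t, _a) in mg_by_taxon_stage}):
            adults = mg_by_taxon_stage.get((taxon, True), [])
            larvals = mg_by_taxon_stage.get((taxon, False), [])
            for a, l in zip(adults, larvals):
                if paired >= eco.n_redundant_pairs:
                    break
                paired += 1
                rg = f"{eco.name}_red{paired:02d}"
                for row in ann_rows:
                    if row["morphogroup_id"] in (a, l):
                        row["redundancy_group"] = rg

    records = pd.concat(rec_frames, ignore_index=True)
    observations = pd.DataFrame(
        obs_rows, columns=["host_individual_id", "morphogroup_id", "count"]
    )
    annotations = pd.DataFrame(ann_rows)
    return make_dataset(
        records,
        observations,
        annotations,
        provenance=[f"simulated ({len(config.ecosystems)} ecosystems)"],
    )


def null_scenario(base: SimulationConfig) -> SimulationConfig:
    """Neutralize the ecosystem effect: identical parasite pools everywhere.

    Every ecosystem keeps its own host configuration but receives a deep
    copy of the first ecosystem's pool, so ecosystems are exchangeable up
    to labels whenever host configurations also match.
    """
    out = copy.deepcopy(base)
    reference = out.ecosystems[0].pool
    for eco in out.ecosystems:
        eco.pool = copy.deepcopy(reference)
        eco.n_redundant_pairs = out.ecosystems[0].n_redundant_pairs
    return out


def ordered_effect_scenario(
    base: SimulationConfig,
    effect: float,
    ordering: list[str] | None = None,
) -> SimulationConfig:
    """Impose a true richness gradient along ``ordering`` (lowest first).

    Starting from the neutralized configuration, ecosystem at rank ``r``
    (0-based) gets detection probabilities scaled by ``1 + effect * r``
    (capped at 0.95) and pool sizes scaled by the same factor (rounded).
    ``effect -> 0`` recovers `null_scenario`.
    """
    if effect < 0:
        raise ValueError("effect must be >= 0")
    out = null_scenario(base)
    if ordering is None:
        ordering = [eco.name for eco in out.ecosystems]
    rank = {name: r for r, name in enumerate(ordering)}
    for eco in out.ecosystems:
        if eco.name not in rank:
            raise ValueError(f"ecosystem {eco.name!r} missing from ordering")
        factor = 1.0 + effect * rank[eco.name]
        for ps in eco.pool:
            ps.detection_prob = min(0.95, ps.detection_prob * factor)
            ps.n_morphogroups = int(round(ps.n_morphogroups * factor))
    return out


def study_scale_config(seed: int = 0) -> SimulationConfig:
    """Default configuration at study scale.

    Three ecosystems with host-species counts per group shaped like a
    kelp-forest / atoll-sandflat / vent comparison (28 / 44 / 28 host
    species), 10-30 dissected individuals per species, and a parasite pool
    mixing direct-life-cycle ectoparasites on fish with indirect-life-cycle
    helminths split between adult stages in fish and larval stages in
    invertebrates.
    """
    ind = (10, 30)

    def pool() -> list[ParasitePoolSpec]:
        # intermediate (encysted) stages can sit in fish as well as in
        # invertebrate prey: fish act as second intermediate hosts
        return [
            ParasitePoolSpec("Trematoda", "ILC", "adult", 5, 0.12, 3, ("fish",)),
            ParasitePoolSpec("Trematoda", "ILC", "metacercaria", 4, 0.10, 3, None),
            ParasitePoolSpec("Trematoda", "ILC", "sporocyst", 1, 0.10, 2, ("mollusk",)),
            ParasitePoolSpec("Copepoda", "DLC", "adult", 3, 0.12, 2, None),
            ParasitePoolSpec("Monogenea", "DLC", "adult", 2, 0.12, 2, ("fish",)),
            ParasitePoolSpec("Nematoda", "ILC", "adult", 2, 0.10, 2, ("fish",)),
            ParasitePoolSpec("Nematoda", "ILC", "larval_nematode", 2, 0.10, 2, None),
            ParasitePoolSpec("Acanthocephala", "ILC", "adult", 1, 0.10, 2, ("fish",)),
            ParasitePoolSpec("Acanthocephala", "ILC", "cystacanth", 2, 0.10, 2, None),
            ParasitePoolSpec("Cestoda", "ILC", "metacestode", 2, 0.10, 2, None),
        ]

    ecosystems = [
        EcosystemSpec(
            "kelp",
            [
                HostGroupSpec("crustacean", 2, ind),
                HostGroupSpec("fish", 12, ind),
                HostGroupSpec("mollusk", 12, ind),
                HostGroupSpec("polychaete", 2, ind),
            ],
            pool(),
        ),
        EcosystemSpec(
            "atoll",
            [
                HostGroupSpec("crustacean", 5, ind),
                HostGroupSpec("fish", 23, ind),
                HostGroupSpec("mollusk", 12, ind),
                HostGroupSpec("polychaete", 4, ind),
            ],
            pool(),
        ),
        EcosystemSpec(
            "vent",
            [
                HostGroupSpec("crustacean", 6, ind),
                HostGroupSpec("fish", 2, ind),
                HostGroupSpec("mollusk", 10, ind),
                HostGroupSpec("polychaete", 10, ind),
            ],
            pool(),
        ),
    ]
    return SimulationConfig(ecosystems=ecosystems, seed=seed)


def calibration_config(seed: int = 0) -> SimulationConfig:
    """Small balanced configuration for repeated ordered-test calibration runs.

    Each ecosystem has the same host layout (3 species in each of the four
    groups, 10-14 individuals each) so that under `null_scenario`
    ecosystems are fully exchangeable.  Detection is high enough (0.10 per
    individual, pool of 30, breadth 6) that within-species Chao2 estimates
    take many distinct values — a near-continuous response, so the
    randomization p-value is close to uniform rather than lumpy.
    """
    ind = (10, 14)
    groups = [
        HostGroupSpec("crustacean", 3, ind),
        HostGroupSpec("fish", 3, ind),
        HostGroupSpec("mollusk", 3, ind),
        HostGroupSpec("polychaete", 3, ind),
    ]

    def pool() -> list[ParasitePoolSpec]:
        return [
            ParasitePoolSpec("Trematoda", "ILC", "adult", 6, 0.10, 6, None),
            ParasitePoolSpec("Trematoda", "ILC", "metacercaria", 4, 0.10, 6, None),
            ParasitePoolSpec("Copepoda", "DLC", "adult", 6, 0.10, 6, None),
            ParasitePoolSpec("Monogenea", "DLC", "adult", 4, 0.10, 6, None),
            ParasitePoolSpec("Nematoda", "ILC", "adult", 5, 0.10, 6, None),
            ParasitePoolSpec("Acanthocephala", "ILC", "cystacanth", 5, 0.10, 6, None),
        ]

    ecosystems = [
        EcosystemSpec(name, copy.deepcopy(groups), pool())
        for name in ("vent", "atoll", "kelp")
    ]
    return SimulationConfig(ecosystems=ecosystems, seed=seed)


def composition_calibration_config(seed: int = 0) -> SimulationConfig:
    """Null scenario tailored to chi-square calibration on invertebrate hosts.

    The Pearson statistic's chi-square null distribution assumes cell
    counts fluctuate like (product-)Poisson or multinomial draws.  Counts
    of *observed* morphogroups are sums of independent Bernoulli
    indicators, one per candidate morphogroup, which approach the Poisson
    regime only when each indicator has small success probability.  This
    configuration therefore uses a large candidate pool (600 morphogroups
    per ecosystem) with a tiny per-individual detection probability, so
    each morphogroup is observed with probability ~0.03 and expected cell
    counts still sit near 10.  All morphogroups infect invertebrates; the
    life-cycle table is taken on the invertebrate partition.
    """
    ind = (10, 14)
    inverts = ("crustacean", "mollusk", "polychaete")
    groups = [
        HostGroupSpec("crustacean", 3, ind),
        HostGroupSpec("mollusk", 3, ind),
        HostGroupSpec("polychaete", 3, ind),
    ]
    p = 0.0009

    def pool() -> list[ParasitePoolSpec]:
        return [
            ParasitePoolSpec("Copepoda", "DLC", "adult", 200, p, 3, inverts),
            ParasitePoolSpec("Rhizocephala", "DLC", "adult", 100, p, 3, ("crustacean",)),
            ParasitePoolSpec("Trematoda", "ILC", "metacercaria", 120, p, 3, inverts),
            ParasitePoolSpec("Trematoda", "ILC", "sporocyst", 60, p, 3, ("mollusk",)),
            ParasitePoolSpec("Nematoda", "ILC", "larval_nematode", 60, p, 3, inverts),
            ParasitePoolSpec("Acanthocephala", "ILC", "cystacanth", 60, p, 3, inverts),
        ]

    ecosystems = [
        EcosystemSpec(name, copy.deepcopy(groups), pool())
        for name in ("vent", "atoll", "kelp")
    ]
    return SimulationConfig(ecosystems=ecosystems, seed=seed)


# ----------------------------------------------------------------------
# Deterministic fixtures
# ----------------------------------------------------------------------

#: (species, group, n individuals, length mm, [(morphogroup, n infected)])
_VENT_HOSTS: list[tuple[str, str, int, float, list[tuple[str, int]]]] = [
    ("vent_fish_A", "fish", 12, 220.0,
     [("acan_adult_01", 3), ("cope_adult_01", 2), ("nema_adult_01", 2),
      ("trem_adult_01", 4), ("trem_adult_02", 3), ("trem_adult_03", 2),
      ("trem_adult_04", 1)]),
    ("vent_fish_B", "fish", 10, 310.0,
     [("acan_adult_02", 2), ("trem_adult_05", 3), ("trem_adult_06", 2),
      ("trem_adult_07", 1)]),
    ("vent_amphipod", "crustacean", 12, 8.0, [("nema_larv_01", 4)]),
    ("vent_squat_lobster", "crustacean", 10, 45.0, [("rhiz_adult_01", 2)]),
    ("vent_shrimp", "crustacean", 11, 30.0,
     [("trem_meta_01", 3), ("trem_meta_02", 2)]),
    ("vent_limpet", "mollusk", 15, 12.0,
     [("trem_spor_01", 2), ("trem_meta_03", 3)]),
    ("vent_snail", "mollusk", 12, 9.0, [("trem_meta_04", 2), ("trem_meta_05", 1)]),
    ("vent_mussel", "mollusk", 20, 80.0, []),
    ("vent_tubeworm", "polychaete", 14, 150.0, [("trem_meta_06", 2)]),
    ("vent_worm", "polychaete", 10, 60.0, [("trem_meta_07", 1)]),
]

_VENT_ANNOTATIONS: list[tuple[str, str, str, str]] = [
    ("acan_adult_01", "Acanthocephala", "ILC", "adult"),
    ("acan_adult_02", "Acanthocephala", "ILC", "adult"),
    ("cope_adult_01", "Copepoda", "DLC", "adult"),
    ("nema_adult_01", "Nematoda", "ILC", "adult"),
    ("nema_larv_01", "Nematoda", "ILC", "larval_nematode"),
    ("rhiz_adult_01", "Rhizocephala", "DLC", "adult"),
    *[(f"trem_adult_{i:02d}", "Trematoda", "ILC", "adult") for i in range(1, 8)],
    *[(f"trem_meta_{i:02d}", "Trematoda", "ILC", "metacercaria") for i in range(1, 8)],
    ("trem_spor_01", "Trematoda", "ILC", "sporocyst"),
]


def vent_composition() -> DissectionDataset:
    """Deterministic vent-like community fixture.

    By construction the observed morphogroup inventory is: 2 adult
    acanthocephalans, 1 adult copepod, 1 adult nematode, 1 larval
    nematode, 1 adult rhizocephalan, 7 adult trematodes, 7 trematode
    metacercariae and 1 trematode sporocyst — 12 adult and 9 larval
    morphogroups, with fish hosting only adult stages.  Every host species
    has at least 10 dissected individuals, so the fixture survives the
    default inclusion filters unchanged.
    """
    rec_rows = []
    obs_rows = []
    for sp, group, n, length, infections in _VENT_HOSTS:
        ids = [f"{sp}_h{j + 1:03d}" for j in range(n)]
        for j, hid in enumerate(ids):
            rec_rows.append(
                {
                    "host_individual_id": hid,
                    "host_species": sp,
                    "host_group": group,
                    "ecosystem": "vent",
                    "site": "vent_site1",
                    "collection_date": None,
                    "host_length_mm": round(length * (1 + 0.02 * j), 1),
                }
            )
        for mid, n_infected in infections:
            for hid in ids[:n_infected]:
                obs_rows.append(
                    {"host_individual_id": hid, "morphogroup_id": mid, "count": 2}
                )
    ann = pd.DataFrame(
        _VENT_ANNOTATIONS,
        columns=["morphogroup_id", "parasite_taxon", "life_cycle", "life_stage"],
    )
    ann["redundancy_group"] = None
    return make_dataset(
        pd.DataFrame(rec_rows),
        pd.DataFrame(obs_rows),
        ann,
        provenance=["fixture: vent_composition (synthetic)"],
    )


#: group -> (n species, n individuals) per ecosystem, at study scale.
_SURVEY_MARGINS: dict[str, dict[str, tuple[int, int]]] = {
    "kelp": {"crustacean": (2, 25), "fish": (12, 195), "mollusk": (12, 379),
             "polychaete": (2, 79)},
    "atoll": {"crustacean": (5, 200), "fish": (23, 574), "mollusk": (12, 1578),
              "polychaete": (4, 285)},
    "vent": {"crustacean": (6, 712), "fish": (2, 35), "mollusk": (10, 880),
             "polychaete": (10, 507)},
}


def _distribute(total: int, parts: int) -> list[int]:
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def survey_margins() -> DissectionDataset:
    """Deterministic hosts-only fixture with study-scale sampling margins.

    Three ecosystems with per-group host-species counts and dissected
    individual totals of (kelp) 28 species / 678 individuals, (atoll) 44 /
    2637, (vent) 28 / 2134; individuals are spread as evenly as possible
    across species, so every species clears the 10-individual floor.  No
    parasite observations: the fixture checks sampling structure.
    """
    rec_frames = []
    for eco, groups in _SURVEY_MARGINS.items():
        for group, (n_species, n_ind) in groups.items():
            for i, n in enumerate(_distribute(n_ind, n_species)):
                sp = f"{eco}_{group}_sp{i + 1:02d}"
                rec_frames.append(
                    pd.DataFrame(
                        {
                            "host_individual_id": [f"{sp}_h{j + 1:04d}" for j in range(n)],
                            "host_species": sp,
                            "host_group": group,
                            "ecosystem": eco,
                            "site": f"{eco}_site1",
                            "collection_date": None,
                            "host_length_mm": round(20.0 + 5.0 * i, 1),
                        }
                    )
                )
    return make_dataset(
        pd.concat(rec_frames, ignore_index=True),
        provenance=["fixture: survey_margins (synthetic)"],
    )
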