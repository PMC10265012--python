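"""Dataset-subsetting protocol that makes ecosystems comparable.

Cross-ecosystem comparisons of parasite richness are only meaningful if
each dataset is restricted to the same host groups, the same parasite
taxa, and host species sampled deeply enough for incidence-based
estimation.  Filters are applied in a fixed, logged order:

1. host-group filter (crustacean / fish / mollusk / polychaete subset),
2. parasite-taxon filter (the eight metazoan taxa under study),
3. minimum-sample-size filter — host species with fewer than
   ``min_individuals`` dissected individuals (infected or not) are
   dropped; the default of 10 is the conventional floor below which
   within-species richness estimates are unstable.

`drop_redundant_stages` removes the double counting that arises when an
adult and a larval morphogroup within the same host partition are
potentially the same biological species: among morphogroups sharing a
redundancy group, the adult stage is kept if present, else the
lexicographically first id — a deterministic stand-in for expert
judgement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import pandas as pd

from .core_data import (
    DissectionDataset,
    HOST_GROUPS,
    PARASITE_TAXA,
    make_dataset,
)

INVERTEBRATE_GROUPS = frozenset({"crustacean", "mollusk", "polychaete"})


class EmptyResultError(ValueError):
    """Raised when a filter removes every record: downstream statistics
    on an empty dataset would be silently meaningless."""


@dataclass
class FilterSpec:
    """Inclusion criteria applied before any cross-ecosystem statistic."""

    min_individuals: int = 10
    allowed_host_groups: frozenset[str] = field(default_factory=lambda: HOST_GROUPS)
    allowed_parasite_taxa: frozenset[str] = field(default_factory=lambda: PARASITE_TAXA)
    partition: str = "all"  # {'fish', 'invertebrate', 'all'}

    def __post_init__(self) -> None:
        if self.min_individuals < 1:
            raise ValueError("min_individuals must be >= 1")
        self.allowed_host_groups = frozenset(self.allowed_host_groups)
        self.allowed_parasite_taxa = frozenset(self.allowed_parasite_taxa)
        if not self.allowed_host_groups or not self.allowed_parasite_taxa:
            raise ValueError("allowed host groups / parasite taxa must be non-empty")
        bad = self.allowed_host_groups - HOST_GROUPS
        if bad:
            raise ValueError(f"unknown host group(s): {sorted(bad)}")
        bad = self.allowed_parasite_taxa - PARASITE_TAXA
        if bad:
            raise ValueError(f"unknown parasite taxon(-a): {sorted(bad)}")
        if self.partition not in {"fish", "invertebrate", "all"}:
            raise ValueError(f"unknown partition {self.partition!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["allowed_host_groups"] = sorted(self.allowed_host_groups)
        d["allowed_parasite_taxa"] = sorted(self.allowed_parasite_taxa)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FilterSpec":
        kwargs = dict(d)
        if "allowed_host_groups" in kwargs:
            kwargs["allowed_host_groups"] = frozenset(kwargs["allowed_host_groups"])
        if "allowed_parasite_taxa" in kwargs:
            kwargs["allowed_parasite_taxa"] = frozenset(kwargs["allowed_parasite_taxa"])
        return cls(**kwargs)


def _subset(dataset: DissectionDataset, keep_hosts, keep_morphogroups=None) -> DissectionDataset:
    rec = dataset.records[dataset.records["host_individual_id"].isin(keep_hosts)]
    obs = dataset.observations[
        dataset.observations["host_individual_id"].isin(keep_hosts)
    ]
    ann = dataset.annotations
    if keep_morphogroups is not None:
        obs = obs[obs["morphogroup_id"].isin(keep_morphogroups)]
        ann = ann[ann["morphogroup_id"].isin(keep_morphogroups)]
    return make_dataset(rec, obs, ann, list(dataset.provenance))


def apply_inclusion_filters(dataset: DissectionDataset, spec: FilterSpec) -> DissectionDataset:
    """Apply the host-group, parasite-taxon and sample-size filters in order.

    Idempotent: a dataset already satisfying ``spec`` is returned unchanged
    except for the appended provenance lines.
    """
    ds = dataset

    keep = ds.records.loc[
        ds.records["host_group"].isin(spec.allowed_host_groups), "host_individual_id"
    ]
    n_before = ds.n_hosts
    ds = _subset(ds, set(keep))
    ds.provenance.append(
        f"host-group filter {sorted(spec.allowed_host_groups)}: "
        f"{n_before} -> {ds.n_hosts} hosts"
    )

    if len(ds.annotations):
        allowed_mg = set(
            ds.annotations.loc[
                ds.annotations["parasite_taxon"].isin(spec.allowed_parasite_taxa),
                "morphogroup_id",
            ]
        )
        n_obs_before = ds.n_observations
        ds = _subset(ds, set(ds.records["host_individual_id"]), allowed_mg)
        ds.provenance.append(
            f"parasite-taxon filter {sorted(spec.allowed_parasite_taxa)}: "
            f"{n_obs_before} -> {ds.n_observations} observations"
        )

    # sample size counts dissected individuals per (ecosystem, species),
    # infected or not
    counts = ds.records.groupby(["ecosystem", "host_species"])["host_individual_id"].count()
    deep = counts[counts >= spec.min_individuals].index
    key = pd.MultiIndex.from_frame(ds.records[["ecosystem", "host_species"]])
    keep = ds.records.loc[key.isin(deep), "host_individual_id"]
    n_before = ds.n_hosts
    ds = _subset(ds, set(keep))
    ds.provenance.append(
        f"min-individuals filter (>= {spec.min_individuals} per host species): "
        f"{n_before} -> {ds.n_hosts} hosts"
    )

    if ds.n_hosts == 0:
        raise EmptyResultError(
            "inclusion filters removed every host record; "
            "check min_individuals and allowed sets against the data"
        )
    return ds


def partition_hosts(dataset: DissectionDataset) -> tuple[DissectionDataset, DissectionDataset]:
    """Split into (fish, invertebrate) partitions; their union is the input.

    Fish and invertebrates are analysed separately so that an indirect
    life cycle passing from an invertebrate intermediate host to a fish
    definitive host cannot be counted as two species in one curve.
    """
    fish_ids = set(
        dataset.records.loc[dataset.records["host_group"] == "fish", "host_individual_id"]
    )
    invert_ids = set(dataset.records["host_individual_id"]) - fish_ids
    fish = _subset(dataset, fish_ids)
    fish.provenance.append(f"partition: fish ({len(fish.records)} hosts)")
    invert = _subset(dataset, invert_ids)
    invert.provenance.append(f"partition: invertebrate ({len(invert.records)} hosts)")
    return fish, invert


def drop_redundant_stages(dataset: DissectionDataset) -> DissectionDataset:
    """Collapse potentially redundant life stages within a host partition.

    For every redundancy group with >= 2 observed morphogroups, all but
    one are removed: the adult stage if present, otherwise the
    lexicographically first morphogroup id.
    """
    ann = dataset.annotations
    observed = set(dataset.observations["morphogroup_id"])
    if not len(ann) or not observed:
        out = dataset.copy()
        out.provenance.append("redundant-stage filter: nothing to collapse")
        return out
    present = ann[ann["morphogroup_id"].isin(observed) & ann["redundancy_group"].notna()]
    drop: set[str] = set()
    for _, grp in present.groupby("redundancy_group"):
        if len(grp) < 2:
            continue
        adults = grp.loc[grp["life_stage"] == "adult", "morphogroup_id"]
        keep_id = adults.min() if len(adults) else grp["morphogroup_id"].min()
        drop |= set(grp["morphogroup_id"]) - {keep_id}
    keep_mg = (set(ann["morphogroup_id"]) - drop) if drop else set(ann["morphogroup_id"])
    out = _subset(dataset, set(dataset.records["host_individual_id"]), keep_mg)
    out.provenance.append(
        f"redundant-stage filter: removed {sorted(drop)}" if drop
        else "redundant-stage filter: nothing to collapse"
    )
    return out
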