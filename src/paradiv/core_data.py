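"""Domain model and I/O for host-dissection datasets.

A dissection dataset couples three tables:

* **records** — one row per dissected host individual (species, taxonomic
  group, ecosystem, site, optional collection date and body length in mm);
* **observations** — one row per (host individual, parasite morphogroup)
  detection with a positive count; absence is encoded by no row;
* **annotations** — one row per parasite morphogroup carrying its higher
  taxon, life-cycle category (direct = one host, indirect = multiple
  hosts), life stage, and an optional redundancy group linking life stages
  that may belong to a single biological species.

The canonical on-disk form is two UTF-8 CSV files: a denormalised
dissection table (one row per observation, uninfected hosts appearing once
with empty morphogroup/count cells) and an annotation table.  A *dialect*
mapping translates arbitrary source column headers onto the canonical
names, so differently-labelled source datasets can be ingested without
editing the files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

HOST_GROUPS = frozenset({"crustacean", "fish", "mollusk", "polychaete"})

PARASITE_TAXA = frozenset(
    {
        "Acanthocephala",
        "Cestoda",
        "Copepoda",
        "Isopoda",
        "Monogenea",
        "Nematoda",
        "Rhizocephala",
        "Trematoda",
    }
)

LIFE_CYCLES = frozenset({"DLC", "ILC"})

LIFE_STAGES = frozenset(
    {
        "adult",
        "cystacanth",
        "metacestode",
        "larval_nematode",
        "metacercaria",
        "sporocyst",
        "other_larval",
    }
)

RECORD_COLUMNS = [
    "host_individual_id",
    "host_species",
    "host_group",
    "ecosystem",
    "site",
    "collection_date",
    "host_length_mm",
]

OBSERVATION_COLUMNS = ["host_individual_id", "morphogroup_id", "count"]

ANNOTATION_COLUMNS = [
    "morphogroup_id",
    "parasite_taxon",
    "life_cycle",
    "life_stage",
    "redundancy_group",
]

DISSECTION_COLUMNS = RECORD_COLUMNS + ["morphogroup_id", "count"]


class FormatError(ValueError):
    """Raised when an input file does not conform to the expected schema."""


class IntegrityError(ValueError):
    """Raised when cross-table references or uniqueness constraints fail."""


@dataclass
class DissectionDataset:
    """In-memory dissection dataset (records, observations, annotations).

    ``provenance`` is an append-only audit trail: every transformation
    elsewhere in the package appends one human-readable line describing the
    filter it applied and the record counts before/after.
    """

    records: pd.DataFrame
    observations: pd.DataFrame
    annotations: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def copy(self) -> "DissectionDataset":
        return DissectionDataset(
            records=self.records.copy(),
            observations=self.observations.copy(),
            annotations=self.annotations.copy(),
            provenance=list(self.provenance),
        )

    def with_provenance(self, line: str) -> "DissectionDataset":
        out = replace(self, provenance=self.provenance + [line])
        return out

    @property
    def n_hosts(self) -> int:
        return len(self.records)

    @property
    def n_observations(self) -> int:
        return len(self.observations)

    @property
    def host_species(self) -> pd.Series:
        return self.records["host_species"]

    def observed_morphogroups(self) -> list[str]:
        """Morphogroup ids with at least one observation, sorted."""
        return sorted(self.observations["morphogroup_id"].unique())


def _empty_records() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype="object") for c in RECORD_COLUMNS})
    df["host_length_mm"] = df["host_length_mm"].astype(float)
    return df


def _empty_observations() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype="object") for c in OBSERVATION_COLUMNS})
    df["count"] = df["count"].astype("int64")
    return df


def _empty_annotations() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype="object") for c in ANNOTATION_COLUMNS})


def make_dataset(
    records: pd.DataFrame,
    observations: pd.DataFrame | None = None,
    annotations: pd.DataFrame | None = None,
    provenance: list[str] | None = None,
) -> DissectionDataset:
    """Assemble a dataset from partially-specified frames, normalising dtypes."""
    rec = records.copy() if len(records) else _empty_records()
    for c in RECORD_COLUMNS:
        if c not in rec.columns:
            rec[c] = np.nan if c == "host_length_mm" else None
    rec = rec[RECORD_COLUMNS].reset_index(drop=True)
    rec["host_length_mm"] = pd.to_numeric(rec["host_length_mm"], errors="coerce")

    if observations is None or len(observations) == 0:
        obs = _empty_observations()
    else:
        obs = observations.copy()[OBSERVATION_COLUMNS].reset_index(drop=True)
        obs["count"] = pd.to_numeric(obs["count"]).astype("int64")

    if annotations is None or len(annotations) == 0:
        ann = _empty_annotations()
    else:
        ann = annotations.copy()
        if "redundancy_group" not in ann.columns:
            ann["redundancy_group"] = None
        ann = ann[ANNOTATION_COLUMNS].reset_index(drop=True)
        ann["redundancy_group"] = ann["redundancy_group"].where(
            ann["redundancy_group"].notna(), None
        )

    return DissectionDataset(rec, obs, ann, provenance or [])


def load_dialect(path: str | Path) -> dict[str, str]:
    """Load a column-mapping dialect (source header -> canonical name)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        mapping = json.loads(text)
    else:
        mapping = yaml.safe_load(text)
    if not isinstance(mapping, dict):
        raise FormatError(f"dialect file {path} must contain a flat mapping")
    return {str(k): str(v) for k, v in mapping.items()}


def read_annotation_table(
    path: str | Path, dialect: dict[str, str] | None = None
) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if dialect:
        df = df.rename(columns=dialect)
    missing = [c for c in ANNOTATION_COLUMNS if c != "redundancy_group" and c not in df.columns]
    if missing:
        raise FormatError(f"annotation table missing required column(s): {missing}")
    if "redundancy_group" not in df.columns:
        df["redundancy_group"] = ""
    df = df[ANNOTATION_COLUMNS].copy()
    df["redundancy_group"] = df["redundancy_group"].replace("", None)
    return df.reset_index(drop=True)


def read_dissection_table(
    path: str | Path,
    annotations: pd.DataFrame | str | Path | None = None,
    dialect: dict[str, str] | None = None,
) -> DissectionDataset:
    """Read a denormalised dissection CSV into a validated dataset.

    Parameters
    ----------
    path:
        CSV with one row per parasite observation; hosts without parasites
        appear once with empty ``morphogroup_id``/``count`` cells.
    annotations:
        Morphogroup annotation table (frame or CSV path).  When supplied,
        every observed morphogroup must resolve against it.
    dialect:
        Optional source-column -> canonical-column mapping.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if dialect:
        df = df.rename(columns=dialect)
    required = [c for c in DISSECTION_COLUMNS if c not in ("collection_date", "site")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"dissection table missing required column(s): {missing}")
    for optional in ("collection_date", "site"):
        if optional not in df.columns:
            df[optional] = ""

    rec = df[RECORD_COLUMNS].drop_duplicates(subset="host_individual_id").copy()
    # a host id appearing with conflicting metadata is a duplicate, not a merge
    meta_dupes = df[RECORD_COLUMNS].drop_duplicates()
    dup_ids = meta_dupes["host_individual_id"][
        meta_dupes["host_individual_id"].duplicated()
    ].unique()
    if len(dup_ids):
        raise IntegrityError(
            "duplicate host_individual_id with conflicting metadata: "
            + ", ".join(sorted(dup_ids)[:10])
        )
    rec["collection_date"] = rec["collection_date"].replace("", None)
    rec["site"] = rec["site"].replace("", None)
    rec["host_length_mm"] = pd.to_numeric(
        rec["host_length_mm"].replace("", None), errors="raise"
    )

    has_obs = df["morphogroup_id"].astype(str) != ""
    obs = df.loc[has_obs, OBSERVATION_COLUMNS].copy()
    if len(obs):
        obs["count"] = pd.to_numeric(obs["count"]).astype("int64")

    ann: pd.DataFrame | None
    if annotations is None:
        ann = None
    elif isinstance(annotations, (str, Path)):
        ann = read_annotation_table(annotations)
    else:
        ann = annotations

    ds = make_dataset(rec, obs, ann, provenance=[f"read {Path(path).name}"])
    if ann is not None and len(obs):
        known = set(ann["morphogroup_id"])
        unknown = sorted(set(obs["morphogroup_id"]) - known)
        if unknown:
            raise IntegrityError(f"observations reference unknown morphogroup_id(s): {unknown}")
    violations = validate(ds)
    if violations:
        raise IntegrityError("invalid dataset: " + "; ".join(violations[:10]))
    return ds


def write_dissection_table(
    dataset: DissectionDataset,
    path: str | Path,
    annotation_path: str | Path | None = None,
) -> None:
    """Write the canonical denormalised CSV (and optionally the annotations).

    Rows are sorted by host id then morphogroup id so the write is
    byte-stable; absent lengths/dates are written as empty cells, never 0.
    """
    rec = dataset.records
    obs = dataset.observations
    if len(obs):
        merged = obs.merge(rec, on="host_individual_id", how="left")
        uninfected = rec[~rec["host_individual_id"].isin(obs["host_individual_id"])].copy()
    else:
        merged = pd.DataFrame(columns=DISSECTION_COLUMNS)
        uninfected = rec.copy()
    uninfected["morphogroup_id"] = ""
    uninfected["count"] = ""
    out = pd.concat([merged[DISSECTION_COLUMNS], uninfected[DISSECTION_COLUMNS]])
    out = out.sort_values(["host_individual_id", "morphogroup_id"], kind="stable")
    out = out.fillna("")
    # integer counts must not round-trip through float ("3.0")
    out["count"] = out["count"].map(lambda v: "" if v == "" else str(int(v)))
    out["host_length_mm"] = out["host_length_mm"].map(
        lambda v: "" if v == "" else format(float(v), "g")
    )
    out.to_csv(path, index=False)
    if annotation_path is not None:
        ann = dataset.annotations.fillna("").sort_values("morphogroup_id", kind="stable")
        ann.to_csv(annotation_path, index=False)


def validate(dataset: DissectionDataset) -> list[str]:
    """Check every dataset invariant; return a description per violation.

    Side-effect free: never raises for a data problem, never mutates.
    """
    v: list[str] = []
    rec, obs, ann = dataset.records, dataset.observations, dataset.annotations

    dup = rec["host_individual_id"][rec["host_individual_id"].duplicated()]
    for hid in dup.unique():
        v.append(f"record: duplicate host_individual_id {hid!r}")

    bad_group = rec.loc[~rec["host_group"].isin(HOST_GROUPS)]
    for _, row in bad_group.iterrows():
        v.append(
            f"record {row['host_individual_id']!r}: host_group {row['host_group']!r} "
            f"not in {sorted(HOST_GROUPS)}"
        )

    lengths = rec["host_length_mm"]
    bad_len = rec.loc[lengths.notna() & (lengths <= 0)]
    for _, row in bad_len.iterrows():
        v.append(
            f"record {row['host_individual_id']!r}: host_length_mm must be > 0, "
            f"got {row['host_length_mm']}"
        )

    # a host species' group label must be unanimous across its records
    groups_per_species = rec.groupby("host_species")["host_group"].nunique()
    for sp in groups_per_species.index[groups_per_species > 1]:
        v.append(f"host_species {sp!r}: conflicting host_group labels across records")

    if len(obs):
        bad_count = obs.loc[obs["count"] < 1]
        for _, row in bad_count.iterrows():
            v.append(
                f"observation ({row['host_individual_id']!r}, {row['morphogroup_id']!r}): "
                f"count must be >= 1, got {row['count']}"
            )
        known_hosts = set(rec["host_individual_id"])
        for hid in sorted(set(obs["host_individual_id"]) - known_hosts):
            v.append(f"observation references unknown host_individual_id {hid!r}")
        if len(ann):
            known_mg = set(ann["morphogroup_id"])
            for mid in sorted(set(obs["morphogroup_id"]) - known_mg):
                v.append(f"observation references unknown morphogroup_id {mid!r}")

    if len(ann):
        for mid in ann["morphogroup_id"][ann["morphogroup_id"].duplicated()].unique():
            v.append(f"annotation: duplicate morphogroup_id {mid!r}")
        bad_taxon = ann.loc[~ann["parasite_taxon"].isin(PARASITE_TAXA)]
        for _, row in bad_taxon.iterrows():
            v.append(
                f"annotation {row['morphogroup_id']!r}: parasite_taxon "
                f"{row['parasite_taxon']!r} not recognised"
            )
        bad_lc = ann.loc[~ann["life_cycle"].isin(LIFE_CYCLES)]
        for _, row in bad_lc.iterrows():
            v.append(
                f"annotation {row['morphogroup_id']!r}: life_cycle "
                f"{row['life_cycle']!r} not in ['DLC', 'ILC']"
            )
        bad_stage = ann.loc[~ann["life_stage"].isin(LIFE_STAGES)]
        for _, row in bad_stage.iterrows():
            v.append(
                f"annotation {row['morphogroup_id']!r}: life_stage "
                f"{row['life_stage']!r} not recognised"
            )
        # a direct life cycle has no intermediate host, hence no larval stage
        dlc_nonadult = ann.loc[(ann["life_cycle"] == "DLC") & (ann["life_stage"] != "adult")]
        for _, row in dlc_nonadult.iterrows():
            v.append(
                f"annotation {row['morphogroup_id']!r}: DLC morphogroup must have "
                f"life_stage 'adult', got {row['life_stage']!r}"
            )
    return v
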