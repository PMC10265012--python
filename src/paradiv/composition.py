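"""Contingency analyses of parasite life-cycle and life-stage composition.

Two community-composition questions are asked of each host partition
(fish or invertebrates), both answered with a standard Pearson chi-square
test of homogeneity on morphogroup counts:

* **life cycle** — are the proportions of direct-life-cycle (one host)
  versus indirect-life-cycle (multiple host) parasite species the same
  across ecosystems?  Counts come from the redundancy-filtered partition,
  so a species represented by both an adult and a larval morphogroup is
  not counted twice.
* **life stage** — are the proportions of morphogroups in different life
  stage categories (adult, cystacanth, larval nematode, metacestode,
  metacercaria, ...) the same across ecosystems?  Here every intermediate
  stage morphotype is deliberately retained — the stages themselves are
  the signal, evidence of which trophic pathways parasites use.

A morphogroup observed in an ecosystem's partition counts once in that
ecosystem's column regardless of how many hosts carry it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import DissectionDataset

#: Default life-stage categories for fish hosts: category name -> stages pooled.
FISH_STAGE_CATEGORIES: dict[str, frozenset[str]] = {
    "adult": frozenset({"adult"}),
    "cystacanth": frozenset({"cystacanth"}),
    "larval_nematode": frozenset({"larval_nematode"}),
    "metacestode": frozenset({"metacestode"}),
    "metacercaria": frozenset({"metacercaria"}),
}

#: Default categories for invertebrate hosts; trematode intermediate stages
#: (metacercariae and sporocysts) are pooled into one category so the table
#: keeps five rows.  The pooling is a configurable convention.
INVERTEBRATE_STAGE_CATEGORIES: dict[str, frozenset[str]] = {
    "adult": frozenset({"adult"}),
    "cystacanth": frozenset({"cystacanth"}),
    "larval_nematode": frozenset({"larval_nematode"}),
    "metacestode": frozenset({"metacestode"}),
    "metacercaria_or_sporocyst": frozenset({"metacercaria", "sporocyst"}),
}


@dataclass
class ContingencyTable:
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray  # (rows, cols) non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)


@dataclass
class ChiSquareResult:
    chi2: float
    df: int
    p_value: float
    expected: np.ndarray
    low_expected_warning: bool


def _observed_annotations(dataset: DissectionDataset) -> pd.DataFrame:
    """(morphogroup, ecosystem) pairs observed in the partition, annotated."""
    obs = dataset.observations.merge(
        dataset.records[["host_individual_id", "ecosystem"]], on="host_individual_id"
    )
    pairs = obs[["morphogroup_id", "ecosystem"]].drop_duplicates()
    return pairs.merge(dataset.annotations, on="morphogroup_id", how="left")


def life_cycle_table(
    dataset: DissectionDataset, ecosystems: list[str]
) -> ContingencyTable:
    """2 x E table of distinct morphogroup counts by life cycle x ecosystem.

    The dataset should already be harmonized and redundancy-filtered so
    each biological species contributes once per ecosystem.
    """
    pairs = _observed_annotations(dataset)
    present = set(pairs["ecosystem"])
    absent = [e for e in ecosystems if e not in present]
    if absent:
        raise ValueError(f"ecosystem label(s) absent from data: {absent}")
    rows = ["DLC", "ILC"]
    counts = np.zeros((2, len(ecosystems)), dtype=np.int64)
    for j, eco in enumerate(ecosystems):
        sub = pairs[pairs["ecosystem"] == eco]
        for i, lc in enumerate(rows):
            counts[i, j] = int((sub["life_cycle"] == lc).sum())
    return ContingencyTable(rows, list(ecosystems), counts)


def life_stage_table(
    dataset: DissectionDataset,
    stage_categories: dict[str, frozenset[str]] | list[str],
    ecosystems: list[str],
) -> ContingencyTable:
    """|categories| x E table of morphogroup counts by life stage x ecosystem.

    ``stage_categories`` is either an ordered list of stage names (one
    category each) or a mapping category name -> set of stages pooled into
    it.  A morphogroup whose stage falls outside every category is an
    error: silently dropping stages would bias the composition.
    """
    if not stage_categories:
        raise ValueError("stage_categories must be non-empty")
    if isinstance(stage_categories, list):
        categories = {s: frozenset({s}) for s in stage_categories}
    else:
        categories = {k: frozenset(v) for k, v in stage_categories.items()}
    pairs = _observed_annotations(dataset)
    present = set(pairs["ecosystem"])
    absent = [e for e in ecosystems if e not in present]
    if absent:
        raise ValueError(f"ecosystem label(s) absent from data: {absent}")
    covered = frozenset().union(*categories.values())
    stray = sorted(
        pairs.loc[~pairs["life_stage"].isin(covered), "morphogroup_id"].unique()
    )
    if stray:
        raise ValueError(
            f"morphogroup(s) with life stage outside the category set: {stray}"
        )
    row_labels = list(categories)
    counts = np.zeros((len(row_labels), len(ecosystems)), dtype=np.int64)
    for j, eco in enumerate(ecosystems):
        sub = pairs[pairs["ecosystem"] == eco]
        for i, cat in enumerate(row_labels):
            counts[i, j] = int(sub["life_stage"].isin(categories[cat]).sum())
    return ContingencyTable(row_labels, list(ecosystems), counts)


def chisq_test(table: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square test of homogeneity, no continuity correction.

    An all-zero row or column makes the statistic undefined; the caller
    should collapse or drop that category rather than have it silently
    contribute nothing.  Expected cells below 5 set a warning flag but do
    not switch the method.
    """
    counts = table.counts
    if counts.sum() == 0:
        raise ValueError("contingency table is empty")
    zero_rows = [table.row_labels[i] for i in np.flatnonzero(counts.sum(axis=1) == 0)]
    zero_cols = [table.col_labels[j] for j in np.flatnonzero(counts.sum(axis=0) == 0)]
    if zero_rows or zero_cols:
        raise ValueError(
            "all-zero row(s)/column(s) "
            f"{zero_rows + zero_cols}: collapse these categories before testing"
        )
    chi2, p, df, expected = stats.chi2_contingency(counts, correction=False)
    return ChiSquareResult(
        chi2=float(chi2),
        df=int(df),
        p_value=float(p),
        expected=expected,
        low_expected_warning=bool((expected < 5).any()),
    )
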