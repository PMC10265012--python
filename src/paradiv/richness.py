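"""Incidence-based parasite richness: Chao2 and species-accumulation curves.

Two levels of analysis share one data structure, the binary incidence
matrix (sampling units x morphogroups):

* **within a host species** — sampling units are dissected host
  individuals; the Chao2 estimator corrects observed richness for
  parasites missed because too few individuals were examined;
* **across host species** — sampling units are host species; the
  sample-based rarefaction (species-accumulation) curve gives the exact
  expected number of parasite morphogroups found in a random subset of
  ``k`` host species.

Chao2 uses only the incidence frequencies of the rarest parasites.  With
``S_obs`` observed morphogroups, ``Q1`` found in exactly one sampling unit
and ``Q2`` in exactly two:

* classic:          ``S = S_obs + Q1^2 / (2 Q2)``  (falls back to the
  bias-corrected term when ``Q2 = 0``);
* bias-corrected:   ``S = S_obs + Q1 (Q1 - 1) / (2 (Q2 + 1))``.

The accumulation curve is closed-form hypergeometric: a parasite occupying
``h_i`` of ``H`` host species is missed by a random ``k``-subset with
probability ``C(H - h_i, k) / C(H, k)``, so

    ``E[S(k)] = sum_i [ 1 - C(H - h_i, k) / C(H, k) ]``.

Binomial ratios are evaluated via log-gamma differences, exact to double
precision for ``H`` well beyond 10^3.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core_data import DissectionDataset


@dataclass
class IncidenceMatrix:
    """Binary detection matrix: rows are sampling units, columns morphogroups."""

    sampling_unit_ids: list[str]
    morphogroup_ids: list[str]
    incidence: np.ndarray  # shape (m, S), entries in {0, 1}

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence, dtype=np.int8)
        if self.incidence.shape != (len(self.sampling_unit_ids), len(self.morphogroup_ids)):
            raise ValueError("incidence shape does not match unit/morphogroup labels")
        if len(set(self.sampling_unit_ids)) != len(self.sampling_unit_ids):
            raise ValueError("sampling unit ids must be unique")
        if len(set(self.morphogroup_ids)) != len(self.morphogroup_ids):
            raise ValueError("morphogroup ids must be unique")
        if not np.isin(self.incidence, (0, 1)).all():
            raise ValueError("incidence entries must be 0 or 1")

    @property
    def m(self) -> int:
        """Number of sampling units."""
        return len(self.sampling_unit_ids)

    def incidence_frequencies(self) -> np.ndarray:
        """h_i: number of sampling units occupied by each morphogroup."""
        return self.incidence.sum(axis=0).astype(int)


@dataclass
class Chao2Estimate:
    s_obs: int
    q1: int
    q2: int
    estimate: float
    variant: str  # 'classic' | 'bias_corrected'


@dataclass
class AccumulationCurve:
    H: int
    h: np.ndarray
    k_values: np.ndarray
    expected_richness: np.ndarray
    variance: np.ndarray | None = None


def build_incidence(dataset: DissectionDataset, level: str = "host_individual") -> IncidenceMatrix:
    """Binary incidence from a dissection dataset.

    ``level='host_individual'`` uses dissected individuals as sampling
    units; ``level='host_species'`` pools individuals within each host
    species.  Units with zero observations appear as all-zero rows —
    dissected-but-uninfected hosts are information and count toward m.
    """
    if dataset.n_hosts == 0:
        raise ValueError("cannot build an incidence matrix from an empty dataset")
    if level == "host_individual":
        units = list(dataset.records["host_individual_id"])
        unit_of_host = {h: h for h in units}
    elif level == "host_species":
        units = sorted(dataset.records["host_species"].unique())
        unit_of_host = dict(
            zip(dataset.records["host_individual_id"], dataset.records["host_species"])
        )
    else:
        raise ValueError(f"unknown level {level!r}")

    morphogroups = dataset.observed_morphogroups()
    mat = np.zeros((len(units), len(morphogroups)), dtype=np.int8)
    if morphogroups:
        u_index = {u: i for i, u in enumerate(units)}
        m_index = {m: j for j, m in enumerate(morphogroups)}
        rows = dataset.observations["host_individual_id"].map(
            lambda h: u_index[unit_of_host[h]]
        )
        cols = dataset.observations["morphogroup_id"].map(m_index)
        mat[rows, cols] = 1
    return IncidenceMatrix(units, morphogroups, mat)


def chao2_from_frequencies(
    h: np.ndarray,
    m: int,
    variant: str = "bias_corrected",
    small_sample_correction: bool = False,
) -> Chao2Estimate:
    """Chao2 from per-morphogroup incidence frequencies ``h`` and ``m`` units."""
    if variant not in ("classic", "bias_corrected"):
        raise ValueError(f"unknown variant {variant!r}")
    if m < 1:
        raise ValueError("need at least one sampling unit")
    h = np.asarray(h)
    s_obs = int((h > 0).sum())
    q1 = int((h == 1).sum())
    q2 = int((h == 2).sum())
    factor = (m - 1) / m if small_sample_correction else 1.0
    if q1 == 0:
        correction = 0.0
    elif variant == "classic" and q2 > 0:
        correction = q1 * q1 / (2.0 * q2)
    else:
        # bias-corrected term; also the standard classic fallback at Q2 = 0
        correction = q1 * (q1 - 1) / (2.0 * (q2 + 1))
    return Chao2Estimate(s_obs, q1, q2, s_obs + factor * correction, variant)


def chao2(
    matrix: IncidenceMatrix,
    variant: str = "bias_corrected",
    small_sample_correction: bool = False,
) -> Chao2Estimate:
    """Chao2 incidence-based richness estimate.

    ``small_sample_correction`` applies the (m-1)/m factor to the
    correction term; off by default.
    """
    return chao2_from_frequencies(
        matrix.incidence_frequencies(), matrix.m, variant, small_sample_correction
    )


def host_species_summaries(
    dataset: DissectionDataset,
    variant: str = "bias_corrected",
) -> pd.DataFrame:
    """Per-host-species summary table feeding the rank ANCOVA.

    One row per (ecosystem, host species): number of individuals examined,
    observed richness, Chao2 estimate from the individual-level incidence
    within that species, mean body length over individuals with a length,
    and the host group.
    """
    rec = dataset.records
    obs = dataset.observations.merge(
        rec[["host_individual_id", "ecosystem", "host_species"]], on="host_individual_id"
    )
    # h: per (species, morphogroup) number of distinct infected individuals
    h_by_species: dict[tuple, np.ndarray] = {}
    if len(obs):
        freq = (
            obs.groupby(["ecosystem", "host_species", "morphogroup_id"])[
                "host_individual_id"
            ]
            .nunique()
            .reset_index()
        )
        h_by_species = {
            key: g["host_individual_id"].to_numpy()
            for key, g in freq.groupby(["ecosystem", "host_species"])
        }
    empty = np.array([], dtype=int)
    rows = []
    for (eco, sp), grp in rec.groupby(["ecosystem", "host_species"], sort=True):
        h = h_by_species.get((eco, sp), empty)
        est = chao2_from_frequencies(h, len(grp), variant)
        lengths = grp["host_length_mm"].dropna()
        rows.append(
            {
                "host_species": sp,
                "host_group": grp["host_group"].iloc[0],
                "ecosystem": eco,
                "n_individuals": len(grp),
                "s_obs": est.s_obs,
                "chao2_estimate": est.estimate,
                "mean_length": lengths.mean() if len(lengths) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _log_binom(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def accumulation_curve(
    matrix: IncidenceMatrix,
    var_draws: int = 0,
    seed: int | None = None,
) -> AccumulationCurve:
    """Expected species-accumulation curve over host-species sampling units.

    ``var_draws > 0`` additionally reports a Monte-Carlo variance of
    richness at each ``k`` (over ``var_draws`` random k-subsets, seeded);
    the mean itself is always the closed-form value.
    """
    H = matrix.m
    if H < 1:
        raise ValueError("need at least one sampling unit")
    h = matrix.incidence_frequencies()
    h = h[h > 0]
    k_values = np.arange(1, H + 1)
    if len(h) == 0:
        expected = np.zeros(H)
    else:
        # P(parasite i absent from a k-subset) = C(H - h_i, k) / C(H, k)
        hk = k_values[None, :]
        hh = h[:, None]
        with np.errstate(invalid="ignore"):
            log_absent = _log_binom(H - hh, hk) - _log_binom(H, hk)
        p_absent = np.where(H - hh >= hk, np.exp(log_absent), 0.0)
        expected = (1.0 - p_absent).sum(axis=0)
    variance = None
    if var_draws > 0:
        rng = np.random.default_rng(seed)
        variance = np.empty(H)
        inc = matrix.incidence.astype(bool)
        for idx, k in enumerate(k_values):
            richness = np.array(
                [
                    int(inc[rng.choice(H, size=k, replace=False)].any(axis=0).sum())
                    for _ in range(var_draws)
                ]
            )
            variance[idx] = richness.var(ddof=1) if var_draws > 1 else 0.0
    return AccumulationCurve(H, h, k_values, expected, variance)


def accumulation_oracle(matrix: IncidenceMatrix, k: int, guard: int = 100_000) -> float:
    """Exact mean richness over all k-subsets by brute-force enumeration.

    Independent cross-check for `accumulation_curve`; refuses when
    ``C(H, k)`` exceeds ``guard``.
    """
    H = matrix.m
    if not 1 <= k <= H:
        raise ValueError(f"k must be in 1..{H}, got {k}")
    n_subsets = math.comb(H, k)
    if n_subsets > guard:
        raise ValueError(f"C({H},{k}) = {n_subsets} exceeds enumeration guard {guard}")
    inc = matrix.incidence.astype(bool)
    total = 0
    for subset in itertools.combinations(range(H), k):
        total += int(inc[list(subset)].any(axis=0).sum())
    return total / n_subsets
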