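"""Iterative profile-enrichment of DE gene sets over temporal profiles.

The null hypothesis is that differentially expressed genes are spread across
temporal profiles in proportion to profile size. A Pearson chi-square
goodness-of-fit test gates the procedure: while the gate rejects (p below
gate_alpha), the profile with the largest Pearson contribution
(O - E)^2 / E is removed from the table and the gate re-run. Each removed
profile is then verified with Fisher's exact test on the original universe,
and the Fisher p-values are Benjamini-Hochberg corrected across removed
profiles; a removed profile is called ENRICHED (odds ratio > 1) or DEPLETED
(odds ratio < 1) when its corrected p clears gate_alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from ._exact import fisher_exact_2x2, odds_ratio_2x2
from .de_filter import bh_adjust
from .expression_io import GeneSet, logger
from .temporal_profiles import ProfileSet


@dataclass
class ProfileCounts:
    """Observed DE counts and universe sizes per profile."""

    profile_ids: list[int]
    observed: np.ndarray
    universe_sizes: np.ndarray

    def __post_init__(self):
        self.observed = np.asarray(self.observed, dtype=float)
        self.universe_sizes = np.asarray(self.universe_sizes, dtype=float)
        if not (len(self.profile_ids) == self.observed.size == self.universe_sizes.size):
            raise ValueError("profile_ids, observed and universe_sizes must align")
        if (self.observed < 0).any() or (self.observed > self.universe_sizes).any():
            raise ValueError("need 0 <= observed <= universe size in every profile")

    @property
    def n_de(self) -> float:
        return float(self.observed.sum())

    @property
    def n_universe(self) -> float:
        return float(self.universe_sizes.sum())

    @classmethod
    def from_assignment(
        cls, assignment: pd.Series, de_genes: Iterable[str], universe: Iterable[str]
    ) -> "ProfileCounts":
        """Tabulate per-profile counts; profiles empty in the universe are dropped."""
        universe = set(universe)
        de = set(de_genes) & universe
        in_universe = assignment[assignment.index.isin(universe)]
        sizes = in_universe.value_counts().sort_index()
        observed = in_universe[in_universe.index.isin(de)].value_counts()
        observed = observed.reindex(sizes.index, fill_value=0)
        return cls(list(sizes.index), observed.to_numpy(), sizes.to_numpy())

    def drop(self, profile_id: int) -> "ProfileCounts":
        keep = [i for i, pid in enumerate(self.profile_ids) if pid != profile_id]
        return ProfileCounts(
            [self.profile_ids[i] for i in keep],
            self.observed[keep],
            self.universe_sizes[keep],
        )


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    pvalue: float
    expected: np.ndarray
    contributions: np.ndarray


def chi_square_proportionality(counts: ProfileCounts) -> ChiSquareResult:
    """Pearson chi-square test of proportional DE counts across profiles.

    E_i = n_de * N_i / N; the per-profile Pearson contributions
    (O_i - E_i)^2 / E_i sum to the statistic; df = k - 1.
    """
    if len(counts.profile_ids) < 2:
        raise ValueError("need at least 2 profiles")
    if counts.n_de == 0:
        raise ValueError("no DE genes to test")
    if (counts.universe_sizes == 0).any():
        raise ValueError("profiles with an empty universe must be dropped upstream")
    expected = counts.n_de * counts.universe_sizes / counts.n_universe
    contributions = (counts.observed - expected) ** 2 / expected
    statistic = float(contributions.sum())
    df = len(counts.profile_ids) - 1
    if (expected < 5).any():
        logger.warning(
            "chi-square approximation caveat: %d profiles have expected count < 5",
            int((expected < 5).sum()),
        )
    return ChiSquareResult(statistic, df, float(chi2.sf(statistic, df)), expected, contributions)


@dataclass(frozen=True)
class Removal:
    profile_id: int
    contribution: float
    direction: str  # "over" (O > E) or "under"


@dataclass
class RemovalTrace:
    removals: list[Removal]
    gate_pvalues: list[float]  # gate p at each iteration, including the final pass
    remaining: ProfileCounts


def iterative_profile_removal(
    counts: ProfileCounts,
    gate_alpha: float = 0.05,
    max_removals: int | None = None,
) -> RemovalTrace:
    """Remove the largest-contribution profile until the gate stops rejecting.

    One profile is removed per iteration (ties broken by lowest id) and the
    chi-square gate re-run on the reduced table; the loop stops when the gate
    p reaches `gate_alpha`, only 2 profiles remain, or `max_removals` is hit.
    """
    if max_removals is None:
        max_removals = max(1, len(counts.profile_ids) // 2)
    removals: list[Removal] = []
    gate_ps: list[float] = []
    current = counts
    while True:
        gate = chi_square_proportionality(current)
        gate_ps.append(gate.pvalue)
        if (
            gate.pvalue >= gate_alpha
            or len(removals) >= max_removals
            or len(current.profile_ids) <= 2
        ):
            break
        best = np.flatnonzero(gate.contributions == gate.contributions.max())
        victim = min(current.profile_ids[i] for i in best)
        vi = current.profile_ids.index(victim)
        removals.append(
            Removal(
                profile_id=victim,
                contribution=float(gate.contributions[vi]),
                direction="over" if current.observed[vi] > gate.expected[vi] else "under",
            )
        )
        current = current.drop(victim)
        if current.n_de == 0:  # every remaining profile is DE-free: nothing to test
            break
    return RemovalTrace(removals=removals, gate_pvalues=gate_ps, remaining=current)


@dataclass(frozen=True)
class FisherResult:
    table: np.ndarray  # [[DE&in, DE&out], [nonDE&in, nonDE&out]]
    odds_ratio: float
    pvalue: float


def fisher_verify(
    assignment: pd.Series,
    de_genes: Iterable[str],
    profile_id: int,
    universe: Iterable[str],
    alternative: str = "two-sided",
) -> FisherResult:
    """Fisher's exact test of one profile's DE occupancy over the original universe."""
    universe = set(universe)
    de = set(de_genes) & universe
    members = set(assignment.index[assignment == profile_id]) & universe
    if not members:
        raise ValueError(f"profile {profile_id} is empty in the universe")
    a = len(de & members)
    b = len(de) - a
    c = len(members) - a
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    if len(de) == 0 or len(de) == len(universe):
        logger.warning("degenerate margins for profile %s: p = 1", profile_id)
        return FisherResult(table, odds_ratio_2x2(table), 1.0)
    oddsr, p = fisher_exact_2x2(table, alternative=alternative)
    return FisherResult(table, oddsr, p)


@dataclass
class EnrichmentReport:
    """Per-profile enrichment outcome for one DE gene set."""

    de_label: str
    table: pd.DataFrame  # profile_id, n_universe, observed, expected, contribution,
    #                      removal_rank, direction, odds_ratio, fisher_p, fisher_p_bh, call
    gate_pvalues: list[float]
    final_gate_p: float | None
    n_de_used: int
    n_dropped: int

    def enriched_profiles(self) -> list[int]:
        return list(self.table.loc[self.table["call"] == "enriched", "profile_id"])

    def depleted_profiles(self) -> list[int]:
        return list(self.table.loc[self.table["call"] == "depleted", "profile_id"])


def enrich(
    de_set: GeneSet,
    profiles: ProfileSet,
    universe: Iterable[str] | None = None,
    gate_alpha: float = 0.05,
    max_removals: int | None = None,
    alternative: str = "two-sided",
) -> EnrichmentReport:
    """Run the full iterative enrichment procedure for one DE gene set.

    The universe defaults to all genes with a profile assignment; DE genes
    outside it are dropped (count logged). Fisher verification of each removed
    profile is computed on the original, pre-removal universe, and corrected
    by BH across removed profiles.
    """
    assignment = profiles.assignment
    universe = set(universe) if universe is not None else set(assignment.index)
    universe &= set(assignment.index)
    de = set(de_set.genes) & universe
    n_dropped = len(de_set.genes) - len(de)
    if n_dropped:
        logger.info("%s: %d DE genes outside the universe dropped", de_set.label, n_dropped)

    columns = [
        "profile_id", "n_universe", "observed", "expected", "contribution",
        "removal_rank", "direction", "odds_ratio", "fisher_p", "fisher_p_bh", "call",
    ]
    if not de:
        logger.warning("%s: no DE genes intersect the universe; empty report", de_set.label)
        return EnrichmentReport(de_set.label, pd.DataFrame(columns=columns), [], None, 0, n_dropped)

    counts = ProfileCounts.from_assignment(assignment, de, universe)
    if len(counts.profile_ids) < 2:
        logger.warning("%s: fewer than 2 populated profiles; empty report", de_set.label)
        return EnrichmentReport(
            de_set.label, pd.DataFrame(columns=columns), [], None, len(de), n_dropped
        )
    gate0 = chi_square_proportionality(counts)
    trace = iterative_profile_removal(counts, gate_alpha=gate_alpha, max_removals=max_removals)

    rows = []
    idx = {pid: i for i, pid in enumerate(counts.profile_ids)}
    removal_rank = {r.profile_id: rank for rank, r in enumerate(trace.removals, start=1)}
    fisher_results = {
        r.profile_id: fisher_verify(assignment, de, r.profile_id, universe, alternative=alternative)
        for r in trace.removals
    }
    removed_ids = [r.profile_id for r in trace.removals]
    p_bh = dict(zip(removed_ids, bh_adjust([fisher_results[i].pvalue for i in removed_ids])))

    for pid in counts.profile_ids:
        i = idx[pid]
        row = {
            "profile_id": pid,
            "n_universe": int(counts.universe_sizes[i]),
            "observed": int(counts.observed[i]),
            "expected": gate0.expected[i],
            "contribution": gate0.contributions[i],
            "removal_rank": removal_rank.get(pid, 0),
            "direction": "",
            "odds_ratio": np.nan,
            "fisher_p": np.nan,
            "fisher_p_bh": np.nan,
            "call": "proportional",
        }
        if pid in fisher_results:
            fr = fisher_results[pid]
            removal = trace.removals[removal_rank[pid] - 1]
            row.update(
                direction=removal.direction,
                odds_ratio=fr.odds_ratio,
                fisher_p=fr.pvalue,
                fisher_p_bh=p_bh[pid],
            )
            if p_bh[pid] < gate_alpha and fr.odds_ratio > 1:
                row["call"] = "enriched"
            elif p_bh[pid] < gate_alpha and fr.odds_ratio < 1:
                row["call"] = "depleted"
            else:
                row["call"] = "removed"
        rows.append(row)

    return EnrichmentReport(
        de_label=de_set.label,
        table=pd.DataFrame(rows, columns=columns),
        gate_pvalues=trace.gate_pvalues,
        final_gate_p=trace.gate_pvalues[-1],
        n_de_used=len(de),
        n_dropped=n_dropped,
    )
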