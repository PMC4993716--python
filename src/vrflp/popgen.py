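"""Alignment polymorphism statistics in the style of DnaSP.

Columns containing a gap or any ambiguous base in any sequence are removed
first ("complete deletion"); every statistic is computed over the included
columns only.  Definitions follow the usual DnaSP conventions:

* segregating sites S: included columns with >= 2 distinct bases
* total mutations eta: sum over columns of (distinct bases - 1)
* singleton sites: two-state columns whose minor base occurs once
* parsimony-informative sites: >= 2 bases each present in >= 2 sequences
* haplotypes: distinct row strings over included columns;
  Hd = n (1 - sum f^2) / (n - 1)
* k: mean pairwise difference count; Pi = k / L
* Rm: Hudson-Kaplan four-gamete minimum number of recombination events
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .seqio import AlignedSet, GroupAssignment

_UNAMBIGUOUS = frozenset("ACGT")


@dataclass(frozen=True)
class SiteFilterResult:
    """Outcome of complete deletion: which columns survive and why the
    rest were dropped (first offending record + symbol per column)."""

    included: tuple[int, ...]
    excluded: tuple[int, ...]
    reasons: dict[int, tuple[str, str]]

    @property
    def n_included(self) -> int:
        return len(self.included)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def complete_deletion(aln: AlignedSet) -> SiteFilterResult:
    """Keep only columns where every sequence has an unambiguous base."""
    included: list[int] = []
    excluded: list[int] = []
    reasons: dict[int, tuple[str, str]] = {}
    for col in range(aln.length):
        offender = None
        for rec in aln.records:
            sym = rec.residues[col]
            if sym not in _UNAMBIGUOUS:
                offender = (rec.id, sym)
                break
        if offender is None:
            included.append(col)
        else:
            excluded.append(col)
            reasons[col] = offender
    if not included:
        raise ValueError("complete deletion removed every column")
    return SiteFilterResult(tuple(included), tuple(excluded), reasons)


def _site_array(aln: AlignedSet, filt: SiteFilterResult) -> np.ndarray:
    """(n, L) array of included-column residues as single characters."""
    full = np.array([list(r.residues) for r in aln.records])
    return full[:, list(filt.included)]


@dataclass(frozen=True)
class PopGenSummary:
    n_sequences: int
    n_sites: int
    segregating_sites: int
    total_mutations: int
    singleton_sites: int
    parsimony_informative_sites: int
    monomorphic_sites: int
    n_haplotypes: int
    haplotype_diversity: float
    avg_pairwise_differences: float
    nucleotide_diversity: float
    rm: int

    def __post_init__(self) -> None:
        assert self.monomorphic_sites + self.segregating_sites == self.n_sites
        assert self.segregating_sites <= self.total_mutations
        assert (self.singleton_sites + self.parsimony_informative_sites
                <= self.segregating_sites)
        assert 0.0 <= self.haplotype_diversity <= 1.0 + 1e-12
        assert abs(self.nucleotide_diversity * self.n_sites
                   - self.avg_pairwise_differences) < 1e-9
        assert self.rm >= 0

    def to_dict(self) -> dict:
        return asdict(self)


def summary(aln: AlignedSet, filt: SiteFilterResult | None = None
            ) -> PopGenSummary:
    """Full polymorphism summary over the included columns."""
    n = len(aln)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    if filt is None:
        filt = complete_deletion(aln)
    sites = _site_array(aln, filt)
    L = sites.shape[1]

    seg = eta = singletons = informative = 0
    biallelic_patterns: list[np.ndarray] = []
    biallelic_positions: list[int] = []
    for c in range(L):
        col = sites[:, c]
        states, counts = np.unique(col, return_counts=True)
        k_states = len(states)
        if k_states >= 2:
            seg += 1
            eta += k_states - 1
            if k_states == 2 and counts.min() == 1:
                singletons += 1
            if np.sum(counts >= 2) >= 2:
                informative += 1
            if k_states == 2:
                biallelic_patterns.append(col == states[0])
                biallelic_positions.append(filt.included[c])

    haplotypes = ["".join(row) for row in sites]
    uniq, hap_counts = np.unique(haplotypes, return_counts=True)
    freqs = hap_counts / n
    hd = n * (1.0 - float(np.sum(freqs ** 2))) / (n - 1)

    total_diff = 0
    for i, j in itertools.combinations(range(n), 2):
        total_diff += int(np.sum(sites[i] != sites[j]))
    n_pairs = n * (n - 1) // 2
    k = total_diff / n_pairs
    pi = k / L

    rm = four_gamete_rm(biallelic_patterns, biallelic_positions)

    return PopGenSummary(
        n_sequences=n,
        n_sites=L,
        segregating_sites=seg,
        total_mutations=eta,
        singleton_sites=singletons,
        parsimony_informative_sites=informative,
        monomorphic_sites=L - seg,
        n_haplotypes=len(uniq),
        haplotype_diversity=hd,
        avg_pairwise_differences=k,
        nucleotide_diversity=pi,
        rm=rm,
    )


def four_gamete_rm(
    patterns: Sequence[np.ndarray],
    positions: Sequence[int] | None = None,
) -> int:
    """Hudson-Kaplan minimum recombination count from biallelic sites.

    ``patterns`` are boolean vectors (one per site, True = first allele).
    A pair of sites showing all four gametes defines a conflicting
    interval; Rm is the size of a maximal set of pairwise-disjoint such
    intervals, found by the standard right-endpoint greedy scan.
    """
    m = len(patterns)
    if positions is None:
        positions = list(range(m))
    order = np.argsort(np.asarray(positions))
    pats = [np.asarray(patterns[i], dtype=bool) for i in order]
    pos = [positions[i] for i in order]

    intervals: list[tuple[int, int]] = []
    for a in range(m):
        for b in range(a + 1, m):
            x, y = pats[a], pats[b]
            gametes = {(bool(u), bool(v)) for u, v in zip(x, y)}
            if len(gametes) == 4:
                intervals.append((pos[a], pos[b]))
    if not intervals:
        return 0
    intervals.sort(key=lambda iv: iv[1])
    rm = 0
    last_right = -np.inf
    for left, right in intervals:
        if left >= last_right:
            rm += 1
            last_right = right
    return rm


@dataclass(frozen=True)
class BetweenGroupSummary:
    group_x: str
    group_y: str
    k_between: float
    eta_union: int

    def __post_init__(self) -> None:
        assert self.k_between >= 0
        assert self.eta_union >= 0

    def to_dict(self) -> dict:
        return asdict(self)


def between_groups(
    aln: AlignedSet,
    groups: GroupAssignment,
    pair: tuple[str, str],
    filt: SiteFilterResult | None = None,
) -> BetweenGroupSummary:
    """Cross-group average pairwise differences and pooled mutation count.

    ``k_between`` averages per-pair mismatches over all cross-group pairs;
    ``eta_union`` is eta computed over the pooled rows of both groups.
    """
    gx, gy = pair
    groups.validate_against(aln.ids)
    members_x = [s for s in groups.members(gx) if s in set(aln.ids)]
    members_y = [s for s in groups.members(gy) if s in set(aln.ids)]
    if not members_x or not members_y:
        raise ValueError(f"group pair ({gx!r}, {gy!r}) has an empty side")
    if filt is None:
        filt = complete_deletion(aln)
    sites = _site_array(aln, filt)
    index = {sid: i for i, sid in enumerate(aln.ids)}

    total = 0
    for sx in members_x:
        for sy in members_y:
            total += int(np.sum(sites[index[sx]] != sites[index[sy]]))
    k_between = total / (len(members_x) * len(members_y))

    pooled = sites[[index[s] for s in (*members_x, *members_y)]]
    eta_union = 0
    for c in range(pooled.shape[1]):
        eta_union += len(np.unique(pooled[:, c])) - 1

    return BetweenGroupSummary(
        group_x=gx, group_y=gy, k_between=k_between, eta_union=eta_union
    )


def group_summaries(
    aln: AlignedSet,
    groups: GroupAssignment,
    filt: SiteFilterResult | None = None,
) -> dict[str, PopGenSummary]:
    """Per-group polymorphism summaries (groups of one sequence skipped).

    The global complete-deletion filter is reused so per-group numbers are
    comparable across groups.
    """
    if filt is None:
        filt = complete_deletion(aln)
    out: dict[str, PopGenSummary] = {}
    by_id = {r.id: r for r in aln.records}
    for g in groups.groups:
        members = [by_id[s] for s in groups.members(g) if s in by_id]
        if len(members) < 2:
            continue
        sub = AlignedSet(tuple(members))
        out[g] = summary(sub, filt)
    return out
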