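"""Saturation screening: flag partitions whose informativeness decays more
than a threshold fraction from its peak before a time boundary, and prune
the flagged sites from the alignment."""

from __future__ import annotations

from dataclasses import dataclass

from .informativeness import PIProfile, decay_fraction, profile_slope
from .seqio import (Alignment, PartitionScheme, StrideRange, count_sites,
                    extract_subalignment)

__all__ = ["ScreeningReport", "screen", "prune"]

DEFAULT_BOUNDARY = 145.0  # Ma, Jurassic-Cretaceous
DEFAULT_THRESHOLD = 0.05


@dataclass
class SubsetRecord:
    name: str
    peak_time: float
    slope: float
    decay_at_boundary: float
    flagged: bool
    n_sites: int


@dataclass
class ScreeningReport:
    records: list[SubsetRecord]
    boundary: float
    threshold: float
    sites_removed: int
    sites_retained: int

    def flagged_subsets(self) -> list[str]:
        return [r.name for r in self.records if r.flagged]

    def retained_subsets(self) -> list[str]:
        return [r.name for r in self.records if not r.flagged]

    def to_dict(self) -> dict:
        return {
            "parameters": {"boundary": self.boundary,
                           "threshold": self.threshold},
            "totals": {"sites_removed": self.sites_removed,
                       "sites_retained": self.sites_retained},
            "subsets": [vars(r) for r in self.records],
        }


def screen(profiles: list[PIProfile], scheme: PartitionScheme, *,
           boundary: float = DEFAULT_BOUNDARY,
           threshold: float = DEFAULT_THRESHOLD,
           alignment_length: int | None = None) -> ScreeningReport:
    """Flag exactly the subsets whose decay at the boundary strictly exceeds
    the threshold ("greater than" comparison; a peak sitting on the boundary
    has decay 0 and is retained)."""
    by_name = {p.name: p for p in profiles}
    missing = [n for n in scheme.subsets if n not in by_name]
    if missing:
        raise ValueError(f"no profile for subsets: {missing}")
    records = []
    removed = 0
    scheme_total = 0
    for name, ranges in scheme.subsets.items():
        p = by_name[name]
        d = decay_fraction(p, boundary)
        n = count_sites(ranges)
        scheme_total += n
        flagged = d > threshold
        if flagged:
            removed += n
        records.append(SubsetRecord(
            name=name, peak_time=p.peak_time,
            slope=profile_slope(p, boundary) if not p.empty else 0.0,
            decay_at_boundary=d, flagged=flagged, n_sites=n))
    total = alignment_length if alignment_length is not None else scheme_total
    return ScreeningReport(records, boundary, threshold,
                           removed, total - removed)


def prune(aln: Alignment, scheme: PartitionScheme, report: ScreeningReport):
    """Remove the flagged subsets' sites.

    Returns (pruned alignment, re-indexed scheme for the retained subsets,
    old->new 1-based site map).
    """
    flagged = set(report.flagged_subsets())
    drop: set[int] = set()
    for name in flagged:
        drop |= scheme.sites(name)
    keep = [s for s in range(1, aln.length + 1) if s not in drop]
    site_map = {old: new for new, old in enumerate(keep, start=1)}
    if not drop:
        return aln, scheme, site_map
    pruned = extract_subalignment(aln, keep, allow_empty=True)
    new_subsets: dict[str, list[StrideRange]] = {}
    for name in scheme.subsets:
        if name in flagged:
            continue
        # re-express the retained subset's member sites in new coordinates;
        # strides generally do not survive re-indexing, so emit maximal runs
        new_sites = sorted(site_map[s] for s in scheme.sites(name)
                           if s in site_map)
        new_subsets[name] = _sites_to_ranges(new_sites)
    new_scheme = (PartitionScheme(new_subsets,
                                  {k: v for k, v in scheme.models.items()
                                   if k in new_subsets})
                  if new_subsets else None)
    return pruned, new_scheme, site_map


def _sites_to_ranges(sites: list[int]) -> list[StrideRange]:
    """Greedy decomposition of a sorted site list into stride runs."""
    ranges = []
    i = 0
    n = len(sites)
    while i < n:
        if i + 1 == n:
            ranges.append(StrideRange(sites[i], sites[i], 1))
            break
        step = sites[i + 1] - sites[i]
        j = i + 1
        while j + 1 < n and sites[j + 1] - sites[j] == step:
            j += 1
        ranges.append(StrideRange(sites[i], sites[j], step))
        i = j + 1
    return ranges
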