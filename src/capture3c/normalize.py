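"""Probe-efficiency normalization, low-probe filtering and bait masking.

Capture efficiency varies probe to probe, so raw per-bait totals are not
comparable across baits.  Following the study's scheme, each probe's counts
are scaled to the median raw total over retained probes, after removing the
lowest 22-percentile probes (and, optionally, probes overlapping a
repeat-region track).  Fragments near a bait are dominated by self- and
near-ligation signal and are masked (flagged, never deleted) within a
+/-25 kb window around the probe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import floor

import numpy as np
import pandas as pd

from .extract import ContactTable
from .restriction import BaitRegion, RestrictionMap

RETAINED = "retained"
REMOVED_LOW = "removed_low_efficiency"
REMOVED_REPEAT = "removed_repeat"


@dataclass
class ProbeQC:
    """Per-probe accounting: raw on-target total, scale factor and status.

    ``factor`` is median(raw totals over retained probes) / raw_total and is
    defined only for retained probes (None otherwise).
    """

    bait: str
    raw_total: int
    factor: float | None
    status: str


@dataclass
class NormalizedContacts:
    """Median-scaled contact counts plus the bait-proximal mask.

    ``counts`` carries one row per (bait, fragment) with raw and normalized
    values and a ``masked`` flag; ``mask`` maps each bait to the set of
    fragment indices masked for that bait on the bait's chromosome (fragments
    with zero counts included, since they still enter the mappable set for
    significance testing).
    """

    counts: pd.DataFrame  # bait, chrom, frag_index, frag_start, frag_end, count, norm_count, masked
    factors: dict[str, float]
    mask: dict[str, set[int]] = field(default_factory=dict)
    exclusion_bp: int = 0


def probe_filter(table: ContactTable, pct: float = 22.0,
                 repeats: list[tuple[str, int, int]] | None = None,
                 baits: list[BaitRegion] | None = None) -> list[ProbeQC]:
    """Remove the floor(pct/100 * P) probes with the smallest raw totals.

    Ties are broken by bait name, ascending names removed first.  Probes
    overlapping an optional repeat track are removed regardless of counts
    (and do not consume the percentile quota).  If every probe has zero
    counts, all are removed with a warning.
    """
    if not (0 <= pct < 100):
        raise ValueError("pct must be in [0, 100)")
    totals = dict(table.per_bait_total)
    if not totals:
        raise ValueError("contact table lists no probes")

    repeat_hit: set[str] = set()
    if repeats and baits:
        for b in baits:
            for chrom, s, e in repeats:
                if b.chrom == chrom and b.start < e and b.end > s:
                    repeat_hit.add(b.name)
                    break

    if all(t == 0 for t in totals.values()):
        warnings.warn("all probes have zero counts; removing all")
        return [ProbeQC(n, 0, None, REMOVED_LOW) for n in sorted(totals)]

    eligible = sorted((n for n in totals if n not in repeat_hit),
                      key=lambda n: (totals[n], n))
    n_remove = floor(pct / 100.0 * len(totals))
    low = set(eligible[:n_remove])

    qc = []
    for name in sorted(totals):
        if name in repeat_hit:
            status = REMOVED_REPEAT
        elif name in low:
            status = REMOVED_LOW
        else:
            status = RETAINED
        qc.append(ProbeQC(name, int(totals[name]), None, status))
    return qc


def _retained_with_factors(qc: list[ProbeQC]) -> list[ProbeQC]:
    """Drop zero-total retained probes (warning), then fill in factors from
    the median of the remaining retained totals (average-of-two convention)."""
    retained = [q for q in qc if q.status == RETAINED]
    zero = [q for q in retained if q.raw_total == 0]
    for q in zero:
        warnings.warn(f"retained probe {q.bait} has zero counts; removing")
        q.status = REMOVED_LOW
    retained = [q for q in retained if q.status == RETAINED]
    if not retained:
        raise ValueError("no retained probes with nonzero counts")
    med = float(np.median([q.raw_total for q in retained]))
    for q in retained:
        q.factor = med / q.raw_total
    return qc


def normalize(table: ContactTable, qc: list[ProbeQC]) -> NormalizedContacts:
    """Scale every retained probe's counts so its total equals the median raw
    total over retained probes.  Removed probes are dropped from the output."""
    qc = _retained_with_factors(qc)
    factors = {q.bait: q.factor for q in qc if q.status == RETAINED}
    df = table.counts[table.counts["bait"].isin(factors)].copy()
    df["norm_count"] = df["count"] * df["bait"].map(factors)
    df["masked"] = False
    return NormalizedContacts(counts=df.reset_index(drop=True), factors=factors)


def mask_bait_proximal(contacts: NormalizedContacts, rmap: RestrictionMap,
                       baits: list[BaitRegion],
                       exclusion_bp: int = 25000) -> NormalizedContacts:
    """Flag fragments within ``exclusion_bp`` of each bait's probe interval.

    The window is the probe interval expanded by ``exclusion_bp`` on both
    sides; any fragment overlapping it is masked *for that bait only*.  With
    exclusion 0 this masks exactly the bait's own fragment.  Masked entries
    are flagged, never deleted, and unmasked values are untouched.
    """
    if exclusion_bp < 0:
        raise ValueError("exclusion_bp must be >= 0")
    by_name = {b.name: b for b in baits}
    mask: dict[str, set[int]] = {}
    for name in contacts.factors:
        b = by_name.get(name)
        if b is None:
            continue
        hit = np.nonzero(proximity_mask(rmap, b, exclusion_bp))[0]
        mask[name] = set(int(i) for i in hit)

    df = contacts.counts.copy()
    masked = np.zeros(len(df), dtype=bool)
    for name, frag_set in mask.items():
        b = by_name[name]
        m = (df["bait"] == name) & (df["chrom"] == b.chrom) & \
            df["frag_index"].isin(frag_set)
        masked |= m.to_numpy()
    df["masked"] = masked
    return NormalizedContacts(counts=df, factors=dict(contacts.factors),
                              mask=mask, exclusion_bp=exclusion_bp)


def proximity_mask(rmap: RestrictionMap, bait: BaitRegion,
                   exclusion_bp: int) -> np.ndarray:
    """Boolean mask over the fragments of the bait's chromosome: True for
    fragments overlapping the probe interval expanded by ``exclusion_bp``."""
    starts, ends = rmap.fragment_bounds(bait.chrom)
    return (starts < bait.end + exclusion_bp) & (ends > bait.start - exclusion_bp)


def raw_bait_profile(table: ContactTable, rmap: RestrictionMap,
                     bait: BaitRegion, exclusion_bp: int = 25000
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Dense raw-count vector and bait-proximal mask for one bait, straight
    from the contact table (independent of probe QC — the permutation test
    runs on raw integer counts)."""
    n = rmap.n_fragments(bait.chrom)
    counts = np.zeros(n, dtype=np.int64)
    sub = table.counts[(table.counts["bait"] == bait.name) &
                       (table.counts["chrom"] == bait.chrom)]
    counts[sub["frag_index"].to_numpy()] = sub["count"].to_numpy()
    return counts, proximity_mask(rmap, bait, exclusion_bp)


def bait_profile(contacts: NormalizedContacts, rmap: RestrictionMap,
                 bait: BaitRegion) -> tuple[np.ndarray, np.ndarray]:
    """Dense per-fragment raw-count vector and mask for one bait, over every
    fragment of the bait's chromosome (zeros included).

    Significance testing runs on raw integer counts; normalization only
    rescales cross-bait comparisons.
    """
    n = rmap.n_fragments(bait.chrom)
    counts = np.zeros(n, dtype=np.int64)
    sub = contacts.counts[(contacts.counts["bait"] == bait.name) &
                          (contacts.counts["chrom"] == bait.chrom)]
    counts[sub["frag_index"].to_numpy()] = sub["count"].to_numpy()
    mask = np.zeros(n, dtype=bool)
    for i in contacts.mask.get(bait.name, ()):
        mask[i] = True
    return counts, mask
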