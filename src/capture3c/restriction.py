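"""Restriction map, target loci and capture bait design.

The unit of analysis in capture-3C is the restriction fragment: the genomic
interval between consecutive EcoRI recognition sites.  This module builds the
in-silico digest of a genome (or consumes a precomputed cut-site table),
defines the captured risk loci, and derives the named bait probe regions —
the ``flank`` bp on each side of every cut site inside a locus — that anchor
every downstream contact profile.

Coordinates are 0-based half-open throughout; a cut site is the 0-based start
of the recognition motif (``GAATTC``).  Human-facing report output converts to
1-based inclusive elsewhere.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

ECORI_MOTIF = "GAATTC"

__all__ = [
    "ECORI_MOTIF",
    "RestrictionMap",
    "TargetLocus",
    "BaitRegion",
    "InvalidMotifError",
    "digest",
    "digest_fasta",
    "build_fragments",
    "design_baits",
    "assign_prefixes",
    "parse_bait_name",
    "bait_name",
]


class InvalidMotifError(ValueError):
    """Recognition motif contains characters outside A/C/G/T."""


def digest(sequence: str, motif: str = ECORI_MOTIF) -> list[int]:
    """Return 0-based start coordinates of every exact motif occurrence.

    Matching is case-insensitive (soft-masked lowercase matches), overlapping
    occurrences are all reported, and ``N`` (or any ambiguity code) never
    matches.  An empty sequence yields an empty list.
    """
    if not motif or re.search(r"[^ACGTacgt]", motif):
        raise InvalidMotifError(f"motif must be non-empty A/C/G/T, got {motif!r}")
    if not sequence:
        return []
    # lookahead so overlapping occurrences are all found
    pat = re.compile("(?=" + re.escape(motif.upper()) + ")")
    return [m.start() for m in pat.finditer(sequence.upper())]


def digest_fasta(fasta_path: str, motif: str = ECORI_MOTIF) -> "RestrictionMap":
    """Digest every sequence in a FASTA file into a :class:`RestrictionMap`."""
    from pyfaidx import Fasta

    fa = Fasta(fasta_path)
    sites: dict[str, np.ndarray] = {}
    lengths: dict[str, int] = {}
    for name in fa.keys():
        seq = str(fa[name][:])
        sites[name] = np.asarray(digest(seq, motif), dtype=np.int64)
        lengths[name] = len(seq)
    return RestrictionMap(chrom_sites=sites, chrom_lengths=lengths,
                          motif_length=len(motif))


@dataclass
class RestrictionMap:
    """Per-chromosome sorted cut sites and the fragments they induce.

    Fragments are the half-open intervals between consecutive cut sites
    (plus the chromosome-end pieces); they tile each chromosome exactly once.
    """

    chrom_sites: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]
    motif_length: int = 6

    def __post_init__(self) -> None:
        for chrom, sites in self.chrom_sites.items():
            sites = np.asarray(sites, dtype=np.int64)
            self.chrom_sites[chrom] = sites
            if chrom not in self.chrom_lengths:
                raise KeyError(f"no length recorded for chromosome {chrom!r}")
            L = self.chrom_lengths[chrom]
            if sites.size:
                if np.any(np.diff(sites) <= 0):
                    raise ValueError(f"{chrom}: cut sites not strictly increasing")
                if sites[0] < 0 or sites[-1] > L - self.motif_length:
                    raise ValueError(f"{chrom}: cut site outside [0, {L - self.motif_length}]")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_sites)

    def fragment_starts(self, chrom: str) -> np.ndarray:
        """Start coordinate of every (non-empty) fragment on ``chrom``."""
        sites = self.sites(chrom)
        starts = np.concatenate(([0], sites))
        # a site at coordinate 0 would induce an empty leading fragment
        if sites.size and sites[0] == 0:
            starts = starts[1:]
        return starts

    def fragment_bounds(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        starts = self.fragment_starts(chrom)
        ends = np.concatenate((starts[1:], [self.chrom_lengths[chrom]]))
        return starts, ends

    def n_fragments(self, chrom: str) -> int:
        return int(self.fragment_starts(chrom).size)

    def sites(self, chrom: str) -> np.ndarray:
        try:
            return self.chrom_sites[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def fragment_index(self, chrom: str, pos) -> np.ndarray | int:
        """Index of the fragment containing ``pos`` (scalar or array)."""
        starts = self.fragment_starts(chrom)
        idx = np.searchsorted(starts, pos, side="right") - 1
        return idx if np.ndim(pos) else int(idx)

    def nearest_site_distance(self, chrom: str, pos) -> np.ndarray | int:
        """Distance (bp) from ``pos`` to the nearest cut site; chromosome ends
        are not cut sites.  Returns a large sentinel if the chromosome has no
        sites."""
        sites = self.sites(chrom)
        pos_arr = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        if sites.size == 0:
            d = np.full(pos_arr.shape, np.iinfo(np.int64).max)
        else:
            j = np.searchsorted(sites, pos_arr)
            left = np.where(j > 0, np.abs(pos_arr - sites[np.maximum(j - 1, 0)]),
                            np.iinfo(np.int64).max)
            right = np.where(j < sites.size,
                             np.abs(sites[np.minimum(j, sites.size - 1)] - pos_arr),
                             np.iinfo(np.int64).max)
            d = np.minimum(left, right)
        return d if np.ndim(pos) else int(d[0])


def build_fragments(rmap: RestrictionMap, chrom: str) -> list[tuple[int, int]]:
    """Half-open fragments [0,s1),[s1,s2),…,[sk,L) for ``chrom``.

    An undigested chromosome yields the single fragment [0, L); an empty
    leading fragment (site at coordinate 0) is dropped.
    """
    rmap.sites(chrom)  # raises on unknown chromosome
    starts, ends = rmap.fragment_bounds(chrom)
    return [(int(s), int(e)) for s, e in zip(starts, ends)]


@dataclass
class TargetLocus:
    """A captured risk locus: an LD-block-sized interval on one chromosome.

    ``prefix`` orders multiple loci on a chromosome ('A' first, 'B' second …);
    it is empty when the chromosome carries a single locus, matching how the
    study labels its bait regions.
    """

    name: str
    chrom: str
    start: int
    end: int
    prefix: str = ""
    risk_snps: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"locus {self.name}: start >= end")


def assign_prefixes(loci: list[TargetLocus]) -> list[TargetLocus]:
    """Assign A/B/… prefixes in coordinate order per chromosome (in place).

    Chromosomes carrying a single locus get an empty prefix.
    """
    by_chrom: dict[str, list[TargetLocus]] = {}
    for loc in loci:
        by_chrom.setdefault(loc.chrom, []).append(loc)
    for chrom, group in by_chrom.items():
        group.sort(key=lambda l: l.start)
        for a, b in zip(group, group[1:]):
            if b.start < a.end:
                raise ValueError(f"loci {a.name} and {b.name} overlap on {chrom}")
        if len(group) == 1:
            group[0].prefix = ""
        else:
            for i, loc in enumerate(group):
                loc.prefix = chr(ord("A") + i)
    return loci


@dataclass(frozen=True)
class BaitRegion:
    """One capture probe flank: ``flank`` bp on one side of a cut site.

    ``side`` is U for the upstream flank [site−flank, site) and D for the
    downstream flank [site, site+flank); intervals are truncated at locus
    chromosome bounds so their length is at most ``flank``.
    """

    name: str
    locus: str
    chrom: str
    site: int
    site_index: int  # 1-based EcoRI ordinal within the locus
    side: str
    start: int
    end: int
    flank: int

    def __post_init__(self) -> None:
        if self.side not in ("U", "D"):
            raise ValueError("side must be 'U' or 'D'")
        if self.end - self.start > self.flank:
            raise ValueError(f"bait {self.name}: interval longer than flank")


_BAIT_RE = re.compile(r"^([A-Z]?)E([0-9]+)([UD])$")


def bait_name(prefix: str, site_index: int, side: str) -> str:
    return f"{prefix}E{site_index}{side}"


def parse_bait_name(name: str) -> tuple[str, int, str]:
    """Recover (prefix, site_index, side) from a bait name like ``BE7U``."""
    m = _BAIT_RE.match(name)
    if not m:
        raise ValueError(f"unparseable bait name {name!r}")
    return m.group(1), int(m.group(2)), m.group(3)


def design_baits(rmap: RestrictionMap, loci: list[TargetLocus],
                 flank: int = 250) -> list[BaitRegion]:
    """Two baits (U and D flank) per cut site inside each locus.

    Sites are numbered 1..n in coordinate order per locus; names follow the
    prefix + 'E' + ordinal + side convention.  A locus containing no cut sites
    emits a warning and contributes zero baits.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    baits: list[BaitRegion] = []
    for locus in loci:
        sites = rmap.sites(locus.chrom)
        L = rmap.chrom_lengths[locus.chrom]
        inside = sites[(sites >= locus.start) & (sites < locus.end)]
        if inside.size == 0:
            warnings.warn(f"locus {locus.name} contains no cut sites; no baits designed")
            continue
        for i, site in enumerate(inside, start=1):
            site = int(site)
            for side, lo, hi in (("U", max(0, site - flank), site),
                                 ("D", site, min(L, site + flank))):
                baits.append(BaitRegion(
                    name=bait_name(locus.prefix, i, side),
                    locus=locus.name, chrom=locus.chrom, site=site,
                    site_index=i, side=side, start=lo, end=hi, flank=flank))
    names = [b.name for b in baits]
    if len(set(names)) != len(names):
        # names are the contact-table key; loci must carry distinct prefixes
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"bait names collide across loci: {dupes[:5]} …; "
                         "give loci distinct prefixes")
    return baits
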