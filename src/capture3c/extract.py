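"""Read-pair filtering, fragment assignment, classification and aggregation.

A proximity-ligation read pair reports a physical contact between the two
restriction fragments its ends map to.  A pair is *informative* (on-target)
when at least one end lies inside a captured locus within ``flank`` bp of a
cut site of that locus — i.e. inside a bait probe region.  On-target pairs
are cis when both ends share a chromosome, trans otherwise.  Coordinate-level
duplicates (PCR copies) are counted once.

The table-level functions operate on pandas DataFrames with columns
``chrom1 pos1 strand1 chrom2 pos2 strand2`` (unmapped ends encoded as
chrom '.', pos −1) and are fully vectorised; the per-record operations exist
for clarity and testing and share the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .restriction import BaitRegion, RestrictionMap, TargetLocus

PAIR_COLUMNS = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]

UNMAPPED_CHROM = "."

CATEGORIES = ("unmapped", "off_target", "on_target_cis", "on_target_trans")


@dataclass(frozen=True)
class PairRecord:
    """One aligned read pair; ends stored in canonical order so that
    order-swapped PCR duplicates compare equal."""

    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    mapped1: bool = True
    mapped2: bool = True

    def __post_init__(self) -> None:
        end1 = (self.chrom1, self.pos1, self.strand1)
        end2 = (self.chrom2, self.pos2, self.strand2)
        if end2 < end1:
            for a, b in (("chrom1", "chrom2"), ("pos1", "pos2"),
                         ("strand1", "strand2"), ("mapped1", "mapped2")):
                va, vb = getattr(self, a), getattr(self, b)
                object.__setattr__(self, a, vb)
                object.__setattr__(self, b, va)

    @property
    def key(self) -> tuple:
        return (self.chrom1, self.pos1, self.strand1,
                self.chrom2, self.pos2, self.strand2)


@dataclass
class ClassifiedPair:
    pair: PairRecord
    category: str
    anchor_baits: list[str] = field(default_factory=list)
    anchor_distance: int | None = None
    other_fragment: tuple[str, int] | None = None
    duplicate: bool = False


class _LocusSiteIndex:
    """Per-chromosome flat arrays of in-locus cut sites with their bait names,
    for vectorised anchor lookup."""

    def __init__(self, rmap: RestrictionMap, baits: list[BaitRegion],
                 loci: list[TargetLocus]) -> None:
        self.flank = baits[0].flank if baits else 250
        locus_bounds = {l.name: (l.chrom, l.start, l.end) for l in loci}
        per_chrom: dict[str, dict[int, dict]] = {}
        for b in baits:
            chrom, lo, hi = locus_bounds[b.locus]
            d = per_chrom.setdefault(chrom, {}).setdefault(
                b.site, {"start": lo, "end": hi, "U": None, "D": None})
            d[b.side] = b.name
        self.chrom: dict[str, dict[str, np.ndarray]] = {}
        for chrom, by_site in per_chrom.items():
            sites = np.array(sorted(by_site), dtype=np.int64)
            self.chrom[chrom] = {
                "sites": sites,
                "lo": np.array([by_site[s]["start"] for s in sites], dtype=np.int64),
                "hi": np.array([by_site[s]["end"] for s in sites], dtype=np.int64),
                "uname": np.array([by_site[s]["U"] or "" for s in sites], dtype=object),
                "dname": np.array([by_site[s]["D"] or "" for s in sites], dtype=object),
            }

    def anchor(self, chrom: np.ndarray, pos: np.ndarray, flank: int
               ) -> tuple[np.ndarray, np.ndarray]:
        """For each end return (bait name or '', distance to nearest in-locus
        cut site or -1)."""
        names = np.full(pos.shape, "", dtype=object)
        dist = np.full(pos.shape, -1, dtype=np.int64)
        for c, idx in self.chrom.items():
            m = chrom == c
            if not m.any():
                continue
            p = pos[m]
            sites = idx["sites"]
            j = np.clip(np.searchsorted(sites, p), 0, sites.size - 1)
            jl = np.clip(j - 1, 0, sites.size - 1)
            # nearest of the two flanking candidates
            use_left = np.abs(p - sites[jl]) < np.abs(sites[j] - p)
            near = np.where(use_left, jl, j)
            d = np.abs(p - sites[near])
            in_locus = (p >= idx["lo"][near]) & (p < idx["hi"][near])
            # containment in the half-open probe window [site-flank, site+flank),
            # so the anchoring flank region is always well defined
            s_near = sites[near]
            ok = (p >= s_near - flank) & (p < s_near + flank) & in_locus
            side_u = p < sites[near]
            nm = np.where(side_u, idx["uname"][near], idx["dname"][near])
            ok &= nm != ""
            out_names = np.full(p.shape, "", dtype=object)
            out_dist = np.full(p.shape, -1, dtype=np.int64)
            out_names[ok] = nm[ok]
            out_dist[ok] = d[ok]
            names[m] = out_names
            dist[m] = out_dist
        return names, dist


def assign_end(rmap: RestrictionMap, chrom: str, pos: int) -> tuple[int, int]:
    """Fragment index containing ``pos`` and distance to the nearest cut site.

    Chromosome ends are not cut sites; a site-free chromosome returns a
    sentinel distance (max int64).
    """
    L = rmap.chrom_lengths[chrom]
    if not (0 <= pos < L):
        raise ValueError(f"position {pos} outside [0, {L}) on {chrom}")
    return rmap.fragment_index(chrom, pos), rmap.nearest_site_distance(chrom, pos)


def canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    """Reorder ends lexicographically by (chrom, pos, strand) so that
    order-swapped duplicates become identical rows."""
    df = df.copy()
    k1 = list(zip(df["chrom1"], df["pos1"], df["strand1"]))
    k2 = list(zip(df["chrom2"], df["pos2"], df["strand2"]))
    swap = np.array([b < a for a, b in zip(k1, k2)], dtype=bool)
    for a, b in (("chrom1", "chrom2"), ("pos1", "pos2"), ("strand1", "strand2")):
        va, vb = df[a].to_numpy().copy(), df[b].to_numpy().copy()
        df.loc[swap, a] = vb[swap]
        df.loc[swap, b] = va[swap]
    return df


def classify_table(rmap: RestrictionMap, baits: list[BaitRegion],
                   loci: list[TargetLocus], pairs: pd.DataFrame,
                   flank: int = 250) -> pd.DataFrame:
    """Canonicalise, deduplicate and classify a pair table.

    Returns a copy with columns ``category`` (unmapped / off_target /
    on_target_cis / on_target_trans), ``duplicate`` (bool; duplicates keep
    their category but are excluded from all downstream counting),
    ``anchor1``/``anchor2`` (bait name or ''), ``dist1``/``dist2`` and
    ``frag1``/``frag2`` (fragment index, −1 when unmapped).
    """
    df = canonicalize(pairs[PAIR_COLUMNS])
    n = len(df)
    mapped = ((df["chrom1"] != UNMAPPED_CHROM) & (df["chrom2"] != UNMAPPED_CHROM)
              ).to_numpy()
    dup = np.zeros(n, dtype=bool)
    dup[mapped] = df.loc[mapped].duplicated(subset=PAIR_COLUMNS).to_numpy()

    index = _LocusSiteIndex(rmap, baits, loci)
    anchors, dists, frags = [], [], []
    for end in ("1", "2"):
        chrom = df[f"chrom{end}"].to_numpy()
        pos = df[f"pos{end}"].to_numpy()
        a = np.full(n, "", dtype=object)
        d = np.full(n, -1, dtype=np.int64)
        f = np.full(n, -1, dtype=np.int64)
        a[mapped], d[mapped] = index.anchor(chrom[mapped], pos[mapped], flank)
        for c in rmap.chromosomes:
            m = mapped & (chrom == c)
            if m.any():
                f[m] = rmap.fragment_index(c, pos[m])
        anchors.append(a)
        dists.append(d)
        frags.append(f)

    on_target = (anchors[0] != "") | (anchors[1] != "")
    same_chrom = (df["chrom1"] == df["chrom2"]).to_numpy()
    category = np.full(n, "unmapped", dtype=object)
    category[mapped & ~on_target] = "off_target"
    category[mapped & on_target & same_chrom] = "on_target_cis"
    category[mapped & on_target & ~same_chrom] = "on_target_trans"

    df["category"] = category
    df["duplicate"] = dup
    df["anchor1"], df["anchor2"] = anchors
    df["dist1"], df["dist2"] = dists
    df["frag1"], df["frag2"] = frags
    return df


def classify_pair(rmap: RestrictionMap, baits: list[BaitRegion],
                  loci: list[TargetLocus], pair: PairRecord,
                  flank: int = 250) -> ClassifiedPair:
    """Classify a single pair (thin wrapper over the vectorised path)."""
    if not (pair.mapped1 and pair.mapped2):
        raise ValueError("classify_pair expects a fully mapped pair")
    df = pd.DataFrame([{c: getattr(pair, c) for c in PAIR_COLUMNS}])
    row = classify_table(rmap, baits, loci, df, flank).iloc[0]
    anchor_baits = [a for a in (row["anchor1"], row["anchor2"]) if a]
    other = None
    dist = None
    if anchor_baits:
        # the partner of the first anchored end
        if row["anchor1"]:
            other = (row["chrom2"], int(row["frag2"]))
            dist = int(row["dist1"])
        else:
            other = (row["chrom1"], int(row["frag1"]))
            dist = int(row["dist2"])
    return ClassifiedPair(pair=pair, category=str(row["category"]),
                          anchor_baits=anchor_baits, anchor_distance=dist,
                          other_fragment=other, duplicate=bool(row["duplicate"]))


def dedup(pairs: list[ClassifiedPair]) -> tuple[list[ClassifiedPair], int]:
    """Retain the first occurrence of each coordinate tuple; flag the rest.

    Idempotent; returns (stream, duplicates_removed).
    """
    seen: set[tuple] = set()
    removed = 0
    out = []
    for cp in pairs:
        key = cp.pair.key
        if key in seen:
            cp.duplicate = True
            removed += 1
        else:
            seen.add(key)
            cp.duplicate = False
        out.append(cp)
    return out, removed


@dataclass
class ContactTable:
    """Aggregated per-(bait, fragment) contact counts plus library accounting.

    ``library_stats`` mirrors the study's per-library summary rows: raw,
    unmapped, mapped, off_target, on_target, cis, trans, duplicates.
    Duplicates are excluded from every category tally, so
    raw = unmapped + duplicates + off_target + cis + trans, and
    mapped = off_target + on_target, on_target = cis + trans.
    """

    counts: pd.DataFrame  # columns: bait, chrom, frag_index, frag_start, frag_end, count
    per_bait_total: dict[str, int]
    library_stats: dict[str, int]

    def validate(self) -> None:
        s = self.library_stats
        assert s["mapped"] == s["off_target"] + s["on_target"]
        assert s["on_target"] == s["cis"] + s["trans"]
        assert s["raw"] == s["unmapped"] + s["duplicates"] + s["off_target"] + \
            s["cis"] + s["trans"]
        totals = self.counts.groupby("bait")["count"].sum().to_dict()
        for bait, t in self.per_bait_total.items():
            assert totals.get(bait, 0) == t


def aggregate(classified: pd.DataFrame, rmap: RestrictionMap,
              baits: list[BaitRegion]) -> ContactTable:
    """Build the contact-count table from a classified pair table.

    Each non-duplicate on-target pair contributes one count to the profile of
    every bait that anchors it (a pair with both ends in bait regions counts
    once in each bait's profile, giving the symmetric bait x bait signal seen
    in capture heat maps); the counted fragment is the *partner* end's
    fragment.
    """
    live = classified[~classified["duplicate"]]
    stats = {
        "raw": int(len(classified)),
        "unmapped": int((live["category"] == "unmapped").sum()),
        "duplicates": int(classified["duplicate"].sum()),
        "off_target": int((live["category"] == "off_target").sum()),
        "cis": int((live["category"] == "on_target_cis").sum()),
        "trans": int((live["category"] == "on_target_trans").sum()),
    }
    stats["on_target"] = stats["cis"] + stats["trans"]
    stats["mapped"] = stats["off_target"] + stats["on_target"]

    on = live[live["category"].isin(["on_target_cis", "on_target_trans"])]
    parts = []
    for anchor_col, part_chrom, part_frag in (("anchor1", "chrom2", "frag2"),
                                              ("anchor2", "chrom1", "frag1")):
        sub = on[on[anchor_col] != ""]
        if len(sub):
            parts.append(pd.DataFrame({
                "bait": sub[anchor_col].to_numpy(),
                "chrom": sub[part_chrom].to_numpy(),
                "frag_index": sub[part_frag].to_numpy(),
            }))
    if parts:
        long = pd.concat(parts, ignore_index=True)
        counts = (long.groupby(["bait", "chrom", "frag_index"], sort=True)
                  .size().rename("count").reset_index())
    else:
        counts = pd.DataFrame(columns=["bait", "chrom", "frag_index", "count"])
    # attach fragment bounds
    fs = np.zeros(len(counts), dtype=np.int64)
    fe = np.zeros(len(counts), dtype=np.int64)
    for c in rmap.chromosomes:
        m = (counts["chrom"] == c).to_numpy()
        if m.any():
            starts, ends = rmap.fragment_bounds(c)
            idx = counts.loc[m, "frag_index"].to_numpy()
            fs[m] = starts[idx]
            fe[m] = ends[idx]
    counts["frag_start"] = fs
    counts["frag_end"] = fe
    counts = counts[["bait", "chrom", "frag_index", "frag_start", "frag_end", "count"]]

    per_bait = {b.name: 0 for b in baits}
    per_bait.update(counts.groupby("bait")["count"].sum().astype(int).to_dict())
    table = ContactTable(counts=counts, per_bait_total=per_bait,
                         library_stats=stats)
    table.validate()
    return table
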