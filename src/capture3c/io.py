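"""Readers and writers for the pipeline's plain-text formats.

Dialects (all tab-separated, ``#`` comment lines ignored):

* pairs TSV     — chrom1 pos1 strand1 chrom2 pos2 strand2; unmapped ends are
  ``.`` / −1 / ``.``.
* chromsizes    — chrom length (UCSC chrom.sizes convention).
* sites TSV     — chrom pos (0-based motif start), one cut site per line.
* loci BED      — chrom start end name prefix (BED5 with the locus prefix in
  the score slot).
* baits BED     — chrom start end name.
* contacts TSV  — bait chrom frag_index frag_start frag_end count
  [norm_count masked].
* BEDPE         — 10-column minimum for significant bait-fragment pairs.
* JASPAR PWM    — parsed with Bio.motifs.

BED/BEDPE coordinates are 0-based half-open.  ``write`` then ``read`` is the
identity on valid files; malformed lines raise :class:`FormatError` with the
line number.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .extract import PAIR_COLUMNS, ContactTable
from .integrative import PWM
from .normalize import NormalizedContacts, ProbeQC
from .restriction import BaitRegion, RestrictionMap, TargetLocus, parse_bait_name


class FormatError(ValueError):
    """Malformed input line; message carries the 1-based line number."""


def _rows(path):
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield i, line.split("\t")


def _int(value: str, path, lineno, what: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise FormatError(f"{path} line {lineno}: non-integer {what}: {value!r}") \
            from None


# -- pairs ------------------------------------------------------------------

def write_pairs_tsv(df: pd.DataFrame, path) -> None:
    df[PAIR_COLUMNS].to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom1": str, "chrom2": str,
                                            "strand1": str, "strand2": str})
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df[PAIR_COLUMNS]


# -- restriction map --------------------------------------------------------

def write_chromsizes(rmap: RestrictionMap, path) -> None:
    with open(path, "w") as fh:
        for chrom in rmap.chromosomes:
            fh.write(f"{chrom}\t{rmap.chrom_lengths[chrom]}\n")


def write_sites_tsv(rmap: RestrictionMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\n")
        for chrom in rmap.chromosomes:
            for s in rmap.sites(chrom):
                fh.write(f"{chrom}\t{int(s)}\n")


def read_restriction_map(sites_path, chromsizes_path) -> RestrictionMap:
    lengths: dict[str, int] = {}
    for i, f in _rows(chromsizes_path):
        if len(f) < 2:
            raise FormatError(f"{chromsizes_path} line {i}: need chrom<TAB>length")
        lengths[f[0]] = _int(f[1], chromsizes_path, i, "length")
    sites: dict[str, list[int]] = {c: [] for c in lengths}
    for i, f in _rows(sites_path):
        if f[0] == "chrom":
            continue  # header
        if len(f) < 2:
            raise FormatError(f"{sites_path} line {i}: need chrom<TAB>pos")
        chrom = f[0]
        if chrom not in lengths:
            raise FormatError(f"{sites_path} line {i}: unknown chromosome {chrom!r}")
        sites[chrom].append(_int(f[1], sites_path, i, "position"))
    return RestrictionMap(
        chrom_sites={c: np.array(sorted(v), dtype=np.int64)
                     for c, v in sites.items()},
        chrom_lengths=lengths)


# -- loci and baits ---------------------------------------------------------

def write_loci_bed(loci: list[TargetLocus], path) -> None:
    with open(path, "w") as fh:
        for l in loci:
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{l.name}\t{l.prefix}\n")


def read_loci_bed(path) -> list[TargetLocus]:
    loci = []
    for i, f in _rows(path):
        if len(f) < 4:
            raise FormatError(f"{path} line {i}: need >= 4 BED columns")
        start = _int(f[1], path, i, "start")
        end = _int(f[2], path, i, "end")
        if start >= end:
            raise FormatError(f"{path} line {i}: start >= end")
        prefix = f[4] if len(f) > 4 else ""
        loci.append(TargetLocus(name=f[3], chrom=f[0], start=start, end=end,
                                prefix=prefix))
    return loci


def write_baits_bed(baits: list[BaitRegion], path) -> None:
    with open(path, "w") as fh:
        for b in baits:
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.name}\n")


def read_baits_bed(path, loci: list[TargetLocus], flank: int = 250
                   ) -> list[BaitRegion]:
    """Rebuild bait records from BED4 (the cut site is the U end / D start;
    locus membership by containment)."""
    baits = []
    for i, f in _rows(path):
        if len(f) < 4:
            raise FormatError(f"{path} line {i}: need >= 4 BED columns")
        chrom, name = f[0], f[3]
        start = _int(f[1], path, i, "start")
        end = _int(f[2], path, i, "end")
        if start >= end:
            raise FormatError(f"{path} line {i}: start >= end")
        try:
            _, idx, side = parse_bait_name(name)
        except ValueError as e:
            raise FormatError(f"{path} line {i}: {e}") from None
        site = end if side == "U" else start
        locus = next((l.name for l in loci
                      if l.chrom == chrom and l.start <= site < l.end), None)
        if locus is None:
            raise FormatError(f"{path} line {i}: bait {name} in no known locus")
        baits.append(BaitRegion(name=name, locus=locus, chrom=chrom, site=site,
                                site_index=idx, side=side, start=start,
                                end=end, flank=flank))
    return baits


# -- contacts and QC --------------------------------------------------------

CONTACT_COLUMNS = ["bait", "chrom", "frag_index", "frag_start", "frag_end",
                   "count"]


def write_contacts_tsv(table: ContactTable, path) -> None:
    table.counts.to_csv(path, sep="\t", index=False)


def read_contacts_tsv(path, baits: list[BaitRegion] | None = None
                      ) -> ContactTable:
    df = pd.read_csv(path, sep="\t", dtype={"bait": str, "chrom": str})
    missing = [c for c in CONTACT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if (df["count"] % 1 != 0).any() or (df["count"] < 0).any():
        raise FormatError(f"{path}: counts must be non-negative integers")
    df["count"] = df["count"].astype(np.int64)
    per_bait = {b.name: 0 for b in baits} if baits else {}
    per_bait.update(df.groupby("bait")["count"].sum().astype(int).to_dict())
    return ContactTable(counts=df[CONTACT_COLUMNS], per_bait_total=per_bait,
                        library_stats={})


def write_normalized_tsv(contacts: NormalizedContacts, path) -> None:
    contacts.counts.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_qc_tsv(qc: list[ProbeQC], path) -> None:
    with open(path, "w") as fh:
        fh.write("bait\traw_total\tfactor\tstatus\n")
        for q in qc:
            factor = "NA" if q.factor is None else f"{q.factor:.10g}"
            fh.write(f"{q.bait}\t{q.raw_total}\t{factor}\t{q.status}\n")


# -- BEDPE ------------------------------------------------------------------

def write_bedpe(rows: list[dict], path) -> None:
    """10-column BEDPE; rows carry chrom1 start1 end1 chrom2 start2 end2
    name score strand1 strand2 (missing fields filled with '.')."""
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
            "name", "score", "strand1", "strand2"]
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(r.get(c, ".")) for c in cols) + "\n")


def read_bedpe(path) -> list[dict]:
    out = []
    for i, f in _rows(path):
        if len(f) < 10:
            raise FormatError(f"{path} line {i}: BEDPE needs >= 10 columns")
        s1 = _int(f[1], path, i, "start1")
        e1 = _int(f[2], path, i, "end1")
        s2 = _int(f[4], path, i, "start2")
        e2 = _int(f[5], path, i, "end2")
        if s1 >= e1 or s2 >= e2:
            raise FormatError(f"{path} line {i}: inverted interval")
        out.append({"chrom1": f[0], "start1": s1, "end1": e1, "chrom2": f[3],
                    "start2": s2, "end2": e2, "name": f[6], "score": f[7],
                    "strand1": f[8], "strand2": f[9]})
    return out


# -- generic BED ------------------------------------------------------------

def read_bed(path) -> list[tuple[str, int, int]]:
    out = []
    for i, f in _rows(path):
        if len(f) < 3:
            raise FormatError(f"{path} line {i}: need >= 3 BED columns")
        start = _int(f[1], path, i, "start")
        end = _int(f[2], path, i, "end")
        if start >= end:
            raise FormatError(f"{path} line {i}: start >= end")
        out.append((f[0], start, end))
    return out


# -- JSON -------------------------------------------------------------------

def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


# -- JASPAR PWM -------------------------------------------------------------

def read_jaspar_pwm(path, pseudocount: float = 0.1) -> PWM:
    """Read the first matrix of a JASPAR-format file into a :class:`PWM`.

    Column count totals are checked for consistency (within 10% of the
    per-matrix maximum, tolerating rounded frequency matrices).
    """
    from Bio import motifs

    with open(path) as fh:
        motif = motifs.read(fh, "jaspar")
    counts = np.array([list(motif.counts[b]) for b in "ACGT"], dtype=float).T
    col_tot = counts.sum(axis=1)
    if col_tot.max() > 0 and (col_tot.min() < 0.9 * col_tot.max()):
        raise FormatError(f"{path}: column totals inconsistent "
                          f"({col_tot.min():.3g} vs {col_tot.max():.3g})")
    return PWM.from_counts(counts, pseudocount=pseudocount,
                           name=motif.name or motif.matrix_id or "")
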