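"""Synthetic capture-3C library generator with known ground truth.

Real capture-3C libraries mix several read populations: informative pairs
anchored in a capture probe whose partner follows the canonical polymer
distance decay (contact probability ~ (d + d0)^-alpha along the chromosome),
a ~10% trans component, a large off-target background, PCR duplicates, and
per-probe capture-efficiency variation.  The generator emits a coordinate
pair table in exactly the dialect the extraction module consumes, together
with a :class:`SyntheticTruth` record (full config echo, realized cut sites,
per-probe efficiencies, planted interactions, category counts) so every
pipeline stage can be tested against known truth without external data.

Default composition mirrors the study's library statistics: ~82% of pairs
mapped, ~23% of mapped pairs on-target, ~10% of on-target pairs trans.
Planted bait-fragment interactions receive a multiplicative fold-enrichment
on top of the distance-decay background.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .extract import PAIR_COLUMNS, UNMAPPED_CHROM, canonicalize
from .restriction import (BaitRegion, RestrictionMap, TargetLocus,
                          design_baits)


@dataclass
class PlantedPeak:
    """A bait-fragment interaction enriched ``fold``-times over background.

    The target fragment is given either directly (``frag_index``) or as a
    signed genomic distance from the bait's cut site (``distance_bp``).
    """

    bait: str
    fold: float = 8.0
    frag_index: int | None = None
    distance_bp: int | None = None

    def __post_init__(self) -> None:
        if self.fold < 1:
            raise ValueError("fold enrichment must be >= 1")
        if self.frag_index is None and self.distance_bp is None:
            raise ValueError("give frag_index or distance_bp")


@dataclass
class SimConfig:
    """Generator parameters; rates are fractions in [0, 1].

    ``off_target_rate`` is the off-target fraction of *mapped* pairs and
    ``trans_rate`` the trans fraction of *on-target* pairs; defaults emulate
    the study's average library composition.  ``n_pairs`` counts base pairs
    before duplication; duplicate copies are emitted on top.
    """

    seed: int
    n_chromosomes: int = 3
    chrom_length: int = 1_000_000
    cut_spacing: float = 4096.0
    n_sites_per_locus: int = 14
    loci: list[tuple[str, float]] | None = None  # (chrom, center fraction)
    n_pairs: int = 100_000
    alpha: float = 1.0
    d0: float = 1000.0
    trans_rate: float = 0.10
    off_target_rate: float = 0.766
    unmapped_rate: float = 0.177
    duplicate_rate: float = 0.05
    probe_log_sd: float = 0.5
    flank: int = 250
    planted: list[PlantedPeak] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("trans_rate", "off_target_rate", "unmapped_rate",
                     "duplicate_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.n_chromosomes < 1 or self.n_pairs < 1:
            raise ValueError("need >= 1 chromosome and >= 1 pair")
        if self.trans_rate > 0 and self.n_chromosomes < 2:
            raise ValueError("trans pairs require >= 2 chromosomes")
        if self.n_sites_per_locus < 10:
            # mirrors the smallest captured locus in the study design
            raise ValueError("loci must contain >= 10 cut sites")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["planted"] = [asdict(p) for p in self.planted]
        return d


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated library."""

    config: dict
    cut_sites: dict[str, list[int]]
    efficiency: dict[str, float]
    planted: list[dict]
    n_pairs: int          # base pairs before duplication
    n_total: int          # emitted rows (base + duplicate copies)
    n_unmapped: int
    n_off_target: int
    n_cis: int
    n_trans: int
    n_dup_emitted: int    # copies appended by the generator
    n_duplicates: int     # coordinate-level duplicate rows in the final table

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _default_locus_centers(config: SimConfig) -> list[tuple[str, float]]:
    if config.n_chromosomes == 1:
        return [("chr1", 0.3), ("chr1", 0.7)]
    centers = [("chr1", 0.3), ("chr1", 0.7)]
    for i in range(2, min(config.n_chromosomes, 3) + 1):
        centers.append((f"chr{i}", 0.5))
    return centers


def simulate_genome(config: SimConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[RestrictionMap, list[TargetLocus], list[BaitRegion]]:
    """Draw cut sites with exponential spacing and carve out target loci.

    Each locus is the span of the ``n_sites_per_locus`` cut sites nearest its
    requested center, padded by ``flank`` bp so every bait interval lies
    inside the locus.  Loci get globally unique A/B/C... prefixes (bait names
    key the contact table, so they must not collide across chromosomes).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.chrom_length
    sites: dict[str, np.ndarray] = {}
    lengths: dict[str, int] = {}
    for i in range(config.n_chromosomes):
        chrom = f"chr{i + 1}"
        n_draw = int(2 * L / config.cut_spacing) + 50
        pos = np.cumsum(rng.exponential(config.cut_spacing, size=n_draw))
        pos = np.unique(pos.astype(np.int64))
        pos = pos[(pos >= config.flank) & (pos <= L - config.flank - 6)]
        sites[chrom] = pos
        lengths[chrom] = L
    rmap = RestrictionMap(chrom_sites=sites, chrom_lengths=lengths)

    centers = config.loci if config.loci is not None else \
        _default_locus_centers(config)
    loci: list[TargetLocus] = []
    used: dict[str, list[tuple[int, int]]] = {}
    for k, (chrom, frac) in enumerate(centers):
        s = rmap.sites(chrom)
        if s.size < config.n_sites_per_locus:
            raise ValueError(f"{chrom}: only {s.size} cut sites, locus needs "
                             f"{config.n_sites_per_locus}")
        center = int(frac * lengths[chrom])
        j = int(np.argmin(np.abs(s - center)))
        half = config.n_sites_per_locus // 2
        lo = max(0, min(j - half, s.size - config.n_sites_per_locus))
        inside = s[lo:lo + config.n_sites_per_locus]
        # pad by flank, then re-expand until no further site slips inside the
        # padding (bait intervals must lie fully within the locus)
        while True:
            start = max(0, int(inside[0]) - config.flank)
            end = min(lengths[chrom], int(inside[-1]) + config.flank)
            grown = s[(s >= start) & (s < end)]
            if grown.size == inside.size:
                break
            inside = grown
        for a, b in used.get(chrom, []):
            if start < b and end > a:
                raise ValueError("requested loci overlap; spread the centers")
        used.setdefault(chrom, []).append((start, end))
        loci.append(TargetLocus(name=f"locus{k + 1}", chrom=chrom,
                                start=start, end=end,
                                prefix=chr(ord("A") + k)))
    baits = design_baits(rmap, loci, flank=config.flank)
    return rmap, loci, baits


def _resolve_planted(config: SimConfig, rmap: RestrictionMap,
                     baits: list[BaitRegion]) -> list[dict]:
    by_name = {b.name: b for b in baits}
    resolved = []
    for p in config.planted:
        b = by_name.get(p.bait)
        if b is None:
            raise ValueError(f"planted bait {p.bait!r} not in design")
        if p.frag_index is not None:
            fi = int(p.frag_index)
        else:
            fi = int(rmap.fragment_index(b.chrom, b.site + p.distance_bp))
        starts, ends = rmap.fragment_bounds(b.chrom)
        resolved.append({"bait": p.bait, "chrom": b.chrom, "frag_index": fi,
                         "frag_start": int(starts[fi]), "frag_end": int(ends[fi]),
                         "fold": float(p.fold)})
    return resolved


def _bait_proximal_windows(rmap, loci, flank):
    """Per chromosome, merged [site - flank, site + flank) windows around
    in-locus cut sites (for off-target rejection sampling)."""
    wins: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in rmap.chromosomes:
        s = rmap.sites(chrom)
        parts = []
        for loc in loci:
            if loc.chrom == chrom:
                inside = s[(s >= loc.start) & (s < loc.end)]
                parts.append(inside)
        if parts:
            inside = np.concatenate(parts)
            wins[chrom] = (inside - flank, inside + flank)
    return wins


def _sample_off_locus(rng, rmap, wins, n):
    """n (chrom, pos) ends uniform on the genome, outside every bait-proximal
    window."""
    chroms = rmap.chromosomes
    lens = np.array([rmap.chrom_lengths[c] for c in chroms], dtype=np.int64)
    p = lens / lens.sum()
    out_chrom = np.empty(n, dtype=object)
    out_pos = np.empty(n, dtype=np.int64)
    need = np.arange(n)
    while need.size:
        ci = rng.choice(len(chroms), size=need.size, p=p)
        pos = rng.integers(0, lens[ci])
        bad = np.zeros(need.size, dtype=bool)
        for k, c in enumerate(chroms):
            m = ci == k
            if not m.any() or c not in wins:
                continue
            lo, hi = wins[c]
            j = np.searchsorted(lo, pos[m], side="right") - 1
            inside = (j >= 0) & (pos[m] < hi[np.maximum(j, 0)])
            bad[m] = inside
        ok = ~bad
        out_chrom[need[ok]] = np.array(chroms, dtype=object)[ci[ok]]
        out_pos[need[ok]] = pos[ok]
        need = need[bad]
    return out_chrom, out_pos


def simulate_pairs(rmap: RestrictionMap, loci: list[TargetLocus],
                   baits: list[BaitRegion], config: SimConfig,
                   rng: np.random.Generator | None = None
                   ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Emit the pair table and its ground truth.

    Base pairs are assigned to {unmapped, off-target, on-target cis,
    on-target trans} by the configured rates; on-target anchors are placed
    uniformly inside a bait interval chosen with probability proportional to
    that probe's log-normal efficiency factor; cis partners land in a
    fragment drawn with probability ~ fragment_length x (d + d0)^-alpha
    (planted fragments up-weighted ``fold``-fold), positioned near a
    restriction boundary.  Each mapped base pair is then duplicated with
    probability ``duplicate_rate`` and the rows shuffled.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    flank = config.flank
    n = config.n_pairs
    u, off, tau = config.unmapped_rate, config.off_target_rate, config.trans_rate
    probs = [u, (1 - u) * off, (1 - u) * (1 - off) * (1 - tau),
             (1 - u) * (1 - off) * tau]
    n_unm, n_off, n_cis, n_trans = rng.multinomial(n, probs)

    eff = rng.lognormal(mean=0.0, sigma=config.probe_log_sd, size=len(baits))
    eff_p = eff / eff.sum()
    planted = _resolve_planted(config, rmap, baits)
    planted_by_bait: dict[str, dict[int, float]] = {}
    for p in planted:
        planted_by_bait.setdefault(p["bait"], {})[p["frag_index"]] = p["fold"]

    frag_cache = {c: rmap.fragment_bounds(c) for c in rmap.chromosomes}

    rows_c1, rows_p1, rows_c2, rows_p2 = [], [], [], []

    def emit(c1, p1, c2, p2):
        rows_c1.append(np.asarray(c1, dtype=object))
        rows_p1.append(np.asarray(p1, dtype=np.int64))
        rows_c2.append(np.asarray(c2, dtype=object))
        rows_p2.append(np.asarray(p2, dtype=np.int64))

    # ---- on-target pairs -------------------------------------------------
    anchors_cis = rng.multinomial(n_cis, eff_p)
    anchors_trans = rng.multinomial(n_trans, eff_p)
    other_chroms = {c: [d for d in rmap.chromosomes if d != c]
                    for c in rmap.chromosomes}
    for bi, b in enumerate(baits):
        k_cis, k_trans = int(anchors_cis[bi]), int(anchors_trans[bi])
        if k_cis + k_trans == 0:
            continue
        a_pos = rng.integers(b.start, b.end, size=k_cis + k_trans)
        starts, ends = frag_cache[b.chrom]
        if k_cis:
            mids = (starts + ends) / 2.0
            w = (ends - starts).astype(float) * \
                (np.abs(mids - b.site) + config.d0) ** -config.alpha
            for fi, fold in planted_by_bait.get(b.name, {}).items():
                w[fi] *= fold
            w /= w.sum()
            frag_counts = rng.multinomial(k_cis, w)
            partner_pos = np.empty(k_cis, dtype=np.int64)
            at = 0
            # partner ends uniform within their fragment: these libraries are
            # sonicated after ligation, so only the captured anchor end is
            # junction-proximal
            for fi in np.nonzero(frag_counts)[0]:
                k = int(frag_counts[fi])
                partner_pos[at:at + k] = rng.integers(int(starts[fi]),
                                                      int(ends[fi]), size=k)
                at += k
            emit(np.full(k_cis, b.chrom, dtype=object), a_pos[:k_cis],
                 np.full(k_cis, b.chrom, dtype=object), partner_pos)
        if k_trans:
            others = other_chroms[b.chrom]
            tc = rng.choice(len(others), size=k_trans)
            t_chrom = np.array(others, dtype=object)[tc]
            t_len = np.array([rmap.chrom_lengths[c] for c in t_chrom])
            t_pos = rng.integers(0, t_len)
            emit(np.full(k_trans, b.chrom, dtype=object), a_pos[k_cis:],
                 t_chrom, t_pos)

    # ---- off-target pairs ------------------------------------------------
    wins = _bait_proximal_windows(rmap, loci, flank)
    if n_off:
        c1, p1 = _sample_off_locus(rng, rmap, wins, n_off)
        c2, p2 = _sample_off_locus(rng, rmap, wins, n_off)
        emit(c1, p1, c2, p2)

    # ---- unmapped pairs --------------------------------------------------
    if n_unm:
        both = rng.random(n_unm) < 0.5
        c1 = np.full(n_unm, UNMAPPED_CHROM, dtype=object)
        p1 = np.full(n_unm, -1, dtype=np.int64)
        mc, mp = _sample_off_locus(rng, rmap, {}, n_unm)
        c2 = np.where(both, UNMAPPED_CHROM, mc).astype(object)
        p2 = np.where(both, -1, mp)
        emit(c1, p1, c2, p2)

    chrom1 = np.concatenate(rows_c1)
    pos1 = np.concatenate(rows_p1)
    chrom2 = np.concatenate(rows_c2)
    pos2 = np.concatenate(rows_p2)
    n_base = chrom1.size
    strand = np.array(["+", "-"], dtype=object)
    df = pd.DataFrame({
        "chrom1": chrom1, "pos1": pos1,
        "strand1": strand[rng.integers(0, 2, size=n_base)],
        "chrom2": chrom2, "pos2": pos2,
        "strand2": strand[rng.integers(0, 2, size=n_base)],
    })
    df.loc[df["chrom1"] == UNMAPPED_CHROM, "strand1"] = "."
    df.loc[df["chrom2"] == UNMAPPED_CHROM, "strand2"] = "."

    mapped = ((df["chrom1"] != UNMAPPED_CHROM) &
              (df["chrom2"] != UNMAPPED_CHROM)).to_numpy()
    dup_pick = mapped & (rng.random(n_base) < config.duplicate_rate)
    dup_rows = df.loc[dup_pick]
    full = pd.concat([df, dup_rows], ignore_index=True)
    full = full.iloc[rng.permutation(len(full))].reset_index(drop=True)

    # realized duplicates by the pipeline's own canonical-coordinate rule
    canon = canonicalize(full)
    is_mapped = ((canon["chrom1"] != UNMAPPED_CHROM) &
                 (canon["chrom2"] != UNMAPPED_CHROM)).to_numpy()
    n_dup_real = int(canon.loc[is_mapped].duplicated(subset=PAIR_COLUMNS).sum())

    truth = SyntheticTruth(
        config=config.to_dict(),
        cut_sites={c: [int(s) for s in rmap.sites(c)] for c in rmap.chromosomes},
        efficiency={b.name: float(eff[i]) for i, b in enumerate(baits)},
        planted=planted,
        n_pairs=int(n), n_total=int(len(full)),
        n_unmapped=int(n_unm), n_off_target=int(n_off),
        n_cis=int(n_cis), n_trans=int(n_trans),
        n_dup_emitted=int(dup_pick.sum()), n_duplicates=n_dup_real)
    return full[PAIR_COLUMNS], truth


def simulate_library(config: SimConfig) -> dict:
    """Genome + pairs in one call (single generator seeded from the config)."""
    rng = np.random.default_rng(config.seed)
    rmap, loci, baits = simulate_genome(config, rng)
    pairs, truth = simulate_pairs(rmap, loci, baits, config, rng)
    return {"rmap": rmap, "loci": loci, "baits": baits,
            "pairs": pairs, "truth": truth}


def simulate_replicate_counts(n_fragments: int = 500, depth: float = 6.0,
                              log_sd: float = 1.5, p_spike: float = 0.08,
                              spike_mean: float = 18.0,
                              background: float = 0.8,
                              rng: np.random.Generator | None = None
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Two replicate count vectors over a shared contact profile.

    Each fragment carries a shared log-normal contact intensity (mean
    ``depth``) sampled with independent Poisson noise per replicate, plus two
    replicate-independent artifact components seen in proximity-ligation
    libraries: a uniform spurious-ligation background (Poisson ``background``)
    and occasional one-sided spikes (probability ``p_spike``, Poisson
    ``spike_mean``) mimicking localized ligation/PCR artifacts that do not
    reproduce between libraries.  The spikes are what a joint minimum-count
    filter removes: a spiked fragment is high in one replicate but near the
    background level in the other.
    """
    if rng is None:
        rng = np.random.default_rng()
    mu = np.log(depth) - log_sd ** 2 / 2.0
    lam = rng.lognormal(mean=mu, sigma=log_sd, size=n_fragments)

    def one_replicate() -> np.ndarray:
        c = rng.poisson(lam) + rng.poisson(background, n_fragments)
        spiked = rng.random(n_fragments) < p_spike
        c[spiked] += rng.poisson(spike_mean, int(spiked.sum()))
        return c

    return one_replicate(), one_replicate()


def distance_decay_slope(pairs: pd.DataFrame, d_min: float = 2e4,
                         d_max: float = 4e5, n_bins: int = 12) -> float:
    """Log-log slope of cis contact density vs genomic distance.

    Takes a pair table (cis rows: same chromosome, both mapped), bins
    |pos2 - pos1| into log-spaced bins and fits log10(count / bin width)
    against log10(distance) by least squares.
    """
    cis = pairs[(pairs["chrom1"] == pairs["chrom2"]) &
                (pairs["chrom1"] != UNMAPPED_CHROM)]
    d = np.abs(cis["pos2"].to_numpy() - cis["pos1"].to_numpy()).astype(float)
    d = d[(d >= d_min) & (d < d_max)]
    if d.size < 100:
        raise ValueError("too few cis pairs in the fitting range")
    edges = np.logspace(np.log10(d_min), np.log10(d_max), n_bins + 1)
    hist, _ = np.histogram(d, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    keep = hist > 0
    x = np.log10(centers[keep])
    y = np.log10(hist[keep] / widths[keep])
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)
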