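"""Downstream quantifications: replicate reproducibility, 3C-qPCR contact
frequency, eQTL regression, PWM allele scoring and epigenomic-track overlap.

These operations tie the interaction calls to orthogonal evidence: Pearson
correlation between replicate libraries (after a joint minimum-count filter),
delta-delta-Ct quantification of a 3C contact against a random-ligation
control and an adjacent-fragment reference, additive-dosage linear regression
of genotype on expression (RPKM), log-odds scoring of the two alleles of a
SNP against a transcription-factor position weight matrix, and any-overlap
annotation of interaction peaks with ChIP-seq peak tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


class UndefinedCorrelationError(ValueError):
    """Too few surviving fragments, or a constant filtered vector."""


class MonomorphicSNPError(ValueError):
    """Genotype dosage has zero variance; no regression possible."""


# --------------------------------------------------------------------------
# replicate reproducibility


def replicate_correlation(counts_rep1, counts_rep2, min_count: int = 1) -> float:
    """Pearson r over fragments with count >= min_count in BOTH replicates.

    Inputs are mappings fragment -> count (or equal-length sequences indexed
    by fragment).  Raises if fewer than 3 fragments survive the joint filter
    or a filtered vector is constant.
    """
    if isinstance(counts_rep1, dict) or isinstance(counts_rep2, dict):
        keys = sorted(set(counts_rep1) | set(counts_rep2))
        x = np.array([counts_rep1.get(k, 0) for k in keys], dtype=float)
        y = np.array([counts_rep2.get(k, 0) for k in keys], dtype=float)
    else:
        x = np.asarray(counts_rep1, dtype=float)
        y = np.asarray(counts_rep2, dtype=float)
        if x.shape != y.shape:
            raise ValueError("replicate vectors differ in length")
    keep = (x >= min_count) & (y >= min_count)
    if keep.sum() < 3:
        raise UndefinedCorrelationError(
            f"only {int(keep.sum())} fragments pass min_count={min_count}")
    xs, ys = x[keep], y[keep]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise UndefinedCorrelationError("filtered vector is constant")
    return float(stats.pearsonr(xs, ys).statistic)


# --------------------------------------------------------------------------
# 3C-qPCR


@dataclass
class QPCRMeasurement:
    """Ct replicates for one primer pair, in the 3C library and in the
    random-ligation control library."""

    pair_id: str
    ct_3c: list[float]
    ct_control: list[float]
    is_adjacent_reference: bool = False

    def __post_init__(self) -> None:
        for vals in (self.ct_3c, self.ct_control):
            if len(vals) == 0:
                raise ValueError(f"{self.pair_id}: empty Ct replicate list")
            if not all(np.isfinite(v) and v > 0 for v in vals):
                raise ValueError(f"{self.pair_id}: non-finite or non-positive Ct")


def _ratio(m: QPCRMeasurement, efficiency: float) -> float:
    return efficiency ** -(float(np.mean(m.ct_3c)) - float(np.mean(m.ct_control)))


def qpcr_contact(test: QPCRMeasurement, adjacent: QPCRMeasurement,
                 efficiency: float = 2.0) -> tuple[float, float]:
    """Normalized contact frequency by the delta-delta-Ct scheme.

    ratio(m) = E^-(mean Ct_3C - mean Ct_control); the result is
    ratio(test) / ratio(adjacent), correcting both for template composition
    (control library) and for loading/fixation/ligation efficiency (adjacent
    fragment).  Returns (value, sd) with the replicate SD propagated through
    the exponent by the delta method.
    """
    if not adjacent.is_adjacent_reference:
        raise ValueError("normalizer must be flagged is_adjacent_reference")
    value = _ratio(test, efficiency) / _ratio(adjacent, efficiency)
    lnE = np.log(efficiency)
    var_ln = 0.0
    for m in (test, adjacent):
        for ct in (m.ct_3c, m.ct_control):
            n = len(ct)
            var_ln += lnE ** 2 * (float(np.var(ct, ddof=1)) / n if n > 1 else 0.0)
    return value, value * float(np.sqrt(var_ln))


# --------------------------------------------------------------------------
# eQTL regression


@dataclass
class EqtlRecord:
    rsid: str
    gene: str
    n: int
    slope: float
    stderr: float
    t: float
    p: float


_P_FLOOR = float(np.finfo(float).tiny)


def eqtl_regress(g, y, rsid: str = "", gene: str = "") -> EqtlRecord:
    """OLS of expression on additive genotype dosage: y = a + b*g.

    Two-sided p from Student t with n-2 df.  Constant expression yields
    slope 0, p = 1; a perfect fit saturates at the smallest positive float.
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    if g.shape != y.shape:
        raise ValueError("genotype and expression vectors differ in length")
    n = g.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(g) == 0:
        raise MonomorphicSNPError(f"{rsid or 'SNP'}: constant genotype")
    if np.ptp(y) == 0:
        return EqtlRecord(rsid, gene, n, 0.0, 0.0, 0.0, 1.0)
    res = stats.linregress(g, y)
    p = float(res.pvalue)
    if res.stderr > 0:
        t = float(res.slope / res.stderr)
    else:
        t = np.inf  # perfect fit: zero residual variance
        p = _P_FLOOR
    if not np.isfinite(p) or p <= 0.0:
        p = _P_FLOOR  # documented saturation on (near-)perfect fits
    return EqtlRecord(rsid, gene, n, float(res.slope), float(res.stderr), t, p)


def eqtl_scan(records: list[tuple[str, str, np.ndarray, np.ndarray]]):
    """Fit every (rsid, gene, g, y) tuple; report raw p plus a labeled
    Benjamini-Hochberg column (an extra, not a replacement)."""
    import pandas as pd
    from statsmodels.stats.multitest import multipletests

    fits = [eqtl_regress(g, y, rsid, gene) for rsid, gene, g, y in records]
    df = pd.DataFrame([vars(f) for f in fits])
    if len(df):
        df["p_bh"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df


# --------------------------------------------------------------------------
# PWM allele scoring


@dataclass
class PWM:
    """Position weight matrix: per-position base probabilities.

    ``matrix`` has shape (width, 4) in A/C/G/T order; probabilities at each
    position sum to 1 after pseudocount smoothing.
    """

    matrix: np.ndarray
    name: str = ""
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or \
                self.matrix.shape[0] < 1:
            raise ValueError("matrix must be (width >= 1, 4)")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("position probabilities must sum to 1")

    @property
    def width(self) -> int:
        return int(self.matrix.shape[0])

    @classmethod
    def from_counts(cls, counts: np.ndarray, pseudocount: float = 0.1,
                    name: str = "", background=None) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        probs = (counts + pseudocount) / \
            (counts.sum(axis=1, keepdims=True) + 4 * pseudocount)
        kw = {} if background is None else {"background": background}
        return cls(matrix=probs, name=name, **kw)

    def score(self, seq: str) -> float:
        """Sum of log2(p_i(base) / background(base)) over the window."""
        seq = seq.upper()
        if len(seq) != self.width:
            raise ValueError(f"sequence length {len(seq)} != width {self.width}")
        total = 0.0
        for i, base in enumerate(seq):
            if base not in _BASE_INDEX:
                return -np.inf  # N or ambiguity: unscorable window
            j = _BASE_INDEX[base]
            total += np.log2(self.matrix[i, j] / self.background[j])
        return total


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def pwm_allele_delta(pwm: PWM, context: str, snp_offset: int,
                     allele1: str, allele2: str) -> tuple[float, float, float]:
    """Best motif score for each allele and their difference.

    For each allele the SNP base in ``context`` is substituted and every
    window of PWM width covering the SNP is scored on both strands; the
    per-allele maximum is taken.  delta = score1 - score2, so a positive
    delta means allele1 is the better match (antisymmetric in the alleles).
    """
    context = context.upper()
    w = pwm.width
    if len(context) < w:
        raise ValueError("context shorter than PWM width")
    if not (0 <= snp_offset < len(context)):
        raise ValueError("snp_offset outside context")
    scores = []
    for allele in (allele1, allele2):
        allele = allele.upper()
        if allele not in _BASE_INDEX:
            raise ValueError(f"invalid allele {allele!r}")
        seq = context[:snp_offset] + allele + context[snp_offset + 1:]
        best = -np.inf
        lo = max(0, snp_offset - w + 1)
        hi = min(len(seq) - w, snp_offset)
        for start in range(lo, hi + 1):
            window = seq[start:start + w]
            best = max(best, pwm.score(window), pwm.score(_revcomp(window)))
        scores.append(best)
    return scores[0], scores[1], scores[0] - scores[1]


# --------------------------------------------------------------------------
# epigenomic-track overlap


def annotate_overlap(features: list[tuple], tracks: dict[str, list[tuple]]
                     ) -> list[list[str]]:
    """For each half-open feature interval, the names of tracks with >= 1 bp
    overlap.  Feature order is preserved; each (feature, track) pair is
    reported at most once."""
    trees: dict[str, dict[str, IntervalTree]] = {}
    for name, intervals in tracks.items():
        per_chrom: dict[str, IntervalTree] = {}
        for chrom, s, e in intervals:
            if s >= e:
                raise ValueError(f"track {name}: malformed interval {chrom}:{s}-{e}")
            per_chrom.setdefault(chrom, IntervalTree()).addi(s, e)
        trees[name] = per_chrom
    out = []
    for feat in features:
        chrom, s, e = feat[0], feat[1], feat[2]
        if s >= e:
            raise ValueError(f"malformed feature interval {chrom}:{s}-{e}")
        hits = [name for name in tracks
                if chrom in trees[name] and trees[name][chrom].overlap(s, e)]
        out.append(hits)
    return out
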