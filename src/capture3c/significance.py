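"""Permutation-based significant-interaction calling.

For each bait we observe integer read counts over the mappable (unmasked)
restriction fragments of its chromosome.  The null model shuffles the N
observed reads uniformly among the M mappable fragments (a multinomial with
equal cell probabilities), preserving the read total; windows of ``window``
consecutive mappable fragments are summed (window 1 = the fragments
themselves).  From ``n_perm`` such permutations we take:

* a candidate threshold T0 — the smallest count c whose pooled-permutation
  exceedance fraction P(X >= c) is at most ``top_pct``/100 (the "top fifth
  percentile" rule at the default 5.0), and
* an empirical false discovery rate
  FDR(c) = E_perm[#windows >= c] / max(1, #observed windows >= c).

The calling threshold T is the smallest c >= T0 with FDR(c) <= ``fdr``; if no
such c exists nothing is called.  Per-window empirical p-values use the
add-one pooled estimator p = (1 + #{pooled >= c}) / (n_perm * W + 1).

All randomness flows through one seeded generator; draws are consumed
per-bait, per-permutation, in that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class EmptyNullError(ValueError):
    """No reads (N = 0): the permutation null is empty."""


class DegenerateProfileError(ValueError):
    """Fewer than two mappable fragments: nothing to shuffle among."""


@dataclass
class SigConfig:
    """Caller parameters; defaults are the study's stated settings."""

    window: int = 1
    n_perm: int = 1000
    fdr: float = 0.01
    top_pct: float = 5.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not (0.0 < self.fdr < 1.0):
            raise ValueError("fdr must be in (0, 1)")
        if not (0.0 < self.top_pct <= 100.0):
            raise ValueError("top_pct must be in (0, 100]")


@dataclass
class SignificanceResult:
    """Per-bait calling result over mappable windows.

    ``frag_index`` maps each window back to the index (on the bait's
    chromosome) of its first fragment; with window 1 these are the mappable
    fragments themselves.
    """

    bait: str
    frag_index: np.ndarray
    counts: np.ndarray
    pvalues: np.ndarray
    significant: np.ndarray
    threshold: int | None
    achieved_fdr: float | None
    n_reads: int
    n_fragments: int
    window: int = 1
    extras: dict = field(default_factory=dict)

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bait": self.bait,
            "frag_index": self.frag_index,
            "count": self.counts,
            "p": self.pvalues,
            "significant": self.significant,
        })


def _window_sums(x: np.ndarray, w: int) -> np.ndarray:
    """Sums over w consecutive entries, step 1 (identity for w = 1)."""
    if w == 1:
        return x
    c = np.cumsum(np.concatenate((np.zeros((*x.shape[:-1], 1), dtype=x.dtype), x),
                                 axis=-1), axis=-1)
    return c[..., w:] - c[..., :-w]


def permute_null(counts: np.ndarray, config: SigConfig,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Permutation window-count matrix of shape (n_perm, n_windows).

    Each permutation redistributes the N observed reads uniformly over the M
    mappable fragments; draws are made one permutation at a time so the
    consumption order of the generator is well defined.
    """
    counts = np.asarray(counts, dtype=np.int64)
    M = counts.size
    if M < 2:
        raise DegenerateProfileError(f"need >= 2 mappable fragments, got {M}")
    N = int(counts.sum())
    if N == 0:
        raise EmptyNullError("zero reads: no permutation null")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p = np.full(M, 1.0 / M)
    perm = np.empty((config.n_perm, M), dtype=np.int64)
    for i in range(config.n_perm):
        perm[i] = rng.multinomial(N, p)
    return _window_sums(perm, config.window)


def call_significant(counts: np.ndarray, config: SigConfig,
                     rng: np.random.Generator | None = None,
                     bait: str = "", frag_index: np.ndarray | None = None
                     ) -> SignificanceResult:
    """Call significantly contacted windows for one bait.

    ``counts`` are raw integer reads over the mappable fragments (masked
    fragments already excluded); ``frag_index`` optionally records their
    original indices on the chromosome.
    """
    counts = np.asarray(counts, dtype=np.int64)
    perm = permute_null(counts, config, rng)
    observed = _window_sums(counts, config.window)
    W = observed.size
    N = int(counts.sum())

    pool = np.sort(perm.ravel())
    n_pool = pool.size

    def pool_ge(c: int) -> int:
        return n_pool - int(np.searchsorted(pool, c, side="left"))

    # candidate thresholds: all values where the step functions can change
    cand = np.unique(np.concatenate((observed, pool, [0])))
    cand = np.unique(np.concatenate((cand, cand + 1)))

    q = config.top_pct / 100.0
    t0 = None
    for c in cand:
        if pool_ge(int(c)) / n_pool <= q:
            t0 = int(c)
            break
    # q < 1 and counts are bounded, so some candidate always qualifies
    assert t0 is not None

    obs_sorted = np.sort(observed)

    def obs_ge(c: int) -> int:
        return W - int(np.searchsorted(obs_sorted, c, side="left"))

    threshold = None
    achieved = None
    for c in cand[cand >= t0]:
        c = int(c)
        expected = pool_ge(c) / config.n_perm  # mean permuted exceedances
        fdr_c = expected / max(1, obs_ge(c))
        if fdr_c <= config.fdr:
            threshold = c
            achieved = fdr_c
            break

    pvals = (1.0 + (n_pool - np.searchsorted(pool, observed, side="left"))) \
        / (config.n_perm * W + 1.0)
    sig = np.zeros(W, dtype=bool)
    if threshold is not None:
        sig = observed >= threshold

    if frag_index is None:
        frag_index = np.arange(W)
    else:
        frag_index = np.asarray(frag_index)[: W]
    return SignificanceResult(
        bait=bait, frag_index=frag_index, counts=observed, pvalues=pvals,
        significant=sig, threshold=threshold, achieved_fdr=achieved,
        n_reads=N, n_fragments=counts.size, window=config.window,
        extras={"t0": t0})


def call_all_baits(contacts, rmap, baits, config: SigConfig
                   ) -> dict[str, SignificanceResult]:
    """Run the caller for every retained bait, cis fragments only.

    Baits are processed in sorted-name order with a single seeded generator,
    so results are reproducible from (config, seed).
    """
    from .normalize import NormalizedContacts, bait_profile  # noqa: F401

    rng = np.random.default_rng(config.seed)
    by_name = {b.name: b for b in baits}
    out: dict[str, SignificanceResult] = {}
    for name in sorted(contacts.factors):
        b = by_name.get(name)
        if b is None:
            continue
        counts, mask = bait_profile(contacts, rmap, b)
        mappable = ~mask
        idx = np.nonzero(mappable)[0]
        try:
            out[name] = call_significant(counts[mappable], config, rng,
                                         bait=name, frag_index=idx)
        except (EmptyNullError, DegenerateProfileError):
            continue
    return out
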