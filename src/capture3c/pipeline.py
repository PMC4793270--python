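"""Pipeline orchestration: extract -> normalize -> call -> report.

``run_all`` chains the stages over either a simulated library or user-
supplied input files, writing a library-statistics report (the per-library
accounting rows of the study), the probe QC table, raw and normalized
contact tables, and the significant-interaction table/BEDPE.  All randomness
flows from the single configured seed, so two runs with the same config are
byte-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as c3io
from .extract import aggregate, classify_table
from .normalize import (NormalizedContacts, mask_bait_proximal, normalize,
                        probe_filter)
from .significance import SigConfig, call_all_baits
from .simulate import SimConfig, simulate_library


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All thresholds of the analysis; defaults are the study's settings."""

    flank: int = 250
    window: int = 1
    n_perm: int = 1000
    fdr: float = 0.01
    top_pct: float = 5.0
    low_probe_pct: float = 22.0
    bait_exclusion: int = 25000
    min_counts: tuple[int, ...] = (1, 3)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("flank", "window", "n_perm", "bait_exclusion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be positive")

    def sig_config(self) -> SigConfig:
        return SigConfig(window=self.window, n_perm=self.n_perm, fdr=self.fdr,
                         top_pct=self.top_pct, seed=self.seed)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as e:
                raise StageError(f"[{name}] {e}") from e
        return wrapper
    return deco


@_stage("extract")
def extract_stage(rmap, baits, loci, pairs, flank):
    classified = classify_table(rmap, baits, loci, pairs, flank)
    return classified, aggregate(classified, rmap, baits)


@_stage("normalize")
def normalize_stage(table, rmap, baits, pct, exclusion_bp,
                    repeats=None) -> tuple[list, NormalizedContacts]:
    qc = probe_filter(table, pct=pct, repeats=repeats, baits=baits)
    contacts = normalize(table, qc)
    contacts = mask_bait_proximal(contacts, rmap, baits, exclusion_bp)
    return qc, contacts


@_stage("call")
def call_stage(contacts, rmap, baits, sig_config):
    return call_all_baits(contacts, rmap, baits, sig_config)


def significant_table(results, rmap, baits) -> pd.DataFrame:
    """One row per significant bait-fragment pair, 1-based inclusive
    positions for the human-facing report."""
    by_name = {b.name: b for b in baits}
    rows = []
    for name in sorted(results):
        res = results[name]
        b = by_name[name]
        starts, ends = rmap.fragment_bounds(b.chrom)
        for j in np.nonzero(res.significant)[0]:
            fi = int(res.frag_index[j])
            rows.append({
                "bait": name, "locus": b.locus, "chrom": b.chrom,
                "frag_index": fi,
                "frag_start_1based": int(starts[fi]) + 1,
                "frag_end_1based": int(ends[fi]),
                "count": int(res.counts[j]),
                "p": float(res.pvalues[j]),
            })
    cols = ["bait", "locus", "chrom", "frag_index", "frag_start_1based",
            "frag_end_1based", "count", "p"]
    return pd.DataFrame(rows, columns=cols)


def significant_bedpe(results, rmap, baits) -> list[dict]:
    by_name = {b.name: b for b in baits}
    rows = []
    for name in sorted(results):
        res = results[name]
        b = by_name[name]
        starts, ends = rmap.fragment_bounds(b.chrom)
        for j in np.nonzero(res.significant)[0]:
            fi = int(res.frag_index[j])
            rows.append({
                "chrom1": b.chrom, "start1": b.start, "end1": b.end,
                "chrom2": b.chrom, "start2": int(starts[fi]),
                "end2": int(ends[fi]),
                "name": f"{name}:{fi}", "score": int(res.counts[j]),
                "strand1": ".", "strand2": "."})
    return rows


def export_heatmap(contacts: NormalizedContacts, baits, rmap, chrom: str,
                   out_tsv=None, out_png=None) -> pd.DataFrame:
    """Bait x fragment matrix of normalized counts for one chromosome.

    Rows are retained baits in locus/coordinate order, columns fragments in
    coordinate order; masked cells carry the NA sentinel, never zero.
    """
    retained = [b for b in baits if b.name in contacts.factors]
    if not retained:
        warnings.warn("no retained baits: empty heatmap")
    starts, ends = rmap.fragment_bounds(chrom)
    n = starts.size
    mat = np.zeros((len(retained), n))
    sub = contacts.counts[contacts.counts["chrom"] == chrom]
    row_of = {b.name: i for i, b in enumerate(retained)}
    for _, r in sub.iterrows():
        i = row_of.get(r["bait"])
        if i is not None:
            mat[i, int(r["frag_index"])] = r["norm_count"]
    for i, b in enumerate(retained):
        if b.chrom == chrom:
            for fi in contacts.mask.get(b.name, ()):
                mat[i, fi] = np.nan
    df = pd.DataFrame(mat, index=[b.name for b in retained],
                      columns=[f"{chrom}:{int(s)}-{int(e)}"
                               for s, e in zip(starts, ends)])
    if out_tsv is not None:
        df.to_csv(out_tsv, sep="\t", na_rep="NA", float_format="%.6g",
                  index_label="bait")
    if out_png is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(10, max(2, 0.2 * len(retained))))
        masked = np.ma.masked_invalid(np.log1p(mat))
        im = ax.imshow(masked, aspect="auto", interpolation="nearest",
                       cmap="viridis")
        ax.set_xlabel(f"{chrom} fragments")
        ax.set_yticks(range(len(retained)))
        ax.set_yticklabels([b.name for b in retained], fontsize=5)
        fig.colorbar(im, label="log1p(normalized count)")
        fig.savefig(out_png, dpi=150)
        plt.close(fig)
    return df


def run_all(pcfg: PipelineConfig, sim_config: SimConfig | None = None,
            inputs: dict | None = None, out_dir=None) -> dict:
    """Execute the full pipeline and (optionally) write every artifact.

    Provide either ``sim_config`` (library simulated on the fly) or
    ``inputs`` with keys rmap/loci/baits/pairs.  Returns a report dict with
    the library statistics, probe QC summary and significant interactions.
    """
    if (sim_config is None) == (inputs is None):
        raise StageError("[input] give exactly one of sim_config or inputs")
    truth = None
    if sim_config is not None:
        lib = simulate_library(sim_config)
        rmap, loci, baits = lib["rmap"], lib["loci"], lib["baits"]
        pairs, truth = lib["pairs"], lib["truth"]
    else:
        try:
            rmap, loci = inputs["rmap"], inputs["loci"]
            baits, pairs = inputs["baits"], inputs["pairs"]
        except KeyError as e:
            raise StageError(f"[input] missing input {e}") from None

    classified, table = extract_stage(rmap, baits, loci, pairs, pcfg.flank)
    qc, contacts = normalize_stage(table, rmap, baits, pcfg.low_probe_pct,
                                   pcfg.bait_exclusion,
                                   repeats=(inputs or {}).get("repeats"))
    results = call_stage(contacts, rmap, baits, pcfg.sig_config())
    sig_df = significant_table(results, rmap, baits)

    report = {
        "library_stats": {k: int(v) for k, v in table.library_stats.items()},
        "probes": {
            "total": len(qc),
            "retained": sum(q.status == "retained" for q in qc),
            "removed_low_efficiency":
                sum(q.status == "removed_low_efficiency" for q in qc),
            "removed_repeat": sum(q.status == "removed_repeat" for q in qc),
        },
        "n_significant": int(len(sig_df)),
        "config": {
            "flank": pcfg.flank, "window": pcfg.window, "n_perm": pcfg.n_perm,
            "fdr": pcfg.fdr, "top_pct": pcfg.top_pct,
            "low_probe_pct": pcfg.low_probe_pct,
            "bait_exclusion": pcfg.bait_exclusion, "seed": pcfg.seed,
        },
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        c3io.write_pairs_tsv(pairs, out / "pairs.tsv") if sim_config else None
        c3io.write_sites_tsv(rmap, out / "sites.tsv")
        c3io.write_chromsizes(rmap, out / "chrom.sizes")
        c3io.write_loci_bed(loci, out / "loci.bed")
        c3io.write_baits_bed(baits, out / "baits.bed")
        c3io.write_contacts_tsv(table, out / "contacts.tsv")
        c3io.write_qc_tsv(qc, out / "qc.tsv")
        c3io.write_normalized_tsv(contacts, out / "normalized.tsv")
        sig_df.to_csv(out / "significant.tsv", sep="\t", index=False,
                      float_format="%.6g")
        c3io.write_bedpe(significant_bedpe(results, rmap, baits),
                         out / "significant.bedpe")
        c3io.write_json(report, out / "report.json")
        c3io.write_json(report["library_stats"], out / "stats.json")
        if truth is not None:
            truth.to_json(out / "truth.json")

    report["_objects"] = {
        "rmap": rmap, "loci": loci, "baits": baits, "classified": classified,
        "table": table, "qc": qc, "contacts": contacts, "results": results,
        "significant": sig_df, "truth": truth,
    }
    return report
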