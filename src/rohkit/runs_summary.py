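"""Summaries of detected runs: size-class tables, ROH-based inbreeding
(FROH), per-SNP in-run frequency, run islands, and the run-length /
generations-to-common-ancestor relation.

FROH for one animal is the summed length of its runs divided by the
genome length covered by the panel (LAUTO, in Mb).  Splitting runs by
length class separates ancient from recent inbreeding: autozygous
segments inherited from an ancestor ``g`` generations back have
exponentially distributed length with mean 100/(2g) cM, so long runs
reflect recent common ancestors and short runs old ones.

Run islands are regions where an unusually large fraction of animals
carry a run: per SNP, the fraction of animals whose runs cover it is
computed, a threshold is set (either an empirical quantile of that
distribution, ROH default q = 0.999, or a fixed frequency, ROHet default
0.25), and maximal stretches of consecutive above-threshold SNPs are
reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import MarkerMap, StructuralError
from .runs_detection import RunSet

logger = logging.getLogger(__name__)

__all__ = [
    "ROH_SIZE_CLASSES_MB",
    "ROHET_SIZE_CLASSES_MB",
    "FROH_BINS_MB",
    "IslandRegion",
    "classify_by_size",
    "froh",
    "snp_run_frequency",
    "frequency_table",
    "detect_islands",
    "expected_generations",
]

#: Seven ROH size classes (Mb): 2-4, 4-8, 8-12, 12-16, 16-20, 20-30, >30.
ROH_SIZE_CLASSES_MB: tuple[float, ...] = (2, 4, 8, 12, 16, 20, 30)
#: ROHet size classes (Mb): 250-500, 500-750, 750-1000, 1000-1500,
#: 1500-2000, >2000 kb.
ROHET_SIZE_CLASSES_MB: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0, 1.5, 2.0)
#: FROH length bins (Mb): [2,4), [4,8), [8,16), [16,inf).
FROH_BINS_MB: tuple[float, ...] = (2, 4, 8, 16)


def classify_by_size(runset: RunSet,
                     boundaries_mb: Sequence[float] = ROH_SIZE_CLASSES_MB,
                     ) -> pd.DataFrame:
    """Tabulate runs by length class.

    Bins are left-closed right-open ``[a, b)`` with the last bin
    open-ended; runs shorter than the first boundary fall in an explicit
    ``underflow`` row.  Columns: label, n, avg_size_kb, freq (n over the
    total number of runs).
    """
    b = list(boundaries_mb)
    if any(x >= y for x, y in zip(b, b[1:])):
        raise ValueError("boundaries must be strictly increasing")
    lengths_mb = runset.df["length_bp"].to_numpy() / 1e6
    edges = np.array([-np.inf, *b, np.inf])
    which = np.digitize(lengths_mb, edges[1:-1], right=False)
    total = len(runset)
    rows = []
    labels = ["underflow"] + [
        f"{_fmt(lo)}-{_fmt(hi)}" for lo, hi in zip(b, b[1:])
    ] + [f">{_fmt(b[-1])}"]
    for k, label in enumerate(labels):
        in_bin = which == k
        n = int(in_bin.sum())
        avg_kb = float(lengths_mb[in_bin].mean() * 1000) if n else 0.0
        rows.append((label, n, avg_kb, n / total if total else 0.0))
    table = pd.DataFrame(rows, columns=["label", "n", "avg_size_kb", "freq"])
    if table.loc[0, "n"] == 0:
        table = table.iloc[1:].reset_index(drop=True)
    return table


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)


def froh(runset: RunSet, l_auto_mb: float,
         bins_mb: Sequence[float] = FROH_BINS_MB) -> pd.DataFrame:
    """Per-animal FROH, total and per length bin.

    ``l_auto_mb`` is the autosomal genome length covered by the panel.
    Animals present in the RunSet's panel but without runs get FROH 0.
    Bins are left-closed, the last open-ended; their union covers
    [bins[0], inf), so the per-bin values sum to froh_total whenever the
    detector's minimum length is >= bins[0].
    """
    if l_auto_mb <= 0:
        raise ValueError("l_auto_mb must be positive")
    l_auto_bp = l_auto_mb * 1e6
    if len(runset) and runset.df["length_bp"].max() > l_auto_bp:
        raise StructuralError(
            "a run is longer than the stated genome length l_auto_mb")
    animals = runset.samples or sorted(runset.df["animal"].unique())
    cols = ["froh_total"] + [_bin_name(lo, hi) for lo, hi in
                             zip(bins_mb, list(bins_mb[1:]) + [None])]
    out = pd.DataFrame(0.0, index=pd.Index(animals, name="animal"),
                       columns=cols)
    if len(runset):
        df = runset.df
        lengths = df["length_bp"].to_numpy()
        by_animal = df.groupby("animal")["length_bp"].sum() / l_auto_bp
        out.loc[by_animal.index, "froh_total"] = by_animal
        edges = [x * 1e6 for x in bins_mb] + [np.inf]
        for lo, hi in zip(edges, edges[1:]):
            name = _bin_name(lo / 1e6, None if np.isinf(hi) else hi / 1e6)
            sel = (lengths >= lo) & (lengths < hi)
            s = df.loc[sel].groupby("animal")["length_bp"].sum() / l_auto_bp
            out.loc[s.index, name] = s
    return out


def _bin_name(lo: float, hi: float | None) -> str:
    if hi is None:
        return f"froh_gt{_fmt(lo)}mb"
    return f"froh_{_fmt(lo)}_{_fmt(hi)}mb"


def snp_run_frequency(runset: RunSet, marker_map: MarkerMap,
                      n_animals: int) -> np.ndarray:
    """Fraction of animals whose runs cover each SNP, in map order.

    Counts, per SNP, the number of runs covering its position (each
    animal's runs are non-overlapping, so this equals the number of
    carrier animals) divided by ``n_animals``.
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    counts = np.zeros(marker_map.n_snps, dtype=np.int64)
    pos = marker_map.positions
    blocks = dict(marker_map.chrom_blocks())
    for run in runset.df.itertuples(index=False):
        idx = blocks.get(str(run.chrom))
        if idx is None:
            raise StructuralError(f"run on chromosome {run.chrom!r} "
                                  "absent from the map")
        p = pos[idx]
        if run.start_bp < p[0] or run.end_bp > p[-1]:
            raise StructuralError(
                f"run {run.chrom}:{run.start_bp}-{run.end_bp} extends "
                "outside the mapped positions")
        lo = int(np.searchsorted(p, run.start_bp, side="left"))
        hi = int(np.searchsorted(p, run.end_bp, side="right"))
        counts[idx[lo]:idx[lo] + (hi - lo)] += 1
    return counts / float(n_animals)


def frequency_table(freq: np.ndarray, marker_map: MarkerMap) -> pd.DataFrame:
    """Manhattan-plot-ready table (chrom, pos_bp, freq)."""
    return pd.DataFrame({
        "chrom": marker_map.table["chrom"],
        "pos_bp": marker_map.table["pos_bp"],
        "freq": freq,
    })


@dataclass(frozen=True)
class IslandRegion:
    """A maximal stretch of consecutive above-threshold SNPs."""

    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    peak_freq: float
    kind: str  # "ROH" | "ROHet"


def detect_islands(freq: np.ndarray, marker_map: MarkerMap,
                   mode: str = "quantile", q: float = 0.999,
                   threshold: float = 0.25,
                   kind: str = "ROH") -> list[IslandRegion]:
    """Find run islands from the per-SNP in-run frequency vector.

    ``mode="quantile"``: the threshold is the empirical ``q``-quantile of
    ``freq`` (inverse empirical CDF, no interpolation) and SNPs with
    frequency >= threshold are members.  ``mode="fixed"``: SNPs with
    frequency strictly > ``threshold`` are members.  Maximal stretches of
    consecutive member SNPs on one chromosome become islands; stretches
    separated by even a single below-threshold SNP are not merged.
    """
    freq = np.asarray(freq, dtype=float)
    if freq.shape[0] != marker_map.n_snps:
        raise StructuralError("frequency vector does not match the map")
    if mode == "quantile":
        if not freq.any():
            logger.warning("all-zero frequency vector: no islands")
            return []
        s = np.sort(freq)
        k = int(np.ceil(q * s.size))
        thr = float(s[max(k, 1) - 1])
        member = freq >= thr
    elif mode == "fixed":
        member = freq > threshold
    else:
        raise ValueError(f"unknown island mode {mode!r}")

    pos = marker_map.positions
    islands: list[IslandRegion] = []
    for chrom, idx in marker_map.chrom_blocks():
        m = member[idx]
        if not m.any():
            continue
        hits = np.flatnonzero(m)
        breaks = np.flatnonzero(np.diff(hits) > 1)
        starts = [hits[0], *hits[breaks + 1]]
        ends = [*hits[breaks], hits[-1]]
        for s0, e0 in zip(starts, ends):
            rows = idx[s0:e0 + 1]
            islands.append(IslandRegion(
                chrom=chrom,
                start_bp=int(pos[rows[0]]),
                end_bp=int(pos[rows[-1]]),
                n_snps=int(rows.size),
                peak_freq=float(freq[rows].max()),
                kind=kind,
            ))
    return islands


def islands_to_frame(islands: Sequence[IslandRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [(i.chrom, i.start_bp, i.end_bp, i.n_snps, i.peak_freq, i.kind)
         for i in islands],
        columns=["chrom", "start_bp", "end_bp", "n_snps", "peak_freq", "kind"],
    )


def islands_to_bed(islands: Sequence[IslandRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in islands:
            fh.write(f"{i.chrom}\t{i.start_bp - 1}\t{i.end_bp}\t"
                     f"{i.kind}_island\t{i.peak_freq:.4f}\n")


def expected_generations(length_mb: float, cm_per_mb: float = 1.0) -> float:
    """Generations back to the common ancestor implied by a run length.

    IBD segment length is exponential with mean 100/(2g) cM, so a run of
    ``length_mb`` Mb (at ``cm_per_mb``) points to
    g = 100 / (2 * length_cM) generations: 4 Mb -> 12.5 generations,
    16 Mb -> 3.125, 50 Mb -> 1.
    """
    if length_mb <= 0:
        raise ValueError("length must be positive")
    if cm_per_mb <= 0:
        raise ValueError("cm_per_mb must be positive")
    return 100.0 / (2.0 * length_mb * cm_per_mb)
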