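"""Runs-of-homozygosity detection and ROH-based genomic inbreeding (F_ROH).

A sliding window of consecutive SNPs is classified homozygous when it carries
at most a small allowance of heterozygous and missing calls; a SNP is in
run-state when a sufficient fraction of the windows covering it are
homozygous.  Maximal run-state stretches become ROH segments after length,
SNP-count, density and gap constraints are enforced.  F_ROH for an individual
is the summed length of its segments above a minimum length divided by the
covered autosomal genome length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from herdgen.genio import MISSING, GenotypeDataset


@dataclass(frozen=True)
class ROHParams:
    """Sliding-window ROH criteria.

    Defaults target 50K-array cattle data: 15-SNP window, >= 40 SNPs and
    >= 4 Mb per run, density >= 1 SNP / 100 kb, gaps <= 1 Mb; one
    heterozygote and one missing call allowed per window, and a SNP is in
    run-state when at least 5% of its covering windows are homozygous.
    """

    window_snps: int = 15
    min_snps: int = 40
    min_density: float = 1.0 / 100_000
    max_gap: int = 1_000_000
    min_length: int = 4_000_000
    max_het_per_window: int = 1
    max_miss_per_window: int = 1
    snp_homozygosity_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.min_length <= 0:
            raise ValueError("min_length must be positive")
        if self.window_snps > self.min_snps:
            raise ValueError("window_snps must be <= min_snps")


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run: individual, chromosome, 1-based inclusive span."""

    sample: str
    chromosome: int
    start_bp: int
    end_bp: int
    n_snps: int

    def __post_init__(self) -> None:
        if self.end_bp < self.start_bp:
            raise ValueError("end_bp < start_bp")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def _runs_of_true(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs (stop exclusive) of maximal True runs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def detect_roh(ds: GenotypeDataset, params: ROHParams = ROHParams()) -> list[ROHSegment]:
    """Detect ROH per individual and chromosome by sliding window.

    The input is expected to be the LD-pruned dataset.  Chromosomes with
    fewer SNPs than one window are skipped with a warning.  Output is sorted
    by (sample, chromosome, start).
    """
    w = params.window_snps
    chroms = np.array([s.chromosome for s in ds.snps])
    bps = np.array([s.bp for s in ds.snps], dtype=np.int64)
    segments: list[ROHSegment] = []

    for chrom in np.unique(chroms):
        cidx = np.flatnonzero(chroms == chrom)
        L = len(cidx)
        if L < w:
            warnings.warn(
                f"chromosome {chrom}: {L} SNPs < window of {w}, skipped",
                stacklevel=2,
            )
            continue
        pos = bps[cidx]
        calls = ds.calls[:, cidx]  # (n_samples, L)

        het = (calls == 1).astype(np.int32)
        mis = (calls == MISSING).astype(np.int32)
        # windowed counts via cumulative sums: window i covers SNPs [i, i+w)
        het_c = np.cumsum(np.concatenate([np.zeros((ds.n_samples, 1), np.int32), het], axis=1), axis=1)
        mis_c = np.cumsum(np.concatenate([np.zeros((ds.n_samples, 1), np.int32), mis], axis=1), axis=1)
        n_win = L - w + 1
        het_w = het_c[:, w:] - het_c[:, :-w]    # (n_samples, n_win)
        mis_w = mis_c[:, w:] - mis_c[:, :-w]
        hom_win = (het_w <= params.max_het_per_window) & (mis_w <= params.max_miss_per_window)

        # SNP j is covered by windows max(0, j-w+1) .. min(j, n_win-1)
        homf = hom_win.astype(np.int32)
        hom_c = np.cumsum(np.concatenate([np.zeros((ds.n_samples, 1), np.int32), homf], axis=1), axis=1)
        j = np.arange(L)
        lo = np.maximum(0, j - w + 1)
        hi = np.minimum(j, n_win - 1)
        n_cover = (hi - lo + 1).astype(float)
        hom_cover = hom_c[:, hi + 1] - hom_c[:, lo]
        run_state = hom_cover / n_cover >= params.snp_homozygosity_threshold

        gap_break = np.flatnonzero(np.diff(pos) > params.max_gap)  # break after these indices
        for i, sample in enumerate(ds.samples):
            for a, b in _runs_of_true(run_state[i]):
                # split candidate [a, b) at gaps larger than max_gap
                cuts = gap_break[(gap_break >= a) & (gap_break < b - 1)]
                bounds = [a] + [c + 1 for c in cuts] + [b]
                for s0, s1 in zip(bounds[:-1], bounds[1:]):
                    n_snps = s1 - s0
                    if n_snps < params.min_snps:
                        continue
                    start, end = int(pos[s0]), int(pos[s1 - 1])
                    length = end - start + 1
                    if length < params.min_length:
                        continue
                    if n_snps / length < params.min_density:
                        continue
                    segments.append(
                        ROHSegment(sample, int(chrom), start, end, n_snps)
                    )
    segments.sort(key=lambda s: (s.sample, s.chromosome, s.start_bp))
    return segments


def covered_genome(ds: GenotypeDataset) -> dict[int, int]:
    """SNP-covered length per chromosome (last bp - first bp + 1)."""
    out: dict[int, int] = {}
    chroms = np.array([s.chromosome for s in ds.snps])
    bps = np.array([s.bp for s in ds.snps], dtype=np.int64)
    for chrom in np.unique(chroms):
        p = bps[chroms == chrom]
        out[int(chrom)] = int(p.max() - p.min() + 1)
    return out


def compute_froh(
    segments: Sequence[ROHSegment],
    genome: Mapping[int, int],
    min_length: int = 4_000_000,
    samples: Sequence[str] | None = None,
) -> pd.Series:
    """Per-individual F_ROH: summed segment length >= min_length over genome.

    ``genome`` maps chromosome -> covered length (bp) and must include every
    chromosome appearing in ``segments``.  Individuals without qualifying
    segments get F_ROH = 0; pass ``samples`` to force the output index.
    """
    for seg in segments:
        if seg.chromosome not in genome:
            raise ValueError(f"genome has no length for chromosome {seg.chromosome}")
    total = float(sum(genome.values()))
    sums: dict[str, float] = {}
    for seg in segments:
        if seg.length_bp >= min_length:
            sums[seg.sample] = sums.get(seg.sample, 0.0) + seg.length_bp
    index = list(samples) if samples is not None else sorted(sums)
    froh = pd.Series({s: sums.get(s, 0.0) / total for s in index}, name="froh")
    froh.index.name = "sample"
    return froh


_DEFAULT_EDGES_MB = (4.0, 8.0, 16.0)


def length_class_table(
    segments: Sequence[ROHSegment],
    edges_mb: Sequence[float] = _DEFAULT_EDGES_MB,
) -> pd.DataFrame:
    """Counts and percentage frequencies of segments per length class.

    Classes are [e0, e1], (e1, e2], ..., (e_last, inf) in Mb; every segment
    falls in exactly one class.  Frequencies are 100*count/total rounded to
    one decimal.
    """
    lengths_mb = np.array([s.length_bp / 1e6 for s in segments])
    if len(lengths_mb) and lengths_mb.min() < edges_mb[0]:
        raise ValueError("segment shorter than the smallest class edge")
    labels = []
    for i, e in enumerate(edges_mb):
        if i + 1 < len(edges_mb):
            labels.append(f"{e:g}–{edges_mb[i + 1]:g}")
        else:
            labels.append(f">{e:g}")
    counts = np.zeros(len(edges_mb), dtype=int)
    if len(lengths_mb):
        # length in (e_i, e_{i+1}] -> class i; values at an edge go low
        bins = np.searchsorted(np.asarray(edges_mb)[1:], lengths_mb, side="left")
        counts = np.bincount(bins, minlength=len(edges_mb))
    total = counts.sum()
    freq = np.round(100.0 * counts / total, 1) if total else np.zeros(len(counts))
    return pd.DataFrame(
        {"length_class_mb": labels, "n_roh": counts, "frequency_pct": freq}
    )


def roh_summary(
    segments: Sequence[ROHSegment],
    n_individuals: int,
    genome: Mapping[int, int] | None = None,
    samples: Sequence[str] | None = None,
    froh_min_length: int = 4_000_000,
) -> dict:
    """Descriptive ROH statistics: MN_ROH, L_ROH (Mb), SNPs per run, F_ROH.

    Also returns the per-individual (segment count, total length) pairs that
    feed the count-versus-length scatter.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    lengths_mb = np.array([s.length_bp / 1e6 for s in segments])
    nsnps = np.array([s.n_snps for s in segments])
    per_ind = pd.DataFrame(
        [(s.sample, s.length_bp / 1e6) for s in segments],
        columns=["sample", "length_mb"],
    )
    if len(per_ind):
        scatter = per_ind.groupby("sample")["length_mb"].agg(["count", "sum"])
        scatter.columns = ["n_roh", "total_length_mb"]
    else:
        scatter = pd.DataFrame(columns=["n_roh", "total_length_mb"])

    out = {
        "n_segments": int(len(segments)),
        "mn_roh": round(len(segments) / n_individuals, 1),
        "l_roh_mb": _stats(lengths_mb),
        "snps_per_segment": _stats(nsnps.astype(float)),
        "per_individual": scatter,
    }
    if genome is not None:
        froh = compute_froh(segments, genome, froh_min_length, samples=samples)
        out["froh"] = _stats(froh.to_numpy())
        out["froh_per_individual"] = froh
    return out


def _stats(x: np.ndarray) -> dict:
    if len(x) == 0:
        return {"mean": 0.0, "sd": 0.0, "min": 0.0, "max": 0.0}
    return {
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
        "min": float(np.min(x)),
        "max": float(np.max(x)),
    }


def segments_frame(segments: Sequence[ROHSegment]) -> pd.DataFrame:
    """Segments as a BED-like DataFrame (sample, chrom, start, end, n_snps, Mb)."""
    df = pd.DataFrame([asdict(s) for s in segments])
    if len(df):
        df["length_mb"] = (df["end_bp"] - df["start_bp"] + 1) / 1e6
    else:
        df = pd.DataFrame(
            columns=["sample", "chromosome", "start_bp", "end_bp", "n_snps", "length_mb"]
        )
    return df
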