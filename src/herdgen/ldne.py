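"""Within-chromosome LD, its decay with distance, and ancestral Ne.

Pairwise r² is the squared Pearson correlation of genotype dosages.  Mean r²
per physical-distance bin, adjusted for finite sample size, is inverted
through the drift expectation E[r²] ≈ 1/(alpha + 4·Ne·c) + 1/(beta·n) to an
effective population size roughly 1/(2c) generations ago, following the
standard LD-based ancestral-Ne estimator for unphased SNP-chip data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from herdgen.genio import MISSING, GenotypeDataset


@dataclass(frozen=True)
class NeOptions:
    """Settings for the LD-based Ne estimator.

    map_rate converts bp to Morgans (default 1 cM/Mb); alpha is the
    mutation adjustment in the drift expectation (2 = mutation-adjusted);
    beta_phase is 2 for unphased genotype data; recomb_mapping maps genetic
    map distance to recombination fraction ('linear' f(c)=c, or 'haldane'
    f(c)=(1-exp(-2c))/2).  Bins with fewer than min_pairs pairs are dropped.
    """

    sample_size: int = 0
    map_rate: float = 1e-8
    alpha: float = 2.0
    beta_phase: float = 2.0
    recomb_mapping: str = "linear"
    min_pairs: int = 50

    def __post_init__(self) -> None:
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")
        if self.sample_size < 2:
            raise ValueError("sample_size must be >= 2")
        if self.recomb_mapping not in ("linear", "haldane"):
            raise ValueError(f"unknown recomb_mapping {self.recomb_mapping!r}")


def pairwise_r2(
    ds: GenotypeDataset,
    max_distance: int | None = None,
) -> pd.DataFrame:
    """All within-chromosome SNP-pair r² values with physical distances.

    r² is the squared Pearson correlation of dosages over samples that are
    non-missing at both SNPs; pairs with fewer than two informative samples
    or zero variance at either SNP are skipped (their count is reported via
    a log-style warning only when nonzero).
    """
    chroms = np.array([s.chromosome for s in ds.snps])
    bps = np.array([s.bp for s in ds.snps], dtype=np.int64)
    frames = []
    n_skipped = 0
    for chrom in np.unique(chroms):
        cidx = np.flatnonzero(chroms == chrom)
        if len(cidx) < 2:
            continue
        calls = ds.calls[:, cidx].astype(float)
        pos = bps[cidx]
        has_missing = (calls == MISSING).any()
        if has_missing:
            masked = np.ma.masked_equal(calls, float(MISSING))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = np.asarray(np.ma.filled(np.ma.corrcoef(masked, rowvar=False), np.nan))
        else:
            sd = calls.std(axis=0)
            ok = sd > 0
            r = np.full((len(cidx), len(cidx)), np.nan)
            if ok.sum() >= 2:
                r[np.ix_(ok, ok)] = np.corrcoef(calls[:, ok], rowvar=False)
        iu, ju = np.triu_indices(len(cidx), k=1)
        dist = pos[ju] - pos[iu]
        r2 = r[iu, ju] ** 2
        valid = np.isfinite(r2)
        if max_distance is not None:
            valid &= dist <= max_distance
        n_skipped += int((~np.isfinite(r2)).sum())
        frames.append(
            pd.DataFrame(
                {"chromosome": int(chrom), "distance_bp": dist[valid], "r2": r2[valid]}
            )
        )
    if n_skipped:
        warnings.warn(f"{n_skipped} SNP pairs skipped (monomorphic or <2 informative samples)",
                      stacklevel=2)
    if not frames:
        return pd.DataFrame(columns=["chromosome", "distance_bp", "r2"])
    return pd.concat(frames, ignore_index=True)


def bin_ld_decay(pairs: pd.DataFrame, bin_width: int = 10_000) -> pd.DataFrame:
    """Mean r² per half-open distance bin [k·w, (k+1)·w).

    Returns one row per non-empty bin: bin bounds, midpoint, mean r², count.
    """
    if len(pairs) == 0:
        return pd.DataFrame(
            columns=["bin_left_bp", "bin_right_bp", "midpoint_bp", "mean_r2", "n_pairs"]
        )
    k = (pairs["distance_bp"] // bin_width).astype(int)
    grouped = pairs.groupby(k)["r2"].agg(["mean", "size"])
    out = pd.DataFrame(
        {
            "bin_left_bp": grouped.index * bin_width,
            "bin_right_bp": (grouped.index + 1) * bin_width,
            "midpoint_bp": grouped.index * bin_width + bin_width / 2,
            "mean_r2": grouped["mean"].to_numpy(),
            "n_pairs": grouped["size"].to_numpy(),
        }
    ).reset_index(drop=True)
    return out.sort_values("bin_left_bp", ignore_index=True)


def estimate_ne_trajectory(bins: pd.DataFrame, opts: NeOptions) -> pd.DataFrame:
    """Invert binned LD decay to an ancestral-Ne trajectory.

    Per bin: genetic distance c = midpoint·map_rate mapped through the
    configured recombination mapping f(c); sample-size-adjusted
    r²_adj = mean r² − 1/(beta_phase·n); generations ago t = 1/(2·f(c));
    Ne(t) = (1/r²_adj − alpha) / (4·f(c)).  Bins with non-positive r²_adj or
    f(c) = 0, or fewer than min_pairs pairs, are dropped with a warning.
    Output sorted by t ascending.
    """
    if len(bins) == 0:
        raise ValueError("no LD bins provided")
    c_map = bins["midpoint_bp"].to_numpy() * opts.map_rate
    if opts.recomb_mapping == "haldane":
        f = 0.5 * (1.0 - np.exp(-2.0 * c_map))
    else:
        f = c_map
    r2_adj = bins["mean_r2"].to_numpy() - 1.0 / (opts.beta_phase * opts.sample_size)
    enough = bins["n_pairs"].to_numpy() >= opts.min_pairs
    usable = enough & (r2_adj > 0) & (f > 0)
    n_dropped = int((~usable).sum())
    if n_dropped:
        warnings.warn(
            f"{n_dropped} LD bins dropped (non-positive adjusted r2, zero "
            f"recombination, or < {opts.min_pairs} pairs)",
            stacklevel=2,
        )
    with np.errstate(divide="ignore"):
        t = 1.0 / (2.0 * f[usable])
        ne = (1.0 / r2_adj[usable] - opts.alpha) / (4.0 * f[usable])
    out = pd.DataFrame(
        {
            "generations_ago": t,
            "ne": ne,
            "midpoint_bp": bins["midpoint_bp"].to_numpy()[usable],
            "mean_r2": bins["mean_r2"].to_numpy()[usable],
            "n_pairs": bins["n_pairs"].to_numpy()[usable],
        }
    )
    out = out[out["ne"] > 0].sort_values("generations_ago", ignore_index=True)
    return out
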