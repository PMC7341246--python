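"""Genotype I/O, marker/sample quality control and LD pruning.

Genotypes are held as an integer matrix of A1-allele dosages (0, 1, 2) with a
distinct sentinel for missing calls.  PLINK binary (.bed/.bim/.fam) and text
(.ped/.map) formats are read and written directly; the 2-bit SNP-major .bed
encoding is decoded per the published format: within each byte the first
sample occupies the two lowest-order bits, and the bit pairs mean
00 = hom A1/A1 (dosage 2), 01 = missing, 10 = het (dosage 1),
11 = hom A2/A2 (dosage 0).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

MISSING = -1
"""Sentinel genotype code for a missing call (never 0)."""

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# value of each 2-bit pair -> dosage code (index = pair value)
_PAIR_TO_CODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_CODE_TO_PAIR = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


class PlinkFormatError(ValueError):
    """Raised for malformed PLINK binary files (bad magic, truncation)."""


@dataclass(frozen=True)
class SnpInfo:
    """One array marker: name, autosome label, 1-based position, alleles."""

    id: str
    chromosome: int
    bp: int
    a1: str = "A"
    a2: str = "B"

    def __post_init__(self) -> None:
        if self.bp < 1:
            raise ValueError(f"SNP {self.id}: bp must be >= 1, got {self.bp}")


@dataclass
class GenotypeDataset:
    """Sample x SNP dosage matrix plus marker map and sample IDs.

    ``calls[i, j]`` counts copies of SNP j's A1 allele carried by sample i,
    one of {0, 1, 2, MISSING}.  SNPs are strictly sorted by (chromosome, bp)
    and (chrom, bp, id) triples are unique; sample IDs are unique.
    """

    samples: list[str]
    snps: list[SnpInfo]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)} samples, {len(self.snps)} snps)"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs")
        legal = {0, 1, 2, MISSING}
        bad = set(np.unique(self.calls)) - legal
        if bad:
            raise ValueError(f"illegal genotype codes: {sorted(bad)}")
        keys = [(s.chromosome, s.bp, s.id) for s in self.snps]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chrom, bp, id) SNP keys")
        if any(keys[k] >= keys[k + 1] for k in range(len(keys) - 1)):
            raise ValueError("SNPs not sorted by (chromosome, bp)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_frame(self) -> pd.DataFrame:
        """Marker map as a DataFrame (id, chromosome, bp, a1, a2)."""
        return pd.DataFrame([asdict(s) for s in self.snps])

    def subset(
        self,
        sample_idx: Sequence[int] | np.ndarray | None = None,
        snp_idx: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypeDataset":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeDataset(
            samples=[self.samples[i] for i in si],
            snps=[self.snps[j] for j in vi],
            calls=self.calls[np.ix_(si, vi)].copy(),
        )

    def allele_freq(self) -> np.ndarray:
        """Per-SNP A1 allele frequency over non-missing calls (NaN if none)."""
        calls = self.calls
        obs = calls != MISSING
        n_obs = obs.sum(axis=0)
        dosage_sum = np.where(obs, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, dosage_sum / (2.0 * n_obs), np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)


@dataclass(frozen=True)
class QCParams:
    """Marker- and sample-level quality-control thresholds.

    Defaults follow common 50K-array practice for small herds: SNP and sample
    call rate >= 0.95, MAF >= 0.01, HWE exact p > 0.001, and pairwise-r2
    pruning at 0.5 in 50-SNP windows advanced by 5 SNPs.
    """

    min_call_rate_snp: float = 0.95
    min_call_rate_sample: float = 0.95
    min_maf: float = 0.01
    hwe_alpha: float = 0.001
    prune_window: int = 50
    prune_step: int = 5
    prune_r2: float = 0.5
    autosomes: tuple[int, ...] = tuple(range(1, 30))

    def __post_init__(self) -> None:
        for name in ("min_call_rate_snp", "min_call_rate_sample", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.prune_step > self.prune_window:
            raise ValueError("prune_step must be <= prune_window")


@dataclass
class QCReport:
    """Per-filter removal tallies; removed + retained = input on each axis."""

    n_snps_in: int = 0
    n_samples_in: int = 0
    snps_removed_nonautosomal: int = 0
    snps_removed_missingness: int = 0
    snps_removed_maf: int = 0
    snps_removed_hwe: int = 0
    samples_removed_call_rate: int = 0
    n_snps_retained: int = 0
    n_samples_retained: int = 0
    n_snps_after_prune: int | None = None

    def validate(self) -> None:
        snp_removed = (
            self.snps_removed_nonautosomal
            + self.snps_removed_missingness
            + self.snps_removed_maf
            + self.snps_removed_hwe
        )
        if snp_removed + self.n_snps_retained != self.n_snps_in:
            raise ValueError("SNP tallies do not sum to input count")
        if self.samples_removed_call_rate + self.n_samples_retained != self.n_samples_in:
            raise ValueError("sample tallies do not sum to input count")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


# ---------------------------------------------------------------------------
# PLINK binary I/O
# ---------------------------------------------------------------------------

def read_plink(prefix: str | Path) -> GenotypeDataset:
    """Read a PLINK .bed/.bim/.fam fileset given its shared path prefix.

    The .bed payload must be SNP-major; genotype bytes are decoded with the
    standard 2-bit table (first sample in the lowest bits of each byte).
    """
    prefix = Path(prefix)
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))

    fam_df = pd.read_csv(fam, sep=r"\s+", header=None, dtype=str)
    samples = list(fam_df.iloc[:, 1])
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample IDs in .fam")

    bim_df = pd.read_csv(
        bim, sep=r"\s+", header=None, dtype=str,
        names=["chrom", "id", "cm", "bp", "a1", "a2"],
    )
    snps = [
        SnpInfo(id=r.id, chromosome=int(r.chrom), bp=int(r.bp), a1=r.a1, a2=r.a2)
        for r in bim_df.itertuples()
    ]

    raw = bed.read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(f"{bed}: bad magic bytes {raw[:2]!r}")
    if raw[2] != _SNP_MAJOR:
        raise PlinkFormatError(f"{bed}: not SNP-major (mode byte {raw[2]:#x})")
    n_samples, n_snps = len(samples), len(snps)
    bytes_per_snp = (n_samples + 3) // 4
    expected = 3 + bytes_per_snp * n_snps
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{bed}: payload length {len(raw)} != expected {expected} "
            f"for {n_samples} samples x {n_snps} SNPs"
        )

    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    payload = payload.reshape(n_snps, bytes_per_snp)
    # expand each byte into 4 two-bit pairs, sample-major within byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    pairs = (payload[:, :, None] >> shifts) & 0b11          # (snp, byte, 4)
    pairs = pairs.reshape(n_snps, bytes_per_snp * 4)[:, :n_samples]
    calls = _PAIR_TO_CODE[pairs].T                           # (sample, snp)

    order = np.lexsort(([s.bp for s in snps], [s.chromosome for s in snps]))
    snps = [snps[j] for j in order]
    calls = calls[:, order]
    return GenotypeDataset(samples=samples, snps=snps, calls=calls)


def write_plink(ds: GenotypeDataset, prefix: str | Path) -> None:
    """Write .bed/.bim/.fam; round-trips bit-exactly through :func:`read_plink`."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in ds.samples:
            fh.write(f"{s} {s} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for s in ds.snps:
            fh.write(f"{s.chromosome}\t{s.id}\t0\t{s.bp}\t{s.a1}\t{s.a2}\n")

    n_samples = ds.n_samples
    bytes_per_snp = (n_samples + 3) // 4
    pair = np.empty((ds.n_snps, bytes_per_snp * 4), dtype=np.uint8)
    pair[:] = 0
    codes = ds.calls.T  # (snp, sample)
    pair_vals = np.empty_like(codes, dtype=np.uint8)
    for code, bits in _CODE_TO_PAIR.items():
        pair_vals[codes == code] = bits
    pair[:, :n_samples] = pair_vals
    packed = (
        pair.reshape(ds.n_snps, bytes_per_snp, 4)
        << np.array([0, 2, 4, 6], dtype=np.uint8)
    ).sum(axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        fh.write(packed.tobytes())


def read_pedigree(path: str | Path) -> pd.DataFrame:
    """Read a 3+-column pedigree TSV (animal, sire, dam; 0 = unknown)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    for required in ("animal", "sire", "dam"):
        if required not in cols:
            raise ValueError(f"pedigree file missing column '{required}'")
    return df


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_aa_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count no more probable than the observed one (the
    standard exact test of HWE).  Monomorphic columns return p = 1.
    """
    if min(n_aa_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa_hom1 + n_het + n_hom2
    if n == 0:
        return 1.0
    n_a = 2 * n_aa_hom1 + n_het  # copies of the first allele
    n_b = 2 * n_hom2 + n_het
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0

    # heterozygote count shares the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = (max(n_a, n_b) - hets) // 2
    # log P(n_het = h | allele counts) up to a shared constant
    logp = (
        gammaln(n + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
        + hets * np.log(2.0)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    observed = probs[np.searchsorted(hets, n_het)]
    # two-sided by probability mass; tiny epsilon guards float ties
    return float(min(1.0, probs[probs <= observed * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def qc_filter(ds: GenotypeDataset, params: QCParams) -> tuple[GenotypeDataset, QCReport]:
    """Apply the fixed-order QC cascade and tally removals per step.

    Order: (1) non-autosomal SNPs, (2) low-call-rate samples, (3) low
    call-frequency SNPs, (4) MAF < threshold, (5) HWE exact p <= alpha.
    """
    report = QCReport(n_snps_in=ds.n_snps, n_samples_in=ds.n_samples)

    # 1: autosomes only
    auto = np.array([s.chromosome in params.autosomes for s in ds.snps])
    report.snps_removed_nonautosomal = int((~auto).sum())
    ds = ds.subset(snp_idx=np.flatnonzero(auto))

    # 2: sample call rate (over the autosomal SNP set)
    if ds.n_snps > 0:
        sample_cr = (ds.calls != MISSING).mean(axis=1)
    else:
        sample_cr = np.ones(ds.n_samples)
    keep_s = sample_cr >= params.min_call_rate_sample
    report.samples_removed_call_rate = int((~keep_s).sum())
    ds = ds.subset(sample_idx=np.flatnonzero(keep_s))
    report.n_samples_retained = ds.n_samples

    # 3: SNP call frequency
    if ds.n_samples > 0:
        snp_cr = (ds.calls != MISSING).mean(axis=0)
    else:
        snp_cr = np.zeros(ds.n_snps)
    keep = snp_cr >= params.min_call_rate_snp
    report.snps_removed_missingness = int((~keep).sum())
    ds = ds.subset(snp_idx=np.flatnonzero(keep))

    # 4: MAF
    maf = ds.maf()
    keep = ~np.isnan(maf) & (maf >= params.min_maf)
    report.snps_removed_maf = int((~keep).sum())
    ds = ds.subset(snp_idx=np.flatnonzero(keep))

    # 5: HWE exact test
    calls = ds.calls
    n2 = (calls == 2).sum(axis=0)
    n1 = (calls == 1).sum(axis=0)
    n0 = (calls == 0).sum(axis=0)
    pvals = np.array(
        [hwe_exact_test(int(a), int(h), int(b)) for a, h, b in zip(n2, n1, n0)]
    )
    keep = pvals > params.hwe_alpha
    report.snps_removed_hwe = int((~keep).sum())
    ds = ds.subset(snp_idx=np.flatnonzero(keep))

    report.n_snps_retained = ds.n_snps
    report.validate()
    if ds.n_snps == 0 or ds.n_samples == 0:
        raise ValueError(
            "no data left after QC "
            f"({ds.n_samples} samples, {ds.n_snps} SNPs retained)"
        )
    return ds, report


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _window_r2(calls: np.ndarray) -> np.ndarray:
    """Pairwise squared correlation between genotype columns.

    Missing calls are handled by pairwise-complete masking.
    """
    masked = np.ma.masked_equal(calls.astype(float), float(MISSING))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # masked corrcoef warns on degenerate cols
        r = np.ma.corrcoef(masked, rowvar=False)
    r2 = np.asarray(np.ma.filled(r, 0.0)) ** 2
    np.fill_diagonal(r2, 0.0)
    return r2


def ld_prune(
    ds: GenotypeDataset,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.5,
) -> list[str]:
    """Greedy windowed pairwise-r2 pruning; returns retained SNP ids.

    Within each window of ``window`` SNPs (advanced by ``step`` along each
    chromosome), while any retained pair exceeds ``r2_max`` the member of the
    worst pair with the lower MAF (ties: the later position) is removed.
    Deterministic for fixed input.
    """
    if window < 2:
        raise ValueError(f"window must be >= 2, got {window}")
    maf = ds.maf()
    keep = np.ones(ds.n_snps, dtype=bool)
    chroms = np.array([s.chromosome for s in ds.snps])

    for chrom in np.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        for start in range(0, len(idx), step):
            widx = idx[start : start + window]
            widx = widx[keep[widx]]
            if len(widx) < 2:
                continue
            r2 = _window_r2(ds.calls[:, widx])
            active = np.ones(len(widx), dtype=bool)
            while True:
                act = np.flatnonzero(active)
                if len(act) < 2:
                    break
                block = r2[np.ix_(act, act)]
                worst = block.max()
                if worst <= r2_max:
                    break
                a, b = np.unravel_index(np.argmax(block), block.shape)
                ia, ib = act[a], act[b]
                ga, gb = widx[ia], widx[ib]
                # drop the lower-MAF member; ties -> the later-positioned SNP
                if maf[ga] < maf[gb] or (maf[ga] == maf[gb] and ga > gb):
                    active[ia] = False
                else:
                    active[ib] = False
            keep[widx[~active]] = False
            if start + window >= len(idx):
                break
    return [ds.snps[j].id for j in np.flatnonzero(keep)]


def apply_snp_selection(ds: GenotypeDataset, snp_ids: Iterable[str]) -> GenotypeDataset:
    """Subset a dataset to the given SNP ids (map order preserved)."""
    wanted = set(snp_ids)
    idx = [j for j, s in enumerate(ds.snps) if s.id in wanted]
    return ds.subset(snp_idx=idx)
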