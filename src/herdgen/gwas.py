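"""Single-SNP association scan of deregressed EBVs with stratification control.

Population structure is captured by the leading axes of a variance-
standardized genotype PCA; both phenotype and genotype are residualized on
those axes plus an intercept, and a 1-df score statistic
chi2 = (n − k − 1)·r²(residuals) tests each SNP.  Genomic control rescales
p-values by the deflation/inflation factor λ (here, multiplicatively on the
p scale), SNPs are tiered against genome-wide (5e-6) and suggestive (5e-5)
thresholds, a per-SNP variance explained is attached, and SNPs can be
labelled against a GFF3 gene annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from herdgen.genio import MISSING, GenotypeDataset

_CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, 1)  # 0.4549...


@dataclass(frozen=True)
class GwasOptions:
    """Scan settings: stratification axes, λ method, significance thresholds."""

    trait: str = "trait"
    n_axes: int = 3
    lambda_method: str = "median"          # or "regression"
    adjust_mode: str = "multiply_p"        # literal p*λ; or "divide_chi2"
    genome_wide_p: float = 5e-6
    suggestive_p: float = 5e-5
    pve_method: str = "2pq"                # or "r2" (score-statistic based)

    def __post_init__(self) -> None:
        if not self.genome_wide_p < self.suggestive_p:
            raise ValueError("genome-wide threshold must be below suggestive")
        if self.lambda_method not in ("median", "regression"):
            raise ValueError(f"unknown lambda_method {self.lambda_method!r}")


def stratification_axes(ds: GenotypeDataset, n_axes: int = 3) -> np.ndarray:
    """Top eigenvectors of the standardized-genotype sample covariance.

    Genotypes are centred by 2p̂ and scaled by sqrt(2p̂(1−p̂)) per SNP
    (missing calls mean-imputed for the decomposition only); the returned
    (n_samples, n_axes) scores are orthonormal eigenvectors with the sign
    fixed so each axis's largest-magnitude loading is positive.
    """
    n = ds.n_samples
    if n_axes >= n - 1:
        raise ValueError(f"n_axes={n_axes} too large for {n} samples")
    G = ds.calls.astype(float)
    G[G == MISSING] = np.nan
    p_hat = np.nanmean(G, axis=0) / 2.0
    keep = (p_hat > 0) & (p_hat < 1)
    G = G[:, keep]
    p_hat = p_hat[keep]
    col_mean = 2.0 * p_hat
    G = np.where(np.isnan(G), col_mean, G)
    S = (G - col_mean) / np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    K = S @ S.T / S.shape[1]
    eigvals, eigvecs = np.linalg.eigh(K)
    rank = np.linalg.matrix_rank(K)
    if n_axes > rank:
        raise ValueError(f"n_axes={n_axes} exceeds covariance rank {rank}")
    axes = eigvecs[:, ::-1][:, :n_axes]
    for k in range(n_axes):
        j = np.argmax(np.abs(axes[:, k]))
        if axes[j, k] < 0:
            axes[:, k] = -axes[:, k]
    return axes


def egscore_scan(
    debv: pd.Series,
    ds: GenotypeDataset,
    axes: np.ndarray | None,
    opts: GwasOptions = GwasOptions(),
) -> pd.DataFrame:
    """Score-test association of each SNP with the DEBV phenotype.

    ``debv`` is indexed by animal ID; it is inner-joined with the dataset's
    samples (the overlap count is reported).  Phenotype and genotype are
    residualized on the axes plus intercept; the raw p comes from the upper
    tail of chi2(1).  Monomorphic SNPs in the joined set are skipped.
    """
    common = [s for s in ds.samples if s in debv.index]
    if len(common) < len(ds.samples) or len(common) < len(debv):
        warnings.warn(
            f"inner join: {len(common)} animals in common "
            f"({len(ds.samples)} genotyped, {len(debv)} with DEBV)",
            stacklevel=2,
        )
    if len(common) < 3:
        raise ValueError("fewer than 3 animals with both genotype and DEBV")
    sample_idx = [ds.samples.index(s) for s in common]
    y = debv.loc[common].to_numpy(dtype=float)
    n = len(y)

    if axes is None or (hasattr(axes, "shape") and np.size(axes) == 0):
        Q = np.ones((n, 1)) / np.sqrt(n)
        k = 0
    else:
        A = np.c_[np.ones(n), np.asarray(axes)[sample_idx]]
        Q, _ = np.linalg.qr(A)
        k = A.shape[1] - 1

    G = ds.calls[sample_idx].astype(float)
    G[G == MISSING] = np.nan
    col_mean = np.nanmean(G, axis=0)
    G = np.where(np.isnan(G), col_mean, G)

    yr = y - Q @ (Q.T @ y)
    Gr = G - Q @ (Q.T @ G)
    gss = (Gr**2).sum(axis=0)
    yss = float(yr @ yr)
    poly = G.std(axis=0) == 0
    valid = ~poly & (gss > 1e-12) & (yss > 0)
    if poly.any():
        warnings.warn(f"{int(poly.sum())} monomorphic SNPs skipped", stacklevel=2)

    cov = Gr.T @ yr
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = cov**2 / (gss * yss)
        beta = cov / gss
    chi2 = (n - k - 1) * r2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.abs(beta) / np.sqrt(chi2)
    pvals = stats.chi2.sf(chi2, df=1)

    freq = ds.allele_freq()
    df = pd.DataFrame(
        {
            "snp": [s.id for s in ds.snps],
            "chromosome": [s.chromosome for s in ds.snps],
            "bp": [s.bp for s in ds.snps],
            "freq_a1": freq,
            "beta": beta,
            "se": se,
            "chi2": chi2,
            "p": pvals,
        }
    )
    df = df.loc[valid].reset_index(drop=True)
    df.attrs["n_samples"] = n
    df.attrs["n_axes"] = k
    df.attrs["phenotype_variance"] = float(np.var(y, ddof=1))
    df.attrs["trait"] = opts.trait
    return df


@dataclass
class LambdaResult:
    """Genomic-control factor with Q-Q coordinates for diagnostics."""

    lambda_: float
    method: str
    qq: pd.DataFrame


def genomic_control(
    raw: pd.DataFrame,
    opts: GwasOptions = GwasOptions(),
) -> tuple[LambdaResult, pd.DataFrame]:
    """Estimate λ and attach adjusted p-values and significance tiers.

    λ = median(observed chi2)/median(chi2₁) (or the through-origin regression
    of sorted observed on expected quantiles).  The default adjustment
    multiplies raw p by λ and caps at 1 — the literal small-sample deflation
    correction; ``adjust_mode='divide_chi2'`` instead divides the statistics
    by λ, the conventional direction for inflation (λ > 1).
    """
    chi2 = raw["chi2"].to_numpy()
    m = len(chi2)
    if m < 100:
        warnings.warn(f"only {m} SNPs: lambda estimate may be unstable", stacklevel=2)
    expected = stats.chi2.ppf((np.arange(1, m + 1) - 0.5) / m, df=1)
    observed = np.sort(chi2)
    if opts.lambda_method == "median":
        lam = float(np.median(chi2) / _CHI2_MEDIAN_1DF)
    else:
        lam = float((expected @ observed) / (expected @ expected))
    qq = pd.DataFrame({"expected_chi2": expected, "observed_chi2": observed})

    out = raw.copy()
    if opts.adjust_mode == "multiply_p":
        out["p_adjusted"] = np.minimum(1.0, out["p"] * lam)
    elif opts.adjust_mode == "divide_chi2":
        out["p_adjusted"] = stats.chi2.sf(out["chi2"] / lam, df=1)
    else:
        raise ValueError(f"unknown adjust_mode {opts.adjust_mode!r}")
    out["tier"] = [classify_significance(p, opts) for p in out["p_adjusted"]]

    var_y = raw.attrs.get("phenotype_variance")
    if var_y:
        out["pve"] = [
            estimate_pve(
                b, f, var_y,
                method=opts.pve_method,
                chi2=c, n=raw.attrs.get("n_samples"),
            )
            for b, f, c in zip(out["beta"], out["freq_a1"], out["chi2"])
        ]
    out.attrs = dict(raw.attrs)
    out.attrs["lambda"] = lam
    return LambdaResult(lambda_=lam, method=opts.lambda_method, qq=qq), out


def classify_significance(p: float, opts: GwasOptions = GwasOptions()) -> str:
    """Tier a p-value: 'genome-wide', 'suggestive' or 'none'."""
    if not 0 < p <= 1:
        raise ValueError(f"p must be in (0, 1], got {p}")
    if p < opts.genome_wide_p:
        return "genome-wide"
    if p < opts.suggestive_p:
        return "suggestive"
    return "none"


def estimate_pve(
    beta: float,
    freq: float,
    phenotype_variance: float,
    method: str = "2pq",
    chi2: float | None = None,
    n: int | None = None,
) -> float:
    """Proportion of phenotype (DEBV) variance explained by one SNP.

    Default '2pq': PVE = 2·p̂(1−p̂)·β² / Var(y), capped at 1.  Alternative
    'r2' derives PVE from the score statistic, chi2/(chi2 + n − 2).
    """
    if phenotype_variance <= 0:
        raise ValueError("phenotype variance must be positive")
    if not 0 < freq < 1:
        raise ValueError("allele frequency must be in (0, 1)")
    if method == "2pq":
        return float(min(1.0, 2.0 * freq * (1.0 - freq) * beta**2 / phenotype_variance))
    if method == "r2":
        if chi2 is None or n is None:
            raise ValueError("method 'r2' needs chi2 and n")
        return float(min(1.0, chi2 / (chi2 + n - 2)))
    raise ValueError(f"unknown PVE method {method!r}")


# ---------------------------------------------------------------------------
# SNP feature annotation from GFF3
# ---------------------------------------------------------------------------

def _attr_name(attributes: str) -> str:
    fields = dict(
        kv.split("=", 1) for kv in attributes.split(";") if "=" in kv
    )
    for key in ("Name", "gene_name", "ID", "gene_id"):
        if key in fields:
            return fields[key].strip()
    return "?"


def _read_gff3(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["seqid", "source", "type", "start", "end", "score", "strand",
               "phase", "attributes"],
        dtype={"seqid": str},
    )
    df["name"] = df["attributes"].map(_attr_name)
    return df


def annotate_snp_feature(
    snps: pd.DataFrame,
    gff3_path,
    upstream_window: int = 5_000,
) -> pd.DataFrame:
    """Label SNPs against a GFF3 annotation (gene/exon features).

    A SNP inside a gene is an 'exon variant' when it overlaps an exon, else
    'intron variant'; within ``upstream_window`` bp 5' of a gene (strand
    aware) it is an 'upstream gene variant'; otherwise 'intergenic'.  The
    relevant (or nearest in-window) gene name is attached.  SNP chromosomes
    absent from the annotation are counted in a warning.
    """
    gff = _read_gff3(gff3_path)
    genes = gff[gff["type"] == "gene"]
    exons = gff[gff["type"] == "exon"]

    labels: list[str] = []
    features: list[str] = []
    unmatched = 0
    gene_chroms = set(genes["seqid"])
    for row in snps.itertuples():
        chrom = str(row.chromosome)
        bp = int(row.bp)
        if chrom not in gene_chroms:
            unmatched += 1
            labels.append("intergenic")
            features.append("NA")
            continue
        g = genes[genes["seqid"] == chrom]
        inside = g[(g["start"] <= bp) & (bp <= g["end"])]
        if len(inside):
            gene = inside.iloc[0]
            ex = exons[
                (exons["seqid"] == chrom)
                & (exons["start"] <= bp)
                & (bp <= exons["end"])
            ]
            labels.append("exon variant" if len(ex) else "intron variant")
            features.append(gene["name"])
            continue
        # upstream: 5' of the gene start on its strand
        plus = g[(g["strand"] != "-")
                 & (bp < g["start"]) & (bp >= g["start"] - upstream_window)]
        minus = g[(g["strand"] == "-")
                  & (bp > g["end"]) & (bp <= g["end"] + upstream_window)]
        near = pd.concat([plus, minus])
        if len(near):
            dist = np.minimum(
                np.abs(near["start"] - bp), np.abs(near["end"] - bp)
            )
            labels.append("upstream gene variant")
            features.append(near.iloc[int(np.argmin(dist.to_numpy()))]["name"])
        else:
            labels.append("intergenic")
            features.append("NA")
    if unmatched:
        warnings.warn(
            f"{unmatched} SNPs on chromosomes absent from the annotation",
            stacklevel=2,
        )
    out = snps.copy()
    out["feature_type"] = labels
    out["feature_gene"] = features
    return out
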