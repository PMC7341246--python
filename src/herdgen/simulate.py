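"""Synthetic cohorts with known truth for every pipeline stage.

Three generators: a generational pedigree simulator with controllable
close-kin mating, a pedigree gene-drop that tracks founder-allele labels so
true autozygous (IBD) segments are exact, and a discrete-generation
Wright-Fisher forward simulator whose LD decay reflects a constant effective
population size.  A phenotype simulator draws breeding values down the
pedigree under the animal model (direct, maternal, permanent-environment
terms) and can run BLUP to yield EBV/reliability fixtures end to end.

Meiosis uses Poisson crossovers without interference (Haldane map): the
source haplotype switches between adjacent SNPs with probability
r = (1 - exp(-2*d))/2 for map distance d.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from herdgen.animal_model import (
    ModelSpec,
    PedigreeTable,
    VarianceComponents,
    pedigree_inbreeding_and_ainv,
    solve_mme,
)
from herdgen.genio import GenotypeDataset, SnpInfo


@dataclass(frozen=True)
class ChromosomeSpec:
    """Genome layout: equal-length autosomes at 50K-chip SNP density."""

    n_chrom: int = 29
    length_bp: int = 90_000_000
    map_rate: float = 1e-8          # Morgans per bp (1 cM/Mb)
    snp_spacing: int = 50_000       # mean inter-SNP distance


@dataclass(frozen=True)
class TraitSpec:
    """Target moments of a simulated trait under the animal model."""

    name: str = "trait"
    mean: float = 0.0
    var_p: float = 1.0
    h2: float = 0.3
    m2: float = 0.0
    r_am: float = 0.0
    c2: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.h2 <= 1 or not 0 <= self.m2 <= 1 or not 0 <= self.c2 <= 1:
            raise ValueError("variance fractions must be in [0, 1]")
        if self.h2 + self.m2 + self.c2 > 1 + 1e-12:
            raise ValueError("variance fractions sum above 1")
        if abs(self.r_am) > 1:
            raise ValueError("|r_am| must be <= 1")
        if self.r_am != 0 and self.m2 == 0:
            raise ValueError("r_am set without a maternal term")


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic generators; identical config => identical data."""

    seed: int = 0
    n_founders: int = 30
    n_generations: int = 4
    offspring_per_generation: int | None = None
    mating: str = "random"              # random | close_kin | repeated_sire
    close_kin_prob: float = 0.0
    chrom: ChromosomeSpec = field(default_factory=ChromosomeSpec)
    founder_maf: tuple[float, float] = (0.05, 0.5)
    ne: int = 100                       # Wright-Fisher constant Ne
    drift_generations: int = 300
    sample_size: int = 50
    trait: TraitSpec = field(default_factory=TraitSpec)

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if not 0 <= self.close_kin_prob <= 1:
            raise ValueError("close_kin_prob must be in [0, 1]")
        if self.mating not in ("random", "close_kin", "repeated_sire"):
            raise ValueError(f"unknown mating scheme {self.mating!r}")


@dataclass
class TruthSet:
    """Ground truth of a gene-dropped cohort."""

    ibd_segments: dict[str, list[tuple[int, int, int]]]  # sample -> (chrom, start, end)
    autozygosity: pd.Series          # true IBD fraction of the genome
    pedigree_f: pd.Series
    genome_length_bp: int
    tbv: pd.Series | None = None
    qtl: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Pedigree simulation
# ---------------------------------------------------------------------------

def sim_pedigree(cfg: SimConfig) -> PedigreeTable:
    """Generational pedigree with litters of two (one male, one female).

    Families guarantee opposite-sex full-sib pairs, so a configurable
    fraction ``close_kin_prob`` of matings (from the second offspring
    generation on) can be between full sibs; 'repeated_sire' uses a single
    sire per generation.  Deterministic for a fixed config seed.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    n_off = cfg.offspring_per_generation or cfg.n_founders
    if n_off < 2:
        raise ValueError("need at least 2 offspring per generation")

    rows = []  # animal, sire, dam, sex, generation
    males = [f"G0_M{i}" for i in range(cfg.n_founders // 2 + cfg.n_founders % 2)]
    females = [f"G0_F{i}" for i in range(cfg.n_founders // 2)]
    if not males or not females:
        raise ValueError("founders must include both sexes")
    for m in males:
        rows.append((m, "0", "0", "M", 0))
    for f in females:
        rows.append((f, "0", "0", "F", 0))
    families: list[tuple[str, str]] = []  # full-sib (male, female) pairs of last gen

    for g in range(1, cfg.n_generations + 1):
        n_fam = n_off // 2
        new_rows = []
        new_families = []
        if cfg.mating == "repeated_sire":
            the_sire = males[int(rng.integers(len(males)))]
        for fam in range(n_fam):
            use_kin = (
                cfg.mating == "close_kin"
                and families
                and rng.random() < cfg.close_kin_prob
            )
            if use_kin:
                sire, dam = families[int(rng.integers(len(families)))]
            elif cfg.mating == "repeated_sire":
                sire = the_sire
                dam = females[int(rng.integers(len(females)))]
            else:
                sire = males[int(rng.integers(len(males)))]
                dam = females[int(rng.integers(len(females)))]
            son = f"G{g}_M{fam}"
            daughter = f"G{g}_F{fam}"
            new_rows.append((son, sire, dam, "M", g))
            new_rows.append((daughter, sire, dam, "F", g))
            new_families.append((son, daughter))
        rows.extend(new_rows)
        males = [r[0] for r in new_rows if r[3] == "M"]
        females = [r[0] for r in new_rows if r[3] == "F"]
        families = new_families

    df = pd.DataFrame(rows, columns=["animal", "sire", "dam", "sex", "generation"])
    return PedigreeTable(df)


# ---------------------------------------------------------------------------
# Meiosis helper
# ---------------------------------------------------------------------------

def _switch_prob(pos_bp: np.ndarray, map_rate: float) -> np.ndarray:
    """Haldane recombination fraction between adjacent SNPs."""
    d = np.diff(pos_bp) * map_rate
    return 0.5 * (1.0 - np.exp(-2.0 * d))


def _gamete_mask(rng: np.random.Generator, r: np.ndarray, n: int) -> np.ndarray:
    """(n, L) boolean source mask: True = take the second parental haplotype."""
    L = len(r) + 1
    start = rng.random((n, 1)) < 0.5
    flips = rng.random((n, L - 1)) < r
    switches = np.cumsum(flips, axis=1) % 2
    return np.concatenate([start, start ^ switches.astype(bool)], axis=1)


def _snp_positions(rng: np.random.Generator, cfg: ChromosomeSpec) -> list[np.ndarray]:
    """Random unique SNP positions per chromosome at the target density."""
    out = []
    n_snps = max(2, cfg.length_bp // cfg.snp_spacing)
    for _ in range(cfg.n_chrom):
        pos = np.sort(rng.choice(cfg.length_bp, size=n_snps, replace=False)) + 1
        out.append(pos.astype(np.int64))
    return out


# ---------------------------------------------------------------------------
# Gene drop with founder-allele tracking
# ---------------------------------------------------------------------------

def gene_drop_genotypes(
    ped: PedigreeTable, cfg: SimConfig
) -> tuple[GenotypeDataset, TruthSet]:
    """Drop founder haplotypes through the pedigree, tracking allele origin.

    Founder haplotype alleles are drawn per SNP from the configured founder
    MAF distribution; each founder haplotype carries a unique origin label
    per locus, so loci where an individual's two labels coincide are exactly
    autozygous.  Maximal same-label runs become the true IBD segments.
    """
    if cfg.chrom.length_bp <= 0:
        raise ValueError("chromosome length must be positive")
    rng = np.random.default_rng([cfg.seed, 2])
    positions = _snp_positions(rng, cfg.chrom)
    n_animals = len(ped)
    s_idx, d_idx = ped.sire_idx, ped.dam_idx

    snps: list[SnpInfo] = []
    calls = np.empty((n_animals, sum(len(p) for p in positions)), dtype=np.int8)
    ibd: dict[str, list[tuple[int, int, int]]] = {a: [] for a in ped.animals}
    auto_len = np.zeros(n_animals)

    col = 0
    for c, pos in enumerate(positions, start=1):
        L = len(pos)
        freq = rng.uniform(*cfg.founder_maf, size=L)
        r = _switch_prob(pos, cfg.chrom.map_rate)

        alleles = np.zeros((n_animals, 2, L), dtype=np.int8)
        labels = np.zeros((n_animals, 2, L), dtype=np.int32)
        for i in range(n_animals):
            for h, p in enumerate((s_idx[i], d_idx[i])):
                if p < 0:
                    alleles[i, h] = rng.random(L) < freq
                    labels[i, h] = 2 * i + h + 1  # unique founder-haplotype label
                else:
                    mask = _gamete_mask(rng, r, 1)[0]
                    alleles[i, h] = np.where(mask, alleles[p, 1], alleles[p, 0])
                    labels[i, h] = np.where(mask, labels[p, 1], labels[p, 0])

        calls[:, col : col + L] = alleles.sum(axis=1)
        snps.extend(
            SnpInfo(id=f"snp{c}_{k}", chromosome=c, bp=int(pos[k]), a1="A", a2="B")
            for k in range(L)
        )
        col += L

        same = labels[:, 0, :] == labels[:, 1, :]
        for i, animal in enumerate(ped.animals):
            for a, b in _bool_runs(same[i]):
                start, end = int(pos[a]), int(pos[b - 1])
                ibd[animal].append((c, start, end))
                auto_len[i] += end - start + 1

    genome_length = cfg.chrom.n_chrom * cfg.chrom.length_bp
    truth = TruthSet(
        ibd_segments=ibd,
        autozygosity=pd.Series(auto_len / genome_length, index=ped.animals, name="autozygosity"),
        pedigree_f=pedigree_inbreeding_and_ainv(ped)[0],
        genome_length_bp=genome_length,
    )
    ds = GenotypeDataset(samples=list(ped.animals), snps=snps, calls=calls)
    return ds, truth


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


# ---------------------------------------------------------------------------
# Wright-Fisher constant-Ne forward simulation
# ---------------------------------------------------------------------------

def sim_constant_ne_population(cfg: SimConfig) -> GenotypeDataset:
    """Discrete-generation Wright-Fisher drift with recombination.

    A pool of 2·Ne haplotypes evolves for ``drift_generations``; each gamete
    picks a random parent individual and recombines its two haplotypes.  The
    final generation is sampled as ``sample_size`` diploids (haplotypes drawn
    without replacement).  LD decay in the sample reflects the constant Ne.
    """
    if cfg.ne <= 0:
        raise ValueError("ne must be positive")
    if 2 * cfg.sample_size > 2 * cfg.ne:
        raise ValueError("sample_size exceeds Ne individuals")
    rng = np.random.default_rng([cfg.seed, 3])
    positions = _snp_positions(rng, cfg.chrom)
    two_ne = 2 * cfg.ne

    snps: list[SnpInfo] = []
    blocks = []
    hap_pick = rng.choice(two_ne, size=2 * cfg.sample_size, replace=False)
    for c, pos in enumerate(positions, start=1):
        L = len(pos)
        freq = rng.uniform(*cfg.founder_maf, size=L)
        pool = (rng.random((two_ne, L)) < freq).astype(np.int8)
        r = _switch_prob(pos, cfg.chrom.map_rate)
        for _ in range(cfg.drift_generations):
            parent = rng.integers(cfg.ne, size=two_ne)
            h1 = pool[2 * parent]
            h2 = pool[2 * parent + 1]
            mask = _gamete_mask(rng, r, two_ne)
            pool = np.where(mask, h2, h1)
        haps = pool[hap_pick]
        blocks.append(haps[0::2] + haps[1::2])
        snps.extend(
            SnpInfo(id=f"snp{c}_{k}", chromosome=c, bp=int(pos[k]), a1="A", a2="B")
            for k in range(L)
        )
    calls = np.concatenate(blocks, axis=1).astype(np.int8)
    samples = [f"S{i}" for i in range(cfg.sample_size)]
    return GenotypeDataset(samples=samples, snps=snps, calls=calls)


# ---------------------------------------------------------------------------
# Phenotypes, breeding values, EBV fixtures
# ---------------------------------------------------------------------------

def sim_phenotypes_and_ebv(
    ped: PedigreeTable,
    cfg: SimConfig,
    fit_blup: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame | None, pd.Series]:
    """Simulate records under the animal model; optionally BLUP them.

    True direct (and maternal) breeding values are drawn down the pedigree
    with inbreeding-adjusted Mendelian-sampling variances; permanent-
    environment and residual effects complete the phenotype.  Records are
    produced for every non-founder (founders lack a recorded dam).  Returns
    (records, ebv_table or None, true_breeding_values).
    """
    spec = cfg.trait
    rng = np.random.default_rng([cfg.seed, 4])
    s2a = spec.h2 * spec.var_p
    s2m = spec.m2 * spec.var_p
    s2p = spec.c2 * spec.var_p
    s_am = spec.r_am * np.sqrt(s2a * s2m) if s2m > 0 else 0.0
    s2e = spec.var_p - s2a - s2m - s2p - s_am
    if s2e <= 0:
        raise ValueError("residual variance non-positive under this trait spec")

    F, _ = pedigree_inbreeding_and_ainv(ped)
    n = len(ped)
    G0 = np.array([[s2a, s_am], [s_am, s2m]])
    am = np.zeros((n, 2))
    chol = np.linalg.cholesky(G0 + np.eye(2) * 1e-12) if s2m > 0 else None
    for i in range(n):
        si, di = ped.sire_idx[i], ped.dam_idx[i]
        pa = 0.5 * (am[si] if si >= 0 else 0.0) + 0.5 * (am[di] if di >= 0 else 0.0)
        fs = F.iloc[si] if si >= 0 else 0.0
        fd = F.iloc[di] if di >= 0 else 0.0
        if si >= 0 and di >= 0:
            msv = 0.5 * (1.0 - 0.5 * (fs + fd))
        elif si >= 0 or di >= 0:
            msv = 0.75
        else:
            msv = 1.0
        z = rng.standard_normal(2)
        if chol is not None:
            mend = np.sqrt(msv) * (chol @ z)
        else:
            mend = np.array([np.sqrt(msv * s2a) * z[0], 0.0])
        am[i] = pa + mend
    tbv = pd.Series(am[:, 0], index=ped.animals, name="tbv")

    has_dam = ped.dam_idx >= 0
    rec_idx = np.flatnonzero(has_dam)
    if len(rec_idx) == 0:
        raise ValueError("no animals with a recorded dam to phenotype")
    pe = rng.normal(0.0, np.sqrt(s2p), size=n) if s2p > 0 else np.zeros(n)
    e = rng.normal(0.0, np.sqrt(s2e), size=len(rec_idx))
    y = (
        spec.mean
        + am[rec_idx, 0]
        + (am[ped.dam_idx[rec_idx], 1] if s2m > 0 else 0.0)
        + (pe[ped.dam_idx[rec_idx]] if s2p > 0 else 0.0)
        + e
    )
    records = pd.DataFrame(
        {
            "animal": [ped.animals[i] for i in rec_idx],
            "dam": [ped.animals[ped.dam_idx[i]] for i in rec_idx],
            spec.name: y,
        }
    )

    ebv_table = None
    if fit_blup:
        vc = VarianceComponents(
            sigma2_a=s2a, sigma2_e=s2e, sigma2_m=s2m,
            sigma_am=s_am, sigma2_p=s2p,
        )
        model = ModelSpec(
            trait=spec.name,
            maternal=s2m > 0,
            permanent_env=s2p > 0,
            direct_maternal_cov=s_am != 0,
        )
        res = solve_mme(model, records, ped, vc)
        ebv_table = pd.DataFrame(
            {
                "animal": ped.animals,
                "ebv": res.ebv.to_numpy(),
                "reliability": res.reliability.to_numpy(),
            }
        )
    return records, ebv_table, tbv


def plant_qtl_phenotype(
    ds: GenotypeDataset,
    snp_id: str,
    pve: float,
    seed: int = 0,
) -> pd.Series:
    """Phenotype with one causal SNP explaining ``pve`` of its variance.

    y = beta*g + e with beta scaled so Var(beta*g) = pve and Var(e) = 1-pve;
    used by association power/calibration studies.
    """
    if not 0 <= pve < 1:
        raise ValueError("pve must be in [0, 1)")
    rng = np.random.default_rng([seed, 5])
    ids = [s.id for s in ds.snps]
    g = ds.calls[:, ids.index(snp_id)].astype(float)
    if g.std() == 0:
        raise ValueError(f"QTL SNP {snp_id} is monomorphic")
    y = rng.normal(0.0, np.sqrt(1.0 - pve), size=ds.n_samples)
    if pve > 0:
        beta = np.sqrt(pve / g.var())
        y = beta * (g - g.mean()) + y
    return pd.Series(y, index=ds.samples, name="phenotype")
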