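"""Pedigree-based quantitative genetics.

Inbreeding coefficients by the Meuwissen–Luo recursion, the sparse inverse of
the numerator relationship matrix A assembled with Henderson's rules using
inbreeding-adjusted Mendelian-sampling variances, mixed-model-equation BLUP
for animal models with optional maternal and permanent-environment terms,
EM-REML variance-component estimation for the direct-effects model, and
simplified Garrick deregression of EBVs for use as GWAS pseudo-phenotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

UNKNOWN = "0"
"""Sentinel for an unknown parent in pedigree tables."""


class PedigreeCycleError(ValueError):
    """Raised when an animal is its own ancestor."""


class PedigreeTable:
    """Ordered pedigree (animal, sire, dam) with unknown parents as '0'.

    Records are topologically sorted on construction so that parents precede
    offspring; a cycle (an animal among its own ancestors) raises
    :class:`PedigreeCycleError` naming the cycle.
    """

    def __init__(self, records: pd.DataFrame) -> None:
        df = records.copy()
        df.columns = [c.lower() for c in df.columns]
        for col in ("animal", "sire", "dam"):
            if col not in df.columns:
                raise ValueError(f"pedigree missing column '{col}'")
            df[col] = df[col].astype(str)
        df[["sire", "dam"]] = df[["sire", "dam"]].replace({"nan": UNKNOWN, "": UNKNOWN})
        if df["animal"].duplicated().any():
            dupes = df.loc[df["animal"].duplicated(), "animal"].tolist()
            raise ValueError(f"duplicate pedigree entries: {dupes}")
        self.df = self._toposort(df)
        self.animals: list[str] = list(self.df["animal"])
        self._index = {a: i for i, a in enumerate(self.animals)}
        # parent codes: -1 for unknown
        self.sire_idx = np.array(
            [self._index.get(s, -1) if s != UNKNOWN else -1 for s in self.df["sire"]]
        )
        self.dam_idx = np.array(
            [self._index.get(d, -1) if d != UNKNOWN else -1 for d in self.df["dam"]]
        )

    @staticmethod
    def _toposort(df: pd.DataFrame) -> pd.DataFrame:
        parents = {
            r.animal: {p for p in (r.sire, r.dam) if p != UNKNOWN}
            for r in df.itertuples()
        }
        order: list[str] = []
        state: dict[str, int] = {}  # 0 = visiting, 1 = done

        for root in parents:
            if root in state:
                continue
            stack = [(root, iter(parents.get(root, ())))]
            state[root] = 0
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if p not in parents:
                        continue  # parent outside the table: treated as base
                    if state.get(p) == 0:
                        cycle = [p] + [n for n, _ in reversed(stack)]
                        raise PedigreeCycleError(
                            "pedigree cycle: " + " -> ".join(cycle)
                        )
                    if p not in state:
                        state[p] = 0
                        stack.append((p, iter(parents[p])))
                        advanced = True
                        break
                if not advanced:
                    stack.pop()
                    state[node] = 1
                    order.append(node)
        pos = {a: i for i, a in enumerate(order)}
        return df.iloc[np.argsort([pos[a] for a in df["animal"]])].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.animals)

    def index_of(self, animal: str) -> int:
        return self._index[str(animal)]


def pedigree_inbreeding_and_ainv(
    ped: PedigreeTable,
) -> tuple[pd.Series, sparse.csr_matrix]:
    """Inbreeding coefficients F and the sparse inverse of A.

    F comes from the Meuwissen–Luo tabular recursion; A⁻¹ is assembled with
    Henderson's rules using Mendelian-sampling variances adjusted for parental
    inbreeding (d_i = 0.5 − 0.25(F_s + F_d) with both parents known, etc.).
    """
    n = len(ped)
    s, d = ped.sire_idx, ped.dam_idx
    F = _meuwissen_luo_f(s, d)

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i: int, j: int, v: float) -> None:
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        si, di = s[i], d[i]
        fs = F[si] if si >= 0 else 0.0
        fd = F[di] if di >= 0 else 0.0
        if si >= 0 and di >= 0:
            dm = 0.5 - 0.25 * (fs + fd)
        elif si >= 0 or di >= 0:
            known_f = fs if si >= 0 else fd
            dm = 0.75 - 0.25 * known_f
        else:
            dm = 1.0
        a = 1.0 / dm
        add(i, i, a)
        for p in (si, di):
            if p >= 0:
                add(i, p, -a / 2.0)
                add(p, i, -a / 2.0)
        for p in (si, di):
            if p >= 0:
                add(p, p, a / 4.0)
        if si >= 0 and di >= 0:
            add(si, di, a / 4.0)
            add(di, si, a / 4.0)

    ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return pd.Series(F, index=ped.animals, name="F"), ainv


def _meuwissen_luo_f(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Inbreeding by the Meuwissen & Luo (1992) L-and-D decomposition."""
    n = len(sire)
    F = np.zeros(n)
    # Mendelian-sampling diagonal D computed on the fly
    for i in range(n):
        si, di = sire[i], dam[i]
        if si < 0 and di < 0:
            F[i] = 0.0
            continue
        # trace ancestors of i, accumulating L coefficients
        L = {i: 1.0}
        AII = 0.0
        # process animals in descending id order (parents have lower ids)
        pending = [i]
        processed: set[int] = set()
        while pending:
            j = max(pending)
            pending.remove(j)
            if j in processed:
                continue
            processed.add(j)
            lj = L[j]
            sj, dj = sire[j], dam[j]
            fsj = F[sj] if sj >= 0 else 0.0
            fdj = F[dj] if dj >= 0 else 0.0
            if sj >= 0 and dj >= 0:
                dj_var = 0.5 - 0.25 * (fsj + fdj)
            elif sj >= 0 or dj >= 0:
                dj_var = 0.75 - 0.25 * (fsj if sj >= 0 else fdj)
            else:
                dj_var = 1.0
            if j == i:
                # a_ii = sum_j L_ij^2 d_j over ancestors; handled uniformly below
                pass
            AII += lj * lj * dj_var
            for p in (sj, dj):
                if p >= 0:
                    L[p] = L.get(p, 0.0) + 0.5 * lj
                    if p not in processed:
                        pending.append(p)
        # a_ii = 1 + F_i, but the recursion above computes a_ii directly only
        # when i's own contribution uses d_i with F-parents; F_i = a_sd/2:
        F[i] = AII - 1.0 if si >= 0 and di >= 0 else 0.0
    return F


def relationship_matrix(ped: PedigreeTable) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular method."""
    n = len(ped)
    s, d = ped.sire_idx, ped.dam_idx
    A = np.zeros((n, n))
    for i in range(n):
        si, di = s[i], d[i]
        a_sd = A[si, di] if (si >= 0 and di >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
        for j in range(i):
            aij = 0.0
            if si >= 0:
                aij += 0.5 * A[j, si]
            if di >= 0:
                aij += 0.5 * A[j, di]
            A[i, j] = A[j, i] = aij
    return A


# ---------------------------------------------------------------------------
# Model specification and variance components
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Animal-model structure for one trait.

    ``fixed`` lists the record columns treated as categorical fixed effects
    (an intercept/overall mean is always included).  ``maternal`` adds an
    additive maternal genetic term, ``permanent_env`` a permanent (maternal)
    environment term; ``direct_maternal_cov`` fits the covariance between
    direct and maternal genetic effects.
    """

    trait: str
    fixed: tuple[str, ...] = ()
    maternal: bool = False
    permanent_env: bool = False
    direct_maternal_cov: bool = False

    def __post_init__(self) -> None:
        if self.direct_maternal_cov and not self.maternal:
            raise ValueError("direct_maternal_cov requires the maternal term")


@dataclass
class VarianceComponents:
    """(Co)variance components of the animal model and derived ratios."""

    sigma2_a: float
    sigma2_e: float
    sigma2_m: float = 0.0
    sigma_am: float = 0.0
    sigma2_p: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sigma2_a", "sigma2_e", "sigma2_m", "sigma2_p"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sigma2_m > 0:
            r = self.sigma_am / np.sqrt(self.sigma2_a * self.sigma2_m)
            if abs(r) > 1 + 1e-12:
                raise ValueError("|r_AM| must be <= 1")
        elif self.sigma_am != 0:
            raise ValueError("sigma_am requires sigma2_m > 0")

    @property
    def sigma2_phenotypic(self) -> float:
        return (
            self.sigma2_a + self.sigma2_m + self.sigma_am
            + self.sigma2_p + self.sigma2_e
        )

    @property
    def h2(self) -> float:
        return self.sigma2_a / self.sigma2_phenotypic

    @property
    def m2(self) -> float:
        return self.sigma2_m / self.sigma2_phenotypic

    @property
    def c2(self) -> float:
        return self.sigma2_p / self.sigma2_phenotypic

    @property
    def r_am(self) -> float:
        if self.sigma2_m == 0:
            return 0.0
        return self.sigma_am / np.sqrt(self.sigma2_a * self.sigma2_m)


@dataclass
class MMEResult:
    """BLUP solutions with prediction-error variances and reliabilities."""

    fixed_effects: pd.Series
    ebv: pd.Series          # direct genetic solutions, all pedigree animals
    pev: pd.Series
    reliability: pd.Series
    maternal: pd.Series | None = None
    permanent_env: pd.Series | None = None


def _fixed_design(records: pd.DataFrame, model: ModelSpec) -> tuple[np.ndarray, list[str]]:
    n = len(records)
    blocks = [np.ones((n, 1))]
    names = ["intercept"]
    for col in model.fixed:
        if col not in records.columns:
            raise ValueError(f"fixed effect column '{col}' not in records")
        dummies = pd.get_dummies(records[col].astype(str), prefix=col, drop_first=True)
        blocks.append(dummies.to_numpy(dtype=float))
        names.extend(dummies.columns)
    X = np.hstack(blocks)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"fixed-effects design rank-deficient (columns: {names}); "
            "confounded factor levels"
        )
    return X, names


def solve_mme(
    model: ModelSpec,
    records: pd.DataFrame,
    ped: PedigreeTable,
    vc: VarianceComponents,
) -> MMEResult:
    """Solve Henderson's mixed-model equations for one trait.

    ``records`` needs columns 'animal', the trait value column named by
    ``model.trait``, any fixed-effect columns, and 'dam' when maternal or
    permanent-environment terms are in the model.  Reliability is
    r²_i = 1 − PEV_i/σ²_a.
    """
    records = records.reset_index(drop=True)
    missing = set(records["animal"].astype(str)) - set(ped.animals)
    if missing:
        raise ValueError(f"records reference animals not in pedigree: {sorted(missing)}")
    y = records[model.trait].to_numpy(dtype=float)
    n = len(y)
    q = len(ped)

    X, fixed_names = _fixed_design(records, model)
    p_fix = X.shape[1]

    rec_animal = [ped.index_of(a) for a in records["animal"].astype(str)]
    Za = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), rec_animal)), shape=(n, q)
    )
    design_blocks = [Za]

    if model.maternal or model.permanent_env:
        if "dam" not in records.columns:
            raise ValueError("maternal/permanent-environment model needs a 'dam' column")
        rec_dam = [ped.index_of(a) for a in records["dam"].astype(str)]

    if model.maternal:
        Zm = sparse.csr_matrix(
            (np.ones(n), (np.arange(n), rec_dam)), shape=(n, q)
        )
        design_blocks.append(Zm)
    if model.permanent_env:
        Zp = sparse.csr_matrix(
            (np.ones(n), (np.arange(n), rec_dam)), shape=(n, q)
        )
        design_blocks.append(Zp)

    Z = sparse.hstack(design_blocks, format="csr")
    _, ainv = pedigree_inbreeding_and_ainv(ped)

    # random-effect penalty (times sigma2_e)
    if model.maternal:
        G0 = np.array([[vc.sigma2_a, vc.sigma_am], [vc.sigma_am, vc.sigma2_m]])
        if not model.direct_maternal_cov:
            G0 = np.diag(np.diag(G0))
        eigvals = np.linalg.eigvalsh(G0)
        if eigvals.min() < -1e-10:
            raise ValueError("genetic covariance block not positive semidefinite")
        G0inv = np.linalg.inv(G0)
        penalty = sparse.kron(sparse.csr_matrix(G0inv), ainv) * vc.sigma2_e
    else:
        penalty = ainv * (vc.sigma2_e / vc.sigma2_a)
    if model.permanent_env:
        pen_p = sparse.identity(q) * (vc.sigma2_e / vc.sigma2_p)
        penalty = sparse.block_diag([penalty, pen_p])

    Xs = sparse.csr_matrix(X)
    top = sparse.hstack([Xs.T @ Xs, Xs.T @ Z])
    bottom = sparse.hstack([Z.T @ Xs, Z.T @ Z + penalty])
    C = sparse.vstack([top, bottom]).tocsc()
    rhs = np.concatenate([X.T @ y, Z.T @ y])

    Cdense = C.toarray()
    try:
        Cinv = np.linalg.inv(Cdense)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(f"MME coefficient matrix singular: {err}") from err
    sol = Cinv @ rhs

    b = sol[:p_fix]
    a = sol[p_fix : p_fix + q]
    pev = np.diag(Cinv)[p_fix : p_fix + q] * vc.sigma2_e
    rel = 1.0 - pev / vc.sigma2_a

    out = MMEResult(
        fixed_effects=pd.Series(b, index=fixed_names),
        ebv=pd.Series(a, index=ped.animals, name="ebv"),
        pev=pd.Series(pev, index=ped.animals, name="pev"),
        reliability=pd.Series(np.clip(rel, 0.0, 1.0), index=ped.animals, name="reliability"),
    )
    offset = p_fix + q
    if model.maternal:
        out.maternal = pd.Series(sol[offset : offset + q], index=ped.animals, name="maternal")
        offset += q
    if model.permanent_env:
        out.permanent_env = pd.Series(
            sol[offset : offset + q], index=ped.animals, name="pe"
        )
    return out


# ---------------------------------------------------------------------------
# EM-REML for the direct-effects model
# ---------------------------------------------------------------------------

@dataclass
class RemlResult:
    vc: VarianceComponents
    h2: float
    converged: bool
    n_iter: int
    loglik: float
    loglik_path: list[float] = field(default_factory=list)


def em_reml_direct(
    records: pd.DataFrame,
    ped: PedigreeTable,
    init: VarianceComponents,
    model: ModelSpec | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    track_loglik: bool = False,
) -> RemlResult:
    """EM-REML estimation of (σ²_a, σ²_e) for the direct-effects animal model.

    Iterates EM updates from the mixed-model equations until the relative
    change in both components drops below ``tol`` or ``max_iter`` is reached
    (non-convergence returns the last iterate flagged).  The REML
    log-likelihood is tracked; EM guarantees it is non-decreasing.
    """
    if model is None:
        model = ModelSpec(trait="y")
    if model.maternal or model.permanent_env:
        raise ValueError("em_reml_direct supports the direct-effects model only")
    records = records.reset_index(drop=True)
    y = records[model.trait].to_numpy(dtype=float)
    n = len(y)
    q = len(ped)
    X, _ = _fixed_design(records, model)
    p_fix = X.shape[1]
    rec_animal = [ped.index_of(a) for a in records["animal"].astype(str)]
    Z = np.zeros((n, q))
    Z[np.arange(n), rec_animal] = 1.0
    _, ainv_sp = pedigree_inbreeding_and_ainv(ped)
    Ainv = ainv_sp.toarray()
    A = relationship_matrix(ped) if track_loglik else None

    # Absorb fixed effects (S = I - X(X'X)^-1 X') and diagonalize the animal
    # equations once: with A^-1 = LL' and L^-1 (Z'SZ) L'^-1 = Q diag(lam) Q',
    # the absorbed coefficient block is (Z'SZ + k A^-1)^-1
    # = L'^-1 Q diag(1/(lam+k)) Q' L^-1, so each EM step is O(q^2).
    Qx, _ = np.linalg.qr(X)
    Sy = y - Qx @ (Qx.T @ y)
    SZ = Z - Qx @ (Qx.T @ Z)
    ZtSZ = Z.T @ SZ
    L = np.linalg.cholesky(Ainv)
    from scipy.linalg import solve_triangular

    Linv = solve_triangular(L, np.eye(q), lower=True)
    lam, Qe = np.linalg.eigh(Linv @ ZtSZ @ Linv.T)
    lam = np.maximum(lam, 0.0)
    P = Qe.T @ Linv                       # maps animal space -> eigenbasis
    v = P @ (Z.T @ Sy)
    Pa = P @ Ainv
    gdiag = np.einsum("ij,ij->i", Pa, P)  # diag of P A^-1 P'
    LtQ = Linv.T @ Qe

    s2a, s2e = float(init.sigma2_a), float(init.sigma2_e)
    logliks: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        k = s2e / s2a
        d = 1.0 / (lam + k)
        a = LtQ @ (d * v)
        tr_acaa = s2e * float(gdiag @ d)
        s2a_new = float((a @ (Ainv @ a) + tr_acaa) / q)
        r = y - Z @ a
        e = r - Qx @ (Qx.T @ r)           # S(y - Za) = y - Xb - Za
        s2e_new = float((y @ e) / (n - p_fix))
        if track_loglik:
            logliks.append(_reml_loglik(y, X, Z, A, s2a, s2e))
        rel = max(
            abs(s2a_new - s2a) / max(s2a, 1e-30),
            abs(s2e_new - s2e) / max(s2e, 1e-30),
        )
        s2a, s2e = max(s2a_new, 1e-12), max(s2e_new, 1e-12)
        if rel < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"EM-REML did not converge in {max_iter} iterations", stacklevel=2
        )
    vc = VarianceComponents(sigma2_a=s2a, sigma2_e=s2e)
    return RemlResult(
        vc=vc,
        h2=vc.h2,
        converged=converged,
        n_iter=it,
        loglik=logliks[-1] if logliks else np.nan,
        loglik_path=logliks,
    )


def _reml_loglik(
    y: np.ndarray, X: np.ndarray, Z: np.ndarray, A: np.ndarray,
    s2a: float, s2e: float,
) -> float:
    """Restricted log-likelihood of the direct-effects model (dense V)."""
    n, p = X.shape
    V = Z @ A @ Z.T * s2a + np.eye(n) * s2e
    sign, logdet_v = np.linalg.slogdet(V)
    Vinv = np.linalg.inv(V)
    XtVinvX = X.T @ Vinv @ X
    sign2, logdet_x = np.linalg.slogdet(XtVinvX)
    P = Vinv - Vinv @ X @ np.linalg.inv(XtVinvX) @ X.T @ Vinv
    return float(-0.5 * (logdet_v + logdet_x + y @ P @ y))


# ---------------------------------------------------------------------------
# Deregression
# ---------------------------------------------------------------------------

def deregress_ebv(
    records: pd.DataFrame,
    c: float = 0.10,
    h2: float | None = None,
    reliability_floor: float = 0.05,
) -> pd.DataFrame:
    """Simplified Garrick deregression of EBVs (no parent-average removal).

    ``records`` needs columns 'animal', 'ebv', 'reliability'.  Per animal:
    DEBV = EBV / r² and association weight w = (1 − c) / [c + (1 − r²)/r²],
    where c is the fraction of genetic variance not captured by markers.
    Animals with reliability below ``reliability_floor`` (or exactly zero)
    are excluded with a warning.  ``h2`` is accepted for interface parity
    with the full procedure; the simplified weight does not use it.
    """
    del h2
    df = records.copy()
    for col in ("animal", "ebv", "reliability"):
        if col not in df.columns:
            raise ValueError(f"EBV table missing column '{col}'")
    r2 = df["reliability"].to_numpy(dtype=float)
    if (r2 > 1).any() or (r2 < 0).any():
        raise ValueError("reliability must be in [0, 1]")
    keep = r2 >= max(reliability_floor, np.finfo(float).tiny)
    if (~keep).any():
        warnings.warn(
            f"{(~keep).sum()} animals excluded from deregression "
            f"(reliability < {reliability_floor})",
            stacklevel=2,
        )
    df = df.loc[keep].copy()
    r2 = df["reliability"].to_numpy(dtype=float)
    df["debv"] = df["ebv"].to_numpy(dtype=float) / r2
    df["weight"] = (1.0 - c) / (c + (1.0 - r2) / r2)
    return df.reset_index(drop=True)
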