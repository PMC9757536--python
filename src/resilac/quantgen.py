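"""Pedigree-based mixed-model machinery.

Implements the animal model ``y = Xb + Za + e`` with ``a ~ N(0, A*sigma_a2)``
where A is the additive (numerator) relationship matrix implied by the
pedigree, plus the repeatability extension (a permanent-environment effect
``pe ~ N(0, I*sigma_pe2)`` for repeated records) and the bivariate
extension (2x2 genetic and residual covariance matrices with Kronecker
structure ``A (x) G0`` and ``I (x) R0``).

Variance components are estimated by restricted maximum likelihood using
the average-information (AI) algorithm: the REML log-likelihood is
maximised by Newton-type steps whose curvature matrix is the average of
the observed and expected information, with expectation-maximisation (EM)
fallback steps when an AI step leaves the parameter space, and step
halving whenever a proposed step would decrease the restricted
log-likelihood.  Standard errors come from the inverse AI matrix at the
optimum (delta method for heritability and genetic correlations).

Breeding values are obtained from Henderson's mixed-model equations built
with the sparse A-inverse (assembled directly from pedigree rules with
inbreeding from the Meuwissen-Luo recursion); EBV reliability is
``1 - PEV/sigma_a2`` with the prediction-error variance taken from the
inverse coefficient matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import sparse
from scipy.sparse.linalg import splu

# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

_UNKNOWN = {None, "", "0", 0, "nan", "NA", "."}


class PedigreeError(ValueError):
    pass


class Pedigree:
    """A validated, topologically ordered pedigree.

    Unknown parents are encoded as "0"/empty/NaN.  On construction the
    pedigree is checked for cycles (an animal that is its own ancestor) and
    re-ordered so parents precede offspring.
    """

    def __init__(self, animals, sires, dams, birth_dates=None, sexes=None):
        animals = [str(a) for a in animals]
        if len(set(animals)) != len(animals):
            raise PedigreeError("duplicate animal ids")
        sires = [self._norm(s) for s in sires]
        dams = [self._norm(d) for d in dams]
        order = self._toposort(animals, sires, dams)
        self.animals = [animals[i] for i in order]
        self.index = {a: i for i, a in enumerate(self.animals)}
        self.sire = np.array(
            [self.index.get(sires[i], -1) if sires[i] else -1 for i in order], dtype=int
        )
        self.dam = np.array(
            [self.index.get(dams[i], -1) if dams[i] else -1 for i in order], dtype=int
        )
        for j, i in enumerate(order):
            for par, name in ((sires[i], "sire"), (dams[i], "dam")):
                if par and par not in self.index:
                    raise PedigreeError(f"{name} {par!r} of {animals[i]!r} not in pedigree")
        self.birth_dates = None
        if birth_dates is not None:
            bd = list(birth_dates)
            self.birth_dates = pd.Series(
                [bd[i] for i in order], index=self.animals, name="birth_date"
            )
        self.sexes = None
        if sexes is not None:
            sx = list(sexes)
            self.sexes = pd.Series([sx[i] for i in order], index=self.animals, name="sex")
        self._F: np.ndarray | None = None
        self._D: np.ndarray | None = None

    @staticmethod
    def _norm(p):
        if p is None or (isinstance(p, float) and np.isnan(p)):
            return ""
        p = str(p).strip()
        return "" if p in {"", "0", "nan", "NA", "."} else p

    @staticmethod
    def _toposort(animals, sires, dams) -> list[int]:
        idx = {a: i for i, a in enumerate(animals)}
        state = {}  # 0 visiting, 1 done
        order: list[int] = []

        def visit(i, stack):
            if state.get(i) == 1:
                return
            if state.get(i) == 0:
                cycle = stack[stack.index(i):] + [i]
                names = " -> ".join(animals[j] for j in cycle)
                raise PedigreeError(f"pedigree cycle: {names}")
            state[i] = 0
            stack.append(i)
            for p in (sires[i], dams[i]):
                if p and p in idx:
                    visit(idx[p], stack)
            stack.pop()
            state[i] = 1
            order.append(i)

        for i in range(len(animals)):
            visit(i, [])
        return order

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        return cls(
            df["animal"],
            df["sire"],
            df["dam"],
            birth_dates=df["birth_date"] if "birth_date" in df else None,
            sexes=df["sex"] if "sex" in df else None,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "animal": self.animals,
                "sire": [self.animals[s] if s >= 0 else "0" for s in self.sire],
                "dam": [self.animals[d] if d >= 0 else "0" for d in self.dam],
            }
        )
        if self.birth_dates is not None:
            df["birth_date"] = self.birth_dates.to_numpy()
        if self.sexes is not None:
            df["sex"] = self.sexes.to_numpy()
        return df

    @property
    def n(self) -> int:
        return len(self.animals)

    def known_parents(self) -> dict[str, bool]:
        return {
            a: (self.sire[i] >= 0 and self.dam[i] >= 0)
            for i, a in enumerate(self.animals)
        }

    # -- inbreeding and relationship structure ------------------------------

    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients by the Meuwissen-Luo recursion.

        For each animal the diagonal A_ii = sum_j L_ij^2 * D_j is
        accumulated by tracing back through the ancestors in decreasing
        pedigree order; F_i = A_ii - 1.
        """
        if self._F is not None:
            return self._F
        n = self.n
        F = np.zeros(n)
        D = np.zeros(n)
        for i in range(n):
            s, d = self.sire[i], self.dam[i]
            if s >= 0 and d >= 0:
                D[i] = 0.5 - 0.25 * (F[s] + F[d])
            elif s >= 0 or d >= 0:
                D[i] = 0.75 - 0.25 * F[max(s, d)]
            else:
                D[i] = 1.0
            if s < 0 or d < 0:
                F[i] = 0.0
                continue
            weights = self._ancestor_weights(i)
            a_ii = sum(w ** 2 * D[j] for j, w in weights.items())
            F[i] = a_ii - 1.0
        self._F, self._D = F, D
        return F

    def _ancestor_weights(self, i: int) -> dict[int, float]:
        """L_ij weights of animal i on all its ancestors j (including itself)."""
        L: dict[int, float] = {i: 1.0}
        pending = [i]
        seen = {i}
        while pending:
            j = max(pending)
            pending.remove(j)
            w = L[j]
            for p in (self.sire[j], self.dam[j]):
                if p >= 0:
                    L[p] = L.get(p, 0.0) + 0.5 * w
                    if p not in seen:
                        seen.add(p)
                        pending.append(p)
        return L

    def mendelian_variances(self) -> np.ndarray:
        """Within-family (Mendelian sampling) variance scalars D_i."""
        if self._D is None:
            self.inbreeding()
        return self._D

    def a_inverse(self) -> sparse.csr_matrix:
        """Sparse A-inverse by Henderson's rules with inbreeding."""
        D = self.mendelian_variances()
        rows, cols, vals = [], [], []

        def add(r, c, v):
            rows.append(r)
            cols.append(c)
            vals.append(v)

        for i in range(self.n):
            alpha = 1.0 / D[i]
            s, d = self.sire[i], self.dam[i]
            add(i, i, alpha)
            for p in (s, d):
                if p >= 0:
                    add(i, p, -alpha / 2)
                    add(p, i, -alpha / 2)
                    add(p, p, alpha / 4)
            if s >= 0 and d >= 0:
                add(s, d, alpha / 4)
                add(d, s, alpha / 4)
        return sparse.csr_matrix(
            sparse.coo_matrix((vals, (rows, cols)), shape=(self.n, self.n))
        )

    def logdet_a(self) -> float:
        """log|A| = sum log D_i (from the A = T D T' factorisation)."""
        return float(np.sum(np.log(self.mendelian_variances())))

    def relationship_matrix(self) -> np.ndarray:
        """Dense A by the tabular method; intended for small pedigrees."""
        n = self.n
        A = np.zeros((n, n))
        for i in range(n):
            s, d = self.sire[i], self.dam[i]
            if i > 0:
                row = np.zeros(i)
                if s >= 0:
                    row += 0.5 * A[s, :i]
                if d >= 0:
                    row += 0.5 * A[d, :i]
                A[i, :i] = row
                A[:i, i] = row
            A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
        return A

    def relationship_submatrix(self, ids: list[str]) -> np.ndarray:
        """A restricted to ``ids``, via sparse solves with A-inverse."""
        pos = np.array([self.index[str(a)] for a in ids], dtype=int)
        lu = splu(sparse.csc_matrix(self.a_inverse()))
        rhs = np.zeros((self.n, pos.size))
        rhs[pos, np.arange(pos.size)] = 1.0
        cols = lu.solve(rhs)
        sub = cols[pos, :]
        return 0.5 * (sub + sub.T)


# ---------------------------------------------------------------------------
# fixed-effect design
# ---------------------------------------------------------------------------

DEFAULT_FIXED_FACTORS = ("hys", "parity_class", "cluster", "curve_model", "afc_class")


def hys_factor(df: pd.DataFrame, herd_col="herd", date_col="calving_date") -> pd.Series:
    """Herd-calving year-calving season contemporary group (season = quarter)."""
    dates = pd.to_datetime(df[date_col])
    return (
        df[herd_col].astype(str)
        + "-"
        + dates.dt.year.astype(str)
        + "-Q"
        + dates.dt.quarter.astype(str)
    )


def afc_class(afc_days) -> pd.Series:
    """Age-at-first-calving class: <=22, 23-24, 25-26, >=27 months."""
    months = pd.Series(np.asarray(afc_days, dtype=float) / 30.4375)
    return pd.cut(
        months,
        bins=[-np.inf, 22.5, 24.5, 26.5, np.inf],
        labels=["le22", "23-24", "25-26", "ge27"],
    ).astype(str)


def parity_class(parity) -> pd.Series:
    """Parity grouped as 1, 2, 3, 4 and 5+."""
    p = pd.Series(np.asarray(parity, dtype=int))
    return p.clip(upper=5).map(lambda v: "5+" if v >= 5 else str(v))


def add_model_factors(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Attach the standard fixed-effect factor columns to a phenotype table."""
    df = phenotypes.copy()
    df["hys"] = hys_factor(df)
    df["parity_class"] = parity_class(df["parity"]).to_numpy()
    if "afc_days" in df:
        df["afc_class"] = afc_class(df["afc_days"]).to_numpy()
    return df


def build_design(df: pd.DataFrame, factors: list[str]) -> tuple[np.ndarray, list[str]]:
    """Full-rank fixed-effect design: intercept + drop-first dummies.

    Confounded levels across factors are removed by a pivoted-QR rank
    check, which realises "one constraint per confounded fixed block".
    """
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for fac in factors:
        levels = pd.Categorical(df[fac].astype(str))
        for lev in levels.categories[1:]:
            cols.append((levels == lev).astype(float))
            names.append(f"{fac}[{lev}]")
    X = np.column_stack(cols)
    _, R, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    keep = np.sort(piv[:rank])
    return X[:, keep], [names[i] for i in keep]


# ---------------------------------------------------------------------------
# REML engine (linear covariance structure, dense)
# ---------------------------------------------------------------------------

@dataclass
class REMLFit:
    theta: np.ndarray
    loglik: float
    cov_theta: np.ndarray  # inverse AI matrix at the optimum
    converged: bool
    n_iterations: int
    history: list[float] = field(default_factory=list, repr=False)


class _Eval:
    __slots__ = ("ll", "P", "Py")

    def __init__(self, ll, P, Py):
        self.ll, self.P, self.Py = ll, P, Py


def _evaluate(y, X, V):
    """Restricted log-likelihood and projection quantities for a given V."""
    try:
        c, low = sla.cho_factor(V, lower=True, check_finite=False)
    except sla.LinAlgError:
        return None
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    Vinv = sla.cho_solve((c, low), np.eye(V.shape[0]), check_finite=False)
    VinvX = Vinv @ X
    M = X.T @ VinvX
    try:
        cm, lowm = sla.cho_factor(M, lower=True, check_finite=False)
    except sla.LinAlgError:
        return None
    logdet_m = 2.0 * np.sum(np.log(np.diag(cm)))
    P = Vinv - VinvX @ sla.cho_solve((cm, lowm), VinvX.T, check_finite=False)
    Py = P @ y
    ll = -0.5 * (logdet_v + logdet_m + float(y @ Py))
    return _Eval(ll, P, Py)


def fit_linear_covariance(
    y: np.ndarray,
    X: np.ndarray,
    structures: list[np.ndarray],
    init: np.ndarray,
    em_ranks: list[float] | None = None,
    psd_blocks: list[list[int]] | None = None,
    max_iter: int = 200,
    rtol: float = 1e-8,
    ll_tol: float = 1e-9,
) -> REMLFit:
    """AI-REML for ``V(theta) = sum_k theta_k * S_k``.

    ``em_ranks`` gives, for pure variance parameters, the number of random
    levels q_k behind structure S_k, enabling the EM fallback update
    ``theta_k += theta_k^2 * (y'P S_k P y - tr(P S_k)) / q_k`` when an AI
    step proposes an out-of-bounds value.  ``psd_blocks`` lists parameter
    index triples (var1, cov, var2) of 2x2 covariance blocks that are bent
    back to positive semidefinite after each step.  Step halving guarantees
    the restricted log-likelihood is non-decreasing across accepted
    iterations.
    """
    y = np.asarray(y, dtype=float)
    theta = np.asarray(init, dtype=float).copy()
    n_par = theta.size
    floor = 1e-8 * float(np.var(y))
    var_idx = [k for k in range(n_par) if em_ranks is None or em_ranks[k] is not None]
    if psd_blocks:
        cov_idx = {blk[1] for blk in psd_blocks}
        var_idx = [k for k in range(n_par) if k not in cov_idx]

    def project(t):
        t = t.copy()
        for k in var_idx:
            t[k] = max(t[k], floor)
        if psd_blocks:
            for i, j, k in psd_blocks:
                block = np.array([[t[i], t[j]], [t[j], t[k]]])
                w, Q = np.linalg.eigh(block)
                if w.min() < floor:
                    w = np.clip(w, floor, None)
                    bent = Q @ np.diag(w) @ Q.T
                    t[i], t[j], t[k] = bent[0, 0], bent[0, 1], bent[1, 1]
        return t

    theta = project(theta)
    state = _evaluate(y, X, _build_v(structures, theta))
    if state is None:
        raise ValueError("initial variance components give a non-PD V")

    history = [state.ll]
    converged = False
    ai = np.eye(n_par)
    it = 0
    for it in range(1, max_iter + 1):
        f = np.column_stack([S @ state.Py for S in structures])
        quad = state.Py @ f  # y'P S_k P y per parameter
        tr = np.array([float(np.sum(state.P * S)) for S in structures])
        grad = -0.5 * (tr - quad)
        Pf = state.P @ f
        ai = 0.5 * (f.T @ Pf)
        try:
            delta = np.linalg.solve(ai, grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(ai, grad, rcond=None)[0]

        raw = theta + delta
        out_of_bounds = any(raw[k] <= 0 for k in var_idx)
        if out_of_bounds and em_ranks is not None and all(
            em_ranks[k] is not None for k in range(n_par)
        ):
            # EM fallback: guaranteed in-bounds, monotone in expectation
            new_theta = theta + theta ** 2 * (quad - tr) / np.asarray(em_ranks, dtype=float)
            new_theta = project(new_theta)
            new_state = _evaluate(y, X, _build_v(structures, new_theta))
            if new_state is None:
                break
        else:
            step = 1.0
            new_theta, new_state = None, None
            while step >= 2 ** -30:
                cand = project(theta + step * delta)
                cand_state = _evaluate(y, X, _build_v(structures, cand))
                if cand_state is not None and cand_state.ll >= state.ll - 1e-10:
                    new_theta, new_state = cand, cand_state
                    break
                step *= 0.5
            if new_state is None:
                converged = True  # cannot improve: treat current point as optimum
                break

        dtheta = np.max(np.abs(new_theta - theta) / (np.abs(theta) + 1e-12))
        dll = abs(new_state.ll - state.ll)
        theta, state = new_theta, new_state
        history.append(state.ll)
        if dtheta < rtol or dll < ll_tol:
            converged = True
            break

    try:
        cov_theta = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        cov_theta = np.linalg.pinv(ai)
    return REMLFit(theta, state.ll, cov_theta, converged, it, history)


def _build_v(structures, theta):
    V = theta[0] * structures[0]
    for t, S in zip(theta[1:], structures[1:]):
        V = V + t * S
    return V


# ---------------------------------------------------------------------------
# model wrappers
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    sigma_a2: float
    sigma_e2: float
    h2: float
    se_h2: float
    loglik: float
    converged: bool
    n_iterations: int
    sigma_pe2: float | None = None
    repeatability: float | None = None
    cov_theta: np.ndarray | None = field(default=None, repr=False)

    @property
    def phenotypic_variance(self) -> float:
        return self.sigma_a2 + (self.sigma_pe2 or 0.0) + self.sigma_e2


@dataclass
class BivariateResult:
    G: np.ndarray  # 2x2 additive (co)variance
    R: np.ndarray  # 2x2 residual (co)variance
    r_g: float
    se_r_g: float
    r_p: float
    loglik: float
    converged: bool
    n_iterations: int
    cov_theta: np.ndarray = field(default=None, repr=False)


def _incidence(ids: pd.Series, levels: list[str]) -> np.ndarray:
    lookup = {a: i for i, a in enumerate(levels)}
    Z = np.zeros((len(ids), len(levels)))
    Z[np.arange(len(ids)), [lookup[str(a)] for a in ids]] = 1.0
    return Z


def _prepare(phenotypes, trait, pedigree, fixed_factors, animal_col):
    df = phenotypes.dropna(subset=[trait]).reset_index(drop=True)
    y = df[trait].to_numpy(dtype=float)
    X, names = build_design(df, list(fixed_factors))
    recorded = sorted(df[animal_col].astype(str).unique())
    A_rr = pedigree.relationship_submatrix(recorded)
    Z = _incidence(df[animal_col].astype(str), recorded)
    return df, y, X, Z, A_rr, recorded


def _h2_se(idx_a: int, total_idx: list[int], theta, cov) -> float:
    """Delta-method SE of h2 = theta_a / sum(theta)."""
    tot = sum(theta[i] for i in total_idx)
    grad = np.zeros(len(theta))
    for i in total_idx:
        grad[i] = -theta[idx_a] / tot ** 2
    grad[idx_a] += 1.0 / tot
    return float(np.sqrt(grad @ cov @ grad))


def reml_single(
    phenotypes: pd.DataFrame,
    trait: str,
    pedigree: Pedigree,
    fixed_factors=("hys", "parity_class"),
    animal_col: str = "cow_id",
    max_iter: int = 200,
) -> VarianceComponents:
    """Single-trait animal model variance components by AI-REML."""
    df, y, X, Z, A_rr, recorded = _prepare(phenotypes, trait, pedigree, fixed_factors, animal_col)
    if len(recorded) < 2:
        raise ValueError("need records on at least 2 animals")
    Q_a = Z @ A_rr @ Z.T
    n = y.size
    v0 = float(np.var(y, ddof=1))
    fit = fit_linear_covariance(
        y,
        X,
        [Q_a, np.eye(n)],
        init=np.array([0.5 * v0, 0.5 * v0]),
        em_ranks=[len(recorded), n],
        max_iter=max_iter,
    )
    sa, se_ = fit.theta
    h2 = sa / (sa + se_)
    return VarianceComponents(
        sigma_a2=float(sa),
        sigma_e2=float(se_),
        h2=float(h2),
        se_h2=_h2_se(0, [0, 1], fit.theta, fit.cov_theta),
        loglik=fit.loglik,
        converged=fit.converged,
        n_iterations=fit.n_iterations,
        cov_theta=fit.cov_theta,
    )


def reml_repeatability(
    phenotypes: pd.DataFrame,
    trait: str,
    pedigree: Pedigree,
    fixed_factors=("hys", "parity_class"),
    animal_col: str = "cow_id",
    max_iter: int = 200,
) -> VarianceComponents:
    """Repeatability animal model (adds a permanent-environment effect)."""
    df, y, X, Z, A_rr, recorded = _prepare(phenotypes, trait, pedigree, fixed_factors, animal_col)
    counts = df[animal_col].astype(str).value_counts()
    if (counts < 2).all():
        raise ValueError("permanent-environment variance inestimable: no repeated records")
    Q_a = Z @ A_rr @ Z.T
    Q_pe = Z @ Z.T
    n = y.size
    v0 = float(np.var(y, ddof=1))
    fit = fit_linear_covariance(
        y,
        X,
        [Q_a, Q_pe, np.eye(n)],
        init=np.array([v0 / 3, v0 / 3, v0 / 3]),
        em_ranks=[len(recorded), len(recorded), n],
        max_iter=max_iter,
    )
    sa, spe, se_ = fit.theta
    tot = sa + spe + se_
    return VarianceComponents(
        sigma_a2=float(sa),
        sigma_pe2=float(spe),
        sigma_e2=float(se_),
        h2=float(sa / tot),
        se_h2=_h2_se(0, [0, 1, 2], fit.theta, fit.cov_theta),
        repeatability=float((sa + spe) / tot),
        loglik=fit.loglik,
        converged=fit.converged,
        n_iterations=fit.n_iterations,
        cov_theta=fit.cov_theta,
    )


def reml_bivariate(
    phenotypes: pd.DataFrame,
    traits: tuple[str, str],
    pedigree: Pedigree,
    fixed_factors=("hys", "parity_class"),
    animal_col: str = "cow_id",
    unit_cols: tuple[str, ...] | None = None,
    max_iter: int = 200,
) -> BivariateResult:
    """Bivariate animal model: 2x2 G and R, genetic and phenotypic correlation.

    Residual covariance applies between the two traits' records on the same
    observational unit (``unit_cols``, default animal + parity when
    available).  Starting values come from single-trait fits with the
    genetic covariance at ``0.1*sqrt(sa1*sa2)``.
    """
    t1, t2 = traits
    if unit_cols is None:
        unit_cols = tuple(
            c for c in (animal_col, "parity") if c in phenotypes.columns
        )
    d1 = phenotypes.dropna(subset=[t1]).reset_index(drop=True)
    d2 = phenotypes.dropna(subset=[t2]).reset_index(drop=True)
    y = np.concatenate([d1[t1].to_numpy(float), d2[t2].to_numpy(float)])
    X1, _ = build_design(d1, list(fixed_factors))
    X2, _ = build_design(d2, list(fixed_factors))
    X = sla.block_diag(X1, X2)

    recorded = sorted(
        set(d1[animal_col].astype(str)) | set(d2[animal_col].astype(str))
    )
    A_rr = pedigree.relationship_submatrix(recorded)
    Z1 = _incidence(d1[animal_col].astype(str), recorded)
    Z2 = _incidence(d2[animal_col].astype(str), recorded)
    n1, n2 = len(d1), len(d2)

    def _blk(tl, tr, br):
        top = np.hstack([tl, tr])
        bot = np.hstack([tr.T, br])
        return np.vstack([top, bot])

    Z1A = Z1 @ A_rr
    S_a1 = _blk(Z1A @ Z1.T, np.zeros((n1, n2)), np.zeros((n2, n2)))
    S_a12 = _blk(np.zeros((n1, n1)), Z1A @ Z2.T, np.zeros((n2, n2)))
    S_a2 = _blk(np.zeros((n1, n1)), np.zeros((n1, n2)), Z2 @ A_rr @ Z2.T)
    # residual cross-structure: 1 where the two records share a unit
    u1 = d1[list(unit_cols)].astype(str).agg("|".join, axis=1).to_numpy()
    u2 = d2[list(unit_cols)].astype(str).agg("|".join, axis=1).to_numpy()
    E12 = (u1[:, None] == u2[None, :]).astype(float)
    S_e1 = _blk(np.eye(n1), np.zeros((n1, n2)), np.zeros((n2, n2)))
    S_e12 = _blk(np.zeros((n1, n1)), E12, np.zeros((n2, n2)))
    S_e2 = _blk(np.zeros((n1, n1)), np.zeros((n1, n2)), np.eye(n2))

    vc1 = reml_single(phenotypes, t1, pedigree, fixed_factors, animal_col, max_iter)
    vc2 = reml_single(phenotypes, t2, pedigree, fixed_factors, animal_col, max_iter)
    init = np.array(
        [
            vc1.sigma_a2,
            0.1 * np.sqrt(vc1.sigma_a2 * vc2.sigma_a2),
            vc2.sigma_a2,
            vc1.sigma_e2,
            0.1 * np.sqrt(vc1.sigma_e2 * vc2.sigma_e2),
            vc2.sigma_e2,
        ]
    )
    fit = fit_linear_covariance(
        y,
        X,
        [S_a1, S_a12, S_a2, S_e1, S_e12, S_e2],
        init=init,
        psd_blocks=[(0, 1, 2), (3, 4, 5)],
        max_iter=max_iter,
    )
    g1, g12, g2, e1, e12, e2 = fit.theta
    G = np.array([[g1, g12], [g12, g2]])
    R = np.array([[e1, e12], [e12, e2]])
    r_g = g12 / np.sqrt(g1 * g2)
    grad = np.zeros(6)
    grad[0] = -r_g / (2 * g1)
    grad[1] = 1.0 / np.sqrt(g1 * g2)
    grad[2] = -r_g / (2 * g2)
    se_rg = float(np.sqrt(max(grad @ fit.cov_theta @ grad, 0.0)))
    r_p = (g12 + e12) / np.sqrt((g1 + e1) * (g2 + e2))
    return BivariateResult(
        G=G,
        R=R,
        r_g=float(r_g),
        se_r_g=se_rg,
        r_p=float(r_p),
        loglik=fit.loglik,
        converged=fit.converged,
        n_iterations=fit.n_iterations,
        cov_theta=fit.cov_theta,
    )


# ---------------------------------------------------------------------------
# mixed-model equations and breeding values
# ---------------------------------------------------------------------------

def build_mme(
    y: np.ndarray,
    X: np.ndarray,
    Z: sparse.spmatrix,
    a_inverse: sparse.spmatrix,
    sigma_a2: float,
    sigma_e2: float,
    Z_pe: sparse.spmatrix | None = None,
    sigma_pe2: float | None = None,
):
    """Henderson's mixed-model equations (coefficient matrix and RHS).

    C = [X'X   X'Z            ...      ]        rhs = W'y
        [Z'X   Z'Z + Ainv*lam ...      ]
        [...   ...   Zpe'Zpe + I*lam_pe]
    with lam = sigma_e2/sigma_a2.  Solving C s = rhs yields BLUE fixed
    effects and BLUP random effects.
    """
    if sigma_a2 <= 0 or sigma_e2 <= 0:
        raise ValueError("variance components must be positive")
    Xs = sparse.csr_matrix(X)
    blocks = [Xs, sparse.csr_matrix(Z)]
    p = X.shape[1]
    lam = sigma_e2 / sigma_a2
    reg_blocks = [sparse.csr_matrix((p, p)), sparse.csr_matrix(a_inverse) * lam]
    if Z_pe is not None:
        if not sigma_pe2 or sigma_pe2 <= 0:
            raise ValueError("sigma_pe2 must be positive when Z_pe is given")
        blocks.append(sparse.csr_matrix(Z_pe))
        reg_blocks.append(sparse.identity(Z_pe.shape[1], format="csr") * (sigma_e2 / sigma_pe2))
    W = sparse.hstack(blocks, format="csr")
    C = (W.T @ W + sparse.block_diag(reg_blocks)).tocsc()
    rhs = W.T @ np.asarray(y, dtype=float)
    return C, rhs


def solve_ebv(
    phenotypes: pd.DataFrame,
    trait: str,
    pedigree: Pedigree,
    varcomp: VarianceComponents,
    fixed_factors=("hys", "parity_class"),
    animal_col: str = "cow_id",
    reliabilities: bool = True,
) -> pd.DataFrame:
    """BLUP breeding values for every pedigree animal.

    Reliability is ``1 - PEV/sigma_a2`` with PEV from the animal block of
    the inverse MME coefficient matrix (direct dense inverse; intended for
    cohort-scale systems).  Animals without records or recorded relatives
    get EBV 0 and reliability 0.
    """
    df = phenotypes.dropna(subset=[trait]).reset_index(drop=True)
    y = df[trait].to_numpy(dtype=float)
    X, _ = build_design(df, list(fixed_factors))
    Z = sparse.csr_matrix(_incidence_full(df[animal_col].astype(str), pedigree))
    C, rhs = build_mme(y, X, Z, pedigree.a_inverse(), varcomp.sigma_a2, varcomp.sigma_e2)
    lu = splu(C)
    sol = lu.solve(rhs)
    p = X.shape[1]
    ebv = sol[p : p + pedigree.n]
    out = pd.DataFrame({"animal": pedigree.animals, "ebv": ebv})
    if reliabilities:
        Cinv = lu.solve(np.eye(C.shape[0]))
        pev = np.diag(Cinv)[p : p + pedigree.n] * varcomp.sigma_e2
        out["reliability"] = np.clip(1.0 - pev / varcomp.sigma_a2, 0.0, 1.0)
    return out


def _incidence_full(ids: pd.Series, pedigree: Pedigree) -> np.ndarray:
    Z = np.zeros((len(ids), pedigree.n))
    Z[np.arange(len(ids)), [pedigree.index[str(a)] for a in ids]] = 1.0
    return Z
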