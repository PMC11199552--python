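"""The SMILE variance-component model: likelihood, fitting, and post-processing.

Model (full form, "GPC+S"):

    Y = X pi + u_g + Z_par u_par + Z_child u_child + Z_s u_s + eps

with Y the 0/1 disease indicator modeled on the observed scale by a linear
mixed model,

    u_g     ~ N(0, sigma_g^2 blk_diag(G_1, ..., G_{N_F}))   (kinship blocks)
    u_par   ~ N(0, sigma_par2 I),  u_child ~ N(0, sigma_child2 I)
    u_s     ~ N(0, Sigma_s)       (IND/CAR/SAR over the location graph)
    eps     ~ N(0, sigma_eps2 I)

so the marginal covariance is

    V = sigma_g2 blk_diag(G_f) + sigma_par2 Z_par Z_par'
        + sigma_child2 Z_child Z_child' + Z_s Sigma_s Z_s' + sigma_eps2 I.

Estimation is maximum likelihood with the fixed effects profiled out.  The
likelihood never forms V densely: the family part A (everything except the
spatial term) is block diagonal with blocks of size <= family size that
depend only on the family signature (#parents, #children), and the spatial
term is low rank over locations, handled by the Woodbury identity

    V^-1 = A^-1 - s2 A^-1 Z_s C^-1 Z_s' A^-1,   C = P0 + s2 D_A,
    log|V| = log|A| + log|C| - log|P0|,

where P0 is the unit-variance spatial precision, s2 = sigma_s2, and
D_A = Z_s' A^-1 Z_s is diagonal because every family lives in a single
location.  Analytic gradients use the same decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .pedigree import Cohort, family_env_blocks, kinship_from_signature
from .spatial import (
    LocationGraph,
    SpatialSpec,
    gower_factor_from_counts,
    unit_precision,
)

RHO_MAX = 0.99

#: The eight candidate models compared in the analyses.
EIGHT_MODELS = ("GPC+S", "GP+S", "GC+S", "GPC", "PC+S", "PC", "G+S", "S")


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Which variance components are included and how the spatial term is
    structured.

    ``components`` is a subset of {"G", "P", "C", "S"}.  The residual is
    always present.  An empty set is allowed (pure-residual model,
    V = sigma_eps2 I), used e.g. when collapsing the mixed model onto OLS.
    """

    components: frozenset = frozenset()
    spatial: str = "CAR"

    @classmethod
    def from_name(cls, name: str, spatial: str = "CAR") -> "ModelSpec":
        """Parse names like "GPC+S", "G+S", "PC", "S"."""
        comp = set()
        for token in name.replace("+", ""):
            if token not in "GPCS":
                raise ModelError(f"cannot parse model name {name!r}")
            comp.add(token)
        return cls(components=frozenset(comp), spatial=spatial)

    @property
    def has_spatial(self) -> bool:
        return "S" in self.components

    @property
    def name(self) -> str:
        base = "".join(c for c in "GPC" if c in self.components)
        if self.has_spatial:
            base = (base + "+S") if base else "S"
        elif not base:
            base = "E"
        if self.has_spatial and self.spatial != "IND":
            return f"{base}/{self.spatial}"
        if self.has_spatial:
            return f"{base}/IND"
        return base

    def n_variance_params(self) -> int:
        p = 1 + len(self.components)  # residual + each included component
        if self.has_spatial and self.spatial != "IND":
            p += 1  # rho
        return p


@dataclass
class VarianceComponents:
    """Variance components on the observed (0/1) or liability scale.

    ``gower_sigma_s2`` is the Gower-standardized spatial variance: the
    average per-individual variance contributed by the spatial effect,
    comparable across CAR/SAR/IND structures.
    """

    sigma_g2: float = 0.0
    sigma_par2: float = 0.0
    sigma_child2: float = 0.0
    sigma_s2: float = 0.0
    sigma_eps2: float = 1.0
    rho: float = 0.0
    scale: str = "observed"
    gower_sigma_s2: float | None = None

    def total(self) -> float:
        spatial = self.gower_sigma_s2 if self.gower_sigma_s2 is not None else self.sigma_s2
        return self.sigma_g2 + self.sigma_par2 + self.sigma_child2 + spatial + self.sigma_eps2

    @property
    def h2(self) -> float:
        """Narrow-sense heritability: genetic fraction of total variance."""
        return self.sigma_g2 / self.total()

    def as_dict(self) -> dict:
        return {
            "sigma_g2": self.sigma_g2,
            "sigma_par2": self.sigma_par2,
            "sigma_child2": self.sigma_child2,
            "sigma_s2": self.sigma_s2,
            "sigma_eps2": self.sigma_eps2,
            "rho": self.rho,
            "gower_sigma_s2": self.gower_sigma_s2,
            "scale": self.scale,
        }


# --------------------------------------------------------------------------
# cohort structure cache: signature groups and location maps


class CohortStructure:
    """Index arrays grouping families by signature for fast block algebra."""

    def __init__(self, cohort: Cohort, graph: LocationGraph | None = None):
        self.cohort = cohort
        self.graph = graph
        self.N = cohort.n_individuals
        sigs: dict[tuple[int, int], list[int]] = {}
        for i, fam in enumerate(cohort.families):
            sigs.setdefault(fam.signature, []).append(i)
        sizes = np.array([f.size for f in cohort.families])
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        self.groups = []
        for (n_p, n_c), fam_ids in sorted(sigs.items()):
            k = n_p + n_c
            idx = np.stack([np.arange(offsets[i], offsets[i] + k) for i in fam_ids])
            self.groups.append(
                {
                    "n_parents": n_p,
                    "n_children": n_c,
                    "k": k,
                    "fam_ids": np.array(fam_ids),
                    "idx": idx,
                    "G": kinship_from_signature(n_p, n_c) if k else None,
                    "P_par": family_env_blocks(n_p, n_c)[0],
                    "P_child": family_env_blocks(n_p, n_c)[1],
                }
            )
        if graph is not None:
            self.fam_loc = cohort.family_location_index(graph.locations)
            self.ind_loc = self.fam_loc[cohort.family_index]
            self.loc_counts = np.bincount(self.ind_loc, minlength=graph.L).astype(float)
        else:
            self.fam_loc = None
            self.ind_loc = None
            self.loc_counts = None


def _component_block(group: dict, which: str) -> np.ndarray:
    if which == "G":
        return group["G"]
    if which == "P":
        return group["P_par"]
    if which == "C":
        return group["P_child"]
    if which == "E":
        return np.eye(group["k"])
    raise KeyError(which)


# --------------------------------------------------------------------------
# marginal covariance with solve/logdet contracts


class MarginalCovariance:
    """Implicit N x N marginal covariance V with solve/logdet contracts."""

    def __init__(
        self,
        structure: CohortStructure,
        spec: ModelSpec,
        vc: VarianceComponents,
    ):
        self.structure = structure
        self.spec = spec
        self.vc = vc
        comp = spec.components
        var_sum = vc.sigma_eps2 + sum(
            getattr(vc, f) for f, c in
            [("sigma_g2", "G"), ("sigma_par2", "P"), ("sigma_child2", "C"), ("sigma_s2", "S")]
            if c in comp
        )
        if var_sum <= 0:
            raise ModelError("marginal covariance is not positive definite: "
                             "all included variances are zero")
        self._factor_family_part()
        if spec.has_spatial:
            if structure.graph is None:
                raise ModelError("spatial component requested but no location graph given")
            self._factor_spatial_part()

    # family-block part A
    def _factor_family_part(self) -> None:
        vc, comp = self.vc, self.spec.components
        self._Binv = []
        self._logdetA = 0.0
        fam_sums = np.zeros(self.structure.cohort.n_families)
        for g in self.structure.groups:
            B = vc.sigma_eps2 * np.eye(g["k"])
            if "G" in comp:
                B = B + vc.sigma_g2 * g["G"]
            if "P" in comp:
                B = B + vc.sigma_par2 * g["P_par"]
            if "C" in comp:
                B = B + vc.sigma_child2 * g["P_child"]
            sign, ld = np.linalg.slogdet(B)
            if sign <= 0:
                raise ModelError("family covariance block not positive definite")
            Binv = np.linalg.inv(B)
            self._Binv.append(Binv)
            self._logdetA += len(g["fam_ids"]) * ld
            fam_sums[g["fam_ids"]] = Binv.sum()
        self._fam_sums = fam_sums

    # spatial part via Woodbury capacitance
    def _factor_spatial_part(self) -> None:
        graph = self.structure.graph
        s2 = self.vc.sigma_s2
        self._P0 = unit_precision(graph, self.spec.spatial, self.vc.rho)
        P0d = self._P0.toarray()
        self._P0_chol = cho_factor(P0d, lower=True)
        self._logdetP0 = 2.0 * np.sum(np.log(np.diag(self._P0_chol[0])))
        self._D_A = np.bincount(
            self.structure.fam_loc, weights=self._fam_sums, minlength=graph.L
        )
        C = P0d + s2 * np.diag(self._D_A)
        self._C_chol = cho_factor(C, lower=True)
        self._logdetC = 2.0 * np.sum(np.log(np.diag(self._C_chol[0])))

    def solve_family(self, R: np.ndarray) -> np.ndarray:
        """A^-1 R where A is the family-block-diagonal part of V."""
        R2 = R[:, None] if R.ndim == 1 else R
        out = np.empty_like(R2, dtype=float)
        for g, Binv in zip(self.structure.groups, self._Binv):
            out[g["idx"]] = np.einsum("ij,fjm->fim", Binv, R2[g["idx"]])
        return out[:, 0] if R.ndim == 1 else out

    def solve(self, R: np.ndarray) -> np.ndarray:
        """V^-1 R for a vector or matrix of right-hand sides."""
        T = self.solve_family(R)
        if not self.spec.has_spatial:
            return T
        T2 = T[:, None] if T.ndim == 1 else T
        U = np.zeros((self.structure.graph.L, T2.shape[1]))
        np.add.at(U, self.structure.ind_loc, T2)
        Gm = self.vc.sigma_s2 * cho_solve(self._C_chol, U)
        corr = self.solve_family(Gm[self.structure.ind_loc])
        out = T2 - corr
        return out[:, 0] if R.ndim == 1 else out

    def logdet(self) -> float:
        if not self.spec.has_spatial:
            return self._logdetA
        return self._logdetA + self._logdetC - self._logdetP0

    def spatial_covariance_dense(self) -> np.ndarray:
        """Dense Sigma_s = sigma_s2 * P0^-1 at the current parameters."""
        L = self.structure.graph.L
        Sigma0 = cho_solve(self._P0_chol, np.eye(L))
        return self.vc.sigma_s2 * 0.5 * (Sigma0 + Sigma0.T)

    def dense(self) -> np.ndarray:
        """Explicit dense V; for small problems and validation only."""
        N = self.structure.N
        V = np.zeros((N, N))
        comp = self.spec.components
        vc = self.vc
        for g in self.structure.groups:
            B = vc.sigma_eps2 * np.eye(g["k"])
            if "G" in comp:
                B = B + vc.sigma_g2 * g["G"]
            if "P" in comp:
                B = B + vc.sigma_par2 * g["P_par"]
            if "C" in comp:
                B = B + vc.sigma_child2 * g["P_child"]
            for rows in g["idx"]:
                V[np.ix_(rows, rows)] = B
        if self.spec.has_spatial:
            Sigma_s = self.spatial_covariance_dense()
            V += Sigma_s[np.ix_(self.structure.ind_loc, self.structure.ind_loc)]
        return V


def marginal_covariance(
    cohort: Cohort,
    spec: ModelSpec,
    vc: VarianceComponents,
    graph: LocationGraph | None = None,
) -> MarginalCovariance:
    """Construct the implicit marginal covariance V for the given model."""
    return MarginalCovariance(CohortStructure(cohort, graph), spec, vc)


# --------------------------------------------------------------------------
# likelihood and gradient


def _check_design(X: np.ndarray) -> None:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ModelError("X must be a 2-D design matrix")
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        _, rr = np.linalg.qr(X)
        diag = np.abs(np.diag(rr))
        bad = np.where(diag < 1e-8 * diag.max())[0]
        raise ModelError(
            f"design matrix is rank deficient (rank {r} < {X.shape[1]}); "
            f"collinear columns (0-based): {bad.tolist()}"
        )


def _profile_loglik(mc: MarginalCovariance, Y: np.ndarray, X: np.ndarray):
    """Profiled Gaussian log-likelihood; returns (ll, pi_hat, w=V^-1 r, aux)."""
    N = len(Y)
    RHS = np.column_stack([X, Y])
    Vi = mc.solve(RHS)
    ViX, ViY = Vi[:, :-1], Vi[:, -1]
    XtViX = X.T @ ViX
    XtViY = X.T @ ViY
    pi_hat = np.linalg.solve(XtViX, XtViY)
    quad = float(Y @ ViY - XtViY @ pi_hat)
    ll = -0.5 * (N * np.log(2.0 * np.pi) + mc.logdet() + quad)
    w = ViY - ViX @ pi_hat
    return ll, pi_hat, w, XtViX


def log_likelihood(
    cohort: Cohort,
    Y: np.ndarray,
    X: np.ndarray,
    spec: ModelSpec,
    vc: VarianceComponents,
    graph: LocationGraph | None = None,
) -> float:
    """Gaussian log-likelihood of Y under the model, fixed effects profiled."""
    Y = np.asarray(Y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if len(Y) != cohort.n_individuals:
        raise ModelError("phenotype length does not match cohort size")
    _check_design(X)
    mc = marginal_covariance(cohort, spec, vc, graph)
    ll, *_ = _profile_loglik(mc, Y, X)
    return ll


_COMP_ORDER = [("G", "sigma_g2"), ("P", "sigma_par2"), ("C", "sigma_child2"),
               ("S", "sigma_s2")]


def _param_names(spec: ModelSpec) -> list[str]:
    names = [f for c, f in _COMP_ORDER if c in spec.components]
    names.append("sigma_eps2")
    if spec.has_spatial and spec.spatial != "IND":
        names.append("rho")
    return names


def _vc_from_vector(spec: ModelSpec, theta: np.ndarray) -> VarianceComponents:
    names = _param_names(spec)
    kw = dict(sigma_g2=0.0, sigma_par2=0.0, sigma_child2=0.0, sigma_s2=0.0,
              sigma_eps2=0.0, rho=0.0)
    for name, val in zip(names, theta):
        kw[name] = float(val)
    return VarianceComponents(**kw)


def _nll_and_grad(
    structure: CohortStructure,
    spec: ModelSpec,
    theta: np.ndarray,
    Y: np.ndarray,
    X: np.ndarray,
):
    """Negative profiled log-likelihood and its gradient wrt natural params.

    Gradient: d(-ll)/dt = 0.5 [ tr(V^-1 dV) - w' dV w ],  w = V^-1 r.
    Traces use the Woodbury split; all spatial pieces are L x L dense.
    """
    vc = _vc_from_vector(spec, theta)
    mc = MarginalCovariance(structure, spec, vc)
    ll, pi_hat, w, XtViX = _profile_loglik(mc, Y, X)
    names = _param_names(spec)
    grad = np.zeros(len(names))

    has_s = spec.has_spatial
    if has_s:
        L = structure.graph.L
        Cinv = cho_solve(mc._C_chol, np.eye(L))
        diag_Cinv = np.diag(Cinv)
        D_A = mc._D_A
        s2 = vc.sigma_s2
        v_loc = np.zeros(L)
        np.add.at(v_loc, structure.ind_loc, w)
        # Z_s' V^-1 Z_s = diag(D_A) - s2 * D_A Cinv D_A
        K_mat = np.diag(D_A) - s2 * (D_A[:, None] * Cinv * D_A[None, :])

    fam_letter = {"sigma_g2": "G", "sigma_par2": "P", "sigma_child2": "C",
                  "sigma_eps2": "E"}
    for j, name in enumerate(names):
        if name in fam_letter:
            letter = fam_letter[name]
            tr1 = 0.0
            wquad = 0.0
            q_fam = np.zeros(structure.cohort.n_families) if has_s else None
            for g, Binv in zip(structure.groups, mc._Binv):
                dB = _component_block(g, letter)
                tr1 += len(g["fam_ids"]) * float(np.sum(Binv * dB.T))
                wg = w[g["idx"]]
                wquad += float(np.einsum("fi,ij,fj->", wg, dB, wg))
                if has_s:
                    q_fam[g["fam_ids"]] = float((Binv @ dB @ Binv).sum())
            trace = tr1
            if has_s:
                q_loc = np.bincount(structure.fam_loc, weights=q_fam, minlength=L)
                trace -= s2 * float(np.dot(diag_Cinv, q_loc))
                # w' dV w is exact (dV is block diagonal); no spatial cross term
            grad[j] = 0.5 * (trace - wquad)
        elif name == "sigma_s2":
            Sigma0 = cho_solve(mc._P0_chol, np.eye(L))
            trace = float(np.sum(Sigma0 * K_mat))
            wquad = float(v_loc @ Sigma0 @ v_loc)
            grad[j] = 0.5 * (trace - wquad)
        elif name == "rho":
            Sigma0 = cho_solve(mc._P0_chol, np.eye(L))
            graph = structure.graph
            if spec.spatial == "CAR":
                dP0 = -graph.W.toarray()
            else:  # SAR
                Wt = graph.normalized_adjacency().toarray()
                D = np.diag(graph._d_eff)
                B = np.eye(L) - vc.rho * Wt
                dP0 = -(Wt @ D @ B + B @ D @ Wt)
            dSigma0 = -Sigma0 @ dP0 @ Sigma0
            trace = s2 * float(np.sum(dSigma0 * K_mat))
            wquad = s2 * float(v_loc @ dSigma0 @ v_loc)
            grad[j] = 0.5 * (trace - wquad)
    return -ll, grad, pi_hat, XtViX


# --------------------------------------------------------------------------
# fitting


@dataclass
class SmileFit:
    """Result of a maximum-likelihood SMILE fit."""

    spec: ModelSpec
    vc: VarianceComponents
    fixed_effects: pd.DataFrame
    loglik: float
    bic: float
    n_params: int
    n_individuals: int
    converged: bool
    grad_norm: float
    n_starts_used: int = 1
    se_components: dict = field(default_factory=dict)
    boundary: list = field(default_factory=list)
    # references for downstream BLUP computation (not serialized)
    _structure: CohortStructure | None = field(default=None, repr=False)
    _Y: np.ndarray | None = field(default=None, repr=False)
    _X: np.ndarray | None = field(default=None, repr=False)

    @property
    def h2(self) -> float:
        return self.vc.h2


def _initializations(spec: ModelSpec, v: float) -> list[np.ndarray]:
    """Three deterministic starts: equal split, residual-dominant, and
    spatial- (or genetic-) dominant."""
    names = _param_names(spec)
    var_names = [n for n in names if n != "rho"]
    k = len(var_names)
    starts = []
    eq = {n: v / k for n in var_names}
    starts.append(eq)
    resid = {n: (0.9 * v if n == "sigma_eps2" else 0.1 * v / max(k - 1, 1))
             for n in var_names}
    starts.append(resid)
    dom = "sigma_s2" if "sigma_s2" in var_names else (
        "sigma_g2" if "sigma_g2" in var_names else "sigma_eps2")
    third = {}
    for n in var_names:
        if n == dom:
            third[n] = 0.5 * v
        elif n == "sigma_eps2":
            third[n] = 0.4 * v
        else:
            third[n] = 0.1 * v / max(k - 2, 1)
    if dom == "sigma_eps2":
        third = {n: (0.7 * v if n == "sigma_eps2" else 0.3 * v / max(k - 1, 1))
                 for n in var_names}
    starts.append(third)
    out = []
    for st in starts:
        vec = []
        for n in names:
            if n == "rho":
                vec.append(0.3 if st is third else 0.0)
            else:
                vec.append(st[n])
        out.append(np.array(vec))
    return out


def fit_smile(
    cohort: Cohort,
    Y: np.ndarray,
    X: np.ndarray | None = None,
    spec: ModelSpec | str = "GPC+S",
    graph: LocationGraph | None = None,
    *,
    spatial: str = "CAR",
    n_starts: int = 3,
    compute_se: bool = True,
    max_iter: int = 500,
    structure: CohortStructure | None = None,
) -> SmileFit:
    """Fit the SMILE model by maximum likelihood.

    Variances are optimized on the log scale and rho through a scaled
    atanh transform (|rho| < 0.99), with the fixed effects profiled out at
    every step.  Multi-start from deterministic initializations; the best
    converged optimum is kept.  Standard errors come from the inverse
    observed information at the optimum; component estimates within
    numerical distance of the zero boundary are flagged (their SEs are
    one-sided).
    """
    if isinstance(spec, str):
        spec = ModelSpec.from_name(spec, spatial=spatial)
    Y = np.asarray(Y, dtype=float)
    N = cohort.n_individuals
    if len(Y) != N:
        raise ModelError("phenotype length does not match cohort size")
    prev = Y.mean()
    is_binary = set(np.unique(Y)) <= {0.0, 1.0}
    if is_binary and not (0.0 < prev < 1.0):
        raise ModelError(f"phenotype prevalence is {prev}; must be in (0, 1)")
    if X is None:
        X = np.ones((N, 1))
    X = np.asarray(X, dtype=float)
    _check_design(X)
    p_fixed = X.shape[1]
    n_var = spec.n_variance_params()
    if N < 10 * (n_var + p_fixed):
        warnings.warn(
            f"only {N} individuals for {n_var + p_fixed} parameters; "
            "estimates may be unstable", stacklevel=2)

    if structure is None:
        structure = CohortStructure(cohort, graph)
    elif graph is not None and structure.graph is not graph:
        structure = CohortStructure(cohort, graph)
    if spec.has_spatial and structure.graph is None:
        raise ModelError("spatial component requested but no location graph given")

    # scale: work on standardized phenotype for conditioning
    beta_ols, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta_ols
    v = float(resid.var())
    if v <= 0:
        raise ModelError("phenotype has zero residual variance")
    names = _param_names(spec)
    has_rho = "rho" in names
    n_theta = len(names)
    log_lo, log_hi = np.log(v) - 18.0, np.log(v) + 4.0

    def to_transformed(theta: np.ndarray) -> np.ndarray:
        t = np.empty(n_theta)
        for j, n in enumerate(names):
            if n == "rho":
                t[j] = np.arctanh(np.clip(theta[j] / RHO_MAX, -0.999, 0.999))
            else:
                t[j] = np.log(max(theta[j], np.exp(log_lo)))
        return t

    def from_transformed(t: np.ndarray) -> np.ndarray:
        theta = np.empty(n_theta)
        for j, n in enumerate(names):
            theta[j] = RHO_MAX * np.tanh(t[j]) if n == "rho" else np.exp(t[j])
        return theta

    def objective(t: np.ndarray):
        theta = from_transformed(t)
        nll, grad, *_ = _nll_and_grad(structure, spec, theta, Y, X)
        # chain rule to transformed coordinates
        jac = np.empty(n_theta)
        for j, n in enumerate(names):
            if n == "rho":
                jac[j] = grad[j] * (RHO_MAX**2 - theta[j] ** 2) / RHO_MAX
            else:
                jac[j] = grad[j] * theta[j]
        return nll, jac

    bounds = []
    for n in names:
        bounds.append((-6.0, 6.0) if n == "rho" else (log_lo, log_hi))

    best = None
    starts = _initializations(spec, v)[:max(1, n_starts)]
    for t0_nat in starts:
        res = optimize.minimize(
            objective, to_transformed(t0_nat), jac=True, method="L-BFGS-B",
            bounds=bounds, options={"maxiter": max_iter, "ftol": 1e-14,
                                    "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    theta_hat = from_transformed(best.x)
    nll, grad_nat, pi_hat, XtViX = _nll_and_grad(structure, spec, theta_hat, Y, X)
    ll = -nll
    grad_t = np.array([
        grad_nat[j] * ((RHO_MAX**2 - theta_hat[j] ** 2) / RHO_MAX
                       if n == "rho" else theta_hat[j])
        for j, n in enumerate(names)
    ])
    grad_norm = float(np.max(np.abs(grad_t)))
    converged = grad_norm < 1e-3 * max(1.0, abs(ll)) or bool(best.success)
    if not converged:
        warnings.warn(
            f"fit of {spec.name} flagged as non-converged "
            f"(gradient norm {grad_norm:.3g})", stacklevel=2)

    vc = _vc_from_vector(spec, theta_hat)
    # fixed-effect covariance at the optimum
    cov_pi = np.linalg.inv(XtViX)
    fe = pd.DataFrame({
        "estimate": pi_hat,
        "se": np.sqrt(np.diag(cov_pi)),
    })
    n_params = n_theta + p_fixed
    bic = -2.0 * ll + n_params * np.log(N)

    boundary = [n for j, n in enumerate(names)
                if n != "rho" and theta_hat[j] < 1e-6 * v]
    se_components: dict[str, float] = {}
    if compute_se:
        se_components = _observed_information_se(
            structure, spec, theta_hat, Y, X, names, v)

    fit = SmileFit(
        spec=spec, vc=vc, fixed_effects=fe, loglik=ll, bic=bic,
        n_params=n_params, n_individuals=N, converged=converged,
        grad_norm=grad_norm, n_starts_used=len(starts),
        se_components=se_components, boundary=boundary,
        _structure=structure, _Y=Y, _X=X,
    )
    if spec.has_spatial:
        mc = MarginalCovariance(structure, spec, vc)
        Sigma_s = mc.spatial_covariance_dense()
        fit.vc.gower_sigma_s2 = gower_factor_from_counts(
            structure.loc_counts, Sigma_s)
    return fit


def _observed_information_se(structure, spec, theta_hat, Y, X, names, v):
    """SEs from a central-difference Hessian of the analytic gradient."""
    n = len(theta_hat)
    H = np.zeros((n, n))
    for j in range(n):
        h = 1e-4 if names[j] == "rho" else max(1e-5 * v, 1e-4 * theta_hat[j])
        tp, tm = theta_hat.copy(), theta_hat.copy()
        tp[j] += h
        tm[j] = max(tm[j] - h, 0.0) if names[j] != "rho" else tm[j] - h
        try:
            _, gp, *_ = _nll_and_grad(structure, spec, tp, Y, X)
            _, gm, *_ = _nll_and_grad(structure, spec, tm, Y, X)
        except ModelError:
            return {}
        H[j] = (gp - gm) / (tp[j] - tm[j])
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.pinv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        return {}
    return dict(zip(names, se))


def select_model(fits: Sequence[SmileFit]) -> SmileFit:
    """Return the minimum-BIC fit; ties broken toward fewer parameters."""
    fits = list(fits)
    if not fits:
        raise ModelError("no fits to select from")
    best_bic = min(f.bic for f in fits)
    tied = [f for f in fits if f.bic <= best_bic + 1e-9]
    return min(tied, key=lambda f: (f.n_params, f.bic))


# --------------------------------------------------------------------------
# observed -> liability scale


def liability_multiplier(K: float) -> float:
    """Linear observed->liability factor K(1-K)/z^2 with z the standard
    normal density at the (1-K) quantile (pi/2 at K=0.5)."""
    if not 0.0 < K < 1.0:
        raise ModelError(f"prevalence must be in (0, 1), got {K}")
    t = stats.norm.ppf(1.0 - K)
    z = stats.norm.pdf(t)
    return K * (1.0 - K) / z**2


def _observed_class_correlation(rho_l: float, K: float) -> float:
    """Observed-scale correlation of two 0/1 outcomes whose liabilities are
    bivariate normal with correlation rho_l: (Phi2(t,t;rho) - K^2)/(K(1-K))."""
    t = stats.norm.ppf(1.0 - K)
    if abs(rho_l) < 1e-12:
        return 0.0
    p11 = stats.multivariate_normal.cdf(
        [-t, -t], mean=[0.0, 0.0], cov=[[1.0, rho_l], [rho_l, 1.0]])
    return (p11 - K**2) / (K * (1.0 - K))


def _liability_class_correlation(r_obs: float, K: float) -> float:
    """Invert the tetrachoric map: liability correlation giving the observed
    correlation r_obs at prevalence K."""
    if abs(r_obs) < 1e-12:
        return 0.0
    lo, hi = -0.9999, 0.9999
    g_lo = _observed_class_correlation(lo, K)
    g_hi = _observed_class_correlation(hi, K)
    r = float(np.clip(r_obs, g_lo + 1e-12, g_hi - 1e-12))
    return optimize.brentq(
        lambda x: _observed_class_correlation(x, K) - r, lo, hi, xtol=1e-10)


def observed_to_liability(
    vc: VarianceComponents, K: float, method: str = "tetrachoric"
) -> VarianceComponents:
    """Convert observed-scale variance fractions to the liability scale.

    ``method="linear"`` applies the standard multiplier K(1-K)/z^2 uniformly
    to every variance fraction.  ``method="tetrachoric"`` (default) inverts
    the bivariate-normal orthant map for each within-family correlation
    class (spouse, parent-child, sibling, location-mate) and solves for the
    liability components; it agrees with the linear multiplier as the
    components shrink, and remains accurate at low prevalence where the
    linear map is biased for strongly correlated relatives.
    """
    if vc.scale != "observed":
        raise ModelError("variance components are not on the observed scale")
    if not 0.0 < K < 1.0:
        raise ModelError(f"prevalence must be in (0, 1), got {K}")
    total = vc.total()
    spatial_obs = vc.gower_sigma_s2 if vc.gower_sigma_s2 is not None else vc.sigma_s2
    f_g = vc.sigma_g2 / total
    f_p = vc.sigma_par2 / total
    f_c = vc.sigma_child2 / total
    f_s = spatial_obs / total
    if method == "linear":
        m = liability_multiplier(K)
        h2_l, par_l, child_l, s_l = (m * f_g, m * f_p, m * f_c, m * f_s)
    elif method == "tetrachoric":
        r_s = _liability_class_correlation(f_s, K)
        r_pc = _liability_class_correlation(0.5 * f_g + f_s, K)
        r_pp = _liability_class_correlation(f_p + f_s, K)
        r_ss = _liability_class_correlation(0.5 * f_g + f_c + f_s, K)
        s_l = r_s
        h2_l = 2.0 * (r_pc - r_s)
        par_l = r_pp - r_s
        child_l = r_ss - r_s - 0.5 * h2_l
    else:
        raise ModelError(f"unknown conversion method {method!r}")
    h2_l = float(np.clip(h2_l, 0.0, 1.0))
    par_l = float(np.clip(par_l, 0.0, 1.0))
    child_l = float(np.clip(child_l, 0.0, 1.0))
    s_l = float(np.clip(s_l, 0.0, 1.0))
    eps_l = max(1.0 - (h2_l + par_l + child_l + s_l), 0.0)
    return VarianceComponents(
        sigma_g2=h2_l, sigma_par2=par_l, sigma_child2=child_l,
        sigma_s2=s_l, sigma_eps2=eps_l, rho=vc.rho,
        scale="liability", gower_sigma_s2=s_l,
    )


# --------------------------------------------------------------------------
# BLUPs of the spatial random effect


def blup_spatial(fit: SmileFit) -> np.ndarray:
    """Best linear unbiased predictor of the per-location spatial effect:
    u_hat = Sigma_s Z_s' V^-1 (Y - X pi_hat)."""
    if not fit.spec.has_spatial:
        raise ModelError("fit has no spatial component")
    if fit._structure is None:
        raise ModelError("fit does not retain data references")
    structure = fit._structure
    mc = MarginalCovariance(structure, fit.spec, fit.vc)
    r = fit._Y - fit._X @ fit.fixed_effects["estimate"].to_numpy()
    w = mc.solve(r)
    v_loc = np.zeros(structure.graph.L)
    np.add.at(v_loc, structure.ind_loc, w)
    Sigma_s = mc.spatial_covariance_dense()
    return Sigma_s @ v_loc


def correlate_blup_covariates(
    blups: pd.DataFrame,
    covariates: pd.DataFrame,
    trait_info: pd.DataFrame | None = None,
    *,
    min_prevalence: float = 0.02,
    min_spatial_var: float = 0.02,
) -> pd.DataFrame:
    """Correlate per-location spatial BLUPs with community-level risk factors.

    ``blups``: traits x locations; ``covariates``: locations x covariates;
    ``trait_info`` (optional): per-trait ``prevalence`` and ``spatial_var``
    columns used to filter traits before correlating.  Returns one row per
    (trait, covariate) with the Pearson correlation and the OLS slope of
    BLUP on the covariate; constant covariates yield missing values.
    """
    locs = blups.columns.intersection(covariates.index)
    if len(locs) < 3:
        raise ModelError("fewer than 3 shared locations between BLUPs and covariates")
    rows = []
    for trait, b in blups.iterrows():
        if trait_info is not None and trait in trait_info.index:
            info = trait_info.loc[trait]
            if info["prevalence"] < min_prevalence or info["spatial_var"] < min_spatial_var:
                rows.append({"trait": trait, "covariate": None, "r": np.nan,
                             "slope": np.nan, "n": 0, "excluded": True})
                continue
        bv = b[locs].to_numpy(dtype=float)
        for cov_name in covariates.columns:
            cv = covariates.loc[locs, cov_name].to_numpy(dtype=float)
            if np.std(cv) < 1e-12 or np.std(bv) < 1e-12:
                r = slope = np.nan
            else:
                r = float(np.corrcoef(bv, cv)[0, 1])
                slope = float(np.cov(bv, cv)[0, 1] / np.var(cv, ddof=1))
            rows.append({"trait": trait, "covariate": cov_name, "r": r,
                         "slope": slope, "n": len(locs), "excluded": False})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# default fixed-effect design


def design_matrix(
    cohort: Cohort,
    covariates: Sequence[str] = ("age", "sex", "months_enrolled"),
    reference_year: int = 2017,
) -> np.ndarray:
    """Individual-level fixed-effect design (always includes an intercept).

    Supported covariates: age, age2, sex (indicator of the second observed
    sex code), months_enrolled.
    """
    cols = [np.ones(cohort.n_individuals)]
    age = reference_year - cohort.birth_year
    for name in covariates:
        if name == "age":
            cols.append(age.astype(float))
        elif name == "age2":
            cols.append(age.astype(float) ** 2)
        elif name == "sex":
            codes = sorted(set(cohort.sex))
            cols.append((cohort.sex == codes[-1]).astype(float) if len(codes) > 1
                        else np.zeros(cohort.n_individuals))
        elif name == "months_enrolled":
            cols.append(cohort.months_enrolled.astype(float))
        else:
            raise ModelError(f"unknown covariate {name!r}")
    return np.column_stack(cols)
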