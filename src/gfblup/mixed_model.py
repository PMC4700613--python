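"""Linear mixed models with arbitrary fixed effects and multiple random
terms, fitted by average-information REML.

Models supported include the phenotype-adjustment animal model
(fixed effects + pen + litter + pedigree-based animal effect), the
single-component genomic model (GBLUP)::

    y' = mu + Z g + e,   g ~ N(0, G sigma_g^2),  e ~ N(0, I sigma_e^2)

and the two-component genomic feature model (GFBLUP)::

    y' = mu + Z f + Z r + e,  f ~ N(0, G_f sigma_f^2),  r ~ N(0, G_r sigma_r^2)

Estimation maximizes the restricted likelihood with average-information
updates and an EM fallback whenever an AI step would decrease the
likelihood or push a component negative; components are clamped at a small
positive bound.  Relationship matrices may be singular (centering makes a
GRM rank deficient); nothing here requires their inverse.

For a model with a single random term whose incidence is the identity, the
covariance is eigendecomposed once and all REML iterations run in the
rotated basis in O(n) per step.  This is the path used for the large GBLUP
fits of the set-test pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from .kinship import RelationshipMatrix

__all__ = [
    "RandomTerm",
    "ModelSpec",
    "VarianceEstimates",
    "BlupSolutions",
    "RemlError",
    "fit_reml",
    "solve_blup",
    "heritability",
    "hat_trace",
    "adjusted_phenotypes",
    "make_gblup_spec",
    "make_gfblup_spec",
]


class RemlError(RuntimeError):
    """REML failure; carries the restricted log-likelihood trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = list(trace or [])


def _as_matrix(K):
    return K.values if isinstance(K, RelationshipMatrix) else np.asarray(K, dtype=float)


@dataclass
class RandomTerm:
    """One random effect: u ~ N(0, K sigma^2), entering the model as Z u."""

    name: str
    K: np.ndarray
    Z: np.ndarray | None = None  # None means identity (one level per record)

    def __post_init__(self) -> None:
        self.K = _as_matrix(self.K)
        q = self.K.shape[0]
        if self.K.shape != (q, q):
            raise ValueError(f"covariance of term {self.name!r} must be square")
        if not np.allclose(self.K, self.K.T, atol=1e-6):
            raise ValueError(f"covariance of term {self.name!r} must be symmetric")
        if self.Z is not None:
            self.Z = np.asarray(self.Z, dtype=float)
            if self.Z.shape[1] != q:
                raise ValueError(f"Z of term {self.name!r} not conformable with K")

    def design(self, n: int) -> np.ndarray:
        return np.eye(n) if self.Z is None else self.Z

    def vcov_contribution(self, n: int) -> np.ndarray:
        """Z K Z' (the n x n contribution of this term to V)."""
        if self.Z is None:
            if self.K.shape[0] != n:
                raise ValueError(
                    f"term {self.name!r}: identity design needs K of size n"
                )
            return self.K
        return self.Z @ self.K @ self.Z.T


@dataclass
class ModelSpec:
    """Response, fixed-effect design and random terms of one mixed model.

    ``eig`` may carry a precomputed eigendecomposition ``(d, U)`` of the
    single covariance matrix for the spectral fast path; replicated
    analyses on a fixed panel then skip the O(n^3) factorization.
    """

    y: np.ndarray
    X: np.ndarray
    random_terms: list[RandomTerm]
    eig: tuple | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        n = self.y.size
        if self.X.shape[0] != n:
            raise ValueError("X not conformable with y")
        if not self.random_terms:
            raise ValueError("at least one random term is required")
        for t in self.random_terms:
            if t.design(n).shape[0] != n:
                raise ValueError(f"term {t.name!r} not conformable with y")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effect design is rank deficient")
        self._kernel_cache = None

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.random_terms]

    def kernel(self):
        if self._kernel_cache is None:
            single = len(self.random_terms) == 1 and self.random_terms[0].Z is None
            cls = _SpectralKernel if single else _DenseKernel
            self._kernel_cache = cls(self)
        return self._kernel_cache


@dataclass
class _State:
    theta: np.ndarray
    ll: float
    score: np.ndarray
    ai: np.ndarray
    yPBPy: np.ndarray
    trPB: np.ndarray
    beta: np.ndarray
    Py: np.ndarray


class _SpectralKernel:
    """REML quantities for one identity-design random term, in the
    eigenbasis of its covariance (V is diagonal there)."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        if spec.eig is not None:
            self.d, self.U = spec.eig
        else:
            K = spec.random_terms[0].vcov_contribution(spec.n)
            self.d, self.U = sla.eigh(K)
        self.d = np.maximum(self.d, 0.0)  # K is PSD up to round-off
        self.yt = self.U.T @ spec.y
        self.Xt = self.U.T @ spec.X

    def _common(self, theta):
        v = theta[0] * self.d + theta[1]
        ViX = self.Xt / v[:, None]
        XtViX = self.Xt.T @ ViX
        cf = sla.cho_factor(XtViX)
        beta = sla.cho_solve(cf, ViX.T @ self.yt)
        Py = self.yt / v - ViX @ beta
        return v, ViX, XtViX, cf, beta, Py

    def _apply_P(self, x, v, ViX, cf):
        return x / v - ViX @ sla.cho_solve(cf, ViX.T @ x)

    def state(self, theta) -> _State:
        v, ViX, XtViX, cf, beta, Py = self._common(theta)
        sign, logdetXtViX = np.linalg.slogdet(XtViX)
        ll = -0.5 * (np.log(v).sum() + logdetXtViX + self.yt @ Py)
        Bdiags = [self.d, np.ones_like(self.d)]
        yPBPy = np.array([Py @ (b * Py) for b in Bdiags])
        trPB = np.empty(2)
        for k, b in enumerate(Bdiags):
            tr_vinv_b = (b / v).sum()
            M = ViX.T @ (b[:, None] * ViX)
            trPB[k] = tr_vinv_b - np.trace(sla.cho_solve(cf, M))
        score = -0.5 * (trPB - yPBPy)
        PBPy = [self._apply_P(b * Py, v, ViX, cf) for b in Bdiags]
        ai = 0.5 * np.array(
            [[(bk * Py) @ PBPy[l] for l in range(2)] for k, bk in enumerate(Bdiags)]
        )
        return _State(np.array(theta, float), ll, score, ai, yPBPy, trPB, beta, Py)

    def tr_P(self, theta) -> float:
        v, ViX, XtViX, cf, beta, Py = self._common(theta)
        return (1.0 / v).sum() - np.trace(sla.cho_solve(cf, ViX.T @ ViX))

    def Py_and_beta(self, theta):
        v, ViX, XtViX, cf, beta, Py_t = self._common(theta)
        return self.U @ Py_t, beta

    def solve(self, theta, compute_pev=True):
        spec = self.spec
        v, ViX, XtViX, cf, beta, Py_t = self._common(theta)
        Py = self.U @ Py_t
        term = spec.random_terms[0]
        u = theta[0] * (self.U @ (self.d * Py_t))
        resid = theta[1] * Py
        out = {"beta": beta, "u": {term.name: u}, "resid": resid}
        if compute_pev:
            # Var(u_hat) = sigma^4 K P K; in the eigenbasis K = diag(d)
            DP = self.d[:, None] * (
                np.diag(1.0 / v) - ViX @ sla.cho_solve(cf, ViX.T)
            )
            M = theta[0] ** 2 * (DP * self.d[None, :])
            var_u = self.U @ M @ self.U.T
            K = term.vcov_contribution(spec.n)
            out["var_pred"] = {term.name: var_u}
            out["pev"] = {term.name: theta[0] * K - var_u}
        return out


class _DenseKernel:
    """REML quantities for the general multi-term model (dense algebra)."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        n = spec.n
        self.Bs = [t.vcov_contribution(n) for t in spec.random_terms]
        self.Bs.append(np.eye(n))

    def _common(self, theta):
        spec = self.spec
        n = spec.n
        V = theta[-1] * np.eye(n)
        for th, B in zip(theta[:-1], self.Bs[:-1]):
            V += th * B
        cV = sla.cho_factor(V)
        Vinv = sla.cho_solve(cV, np.eye(n))
        ViX = Vinv @ spec.X
        XtViX = spec.X.T @ ViX
        cX = sla.cho_factor(XtViX)
        beta = sla.cho_solve(cX, ViX.T @ spec.y)
        Py = Vinv @ spec.y - ViX @ beta
        logdetV = 2.0 * np.log(np.diag(cV[0])).sum()
        return Vinv, ViX, XtViX, cX, beta, Py, logdetV

    def state(self, theta) -> _State:
        spec = self.spec
        Vinv, ViX, XtViX, cX, beta, Py, logdetV = self._common(theta)
        sign, logdetXtViX = np.linalg.slogdet(XtViX)
        ll = -0.5 * (logdetV + logdetXtViX + spec.y @ Py)
        k = len(self.Bs)
        BPy = [B @ Py for B in self.Bs]
        yPBPy = np.array([Py @ b for b in BPy])
        trPB = np.empty(k)
        for i, B in enumerate(self.Bs):
            tr_vinv_b = np.sum(Vinv * B)
            M = ViX.T @ (B @ ViX)
            trPB[i] = tr_vinv_b - np.trace(sla.cho_solve(cX, M))
        score = -0.5 * (trPB - yPBPy)
        PBPy = [
            Vinv @ b - ViX @ sla.cho_solve(cX, ViX.T @ b) for b in BPy
        ]
        ai = 0.5 * np.array([[BPy[i] @ PBPy[j] for j in range(k)] for i in range(k)])
        return _State(np.array(theta, float), ll, score, ai, yPBPy, trPB, beta, Py)

    def tr_P(self, theta) -> float:
        Vinv, ViX, XtViX, cX, beta, Py, _ = self._common(theta)
        return np.trace(Vinv) - np.trace(sla.cho_solve(cX, ViX.T @ ViX))

    def Py_and_beta(self, theta):
        Vinv, ViX, XtViX, cX, beta, Py, _ = self._common(theta)
        return Py, beta

    def solve(self, theta, compute_pev=True):
        spec = self.spec
        n = spec.n
        Vinv, ViX, XtViX, cX, beta, Py, _ = self._common(theta)
        out = {"beta": beta, "u": {}, "resid": theta[-1] * Py}
        if compute_pev:
            out["var_pred"] = {}
            out["pev"] = {}
        for th, term in zip(theta[:-1], spec.random_terms):
            ZK = term.K if term.Z is None else term.Z @ term.K
            out["u"][term.name] = th * (ZK.T @ Py)
            if compute_pev:
                PZK = Vinv @ ZK - ViX @ sla.cho_solve(cX, ViX.T @ ZK)
                var_u = th**2 * (ZK.T @ PZK)
                out["var_pred"][term.name] = var_u
                out["pev"][term.name] = th * term.K - var_u
        return out


@dataclass
class VarianceEstimates:
    """REML variance components with standard errors and fit diagnostics."""

    components: dict[str, float]  # per-term variances plus "residual"
    se: dict[str, float]
    loglik: float
    trace: list[float]
    converged: bool
    n_iterations: int
    lower_bound: float

    @property
    def residual(self) -> float:
        return self.components["residual"]

    def as_vector(self, term_names) -> np.ndarray:
        return np.array([self.components[t] for t in term_names] + [self.residual])


@dataclass
class BlupSolutions:
    """Solutions of Henderson's mixed-model equations at given variances."""

    fixed: np.ndarray
    random: dict[str, np.ndarray]
    residuals: np.ndarray
    pev: dict[str, np.ndarray] = field(default_factory=dict)
    var_pred: dict[str, np.ndarray] = field(default_factory=dict)

    def total_genomic(self, terms=None) -> np.ndarray:
        """Sum of random-effect predictions (g_hat = g_f_hat + g_r_hat for
        the two-component model)."""
        names = terms if terms is not None else list(self.random)
        return np.sum([self.random[t] for t in names], axis=0)


def _em_update(theta, state, n):
    return theta + theta**2 * (state.yPBPy - state.trPB) / n


def fit_reml(
    spec: ModelSpec,
    init=None,
    max_iter: int = 100,
    tol: float = 1e-8,
    param_tol: float = 1e-6,
) -> VarianceEstimates:
    """Estimate variance components by AI-REML with EM fallback.

    Components are initialized at an equal split of the sample phenotypic
    variance unless ``init`` is given.  An AI step that decreases the
    restricted likelihood (or is clamped at the lower bound
    ``eps = 1e-6 * var(y)``) is replaced by an EM step.  Convergence is
    declared when the change in restricted log-likelihood falls below
    ``tol`` and the relative parameter change below ``param_tol``.
    """
    kernel = spec.kernel()
    k = len(spec.random_terms) + 1
    vary = float(np.var(spec.y))
    eps = max(1e-6 * vary, 1e-12)
    if init is None:
        theta = np.full(k, max(vary / k, eps))
    else:
        theta = np.maximum(np.asarray(init, dtype=float), eps)
        if theta.size != k:
            raise ValueError("init must have one entry per term plus residual")

    state = kernel.state(theta)
    trace = [state.ll]
    converged = False
    n_it = 0
    flat_streak = 0
    for n_it in range(1, max_iter + 1):
        # AI proposal, step-halved while it decreases the likelihood; EM as
        # last resort.  Components clamped at the bound whose gradient still
        # points outward are held fixed and dropped from the AI system, so
        # they cannot distort the step for the free components.
        bounded = (theta <= 1.5 * eps) & (state.score < 0.0)
        free_ix = np.flatnonzero(~bounded)
        delta = np.zeros(k)
        if free_ix.size:
            ai_f = state.ai[np.ix_(free_ix, free_ix)]
            try:
                delta[free_ix] = np.linalg.solve(ai_f, state.score[free_ix])
            except np.linalg.LinAlgError:
                delta[free_ix] = np.linalg.pinv(ai_f) @ state.score[free_ix]
        prop = new_state = None
        for shrink in (1.0, 0.5, 0.25, 0.125, 0.0625):
            cand = np.maximum(theta + shrink * delta, eps)
            cand_state = kernel.state(cand)
            if cand_state.ll >= state.ll - 1e-10:
                prop, new_state = cand, cand_state
                break
        if prop is None:
            prop = np.maximum(_em_update(theta, state, spec.n), eps)
            new_state = kernel.state(prop)
        # components clamped at the bound are excluded from the parameter
        # criterion: the likelihood is flat there and EM crawls
        free = prop > 1.5 * eps
        rel = np.abs(prop - theta) / np.maximum(np.abs(theta), eps)
        rel_change = rel[free].max() if free.any() else 0.0
        dll = new_state.ll - state.ll
        theta, state = prop, new_state
        trace.append(state.ll)
        flat_streak = flat_streak + 1 if abs(dll) < tol else 0
        if abs(dll) < tol and (rel_change < param_tol or flat_streak >= 3):
            # a persistent likelihood plateau with moving parameters is a
            # flat ridge (or a boundary); the fit is as converged as the
            # data allow
            converged = True
            break
    if not converged:
        raise RemlError(
            f"AI-REML did not converge in {max_iter} iterations", trace=trace
        )

    try:
        ai_inv = np.linalg.inv(state.ai)
        se = np.sqrt(np.maximum(np.diag(ai_inv), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    names = spec.term_names + ["residual"]
    return VarianceEstimates(
        components=dict(zip(names, theta)),
        se=dict(zip(names, se)),
        loglik=state.ll,
        trace=trace,
        converged=converged,
        n_iterations=n_it,
        lower_bound=eps,
    )


def solve_blup(spec: ModelSpec, v: VarianceEstimates, compute_pev: bool = True) -> BlupSolutions:
    """Solve the mixed-model equations at the estimated variances.

    Predictions are computed in the equivalent variance-matrix form
    ``u_hat_k = sigma_k^2 K_k Z_k' P y`` (valid for singular K), with the
    prediction-error covariance ``PEV_k = sigma_k^2 K_k - Var(u_hat_k)``
    and ``Var(u_hat_k) = sigma_k^4 K_k Z_k' P Z_k K_k``.  The identity
    ``y = X b_hat + sum_k Z_k u_hat_k + e_hat`` holds exactly.
    """
    theta = v.as_vector(spec.term_names)
    sol = spec.kernel().solve(theta, compute_pev=compute_pev)
    return BlupSolutions(
        fixed=sol["beta"],
        random=sol["u"],
        residuals=sol["resid"],
        pev=sol.get("pev", {}),
        var_pred=sol.get("var_pred", {}),
    )


def heritability(v: VarianceEstimates, model: str = "gblup") -> dict[str, float]:
    """Heritability and genomic-variance partition ratios.

    For ``gblup``: ``h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2)``.
    For ``gfblup``: ``h2 = (sigma_f^2 + sigma_r^2) / (sigma_f^2 +
    sigma_r^2 + sigma_e^2)`` together with the partition
    ``h2_f = sigma_f^2 / (sigma_f^2 + sigma_r^2)`` and its complement.
    """
    genetic = [n for n in v.components if n != "residual"]
    se2 = v.residual
    if model == "gblup":
        if len(genetic) != 1:
            raise ValueError("gblup ratios need exactly one genomic term")
        sg2 = v.components[genetic[0]]
        total = sg2 + se2
        if total <= 0:
            raise ZeroDivisionError("zero total variance")
        return {"h2": sg2 / total}
    if model == "gfblup":
        if len(genetic) != 2:
            raise ValueError("gfblup ratios need exactly two genomic terms")
        sf2, sr2 = (v.components[n] for n in genetic)
        total = sf2 + sr2 + se2
        if total <= 0 or sf2 + sr2 <= 0:
            raise ZeroDivisionError("zero total variance")
        return {
            "h2": (sf2 + sr2) / total,
            "h2_f": sf2 / (sf2 + sr2),
            "h2_r": sr2 / (sf2 + sr2),
        }
    raise ValueError(f"unknown model {model!r}")


def hat_trace(spec: ModelSpec, v: VarianceEstimates) -> tuple[float, float]:
    """Trace of the hat matrix H mapping y to fitted values, and the
    effective residual degrees of freedom df_e = n - tr(H) = tr(I - H).

    Since ``e_hat = sigma_e^2 P y``, the smoother is
    ``H = I - sigma_e^2 P`` and ``tr(H) = n - sigma_e^2 tr(P)``.
    """
    theta = v.as_vector(spec.term_names)
    trP = spec.kernel().tr_P(theta)
    tr_h = spec.n - v.residual * trP
    return float(tr_h), float(spec.n - tr_h)


def adjusted_phenotypes(
    spec: ModelSpec,
    v: VarianceEstimates,
    animal_term: str = "animal",
) -> np.ndarray:
    """Adjusted phenotypes: estimated residual plus additive genetic effect
    per phenotyped record, from a fitted animal model.

    This strips fixed effects and non-genetic random effects (pen, litter)
    while keeping all phenotypes usable for their estimation; the result is
    restrictable by the caller to the genotyped subset.
    """
    if animal_term not in spec.term_names:
        raise ValueError(f"model has no random term named {animal_term!r}")
    sol = solve_blup(spec, v, compute_pev=False)
    term = next(t for t in spec.random_terms if t.name == animal_term)
    a = sol.random[animal_term]
    Za = term.design(spec.n)
    return (Za @ a if term.Z is not None else a) + sol.residuals


def make_gblup_spec(y, G, eig=None) -> ModelSpec:
    """Intercept-only single-component genomic model."""
    y = np.asarray(y, dtype=float).ravel()
    return ModelSpec(
        y=y,
        X=np.ones((y.size, 1)),
        random_terms=[RandomTerm("genomic", _as_matrix(G))],
        eig=eig,
    )


def make_gfblup_spec(y, G_f, G_r) -> ModelSpec:
    """Intercept-only two-component genomic feature model.

    ``G_r`` may be the rest-marker matrix (default partition) or the
    all-marker matrix (the alternative second component)."""
    y = np.asarray(y, dtype=float).ravel()
    return ModelSpec(
        y=y,
        X=np.ones((y.size, 1)),
        random_terms=[
            RandomTerm("feature", _as_matrix(G_f)),
            RandomTerm("rest", _as_matrix(G_r)),
        ],
    )
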