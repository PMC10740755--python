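"""REML variance components, principal components and phenotype correction.

Variance components for models of the form

    y = X b + sum_k u_k + e,   u_k ~ N(0, G_k s2_k),   e ~ N(0, I s2_e)

are estimated by average-information REML (AI-REML) with an
expectation-maximization fallback whenever the AI step would leave the
parameter space or decrease the restricted likelihood — the EM step is a
guaranteed-ascent move, so accepted iterations never lower the
restricted log-likelihood. Variances are floored at 1e-8 * var(y) to keep
the AI matrix invertible; estimates that finish on the floor are flagged
as boundary cases.

Single-kernel models take a fast path: the kernel is eigendecomposed once
and the data rotated to its eigenbasis, where every REML iteration costs
O(n p^2) instead of O(n^3). Standard errors come from the inverse AI
matrix; the heritability standard error uses the delta method.

Phenotype correction fits the animal model with a genomic relationship
kernel and strips the estimated fixed effects: corrected = y - X b_hat,
with b_hat the GLS estimate at the REML variances. The genetic and
residual parts are deliberately retained — they carry the signal genomic
prediction needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .exceptions import (
    AlignmentError,
    IdentifiabilityError,
    ZeroVarianceError,
)
from .genio import PhenotypeTable
from .kinship import Kinship

_ROLE_TO_NAME = {
    "full": "sigma2_g",
    "combined": "sigma2_g",
    "feature": "sigma2_f",
    "remainder": "sigma2_r",
}


@dataclass
class MixedModelSpec:
    """Aligned inputs for a mixed-model fit.

    ``fixed_design`` must include the intercept column; one record per
    genotyped individual (identity incidence).
    """

    response: np.ndarray
    fixed_design: np.ndarray
    kernels: list[Kinship]
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float).ravel()
        self.fixed_design = np.atleast_2d(np.asarray(self.fixed_design, dtype=float))
        if self.fixed_design.shape[0] != self.response.size:
            raise AlignmentError("fixed_design rows != response length")
        for k in self.kernels:
            if k.n != self.response.size:
                raise AlignmentError("kernel dimension != response length")
            if self.ids is not None and list(k.ids) != list(self.ids):
                raise AlignmentError("kernel ids differ from spec ids")
        if np.linalg.matrix_rank(self.fixed_design) < self.fixed_design.shape[1]:
            raise ValueError("fixed_design is not full column rank")


@dataclass
class VarianceComponents:
    """Named variance estimates with SEs and fit diagnostics."""

    components: dict[str, float]
    h2: float
    se: dict[str, float]
    loglik: float
    n_iter: int
    converged: bool
    boundary: bool = False

    @property
    def total(self) -> float:
        return float(sum(self.components.values()))

    @property
    def genetic(self) -> float:
        return float(
            sum(v for k, v in self.components.items() if k != "sigma2_e")
        )


# ---------------------------------------------------------------------------
# REML backends
# ---------------------------------------------------------------------------

class _EigBackend:
    """Single genetic kernel: iterate in the kernel's eigenbasis."""

    def __init__(self, y: np.ndarray, X: np.ndarray, G: np.ndarray) -> None:
        d, U = linalg.eigh(G)
        self.d = np.clip(d, 0.0, None)
        self.y = U.T @ y
        self.X = U.T @ X
        self.n, self.p = self.X.shape
        self.n_par = 2

    def _common(self, sig):
        v = sig[0] * self.d + sig[1]
        if np.any(v <= 0):
            return None
        VinvX = self.X / v[:, None]
        XtViX = self.X.T @ VinvX
        sign, logdet_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return None
        Cxx = np.linalg.inv(XtViX)
        Py = self.y / v - VinvX @ (Cxx @ (VinvX.T @ self.y))
        ll = -0.5 * (np.log(v).sum() + logdet_x + self.y @ Py)
        return v, VinvX, Cxx, Py, ll

    def ll(self, sig) -> float:
        out = self._common(sig)
        return -np.inf if out is None else out[4]

    def state(self, sig):
        out = self._common(sig)
        if out is None:
            return None
        v, VinvX, Cxx, Py, ll = out
        diags = (self.d, np.ones(self.n))

        def project(vec):
            return vec / v - VinvX @ (Cxx @ (VinvX.T @ vec))

        trPG = np.empty(2)
        yPGPy = np.empty(2)
        GPy = []
        for k, dk in enumerate(diags):
            trPG[k] = (dk / v).sum() - np.trace(Cxx @ (VinvX.T @ (dk[:, None] * VinvX)))
            gpy = dk * Py
            GPy.append(gpy)
            yPGPy[k] = Py @ gpy
        score = -0.5 * (trPG - yPGPy)
        AI = np.empty((2, 2))
        PGPy = [project(g) for g in GPy]
        for k in range(2):
            for l in range(k, 2):
                AI[k, l] = AI[l, k] = 0.5 * GPy[k] @ PGPy[l]
        return {"ll": ll, "score": score, "AI": AI, "trPG": trPG, "yPGPy": yPGPy}


class _DenseBackend:
    """Arbitrary kernel count: explicit V inverse per iteration."""

    def __init__(self, y: np.ndarray, X: np.ndarray, Gs: list[np.ndarray]) -> None:
        self.y = y
        self.X = X
        self.n, self.p = X.shape
        self.mats = list(Gs) + [np.eye(self.n)]
        self.n_par = len(self.mats)

    def _common(self, sig):
        V = sum(s * M for s, M in zip(sig, self.mats))
        try:
            cho = linalg.cho_factor(V, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return None
        logdet_v = 2.0 * np.log(np.diag(cho[0])).sum()
        Vinv = linalg.cho_solve(cho, np.eye(self.n), check_finite=False)
        VinvX = Vinv @ self.X
        XtViX = self.X.T @ VinvX
        sign, logdet_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return None
        Cxx = np.linalg.inv(XtViX)
        Py = Vinv @ self.y - VinvX @ (Cxx @ (VinvX.T @ self.y))
        ll = -0.5 * (logdet_v + logdet_x + self.y @ Py)
        return Vinv, VinvX, Cxx, Py, ll

    def ll(self, sig) -> float:
        out = self._common(sig)
        return -np.inf if out is None else out[4]

    def state(self, sig):
        out = self._common(sig)
        if out is None:
            return None
        Vinv, VinvX, Cxx, Py, ll = out
        K = self.n_par

        def project(vec):
            return Vinv @ vec - VinvX @ (Cxx @ (VinvX.T @ vec))

        trPG = np.empty(K)
        yPGPy = np.empty(K)
        GPy = []
        for k, M in enumerate(self.mats):
            trPG[k] = (Vinv * M).sum() - np.trace(Cxx @ (VinvX.T @ (M @ VinvX)))
            gpy = M @ Py
            GPy.append(gpy)
            yPGPy[k] = Py @ gpy
        score = -0.5 * (trPG - yPGPy)
        AI = np.empty((K, K))
        PGPy = [project(g) for g in GPy]
        for k in range(K):
            for l in range(k, K):
                AI[k, l] = AI[l, k] = 0.5 * GPy[k] @ PGPy[l]
        return {"ll": ll, "score": score, "AI": AI, "trPG": trPG, "yPGPy": yPGPy}


def _reml_driver(backend, var_y: float, tol: float, max_iter: int):
    K = backend.n_par
    n = backend.n
    floor = 1e-8 * var_y
    sig = np.full(K, var_y / K)
    st = backend.state(sig)
    if st is None:
        raise RuntimeError("restricted likelihood undefined at the starting point")
    ll = st["ll"]
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        # EM proposal is the guaranteed-ascent fallback
        em = np.clip(sig + sig**2 * (st["yPGPy"] - st["trPG"]) / n, floor, None)
        candidates = [em]
        if n_iter > 1:  # one EM step first stabilizes AI
            # active set: components sitting on the floor whose score wants
            # to push them lower are held fixed, and the AI system is
            # solved over the free components only
            free = ~((sig <= floor * (1 + 1e-6)) & (st["score"] < 0))
            step = None
            if free.any():
                try:
                    # lstsq handles a singular AI matrix (confounded
                    # kernels) with the minimum-norm step along
                    # informative directions
                    sub = np.linalg.lstsq(
                        st["AI"][np.ix_(free, free)], st["score"][free], rcond=None
                    )[0]
                    step = np.zeros(K)
                    step[free] = sub
                except np.linalg.LinAlgError:
                    step = None
            if step is not None:
                full = np.clip(sig + step, floor, None)
                half = np.clip(sig + 0.5 * step, floor, None)
                # boundary move: floor the components the AI step pushed
                # negative, leave the others where they are
                hit = sig + step < floor
                pinned = np.where(hit, floor, sig)
                candidates = [full, half, pinned, em] if hit.any() else [full, half, em]
        lls = [backend.ll(c) for c in candidates]
        best = int(np.argmax(lls))
        if not np.isfinite(lls[best]):
            break  # no admissible step; keep current estimates
        proposal = candidates[best]
        st_new = backend.state(proposal)
        delta = st_new["ll"] - ll
        sig, st, ll = proposal, st_new, st_new["ll"]
        if abs(delta) < tol:
            converged = True
            break
    boundary = bool(np.any(sig <= floor * (1 + 1e-6)))
    return sig, st, ll, n_iter, converged, boundary


def estimate_reml(
    spec: MixedModelSpec, tol: float = 1e-8, max_iter: int = 200
) -> VarianceComponents:
    """AI-REML variance components for a one- or multi-kernel mixed model.

    Raises
    ------
    IdentifiabilityError
        If any genetic kernel equals the identity within tolerance (the
        genetic and residual variances would be confounded).
    ZeroVarianceError
        If the response is constant.
    """
    y = spec.response
    X = spec.fixed_design
    var_y = y.var(ddof=1) if y.size > 1 else 0.0
    if var_y == 0:
        raise ZeroVarianceError("response has zero phenotypic variance")
    n = y.size
    if n < 30:
        warnings.warn(
            f"variance components from only {n} individuals are unstable",
            stacklevel=2,
        )
    for k in spec.kernels:
        if np.allclose(k.matrix, np.eye(n), atol=1e-8):
            raise IdentifiabilityError(
                "a genetic kernel equals the identity: genetic and residual "
                "variances are confounded"
            )
    if len(spec.kernels) == 1:
        backend = _EigBackend(y, X, spec.kernels[0].matrix)
    else:
        backend = _DenseBackend(y, X, [k.matrix for k in spec.kernels])

    sig, st, ll, n_iter, converged, boundary = _reml_driver(backend, var_y, tol, max_iter)

    names = []
    seen = {}
    for k in spec.kernels:
        name = _ROLE_TO_NAME.get(k.role, None) or f"sigma2_{k.role}"
        if name in seen:
            seen[name] += 1
            name = f"{name}{seen[name]}"
        else:
            seen[name] = 1
        names.append(name)
    names.append("sigma2_e")
    components = dict(zip(names, map(float, sig)))

    # SEs from the inverse AI matrix; h2 SE via the delta method
    se = {}
    h2_se = float("nan")
    try:
        ai_inv = np.linalg.inv(st["AI"])
        se = {nm: float(np.sqrt(max(ai_inv[i, i], 0.0))) for i, nm in enumerate(names)}
        total = sig.sum()
        gen = sig[:-1].sum()
        grad = np.empty(len(sig))
        grad[:-1] = (total - gen) / total**2
        grad[-1] = -gen / total**2
        h2_se = float(np.sqrt(max(grad @ ai_inv @ grad, 0.0)))
    except np.linalg.LinAlgError:
        se = {nm: float("nan") for nm in names}
    se["h2"] = h2_se

    h2 = float(sig[:-1].sum() / sig.sum())
    return VarianceComponents(
        components=components,
        h2=h2,
        se=se,
        loglik=float(ll),
        n_iter=n_iter,
        converged=converged,
        boundary=boundary,
    )


# ---------------------------------------------------------------------------
# Principal components and phenotype correction
# ---------------------------------------------------------------------------

def principal_components(k: Kinship, n_pc: int) -> np.ndarray:
    """Top-``n_pc`` PC scores from a GRM: eigenvectors scaled by sqrt(eigenvalue).

    Sign convention: the largest-magnitude loading of each component is
    made positive, so repeated calls are bit-identical.
    """
    if not 1 <= n_pc <= k.n - 1:
        raise ValueError(f"n_pc must be in [1, {k.n - 1}], got {n_pc}")
    vals, vecs = linalg.eigh(k.matrix)
    order = np.argsort(vals)[::-1][:n_pc]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    for j in range(n_pc):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return vecs * np.sqrt(vals)


def gls_fixed_effects(
    spec: MixedModelSpec, vc: VarianceComponents
) -> np.ndarray:
    """GLS estimate of the fixed effects at the given variance components."""
    n = spec.response.size
    V = vc.components["sigma2_e"] * np.eye(n)
    for k, name in zip(spec.kernels, list(vc.components)[:-1]):
        V += vc.components[name] * k.matrix
    cho = linalg.cho_factor(V, lower=True)
    VinvX = linalg.cho_solve(cho, spec.fixed_design)
    Vinvy = linalg.cho_solve(cho, spec.response)
    return np.linalg.solve(spec.fixed_design.T @ VinvX, spec.fixed_design.T @ Vinvy)


def correct_phenotypes(
    spec: MixedModelSpec, table: PhenotypeTable | None = None
) -> PhenotypeTable:
    """Strip fixed effects from the response via the animal model.

    Fits ``y = X b + u + e`` (u with the genomic kernel) by REML, then
    sets corrected = y - X b_hat using the GLS fixed-effect estimates.
    The additive-genetic and residual parts stay in the corrected value.
    """
    vc = estimate_reml(spec)
    b = gls_fixed_effects(spec, vc)
    corrected = spec.response - spec.fixed_design @ b
    if table is None:
        n = spec.response.size
        ids = spec.ids if spec.ids is not None else [str(i) for i in range(n)]
        table = PhenotypeTable(
            iid=np.asarray(ids),
            value=spec.response,
            sex=np.zeros(n, dtype=int),
            age=np.zeros(n),
        )
    else:
        table = PhenotypeTable(
            iid=table.iid, value=table.value, sex=table.sex, age=table.age
        )
    table.corrected = corrected
    return table
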