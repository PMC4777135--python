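"""Multi-kernel REML variance-component estimation and BLUP.

Fits individual-tree mixed models of the form

    y = Xb + sum_t Z_t u_t + e,     u_t ~ N(0, s2_t K_t),  e ~ N(0, s2_e I)

where the fixed part is the overall mean and each random term is either
a genetic term with a relationship kernel ``K_t`` (pedigree A, genomic
G_add, G_dom, or a Hadamard epistatic kernel) or a design factor
(replication, replication×family) with identity covariance.

Estimation is average-information (AI) REML, started with a few EM-type
updates for stability, with step halving on likelihood decreases and
variance components constrained to a small positive lower bound.
Standard errors come from the inverse AI matrix, BLUPs and their
standard errors of prediction (SEP) from the converged variance
parameters, and the model ladder mirrors the standard OP-family
analysis sequence: ABLUP, GBLUP-A, GBLUP-AD, GBLUP-ADE, GBLUP-AE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .kernels import RelationshipKernel

__all__ = [
    "RandomTerm",
    "MixedModelSpec",
    "FitOptions",
    "REMLFit",
    "EigenDiagnostic",
    "MODEL_LADDER",
    "model_spec",
    "fit",
    "model_ladder",
    "heritability",
    "heritability_from_components",
    "variance_proportions",
    "variance_proportions_from_components",
    "aic",
    "sampling_correlation_diagnostic",
]

GENETIC_TERM_NAMES = ("additive", "dominance", "add_x_add", "dom_x_dom", "add_x_dom")


class FitError(RuntimeError):
    """Raised when a mixed model cannot be set up or solved."""


@dataclass(frozen=True)
class RandomTerm:
    """One random effect: either kernel-structured or a grouping factor.

    ``kernel`` names an entry of the kernel mapping passed to
    :func:`fit`; ``factor`` names a phenotype column, or ``"a:b"`` for
    the crossing of two columns (used for replication×family).
    """

    name: str
    kernel: str | None = None
    factor: str | None = None

    def __post_init__(self) -> None:
        if (self.kernel is None) == (self.factor is None):
            raise ValueError("a RandomTerm needs exactly one of kernel/factor")


@dataclass
class MixedModelSpec:
    """Declarative model description: trait, transform, random terms."""

    trait: str
    random_terms: list[RandomTerm]
    transform: str = "none"  # none | log

    def __post_init__(self) -> None:
        names = [t.name for t in self.random_terms]
        if len(set(names)) != len(names):
            raise ValueError("random term names must be unique")
        if "residual" in names:
            raise ValueError("the residual term is implicit")
        if self.transform not in ("none", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass
class FitOptions:
    max_iter: int = 200
    n_em_steps: int = 3
    loglik_tol: float = 1e-6
    param_tol: float = 1e-6
    bound_fraction: float = 1e-6  # lower bound as fraction of phenotypic variance
    fixed_variances: Mapping[str, float] | None = None


@dataclass
class EigenDiagnostic:
    """Eigen-structure of the sampling correlation matrix F = L^-1/2 V L^-1/2."""

    parameters: list[str]
    F: np.ndarray
    eigenvalues: np.ndarray
    cumulative_proportion: np.ndarray
    excluded: list[str] = field(default_factory=list)


@dataclass
class REMLFit:
    """Converged (or flagged) REML fit with all downstream quantities."""

    spec: MixedModelSpec
    estimates: dict[str, float]  # per term incl. "residual"
    se: dict[str, float]  # NaN where not estimable (pinned at bound)
    cov: pd.DataFrame  # asymptotic covariance of free variance parameters
    loglik: float
    converged: bool
    n_iter: int
    trace: list[dict]
    pinned: set[str]
    blups: dict[str, pd.DataFrame]  # term -> DataFrame(index=id, blup, sep)
    n_obs: int
    model: str = ""

    @property
    def n_parameters(self) -> int:
        return len(self.estimates)

    @property
    def ebv(self) -> pd.Series:
        """Estimated additive breeding values over all kernel individuals."""
        if "additive" not in self.blups:
            raise KeyError("fit has no additive term")
        return self.blups["additive"]["blup"]

    @property
    def sep(self) -> pd.Series:
        return self.blups["additive"]["sep"]


# ---------------------------------------------------------------------------
# model setup

@dataclass
class _Term:
    name: str
    B: np.ndarray  # n x n contribution Z K Z'
    # for BLUP back-mapping
    kind: str  # kernel | factor
    effect_ids: list[str]
    T: np.ndarray | None  # K Z' (q x n) for kernel terms; indicator Z' for factors
    prior_diag: np.ndarray | None  # diag of K (kernel) or ones (factor)


def _prepare_response(
    spec: MixedModelSpec, phenotypes: pd.DataFrame
) -> pd.DataFrame:
    for col in ("id", "family", "block"):
        if col not in phenotypes.columns:
            raise FitError(f"phenotype table lacks required column {col!r}")
    if spec.trait not in phenotypes.columns:
        raise FitError(f"phenotype table lacks trait column {spec.trait!r}")
    phen = phenotypes.dropna(subset=[spec.trait]).copy()
    if phen.empty:
        raise FitError(f"no non-missing values for trait {spec.trait!r}")
    if phen["id"].duplicated().any():
        raise FitError("duplicate individual ids in phenotype table")
    if spec.transform == "log":
        vals = phen[spec.trait].to_numpy(float)
        if (vals <= 0).any():
            raise FitError("log transform requires strictly positive trait values")
        phen[spec.trait] = np.log(vals)
    return phen


def _build_terms(
    spec: MixedModelSpec,
    phen: pd.DataFrame,
    kernels: Mapping[str, RelationshipKernel] | None,
) -> list[_Term]:
    ids = phen["id"].astype(str).tolist()
    terms: list[_Term] = []
    for rt in spec.random_terms:
        if rt.kernel is not None:
            if kernels is None or rt.kernel not in kernels:
                raise FitError(f"term {rt.name!r} needs kernel {rt.kernel!r}")
            K = kernels[rt.kernel]
            pos = {s: i for i, s in enumerate(K.sample_ids)}
            missing = [i for i in ids if i not in pos]
            if missing:
                raise FitError(
                    f"kernel {rt.kernel!r} lacks phenotyped individuals "
                    f"{missing[:5]}"
                )
            idx = np.array([pos[i] for i in ids])
            B = K.matrix[np.ix_(idx, idx)]
            T = K.matrix[:, idx]  # K Z', q x n
            terms.append(
                _Term(rt.name, B, "kernel", list(K.sample_ids), T, np.diag(K.matrix).copy())
            )
        else:
            if ":" in rt.factor:
                a, b = rt.factor.split(":", 1)
                for col in (a, b):
                    if col not in phen.columns:
                        raise FitError(f"factor column {col!r} missing")
                labels = phen[a].astype(str) + ":" + phen[b].astype(str)
            else:
                if rt.factor not in phen.columns:
                    raise FitError(f"factor column {rt.factor!r} missing")
                labels = phen[rt.factor].astype(str)
            codes, levels = pd.factorize(labels, sort=True)
            Z = np.zeros((len(ids), len(levels)))
            Z[np.arange(len(ids)), codes] = 1.0
            terms.append(
                _Term(
                    rt.name,
                    (codes[:, None] == codes[None, :]).astype(float),
                    "factor",
                    [str(l) for l in levels],
                    Z.T,
                    np.ones(len(levels)),
                )
            )
    return terms


# ---------------------------------------------------------------------------
# AI-REML core

def _reml_quantities(y, X, Bs, theta):
    """V-dependent pieces: P, Py, restricted logL."""
    n = y.size
    V = theta[-1] * np.eye(n)
    for th, B in zip(theta[:-1], Bs):
        V += th * B
    try:
        cf = cho_factor(V, lower=True, check_finite=False)
    except np.linalg.LinAlgError as err:
        raise FitError(
            "covariance matrix not positive definite at current estimates; "
            "stabilize() the offending kernel or rescale the trait"
        ) from err
    logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vinv = cho_solve(cf, np.eye(n), check_finite=False)
    VinvX = Vinv @ X
    XtVinvX = X.T @ VinvX
    sign, logdetX = np.linalg.slogdet(XtVinvX)
    if sign <= 0:
        raise FitError("singular fixed-effects design")
    P = Vinv - VinvX @ np.linalg.solve(XtVinvX, VinvX.T)
    P = (P + P.T) / 2.0
    Py = P @ y
    logL = -0.5 * (logdetV + logdetX + float(y @ Py))
    return P, Py, logL


def _scores_and_ai(y, Bs, P, Py):
    p = len(Bs) + 1
    BPy = [B @ Py for B in Bs] + [Py]
    trPB = [float(np.sum(P * B)) for B in Bs] + [float(np.trace(P))]
    yPBPy = [float(Py @ w) for w in BPy]
    score = np.array([-0.5 * (trPB[k] - yPBPy[k]) for k in range(p)])
    PW = [P @ w for w in BPy]
    AI = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            AI[i, j] = AI[j, i] = 0.5 * float(BPy[i] @ PW[j])
    return score, AI, np.array(trPB), np.array(yPBPy)


def _ai_reml(y, X, Bs, opts: FitOptions):
    n = y.size
    p = len(Bs) + 1
    vp = float(np.var(y, ddof=1)) if n > 1 else 0.0
    bound = max(opts.bound_fraction * vp, 1e-12)
    theta = np.full(p, max(vp, 1e-8) / p)
    P, Py, logL = _reml_quantities(y, X, Bs, theta)
    trace = [{"iter": 0, "loglik": logL, **{f"theta{k}": theta[k] for k in range(p)}}]
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        score, AI, trPB, yPBPy = _scores_and_ai(y, Bs, P, Py)
        if it <= opts.n_em_steps:
            # EM-flavored update: guaranteed-direction small steps
            delta = theta**2 * (yPBPy - trPB) / n
        else:
            try:
                delta = np.linalg.solve(AI, score)
            except np.linalg.LinAlgError:
                delta = np.linalg.lstsq(AI, score, rcond=None)[0]
        step = 1.0
        accepted = False
        for _ in range(30):
            cand = np.maximum(theta + step * delta, bound)
            try:
                P2, Py2, logL2 = _reml_quantities(y, X, Bs, cand)
            except FitError:
                step /= 2.0
                continue
            if logL2 >= logL - 1e-10 or step < 1e-8:
                accepted = True
                break
            step /= 2.0
        if not accepted:
            break
        dtheta = np.abs(cand - theta) / np.maximum(np.abs(theta), 1e-12)
        dlog = abs(logL2 - logL)
        prev = theta
        theta, P, Py, logL = cand, P2, Py2, logL2
        trace.append(
            {"iter": it, "loglik": logL, **{f"theta{k}": theta[k] for k in range(p)}}
        )
        free = theta > bound * (1 + 1e-9)
        rel_ok = dtheta[free].max(initial=0.0) < opts.param_tol
        abs_ok = np.abs(cand - prev)[free].max(initial=0.0) < opts.param_tol * max(vp, 1e-8)
        if dlog < opts.loglik_tol and (rel_ok or abs_ok):
            converged = True
            break
    score, AI, _, _ = _scores_and_ai(y, Bs, P, Py)
    pinned = theta <= bound * (1 + 1e-9)
    return theta, AI, logL, P, Py, converged, it, trace, pinned, bound


def fit(
    spec: MixedModelSpec,
    phenotypes: pd.DataFrame,
    kernels: Mapping[str, RelationshipKernel] | None = None,
    options: FitOptions | None = None,
    model: str = "",
) -> REMLFit:
    """REML-fit a mixed model and compute BLUPs with SEPs.

    Parameters
    ----------
    spec
        Model description (trait, transform, random terms).
    phenotypes
        Table with columns ``id, family, block`` and the trait; rows
        with a missing trait value are dropped.
    kernels
        Mapping of kernel name → :class:`RelationshipKernel` for the
        kernel-structured terms.  Kernels may cover more individuals
        than are phenotyped; BLUPs are then produced for all kernel
        individuals (genomic prediction of unphenotyped trees).
    options
        Numerical controls; ``fixed_variances`` skips estimation and
        computes BLUPs at the supplied variance components.
    """
    opts = options or FitOptions()
    phen = _prepare_response(spec, phenotypes)
    y = phen[spec.trait].to_numpy(float)
    n = y.size
    X = np.ones((n, 1))
    terms = _build_terms(spec, phen, kernels)
    Bs = [t.B for t in terms]
    names = [t.name for t in terms] + ["residual"]

    if opts.fixed_variances is not None:
        fixed = dict(opts.fixed_variances)
        missing = set(names) - set(fixed)
        if missing:
            raise FitError(f"fixed_variances lacks terms {sorted(missing)}")
        theta = np.array([float(fixed[nm]) for nm in names])
        P, Py, logL = _reml_quantities(y, X, Bs, theta)
        se = {nm: float("nan") for nm in names}
        cov = pd.DataFrame(index=[], columns=[], dtype=float)
        converged, n_iter, trace, pinned_mask = True, 0, [], np.zeros(len(names), bool)
    else:
        theta, AI, logL, P, Py, converged, n_iter, trace, pinned_mask, bound = _ai_reml(
            y, X, Bs, opts
        )
        if not converged:
            warnings.warn(
                f"REML did not converge in {n_iter} iterations for trait "
                f"{spec.trait!r}; inspect the iteration trace"
            )
        free_idx = np.flatnonzero(~pinned_mask)
        se = {nm: float("nan") for nm in names}
        if free_idx.size:
            AIf = AI[np.ix_(free_idx, free_idx)]
            try:
                covf = np.linalg.inv(AIf)
            except np.linalg.LinAlgError:
                covf = np.linalg.pinv(AIf)
            covf = (covf + covf.T) / 2.0
            free_names = [names[i] for i in free_idx]
            cov = pd.DataFrame(covf, index=free_names, columns=free_names)
            for nm, v in zip(free_names, np.diag(covf)):
                se[nm] = float(np.sqrt(max(v, 0.0)))
        else:
            cov = pd.DataFrame(index=[], columns=[], dtype=float)

    estimates = {nm: float(th) for nm, th in zip(names, theta)}
    pinned = {nm for nm, flag in zip(names, pinned_mask) if flag}

    # BLUPs: u_hat = s2 K Z' P y ; PEV = s2 K - s2^2 K Z' P Z K
    blups: dict[str, pd.DataFrame] = {}
    for t, th in zip(terms, theta[:-1]):
        u = th * (t.T @ Py)
        TP = t.T @ P  # q x n
        pev = th * t.prior_diag - th**2 * np.einsum("ij,ij->i", TP, t.T)
        sep = np.sqrt(np.maximum(pev, 0.0))
        blups[t.name] = pd.DataFrame(
            {"blup": u, "sep": sep}, index=pd.Index(t.effect_ids, name="id")
        )
    return REMLFit(
        spec=spec,
        estimates=estimates,
        se=se,
        cov=cov,
        loglik=float(logL),
        converged=converged,
        n_iter=n_iter,
        trace=trace,
        pinned=pinned,
        blups=blups,
        n_obs=n,
        model=model,
    )


# ---------------------------------------------------------------------------
# the model ladder

_DESIGN = [
    RandomTerm("replication", factor="block"),
    RandomTerm("rep_x_family", factor="block:family"),
]

MODEL_LADDER: dict[str, list[RandomTerm]] = {
    "ABLUP": [RandomTerm("additive", kernel="A")] + _DESIGN,
    "GBLUP-A": [RandomTerm("additive", kernel="G_add")] + _DESIGN,
    "GBLUP-AD": [
        RandomTerm("additive", kernel="G_add"),
        RandomTerm("dominance", kernel="G_dom"),
    ]
    + _DESIGN,
    "GBLUP-ADE": [
        RandomTerm("additive", kernel="G_add"),
        RandomTerm("dominance", kernel="G_dom"),
        RandomTerm("add_x_add", kernel="AxA"),
        RandomTerm("dom_x_dom", kernel="DxD"),
        RandomTerm("add_x_dom", kernel="AxD"),
    ]
    + _DESIGN,
    "GBLUP-AE": [
        RandomTerm("additive", kernel="G_add"),
        RandomTerm("add_x_add", kernel="AxA"),
    ]
    + _DESIGN,
}


def model_spec(model: str, trait: str, transform: str = "none") -> MixedModelSpec:
    if model not in MODEL_LADDER:
        raise FitError(
            f"unknown model {model!r}; choose from {sorted(MODEL_LADDER)}"
        )
    return MixedModelSpec(trait, list(MODEL_LADDER[model]), transform)


def model_ladder(
    phenotypes: pd.DataFrame,
    trait: str,
    kernels: Mapping[str, RelationshipKernel],
    transform: str = "none",
    models: Sequence[str] | None = None,
    options: FitOptions | None = None,
) -> dict[str, REMLFit]:
    """Fit the OP-family model sequence on shared data.

    ABLUP uses the pedigree A-matrix; GBLUP-A substitutes the genomic
    additive kernel; GBLUP-AD adds dominance; GBLUP-ADE adds the three
    first-order epistatic kernels; GBLUP-AE drops the
    dominance-containing terms.  All include replication and
    replication×family random effects.
    """
    out: dict[str, REMLFit] = {}
    for name in models or list(MODEL_LADDER):
        out[name] = fit(
            model_spec(name, trait, transform), phenotypes, kernels, options, model=name
        )
    return out


# ---------------------------------------------------------------------------
# derived statistics

def heritability_from_components(components: Mapping[str, float]) -> float:
    """Narrow-sense h² = additive / (all genetic terms + residual).

    Design variances (replication, replication×family) are excluded
    from the denominator.
    """
    if "additive" not in components:
        raise KeyError("components lack an additive term")
    denom = components.get("residual", 0.0) + sum(
        components.get(nm, 0.0) for nm in GENETIC_TERM_NAMES
    )
    if denom <= 0:
        raise ZeroDivisionError("phenotypic variance is zero")
    return components["additive"] / denom


def heritability(fit_: REMLFit) -> tuple[float, float]:
    """Point estimate and delta-method SE of narrow-sense heritability."""
    est = fit_.estimates
    h2 = heritability_from_components(est)
    denom = est.get("residual", 0.0) + sum(
        est.get(nm, 0.0) for nm in GENETIC_TERM_NAMES
    )
    grad = {}
    for nm in fit_.cov.index:
        if nm == "additive":
            grad[nm] = (denom - est["additive"]) / denom**2
        elif nm in GENETIC_TERM_NAMES or nm == "residual":
            grad[nm] = -est["additive"] / denom**2
        else:
            grad[nm] = 0.0
    if grad:
        g = np.array([grad[nm] for nm in fit_.cov.index])
        var = float(g @ fit_.cov.to_numpy() @ g)
        se = float(np.sqrt(max(var, 0.0)))
    else:
        se = float("nan")
    return h2, se


def variance_proportions_from_components(
    components: Mapping[str, float]
) -> dict[str, float]:
    """Each component as a percent of the total of *all* components."""
    total = sum(components.values())
    if total <= 0:
        raise ZeroDivisionError("total variance is zero")
    return {nm: 100.0 * v / total for nm, v in components.items()}


def variance_proportions(fit_: REMLFit) -> dict[str, float]:
    return variance_proportions_from_components(fit_.estimates)


def aic(fit_: REMLFit) -> float:
    """AIC = -2 logL + 2t over the t variance parameters of the model.

    The REML log-likelihood omits software-specific constants, so AIC
    values are comparable between fits of this implementation on the
    same data, not across packages.
    """
    return -2.0 * fit_.loglik + 2.0 * fit_.n_parameters


def sampling_correlation_diagnostic(fit_: REMLFit) -> EigenDiagnostic:
    """Eigen-analysis of F = L^-1/2 V L^-1/2.

    V is the asymptotic covariance matrix of the variance-component
    estimates and L its diagonal; F is their sampling correlation
    matrix.  Orthogonal (well-separated) components give all
    eigenvalues 1 and a straight cumulative-proportion line.
    """
    V = fit_.cov.to_numpy(float)
    if V.size == 0:
        raise FitError("no free variance parameters; diagnostic undefined")
    names = list(fit_.cov.index)
    d = np.diag(V).copy()
    keep = d > 0
    excluded = [nm for nm, k in zip(names, keep) if not k]
    if excluded:
        warnings.warn(f"excluding boundary parameters {excluded} from diagnostic")
    Vk = V[np.ix_(keep, keep)]
    dk = np.sqrt(np.diag(Vk))
    F = Vk / np.outer(dk, dk)
    np.fill_diagonal(F, 1.0)
    eig = np.sort(np.linalg.eigvalsh(F))[::-1]
    cum = np.cumsum(eig) / len(eig)
    return EigenDiagnostic(
        parameters=[nm for nm, k in zip(names, keep) if k],
        F=F,
        eigenvalues=eig,
        cumulative_proportion=cum,
        excluded=excluded,
    )
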