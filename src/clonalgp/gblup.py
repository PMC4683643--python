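"""Multi-kernel GBLUP with genotype-by-site interactions, fitted by REML.

The stage-2 model for a single trait stacks the per-site adjusted phenotypes
(BLUEs) site-major into y (ns × 1) and decomposes

    y = X b + Z1 a + Z2 d + Z3 i + Z4 t1 + Z5 t2 + Z6 t3 + e

with fixed effects b (intercept + site), main genetic effects a ~ N(0, G_a
s2a), d ~ N(0, G_d s2d), i ~ N(0, G_aa s2aa), their site interactions
t1..t3 ~ N(0, I_s (x) G s2_gs), and e ~ N(0, I s2e). Under site-major
ordering a main-effect kernel G contributes (1 1' (x) G) to Var(y) and an
interaction contributes (I_s (x) G); rows of individuals missing at a site
are simply dropped, which subsets every structure consistently.

Variance components are estimated by average-information (AI) REML with
expectation-maximization fallback steps: an AI step is accepted only when it
keeps all components positive and increases the restricted log-likelihood;
otherwise an EM step (guaranteed ascent) is taken. Components collapsing to
zero are pinned to a small floor and flagged, mirroring the "0.00" boundary
estimates typical of constrained-REML software.

The estimator :class:`KernelGBLUP` wraps all of this in the scikit-learn
fit/predict idiom; the module-level functions are thin wrappers over it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.base import BaseEstimator

from .datatypes import RelationshipMatrix, VarianceComponents

__all__ = [
    "ModelDesign",
    "ModelFit",
    "VARIANT_COMPONENTS",
    "assemble_design",
    "reml_fit",
    "solve_blups",
    "heritabilities",
    "genotypic_correlation",
    "likelihood_ratio_test",
    "cross_trait_stats",
    "KernelGBLUP",
]

#: genetic kernels active under each model variant
VARIANT_COMPONENTS = {
    "A": ("a",),
    "AD": ("a", "d"),
    "ADE": ("a", "d", "aa"),
}

_INTERACTION_OF = {"a": "a_site", "d": "d_site", "aa": "aa_site"}


@dataclass
class _Component:
    """One variance component: its record-level covariance structure K and
    the bookkeeping needed to recover BLUPs of the underlying effect."""

    name: str
    kind: str  # "main" | "interaction" | "residual"
    K: np.ndarray  # ns x ns covariance structure
    q: int  # dimension of the underlying random vector (EM divisor)


@dataclass
class ModelDesign:
    """Assembled stage-2 design: y, X and the covariance structures."""

    y: np.ndarray
    X: np.ndarray
    ids: list[str]  # all individuals carried by the kernels
    sites: list[str]
    row_individual: np.ndarray  # index into ids, per record
    row_site: np.ndarray  # index into sites, per record
    components: list[_Component]
    kernels: dict[str, np.ndarray] = field(default_factory=dict)
    variant: str = "ADE"

    @property
    def n_records(self) -> int:
        return len(self.y)


@dataclass
class ModelFit:
    """REML solution: variance components, fixed/random effect solutions and
    the restricted log-likelihood."""

    varcomps: VarianceComponents
    b_hat: np.ndarray
    effects: dict[str, np.ndarray]
    restricted_loglik: float
    converged: bool
    iterations: int
    boundary_flags: dict[str, bool]
    design: ModelDesign
    Py: np.ndarray

    @property
    def gegv(self) -> np.ndarray:
        """Genomic estimated genetic value per individual: the sum of the
        fitted main genetic effects (a + d + i under ADE)."""
        out = np.zeros(len(self.design.ids))
        for comp in self.design.components:
            if comp.kind == "main":
                out += self.effects[comp.name]
        return out

    @property
    def fractions(self) -> dict[str, float]:
        return self.varcomps.fractions


def _as_matrix(K: RelationshipMatrix | np.ndarray) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(K, RelationshipMatrix):
        return K.values, list(K.ids)
    return np.asarray(K, float), None


def assemble_design(
    blues: pd.DataFrame,
    kernels: dict[str, RelationshipMatrix | np.ndarray],
    variant: str = "ADE",
    gxe: bool | None = None,
) -> ModelDesign:
    """Build the stage-2 design from a BLUE table and genetic kernels.

    ``blues`` needs columns ``individual_id``, ``site`` and ``blue_value``
    (one trait). ``kernels`` maps a subset of {"a", "d", "aa"} to n x n
    relationship matrices over a common id set; every individual appearing in
    ``blues`` must have a kernel row, but kernels may carry additional
    (unphenotyped) individuals, whose genetic values are then predicted.
    Records are stacked site-major; missing individual-site cells are simply
    absent rows. Interaction components are included when at least two sites
    are present (``gxe=None`` means auto).
    """
    if variant not in VARIANT_COMPONENTS:
        raise ValueError(f"unknown model variant {variant!r}")
    needed = VARIANT_COMPONENTS[variant]
    missing = [k for k in needed if k not in kernels]
    if missing:
        raise ValueError(f"variant {variant} needs kernels {missing}")

    ids: list[str] | None = None
    kmats: dict[str, np.ndarray] = {}
    for name in needed:
        mat, kids = _as_matrix(kernels[name])
        kmats[name] = mat
        if kids is not None:
            if ids is None:
                ids = kids
            elif kids != ids:
                raise ValueError("kernels carry inconsistent id orderings")
    if ids is None:
        ids = [str(i) for i in range(next(iter(kmats.values())).shape[0])]

    index = {v: i for i, v in enumerate(ids)}
    unknown = set(blues["individual_id"].astype(str)) - set(ids)
    if unknown:
        raise KeyError(f"individuals absent from kernels: {sorted(unknown)[:5]}")

    sites = sorted(blues["site"].astype(str).unique())
    if gxe is None:
        gxe = len(sites) >= 2

    # site-major stacking
    b = blues.copy()
    b["__site_ord"] = b["site"].astype(str).map({s: i for i, s in enumerate(sites)})
    b["__ind_ord"] = b["individual_id"].astype(str).map(index)
    b = b.sort_values(["__site_ord", "__ind_ord"], kind="mergesort")
    y = b["blue_value"].to_numpy(float)
    row_ind = b["__ind_ord"].to_numpy(int)
    row_site = b["__site_ord"].to_numpy(int)

    ns = len(y)
    X = np.column_stack(
        [np.ones(ns)] + [(row_site == s).astype(float) for s in range(1, len(sites))]
    )

    components: list[_Component] = []
    same_site = row_site[:, None] == row_site[None, :]
    for name in needed:
        G = kmats[name]
        Kmain = G[np.ix_(row_ind, row_ind)]
        components.append(_Component(name, "main", Kmain, len(ids)))
    if gxe:
        for name in needed:
            G = kmats[name]
            Kint = kmats[name][np.ix_(row_ind, row_ind)] * same_site
            components.append(
                _Component(_INTERACTION_OF[name], "interaction", Kint, len(ids) * len(sites))
            )
    components.append(_Component("e", "residual", np.eye(ns), ns))

    return ModelDesign(y, X, ids, sites, row_ind, row_site, components, kmats, variant)


# --- restricted likelihood machinery -------------------------------------


def _reml_pieces(design: ModelDesign, theta: np.ndarray):
    """Evaluate the restricted log-likelihood and its reusable byproducts.

    Returns None when V (or X'V^-1 X) is numerically non-PD, signalling the
    caller to reject the proposal.
    """
    ns = design.n_records
    V = np.zeros((ns, ns))
    for t, comp in zip(theta, design.components):
        V += t * comp.K
    try:
        cho = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return None
    logdetV = 2.0 * np.sum(np.log(np.diag(cho[0])))
    Vi = linalg.cho_solve(cho, np.eye(ns), check_finite=False)
    ViX = Vi @ design.X
    XtViX = design.X.T @ ViX
    try:
        cho_x = linalg.cho_factor(XtViX, check_finite=False)
    except linalg.LinAlgError:
        return None
    logdetX = 2.0 * np.sum(np.log(np.diag(cho_x[0])))
    P = Vi - ViX @ linalg.cho_solve(cho_x, ViX.T, check_finite=False)
    P = (P + P.T) / 2.0
    Py = P @ design.y
    yPy = float(design.y @ Py)
    ll = -0.5 * (logdetV + logdetX + yPy)
    return {"ll": ll, "P": P, "Py": Py, "Vi": Vi, "XtViX_cho": cho_x, "ViX": ViX}


def reml_fit(
    design: ModelDesign,
    max_iter: int = 200,
    tol: float = 1e-6,
    rtol: float = 1e-4,
    var_floor_frac: float = 1e-8,
    start: np.ndarray | None = None,
    verbose: int = 0,
) -> ModelFit:
    """AI-REML with EM fallback over the design's variance components.

    Maximizes  l_R = -1/2 [ log|V| + log|X'V^-1 X| + y'Py ]  with
    P = V^-1 - V^-1 X (X'V^-1 X)^-1 X'V^-1. Starting values split the
    phenotypic variance equally across components. Convergence requires both
    |delta l_R| < tol and max relative component change < rtol. A fit that
    exhausts ``max_iter`` is returned with ``converged=False`` rather than
    raising.
    """
    ncomp = len(design.components)
    ns = design.n_records
    p = design.X.shape[1]
    if ns < p + 2:
        raise ValueError("too few records for the fixed-effect design")
    vy = float(np.var(design.y, ddof=1)) if ns > 1 else 1.0
    if vy <= 0:
        vy = 1.0
    floor = var_floor_frac * vy
    theta = np.full(ncomp, vy / ncomp) if start is None else np.asarray(start, float).copy()
    theta = np.maximum(theta, floor)

    pieces = _reml_pieces(design, theta)
    if pieces is None:
        raise linalg.LinAlgError("initial V not positive definite")
    ll = pieces["ll"]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        P, Py = pieces["P"], pieces["Py"]
        w = [comp.K @ Py for comp in design.components]
        trPK = np.array([float(np.sum(P * comp.K)) for comp in design.components])
        yPKPy = np.array([float(wk @ Py) for wk in w])
        score = 0.5 * (yPKPy - trPK)

        # EM update: guaranteed ascent, stays positive — the fallback when
        # the AI proposal fails to improve the restricted likelihood
        q = np.array([comp.q for comp in design.components], float)
        theta_em = np.maximum(theta + (theta**2) * (yPKPy - trPK) / q, floor)

        # average-information matrix: AI_jk = 1/2 (K_j Py)' P (K_k Py);
        # the Newton-like step is taken in log-variance space, which keeps
        # every component positive and sends boundary components to the
        # floor geometrically instead of crawling
        Pw = [P @ wk for wk in w]
        AI = 0.5 * np.array(
            [[float(w[j] @ Pw[k]) for k in range(ncomp)] for j in range(ncomp)]
        )
        theta_new = None
        AI_log = AI * np.outer(theta, theta)
        grad_log = theta * score
        # Levenberg–Marquardt damping: escalate towards a scaled-gradient
        # direction whenever the (often ill-conditioned) AI direction fails
        diag = np.maximum(np.diag(AI_log), 1e-12 * max(float(np.trace(AI_log)), 1e-30))
        for lam in (1e-6, 1e-2, 1.0, 100.0):
            try:
                step = np.linalg.solve(AI_log + lam * np.diag(diag), grad_log)
            except np.linalg.LinAlgError:
                continue
            step = np.clip(step, -8.0, 8.0)
            for h in (1.0, 0.5):
                cand = np.maximum(theta * np.exp(h * step), floor)
                cand_pieces = _reml_pieces(design, cand)
                if cand_pieces is not None and cand_pieces["ll"] >= ll - 1e-12:
                    theta_new, new_pieces = cand, cand_pieces
                    break
            if theta_new is not None:
                break

        if theta_new is None:
            cand_pieces = _reml_pieces(design, theta_em)
            if cand_pieces is None:
                break
            theta_new, new_pieces = theta_em, cand_pieces

        delta_ll = new_pieces["ll"] - ll
        rel_change = np.max(np.abs(theta_new - theta) / np.maximum(theta, floor))
        theta, pieces, ll = theta_new, new_pieces, new_pieces["ll"]
        if verbose:
            print(f"iter {it}: ll={ll:.6f} theta={theta}")
        if abs(delta_ll) < tol and rel_change < rtol:
            converged = True
            break

    boundary = {
        comp.name: bool(theta[k] <= floor * (1 + 1e-6))
        for k, comp in enumerate(design.components)
    }
    sigma2 = {comp.name: float(theta[k]) for k, comp in enumerate(design.components)}
    varcomps = VarianceComponents(sigma2)
    effects = _solve_effects(design, theta, pieces["Py"])
    b_hat = linalg.cho_solve(pieces["XtViX_cho"], design.X.T @ (pieces["Vi"] @ design.y))
    return ModelFit(
        varcomps=varcomps,
        b_hat=b_hat,
        effects=effects,
        restricted_loglik=float(ll),
        converged=converged,
        iterations=it,
        boundary_flags=boundary,
        design=design,
        Py=pieces["Py"],
    )


def _solve_effects(design: ModelDesign, theta: np.ndarray, Py: np.ndarray) -> dict[str, np.ndarray]:
    """BLUPs via the V-inverse projection u_hat = s2 Cov(u, y) P y.

    Main effects come back as length-n vectors over every kernel individual
    (including ones without records — that is the prediction path);
    interaction effects as (n_sites x n) arrays; the residual as the fitted
    record-level residual vector.
    """
    effects: dict[str, np.ndarray] = {}
    for t, comp in zip(theta, design.components):
        if comp.kind == "main":
            G = design.kernels[comp.name]
            cross = G[:, design.row_individual]  # Cov(u_i, y_r)/s2
            effects[comp.name] = t * (cross @ Py)
        elif comp.kind == "interaction":
            main_name = comp.name[: -len("_site")]
            G = design.kernels[main_name]
            out = np.zeros((len(design.sites), len(design.ids)))
            for s in range(len(design.sites)):
                mask = design.row_site == s
                out[s] = t * (G[:, design.row_individual[mask]] @ Py[mask])
            effects[comp.name] = out
        else:
            effects[comp.name] = t * Py
    return effects


def solve_blups(design: ModelDesign, varcomps: VarianceComponents) -> dict[str, np.ndarray]:
    """BLUPs of all random effects at fixed variance components."""
    theta = np.array([varcomps.get(comp.name) for comp in design.components])
    pieces = _reml_pieces(design, theta)
    if pieces is None:
        raise linalg.LinAlgError("V not positive definite at the given components")
    return _solve_effects(design, theta, pieces["Py"])


# --- derived quantities ----------------------------------------------------


def heritabilities(varcomps: VarianceComponents | dict) -> tuple[float, float]:
    """Narrow- and broad-sense heritability.

    h2 = s2a / total; H2 = (s2a + s2d + s2aa) / total, the total being the
    sum of every variance component in the fitted model.
    """
    vc = varcomps if isinstance(varcomps, VarianceComponents) else VarianceComponents.from_mapping(varcomps)
    tot = vc.total
    if tot <= 0:
        raise ZeroDivisionError("total phenotypic variance is zero")
    return vc.get("a") / tot, vc.genetic / tot


def genotypic_correlation(varcomps: VarianceComponents | dict) -> float:
    """Between-site genotypic correlation from the variance decomposition.

    r_B = s2_G / (s2_G + s2_GxS) with s2_G the summed main genetic variances
    and s2_GxS the summed genetic-by-site interaction variances — the classic
    Yamada-type ratio relating the genetic covariance across sites to the
    within-site genetic variance.
    """
    vc = varcomps if isinstance(varcomps, VarianceComponents) else VarianceComponents.from_mapping(varcomps)
    denom = vc.genetic + vc.interaction
    if denom <= 0:
        raise ZeroDivisionError("no genetic variance: r_B undefined")
    return vc.genetic / denom


def likelihood_ratio_test(fit_reduced: ModelFit, fit_full: ModelFit) -> dict:
    """LRT between nested model variants fitted to the same records.

    The statistic is 2(l_full - l_reduced) with df the difference in the
    number of variance components (ADE vs A with interactions: 4). The
    primary p-value uses the plain chi-square reference; a chi-bar-square
    mixture p-value (binomial weights over chi2_0..chi2_df) is reported as a
    diagnostic for the boundary-parameter caveat.
    """
    red = set(c.name for c in fit_reduced.design.components)
    full = set(c.name for c in fit_full.design.components)
    if not red < full:
        raise ValueError("models are not nested")
    if fit_reduced.design.n_records != fit_full.design.n_records:
        raise ValueError("fits are not on identical data")
    df = len(full) - len(red)
    stat = 2.0 * (fit_full.restricted_loglik - fit_reduced.restricted_loglik)
    stat_c = max(stat, 0.0)
    p_plain = float(stats.chi2.sf(stat_c, df)) if stat_c > 0 else 1.0
    # chi-bar-square: point mass (weight 2^-df) at 0 plus chi2_1..chi2_df
    p_mix = 0.0
    for j in range(df + 1):
        wgt = math.comb(df, j) / 2.0**df
        p_mix += wgt * (float(stats.chi2.sf(stat_c, j)) if j > 0 else (1.0 if stat_c <= 0 else 0.0))
    return {"statistic": stat, "df": df, "p_value": p_plain, "p_value_mixture": p_mix}


def cross_trait_stats(varcomps_by_trait: dict[str, VarianceComponents | dict]) -> dict:
    """Cross-trait summaries of the variance decomposition.

    Reports the across-trait mean additive/dominance/epistatic fractions (as
    percentages of phenotypic variance) and the per-trait nonadditive:additive
    ratio (s2d + s2aa)/s2a with its mean. A trait with zero additive variance
    yields an undefined (NaN) ratio, excluded from the mean.
    """
    fracs, ratios = {}, {}
    for trait, vc in varcomps_by_trait.items():
        v = vc if isinstance(vc, VarianceComponents) else VarianceComponents.from_mapping(vc)
        f = v.fractions
        fracs[trait] = f
        sa = v.get("a")
        ratios[trait] = (v.get("d") + v.get("aa")) / sa if sa > 0 else float("nan")
    ratio_s = pd.Series(ratios, name="nonadditive_additive_ratio")
    return {
        "mean_additive_pct": 100.0 * float(np.mean([f.get("a", 0.0) for f in fracs.values()])),
        "mean_dominance_pct": 100.0 * float(np.mean([f.get("d", 0.0) for f in fracs.values()])),
        "mean_epistatic_pct": 100.0 * float(np.mean([f.get("aa", 0.0) for f in fracs.values()])),
        "nonadditive_additive_ratio": ratio_s,
        "mean_nonadditive_additive_ratio": float(ratio_s.dropna().mean()),
    }


# --- scikit-learn estimator ------------------------------------------------


class KernelGBLUP(BaseEstimator):
    """Multi-kernel GBLUP estimator in the scikit-learn idiom.

    Parameters
    ----------
    kernels : dict mapping {"a", "d", "aa"} (per variant) to
        :class:`RelationshipMatrix` or ndarray over a common id ordering.
    variant : "A", "AD" or "ADE" — which genetic kernels enter the model.
    gxe : include genetic-by-site interaction components (None = auto when
        two or more sites are present).
    max_iter, tol, rtol, var_floor_frac : REML iteration controls.

    ``fit(X, y)`` takes X as a DataFrame with ``individual_id`` and ``site``
    columns (or a 2-column array in that order) and y the adjusted phenotype
    per row. Fitted attributes follow the trailing-underscore convention:
    ``varcomps_``, ``fractions_``, ``h2_``, ``H2_``, ``rB_``, ``loglik_``,
    ``beta_``, ``effects_``, ``gegv_``, ``converged_``, ``n_iter_``.
    """

    def __init__(
        self,
        kernels: dict | None = None,
        variant: str = "ADE",
        gxe: bool | None = None,
        max_iter: int = 200,
        tol: float = 1e-6,
        rtol: float = 1e-4,
        var_floor_frac: float = 1e-8,
    ):
        self.kernels = kernels
        self.variant = variant
        self.gxe = gxe
        self.max_iter = max_iter
        self.tol = tol
        self.rtol = rtol
        self.var_floor_frac = var_floor_frac

    @staticmethod
    def _rows_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            if not {"individual_id", "site"} <= set(X.columns):
                raise ValueError("X needs individual_id and site columns")
            return X[["individual_id", "site"]].astype(str)
        arr = np.asarray(X, dtype=object)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("X must be (n_records, 2): individual_id, site")
        return pd.DataFrame(arr, columns=["individual_id", "site"]).astype(str)

    def fit(self, X, y):
        if self.kernels is None:
            raise ValueError("kernels must be provided")
        rows = self._rows_frame(X)
        y = np.asarray(y, float).ravel()
        if len(y) != len(rows):
            raise ValueError("X and y lengths differ")
        blues = rows.assign(blue_value=y)
        design = assemble_design(blues, self.kernels, self.variant, self.gxe)
        fit = reml_fit(
            design,
            max_iter=self.max_iter,
            tol=self.tol,
            rtol=self.rtol,
            var_floor_frac=self.var_floor_frac,
        )
        self.fit_ = fit
        self.design_ = design
        self.varcomps_ = fit.varcomps
        self.fractions_ = fit.varcomps.fractions
        self.h2_, self.H2_ = heritabilities(fit.varcomps)
        self.rB_ = (
            genotypic_correlation(fit.varcomps)
            if any(c.kind == "interaction" for c in design.components)
            else None
        )
        self.loglik_ = fit.restricted_loglik
        self.beta_ = fit.b_hat
        self.effects_ = fit.effects
        self.boundary_flags_ = fit.boundary_flags
        self.converged_ = fit.converged
        self.n_iter_ = fit.iterations
        self.ids_ = list(design.ids)
        self.gegv_ = pd.Series(fit.gegv, index=self.ids_, name="gegv")
        return self

    def genetic_values(self, ids=None) -> pd.Series:
        """GEGV (sum of fitted main genetic effects) for the given individuals;
        defaults to every individual the kernels carry, including ones whose
        records were absent from the fit (prediction through the kernel
        cross-covariance)."""
        if ids is None:
            return self.gegv_.copy()
        return self.gegv_.loc[list(map(str, ids))]

    def predict(self, X) -> np.ndarray:
        """Model prediction for (individual, site) rows: fixed effects plus
        main genetic effects plus (when fitted) the site-interaction effects."""
        rows = self._rows_frame(X)
        site_index = {s: i for i, s in enumerate(self.design_.sites)}
        id_index = {v: i for i, v in enumerate(self.ids_)}
        out = np.empty(len(rows))
        gegv = self.gegv_.to_numpy()
        for r, (ind, site) in enumerate(zip(rows["individual_id"], rows["site"])):
            if site not in site_index:
                raise KeyError(f"unknown site {site!r}")
            if ind not in id_index:
                raise KeyError(f"individual {ind!r} absent from kernels")
            s, i = site_index[site], id_index[ind]
            xb = self.beta_[0] + (self.beta_[s] if s >= 1 else 0.0)
            val = xb + gegv[i]
            for comp in self.design_.components:
                if comp.kind == "interaction":
                    val += self.effects_[comp.name][s, i]
            out[r] = val
        return out
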