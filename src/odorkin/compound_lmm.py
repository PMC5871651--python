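"""Vectorized mixed model for per-compound predictor effects.

The samples-by-compounds matrix of (transformed) relative abundances is
vectorized into one long Gaussian response with n_samples * n_compounds
rows. Fixed effects are the attribute predictors (sex, social group,
z-transformed age, and optionally standardized rank). Random intercepts
for the matrix rows and columns (sample and compound) absorb the
pseudo-replication introduced by vectorizing; random intercepts for the
sampled individual, its mother and its father absorb repeated sampling
and parental structure. The test predictors proper are per-compound
random slopes of every fixed effect within compound: a predictor
matters when compounds differ in how they respond to it, and the
compound-specific conditional slopes identify the responsible
compounds.

Model, in variance-component form:

    y = X beta + sum_r Z_r b_r + e,   b_r ~ N(0, sigma_r^2 I),  e ~ N(0, sigma^2 I)

with one variance component per random term. Random slopes are
independent of each other and of the compound intercepts (no
correlation parameters); the categorical group slope is parameterized
per compound on an orthonormal sum-to-zero basis over group levels,
giving exchangeable level deviations and one shared variance.

Fitting is maximum likelihood (not REML) so likelihood-ratio tests
between nested models are coherent. The fixed effects and the residual
variance are profiled out analytically; the optimizer works on the log
variance ratios gamma_r = sigma_r^2 / sigma^2 with an analytic
gradient, using the Woodbury identity so every objective evaluation
costs O(q^3) in the total random-effect dimension q (a few hundred
here), not in the number of rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize
from scipy.stats import chi2 as chi2_dist

from .pedigree import PedigreeTable
from .preprocess import ztransform
from .profile_io import IndividualMetadata, PeakTable

__all__ = [
    "VectorizedDataset",
    "LmmFit",
    "LrtResult",
    "SlopeTable",
    "vectorize",
    "fit_model",
    "lrt",
    "predictor_tests",
    "slope_table",
]

NUMERIC_PREDICTORS = ("sex", "age", "rank")  # sex enters as a +/-1/2 contrast


class ModelError(ValueError):
    pass


@dataclass
class VectorizedDataset:
    """Long-format model data: one row per (sample, compound)."""

    frame: pd.DataFrame
    n_samples: int
    n_compounds: int

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class LrtResult:
    chi_sq: float
    df: int
    p: float


@dataclass
class SlopeTable:
    """Per compound x predictor slope estimates with selection flags.

    For numeric predictors the slope is the fixed effect plus the
    compound's conditional (BLUP) slope deviation. For group it is the
    largest pairwise difference among the compound's group-level
    effects. `selected` marks compounds whose absolute slope is at
    least one sample SD above the mean absolute slope for that
    predictor (the strongest-effect rule); if the slopes are all equal
    the rule is vacuous and nothing is selected.
    """

    table: pd.DataFrame  # index compound_id; per predictor: slope + selected flag

    def to_tsv(self, path) -> None:
        long = self.table.stack(level=0, future_stack=True)
        long.index.names = ["compound", "predictor"]
        long.reset_index().to_csv(path, sep="\t", index=False, float_format="%.6g")


def vectorize(
    rel_transformed: pd.DataFrame | PeakTable,
    meta: IndividualMetadata,
    ped: PedigreeTable,
) -> VectorizedDataset:
    """Melt a transformed abundance matrix into model-ready long format.

    `rel_transformed` holds the model-transformed relative abundances
    (see `preprocess.transform_model`) as a samples-by-compounds frame
    (or a PeakTable, whose axes are reused). Age is z-transformed over
    the sample rows here, matching the design in which each model row
    carries its sample's individual-level age.
    """
    if isinstance(rel_transformed, PeakTable):
        rel_transformed = rel_transformed.to_frame()
    sample_ids = [str(s) for s in rel_transformed.index]
    compound_ids = [str(c) for c in rel_transformed.columns]
    values = rel_transformed.to_numpy(dtype=float)
    inds = meta.individuals_of(sample_ids)
    attrs = meta.individuals.loc[inds]
    missing_age = attrs.index[attrs["age"].isna()].tolist()
    if missing_age:
        raise ModelError(f"missing age for individuals {missing_age}")
    z_age = ztransform(attrs["age"].to_numpy())

    mothers, fathers = [], []
    for ind in inds:
        mo, fa = ped.parents_of(ind)
        mothers.append(mo if mo is not None else f"founder_mo:{ind}")
        fathers.append(fa if fa is not None else f"founder_fa:{ind}")

    n_s, n_c = len(sample_ids), len(compound_ids)
    frame = pd.DataFrame(
        {
            "sample_id": np.repeat(sample_ids, n_c),
            "compound_id": np.tile(compound_ids, n_s),
            "y": values.ravel(),
            "sex": np.repeat(attrs["sex"].to_numpy(), n_c),
            "group": np.repeat(attrs["group"].to_numpy(), n_c),
            "z_age": np.repeat(z_age, n_c),
            "rank": np.repeat(attrs["rank"].to_numpy(dtype=float), n_c),
            "individual_id": np.repeat(inds, n_c),
            "mother_id": np.repeat(mothers, n_c),
            "father_id": np.repeat(fathers, n_c),
        }
    )
    if not np.all(np.isfinite(frame["y"])):
        raise ModelError("non-finite response values after transformation")
    return VectorizedDataset(frame, n_samples=n_s, n_compounds=n_c)


# ---------------------------------------------------------------------------
# design construction


def _indicator(codes: np.ndarray, n_levels: int) -> sparse.csc_matrix:
    n = codes.size
    return sparse.csc_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, n_levels)
    )


def _sum_to_zero_basis(g: int) -> np.ndarray:
    """Orthonormal basis of the sum-to-zero subspace of R^g (g x (g-1))."""
    # Helmert-style contrasts, normalized
    H = np.zeros((g, g - 1))
    for j in range(1, g):
        H[:j, j - 1] = 1.0
        H[j, j - 1] = -j
        H[:, j - 1] /= np.sqrt(j * (j + 1))
    return H


@dataclass
class _Design:
    X: np.ndarray
    y: np.ndarray
    Z: sparse.csc_matrix
    fixed_names: list[str]
    blocks: dict[str, slice]  # random term -> column slice of Z
    compound_levels: list[str]
    group_levels: list[str]
    group_basis: np.ndarray | None
    predictors: tuple[str, ...]
    slope_terms: tuple[str, ...]


def _build_design(
    data: VectorizedDataset,
    predictors: tuple[str, ...],
    slope_terms: tuple[str, ...],
) -> _Design:
    df = data.frame
    n = len(df)

    cols = [np.ones(n)]
    names = ["intercept"]
    group_levels: list[str] = []
    if "sex" in predictors:
        sexes = set(df["sex"])
        if not sexes.issubset({"F", "M"}) or len(sexes) < 2:
            raise ModelError("sex predictor requires both F and M present")
        cols.append(np.where(df["sex"].to_numpy() == "F", 0.5, -0.5))
        names.append("sex(F-M)")
    if "group" in predictors:
        group_levels = sorted(set(df["group"]))
        if len(group_levels) < 2:
            raise ModelError("group predictor requires at least two groups")
        for g in group_levels[1:]:
            cols.append((df["group"].to_numpy() == g).astype(float))
            names.append(f"group[{g}]")
    if "age" in predictors:
        cols.append(df["z_age"].to_numpy())
        names.append("z_age")
    if "rank" in predictors:
        rank = df["rank"].to_numpy(dtype=float)
        if np.isnan(rank).any():
            bad = sorted(set(df.loc[np.isnan(rank), "individual_id"]))
            raise ModelError(f"rank predictor requested but missing for {bad}")
        cols.append(rank - rank.mean())
        names.append("rank")
    X = np.column_stack(cols)

    def codes(col: str) -> tuple[np.ndarray, list[str]]:
        cat = pd.Categorical(df[col])
        return cat.codes.astype(int), [str(c) for c in cat.categories]

    blocks: dict[str, slice] = {}
    Z_parts: list[sparse.csc_matrix] = []
    start = 0

    def add(name: str, mat: sparse.csc_matrix) -> None:
        nonlocal start
        Z_parts.append(mat)
        blocks[name] = slice(start, start + mat.shape[1])
        start += mat.shape[1]

    samp_codes, _ = codes("sample_id")
    comp_codes, comp_levels = codes("compound_id")
    ind_codes, _ = codes("individual_id")
    mo_codes, _ = codes("mother_id")
    fa_codes, _ = codes("father_id")

    comp_ind = _indicator(comp_codes, len(comp_levels))
    add("sample", _indicator(samp_codes, samp_codes.max() + 1))
    add("compound", comp_ind)
    add("individual", _indicator(ind_codes, ind_codes.max() + 1))
    add("mother", _indicator(mo_codes, mo_codes.max() + 1))
    add("father", _indicator(fa_codes, fa_codes.max() + 1))

    group_basis = None
    for pred in slope_terms:
        if pred == "group":
            gcodes = pd.Categorical(df["group"], categories=group_levels or sorted(set(df["group"])))
            glv = list(gcodes.categories)
            group_basis = _sum_to_zero_basis(len(glv))
            # column (k, j): indicator(compound k) * H[group(row), j]
            contr = group_basis[gcodes.codes.astype(int), :]  # n x (g-1)
            parts = [comp_ind.multiply(contr[:, [j]]) for j in range(contr.shape[1])]
            add("slope_group", sparse.hstack(parts, format="csc"))
            group_levels = glv
        else:
            if pred == "sex":
                x = np.where(df["sex"].to_numpy() == "F", 0.5, -0.5)
            elif pred == "age":
                x = df["z_age"].to_numpy()
            elif pred == "rank":
                r = df["rank"].to_numpy(dtype=float)
                x = r - np.nanmean(r)
            else:
                raise ModelError(f"unknown slope predictor {pred!r}")
            add(f"slope_{pred}", comp_ind.multiply(x[:, None]).tocsc())

    Z = sparse.hstack(Z_parts, format="csc")
    return _Design(
        X=X, y=df["y"].to_numpy(dtype=float), Z=Z, fixed_names=names,
        blocks=blocks, compound_levels=comp_levels, group_levels=group_levels,
        group_basis=group_basis, predictors=predictors, slope_terms=tuple(slope_terms),
    )


# ---------------------------------------------------------------------------
# likelihood machinery


class _ProfiledLikelihood:
    """Profiled Gaussian ML over log variance ratios theta_r = log gamma_r."""

    def __init__(self, design: _Design):
        self.design = design
        Z, X, y = design.Z, design.X, design.y
        self.n, self.q = Z.shape
        self.p = X.shape[1]
        self.G0 = (Z.T @ Z).toarray()
        self.Zx = Z.T @ X
        self.Zy = Z.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.block_names = list(design.blocks)
        self.col_block = np.empty(self.q, dtype=int)
        for r, name in enumerate(self.block_names):
            self.col_block[design.blocks[name]] = r
        self.n_blocks = len(self.block_names)

    def _col_gamma(self, theta: np.ndarray) -> np.ndarray:
        return np.exp(theta)[self.col_block]

    def value_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Negative profiled log-likelihood and its gradient in theta."""
        s = np.sqrt(self._col_gamma(theta))
        M = self.G0 * s[:, None] * s[None, :]
        M[np.diag_indices_from(M)] += 1.0
        L, lower = cho_factor(M, lower=True, check_finite=False)
        logdetW = 2.0 * np.sum(np.log(np.diag(L)))

        Ux = self.Zx * s[:, None]
        Uy = self.Zy * s
        AiUx = cho_solve((L, lower), Ux, check_finite=False)
        AiUy = cho_solve((L, lower), Uy, check_finite=False)
        XtWX = self.XtX - Ux.T @ AiUx
        XtWy = self.Xty - Ux.T @ AiUy
        ytWy = self.yty - Uy @ AiUy
        beta = np.linalg.solve(XtWX, XtWy)
        rss = ytWy - beta @ XtWy
        rss = max(rss, 1e-12)
        sigma2 = rss / self.n
        ll = -0.5 * (self.n * np.log(2 * np.pi * sigma2) + self.n + logdetW)

        # u = Z' W^-1 (y - X beta);  Z'U = G0 * s -> (Z'U) A^-1 (s*Z'r)
        Zr = self.Zy - self.Zx @ beta
        u = Zr - (self.G0 * s[None, :]) @ cho_solve((L, lower), s * Zr, check_finite=False)
        # diag of T = Z' W^-1 Z via triangular solve
        P = self.G0 * s[:, None]  # U'Z
        LiP = solve_triangular(L, P, lower=True, check_finite=False)
        diagT = np.diag(self.G0) - np.einsum("ij,ij->j", LiP, LiP)

        grad = np.empty(self.n_blocks)
        u2 = u * u
        for r in range(self.n_blocks):
            mask = self.col_block == r
            dl_dgamma = 0.5 * (u2[mask].sum() / sigma2 - diagT[mask].sum())
            grad[r] = dl_dgamma * np.exp(theta[r])
        # cache pieces for post-fit extraction
        self._last = {
            "beta": beta, "sigma2": sigma2, "u": u, "ll": ll,
            "s": s, "XtWX": XtWX,
        }
        return -ll, -grad


@dataclass
class LmmFit:
    """Converged (or flagged) mixed-model fit."""

    loglik: float
    beta: pd.Series
    sigma2: float
    variance_components: dict[str, float]
    converged: bool
    n_parameters: int
    predictors: tuple[str, ...]
    slope_terms: tuple[str, ...]
    n_obs: int
    messages: list[str] = field(default_factory=list)
    _design: _Design | None = field(default=None, repr=False)
    _blups: dict[str, np.ndarray] | None = field(default=None, repr=False)

    @property
    def with_slopes(self) -> bool:
        return bool(self.slope_terms)


def fit_model(
    data: VectorizedDataset,
    predictors: tuple[str, ...] = ("sex", "group", "age"),
    with_slopes: bool = True,
    drop_slopes: tuple[str, ...] = (),
    seed: int | None = None,
    max_restarts: int = 5,
    gtol: float = 1e-5,
) -> LmmFit:
    """Fit the vectorized mixed model by maximum likelihood.

    `drop_slopes` removes the random slopes of the named predictors
    while keeping their fixed effects (the reduced models of the
    per-predictor likelihood-ratio tests). `with_slopes=False` drops
    all random slopes (the null model of the omnibus test).
    """
    known = {"sex", "group", "age", "rank"}
    bad = set(predictors) - known
    if bad:
        raise ModelError(f"unknown predictors {sorted(bad)}")
    slope_terms = tuple(p for p in predictors if with_slopes and p not in drop_slopes)
    design = _build_design(data, tuple(predictors), slope_terms)
    pl = _ProfiledLikelihood(design)

    rng = np.random.default_rng(seed)
    theta0 = np.full(pl.n_blocks, np.log(0.5))
    best = None
    messages: list[str] = []
    converged = False
    for attempt in range(max_restarts + 1):
        start = theta0 if attempt == 0 else theta0 + rng.normal(0, 1.5, pl.n_blocks)
        res = minimize(
            pl.value_and_grad, start, jac=True, method="L-BFGS-B",
            bounds=[(-14.0, 8.0)] * pl.n_blocks,
            options={"maxiter": 500, "gtol": gtol, "ftol": 1e-12},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if res.success:
            converged = True
            if res.fun <= best.fun + 1e-6:
                best = res
            break
        messages.append(f"restart {attempt}: {res.message}")
    if not converged:
        messages.append("optimizer did not report convergence; returning best point")

    # re-evaluate at the optimum to populate the cache
    pl.value_and_grad(best.x)
    cache = pl._last
    sigma2 = cache["sigma2"]
    gammas = np.exp(best.x)
    vc = {name: float(sigma2 * gammas[r]) for r, name in enumerate(pl.block_names)}
    boundary = [name for name, v in vc.items() if v / sigma2 < 1e-5]
    if boundary:
        messages.append(f"variance components at boundary (~0): {boundary}")

    blups = {}
    col_gamma = pl._col_gamma(best.x)
    b = col_gamma * cache["u"]
    for name, sl in design.blocks.items():
        blups[name] = b[sl]

    n_par = design.X.shape[1] + pl.n_blocks + 1
    return LmmFit(
        loglik=float(cache["ll"]),
        beta=pd.Series(cache["beta"], index=design.fixed_names),
        sigma2=float(sigma2),
        variance_components=vc,
        converged=converged,
        n_parameters=n_par,
        predictors=tuple(predictors),
        slope_terms=slope_terms,
        n_obs=pl.n,
        messages=messages,
        _design=design,
        _blups=blups,
    )


def lrt(full: LmmFit, reduced: LmmFit) -> LrtResult:
    """Likelihood-ratio test of nested ML fits against chi-square(df)."""
    if full.n_obs != reduced.n_obs:
        raise ModelError("models fitted on different data")
    if full.n_parameters < reduced.n_parameters or not set(reduced.slope_terms) <= set(full.slope_terms):
        raise ModelError("reduced model is not nested in the full model")
    df = full.n_parameters - reduced.n_parameters
    if df == 0 and full.slope_terms == reduced.slope_terms:
        chi = max(0.0, 2.0 * (full.loglik - reduced.loglik))
        return LrtResult(chi_sq=chi, df=0, p=1.0)
    chi = 2.0 * (full.loglik - reduced.loglik)
    if chi < 0 and chi > -5e-3:  # optimizer noise at the boundary
        chi = 0.0
    if chi < 0:
        warnings.warn(
            f"reduced model attained higher likelihood (delta={chi/2:.3g}); clipping LRT at 0"
        )
        chi = 0.0
    p = float(chi2_dist.sf(chi, df)) if df > 0 else 1.0
    return LrtResult(chi_sq=float(chi), df=df, p=p)


def predictor_tests(
    data: VectorizedDataset,
    predictors: tuple[str, ...] = ("sex", "group", "age"),
    seed: int | None = None,
) -> tuple[LmmFit, list[tuple[str, LrtResult]]]:
    """Omnibus and per-predictor random-slope likelihood-ratio tests.

    Returns the full fit plus one result per test: 'omnibus' compares
    the full model with all random slopes against the no-slope null;
    each named predictor's test drops only that predictor's slopes.
    """
    full = fit_model(data, predictors, with_slopes=True, seed=seed)
    if not full.converged:
        warnings.warn("full model did not converge; LRTs may be unreliable")
    null = fit_model(data, predictors, with_slopes=False, seed=seed)
    out: list[tuple[str, LrtResult]] = [("omnibus", lrt(full, null))]
    for pred in predictors:
        reduced = fit_model(data, predictors, with_slopes=True, drop_slopes=(pred,), seed=seed)
        out.append((pred, lrt(full, reduced)))
    return full, out


def slope_table(fit: LmmFit) -> SlopeTable:
    """Per-compound slope estimates and the strongest-effect selection.

    Numeric predictors: slope = fixed effect + conditional compound
    deviation (positive sex slopes mean higher in females). Group:
    largest pairwise difference among the compound's group-level
    effects (fixed level effects plus conditional sum-to-zero
    deviations), invariant to the reference level.
    """
    if not fit.with_slopes:
        raise ModelError("fit has no random slopes to extract")
    design = fit._design
    blups = fit._blups
    comps = design.compound_levels
    n_c = len(comps)
    out: dict[tuple[str, str], np.ndarray] = {}

    for pred in fit.slope_terms:
        if pred == "group":
            glv = design.group_levels
            fixed = np.zeros(len(glv))
            for j, g in enumerate(glv[1:], start=1):
                fixed[j] = fit.beta[f"group[{g}]"]
            dev = blups["slope_group"].reshape(len(glv) - 1, n_c).T  # n_c x (g-1)
            effects = fixed[None, :] + dev @ design.group_basis.T
            slopes = effects.max(axis=1) - effects.min(axis=1)
        else:
            fixed_name = {"sex": "sex(F-M)", "age": "z_age", "rank": "rank"}[pred]
            slopes = fit.beta[fixed_name] + blups[f"slope_{pred}"]
        out[(pred, "slope")] = np.asarray(slopes, dtype=float)

    for pred in fit.slope_terms:
        a = np.abs(out[(pred, "slope")])
        sd = a.std(ddof=1) if n_c > 1 else 0.0
        if sd > 0:
            sel = a >= a.mean() + sd
        else:
            warnings.warn(f"all |slopes| equal for {pred!r}; selection rule is vacuous")
            sel = np.zeros(n_c, dtype=bool)
        out[(pred, "selected")] = sel

    table = pd.DataFrame(out, index=pd.Index(comps, name="compound_id"))
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["predictor", "field"])
    return SlopeTable(table)
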