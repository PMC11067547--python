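"""Cross-sectional and inter-visit structure-function mixed models.

Both models are linear mixed-effect models with three crossed/nested random
intercepts — patient, visit within patient, and stimulus grid position —
fitted by REML with Wald (normal-approximation) standard errors, confidence
intervals and p-values:

* cross-sectional: point-wise sensitivity deviation (dB) ~ intercept + age +
  pseudophakic + 8 biomarker presence flags;
* inter-visit: point-wise sensitivity change between consecutive visits ~
  the same exogenous terms + years elapsed + 9 layer-thickness z-scores
  (taken, like the flags, at the earlier visit of the pair).

Mesopic and scotopic sensitivities are fitted as two separate models.

The default solver exploits that every random term is a pure intercept over
a categorical factor: with variance ratios gamma_c = sigma_c^2 / sigma^2 the
profiled REML criterion depends on the data only through fixed cross
products (Z'Z, Z'X, Z'y, X'X, X'y, y'y), so each objective evaluation is a
single q x q Cholesky factorization (q = total number of random levels,
~300 here) and the whole fit takes seconds.  ``backend="mixedlm"`` fits the
identical model through statsmodels MixedLM (one-group variance-component
formulation) as an independent route.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import BIOMARKERS, ConvergenceError, LAYERS

#: Fixed-effect term lists (design-matrix column order).
CROSS_SECTIONAL_TERMS: tuple[str, ...] = (
    "intercept", "age", "pseudophakic", *(f"flag_{b}" for b in BIOMARKERS),
)
INTERVISIT_TERMS: tuple[str, ...] = (
    "intercept", "age", "years_elapsed", "pseudophakic",
    *(f"flag_{b}" for b in BIOMARKERS), *(f"z_{layer}" for layer in LAYERS),
)

RANDOM_TERMS: tuple[str, ...] = ("patient", "visit", "grid")

_DEGENERATE_SCALE: float = 1e-10


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: endogenous modality, model kind, estimation options."""

    modality: str = "mesopic"              # "mesopic" | "scotopic"
    kind: str = "cross_sectional"          # "cross_sectional" | "intervisit"
    method: str = "reml"                   # "reml" | "ml"
    backend: str = "profiled"              # "profiled" | "mixedlm"
    drop_censored: bool = False            # sensitivity-analysis mode

    def __post_init__(self):
        if self.modality not in ("mesopic", "scotopic"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.kind not in ("cross_sectional", "intervisit"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.method not in ("reml", "ml"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.backend not in ("profiled", "mixedlm"):
            raise ValueError(f"unknown backend {self.backend!r}")

    @property
    def terms(self) -> tuple[str, ...]:
        return (CROSS_SECTIONAL_TERMS if self.kind == "cross_sectional"
                else INTERVISIT_TERMS)

    @property
    def endog_column(self) -> str:
        base = f"{self.modality}_dev"
        return base if self.kind == "cross_sectional" else f"d_{base}"


@dataclass
class ModelResult:
    """Fitted fixed effects, variance components and metadata."""

    fixed_effects: pd.DataFrame  # index: term; estimate, se, ci_low, ci_high, p_value
    vcomp: dict[str, float]      # variances: patient, visit, grid, residual
    n_obs: int
    n_dropped: int
    converged: bool
    loglike: float
    spec: ModelSpec
    inference: str = "wald-normal"

    def coef(self, term: str) -> float:
        return float(self.fixed_effects.loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.fixed_effects.loc[term, "se"])

    def to_frame(self) -> pd.DataFrame:
        out = self.fixed_effects.reset_index().rename(columns={"index": "term"})
        return out

    def to_dict(self) -> dict:
        return {
            "modality": self.spec.modality,
            "kind": self.spec.kind,
            "fixed_effects": {
                term: {k: float(v) for k, v in row.items()}
                for term, row in self.fixed_effects.iterrows()
            },
            "vcomp": {k: float(v) for k, v in self.vcomp.items()},
            "n_obs": int(self.n_obs),
            "n_dropped": int(self.n_dropped),
            "converged": bool(self.converged),
            "loglike": float(self.loglike),
            "inference": self.inference,
        }


# ---------------------------------------------------------------------------
# profiled REML for crossed random intercepts
# ---------------------------------------------------------------------------

def _reml_crossed(
    X: np.ndarray,
    y: np.ndarray,
    factors: list[np.ndarray],
    reml: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float, bool]:
    """Fit y = X b + sum_c Z_c u_c + e, u_c ~ N(0, s2_c I), e ~ N(0, s2 I).

    ``factors`` are integer-coded arrays (one per random intercept).
    Returns (beta, se, vcomp, scale, loglike, converged).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    n, p = X.shape
    n_fac = len(factors)

    # OLS shortcut doubles as the degenerate (zero-variance) path
    beta_ols, rss_ols, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise ConvergenceError(
            "fixed-effect design matrix is rank deficient; check for "
            "constant biomarker flags or collinear covariates"
        )
    resid = y - X @ beta_ols
    sig2_ols = float(resid @ resid) / max(n - p, 1)
    yscale = max(1.0, float(y @ y) / n)
    if sig2_ols < _DEGENERATE_SCALE * yscale:
        XtX = X.T @ X
        se = np.sqrt(np.maximum(np.diag(sig2_ols * np.linalg.inv(XtX)), 0.0))
        return beta_ols, se, np.zeros(n_fac), sig2_ols, np.nan, True

    sizes = [int(f.max()) + 1 for f in factors]
    q = sum(sizes)
    Z = np.zeros((n, q))
    offset = 0
    blocks = np.empty(q, dtype=int)
    for i, (f, s) in enumerate(zip(factors, sizes)):
        Z[np.arange(n), offset + f] = 1.0
        blocks[offset:offset + s] = i
        offset += s
    ZtZ = Z.T @ Z
    ZtX = Z.T @ X
    Zty = Z.T @ y
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    denom = n - p if reml else n

    def _solve(logg):
        g = np.exp(np.clip(logg, -30.0, 30.0))
        d = np.sqrt(g[blocks])
        M = d[:, None] * ZtZ * d[None, :]
        M[np.diag_indices(q)] += 1.0
        L = np.linalg.cholesky(M)
        logdet_m = 2.0 * float(np.log(np.diag(L)).sum())
        SA = np.linalg.solve(L, d[:, None] * ZtX)
        Sb = np.linalg.solve(L, d * Zty)
        XtVX = XtX - SA.T @ SA
        XtVy = Xty - SA.T @ Sb
        ytVy = yty - float(Sb @ Sb)
        Lx = np.linalg.cholesky(XtVX)
        beta = np.linalg.solve(XtVX, XtVy)
        rss = max(ytVy - float(XtVy @ beta), 1e-300)
        sig2 = rss / denom
        logdet_xvx = 2.0 * float(np.log(np.diag(Lx)).sum())
        crit = denom * np.log(sig2) + logdet_m
        if reml:
            crit += logdet_xvx
        return crit, beta, sig2, XtVX

    def objective(logg):
        try:
            return _solve(logg)[0]
        except np.linalg.LinAlgError:
            return np.inf

    res = optimize.minimize(
        objective, np.zeros(n_fac), method="Nelder-Mead",
        options=dict(xatol=1e-7, fatol=1e-9, maxiter=4000, maxfev=4000),
    )
    crit, beta, sig2, XtVX = _solve(res.x)
    se = np.sqrt(np.maximum(np.diag(sig2 * np.linalg.inv(XtVX)), 0.0))
    vcomp = np.exp(np.clip(res.x, -30.0, 30.0)) * sig2
    const = denom * (1.0 + np.log(2.0 * np.pi))
    loglike = -0.5 * (crit + const)
    return beta, se, vcomp, sig2, float(loglike), bool(res.success)


def _mixedlm_crossed(X, y, factors, term_names, reml=True):
    """Same model through statsmodels MixedLM (independent route)."""
    from statsmodels.regression.mixed_linear_model import MixedLM

    n = len(y)
    df = pd.DataFrame(X, columns=list(term_names))
    df["_y"] = y
    df["_one"] = 1
    vc_formula = {}
    for name, f in zip(RANDOM_TERMS, factors):
        df[f"_{name}"] = f
        vc_formula[name] = f"0 + C(_{name})"
    fixed = " + ".join(t for t in term_names if t != "intercept")
    model = MixedLM.from_formula(
        f"_y ~ {fixed}" if fixed else "_y ~ 1",
        groups="_one", vc_formula=vc_formula, re_formula="0", data=df,
    )
    fit = model.fit(reml=reml, method="lbfgs")
    order = ["Intercept"] + [t for t in term_names if t != "intercept"]
    beta = fit.fe_params.reindex(order).to_numpy()
    se = fit.bse_fe.reindex(order).to_numpy()
    # statsmodels orders variance components alphabetically by name
    vc_names = sorted(RANDOM_TERMS)
    vc_map = dict(zip(vc_names, fit.vcomp))
    vcomp = np.array([vc_map[name] for name in RANDOM_TERMS])
    return beta, se, vcomp, float(fit.scale), float(fit.llf), bool(fit.converged)


# ---------------------------------------------------------------------------
# table preparation and public fits
# ---------------------------------------------------------------------------

def _prepare(table: pd.DataFrame, spec: ModelSpec):
    df = table
    if "group" in df.columns:
        df = df[df["group"] == "amd"]
    n_before = len(df)
    if "valid" in df.columns:
        df = df[df["valid"].astype(bool)]
    if spec.drop_censored:
        cens_col = (f"{spec.modality}_censored" if spec.kind == "cross_sectional"
                    else f"d_{spec.modality}_dev_censored")
        if cens_col in df.columns:
            df = df[~df[cens_col].astype(bool)]
    needed = [spec.endog_column]
    for t in spec.terms:
        if t == "intercept":
            continue
        col = {"age": "age_years", "years_elapsed": "years_elapsed",
               "pseudophakic": "pseudophakic"}.get(t, t)
        needed.append(col)
    df = df.dropna(subset=[c for c in needed if c in df.columns])
    n_dropped = n_before - len(df)
    if df.empty:
        raise ValueError("no usable rows after filtering for the model")

    X = np.ones((len(df), len(spec.terms)))
    for j, t in enumerate(spec.terms):
        if t == "intercept":
            continue
        col = {"age": "age_years"}.get(t, t)
        X[:, j] = df[col].to_numpy(dtype=float)
    y = df[spec.endog_column].to_numpy(dtype=float)

    # drop aliased columns left to right (constant flags, collinear
    # z-scores in degenerate cohorts); they are reported as NaN, matching
    # how lmer handles a rank-deficient fixed-effect matrix
    keep: list[int] = [0]  # intercept
    for j in range(1, X.shape[1]):
        col = X[:, j]
        basis = X[:, keep]
        coefs, *_ = np.linalg.lstsq(basis, col, rcond=None)
        resid = col - basis @ coefs
        if np.linalg.norm(resid) > 1e-8 * max(1.0, np.linalg.norm(col)):
            keep.append(j)
    dropped_terms = [t for j, t in enumerate(spec.terms) if j not in keep]
    X = X[:, keep]
    kept_terms = [spec.terms[j] for j in keep]

    patient = pd.factorize(df["patient_id"])[0]
    visit_key = (df["patient_id"].astype(str) + "#"
                 + df["visit_index"].astype(int).astype(str))
    visit = pd.factorize(visit_key)[0]
    grid = pd.factorize(df["grid_index"])[0]
    return X, y, [patient, visit, grid], n_dropped, kept_terms, dropped_terms


def _fit(table: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    X, y, factors, n_dropped, kept_terms, dropped_terms = _prepare(table, spec)
    reml = spec.method == "reml"
    if spec.backend == "profiled":
        beta, se, vcomp, scale, llf, converged = _reml_crossed(
            X, y, factors, reml=reml
        )
    else:
        beta, se, vcomp, scale, llf, converged = _mixedlm_crossed(
            X, y, factors, kept_terms, reml=reml
        )
    if not converged:
        raise ConvergenceError(
            f"{spec.kind}/{spec.modality} mixed model did not converge "
            f"(backend={spec.backend}, n={len(y)})"
        )
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    halfwidth = stats.norm.ppf(0.975) * se
    fe = pd.DataFrame(
        {
            "estimate": beta,
            "se": se,
            "ci_low": beta - halfwidth,
            "ci_high": beta + halfwidth,
            "p_value": p,
        },
        index=list(kept_terms),
    )
    fe = fe.reindex(list(spec.terms))  # dropped (aliased) terms become NaN
    vc = dict(zip(RANDOM_TERMS, (float(v) for v in vcomp)))
    vc["residual"] = float(scale)
    return ModelResult(
        fixed_effects=fe, vcomp=vc, n_obs=len(y), n_dropped=int(n_dropped),
        converged=converged, loglike=llf, spec=spec,
    )


def fit_cross_sectional(table: pd.DataFrame, spec: ModelSpec | None = None,
                        **kwargs) -> ModelResult:
    """Fit the cross-sectional structure-function model on a point-wise table.

    The table must carry ``{modality}_dev`` columns (see
    :func:`fcpoct.normalization.apply_normalization`).
    """
    if spec is None:
        spec = ModelSpec(kind="cross_sectional", **kwargs)
    if spec.kind != "cross_sectional":
        raise ValueError("spec.kind must be 'cross_sectional'")
    return _fit(table, spec)


def intervisit_differences(table: pd.DataFrame) -> pd.DataFrame:
    """Point-wise sensitivity differences between consecutive visits.

    One row per (eye, consecutive visit pair, grid position), with the
    change (later minus earlier) of each modality's deviation as endogenous
    material and all exogenous covariates (flags, layer z-scores) taken from
    the earlier visit of the pair.  Eyes with a single visit contribute
    nothing; the result may be empty.
    """
    dev_cols = [c for c in ("mesopic_dev", "scotopic_dev") if c in table.columns]
    if not dev_cols:
        raise ValueError(
            "table has no deviation columns; run apply_normalization first"
        )
    df = table.sort_values(["eye_id", "visit_index", "grid_index"])
    out_rows = []
    carry = [c for c in df.columns
             if c.startswith("flag_") or c.startswith("z_")]
    for (eye_id, grid_index), g in df.groupby(["eye_id", "grid_index"],
                                              sort=False):
        g = g.sort_values("visit_index")
        for earlier, later in zip(
            g.to_dict("records")[:-1], g.to_dict("records")[1:]
        ):
            row = {
                "eye_id": eye_id,
                "patient_id": earlier["patient_id"],
                "group": earlier.get("group", "amd"),
                "grid_index": grid_index,
                "visit_index": later["visit_index"],
                "earlier_visit_index": earlier["visit_index"],
                "years_elapsed": (later["months_since_baseline"]
                                  - earlier["months_since_baseline"]) / 12.0,
                "age_years": earlier["age_years"],
                "pseudophakic": earlier["pseudophakic"],
                "valid": bool(earlier.get("valid", True))
                and bool(later.get("valid", True)),
            }
            for c in dev_cols:
                row[f"d_{c}"] = later[c] - earlier[c]
                cens = f"{c.split('_')[0]}_censored"
                if cens in earlier:
                    row[f"d_{c.split('_')[0]}_dev_censored"] = bool(
                        earlier[cens]
                    ) or bool(later[cens])
            for c in carry:
                row[c] = earlier[c]
            out_rows.append(row)
    return pd.DataFrame(out_rows)


def fit_intervisit(diff_table: pd.DataFrame, spec: ModelSpec | None = None,
                   **kwargs) -> ModelResult:
    """Fit the inter-visit change model on a difference table."""
    if spec is None:
        spec = ModelSpec(kind="intervisit", **kwargs)
    if spec.kind != "intervisit":
        raise ValueError("spec.kind must be 'intervisit'")
    return _fit(diff_table, spec)
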