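"""Quadratic linear mixed models for heterogeneity-diversity relationships.

The response is the per-observation log response ratio (lnRR); standardized
heterogeneity enters as a fixed quadratic term (x, x²), with the HDR-level
coefficient of variation and any requested moderators as covariates.  The
random structure is fixed across all models: a correlated study-level
intercept and slope on x, plus an HDR-level intercept nested in study.

Model selection follows the convention of pruning candidate interaction
terms by backward elimination under ML (variance structure comparable across
nested fixed-effect models), then refitting the final model by REML for
inference.  Wald t statistics use residual degrees of freedom
(n_obs - n_fixed); the df method is recorded in the results metadata.

The public surface mirrors statsmodels: build an :class:`HDRModel` from a
design frame (or HDR groups), call :meth:`~HDRModel.fit`, and read
estimates, variance components, R², shape and diagnostics off the returned
:class:`HDRModelResults`.
"""

from __future__ import annotations

import contextlib
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .datatypes import OTHER_POOLED, POOLABLE_FACETS, HDRGroup
from .exceptions import ConfigurationError, ModelFitError

_Z975 = stats.norm.ppf(0.975)

# ---------------------------------------------------------------------------
# specification


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect specification for one HDR model.

    ``moderators`` are main-effect terms (column names in the design frame);
    ``interactions`` are candidate product terms (``"a:b"``) subject to
    backward elimination.  x and x² are always present and never pruned, as
    is every main effect.  The random structure is not configurable: study
    intercept + slope on x (correlated) and HDR intercept nested in study.
    """

    moderators: tuple[str, ...] = ()
    interactions: tuple[str, ...] = ()
    alpha: float = 0.05

    def formula(self) -> str:
        terms = ["x", "x2", *self.moderators, *self.interactions]
        return "lnrr ~ " + " + ".join(terms)


@dataclass
class ShapeClass:
    """Qualitative form of the fitted heterogeneity response curve."""

    value: str  # flat | linear_increasing | linear_decreasing | saturating | hump | u_shaped
    vertex: Optional[float] = None


@dataclass
class PruneStep:
    term: str
    p_value: float
    step: int


@dataclass
class DesignLog:
    n_input_rows: int = 0
    n_rows: int = 0
    n_dropped_missing: int = 0
    dropped_terms: list[tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# design construction

#: frame columns always carried when available
_CONTEXT_COLUMNS = (
    "het_cv", "facet", "facet_pooled", "organismal_group", "response_metric",
    "n_species", "latitude_abs", "latitude_c", "depth_zone", "season",
    "substrate_type", "sample_size", "pub_year",
)


def _term_variables(term: str) -> list[str]:
    return [v.strip() for v in term.split(":")]


def build_design(
    groups: Sequence[HDRGroup],
    spec: Optional[ModelSpec] = None,
) -> tuple[pd.DataFrame, DesignLog]:
    """One row per usable observation, with model and context columns.

    Rows whose lnRR is NaN (excluded zero responses) or that lack a value
    for any variable the spec requests are removed listwise and counted in
    the log.  ``latitude_c`` is latitude centred at the estimation-sample
    mean; categorical columns are plain strings, coded by patsy as treatment
    contrasts with the alphabetically first level as reference.
    """
    spec = spec or ModelSpec()
    rows = []
    for g in groups:
        if g.het_standardized is None or g.lnrr is None:
            raise ConfigurationError(
                f"group {g.hdr_id} must be standardized and effect-sized first"
            )
        for o, x, r in zip(g.observations, g.het_standardized, g.lnrr):
            rows.append({
                "lnrr": r,
                "x": float(x),
                "x2": float(x) ** 2,
                "study": g.study_id,
                "hdr": g.hdr_id,
                "het_cv": g.het_cv,
                "facet": o.facet,
                "facet_pooled": OTHER_POOLED if o.facet in POOLABLE_FACETS else o.facet,
                "organismal_group": o.organismal_group,
                "response_metric": o.response_metric,
                "n_species": o.n_species,
                "latitude_abs": o.latitude_abs,
                "depth_zone": o.depth_zone,
                "season": o.season,
                "substrate_type": o.substrate_type,
                "sample_size": o.sample_size,
                "pub_year": o.pub_year,
            })
    frame = pd.DataFrame(rows)
    log = DesignLog(n_input_rows=len(frame))
    if frame.empty:
        log.n_rows = 0
        return frame, log

    needed = {"lnrr", "x", "x2"}
    for term in list(spec.moderators) + list(spec.interactions):
        for v in _term_variables(term):
            if v in ("x", "x2"):
                continue
            src = "latitude_abs" if v == "latitude_c" else v
            if src not in frame.columns:
                raise ConfigurationError(f"requested moderator {v!r} is unknown")
            if frame[src].isna().all():
                raise ConfigurationError(f"requested moderator {v!r} is entirely missing")
            needed.add(src)

    mask = frame[sorted(needed)].notna().all(axis=1)
    log.n_dropped_missing = int((~mask).sum())
    frame = frame.loc[mask].reset_index(drop=True)
    if "latitude_abs" in frame.columns and frame["latitude_abs"].notna().any():
        frame["latitude_c"] = frame["latitude_abs"] - frame["latitude_abs"].mean()
    log.n_rows = len(frame)
    return frame, log


# ---------------------------------------------------------------------------
# model and results


class HDRModel:
    """Mixed model for one heterogeneity-diversity relationship stratum.

    Parameters
    ----------
    frame : DataFrame
        Design frame from :func:`build_design` (columns ``lnrr``, ``x``,
        ``x2``, ``study``, ``hdr`` plus moderators).
    spec : ModelSpec, optional
        Fixed-effect specification; defaults to the bare quadratic model.

    Examples
    --------
    >>> model = HDRModel.from_groups(groups, ModelSpec(moderators=("het_cv",),
    ...                                                interactions=("x:het_cv",)))
    >>> res = model.fit()
    >>> res.beta1, res.shape.value       # doctest: +SKIP
    """

    def __init__(self, frame: pd.DataFrame, spec: Optional[ModelSpec] = None):
        self.spec = spec or ModelSpec()
        self.frame = frame
        self.design_log: Optional[DesignLog] = None

    @classmethod
    def from_groups(cls, groups: Sequence[HDRGroup],
                    spec: Optional[ModelSpec] = None) -> "HDRModel":
        model = cls.__new__(cls)
        model.spec = spec or ModelSpec()
        model.frame, model.design_log = build_design(groups, model.spec)
        return model

    # -- fitting ------------------------------------------------------------

    def fit(self, prune: bool = True, reml: bool = True) -> "HDRModelResults":
        """Prune candidate interactions (ML), then fit the final model (REML)."""
        frame = self.frame
        if frame is None or len(frame) == 0:
            raise ModelFitError("empty design frame")
        n_study = frame["study"].nunique()
        n_hdr = frame["hdr"].nunique()
        if n_study < 2:
            raise ModelFitError(
                f"insufficient grouping levels: {n_study} study (need >= 2)"
            )
        if n_hdr < 3:
            raise ModelFitError(
                f"insufficient grouping levels: {n_hdr} HDR groups (need >= 3)"
            )

        spec, degenerate = _drop_degenerate_factors(self.spec, frame)
        audit: list[PruneStep] = []
        if prune and spec.interactions:
            spec, audit = prune_interactions(frame, spec)

        smres, fit_warnings, converged = _fit_mixedlm(spec.formula(), frame, reml=reml)
        return HDRModelResults(
            model=self, spec=spec, smres=smres, frame=frame,
            audit_trail=audit, dropped_terms=degenerate,
            warnings=fit_warnings, converged=converged, reml=reml,
        )


def _drop_degenerate_factors(spec: ModelSpec, frame: pd.DataFrame):
    """Remove moderators with a single observed level (and their interactions)."""
    dropped = []
    moderators = []
    for m in spec.moderators:
        col = frame[m]
        if not pd.api.types.is_numeric_dtype(col) and col.nunique() < 2:
            dropped.append((m, "single observed level"))
        else:
            moderators.append(m)
    bad = {m for m, _ in dropped}
    interactions = tuple(
        t for t in spec.interactions if not (set(_term_variables(t)) & bad)
    )
    for t in spec.interactions:
        if t not in interactions:
            dropped.append((t, "involves degenerate factor"))
    return replace(spec, moderators=tuple(moderators), interactions=interactions), dropped


@contextlib.contextmanager
def _pinv_fallback():
    """Let a singular matrix inversion fall back to the Moore-Penrose
    pseudo-inverse (needed only for the post-fit covariance of boundary
    optima, where the Hessian is exactly singular)."""
    orig = np.linalg.inv

    def safe_inv(a, *args, **kwargs):
        try:
            return orig(a, *args, **kwargs)
        except np.linalg.LinAlgError:
            return np.linalg.pinv(a)

    np.linalg.inv = safe_inv
    try:
        yield
    finally:
        np.linalg.inv = orig


def _fit_mixedlm(formula: str, frame: pd.DataFrame, reml: bool):
    """Fit one MixedLM with the fixed random structure, retrying optimizers."""
    md = sm.MixedLM.from_formula(
        formula, data=frame, groups=frame["study"],
        re_formula="~x", vc_formula={"hdr": "0 + C(hdr)"},
    )
    messages: list[str] = []
    best = None

    def attempt(method, start=None):
        nonlocal best
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                res = md.fit(reml=reml, method=method, maxiter=500,
                             start_params=start)
            except np.linalg.LinAlgError:
                # exactly singular Hessian at a boundary optimum: retry with
                # a generalized inverse for the covariance step
                try:
                    with _pinv_fallback():
                        res = md.fit(reml=reml, method=method, maxiter=500,
                                     start_params=start)
                    messages.append(
                        f"{method}: singular Hessian; pseudo-inverse covariance")
                except (np.linalg.LinAlgError, ValueError) as e:
                    messages.append(f"{method}: {e}")
                    return None
            except ValueError as e:  # singular step etc.
                messages.append(f"{method}: {e}")
                return None
        messages.extend(
            f"{method}: {w.message}" for w in caught
            if issubclass(w.category, (ConvergenceWarning, RuntimeWarning, UserWarning)))
        if best is None:
            best = res
        return res

    # lbfgs first; when its convergence flag trips at a variance boundary,
    # polish with powell from the lbfgs solution; then fresh powell / cg
    res = attempt("lbfgs")
    if res is not None:
        if res.converged:
            return res, messages, True
        polished = attempt("powell", start=res.params_object)
        if polished is not None and polished.converged:
            return polished, messages, True
    for method in ("powell", "cg"):
        res = attempt(method)
        if res is not None and res.converged:
            return res, messages, True
    if best is None:
        raise ModelFitError(f"mixed-model fit failed: {messages}")
    return best, messages + ["no optimizer reported convergence"], False


# -- interaction pruning -----------------------------------------------------


def prune_interactions(
    frame: pd.DataFrame,
    spec: ModelSpec,
) -> tuple[ModelSpec, list[PruneStep]]:
    """Backward-eliminate candidate interactions under ML.

    Iteratively refits, finds the interaction with the largest joint Wald
    p-value above ``spec.alpha``, removes it, and repeats.  Main effects and
    the x/x² terms are never candidates.  Returns the pruned spec and the
    audit trail of removals.
    """
    current = spec
    audit: list[PruneStep] = []
    step = 0
    while current.interactions:
        smres, _, converged = _fit_mixedlm(current.formula(), frame, reml=False)
        pvals = {}
        for term in current.interactions:
            pvals[term] = _joint_wald_p(smres, term)
        worst = max(pvals, key=lambda t: pvals[t])
        if pvals[worst] > current.alpha:
            step += 1
            audit.append(PruneStep(term=worst, p_value=float(pvals[worst]), step=step))
            current = replace(
                current,
                interactions=tuple(t for t in current.interactions if t != worst),
            )
        else:
            break
    return current, audit


def _fe_cov(smres) -> np.ndarray:
    k = len(smres.fe_params)
    cov = np.asarray(smres.cov_params())[:k, :k]
    return cov


def _term_slice(smres, term: str) -> slice:
    design_info = smres.model.data.design_info
    try:
        return design_info.term_name_slices[term]
    except KeyError:
        raise ConfigurationError(
            f"term {term!r} not in design ({list(design_info.term_name_slices)})"
        )


def _joint_wald_p(smres, term: str) -> float:
    sl = _term_slice(smres, term)
    beta = np.asarray(smres.fe_params)[sl]
    V = _fe_cov(smres)[sl, sl]
    try:
        W = float(beta @ np.linalg.solve(V, beta))
    except np.linalg.LinAlgError:
        return 1.0
    return float(stats.chi2.sf(W, df=len(beta)))


# -- results ----------------------------------------------------------------


class HDRModelResults:
    """Estimates, uncertainties and diagnostics for one fitted HDR model.

    Wald t-tests per coefficient use residual df (n_obs - n_fixed_terms);
    ``df_method`` records this.  Variance components are reported on the
    response scale.  ``shape`` classifies the fitted quadratic into
    flat / linear / saturating / hump / u-shaped forms.
    """

    df_method = "residual"

    def __init__(self, model, spec, smres, frame, audit_trail, dropped_terms,
                 warnings, converged, reml):
        self.model = model
        self.spec = spec
        self._smres = smres
        self.frame = frame
        self.audit_trail = audit_trail
        self.dropped_terms = dropped_terms
        self.fit_warnings = list(warnings)
        self.converged = converged
        self.reml = reml

        self.n_obs = len(frame)
        self.n_hdr = frame["hdr"].nunique()
        self.n_study = frame["study"].nunique()

        fe = smres.fe_params
        self._fe_names = list(fe.index)
        k = len(fe)
        self.df_resid = self.n_obs - k
        se = np.asarray(smres.bse_fe)
        est = np.asarray(fe)
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = np.where(se > 0, est / se, np.where(est == 0, 0.0, np.inf))
        pval = 2 * stats.t.sf(np.abs(tval), df=self.df_resid)
        self.params = pd.DataFrame({
            "term": self._fe_names, "estimate": est, "se": se,
            "tvalue": tval, "df": self.df_resid, "pvalue": pval,
        }).set_index("term")

        cov_re = np.asarray(smres.cov_re)
        vcomp = np.asarray(smres.vcomp)
        self.variance_components = {
            "study_intercept_var": float(cov_re[0, 0]),
            "study_slope_var": float(cov_re[1, 1]) if cov_re.shape[0] > 1 else 0.0,
            "study_intercept_slope_cov": float(cov_re[0, 1]) if cov_re.shape[0] > 1 else 0.0,
            "hdr_intercept_var": float(vcomp[0]) if vcomp.size else 0.0,
            "residual_var": float(smres.scale),
        }
        self.singular = (
            min(self.variance_components["study_intercept_var"],
                self.variance_components["study_slope_var"],
                self.variance_components["hdr_intercept_var"]) < 1e-10
        )
        self.r2_marginal, self.r2_conditional = r2_nakagawa(self)
        self.shape = classify_shape(self.beta1, self.beta2,
                                    self.p_value("x"), self.p_value("x2"),
                                    alpha=spec.alpha)

    # -- convenience accessors ----------------------------------------------

    def coef(self, term: str) -> float:
        return float(self.params.loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.params.loc[term, "se"])

    def p_value(self, term: str) -> float:
        return float(self.params.loc[term, "pvalue"])

    @property
    def beta1(self) -> float:
        return self.coef("x")

    @property
    def beta2(self) -> float:
        return self.coef("x2")

    def conf_int(self, term: str, level: float = 0.95) -> tuple[float, float]:
        q = stats.t.ppf(0.5 + level / 2, df=self.df_resid)
        e, s = self.coef(term), self.se(term)
        return (e - q * s, e + q * s)

    @property
    def fe_cov(self) -> np.ndarray:
        return _fe_cov(self._smres)

    # -- prediction and contrasts -------------------------------------------

    def _default_profile(self) -> dict:
        """Reference levels for categoricals, estimation means for continuous."""
        profile = {}
        for term in self.spec.moderators:
            col = self.frame[term]
            if pd.api.types.is_numeric_dtype(col):
                profile[term] = float(col.mean())
            else:
                profile[term] = sorted(col.dropna().unique())[0]
        return profile

    def _design_rows(self, data: pd.DataFrame) -> np.ndarray:
        design_info = self._smres.model.data.design_info
        (X,) = patsy.build_design_matrices([design_info], data)
        return np.asarray(X)

    def predict_curve(
        self,
        x_grid: Sequence[float],
        moderator_profile: Optional[Mapping] = None,
    ) -> pd.DataFrame:
        """Fixed-effect prediction on a grid in [0, 1] with delta-method 95% CI.

        Moderators default to reference levels (categorical) or estimation
        -sample means (continuous); extrapolation beyond the standardized
        range is refused.
        """
        x = np.asarray(x_grid, dtype=float)
        if np.any((x < 0) | (x > 1)):
            raise ConfigurationError("x grid must lie within [0, 1]")
        profile = self._default_profile()
        profile.update(moderator_profile or {})
        data = pd.DataFrame({"x": x, "x2": x ** 2})
        for kcol, v in profile.items():
            data[kcol] = v
        X = self._design_rows(data)
        fe = np.asarray(self._smres.fe_params)
        pred = X @ fe
        var = np.einsum("ij,jk,ik->i", X, self.fe_cov, X)
        se = np.sqrt(np.clip(var, 0, None))
        return pd.DataFrame({
            "x": x, "predicted": pred,
            "ci_low": pred - _Z975 * se, "ci_high": pred + _Z975 * se,
        })

    def pairwise_contrasts(self, factor: str) -> pd.DataFrame:
        """All pairwise Wald contrasts of factor levels at mean x, Holm-adjusted.

        Returns a table with one row per level pair (estimate, se, t, p,
        p_holm) plus a ``letters`` compact letter display column mapping via
        the ``cld`` attribute of the frame (levels sharing a letter do not
        differ at alpha).
        """
        if factor not in self.frame.columns:
            raise ConfigurationError(f"factor {factor!r} not in design frame")
        levels = sorted(self.frame[factor].dropna().unique())
        if len(levels) < 2:
            out = pd.DataFrame(columns=["level_a", "level_b", "estimate", "se",
                                        "tvalue", "pvalue", "p_holm"])
            out.attrs["cld"] = {}
            return out
        profile = self._default_profile()
        mean_x = float(self.frame["x"].mean())
        data = pd.DataFrame({"x": mean_x, "x2": mean_x ** 2,
                             factor: levels})
        for kcol, v in profile.items():
            if kcol != factor:
                data[kcol] = v
        X = self._design_rows(data)
        fe = np.asarray(self._smres.fe_params)
        cov = self.fe_cov
        rows = []
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                d = X[i] - X[j]
                est = float(d @ fe)
                var = float(d @ cov @ d)
                se = np.sqrt(max(var, 0.0))
                if se == 0:
                    tval, p = (0.0, 1.0) if est == 0 else (np.inf, 0.0)
                else:
                    tval = est / se
                    p = float(2 * stats.t.sf(abs(tval), df=self.df_resid))
                rows.append({"level_a": levels[i], "level_b": levels[j],
                             "estimate": est, "se": se, "tvalue": tval,
                             "pvalue": p})
        out = pd.DataFrame(rows)
        out["p_holm"] = multipletests(out["pvalue"], method="holm")[1]
        est_by_level = {lev: float(X[i] @ fe) for i, lev in enumerate(levels)}
        sig = {
            (r.level_a, r.level_b): r.p_holm <= self.spec.alpha
            for r in out.itertuples()
        }
        out.attrs["cld"] = compact_letters(levels, est_by_level, sig)
        return out

    # -- reporting ----------------------------------------------------------

    def metadata(self) -> dict:
        """Structured sidecar: spec, estimation, df method, variance
        components, R², shape, convergence, audit trail."""
        return {
            "formula": self.spec.formula(),
            "moderators": list(self.spec.moderators),
            "interactions": list(self.spec.interactions),
            "alpha": self.spec.alpha,
            "estimation": "REML" if self.reml else "ML",
            "df_method": self.df_method,
            "converged": self.converged,
            "singular": self.singular,
            "n_obs": self.n_obs, "n_hdr": self.n_hdr, "n_study": self.n_study,
            "variance_components": self.variance_components,
            "r2_marginal": self.r2_marginal,
            "r2_conditional": self.r2_conditional,
            "shape": self.shape.value,
            "vertex": self.shape.vertex,
            "pruned": [{"term": s.term, "p_value": s.p_value, "step": s.step}
                       for s in self.audit_trail],
            "dropped_terms": [list(t) for t in self.dropped_terms],
            "fit_warnings": self.fit_warnings,
        }

    def save(self, path_prefix) -> None:
        """Write the coefficient table as CSV and the metadata sidecar as JSON
        (``<prefix>_coefficients.csv`` / ``<prefix>_metadata.json``)."""
        import json

        self.params.to_csv(f"{path_prefix}_coefficients.csv")
        with open(f"{path_prefix}_metadata.json", "w") as fh:
            json.dump(self.metadata(), fh, indent=2)

    def summary(self) -> str:
        """Human-readable fit summary (coefficients, variances, R², shape)."""
        lines = [
            "HDR quadratic mixed model",
            f"  formula:   {self.spec.formula()}",
            f"  estimation: {'REML' if self.reml else 'ML'}; "
            f"df method: {self.df_method}; converged: {self.converged}",
            f"  n_obs={self.n_obs}  n_hdr={self.n_hdr}  n_study={self.n_study}",
            "",
            self.params.to_string(float_format=lambda v: f"{v: .4f}"),
            "",
            "Variance components:",
        ]
        for kname, v in self.variance_components.items():
            lines.append(f"  {kname:28s} {v: .5f}")
        lines += [
            "",
            f"R2 marginal = {self.r2_marginal:.4f}   "
            f"R2 conditional = {self.r2_conditional:.4f}",
            f"shape: {self.shape.value}"
            + (f" (vertex at x = {self.shape.vertex:.3f})"
               if self.shape.vertex is not None else ""),
        ]
        if self.audit_trail:
            lines.append("Pruned interactions:")
            for s in self.audit_trail:
                lines.append(f"  step {s.step}: removed {s.term} (p = {s.p_value:.3f})")
        if self.dropped_terms:
            lines.append("Dropped terms: " +
                         ", ".join(f"{t} ({r})" for t, r in self.dropped_terms))
        if self.singular:
            lines.append("note: at least one variance component is at the boundary")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# derived quantities


def r2_from_components(var_fixed: float, var_random: float,
                       var_residual: float) -> tuple[float, float]:
    """Marginal and conditional R² from variance components."""
    denom = var_fixed + var_random + var_residual
    if denom == 0:
        warnings.warn("all variance components are zero; R² defined as 0")
        return 0.0, 0.0
    return var_fixed / denom, (var_fixed + var_random) / denom


def r2_nakagawa(fit: HDRModelResults) -> tuple[float, float]:
    """Variance explained by fixed effects (marginal) and fixed+random
    (conditional).

    The fixed-effect variance is the variance of the fixed linear predictor
    over the estimation sample.  The random-effect total evaluates the study
    intercept+slope structure at the sample's x distribution
    (τ00 + 2·τ01·mean(x) + τ11·mean(x²)) and adds the HDR intercept
    variance; a negative total (possible with strongly negative covariance)
    is clipped at zero.
    """
    smres = fit._smres
    X = smres.model.exog
    fe = np.asarray(smres.fe_params)
    var_fixed = float(np.var(X @ fe))
    vc = fit.variance_components
    x = fit.frame["x"].to_numpy()
    var_random = (
        vc["study_intercept_var"]
        + 2 * vc["study_intercept_slope_cov"] * x.mean()
        + vc["study_slope_var"] * np.mean(x ** 2)
        + vc["hdr_intercept_var"]
    )
    var_random = max(var_random, 0.0)
    return r2_from_components(var_fixed, var_random, vc["residual_var"])


def classify_shape(beta1: float, beta2: float, p1: float, p2: float,
                   alpha: float = 0.05) -> ShapeClass:
    """Classify the fitted quadratic lnRR ~ β1·x + β2·x² curve.

    Non-significant quadratic: flat / linear_increasing / linear_decreasing
    by the linear term.  Significant concave quadratic: vertex
    x* = -β1/(2β2); hump when the peak falls strictly inside the gradient
    (0 < x* < 1), saturating when it sits at or beyond the top (x* >= 1),
    linear_decreasing when x* <= 0 (declining throughout).  Significant
    convex quadratic: u_shaped.
    """
    if p2 > alpha:
        if p1 > alpha:
            return ShapeClass("flat")
        return ShapeClass("linear_increasing" if beta1 > 0 else "linear_decreasing")
    if beta2 == 0:
        raise ValueError("significant quadratic term with beta2 == 0")
    vertex = -beta1 / (2.0 * beta2)
    if beta2 > 0:
        return ShapeClass("u_shaped", vertex=vertex)
    if vertex >= 1.0:
        return ShapeClass("saturating", vertex=vertex)
    if vertex <= 0.0:
        return ShapeClass("linear_decreasing", vertex=vertex)
    return ShapeClass("hump", vertex=vertex)


def compact_letters(
    levels: Sequence[str],
    estimates: Mapping[str, float],
    significant: Mapping[tuple[str, str], bool],
) -> dict[str, str]:
    """Compact letter display: levels sharing a letter are not significantly
    different.

    Levels are ordered by estimate; letters are assigned to maximal runs
    containing no significant pair.
    """
    order = sorted(levels, key=lambda l: estimates[l])

    def sig(a: str, b: str) -> bool:
        return significant.get((a, b), significant.get((b, a), False))

    n = len(order)
    runs: list[tuple[int, int]] = []
    for i in range(n):
        j = i
        while j + 1 < n and not any(sig(order[a], order[j + 1]) for a in range(i, j + 1)):
            j += 1
        if not runs or j > runs[-1][1]:  # keep only maximal intervals
            runs.append((i, j))
    letters = {lev: "" for lev in order}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for rix, (a, b) in enumerate(runs):
        for kix in range(a, b + 1):
            letters[order[kix]] += alphabet[rix % len(alphabet)]
    return letters
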