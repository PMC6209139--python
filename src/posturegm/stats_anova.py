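"""Mixed-model ANOVA of PC scores and the method-comparison harness.

Each photograph contributes one score per principal component, and the
same horse appears in many photographs, so the effect of a horse-level
factor (riding school, equid type, body proportions, age, sex) on a PC
is tested with a linear mixed model: a fixed effect for the factor and
a random intercept per horse, fitted by restricted maximum likelihood.
The factor's F statistic is the Wald quadratic form on its fixed-effect
coefficients; the denominator degrees of freedom follow the containment
rule for a horse-level factor, n_horses − df_num − 1.  Significance is
read at the 5% level and no multiplicity correction is applied (a flag
exists for one).

The harness runs several geometric-morphometric method variants —
point scheme × outline subset × with/without neck derotation — on the
same photographs, each through superimposition, sliding (when the
scheme has semilandmarks), PCA and the per-PC mixed ANOVA, and tabulates
F and p per (method, context, PC, factor).  Larger F for the same
factor means the method separates the populations more sharply.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .io_formats import PointScheme, load_scheme
from .semilandmarks import slide_until_converged
from .shape_space import retained_components, shape_pca
from .superimposition import derotate_sample, gpa
from .synthetic import SimulatedDataset

__all__ = ["AnovaResult", "MethodComparisonTable", "MethodVariant",
           "standard_variants", "fit_mixed_anova",
           "method_comparison_table", "identity_parameter_table",
           "pearson_r", "run_variant_pipeline"]

logger = logging.getLogger(__name__)

TABLE_COLUMNS = ("method", "context", "pc", "factor", "F", "p",
                 "df_num", "df_den", "n_obs", "n_individuals")


@dataclass
class AnovaResult:
    """F test of one fixed factor on one PC's scores."""

    factor: str
    pc: int                 # 1-based, as printed
    F: float
    p: float
    df_num: float
    df_den: float
    n_obs: int
    n_individuals: int
    warning: str | None = None


def fit_mixed_anova(scores, metadata: pd.DataFrame, fixed_factor: str,
                    random_factor: str = "horse_id", pc: int = 1,
                    method: str = "reml") -> AnovaResult:
    """Mixed ANOVA of per-photograph scores with a random individual.

    Parameters
    ----------
    scores : per-photograph values, aligned with ``metadata`` rows.
    fixed_factor : metadata column; categorical columns enter as
        treatment-coded dummies (df_num = levels − 1), numeric columns
        (age) as a single-df covariate.
    method : "reml" fits the random-intercept model by restricted
        likelihood and takes a Wald F on the factor's coefficients;
        "horse_means" is the cross-check mode — a one-way ANOVA (or OLS
        slope test for a numeric factor) on per-horse mean scores.
    """
    y = np.asarray(scores, float)
    if len(y) != len(metadata):
        raise ValueError("scores and metadata length mismatch")
    fac = metadata[fixed_factor]
    groups = metadata[random_factor].to_numpy()
    n_ind = len(pd.unique(groups))
    numeric = pd.api.types.is_numeric_dtype(fac)
    if numeric:
        x = fac.to_numpy(float)
        if np.ptp(x) == 0:
            raise ValueError(f"factor {fixed_factor!r} is constant")
        X = np.column_stack([np.ones_like(x), x])
        df_num = 1.0
    else:
        levels = pd.unique(fac)
        if len(levels) < 2:
            raise ValueError(f"factor {fixed_factor!r} has a single level")
        dummies = pd.get_dummies(fac, drop_first=True).to_numpy(float)
        X = np.column_stack([np.ones(len(y)), dummies])
        df_num = float(len(levels) - 1)
        per_level = metadata.groupby(fixed_factor, observed=True)[
            random_factor].nunique()
        if (per_level < 2).any():
            logger.warning("factor %s: level(s) %s have < 2 individuals",
                           fixed_factor,
                           list(per_level.index[per_level < 2]))
    df_den = n_ind - df_num - 1
    if df_den < 1:
        raise ValueError(
            f"singular fit: {n_ind} individuals cannot support "
            f"{int(df_num) + 1} between-individual parameters")

    if method == "reml":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=groups)
            res = model.fit(reml=True)
        beta = res.fe_params[1:]
        V = np.asarray(res.cov_params())[1:X.shape[1], 1:X.shape[1]]
        F = float(beta @ np.linalg.solve(V, beta) / df_num)
    elif method == "horse_means":
        tab = pd.DataFrame({"y": y, "g": groups,
                            "x": fac.to_numpy()}).groupby("g").agg(
            y=("y", "mean"), x=("x", "first"))
        if numeric:
            slope = sps.linregress(tab["x"].astype(float), tab["y"])
            F = float(slope.rvalue ** 2 / (1 - slope.rvalue ** 2) * df_den)
        else:
            groups_means = [v["y"].to_numpy()
                            for _, v in tab.groupby("x", observed=True)]
            F = float(sps.f_oneway(*groups_means).statistic)
    else:
        raise ValueError("method must be 'reml' or 'horse_means'")
    p = float(sps.f.sf(F, df_num, df_den))
    return AnovaResult(factor=fixed_factor, pc=pc, F=F, p=p,
                       df_num=df_num, df_den=float(df_den),
                       n_obs=len(y), n_individuals=n_ind)


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length samples of n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has no defined correlation")
    return float(sps.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# method variants and the comparison harness
# ---------------------------------------------------------------------------

@dataclass
class MethodVariant:
    """One GM analysis route: scheme × outline subset × derotation."""

    name: str
    scheme: PointScheme
    subset: str | None = None       # named subset of the scheme, or all
    derotate: bool = False


def standard_variants() -> list[MethodVariant]:
    """The nine standard method rows of the comparison tables.

    The 9-landmark route, then the semilandmark (ssl) and mixed schemes
    each on the full dorsum, the derotated dorsum, the croup+back and
    the neck+head subsets.
    """
    lm = load_scheme("landmarks")
    ssl = load_scheme("ssl")
    mixed = load_scheme("mixed")
    out = [MethodVariant("landmarks", lm)]
    for label, scheme in (("ssl", ssl), ("mixed", mixed)):
        out += [
            MethodVariant(f"{label}_dorsum", scheme),
            MethodVariant(f"{label}_dorsum_derotated", scheme,
                          derotate=True),
            MethodVariant(f"{label}_croup_back", scheme,
                          subset="croup_back"),
            MethodVariant(f"{label}_neck_head", scheme,
                          subset="neck_head"),
        ]
    return out


@dataclass
class MethodComparisonTable:
    """F/p rows keyed by (method, context, pc, factor)."""

    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=list(TABLE_COLUMNS)))

    def __post_init__(self) -> None:
        missing = [c for c in TABLE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"table missing column(s): {missing}")

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.10g")


def run_variant_pipeline(configs, variant: MethodVariant,
                         slide_tol: float = 1e-6,
                         slide_max_iter: int = 10):
    """Derotate? → subset/active points → GPA (+ sliding) → shape PCA.

    Returns ``(ShapePCA, AlignedEnsemble)`` for the variant.  Derotation
    (when requested) acts on the raw full configurations, before any
    point subsetting, so the fixed angle is measured on the anatomical
    triple; the effective scheme is then restricted to the variant's
    subset and to the method's active points.
    """
    scheme = variant.scheme
    if variant.derotate:
        configs, _ref = derotate_sample(configs, scheme)
    pts = np.stack([c.points if hasattr(c, "points") else np.asarray(c)
                    for c in configs])
    eff = scheme
    if variant.subset is not None:
        eff = scheme.restrict(variant.subset)
        pts = pts[:, scheme.subsets[variant.subset], :]
    if eff.active is not None:
        idx = eff.active
        pts = pts[:, idx, :]
        eff = eff.restrict(idx)
    if eff.n_sliders > 0:
        result = slide_until_converged(pts, eff, tol=slide_tol,
                                       max_iter=slide_max_iter)
        ensemble = result.ensemble
    else:
        ensemble = gpa(pts)
    return shape_pca(ensemble), ensemble


def _anova_rows(pca, meta: pd.DataFrame, mask: np.ndarray, factors,
                variant_name: str, context: str, threshold: float,
                anova_method: str) -> list[dict]:
    rows = []
    sub_meta = meta.loc[mask].reset_index(drop=True)
    kept = retained_components(pca, threshold_percent=threshold,
                               max_components=3)
    for factor in factors:
        fac = sub_meta[factor]
        constant = (np.ptp(fac.to_numpy(float)) == 0
                    if pd.api.types.is_numeric_dtype(fac)
                    else fac.nunique() < 2)
        for j in kept:
            row = dict(method=variant_name, context=context, pc=j + 1,
                       factor=factor)
            if constant:
                logger.warning("skipping constant factor %r (%s, %s)",
                               factor, variant_name, context)
                row.update(F=np.nan, p=np.nan, df_num=np.nan,
                           df_den=np.nan, n_obs=int(mask.sum()),
                           n_individuals=sub_meta["horse_id"].nunique(),
                           note="constant factor")
            else:
                try:
                    res = fit_mixed_anova(pca.scores[mask, j], sub_meta,
                                          factor, pc=j + 1,
                                          method=anova_method)
                    row.update(F=res.F, p=res.p, df_num=res.df_num,
                               df_den=res.df_den, n_obs=res.n_obs,
                               n_individuals=res.n_individuals, note="")
                except Exception as exc:  # diagnostic row, table survives
                    logger.warning("ANOVA failed for %s/%s/PC%d: %s",
                                   variant_name, factor, j + 1, exc)
                    row.update(F=np.nan, p=np.nan, df_num=np.nan,
                               df_den=np.nan, n_obs=int(mask.sum()),
                               n_individuals=sub_meta["horse_id"].nunique(),
                               note=f"failed: {exc}")
            rows.append(row)
    return rows


def method_comparison_table(configs, metadata: pd.DataFrame | None = None,
                            variants: list[MethodVariant] | None = None,
                            factor: str = "school",
                            threshold_percent: float = 10.0,
                            anova_method: str = "reml",
                            contexts=("standing", "walking"),
                            slide_tol: float = 1e-6,
                            slide_max_iter: int = 10
                            ) -> MethodComparisonTable:
    """F/p of one grouping factor for every method variant × context × PC.

    Photographs are split by context first; each variant's
    superimposition, sliding and PCA run per context (derotation uses
    the pooled mean angle, computed before the split).  The retained
    PCs (≥ ``threshold_percent`` of variance, at most three) are each
    tested with the mixed ANOVA.
    """
    if variants is None:
        variants = standard_variants()
    if isinstance(configs, SimulatedDataset):
        configs, metadata = configs.configs, configs.metadata
    metadata = metadata.reset_index(drop=True)
    rows: list[dict] = []
    for variant in variants:
        for context in contexts:
            mask = (metadata["context"] == context).to_numpy()
            if not mask.any():
                continue
            sub = [c for c, m in zip(configs, mask) if m]
            try:
                pca, _ = run_variant_pipeline(
                    sub, variant, slide_tol=slide_tol,
                    slide_max_iter=slide_max_iter)
            except Exception as exc:
                logger.warning("pipeline failed for %s/%s: %s",
                               variant.name, context, exc)
                rows.append(dict(method=variant.name, context=context,
                                 pc=np.nan, factor=factor, F=np.nan,
                                 p=np.nan, df_num=np.nan, df_den=np.nan,
                                 n_obs=int(mask.sum()),
                                 n_individuals=np.nan,
                                 note=f"pipeline failed: {exc}"))
                continue
            full_scores = np.full((len(metadata), pca.n_components),
                                  np.nan)
            full_scores[mask] = pca.scores
            pca_view = type(pca)(loadings=pca.loadings,
                                 scores=full_scores,
                                 percent_variance=pca.percent_variance,
                                 consensus=pca.consensus)
            rows += _anova_rows(pca_view, metadata, mask, [factor],
                                variant.name, context, threshold_percent,
                                anova_method)
    frame = pd.DataFrame(rows)
    for c in TABLE_COLUMNS:
        if c not in frame.columns:
            frame[c] = np.nan
    return MethodComparisonTable(frame=frame)


def identity_parameter_table(configs, metadata: pd.DataFrame | None,
                             variant: MethodVariant,
                             factors=("equid_type", "proportion", "age",
                                      "sex"),
                             threshold_percent: float = 10.0,
                             anova_method: str = "reml",
                             contexts=("standing", "walking")
                             ) -> MethodComparisonTable:
    """Identity-parameter ANOVAs for one method variant.

    One F/p row per factor × retained PC × context; age enters as a
    single-df continuous covariate.  Constant factors are skipped with
    a logged warning (the row is kept with a note).
    """
    if isinstance(configs, SimulatedDataset):
        configs, metadata = configs.configs, configs.metadata
    metadata = metadata.reset_index(drop=True)
    missing = [f for f in factors if f not in metadata.columns]
    if missing:
        raise ValueError(f"factor(s) not in metadata: {missing}")
    rows: list[dict] = []
    for context in contexts:
        mask = (metadata["context"] == context).to_numpy()
        if not mask.any():
            continue
        sub = [c for c, m in zip(configs, mask) if m]
        pca, _ = run_variant_pipeline(sub, variant)
        full_scores = np.full((len(metadata), pca.n_components), np.nan)
        full_scores[mask] = pca.scores
        pca_view = type(pca)(loadings=pca.loadings, scores=full_scores,
                             percent_variance=pca.percent_variance,
                             consensus=pca.consensus)
        rows += _anova_rows(pca_view, metadata, mask, list(factors),
                            variant.name, context, threshold_percent,
                            anova_method)
    frame = pd.DataFrame(rows)
    for c in TABLE_COLUMNS:
        if c not in frame.columns:
            frame[c] = np.nan
    return MethodComparisonTable(frame=frame)
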