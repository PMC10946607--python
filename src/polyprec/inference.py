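"""Model-based tests for the focal-male scores.

Covers the analysis battery run on the per-vial scores table:

* quasi-binomial GLM of the mating-order index and quasi-Poisson GLM of the
  repetitive-mating count on social composition (Hom/Het) x focal male size,
  controlling for average group fecundity, with type-II F tests on
  dispersion-scaled deviance differences;
* backward model selection on AIC (computed on the paired non-quasi fit,
  because quasi-likelihoods have no AIC; QAIC is available as an option);
* per-experiment linear models of paternity share with score x treatment
  interactions;
* the median-split summary of paternity share above/below each group's median
  mating-order index;
* Pearson correlation between mating order and repetitive matings
  (collinearity check) and the assortative-mating ANOVA;
* pairwise contrasts with Holm correction as the post-hoc procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, FittingError, NoDataError, SingularDesignError
from .records import Dataset
from .scoring import standardize

logger = logging.getLogger("polyprec")

__all__ = [
    "ModelTable",
    "MedianSplitSummary",
    "fit_order_glm",
    "fit_repeat_glm",
    "select_model",
    "interaction_models",
    "median_split",
    "order_repeat_correlation",
    "assortative_test",
    "pairwise_contrasts",
]


@dataclass
class ModelTable:
    """Term-level test table for one fitted model."""

    name: str
    family: str
    terms: pd.DataFrame  # columns: term, df_num, df_den, F, p
    dispersion: float
    nobs: int
    trace: list = field(default_factory=list)
    params: dict = field(default_factory=dict)  # full-model coefficients

    def __post_init__(self) -> None:
        t = self.terms
        if len(t) and ((t["p"] < 0) | (t["p"] > 1)).any():
            raise FittingError("p-values outside [0, 1]")
        if len(t) and (t["F"] < -1e-10).any():
            raise FittingError("negative F statistic")
        if self.dispersion <= 0:
            raise FittingError("non-positive dispersion estimate")

    def p_of(self, term: str) -> float:
        row = self.terms[self.terms["term"] == term]
        if row.empty:
            raise KeyError(term)
        return float(row["p"].iloc[0])

    def coef(self, pattern: str) -> float:
        """First full-model coefficient whose name contains ``pattern``."""
        for k, v in self.params.items():
            if pattern in k:
                return float(v)
        raise KeyError(pattern)

    def summary(self) -> str:
        lines = [
            f"{self.name}  ({self.family}, n = {self.nobs}, "
            f"dispersion = {self.dispersion:.3f})",
            "-" * 66,
            f"{'term':<34}{'F':>8}{'df':>10}{'p':>12}",
        ]
        for _, r in self.terms.iterrows():
            lines.append(
                f"{r['term']:<34}{r['F']:>8.3f}"
                f"{f'{int(r.df_num)},{int(r.df_den)}':>10}{r['p']:>12.4g}"
            )
        for step in self.trace:
            lines.append(f"  selection: {step}")
        return "\n".join(lines)


@dataclass(frozen=True)
class MedianSplitSummary:
    """Mean paternity share of vials on one side of a group's median order index."""

    group: str
    side: str  # "<= median" | "> median"
    mean_paternity_share: float
    se: float
    n: int


# ---------------------------------------------------------------------------
# quasi-GLM machinery


def _components(term: str) -> set[str]:
    return set(term.split(":"))


def _contains(term: str, other: str) -> bool:
    """True when ``term`` is an interaction strictly containing ``other``."""
    return term != other and _components(other) <= _components(term)


def _formula(response: str, terms: Sequence[str]) -> str:
    rhs = " + ".join(terms) if terms else "1"
    return f"{response} ~ {rhs}"


def _glm_deviance(data: pd.DataFrame, response: str, terms: Sequence[str], family):
    try:
        res = smf.glm(_formula(response, terms), data=data, family=family).fit()
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise FittingError(f"GLM fit failed for terms {list(terms)}: {exc}") from exc
    return res


def _quasi_term_tests(
    data: pd.DataFrame,
    response: str,
    terms: Sequence[str],
    family,
    name: str,
    family_label: str,
) -> ModelTable:
    y = data[response].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        raise FittingError(f"{response} is constant; nothing to model")
    full = _glm_deviance(data, response, terms, family)
    if full.df_resid <= 0:
        raise FittingError("no residual degrees of freedom")
    dispersion = float(full.pearson_chi2 / full.df_resid)
    if not np.isfinite(dispersion) or dispersion <= 0:
        raise FittingError(f"degenerate dispersion estimate {dispersion}")
    rows = []
    for term in terms:
        # type-II: compare models that both exclude interactions containing term;
        # dispersion and denominator df come from the larger model of each
        # comparison, so per-term dfs vary as in reported quasi-GLM tables
        base_terms = [t for t in terms if t != term and not _contains(t, term)]
        with_term = base_terms + [term]
        res_with = _glm_deviance(data, response, with_term, family)
        res_without = _glm_deviance(data, response, base_terms, family)
        df_num = res_without.df_resid - res_with.df_resid
        if df_num <= 0:
            raise FittingError(f"term {term!r} adds no degrees of freedom (degenerate cell)")
        phi = float(res_with.pearson_chi2 / res_with.df_resid)
        if not np.isfinite(phi) or phi <= 0:
            raise FittingError(f"degenerate dispersion estimate for term {term!r}")
        f_stat = max(0.0, (res_without.deviance - res_with.deviance) / df_num / phi)
        df_den = int(res_with.df_resid)
        rows.append(
            {
                "term": term,
                "df_num": int(df_num),
                "df_den": df_den,
                "F": f_stat,
                "p": float(st.f.sf(f_stat, df_num, df_den)),
            }
        )
    return ModelTable(
        name=name,
        family=family_label,
        terms=pd.DataFrame(rows),
        dispersion=dispersion,
        nobs=int(full.nobs),
        params=dict(full.params),
    )


def _design_terms(data: pd.DataFrame, covariate: str | None) -> list[str]:
    terms = []
    has_social = "social" in data.columns and data["social"].nunique() > 1
    has_size = "focal_size" in data.columns and data["focal_size"].nunique() > 1
    if has_social:
        terms.append("C(social)")
    if has_size:
        terms.append("C(focal_size)")
    if has_social and has_size:
        terms.append("C(social):C(focal_size)")
    if covariate:
        terms.append(covariate)
    if not terms:
        raise DegenerateInputError("no varying design factors to model")
    return terms


def fit_order_glm(
    scores: pd.DataFrame,
    covariate: str | None = "group_mean_fecundity",
    weight_by_days: bool = False,
    name: str = "mating order ~ social x size",
) -> ModelTable:
    """Quasi-binomial GLM of the mating-order index on the design factors.

    The order index is treated as a continuous proportion; with
    ``weight_by_days`` each vial is weighted by its number of scored
    female-days. Terms are tested with F statistics on dispersion-scaled
    deviance differences (type-II comparisons).
    """
    data = scores.dropna(subset=["order_index"]).copy()
    if len(data) < 4:
        raise NoDataError("too few vials with a defined order index")
    terms = _design_terms(data, covariate)
    family = sm.families.Binomial()
    if weight_by_days:
        data = data[data["n_female_days"] > 0]
        # var_weights via the formula interface
        y = data["order_index"].to_numpy(dtype=float)
        if np.allclose(y, y[0]):
            raise FittingError("order_index is constant; nothing to model")
        full = smf.glm(
            _formula("order_index", terms),
            data=data,
            family=family,
            var_weights=data["n_female_days"].to_numpy(dtype=float),
        ).fit()
        # reuse the unweighted machinery for the term table, then swap scale
        table = _quasi_term_tests(
            data, "order_index", terms, family, name, "quasi-binomial (weighted)"
        )
        table.dispersion = float(full.pearson_chi2 / full.df_resid)
        return table
    return _quasi_term_tests(data, "order_index", terms, family, name, "quasi-binomial")


def fit_repeat_glm(
    scores: pd.DataFrame,
    covariate: str | None = "group_mean_fecundity",
    name: str = "repetitive matings ~ social x size",
) -> ModelTable:
    """Quasi-Poisson GLM of the repetitive-mating count on the design factors."""
    data = scores.dropna(subset=["repetitive_count"]).copy()
    if len(data) < 4:
        raise NoDataError("too few vials with a repetitive-mating count")
    terms = _design_terms(data, covariate)
    return _quasi_term_tests(
        data, "repetitive_count", terms, sm.families.Poisson(), name, "quasi-Poisson"
    )


def select_model(
    data: pd.DataFrame,
    response: str,
    terms: Sequence[str],
    family: str = "binomial",
    criterion: str = "aic",
) -> tuple[list[str], list[dict]]:
    """Backward elimination over nested term sets.

    Because AIC is undefined for quasi-likelihood fits, the default criterion
    is the AIC of the paired non-quasi fit; ``criterion='qaic'`` instead
    penalises the quasi-scaled log-likelihood, with the dispersion estimated
    once from the full model. Interactions are dropped before the main
    effects they contain, and the last remaining term is never eliminated
    (a single-term model is returned unchanged). Returns the selected terms
    and a trace of steps.
    """
    fam = {"binomial": sm.families.Binomial(), "poisson": sm.families.Poisson()}[family]
    current = list(terms)
    full = _glm_deviance(data, response, current, fam)
    c_hat = float(full.pearson_chi2 / full.df_resid) if full.df_resid > 0 else 1.0
    c_hat = max(c_hat, 1e-8)

    def crit(res) -> float:
        k = res.df_model + 1
        if criterion == "qaic":
            return float(-2 * res.llf / c_hat + 2 * k)
        if criterion == "aic":
            return float(res.aic)
        raise ValueError(f"unknown criterion {criterion!r}")

    trace: list[dict] = []
    best = crit(full)
    trace.append({"step": 0, "terms": list(current), "criterion": best, "dropped": None})
    step = 0
    while len(current) > 1:  # never eliminate the final term
        droppable = [
            t for t in current if not any(_contains(u, t) for u in current)
        ]
        candidates = []
        for t in droppable:
            reduced = [u for u in current if u != t]
            res = _glm_deviance(data, response, reduced, fam)
            candidates.append((crit(res), t, reduced))
        if not candidates:
            break
        candidates.sort(key=lambda c: c[0])
        best_c, best_t, best_terms = candidates[0]
        if best_c >= best:
            break
        step += 1
        current = best_terms
        best = best_c
        trace.append(
            {"step": step, "terms": list(current), "criterion": best, "dropped": best_t}
        )
    return current, trace


# ---------------------------------------------------------------------------
# linear interaction models of paternity share


def _ols_table(data: pd.DataFrame, formula: str, name: str) -> ModelTable:
    try:
        res = smf.ols(formula, data=data).fit()
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise SingularDesignError(f"OLS fit failed: {exc}") from exc
    if res.df_resid <= 0:
        raise FittingError("no residual degrees of freedom")
    if np.linalg.matrix_rank(res.model.exog) < res.model.exog.shape[1]:
        raise SingularDesignError(f"collinear design in {name!r}")
    an = anova_lm(res, typ=2)
    an = an.drop(index=[i for i in an.index if i == "Residual"])
    rows = [
        {
            "term": term,
            "df_num": int(r["df"]),
            "df_den": int(res.df_resid),
            "F": float(r["F"]),
            "p": float(r["PR(>F)"]),
        }
        for term, r in an.iterrows()
    ]
    scale = float(res.mse_resid)
    return ModelTable(
        name=name,
        family="gaussian (OLS)",
        terms=pd.DataFrame(rows),
        dispersion=scale if scale > 0 else 1e-300,
        nobs=int(res.nobs),
        params=dict(res.params),
    )


def interaction_models(scores: pd.DataFrame) -> dict[tuple[str, str], ModelTable]:
    """Per-experiment linear models of paternity share with score x treatment
    interactions.

    For each experiment code present, fits two OLS models: paternity share on
    the standardized order index interacting with social composition (and
    focal size where sizes vary), and the same with the standardized
    repetitive-mating count. Standardization is within experiment.
    """
    if "experiment" not in scores.columns:
        scores = scores.assign(experiment="ALL")
    out: dict[tuple[str, str], ModelTable] = {}
    for exp, sub in scores.groupby("experiment", sort=True):
        sub = sub.dropna(subset=["paternity_share", "order_index"]).copy()
        if len(sub) < 6:
            raise NoDataError(f"experiment {exp!r}: too few vials for interaction models")
        if sub["social"].nunique() < 2:
            raise DegenerateInputError(
                f"experiment {exp!r}: a single social level; interaction inestimable"
            )
        sub["order_std"] = standardize(sub["order_index"].to_numpy())
        sub["repeat_std"] = standardize(sub["repetitive_count"].to_numpy(dtype=float))
        sizes_vary = sub["focal_size"].nunique() > 1
        for score, label in (("order_std", "order"), ("repeat_std", "repeat")):
            rhs = f"{score} * C(social)"
            if sizes_vary:
                rhs += f" + {score} * C(focal_size)"
            table = _ols_table(
                sub,
                f"paternity_share ~ {rhs}",
                name=f"PS ~ {label} x treatment ({exp})",
            )
            out[(exp, label)] = table
    return out


def slope_by_group(
    scores: pd.DataFrame, score_col: str = "order_index", group_col: str = "social"
) -> pd.DataFrame:
    """OLS slope of paternity share on a (standardized) score, per group."""
    rows = []
    for g, sub in scores.dropna(subset=["paternity_share", score_col]).groupby(group_col):
        if len(sub) < 3 or sub[score_col].nunique() < 2:
            continue
        x = standardize(sub[score_col].to_numpy(dtype=float))
        slope, intercept, r, p, se = st.linregress(x, sub["paternity_share"])
        rows.append(
            {group_col: g, "slope": slope, "se": se, "r": r, "p": p, "n": len(sub)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# descriptive splits and checks


def median_split(
    scores: pd.DataFrame, by: Sequence[str] = ("experiment", "social")
) -> pd.DataFrame:
    """Mean +/- SE of paternity share above and below each group's median
    order index.

    Vials at exactly the median go to the ``<= median`` side. Groups whose
    order index is constant yield a single-sided row (with a warning).
    """
    by = [c for c in by if c in scores.columns]
    data = scores.dropna(subset=["order_index", "paternity_share"])
    if data.empty:
        raise NoDataError("no vials with both order index and paternity share")
    rows: list[dict] = []
    grouped = data.groupby(list(by)) if by else [((), data)]
    for keys, sub in grouped:
        keys = keys if isinstance(keys, tuple) else (keys,)
        label = dict(zip(by, keys))
        if len(sub) < 2:
            logger.warning("median split group %s has < 2 vials; skipped", label)
            continue
        med = float(sub["order_index"].median())
        for side, mask in (
            ("<= median", sub["order_index"] <= med),
            ("> median", sub["order_index"] > med),
        ):
            part = sub[mask]
            if part.empty:
                logger.warning(
                    "median split group %s: all order indices equal; one-sided output",
                    label,
                )
                continue
            ps = part["paternity_share"].to_numpy(dtype=float)
            se = float(ps.std(ddof=1) / np.sqrt(len(ps))) if len(ps) > 1 else np.nan
            rows.append(
                {
                    **label,
                    "side": side,
                    "median_order_index": med,
                    "mean_paternity_share": float(ps.mean()),
                    "se": se,
                    "n": int(len(ps)),
                }
            )
    return pd.DataFrame(rows)


def order_repeat_correlation(scores: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation (r, p) between order index and repetitive count."""
    data = scores.dropna(subset=["order_index", "repetitive_count"])
    if len(data) < 3:
        raise NoDataError("need >= 3 vials for a correlation")
    x = data["order_index"].to_numpy(dtype=float)
    y = data["repetitive_count"].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("zero variance in correlation input")
    r, p = st.pearsonr(x, y)
    return float(r), float(p)


def _focal_matings_by_female_size(ds: Dataset) -> pd.DataFrame:
    """Per (vial, female size class) count of focal-male copulations."""
    roster = ds.roster
    focal = roster[roster["role"] == "focal_male"].set_index("vial")["id"]
    fem_size = roster[roster["sex"] == "female"].set_index("id")["size_class"]
    ev = ds.events.copy()
    ev["is_focal"] = [
        focal.get(v) == m for v, m in zip(ev["vial"], ev["male_id"])
    ]
    ev = ev[ev["is_focal"]]
    ev["female_size"] = ev["female_id"].map(fem_size)
    counts = (
        ev.groupby(["vial", "female_size"]).size().rename("n_matings").reset_index()
    )
    return counts


def assortative_test(ds: Dataset, experiment: str) -> ModelTable:
    """ANOVA for size-assortative mating in the size-varying experiments.

    ``F``: one-way ANOVA of the focal male's copulation count across the
    homogeneous-female vials, factor = female size class. ``FM``: two-way
    ANOVA over heterogeneous vials with one row per (vial, female size):
    focal copulation count on female size x focal male size. ``M`` has a
    single female size class and raises :class:`DegenerateInputError`.
    """
    if ds.design is None:
        raise NoDataError("assortative test needs the design (treatment) table")
    design = ds.design[ds.design["experiment"] == experiment]
    if design.empty:
        raise NoDataError(f"no vials for experiment {experiment!r}")
    fem_sizes = ds.roster[ds.roster["sex"] == "female"].groupby("vial")["size_class"]
    if experiment == "M":
        raise DegenerateInputError("female size does not vary in the M experiment")
    counts = _focal_matings_by_female_size(ds)
    if experiment == "F":
        hom = design[design["social"] == "Hom"]["vial"]
        vial_fsize = fem_sizes.agg(lambda s: s.iloc[0]).rename("female_size")
        data = pd.DataFrame({"vial": hom}).merge(vial_fsize, on="vial")
        total = counts.groupby("vial")["n_matings"].sum()
        data["n_matings"] = data["vial"].map(total).fillna(0).astype(float)
        if data["female_size"].nunique() < 2:
            raise DegenerateInputError("single female size level in F Hom vials")
        return _ols_table(
            data, "n_matings ~ C(female_size)", name="assortative matings (F, Hom vials)"
        )
    # FM: Het vials, within-vial female-size factor
    het = design[design["social"] == "Het"][["vial", "focal_size"]]
    if het.empty:
        raise NoDataError("no heterogeneous FM vials")
    grid = pd.MultiIndex.from_product(
        [het["vial"], ["large", "small"]], names=["vial", "female_size"]
    ).to_frame(index=False)
    data = grid.merge(counts, on=["vial", "female_size"], how="left").merge(
        het, on="vial"
    )
    data["n_matings"] = data["n_matings"].fillna(0).astype(float)
    if data["focal_size"].nunique() < 2:
        raise DegenerateInputError("single focal size level in FM Het vials")
    return _ols_table(
        data,
        "n_matings ~ C(female_size) * C(focal_size)",
        name="assortative matings (FM, Het vials)",
    )


def pairwise_contrasts(
    data: pd.DataFrame, response: str, group_col: str
) -> pd.DataFrame:
    """All pairwise Welch t contrasts between group levels, Holm-corrected."""
    levels = sorted(data[group_col].dropna().unique())
    if len(levels) < 2:
        raise DegenerateInputError(f"{group_col!r} has fewer than two levels")
    rows = []
    for a, b in combinations(levels, 2):
        xa = data.loc[data[group_col] == a, response].dropna()
        xb = data.loc[data[group_col] == b, response].dropna()
        if len(xa) < 2 or len(xb) < 2:
            continue
        t, p = st.ttest_ind(xa, xb, equal_var=False)
        rows.append(
            {
                "contrast": f"{a} vs {b}",
                "estimate": float(xa.mean() - xb.mean()),
                "t": float(t),
                "p_raw": float(p),
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_holm"] = multipletests(out["p_raw"], method="holm")[1]
    return out
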