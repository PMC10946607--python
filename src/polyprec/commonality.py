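"""All-possible-subsets commonality analysis of a linear model's R².

Commonality analysis decomposes the coefficient of determination of an OLS
regression into 2^k - 1 components, one per non-empty subset S of the k
predictors. The components C(S) are defined by the linear system

    R²(W) = Σ_{S : S ∩ W ≠ ∅} C(S)   for every non-empty subset W,

where R²(W) is the R² of the model restricted to the predictors in W.
Singleton components are the *unique* contributions; larger subsets are
*common* (shared) variance, which can be negative under suppression. The
implementation computes C(S) in closed form by inclusion–exclusion,

    C(S) = Σ_{T ⊆ S} (-1)^{|S| - |T|} [R²(all) - R²((all \\ S) ∪ T)],

and verifies the defining system numerically after every decomposition.

The applied entry point is :class:`CommonalityModel`, which regresses focal
paternity share on the standardized mating-order index and standardized
repetitive-mating count while controlling for mate fecundity, then reports
the three-bucket partition of explained variance (mating order, repetitive
mating, remaining).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import chain, combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CapacityError,
    DegenerateInputError,
    FittingError,
    SingularDesignError,
    ValidationError,
)
from .scoring import standardize

MAX_PREDICTORS = 15
_SYSTEM_TOL = 1e-10

__all__ = [
    "fit_r2",
    "all_subsets_r2",
    "commonality_coefficients",
    "bucket_partition",
    "CommonalityModel",
    "CommonalityResults",
    "partition_by_treatment",
]


def fit_r2(response, design: pd.DataFrame) -> float:
    """OLS coefficient of determination (with intercept) of response on design.

    Raises :class:`SingularDesignError` on a rank-deficient design and
    :class:`DegenerateInputError` on a constant response or too few rows.
    """
    y = np.asarray(response, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim != 2:
        X = X.reshape(len(y), -1)
    n, p = X.shape
    if n <= p + 1:
        raise DegenerateInputError(f"need more than {p + 1} rows to fit {p} predictors")
    A = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(A) < p + 1:
        raise SingularDesignError("design matrix is rank deficient")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise DegenerateInputError("response has zero variance")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    ssr = float(np.sum((y - A @ beta) ** 2))
    return float(min(1.0, max(0.0, 1.0 - ssr / sst)))


def _nonempty_subsets(names: Sequence[str]) -> Iterable[frozenset]:
    return (
        frozenset(c)
        for c in chain.from_iterable(
            combinations(names, r) for r in range(1, len(names) + 1)
        )
    )


def all_subsets_r2(response, design: pd.DataFrame) -> dict[frozenset, float]:
    """R² of every non-empty predictor subset (guarded at 15 predictors)."""
    names = list(design.columns)
    if len(names) > MAX_PREDICTORS:
        raise CapacityError(
            f"{len(names)} predictors exceed the {MAX_PREDICTORS}-predictor guard"
        )
    return {
        s: fit_r2(response, design[sorted(s)]) for s in _nonempty_subsets(names)
    }


def commonality_coefficients(
    subset_r2: Mapping[frozenset, float]
) -> dict[frozenset, float]:
    """Solve the commonality system by inclusion–exclusion.

    ``subset_r2`` must contain every non-empty subset of the predictor set
    (keys are frozensets of names). Negative (suppression) components are
    returned as-is. The defining linear system is re-checked to 1e-10.
    """
    predictors = frozenset().union(*subset_r2.keys()) if subset_r2 else frozenset()
    expected = 2 ** len(predictors) - 1
    if len(subset_r2) != expected or any(
        frozenset(s) not in subset_r2 for s in _nonempty_subsets(sorted(predictors))
    ):
        raise ValidationError(
            f"subset_r2 must contain all {expected} non-empty subsets of {sorted(predictors)}"
        )
    full = subset_r2[predictors]

    def r2(subset: frozenset) -> float:
        return subset_r2[subset] if subset else 0.0

    coeffs: dict[frozenset, float] = {}
    for s in _nonempty_subsets(sorted(predictors)):
        total = 0.0
        for r in range(len(s) + 1):
            for t in combinations(sorted(s), r):
                sign = (-1) ** (len(s) - r)
                total += sign * (full - r2(predictors - frozenset(t)))
        coeffs[s] = total

    _check_system(subset_r2, coeffs, predictors)
    return coeffs


def _check_system(
    subset_r2: Mapping[frozenset, float],
    coeffs: Mapping[frozenset, float],
    predictors: frozenset,
) -> None:
    for w in _nonempty_subsets(sorted(predictors)):
        implied = sum(c for s, c in coeffs.items() if s & w)
        if abs(implied - subset_r2[w]) > _SYSTEM_TOL:
            raise FittingError(
                f"commonality system violated for subset {sorted(w)}: "
                f"{implied} != {subset_r2[w]}"
            )


def bucket_partition(
    coefficients: Mapping[frozenset, float],
    total_r2: float,
    roles: Mapping[str, str],
    rule: str = "unique",
) -> dict[str, float]:
    """Collapse commonality components into order / repeat / remaining buckets.

    ``roles`` maps each predictor name to ``order``, ``repeat`` or
    ``covariate`` and must name exactly one order and one repeat predictor.
    The default ``unique`` rule takes each focal bucket as that predictor's
    unique component and sweeps everything else (common components and
    covariate-unique variance) into *remaining*. The ``shared_split`` rule
    instead splits every common component equally among its members.
    """
    order = [p for p, r in roles.items() if r == "order"]
    repeat = [p for p, r in roles.items() if r == "repeat"]
    if len(order) != 1 or len(repeat) != 1:
        raise ValidationError("roles must assign exactly one order and one repeat predictor")
    known = set().union(*coefficients.keys())
    if not set(roles) >= known:
        raise ValidationError(f"roles missing predictors {sorted(known - set(roles))}")
    if rule == "unique":
        order_var = coefficients[frozenset(order)]
        repeat_var = coefficients[frozenset(repeat)]
    elif rule == "shared_split":
        order_var = sum(c / len(s) for s, c in coefficients.items() if order[0] in s)
        repeat_var = sum(c / len(s) for s, c in coefficients.items() if repeat[0] in s)
    else:
        raise ValueError(f"unknown bucket rule {rule!r}")
    remaining = total_r2 - order_var - repeat_var
    out = {
        "order_variance": order_var,
        "repeat_variance": repeat_var,
        "remaining_variance": remaining,
    }
    if total_r2 > 0:
        out.update(
            order_pct=100.0 * order_var / total_r2,
            repeat_pct=100.0 * repeat_var / total_r2,
            remaining_pct=100.0 * remaining / total_r2,
        )
    else:
        out.update(order_pct=np.nan, repeat_pct=np.nan, remaining_pct=np.nan)
    return out


@dataclass
class CommonalityResults:
    """Fitted commonality decomposition of paternity-share variance."""

    predictors: list[str]
    roles: dict[str, str]
    subset_r2: dict[frozenset, float]
    coefficients: dict[frozenset, float]
    total_r2: float
    buckets: dict[str, float]
    nobs: int
    bucket_rule: str = "unique"

    @property
    def has_suppression(self) -> bool:
        return any(v < 0 for v in self.coefficients.values())

    def coefficient_table(self) -> pd.DataFrame:
        rows = [
            {
                "subset": " & ".join(sorted(s)),
                "size": len(s),
                "kind": "unique" if len(s) == 1 else "common",
                "coefficient": c,
                "pct_of_r2": 100.0 * c / self.total_r2 if self.total_r2 > 0 else np.nan,
            }
            for s, c in sorted(self.coefficients.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "predictors": self.predictors,
            "roles": self.roles,
            "nobs": self.nobs,
            "total_r2": self.total_r2,
            "bucket_rule": self.bucket_rule,
            "subset_r2": {"+".join(sorted(s)): v for s, v in self.subset_r2.items()},
            "coefficients": {"+".join(sorted(s)): v for s, v in self.coefficients.items()},
            "buckets": dict(self.buckets),
        }

    def summary(self) -> str:
        lines = [
            "Commonality analysis of paternity share",
            "=" * 55,
            f"n vials:        {self.nobs}",
            f"predictors:     {', '.join(self.predictors)}",
            f"total R²:       {self.total_r2:.4f}",
            f"bucket rule:    {self.bucket_rule}",
            "-" * 55,
            f"{'component':<32}{'variance':>10}{'% of R²':>12}",
        ]
        for _, row in self.coefficient_table().iterrows():
            lines.append(
                f"{row['kind'] + ' ' + row['subset']:<32}"
                f"{row['coefficient']:>10.4f}{row['pct_of_r2']:>12.2f}"
            )
        lines.append("-" * 55)
        for name, label in (
            ("order", "mating order"),
            ("repeat", "repetitive mating"),
            ("remaining", "remaining"),
        ):
            lines.append(
                f"{label:<32}{self.buckets[name + '_variance']:>10.4f}"
                f"{self.buckets[name + '_pct']:>12.2f}"
            )
        if self.has_suppression:
            lines.append("warning: negative commonality (suppression) present")
        return "\n".join(lines)

    def plot_buckets(self, ax=None):
        """Bar chart of the three-bucket partition (% of explained variance)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        labels = ["mating order", "repetitive mating", "remaining"]
        vals = [self.buckets[k] for k in ("order_pct", "repeat_pct", "remaining_pct")]
        ax.bar(labels, vals, color=["#3b6ea5", "#b5651d", "#8a8a8a"])
        ax.set_ylabel("% of explained variance")
        ax.set_ylim(0, 100)
        ax.set_title(f"R² = {self.total_r2:.3f} (n = {self.nobs})")
        return ax


class CommonalityModel:
    """Linear model of paternity share set up for commonality analysis.

    Parameters
    ----------
    data
        Scores table with one row per vial (output of
        :func:`polyprec.scoring.score_dataset`). Rows with missing response
        or predictor values are dropped.
    response, order, repeat_, covariates
        Column names. ``order`` and ``repeat_`` are z-scored before fitting
        (the covariates are not), matching the analysis convention.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str = "paternity_share",
        order: str = "order_index",
        repeat_: str = "repetitive_count",
        covariates: Sequence[str] = ("mate_mean_fecundity",),
        standardize_scores: bool = True,
    ) -> None:
        cols = [response, order, repeat_, *covariates]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValidationError(f"scores table lacks column(s) {missing}")
        sub = data[cols].dropna().astype(float)
        self.nobs = len(sub)
        self.response_name = response
        self.roles = {order: "order", repeat_: "repeat"}
        self.roles.update({c: "covariate" for c in covariates})
        self.endog = sub[response].to_numpy()
        exog = sub[[order, repeat_, *covariates]].copy()
        if standardize_scores:
            for c in (order, repeat_):
                exog[c] = standardize(exog[c].to_numpy())
        self.exog = exog

    @classmethod
    def from_scores(cls, scores: pd.DataFrame, **kwargs) -> "CommonalityModel":
        return cls(scores, **kwargs)

    def fit(self, bucket_rule: str = "unique") -> CommonalityResults:
        subset_r2 = all_subsets_r2(self.endog, self.exog)
        coeffs = commonality_coefficients(subset_r2)
        total = subset_r2[frozenset(self.exog.columns)]
        buckets = bucket_partition(coeffs, total, self.roles, rule=bucket_rule)
        return CommonalityResults(
            predictors=list(self.exog.columns),
            roles=dict(self.roles),
            subset_r2=subset_r2,
            coefficients=coeffs,
            total_r2=total,
            buckets=buckets,
            nobs=self.nobs,
            bucket_rule=bucket_rule,
        )


def partition_by_treatment(
    scores: pd.DataFrame,
    by: Sequence[str] = ("experiment", "social", "focal_size", "treatment"),
    min_extra_rows: int = 3,
    bucket_rule: str = "unique",
    **model_kwargs,
) -> pd.DataFrame:
    """Commonality buckets per treatment cell plus per-experiment totals.

    Cells with fewer rows than predictors + ``min_extra_rows`` are skipped.
    Returns one row per fitted cell with total R² and the three buckets as
    variances and percentages.
    """
    by = [c for c in by if c in scores.columns]
    rows = []

    def _fit(label: dict, sub: pd.DataFrame) -> None:
        try:
            model = CommonalityModel(sub, **model_kwargs)
        except (ValidationError, DegenerateInputError):
            return
        n_pred = model.exog.shape[1]
        if model.nobs < n_pred + min_extra_rows:
            return
        try:
            res = model.fit(bucket_rule=bucket_rule)
        except (DegenerateInputError, SingularDesignError, FittingError):
            return
        rows.append(
            {
                **label,
                "n": res.nobs,
                "total_r2": res.total_r2,
                "order_variance": res.buckets["order_variance"],
                "order_pct": res.buckets["order_pct"],
                "repeat_variance": res.buckets["repeat_variance"],
                "repeat_pct": res.buckets["repeat_pct"],
                "remaining_variance": res.buckets["remaining_variance"],
                "remaining_pct": res.buckets["remaining_pct"],
            }
        )

    if "experiment" in scores.columns:
        for exp, sub in scores.groupby("experiment", sort=True):
            _fit({"experiment": exp, "scope": "overall"}, sub)
    else:
        _fit({"scope": "overall"}, scores)
    if by:
        for keys, sub in scores.groupby(list(by), sort=True):
            keys = keys if isinstance(keys, tuple) else (keys,)
            _fit({**dict(zip(by, keys)), "scope": "treatment"}, sub)
    return pd.DataFrame(rows)
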