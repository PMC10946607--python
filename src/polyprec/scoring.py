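"""Focal-male statistics derived from mating logs and offspring counts.

For each vial the focal male (the one wild-type male) gets:

paternity share (PS)
    pooled wild-type fraction of offspring laid by his *eligible* mates
    (females that mated both him and at least one rival) on laying days at or
    after the first day direct sperm competition was possible for that female.
mating-order index
    mean, over eligible female-days inside the sperm-competition window, of an
    indicator that the focal male was the most recent male to have mated that
    female; last-male status carries forward through days on which the female
    does not remate.
repetitive-mating count
    number of focal copulations with eligible females (``total`` convention),
    or the same minus one per eligible female (``rematings`` convention).

Fecundity covariates (group mean and eligible-mate mean offspring production)
and the same-size assortative mating count round out the per-vial scores.

Undefined quantities (no eligible females, no competition-window offspring)
are returned as ``None`` from the scalar operations and as ``NaN`` in the
scores table; they are data states, not errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, NoDataError
from .records import Dataset, N_DAYS

__all__ = [
    "eligible_females",
    "competition_start_day",
    "paternity_share",
    "order_index",
    "order_day_scores",
    "repetitive_count",
    "assortative_count",
    "standardize",
    "score_vial",
    "score_dataset",
]


@dataclass(frozen=True)
class _VialLog:
    """Pre-extracted per-vial view of a dataset used by every scoring op."""

    vial: str
    focal_id: str
    female_ids: tuple[str, ...]
    female_sizes: dict[str, str]
    focal_size: str
    # per-female mating history, each sorted by (day, seq)
    matings: dict[str, list[tuple[int, int, str]]]
    # per-female offspring: {female: [(lay_day, wt, spa), ...]}
    batches: dict[str, list[tuple[int, int, int]]]


def _vial_log(ds: Dataset, vial: str) -> _VialLog:
    roster = ds.roster[ds.roster["vial"] == vial]
    if roster.empty:
        raise NoDataError(f"vial {vial!r} not in dataset")
    focal = roster[roster["role"] == "focal_male"]
    focal_id = focal["id"].iloc[0]
    females = roster[roster["sex"] == "female"]
    female_ids = tuple(females["id"])
    female_sizes = dict(zip(females["id"], females["size_class"]))
    matings: dict[str, list[tuple[int, int, str]]] = {f: [] for f in female_ids}
    ev = ds.events
    ev = ev[ev["vial"] == vial]
    for row in ev.sort_values(["day", "seq"]).itertuples(index=False):
        matings[row.female_id].append((row.day, row.seq, row.male_id))
    batches: dict[str, list[tuple[int, int, int]]] = {f: [] for f in female_ids}
    off = ds.offspring
    off = off[off["vial"] == vial]
    for row in off.itertuples(index=False):
        batches[row.female_id].append((row.lay_day, row.count_wildtype, row.count_spa))
    return _VialLog(
        vial=vial,
        focal_id=focal_id,
        female_ids=female_ids,
        female_sizes=female_sizes,
        focal_size=focal["size_class"].iloc[0],
        matings=matings,
        batches=batches,
    )


def _eligible(log: _VialLog) -> dict[str, int]:
    """Eligible females and, for each, the first day sperm competition holds.

    A female is eligible iff she mated the focal male at least once and at
    least one rival at least once over the four days. The start day is the
    earliest day by whose end both conditions are met.
    """
    out: dict[str, int] = {}
    for fem, hist in log.matings.items():
        first_focal = None
        first_rival = None
        for day, _seq, male in hist:
            if male == log.focal_id:
                first_focal = day if first_focal is None else first_focal
            else:
                first_rival = day if first_rival is None else first_rival
        if first_focal is not None and first_rival is not None:
            out[fem] = max(first_focal, first_rival)
    return out


def eligible_females(ds: Dataset, vial: str) -> set[str]:
    """Females of ``vial`` that mated the focal male and >=1 rival male."""
    return set(_eligible(_vial_log(ds, vial)))


def competition_start_day(ds: Dataset, vial: str, female_id: str) -> int | None:
    """Earliest day by whose end ``female_id`` had mated both focal and a rival.

    Returns ``None`` for ineligible females.
    """
    return _eligible(_vial_log(ds, vial)).get(female_id)


def _paternity_share(log: _VialLog, pooling: str) -> float | None:
    starts = _eligible(log)
    if pooling not in ("pooled", "per_female_mean"):
        raise ValueError(f"unknown pooling {pooling!r}")
    per_female: list[tuple[int, int]] = []
    for fem, start in starts.items():
        wt = tot = 0
        for lay_day, n_wt, n_spa in log.batches.get(fem, []):
            if lay_day >= start:
                wt += n_wt
                tot += n_wt + n_spa
        per_female.append((wt, tot))
    if pooling == "pooled":
        wt = sum(w for w, _ in per_female)
        tot = sum(t for _, t in per_female)
        return wt / tot if tot > 0 else None
    props = [w / t for w, t in per_female if t > 0]
    return float(np.mean(props)) if props else None


def paternity_share(ds: Dataset, vial: str, pooling: str = "pooled") -> float | None:
    """Focal paternity share over competition-window offspring.

    ``pooled`` (default) sums wild-type and total counts over all eligible
    females' window batches; ``per_female_mean`` averages per-female
    proportions. ``None`` when no window batch has offspring.
    """
    return _paternity_share(_vial_log(ds, vial), pooling)


def _day_scores(log: _VialLog, prestart: str) -> list[tuple[str, int, int]]:
    if prestart not in ("exclude", "from_first_mating"):
        raise ValueError(f"unknown prestart option {prestart!r}")
    starts = _eligible(log)
    rows: list[tuple[str, int, int]] = []
    for fem, comp_start in starts.items():
        hist = log.matings[fem]
        start = comp_start if prestart == "exclude" else hist[0][0]
        for day in range(start, N_DAYS + 1):
            last_male = None
            for d, _seq, male in hist:  # hist sorted by (day, seq)
                if d > day:
                    break
                last_male = male
            rows.append((fem, day, int(last_male == log.focal_id)))
    return rows


def order_day_scores(ds: Dataset, vial: str, prestart: str = "exclude") -> pd.DataFrame:
    """Per-female, per-day last-male indicators for the focal male.

    One row per eligible female per scored day with columns ``female_id``,
    ``day``, ``indicator``. With ``prestart='exclude'`` (default) scoring
    begins on the female's competition start day; ``'from_first_mating'``
    scores from her first mating instead.
    """
    rows = _day_scores(_vial_log(ds, vial), prestart)
    return pd.DataFrame(rows, columns=["female_id", "day", "indicator"])


def order_index(ds: Dataset, vial: str, prestart: str = "exclude") -> float | None:
    """Mean last-male indicator over all scored female-days (``None`` if none)."""
    rows = _day_scores(_vial_log(ds, vial), prestart)
    if not rows:
        return None
    return float(np.mean([r[2] for r in rows]))


def repetitive_count(ds: Dataset, vial: str, convention: str = "total") -> int:
    """Focal matings with eligible partners.

    ``total`` counts every focal copulation with each eligible female;
    ``rematings`` subtracts one per eligible female (copulations beyond the
    first).
    """
    log = _vial_log(ds, vial)
    return _repetitive_count(log, convention)


def _repetitive_count(log: _VialLog, convention: str) -> int:
    if convention not in ("total", "rematings"):
        raise ValueError(f"unknown convention {convention!r}")
    starts = _eligible(log)
    total = sum(
        sum(1 for _d, _s, male in log.matings[fem] if male == log.focal_id)
        for fem in starts
    )
    if convention == "rematings":
        return total - len(starts)
    return total


def _assortative(log: _VialLog) -> int:
    return sum(
        1
        for fem, hist in log.matings.items()
        if log.female_sizes[fem] == log.focal_size
        for _d, _s, male in hist
        if male == log.focal_id
    )


def assortative_count(ds: Dataset, vial: str) -> int:
    """Number of focal copulations with females of the focal male's size class."""
    return _assortative(_vial_log(ds, vial))


def standardize(values) -> np.ndarray:
    """z-score a vector: subtract the mean, divide by the sd (n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2 or not np.all(np.isfinite(x)):
        raise DegenerateInputError("standardize needs >=2 finite values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


def _fecundity(log: _VialLog, females) -> float:
    totals = [
        sum(wt + spa for _d, wt, spa in log.batches.get(fem, [])) for fem in females
    ]
    return float(np.mean(totals)) if totals else float("nan")


def score_vial(
    ds: Dataset,
    vial: str,
    ps_pooling: str = "pooled",
    repetitive_convention: str = "total",
    order_prestart: str = "exclude",
) -> dict:
    """All focal-male scores for one vial, as a plain dict (one table row)."""
    log = _vial_log(ds, vial)
    starts = _eligible(log)
    ps = _paternity_share(log, ps_pooling)
    day_rows = _day_scores(log, order_prestart)
    oi = float(np.mean([r[2] for r in day_rows])) if day_rows else None
    return {
        "vial": vial,
        "focal_id": log.focal_id,
        "paternity_share": np.nan if ps is None else ps,
        "order_index": np.nan if oi is None else oi,
        "repetitive_count": _repetitive_count(log, repetitive_convention),
        "n_eligible_females": len(starts),
        "n_female_days": len(day_rows),
        "group_mean_fecundity": _fecundity(log, log.female_ids),
        "mate_mean_fecundity": _fecundity(log, list(starts)) if starts else np.nan,
        "assortative_count": _assortative(log),
        "focal_size": log.focal_size,
    }


def score_dataset(
    ds: Dataset,
    ps_pooling: str = "pooled",
    repetitive_convention: str = "total",
    order_prestart: str = "exclude",
) -> pd.DataFrame:
    """Score every vial; one row per vial, design labels joined when present."""
    rows = [
        score_vial(ds, v, ps_pooling, repetitive_convention, order_prestart)
        for v in ds.vials
    ]
    scores = pd.DataFrame(rows)
    if ds.design is not None:
        label_cols = ["vial", "experiment", "social", "focal_size"]
        if "treatment" in ds.design.columns:
            label_cols.append("treatment")
        scores = scores.merge(
            ds.design[label_cols].rename(columns={"focal_size": "focal_size_design"}),
            on="vial",
            how="left",
        )
        scores["focal_size"] = scores["focal_size_design"].fillna(scores["focal_size"])
        scores = scores.drop(columns=["focal_size_design"])
    return scores.sort_values("vial", kind="mergesort").reset_index(drop=True)
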