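"""Synthetic mating-group generator with last-male sperm precedence.

Emulates the experimental design the analysis assumes: replicate vials of
four males and four females interacting for 4 h on each of four consecutive
days, one wild-type focal male per vial, 20-h egg-laying intervals between
sessions, and Hom/Het size-structured treatments for the F (female sizes
vary), M (male sizes vary) and FM (both vary) experiments.

The generative model, per vial and day:

* each of ``slots_per_session`` courtship slots draws a male with probability
  proportional to his size-dependent weight and a female uniformly;
* the female accepts with ``virgin_receptivity`` if she has never mated, else
  ``remated_receptivity_base``, further multiplied by ``receptivity_size_mod``
  when a small male courts an already-mated large female (mated females resist
  small males more);
* an accepted copulation appends a mating event and updates the female's
  stored-sperm shares: the newest male captures a fraction ``p_disp`` of her
  sperm representation and all prior shares shrink by ``1 - p_disp``
  (proportional last-male displacement). A ``raffle`` alternative instead
  gives every copulation one equal ticket, so shares are mating-count
  proportions and precedence vanishes;
* after the session each mated female lays a Poisson(``fecundity_mean``)
  batch; each offspring's sire is a categorical draw from her current sperm
  shares, recorded as wild-type (focal-sired) versus spa.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .records import Dataset, Individual, VialDesign

__all__ = [
    "SimulationParams",
    "SpermState",
    "sperm_update",
    "simulate_vial",
    "build_designs",
    "simulate_experiment",
    "recovery_suite",
]


@dataclass(frozen=True)
class SimulationParams:
    """Generative parameters of the vial simulator.

    Defaults describe a strongly last-male-biased, moderately size-structured
    population: displacement ``p_disp`` of 0.85 (typical of reported
    D. melanogaster second-male paternity), a 1.5:1 large:small courtship
    advantage, high virgin receptivity with much lower remating receptivity,
    and ~20 offspring per female per 20-h laying interval.
    """

    p_disp: float = 0.85
    male_weight_large: float = 1.5
    male_weight_small: float = 1.0
    virgin_receptivity: float = 0.9
    remated_receptivity_base: float = 0.25
    receptivity_size_mod: float = 0.7
    slots_per_session: int = 20
    fecundity_mean: float = 20.0
    days: int = 4
    sperm_model: str = "displacement"  # or "raffle"

    def __post_init__(self) -> None:
        for name in (
            "p_disp",
            "virgin_receptivity",
            "remated_receptivity_base",
            "receptivity_size_mod",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.male_weight_large <= 0 or self.male_weight_small <= 0:
            raise ValidationError("male weights must be positive")
        if self.fecundity_mean < 0:
            raise ValidationError("fecundity_mean must be >= 0")
        if self.sperm_model not in ("displacement", "raffle"):
            raise ValidationError(f"unknown sperm_model {self.sperm_model!r}")


@dataclass
class SpermState:
    """One female's stored-sperm representation, as shares summing to one."""

    shares: dict[str, float] = field(default_factory=dict)
    tickets: dict[str, int] = field(default_factory=dict)  # raffle bookkeeping

    @property
    def mated(self) -> bool:
        return bool(self.shares)

    def check(self, tol: float = 1e-12) -> None:
        if self.shares:
            total = sum(self.shares.values())
            if abs(total - 1.0) > tol or min(self.shares.values()) < 0:
                raise ValidationError(f"invalid sperm shares {self.shares}")


def sperm_update(state: SpermState, male_id: str, p_disp: float) -> SpermState:
    """Proportional last-male displacement update (pure; returns a new state).

    The mating male's new share is ``p_disp`` plus the surviving fraction of
    any share he already held; all other males' shares scale by
    ``1 - p_disp``. A first mating yields a full share of 1 regardless of
    ``p_disp``.
    """
    if not 0.0 <= p_disp <= 1.0:
        raise ValidationError(f"p_disp={p_disp} outside [0, 1]")
    if not state.shares:
        return SpermState(shares={male_id: 1.0})
    shares = {m: s * (1.0 - p_disp) for m, s in state.shares.items()}
    shares[male_id] = shares.get(male_id, 0.0) + p_disp
    new = SpermState(shares=shares)
    new.check()
    return new


def _raffle_update(state: SpermState, male_id: str) -> SpermState:
    tickets = dict(state.tickets)
    tickets[male_id] = tickets.get(male_id, 0) + 1
    total = sum(tickets.values())
    return SpermState(
        shares={m: t / total for m, t in tickets.items()}, tickets=tickets
    )


def simulate_vial(
    design: VialDesign, params: SimulationParams, rng: np.random.Generator
) -> tuple[list[dict], list[dict]]:
    """Simulate one vial; returns (event rows, offspring rows)."""
    males = [m for m in design.members if m.sex == "male"]
    females = [m for m in design.members if m.sex == "female"]
    focal_id = design.focal.id
    weights = np.array(
        [
            params.male_weight_large if m.size_class == "large" else params.male_weight_small
            for m in males
        ]
    )
    weights = weights / weights.sum()
    states: dict[str, SpermState] = {f.id: SpermState() for f in females}
    events: list[dict] = []
    offspring: list[dict] = []
    for day in range(1, params.days + 1):
        seq = 0
        for _ in range(params.slots_per_session):
            male = males[rng.choice(len(males), p=weights)]
            female = females[rng.integers(len(females))]
            st = states[female.id]
            if not st.mated:
                p_accept = params.virgin_receptivity
            else:
                p_accept = params.remated_receptivity_base
                if male.size_class == "small" and female.size_class == "large":
                    p_accept *= params.receptivity_size_mod
            if rng.random() >= p_accept:
                continue
            seq += 1
            events.append(
                {
                    "vial": design.vial,
                    "day": day,
                    "seq": seq,
                    "male_id": male.id,
                    "female_id": female.id,
                }
            )
            if params.sperm_model == "raffle":
                states[female.id] = _raffle_update(st, male.id)
            else:
                states[female.id] = sperm_update(st, male.id, params.p_disp)
        # 20-h laying interval: sires drawn from end-of-day sperm shares
        for female in females:
            st = states[female.id]
            if not st.mated:
                continue
            n = int(rng.poisson(params.fecundity_mean))
            sires = list(st.shares)
            probs = np.array([st.shares[s] for s in sires])
            counts = rng.multinomial(n, probs) if n > 0 else np.zeros(len(sires), int)
            wt = int(sum(c for s, c in zip(sires, counts) if s == focal_id))
            offspring.append(
                {
                    "vial": design.vial,
                    "female_id": female.id,
                    "lay_day": day,
                    "count_wildtype": wt,
                    "count_spa": int(n - wt),
                }
            )
    return events, offspring


def _make_members(
    vial: str, male_sizes: Sequence[str], female_sizes: Sequence[str], focal_idx: int = 0
) -> tuple[Individual, ...]:
    members = []
    for i, size in enumerate(male_sizes):
        role = "focal_male" if i == focal_idx else "rival_male"
        members.append(
            Individual(
                id=f"{vial}-m{i + 1}",
                vial=vial,
                sex="male",
                size_class=size,
                marker="wildtype" if role == "focal_male" else "spa",
                role=role,
            )
        )
    for i, size in enumerate(female_sizes):
        members.append(
            Individual(
                id=f"{vial}-f{i + 1}",
                vial=vial,
                sex="female",
                size_class=size,
                marker="spa",
                role="female",
            )
        )
    return tuple(members)


def _het_males(focal_size: str) -> list[str]:
    """Het male composition: focal + one same-size rival + two of the other size."""
    other = "small" if focal_size == "large" else "large"
    return [focal_size, focal_size, other, other]


def build_designs(experiment: str, n_het: int = 20, n_hom: int = 10) -> list[VialDesign]:
    """Vial designs for one experiment.

    ``n_hom`` vials are built for *each* of the two homogeneous compositions
    and ``n_het`` heterogeneous vials, split evenly between large and small
    focal males where focal size varies (M, FM); the replicated design is
    therefore ``n_het + 2 * n_hom`` vials (40 at the defaults).
    """
    if experiment not in ("F", "M", "FM"):
        raise ValidationError(f"unknown experiment code {experiment!r}")
    if n_het < 1 or n_hom < 1:
        raise ValidationError("n_het and n_hom must be >= 1")
    designs: list[VialDesign] = []
    counter = 0

    def add(social: str, focal_size: str, male_sizes, female_sizes, treatment: str) -> None:
        nonlocal counter
        counter += 1
        vial = f"{experiment}-{social}-{counter:03d}"
        designs.append(
            VialDesign(
                vial=vial,
                experiment=experiment,
                social=social,
                focal_size=focal_size,
                members=_make_members(vial, male_sizes, female_sizes),
                treatment=treatment,
            )
        )

    L, S = "large", "small"
    if experiment == "F":
        for _ in range(n_hom):
            add("Hom", L, [L] * 4, [L] * 4, "LM:LF")
        for _ in range(n_hom):
            add("Hom", L, [L] * 4, [S] * 4, "LM:SF")
        for _ in range(n_het):
            add("Het", L, [L] * 4, [L, L, S, S], "LM:HetF")
    elif experiment == "M":
        for _ in range(n_hom):
            add("Hom", L, [L] * 4, [L] * 4, "LM:LF")
        for _ in range(n_hom):
            add("Hom", S, [S] * 4, [L] * 4, "SM:LF")
        for i in range(n_het):
            focal = L if i < n_het - n_het // 2 else S
            add("Het", focal, _het_males(focal), [L] * 4, "HetM:LF")
    else:  # FM
        for _ in range(n_hom):
            add("Hom", L, [L] * 4, [L] * 4, "LM:LF")
        for _ in range(n_hom):
            add("Hom", S, [S] * 4, [S] * 4, "SM:SF")
        for i in range(n_het):
            focal = L if i < n_het - n_het // 2 else S
            add("Het", focal, _het_males(focal), [L, L, S, S], "HetM:HetF")
    return designs


def simulate_experiment(
    experiment: str,
    n_het: int = 20,
    n_hom: int = 10,
    params: SimulationParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> Dataset:
    """Simulate a full replicated experiment and return a validated Dataset."""
    params = params or SimulationParams()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    designs = build_designs(experiment, n_het=n_het, n_hom=n_hom)
    roster_rows: list[dict] = []
    event_rows: list[dict] = []
    offspring_rows: list[dict] = []
    design_rows: list[dict] = []
    for d in designs:
        roster_rows.extend(d.roster_rows())
        design_rows.append(
            {
                "vial": d.vial,
                "experiment": d.experiment,
                "social": d.social,
                "focal_size": d.focal_size,
                "treatment": d.treatment,
            }
        )
        ev, off = simulate_vial(d, params, rng)
        event_rows.extend(ev)
        offspring_rows.extend(off)
    roster = pd.DataFrame(roster_rows)
    events = pd.DataFrame(
        event_rows, columns=["vial", "day", "seq", "male_id", "female_id"]
    )
    offspring = pd.DataFrame(
        offspring_rows,
        columns=["vial", "female_id", "lay_day", "count_wildtype", "count_spa"],
    )
    if events.empty:
        events = events.astype({"day": int, "seq": int}, errors="ignore")
    design = pd.DataFrame(design_rows)
    return Dataset.from_frames(roster, events, offspring, design)


def recovery_suite(
    grid: Iterable[Mapping | str] = ("raffle", {"p_disp": 0.8}, {"p_disp": 0.95}),
    replicates: int = 20,
    experiment: str = "FM",
    n_het: int = 20,
    n_hom: int = 10,
    params: SimulationParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Run the scoring + commonality pipeline over a grid of sperm models.

    Each grid cell is either the string ``"raffle"`` or a mapping of
    :class:`SimulationParams` overrides. Returns one row per (cell,
    replicate) with the commonality buckets and simple score summaries.
    """
    from .commonality import CommonalityModel
    from .scoring import score_dataset

    base = params or SimulationParams()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rows = []
    for cell in grid:
        if cell == "raffle":
            p = replace(base, sperm_model="raffle")
            label = "raffle"
        else:
            p = replace(base, **dict(cell))
            label = ",".join(f"{k}={v}" for k, v in sorted(dict(cell).items()))
        for rep in range(replicates):
            ds = simulate_experiment(experiment, n_het=n_het, n_hom=n_hom, params=p, rng=rng)
            scores = score_dataset(ds)
            res = CommonalityModel(scores).fit()
            by_size = scores.groupby("focal_size")["order_index"].mean()
            rows.append(
                {
                    "cell": label,
                    "replicate": rep,
                    "total_r2": res.total_r2,
                    "order_pct": res.buckets["order_pct"],
                    "repeat_pct": res.buckets["repeat_pct"],
                    "remaining_pct": res.buckets["remaining_pct"],
                    "mean_order_index": scores["order_index"].mean(),
                    "mean_paternity_share": scores["paternity_share"].mean(),
                    "order_index_large_focal": by_size.get("large", np.nan),
                    "order_index_small_focal": by_size.get("small", np.nan),
                }
            )
    return pd.DataFrame(rows)
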