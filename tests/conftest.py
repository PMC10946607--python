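"""Shared fixtures: handcrafted single-vial datasets and small simulations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from polyprec import Dataset, simulate_experiment


def build_vial(
    events=(),
    offspring=(),
    vial: str = "V1",
    focal_size: str = "large",
    male_sizes=("large", "large", "large", "large"),
    female_sizes=("large", "large", "large", "large"),
    design_labels: dict | None = None,
) -> Dataset:
    """One 4M:4F vial with focal male ``m1`` and females ``f1``..``f4``.

    ``events`` rows are ``(day, seq, male, female)`` using the short names;
    ``offspring`` rows are ``(female, lay_day, count_wildtype, count_spa)``.
    """
    roster_rows = []
    for i, size in enumerate(male_sizes, start=1):
        role = "focal_male" if i == 1 else "rival_male"
        roster_rows.append(
            {
                "id": f"m{i}",
                "vial": vial,
                "sex": "male",
                "size_class": focal_size if i == 1 else size,
                "marker": "wildtype" if i == 1 else "spa",
                "role": role,
            }
        )
    for i, size in enumerate(female_sizes, start=1):
        roster_rows.append(
            {
                "id": f"f{i}",
                "vial": vial,
                "sex": "female",
                "size_class": size,
                "marker": "spa",
                "role": "female",
            }
        )
    events_df = pd.DataFrame(
        [
            {"vial": vial, "day": d, "seq": s, "male_id": m, "female_id": f}
            for d, s, m, f in events
        ],
        columns=["vial", "day", "seq", "male_id", "female_id"],
    )
    offspring_df = pd.DataFrame(
        [
            {
                "vial": vial,
                "female_id": f,
                "lay_day": d,
                "count_wildtype": wt,
                "count_spa": spa,
            }
            for f, d, wt, spa in offspring
        ],
        columns=["vial", "female_id", "lay_day", "count_wildtype", "count_spa"],
    )
    design = None
    if design_labels is not None:
        design = pd.DataFrame([{"vial": vial, **design_labels}])
    return Dataset.from_frames(pd.DataFrame(roster_rows), events_df, offspring_df, design)


@pytest.fixture
def make_vial():
    return build_vial


@pytest.fixture(scope="session")
def sim_fm() -> Dataset:
    """A full-size simulated FM experiment (40 vials), fixed seed."""
    return simulate_experiment("FM", n_het=20, n_hom=10, rng=np.random.default_rng(42))


@pytest.fixture(scope="session")
def sim_fm_scores(sim_fm):
    from polyprec import score_dataset

    return score_dataset(sim_fm)
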