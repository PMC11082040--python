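"""Shared fixtures: small deterministic plots and CHMs for fast tests."""

from __future__ import annotations

import numpy as np
import pytest

from uasforest.data import TreePlot, TreeRecord


def make_random_plot(
    seed: int,
    n: int = 40,
    size: float = 100.0,
    height_range: tuple[float, float] = (1.5, 25.0),
    with_dbh: bool = False,
) -> TreePlot:
    """Uniformly scattered plot with random heights (and optional DBH/crowns)."""
    rng = np.random.default_rng(seed)
    trees = []
    for i in range(n):
        h = float(rng.uniform(*height_range))
        trees.append(
            TreeRecord(
                tree_id=f"t{i:03d}",
                x_m=float(rng.uniform(0, size)),
                y_m=float(rng.uniform(0, size)),
                height_m=h,
                dbh_cm=float(4.29 * h**0.68) if with_dbh else None,
                crown_radius_m=float(0.5 + 0.15 * h) if with_dbh else None,
            )
        )
    return TreePlot(plot_id=f"rand{seed}", trees=trees, bounds=(0, 0, size, size))


def make_separated_plot(
    seed: int,
    spacing: float = 12.0,
    size: float = 100.0,
    height_range: tuple[float, float] = (5.0, 15.0),
) -> TreePlot:
    """Grid-jittered stand whose trees are farther apart than any search window."""
    rng = np.random.default_rng(seed)
    trees = []
    k = 0
    for x in np.arange(spacing / 2 + 2, size - 2, spacing):
        for y in np.arange(spacing / 2 + 2, size - 2, spacing):
            h = float(rng.uniform(*height_range))
            trees.append(
                TreeRecord(
                    tree_id=f"t{k:03d}",
                    x_m=float(x + rng.uniform(-1, 1)),
                    y_m=float(y + rng.uniform(-1, 1)),
                    height_m=h,
                    dbh_cm=float(4.29 * h**0.68),
                    crown_radius_m=float(0.5 + 0.15 * h),
                )
            )
            k += 1
    return TreePlot(plot_id=f"sep{seed}", trees=trees, bounds=(0, 0, size, size))


@pytest.fixture
def random_plot() -> TreePlot:
    return make_random_plot(seed=11, with_dbh=True)


@pytest.fixture
def separated_plot() -> TreePlot:
    return make_separated_plot(seed=7)
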