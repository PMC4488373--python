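"""Model integration: transition map, headline percentages, conserved lands.

Subtracting the current model's binary prediction from the potential
model's yields a per-unit transition value: +1 flags units suitable on
intrinsic grounds but not under current land cover (restoration
candidates), -1 the reverse, 0 no change. The summary report carries
the headline percentages; the conserved-lands overlay reports how much
of each habitat category falls on protected polygons.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from shapely.ops import unary_union

from streamsdm.units import SampleUnitGrid


@dataclass
class BinaryMap:
    """Per-unit 0/1 habitat prediction."""

    values: pd.Series  # indexed by unit_id, values in {0, 1}
    model_tag: str = ""

    def __post_init__(self) -> None:
        self.values = self.values.astype(int)
        if not self.values.isin([0, 1]).all():
            raise ValueError("binary map values must be 0 or 1")


@dataclass
class TransitionMap:
    """Per-unit potential-minus-current value in {-1, 0, +1}."""

    values: pd.Series

    def __post_init__(self) -> None:
        if not self.values.isin([-1, 0, 1]).all():
            raise ValueError("transition values must be in {-1, 0, 1}")


@dataclass
class SummaryReport:
    """Headline statistics (percentages rounded to two decimals for
    reporting; full-precision values kept alongside)."""

    n_units: int
    n_potential: int
    n_current: int
    n_plus1: int
    n_minus1: int
    pct_potential: float
    pct_current: float
    pct_plus1: float
    net_change_pct: float | None  # (|P|-|C|)/|P|, None when |P| = 0
    potential_increase_pct: float | None  # n+1 / |C|, None when |C| = 0
    full_precision: dict | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def transition_map(potential: BinaryMap, current: BinaryMap) -> TransitionMap:
    """T(u) = potential(u) - current(u) on a shared unit set."""
    pi, ci = set(potential.values.index), set(current.values.index)
    if pi != ci:
        diff = sorted(pi.symmetric_difference(ci))
        raise ValueError(f"unit sets differ; symmetric difference (first 10): {diff[:10]}")
    return TransitionMap(potential.values - current.values.reindex(potential.values.index))


def _round2(x: float) -> float:
    return float(round(x, 2))


def summarize(transition: TransitionMap, potential: BinaryMap, current: BinaryMap) -> SummaryReport:
    """Headline percentages of the integrated analysis."""
    n = len(transition.values)
    if n == 0 or len(potential.values) != n or len(current.values) != n:
        raise ValueError("inconsistent unit sets")
    n_pot = int((potential.values == 1).sum())
    n_cur = int((current.values == 1).sum())
    n_plus = int((transition.values == 1).sum())
    n_minus = int((transition.values == -1).sum())
    net = 100.0 * (n_pot - n_cur) / n_pot if n_pot else None
    inc = 100.0 * n_plus / n_cur if n_cur else None
    full = {
        "pct_potential": 100.0 * n_pot / n,
        "pct_current": 100.0 * n_cur / n,
        "pct_plus1": 100.0 * n_plus / n,
        "net_change_pct": net,
        "potential_increase_pct": inc,
    }
    return SummaryReport(
        n_units=n, n_potential=n_pot, n_current=n_cur, n_plus1=n_plus, n_minus1=n_minus,
        pct_potential=_round2(full["pct_potential"]),
        pct_current=_round2(full["pct_current"]),
        pct_plus1=_round2(full["pct_plus1"]),
        net_change_pct=_round2(net) if net is not None else None,
        potential_increase_pct=_round2(inc) if inc is not None else None,
        full_precision=full,
    )


def conserved_overlay(map_: BinaryMap | TransitionMap, conserved: list, grid: SampleUnitGrid,
                      coverage_threshold: float = 0.5) -> dict[str, float | None]:
    """Percent of each habitat category on conserved lands.

    A unit counts as conserved when conserved polygons cover more than
    ``coverage_threshold`` of its cell area. For a BinaryMap the single
    category is ``habitat``; for a TransitionMap the categories are the
    three transition classes. Categories with no units report None.
    """
    for poly in conserved:
        if not poly.is_valid:
            raise ValueError("invalid conserved-land polygon")
    union = unary_union(conserved) if conserved else None
    cell_area = grid.cell_m**2

    def is_conserved(uid: int) -> bool:
        if union is None:
            return False
        cell = grid.cell_box(grid.rc(uid))
        return cell.intersection(union).area / cell_area > coverage_threshold

    if isinstance(map_, BinaryMap):
        categories = {"habitat": [int(u) for u in map_.values.index[map_.values == 1]]}
    else:
        categories = {
            "plus1": [int(u) for u in map_.values.index[map_.values == 1]],
            "zero": [int(u) for u in map_.values.index[map_.values == 0]],
            "minus1": [int(u) for u in map_.values.index[map_.values == -1]],
        }
    out: dict[str, float | None] = {}
    for name, uids in categories.items():
        if not uids:
            out[name] = None
            continue
        n_cons = sum(is_conserved(u) for u in uids)
        out[name] = 100.0 * n_cons / len(uids)
    return out
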