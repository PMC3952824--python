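"""Resection kinetics from focus-loss times.

Converts called loss times into the headline quantities of the assay: the
loss-time distribution per cassette, the resection duration (anchored at the
earliest possible cleavage time, since per-cell cleavage is unobservable; a
mean-anchored variant is reported alongside), the slow-phase speed over the
cut-to-INT1 distance, the fast-phase speed over the INT1-to-INT2 distal span
in cells that lose both foci, and the commitment delay between two genotype
scenarios (wild-type mean loss minus mutant mean loss).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["KineticsConstants", "LossTimeDistribution", "ResectionReport",
           "fit_loss_time_distribution", "resection_duration",
           "resection_speed", "two_phase_speed", "commitment_delay",
           "build_report"]


@dataclass(frozen=True)
class KineticsConstants:
    """Genomic geometry and the earliest-cleavage anchor (minutes)."""

    int1_distal_nt: float = 1231.0
    int2_distal_nt: float = 7612.0
    earliest_cleavage_min: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.int1_distal_nt < self.int2_distal_nt:
            raise ValueError("require 0 < int1_distal < int2_distal")


@dataclass(frozen=True)
class LossTimeDistribution:
    n: int
    mean_min: float
    sd_min: float
    min_min: float
    max_min: float


def fit_loss_time_distribution(t_losses: Sequence[float]) -> LossTimeDistribution:
    """Sample moments (sd with n-1 denominator) and range of loss times."""
    t = np.asarray(list(t_losses), dtype=float)
    if t.size == 0:
        raise ValueError("no loss times")
    sd = float(t.std(ddof=1)) if t.size > 1 else 0.0
    return LossTimeDistribution(n=int(t.size), mean_min=float(t.mean()),
                                sd_min=sd, min_min=float(t.min()),
                                max_min=float(t.max()))


def resection_duration(t_loss_min: float,
                       constants: KineticsConstants = KineticsConstants()) -> float:
    """Minutes from the earliest possible cleavage to the given loss time."""
    if t_loss_min < constants.earliest_cleavage_min:
        raise ValueError(
            f"loss at {t_loss_min} min precedes the earliest cleavage "
            f"({constants.earliest_cleavage_min} min): mis-called loss")
    return t_loss_min - constants.earliest_cleavage_min


def resection_speed(distance_nt: float, duration_min: float) -> float:
    """Resection speed in nt/min."""
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    return distance_nt / duration_min


def two_phase_speed(t_loss_int1_min: float, t_loss_int2_min: float,
                    constants: KineticsConstants = KineticsConstants()) -> float:
    """Fast-phase speed from the INT1->INT2 loss interval of one cell."""
    interval = t_loss_int2_min - t_loss_int1_min
    if interval <= 0:
        raise ValueError("INT2 loss must follow INT1 loss")
    return (constants.int2_distal_nt - constants.int1_distal_nt) / interval


def commitment_delay(dist_wt: LossTimeDistribution,
                     dist_mutant: LossTimeDistribution) -> float:
    """Mean loss-time difference, wild type minus mutant (minutes)."""
    return dist_wt.mean_min - dist_mutant.mean_min


def _dist_dict(d: Optional[LossTimeDistribution]):
    return None if d is None else asdict(d)


@dataclass
class ResectionReport:
    """Assembled kinetics for one or more genotype scenarios."""

    constants: KineticsConstants
    scenarios: dict = field(default_factory=dict)
    commitment_delay_min: Optional[float] = None
    delay_scenarios: Optional[tuple[str, str]] = None

    def to_dict(self) -> dict:
        out = {"constants": asdict(self.constants), "scenarios": {}}
        for name, s in self.scenarios.items():
            entry = dict(s)
            for key in ("int1", "int2"):
                entry[key] = dict(entry[key])
                entry[key]["distribution"] = _dist_dict(entry[key]["distribution"])
            out["scenarios"][name] = entry
        if self.commitment_delay_min is not None:
            out["commitment_delay_min"] = self.commitment_delay_min
            out["delay_scenarios"] = list(self.delay_scenarios)
        return out

    def to_table(self) -> str:
        rows = []
        for name, s in self.scenarios.items():
            for ch in ("int1", "int2"):
                c = s[ch]
                d = c["distribution"]
                rows.append({
                    "scenario": name, "channel": ch,
                    "n_cells": s["n_cells"], "n_lost": c["n_lost"],
                    "fraction_lost": round(c["fraction_lost"], 3),
                    "mean_loss_min": None if d is None else round(d.mean_min, 2),
                    "sd_min": None if d is None else round(d.sd_min, 2),
                    "range_min": None if d is None else f"{d.min_min:.1f}-{d.max_min:.1f}",
                    "speed_earliest_nt_min": _round(c.get("speed_earliest_nt_min")),
                    "speed_mean_nt_min": _round(c.get("speed_mean_nt_min")),
                })
            if s.get("fast_speed_nt_min") is not None:
                rows[-1]["fast_speed_nt_min"] = round(s["fast_speed_nt_min"], 1)
        table = pd.DataFrame(rows).to_string(index=False)
        if self.commitment_delay_min is not None:
            a, b = self.delay_scenarios
            table += (f"\ncommitment delay ({a} - {b}): "
                      f"{self.commitment_delay_min:.2f} min")
        return table


def _round(v, nd=1):
    return None if v is None else round(v, nd)


def _channel_summary(sub: pd.DataFrame, distance_nt: float,
                     constants: KineticsConstants, n_cells: int) -> dict:
    lost = sub[sub["lost"].astype(bool)]
    times = lost["t_loss_min"].astype(float).to_numpy()
    entry: dict = {
        "n_lost": int(len(lost)),
        "fraction_lost": (len(lost) / n_cells) if n_cells else 0.0,
        "distribution": None,
        "duration_earliest_min": None, "duration_mean_min": None,
        "speed_earliest_nt_min": None, "speed_mean_nt_min": None,
    }
    if len(lost) == 0:
        return entry
    dist = fit_loss_time_distribution(times)
    entry["distribution"] = dist
    for anchor, key in ((dist.min_min, "earliest"), (dist.mean_min, "mean")):
        try:
            dur = resection_duration(anchor, constants)
        except ValueError:
            continue
        entry[f"duration_{key}_min"] = dur
        if dur > 0:
            entry[f"speed_{key}_nt_min"] = resection_speed(distance_nt, dur)
    return entry


def build_report(events_by_scenario: Mapping[str, pd.DataFrame],
                 constants: KineticsConstants = KineticsConstants(),
                 n_cells_by_scenario: Optional[Mapping[str, int]] = None,
                 delay_pair: Optional[tuple[str, str]] = None) -> ResectionReport:
    """Assemble a ResectionReport from per-scenario loss-event tables.

    Each events table needs columns cell_id, channel, lost, t_loss_min.  The
    commitment delay is computed over INT1 distributions for ``delay_pair``
    (wild type first); by default a scenario named ``"wt"`` is compared with
    the single other scenario when exactly two are present.
    """
    if not events_by_scenario:
        raise ValueError("no scenarios given")
    report = ResectionReport(constants=constants)
    for name, ev in events_by_scenario.items():
        n_cells = (n_cells_by_scenario[name] if n_cells_by_scenario
                   else int(ev["cell_id"].nunique()))
        entry: dict = {"n_cells": n_cells}
        for ch, dist_nt in (("int1", constants.int1_distal_nt),
                            ("int2", constants.int2_distal_nt)):
            sub = ev[ev["channel"] == ch]
            entry[ch] = _channel_summary(sub, dist_nt, constants, n_cells)
        # fast-phase speed over cells that lose both foci
        speeds = []
        lost1 = ev[(ev["channel"] == "int1") & ev["lost"].astype(bool)]
        lost2 = ev[(ev["channel"] == "int2") & ev["lost"].astype(bool)]
        both = pd.merge(lost1, lost2, on="cell_id", suffixes=("_1", "_2"))
        for _, row in both.iterrows():
            if row["t_loss_min_2"] > row["t_loss_min_1"]:
                speeds.append(two_phase_speed(row["t_loss_min_1"],
                                              row["t_loss_min_2"], constants))
        entry["fast_speed_nt_min"] = float(np.mean(speeds)) if speeds else None
        entry["n_fast_cells"] = len(speeds)
        report.scenarios[name] = entry

    names = list(events_by_scenario)
    if delay_pair is None and len(names) == 2 and "wt" in names:
        other = names[0] if names[1] == "wt" else names[1]
        delay_pair = ("wt", other)
    if delay_pair is not None:
        a, b = delay_pair
        da = report.scenarios.get(a, {}).get("int1", {}).get("distribution")
        db = report.scenarios.get(b, {}).get("int1", {}).get("distribution")
        if da is not None and db is not None:
            report.commitment_delay_min = commitment_delay(da, db)
            report.delay_scenarios = (a, b)
    return report
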