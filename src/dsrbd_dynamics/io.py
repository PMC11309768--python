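"""Tabular I/O and core domain types for the relaxation/binding pipeline.

Everything the pipeline touches on disk is plain text: peak-height tables
(CSV or whitespace-delimited assignment-tool exports), relaxation delay
schedules with duplicate markers, per-residue rate tables, and binding
tables.  Delays are printed in ms (as acquisition schedules are) but held
in seconds internally.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ResidueID",
    "DelaySchedule",
    "SpectrometerContext",
    "IntensitySeries",
    "RateTable",
    "read_delay_schedule",
    "format_delay_schedule",
    "read_intensity_table",
    "read_rate_table",
    "write_rate_table",
    "load_config",
    "DEFAULT_CONFIG",
]

#: gyromagnetic ratios, rad s^-1 T^-1 (1H positive, 15N negative)
GAMMA_H = 2.6752218744e8
GAMMA_N = -2.7126e7

RATE_KINDS = ("R1", "R2", "noe", "R1rho", "R2rho", "R2eff")


@dataclass(frozen=True, order=True)
class ResidueID:
    """A residue in full-length numbering (1-366 for TRBP2 constructs)."""

    number: int
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.number < 1:
            raise ValueError(f"residue number must be >= 1, got {self.number}")

    def in_window(self, lo: int, hi: int) -> bool:
        """Core-membership predicate, e.g. 159-227 for the dsRBD2 core."""
        return lo <= self.number <= hi

    @classmethod
    def from_label(cls, label: str) -> "ResidueID":
        """Parse labels like 'G162', '162', or 'G162N-H' (assignment exports)."""
        m = re.match(r"^([A-Za-z]?)(\d+)", label.strip())
        if not m or not m.group(2):
            raise ValueError(f"cannot parse residue label {label!r}")
        name = m.group(1).upper() or None
        return cls(int(m.group(2)), name)


@dataclass(frozen=True)
class DelaySchedule:
    """Relaxation delays in seconds with flags for delays acquired twice."""

    delays: tuple[float, ...]
    duplicate_flags: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.delays) != len(self.duplicate_flags):
            raise ValueError("delays and duplicate_flags must be the same length")
        if len(self.delays) == 0:
            raise ValueError("schedule must contain at least one delay")
        if any(d < 0 for d in self.delays):
            raise ValueError("delays must be non-negative")

    @property
    def n_duplicates(self) -> int:
        return sum(self.duplicate_flags)

    @property
    def total_points(self) -> int:
        return len(self.delays) + self.n_duplicates

    @property
    def acquired_delays(self) -> tuple[float, ...]:
        """Delays expanded so that flagged entries appear twice, in order."""
        out: list[float] = []
        for d, dup in zip(self.delays, self.duplicate_flags):
            out.append(d)
            if dup:
                out.append(d)
        return tuple(out)

    def duplicate_pairs(self, heights: Sequence[float]) -> list[tuple[float, float]]:
        """Pairs of heights acquired at the same (flagged) delay."""
        if len(heights) != self.total_points:
            raise ValueError(
                f"expected {self.total_points} heights, got {len(heights)}"
            )
        pairs, i = [], 0
        for dup in self.duplicate_flags:
            if dup:
                pairs.append((float(heights[i]), float(heights[i + 1])))
                i += 2
            else:
                i += 1
        return pairs


def read_delay_schedule(text: str) -> DelaySchedule:
    """Parse a printed delay list, ms with optional '*' duplicate markers.

    ``"10, 30*, 50"`` -> delays (0.010, 0.030, 0.050) s with the 30 ms
    point flagged as acquired in duplicate.
    """
    tokens = [t for t in re.split(r"[,\s]+", text.strip()) if t]
    if not tokens:
        raise ValueError("empty delay schedule")
    delays, flags = [], []
    for tok in tokens:
        dup = tok.endswith("*")
        body = tok[:-1] if dup else tok
        try:
            value_ms = float(body)
        except ValueError:
            raise ValueError(f"non-numeric delay token {tok!r}") from None
        delays.append(value_ms * 1e-3)
        flags.append(dup)
    return DelaySchedule(tuple(delays), tuple(flags))


def format_delay_schedule(schedule: DelaySchedule) -> str:
    """Inverse of :func:`read_delay_schedule` (ms, '*' for duplicates)."""
    parts = []
    for d, dup in zip(schedule.delays, schedule.duplicate_flags):
        ms = d * 1e3
        body = f"{ms:.10g}"
        parts.append(body + "*" if dup else body)
    return ", ".join(parts)


@dataclass(frozen=True)
class SpectrometerContext:
    """Static field context: proton frequency in MHz, temperature in K."""

    proton_frequency: float
    temperature: float = 298.0

    @property
    def b0(self) -> float:
        """Static field in tesla."""
        return 2.0 * np.pi * self.proton_frequency * 1e6 / GAMMA_H

    @property
    def omega_h(self) -> float:
        """1H Larmor frequency magnitude, rad/s."""
        return 2.0 * np.pi * self.proton_frequency * 1e6

    @property
    def omega_n(self) -> float:
        """15N Larmor frequency magnitude, rad/s."""
        return self.omega_h * abs(GAMMA_N) / GAMMA_H


@dataclass
class IntensitySeries:
    """Peak heights for one residue across the acquired points of a schedule."""

    residue: ResidueID
    schedule: DelaySchedule
    heights: np.ndarray
    noise_sigma: float | None = None

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 1:
            raise ValueError("heights must be one-dimensional")
        if len(self.heights) != self.schedule.total_points:
            raise ValueError(
                f"residue {self.residue.number}: expected "
                f"{self.schedule.total_points} heights, got {len(self.heights)}"
            )
        if not np.all(np.isfinite(self.heights)):
            raise ValueError(f"residue {self.residue.number}: non-finite heights")
        if self.noise_sigma is not None and self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


_RATE_COLUMNS = ["residue", "resname", "kind", "condition", "value",
                 "sigma", "field_mhz", "state"]


class RateTable:
    """Per-residue relaxation observables with uncertainties.

    Thin wrapper over a :class:`pandas.DataFrame` with one record per
    (residue, kind, condition, field, state).  ``kind`` is one of R1, R2,
    noe, R1rho, R2rho, R2eff; ``condition`` carries the HSn label for
    rotating-frame rates or the CPMG frequency in Hz, and is empty
    otherwise.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        for col in _RATE_COLUMNS:
            if col not in df.columns:
                if col == "resname":
                    df[col] = ""
                elif col == "condition":
                    df[col] = ""
                else:
                    raise ValueError(f"rate table missing column {col!r}")
        df = df[_RATE_COLUMNS]
        df["residue"] = df["residue"].astype(int)
        df["condition"] = df["condition"].fillna("").astype(str)
        df["resname"] = df["resname"].fillna("").astype(str)
        bad = ~df["kind"].isin(RATE_KINDS)
        if bad.any():
            raise ValueError(
                f"unknown observable kind(s): {sorted(df.loc[bad, 'kind'].unique())}"
            )
        if (df["sigma"].dropna() < 0).any():
            raise ValueError("uncertainties must be >= 0")
        keys = df[["residue", "kind", "condition", "field_mhz", "state"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].to_dict()
            raise ValueError(f"duplicate rate record key: {dup}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RateTable):
            return NotImplemented
        a = self.df.sort_values(_RATE_COLUMNS[:4]).reset_index(drop=True)
        b = other.df.sort_values(_RATE_COLUMNS[:4]).reset_index(drop=True)
        if len(a) != len(b):
            return False
        for col in _RATE_COLUMNS:
            if col in ("value", "sigma", "field_mhz"):
                x, y = a[col].to_numpy(float), b[col].to_numpy(float)
                both_nan = np.isnan(x) & np.isnan(y)
                close = np.isclose(x, y, rtol=1e-12, atol=0.0)
                if not np.all(both_nan | close):
                    return False
            elif not (a[col] == b[col]).all():
                return False
        return True

    def select(self, kind: str, field_mhz: float | None = None,
               state: str | None = None, condition: str | None = None,
               window: tuple[int, int] | None = None) -> pd.DataFrame:
        df = self.df[self.df["kind"] == kind]
        if field_mhz is not None:
            df = df[np.isclose(df["field_mhz"].to_numpy(float), field_mhz)]
        if state is not None:
            df = df[df["state"] == state]
        if condition is not None:
            df = df[df["condition"] == str(condition)]
        if window is not None:
            lo, hi = window
            df = df[(df["residue"] >= lo) & (df["residue"] <= hi)]
        return df

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "RateTable":
        return cls(pd.DataFrame(list(records)))


def write_rate_table(table: RateTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False, float_format="%.17g")


def read_rate_table(path: str | Path) -> RateTable:
    df = pd.read_csv(path, dtype={"condition": str, "resname": str},
                     keep_default_na=True)
    df["condition"] = df["condition"].fillna("")
    df["resname"] = df["resname"].fillna("")
    return RateTable(df)


def read_intensity_table(path: str | Path, schedule: DelaySchedule,
                         dialect: str = "csv") -> list[IntensitySeries]:
    """Read a residues x acquired-points peak-height table.

    ``csv``: one header line, first column the residue label, remaining
    columns one per acquired point in schedule order.  ``peak-height-export``:
    whitespace-delimited with an ``Assignment`` first column, as emitted by
    common assignment tools.  Empty cells are treated as missing points and
    the series is shortened accordingly only if trailing; interior gaps are
    an error (the schedule no longer lines up).
    """
    path = Path(path)
    if dialect == "csv":
        df = pd.read_csv(path, index_col=0)
    elif dialect == "peak-height-export":
        df = pd.read_csv(path, sep=r"\s+", index_col=0)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    n_expected = schedule.total_points
    if df.shape[1] != n_expected:
        raise ValueError(
            f"{path.name}: expected {n_expected} intensity columns "
            f"(schedule points), found {df.shape[1]}"
        )
    out: list[IntensitySeries] = []
    seen: set[int] = set()
    for label, row in df.iterrows():
        residue = ResidueID.from_label(str(label))
        if residue.number in seen:
            raise ValueError(f"duplicate residue row {label!r}")
        seen.add(residue.number)
        values = row.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValueError(
                f"residue {label!r}: missing intensity values (ragged row)"
            )
        out.append(IntensitySeries(residue, schedule, values))
    return out


#: Flat run configuration: field strengths, core windows, physical constants,
#: and seeds.  CLI flags override these keys one-for-one.
DEFAULT_CONFIG: dict = {
    "fields_mhz": [600.0, 800.0],
    "reference_field_mhz": 600.0,
    "core_window_dsrbd2": [159, 227],
    "core_window_dsrbd1": [1, 105],
    "r_nh_m": 1.02e-10,
    "csa_n_ppm": -172.0,
    "gamma_h": GAMMA_H,
    "gamma_n": GAMMA_N,
    "temperature_k": 298.0,
    "rigid_noe_cutoff": 0.65,
    "rex_thresholds_s": [1.0, 2.0],
    "kex_bins_s": [5000.0, 50000.0],
    "delta_kex_threshold_s": 10000.0,
    "seed": 2024,
}


def load_config(path: str | Path | None = None) -> dict:
    """Load a flat YAML key/value config, merged over the defaults."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError("config must be a flat key/value document")
        cfg.update(user)
    return cfg
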