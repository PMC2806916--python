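"""Depth-resolved data containers.

All depths are centimeters below the sediment-water interface, positive
downward, with 0 at the interface. Measured core intervals are half-open
[top, bottom) and are represented by their midpoints wherever a point depth
is required. Canonical units are fixed at ingest: concentrations in mM
(= micromol per cm^3 of porewater), volumetric rates in nmol cm^-3 d^-1,
isotopic composition in per-mil.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

PROFILE_COLUMNS = ["core_id", "variable", "depth_top_cm", "depth_bottom_cm", "value", "replicate"]
PROFILE_VARIABLES = frozenset({"sulfate", "methane", "rate_srr", "rate_aom", "d13C"})
_NONNEGATIVE_VARIABLES = frozenset({"sulfate", "methane"})


@dataclass(frozen=True)
class DepthGrid:
    """Ordered node depths (cm), strictly increasing."""

    x: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        if x.ndim != 1 or x.size < 2:
            raise ValidationError("DepthGrid needs at least two 1-D node depths")
        if np.any(np.diff(x) <= 0):
            raise ValidationError("DepthGrid depths must be strictly increasing")
        if np.any(x < 0):
            raise ValidationError("DepthGrid depths must be non-negative (cm below seafloor)")
        object.__setattr__(self, "x", x)

    @classmethod
    def uniform(cls, bottom_cm: float, dx_cm: float = 0.1) -> "DepthGrid":
        n = int(round(bottom_cm / dx_cm))
        return cls(np.linspace(0.0, n * dx_cm, n + 1))

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def bottom(self) -> float:
        return float(self.x[-1])

    def __len__(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class SoluteProfile:
    """Porewater concentration C(x) in mM on a depth grid."""

    grid: DepthGrid
    concentration: np.ndarray
    solute: str = "sulfate"
    precision_fraction: float = 0.03  # relative measurement precision of replicates

    def __post_init__(self):
        c = np.asarray(self.concentration, dtype=float)
        if c.shape != self.grid.x.shape:
            raise ValidationError("concentration and grid lengths differ")
        if not np.all(np.isfinite(c)):
            raise ValidationError("concentrations must be finite")
        object.__setattr__(self, "concentration", c)

    def with_concentration(self, c: np.ndarray) -> "SoluteProfile":
        return replace(self, concentration=np.asarray(c, dtype=float))


@dataclass(frozen=True)
class RateProfile:
    """Volumetric process rate R(x) in nmol cm^-3 d^-1 on a depth grid.

    Positive values consume the modeled solute (sulfate reduction consumes
    sulfate); production enters as a negative rate.
    """

    grid: DepthGrid
    rate: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rate, dtype=float)
        if r.shape != self.grid.x.shape:
            raise ValidationError("rate and grid lengths differ")
        if not np.all(np.isfinite(r)):
            raise ValidationError("rates must be finite")
        object.__setattr__(self, "rate", r)

    @classmethod
    def from_layers(cls, grid: DepthGrid, layers) -> "RateProfile":
        """Build a node rate profile from (top_cm, bottom_cm, rate) layers.

        Layers must not overlap; depths not covered by any layer are
        zero-filled. A node belongs to a layer when top <= x < bottom
        (half-open intervals, matching core sectioning).
        """
        layers = sorted((float(t), float(b), float(r)) for t, b, r in layers)
        for (t1, b1, _), (t2, _, _) in zip(layers, layers[1:]):
            if t2 < b1:
                raise ValidationError(f"rate layers overlap at {t2} cm")
        r = np.zeros_like(grid.x)
        for top, bottom, rate in layers:
            if bottom <= top:
                raise ValidationError(f"layer ({top}, {bottom}) has non-positive thickness")
            r[(grid.x >= top) & (grid.x < bottom)] = rate
        return cls(grid, r)


@dataclass(frozen=True)
class IsotopeProfile:
    """delta-13C of methane (per-mil vs. VPDB) per depth; NaN marks depths
    where methane was too low to measure."""

    grid: DepthGrid
    delta13c: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.delta13c, dtype=float)
        if d.shape != self.grid.x.shape:
            raise ValidationError("delta13c and grid lengths differ")
        if np.any(np.isinf(d)):
            raise ValidationError("delta13c values must be finite where present")
        object.__setattr__(self, "delta13c", d)

    @property
    def measured_mask(self) -> np.ndarray:
        return ~np.isnan(self.delta13c)


@dataclass
class ProfileTable:
    """Tidy table of interval-resolved core measurements.

    Columns: core_id, variable, depth_top_cm, depth_bottom_cm, value,
    replicate (nullable integer). One row per measured interval.
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=PROFILE_COLUMNS))

    def __post_init__(self):
        df = self.df.copy()
        missing = [c for c in PROFILE_COLUMNS if c not in df.columns and c != "replicate"]
        if missing:
            raise FormatError(f"ProfileTable missing required column(s): {', '.join(missing)}")
        if "replicate" not in df.columns:
            df["replicate"] = pd.array([pd.NA] * len(df), dtype="Int64")
        df["replicate"] = df["replicate"].astype("Int64")
        for col in ("depth_top_cm", "depth_bottom_cm", "value"):
            df[col] = pd.to_numeric(df[col]).astype(float)
        df = df[PROFILE_COLUMNS]
        self.df = df
        self.validate()
        self.df = df.sort_values(
            ["core_id", "variable", "replicate", "depth_top_cm"], kind="stable"
        ).reset_index(drop=True)

    def validate(self) -> None:
        df = self.df
        bad_var = set(df["variable"]) - PROFILE_VARIABLES
        if bad_var:
            raise ValidationError(f"unknown variable(s): {sorted(bad_var)}")
        if (df["depth_top_cm"] < 0).any():
            raise ValidationError("depth_top_cm must be non-negative")
        bad = df[df["depth_top_cm"] >= df["depth_bottom_cm"]]
        if len(bad):
            raise ValidationError(f"interval top >= bottom in rows {list(bad.index)}")
        neg = df[df["variable"].isin(_NONNEGATIVE_VARIABLES) & (df["value"] < 0)]
        if len(neg):
            raise ValidationError(
                f"negative concentration for {sorted(set(neg['variable']))} in rows {list(neg.index)}"
            )
        for key, grp in df.groupby(["core_id", "variable", "replicate"], dropna=False):
            g = grp.sort_values("depth_top_cm")
            overlap = g["depth_top_cm"].values[1:] < g["depth_bottom_cm"].values[:-1]
            if overlap.any():
                rows = list(g.index[1:][overlap])
                raise ValidationError(f"overlapping depth intervals for {key}: rows {rows}")

    @property
    def midpoints(self) -> pd.Series:
        return (self.df["depth_top_cm"] + self.df["depth_bottom_cm"]) / 2.0

    def select(self, core_id: str, variable: str, replicate=None) -> pd.DataFrame:
        df = self.df
        m = (df["core_id"] == core_id) & (df["variable"] == variable)
        if replicate is not None:
            m &= df["replicate"] == replicate
        out = df[m].copy()
        out["depth_mid_cm"] = (out["depth_top_cm"] + out["depth_bottom_cm"]) / 2.0
        return out.sort_values("depth_mid_cm").reset_index(drop=True)

    def averaged_points(self, core_id: str, variable: str):
        """(midpoint depths, values) with replicate values at the same depth averaged."""
        sel = self.select(core_id, variable)
        g = sel.groupby("depth_mid_cm")["value"].mean()
        return g.index.to_numpy(), g.to_numpy()

    def __eq__(self, other) -> bool:
        return isinstance(other, ProfileTable) and self.df.equals(other.df)

    def __len__(self) -> int:
        return len(self.df)
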