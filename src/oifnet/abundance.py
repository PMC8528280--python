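"""Census-table handling: loading, normalization, temperature partitions, windows.

The analysis operates on a community census: rows are census dates (roughly
biweekly in the motivating coastal survey), columns are per-species abundance
plus sea-surface and sea-bottom temperature.  Everything downstream consumes
either the raw counts (presence/absence diversity) or the per-species z-scored
abundance (information-theoretic inference), so both are kept side by side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesMeta",
    "CensusTable",
    "NormalizedAbundance",
    "TRPartition",
    "WindowSpec",
    "DiversitySeries",
    "load_census",
    "normalize",
    "partition_by_TR",
    "make_windows",
    "alpha_diversity",
    "group_abundance",
    "DEFAULT_TR_EDGES",
]

#: Default temperature cut points (°C) giving the five canonical ranges
#: (-inf, 10], [10, 15), [15, 20), [20, 25), [25, inf).
DEFAULT_TR_EDGES = (10.0, 15.0, 20.0, 25.0)

GROUPS = ("EP", "FS", "native", "invasive")


@dataclass
class SpeciesMeta:
    """Per-species metadata: identity, stock/endemicity flags, dynamical role."""

    index: int  # 1-based species id
    scientific_name: str = ""
    common_name: str = ""
    is_fish_stock: bool = False
    is_native: bool = True
    dynamical_role: str = "cooperative"  # "competitive" | "cooperative"

    def __post_init__(self):
        if self.dynamical_role not in ("competitive", "cooperative"):
            raise ValueError(
                f"dynamical_role must be 'competitive' or 'cooperative', "
                f"got {self.dynamical_role!r}"
            )


def default_species_meta(n: int, competitive: Sequence[int] = range(4, 10)) -> list[SpeciesMeta]:
    """Metadata with 1-based ids ``1..n``; species in ``competitive`` (default
    4-9, the competitive block of the motivating community) get that role."""
    comp = set(competitive)
    return [
        SpeciesMeta(
            index=i,
            scientific_name=f"sp{i}",
            common_name=f"species {i}",
            dynamical_role="competitive" if i in comp else "cooperative",
        )
        for i in range(1, n + 1)
    ]


@dataclass
class CensusTable:
    """Validated community census: counts, temperatures and species metadata.

    ``counts`` is species x time (nonnegative reals; one planktonic species in
    the motivating dataset is area-normalized and fractional).
    """

    timestamps: pd.DatetimeIndex
    counts: np.ndarray
    surface_temp: np.ndarray
    bottom_temp: np.ndarray
    species_meta: list[SpeciesMeta]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.surface_temp = np.asarray(self.surface_temp, dtype=float)
        self.bottom_temp = np.asarray(self.bottom_temp, dtype=float)
        n, L = self.counts.shape
        if len(self.species_meta) != n:
            raise ValueError(
                f"species metadata lists {len(self.species_meta)} species but "
                f"the table has {n} species columns"
            )
        ids = [m.index for m in self.species_meta]
        if ids != list(range(1, n + 1)):
            raise ValueError("species indices must form a contiguous 1..n sequence")
        if len(self.timestamps) != L:
            raise ValueError("timestamps length does not match counts")
        diffs = np.diff(self.timestamps.view(np.int64))
        if np.any(diffs <= 0):
            bad = np.nonzero(diffs <= 0)[0] + 1
            raise ValueError(
                f"census dates must be strictly increasing; offending rows "
                f"(0-based): {bad.tolist()}"
            )
        if np.any(self.counts < 0):
            sp, tp = np.nonzero(self.counts < 0)
            raise ValueError(
                f"negative abundance at species {sp[0] + 1}, time index {tp[0]}"
            )
        for name, arr in (("surface", self.surface_temp), ("bottom", self.bottom_temp)):
            if arr.shape != (L,):
                raise ValueError(f"{name} temperature length mismatch")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} temperature contains non-finite values")

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def L(self) -> int:
        return self.counts.shape[1]

    @property
    def mean_temp(self) -> np.ndarray:
        return (self.surface_temp + self.bottom_temp) / 2.0

    def to_frame(self) -> pd.DataFrame:
        """Tidy wide frame in the on-disk dialect (date, surface.t, bottom.t, species...)."""
        data = {"date": self.timestamps, "surface.t": self.surface_temp,
                "bottom.t": self.bottom_temp}
        for i, m in enumerate(self.species_meta):
            data[m.scientific_name or f"sp{m.index}"] = self.counts[i]
        return pd.DataFrame(data)


@dataclass
class NormalizedAbundance:
    """Per-species z-scored abundance with covariates.

    ``x`` is species x time; each row has sample mean 0 and sample standard
    deviation 1 (denominator L-1) over all L points.  Raw counts are retained
    because presence/absence diversity must be computed on them (a z-score is
    negative at an absence).
    """

    x: np.ndarray
    timestamps: pd.DatetimeIndex
    mean_temp: np.ndarray
    raw_counts: np.ndarray | None = None
    species_meta: list[SpeciesMeta] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def L(self) -> int:
        return self.x.shape[1]

    def subset(self, idx: np.ndarray) -> "NormalizedAbundance":
        """Restriction to the census points ``idx`` (original order preserved).
        z-scores are inherited from the full record, not recomputed."""
        idx = np.asarray(idx)
        return NormalizedAbundance(
            x=self.x[:, idx],
            timestamps=self.timestamps[idx],
            mean_temp=self.mean_temp[idx],
            raw_counts=None if self.raw_counts is None else self.raw_counts[:, idx],
            species_meta=self.species_meta,
        )


@dataclass
class TRPartition:
    """Census points split into ordered temperature-range bins."""

    edges: tuple[float, ...]
    bins: list[str]
    subsets: list[NormalizedAbundance]
    membership: np.ndarray  # per census point, bin index

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(s.L for s in self.subsets)


@dataclass
class WindowSpec:
    """Sliding-window layout along time (census points) or temperature (°C).

    The number of windows is ``G = floor((L - l) / step) + 1``.  Time windows
    hold exactly ``l`` consecutive census points advanced by ``step`` points;
    temperature windows are half-open ``[T, T + width)`` intervals whose lower
    bound advances by ``step`` °C, with ``l`` the upper limit of the first
    window and ``width`` the window extent (default 5 °C).
    """

    axis: str  # "time" | "temperature"
    L: int
    l: int
    step: int
    width: float | None = None  # temperature-window extent, °C

    def __post_init__(self):
        if self.axis not in ("time", "temperature"):
            raise ValueError("axis must be 'time' or 'temperature'")
        if self.step <= 0:
            raise ValueError("window step must be positive")
        if self.axis == "temperature" and self.width is None:
            self.width = 5.0

    @property
    def G(self) -> int:
        if self.L <= self.l:
            return 1
        return int(np.floor((self.L - self.l) / self.step)) + 1

    def starts(self) -> np.ndarray:
        """Window start positions: point indices (time) or lower bounds °C
        (temperature, first lower bound ``l - width``)."""
        if self.axis == "time":
            return np.arange(self.G) * self.step
        first = self.l - self.width
        return first + np.arange(self.G) * float(self.step)

    def time_slices(self) -> list[slice]:
        if self.axis != "time":
            raise ValueError("time_slices only defined for the time axis")
        return [slice(s, s + self.l) for s in self.starts()]

    def temperature_intervals(self) -> list[tuple[float, float]]:
        if self.axis != "temperature":
            raise ValueError("temperature_intervals only defined for the temperature axis")
        return [(lo, lo + self.width) for lo in self.starts()]


@dataclass
class DiversitySeries:
    """Taxonomic diversity and group-abundance series."""

    alpha_t: np.ndarray
    mean_temp: np.ndarray
    timestamps: pd.DatetimeIndex
    group_A: dict[str, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# operations


def load_census(path: str | Path, meta: Sequence[SpeciesMeta] | str | Path | None = None,
                ) -> CensusTable:
    """Load a delimited (or spreadsheet) census table.

    Expected columns: ``date`` (ISO-8601), ``surface.t``, ``bottom.t`` and one
    column per species, in metadata order.  ``meta`` may be a list of
    :class:`SpeciesMeta`, a path to a metadata CSV
    (columns: index, scientific_name, common_name, fish_stock, native, role),
    or None to default roles (competitive block = species 4-9).
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip() for c in df.columns]
    temp_cols = [c for c in df.columns if c.lower() in ("surface.t", "bottom.t")]
    if len(temp_cols) < 2:
        raise ValueError(
            "census table must contain 'surface.t' and 'bottom.t' columns; "
            f"found temperature columns: {temp_cols}"
        )
    if "date" not in [c.lower() for c in df.columns]:
        raise ValueError("census table must contain a 'date' column")
    date_col = next(c for c in df.columns if c.lower() == "date")
    sp_cols = [c for c in df.columns if c != date_col and c.lower() not in
               ("surface.t", "bottom.t")]

    if meta is None:
        species_meta = default_species_meta(len(sp_cols))
        for m, c in zip(species_meta, sp_cols):
            m.scientific_name = c
    elif isinstance(meta, (str, Path)):
        species_meta = load_species_meta(meta)
    else:
        species_meta = list(meta)
    if len(species_meta) != len(sp_cols):
        raise ValueError(
            f"table has {len(sp_cols)} species columns but metadata lists "
            f"{len(species_meta)} species"
        )
    # match by name where possible, otherwise by position
    by_name = {m.scientific_name: m for m in species_meta}
    ordered = []
    if all(c in by_name for c in sp_cols):
        order = sorted(range(len(sp_cols)), key=lambda k: by_name[sp_cols[k]].index)
        sp_cols = [sp_cols[k] for k in order]
        ordered = [by_name[c] for c in sp_cols]
    else:
        ordered = species_meta

    timestamps = pd.DatetimeIndex(pd.to_datetime(df[date_col]))
    counts = df[sp_cols].to_numpy(dtype=float).T
    return CensusTable(
        timestamps=timestamps,
        counts=counts,
        surface_temp=df[next(c for c in df.columns if c.lower() == "surface.t")].to_numpy(float),
        bottom_temp=df[next(c for c in df.columns if c.lower() == "bottom.t")].to_numpy(float),
        species_meta=ordered,
    )


def load_species_meta(path: str | Path) -> list[SpeciesMeta]:
    df = pd.read_csv(path)
    metas = []
    for _, row in df.iterrows():
        metas.append(SpeciesMeta(
            index=int(row["index"]),
            scientific_name=str(row.get("scientific_name", "")),
            common_name=str(row.get("common_name", "")),
            is_fish_stock=bool(row.get("fish_stock", False)),
            is_native=bool(row.get("native", True)),
            dynamical_role=str(row.get("role", "cooperative")),
        ))
    return sorted(metas, key=lambda m: m.index)


def normalize(tab: CensusTable) -> NormalizedAbundance:
    """z-score each species over the full record (sample sd, denominator L-1)."""
    counts = tab.counts
    sd = counts.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = [tab.species_meta[i].scientific_name or str(i + 1)
               for i in np.nonzero(sd == 0)[0]]
        raise ValueError(f"cannot z-score constant species column(s): {bad}")
    x = (counts - counts.mean(axis=1, keepdims=True)) / sd[:, None]
    return NormalizedAbundance(
        x=x,
        timestamps=tab.timestamps,
        mean_temp=tab.mean_temp,
        raw_counts=counts,
        species_meta=tab.species_meta,
    )


def partition_by_TR(na: NormalizedAbundance,
                    edges: Sequence[float] = DEFAULT_TR_EDGES) -> TRPartition:
    """Assign each census point to a temperature-range bin by its mean
    temperature.

    Interior boundaries are half-open upward (a point exactly at 15.0 °C goes
    to the 15-20 bin); the extreme bins are (-inf, e0] and [e_last, inf), so
    the first boundary is closed downward, matching the "<=10" / ">=25"
    convention of the canonical five ranges.
    """
    edges = tuple(float(e) for e in edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("temperature edges must be strictly increasing")
    T = na.mean_temp
    # membership: bin 0 is T <= e0; bin k (interior) is [e_{k-1}, e_k); last is T >= e_last
    membership = np.searchsorted(edges, T, side="right")
    # searchsorted puts T == e0 into bin 1; the first bin is closed at e0
    membership[T == edges[0]] = 0
    labels = ([f"<= {edges[0]:g}"] +
              [f"{a:g}-{b:g}" for a, b in zip(edges, edges[1:])] +
              [f">= {edges[-1]:g}"])
    subsets = []
    for k in range(len(edges) + 1):
        idx = np.nonzero(membership == k)[0]
        if idx.size == 0:
            warnings.warn(f"temperature bin {labels[k]} is empty")
        subsets.append(na.subset(idx))
    return TRPartition(edges=edges, bins=labels, subsets=subsets, membership=membership)


def make_windows(axis: str, L: int, l: int, step: int, width: float = 5.0) -> WindowSpec:
    """Build a sliding-window spec; see :class:`WindowSpec` for the G formula."""
    if step <= 0:
        raise ValueError("window step must be positive")
    if l <= 0:
        raise ValueError("window parameter l must be positive")
    if L <= l:
        warnings.warn(f"extent L={L} <= l={l}: single window")
    return WindowSpec(axis=axis, L=L, l=l, step=step,
                      width=width if axis == "temperature" else None)


def alpha_diversity(tab: CensusTable) -> DiversitySeries:
    """Taxonomic alpha-diversity: the number of species with strictly positive
    raw abundance at each census point (the 0^0 := 0 convention, i.e. absent
    species do not count)."""
    alpha = (tab.counts > 0).sum(axis=0).astype(int)
    return DiversitySeries(alpha_t=alpha, mean_temp=tab.mean_temp,
                           timestamps=tab.timestamps)


def group_abundance(tab: CensusTable, group: str,
                    na: NormalizedAbundance | None = None) -> np.ndarray:
    """Total normalized abundance over a species group at each census point.

    Groups: ``EP`` (all species; the ecological-productivity proxy), ``FS``
    (fish stocks), ``native``, ``invasive``.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; valid groups: {GROUPS}")
    if na is None:
        na = normalize(tab)
    if group == "EP":
        mask = np.ones(tab.n, dtype=bool)
    elif group == "FS":
        mask = np.array([m.is_fish_stock for m in tab.species_meta])
    elif group == "native":
        mask = np.array([m.is_native for m in tab.species_meta])
    else:
        mask = np.array([not m.is_native for m in tab.species_meta])
    return na.x[mask].sum(axis=0)
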