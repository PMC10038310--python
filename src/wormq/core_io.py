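"""Domain types, readers/writers, detection presets and logging.

The package quantifies sleep (mobility quiescence) and neuronal activity of
single C. elegans larvae recorded in agarose microchambers at slow frame
rates (0.1-0.33 Hz), plus starvation-survival statistics.  Everything here is
plumbing shared by the analysis stages: the per-animal ``Trace`` container,
interval (``Bout``) bookkeeping in 0-based half-open frame coordinates,
named detection presets, and plain-text table I/O.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("wormq")

#: Column order of the per-animal trace table (CSV/TSV).
TRACE_COLUMNS = ("animal_id", "frame", "x", "y", "gcamp", "mkate2", "motion", "valid")

#: Bout labels used across the package.
BOUT_LABELS = ("mobility_quiescence", "neuronal_inactivity", "rim_inactivity")


def configure_logging(level: int = logging.INFO) -> None:
    """Attach a basic stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Trace:
    """One animal's per-frame record on a uniform time grid.

    Channels are optional (``None``) because different experiments record
    different subsets: DIC movies carry only ``motion``; calcium movies carry
    positions and the GCaMP/mKate2 pair.  Frames where ROI tracking failed
    are flagged invalid rather than zero-filled -- zeros would fake
    immobility and corrupt the per-animal min/max normalization.
    """

    animal_id: str
    strain: str
    dt: float
    t: np.ndarray
    x: np.ndarray | None = None
    y: np.ndarray | None = None
    gcamp: np.ndarray | None = None
    mkate2: np.ndarray | None = None
    motion: np.ndarray | None = None
    speed: np.ndarray | None = None
    rim: np.ndarray | None = None
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        self.t = np.asarray(self.t, dtype=float)
        n = self.t.size
        if n >= 2:
            steps = np.diff(self.t)
            if np.any(steps <= 0) or np.any(np.abs(steps - self.dt) > 1e-9 * max(self.dt, 1.0)):
                raise ValueError("timestamps must increase uniformly by dt")
        for name in ("x", "y", "gcamp", "mkate2", "motion", "speed", "rim"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.size != n:
                    raise ValueError(f"channel {name!r} length {arr.size} != {n} frames")
                setattr(self, name, arr)
        for name in ("gcamp", "mkate2", "motion"):
            arr = getattr(self, name)
            if arr is not None and np.any(arr[np.isfinite(arr)] < 0):
                raise ValueError(f"negative intensities in channel {name!r}")
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.size != n:
                raise ValueError("valid flag length mismatch")

    @property
    def n_frames(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        """Total recorded time in seconds (n_frames x dt)."""
        return self.n_frames * self.dt


@dataclass(frozen=True)
class Bout:
    """A detected interval, 0-based half-open in frames: [start, end)."""

    start_index: int
    end_index: int
    dt: float
    label: str

    def __post_init__(self) -> None:
        if self.end_index <= self.start_index:
            raise ValueError("bout must span at least one frame")
        if self.label not in BOUT_LABELS:
            raise ValueError(f"unknown bout label {self.label!r}")

    @property
    def start_time(self) -> float:
        return self.start_index * self.dt

    @property
    def end_time(self) -> float:
        return self.end_index * self.dt

    @property
    def duration(self) -> float:
        return (self.end_index - self.start_index) * self.dt


@dataclass
class BoutSet:
    """Ordered, non-overlapping bouts of one label on one trace."""

    animal_id: str
    label: str
    bouts: list[Bout]
    trace_duration: float

    def __post_init__(self) -> None:
        self.bouts = sorted(self.bouts, key=lambda b: b.start_index)
        for prev, cur in zip(self.bouts, self.bouts[1:]):
            if cur.start_index < prev.end_index + 1:
                raise ValueError("bouts must be separated by at least one frame")
        if sum(b.duration for b in self.bouts) > self.trace_duration + 1e-9:
            raise ValueError("total bout time exceeds trace duration")

    def __len__(self) -> int:
        return len(self.bouts)

    def __iter__(self):
        return iter(self.bouts)

    @property
    def total_duration(self) -> float:
        return float(sum(b.duration for b in self.bouts))


@dataclass(frozen=True)
class DetectionParams:
    """Named detection preset.

    ``kind='threshold'`` presets detect runs of the smoothed, per-animal
    0-1 normalized series beyond a fractional threshold lasting at least
    ``min_duration`` seconds.  ``kind='prominence'`` presets (RIM) detect
    calcium peaks of minimum topographic prominence and call the animal
    inactive during peak-free gaps of at least ``min_duration`` seconds.
    """

    name: str
    smooth_window: int
    threshold: float
    min_duration: float
    direction: Literal["below", "above"] = "below"
    eligibility_pre: float = 180.0
    kind: Literal["threshold", "prominence"] = "threshold"

    def __post_init__(self) -> None:
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")
        if self.kind == "threshold" and not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        if self.min_duration <= 0:
            raise ValueError("min_duration must be positive")
        if self.direction not in ("below", "above"):
            raise ValueError("direction must be 'below' or 'above'")


@dataclass
class SurvivalTable:
    """Per strain x day counts of alive (or recovered) vs scored animals."""

    data: pd.DataFrame

    REQUIRED = ("strain", "day", "n_alive", "n_scored", "endpoint")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data).copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"survival table missing columns {missing}")
        df["day"] = df["day"].astype(int)
        df["n_alive"] = df["n_alive"].astype(int)
        df["n_scored"] = df["n_scored"].astype(int)
        if (df["day"] < 0).any():
            raise ValueError("days must be >= 0")
        if (df["n_scored"] <= 0).any():
            raise ValueError("n_scored must be positive")
        if (df["n_alive"] > df["n_scored"]).any() or (df["n_alive"] < 0).any():
            raise ValueError("need 0 <= n_alive <= n_scored")
        bad = set(df["endpoint"]) - {"survival", "recovery"}
        if bad:
            raise ValueError(f"unknown endpoint values {sorted(bad)}")
        df["fraction"] = df["n_alive"] / df["n_scored"]
        self.data = df.sort_values(["strain", "day"]).reset_index(drop=True)

    @property
    def strains(self) -> list[str]:
        return sorted(self.data["strain"].unique())

    def for_strain(self, strain: str, endpoint: str | None = None) -> pd.DataFrame:
        df = self.data[self.data["strain"] == strain]
        if endpoint is not None:
            df = df[df["endpoint"] == endpoint]
        if df.empty:
            raise KeyError(f"no rows for strain {strain!r}")
        return df.reset_index(drop=True)


@dataclass
class LogisticFit:
    """Three-parameter logistic survival fit S(t) = A / (1 + exp(k (t - t50)))."""

    A: float
    t50: float
    k: float
    rss: float
    converged: bool

    def predict(self, day) -> np.ndarray:
        day = np.asarray(day, dtype=float)
        return self.A / (1.0 + np.exp(self.k * (day - self.t50)))


@dataclass(frozen=True)
class LinearFit:
    """Ordinary least squares line y = intercept + slope * x."""

    intercept: float
    slope: float
    r_squared: float

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass
class PeakSet:
    """Local maxima of a series with their topographic prominences."""

    indices: np.ndarray
    prominences: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.prominences = np.asarray(self.prominences, dtype=float)
        if self.indices.size != self.prominences.size:
            raise ValueError("indices and prominences must have equal length")

    def __len__(self) -> int:
        return self.indices.size


@dataclass
class AlignedEnsemble:
    """Trace snippets stacked relative to bout onsets.

    ``relative_time`` spans [-pre, +post) in seconds with 0 at the bout onset
    frame; ``snippets`` has one row per eligibility-passing bout.
    """

    relative_time: np.ndarray
    snippets: np.ndarray
    quantity_label: str

    def __post_init__(self) -> None:
        self.relative_time = np.asarray(self.relative_time, dtype=float)
        self.snippets = np.asarray(self.snippets, dtype=float)
        if self.snippets.ndim != 2 or self.snippets.shape[1] != self.relative_time.size:
            raise ValueError("snippets must be (n_bouts, n_timepoints)")

    @property
    def n_bouts(self) -> int:
        return self.snippets.shape[0]

    def mean(self) -> np.ndarray:
        return self.snippets.mean(axis=0) if self.n_bouts else np.full_like(self.relative_time, np.nan)

    def sem(self) -> np.ndarray:
        if self.n_bouts < 2:
            return np.full_like(self.relative_time, np.nan)
        return self.snippets.std(axis=0, ddof=1) / np.sqrt(self.n_bouts)

    def paired_pre_post(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-bout mean over the pre window vs mean over the post window.

        This is the paired summary fed to the signed-rank comparison of the
        aligned quantity before vs after quiescence onset.
        """
        pre = self.relative_time < 0
        post = ~pre
        return self.snippets[:, pre].mean(axis=1), self.snippets[:, post].mean(axis=1)


# ---------------------------------------------------------------------------
# Detection presets
# ---------------------------------------------------------------------------

# Built-in presets.  Thresholds are fractions of the per-animal normalized
# range; minimum durations in seconds; smoothing windows in time points
# (points, not seconds -- the convention is frame-rate independent).
_BUILTIN_PRESETS: dict[str, dict] = {
    # calcium imaging, 20x objective: below 10% for >= 3 min
    "calcium_20x": dict(smooth_window=30, threshold=0.10, min_duration=180.0, direction="below"),
    # calcium imaging, 10x objective: below 5% for >= 4 min
    "calcium_10x": dict(smooth_window=30, threshold=0.05, min_duration=240.0, direction="below"),
    # DIC frame-subtraction movies, 20x: below 15% for >= 3 min
    "dic_20x": dict(smooth_window=30, threshold=0.15, min_duration=180.0, direction="below"),
    # pan-neuronal inactivity: below 20% for >= 3 min
    "neuronal": dict(smooth_window=30, threshold=0.20, min_duration=180.0, direction="below"),
    # RIM peaks: smooth over 5 points, prominence >= 0.2, inactive when no
    # peak for >= 5 min ("threshold" holds the prominence here)
    "rim_peaks": dict(smooth_window=5, threshold=0.2, min_duration=300.0,
                      direction="below", kind="prominence"),
}


def load_presets(config_path: str | Path | None = None,
                 overrides: Mapping[str, Mapping] | None = None) -> dict[str, DetectionParams]:
    """Return the named detection presets, optionally layered with overrides.

    Layering: built-in defaults < YAML config file < in-memory ``overrides``
    (the CLI passes flag values through ``overrides``).  The config file maps
    preset names to partial parameter dicts; unknown keys are rejected.
    """
    merged: dict[str, dict] = {name: dict(cfg) for name, cfg in _BUILTIN_PRESETS.items()}

    def apply(layer: Mapping[str, Mapping], source: str) -> None:
        for name, cfg in layer.items():
            base = merged.setdefault(name, {})
            allowed = {f.name for f in dataclasses.fields(DetectionParams)} - {"name"}
            unknown = set(cfg) - allowed
            if unknown:
                raise ValueError(f"unknown preset keys {sorted(unknown)} in {source}")
            base.update(cfg)

    if config_path is not None:
        with open(config_path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError("preset config must be a mapping of preset name -> params")
        apply(loaded, str(config_path))
    if overrides:
        apply(overrides, "overrides")

    return {name: DetectionParams(name=name, **cfg) for name, cfg in merged.items()}


def get_preset(name: str, presets: Mapping[str, DetectionParams] | None = None) -> DetectionParams:
    """Look up one preset, raising with the list of available names."""
    presets = presets if presets is not None else load_presets()
    try:
        return presets[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}") from None


# ---------------------------------------------------------------------------
# Trace table I/O
# ---------------------------------------------------------------------------

def read_trace_table(path: str | Path, dt: float, unit_scale: float = 1.0,
                     strain_map: Mapping[str, str] | None = None) -> list[Trace]:
    """Read a per-frame trace table (CSV/TSV) into one Trace per animal.

    Expected columns: animal_id, frame, x, y, gcamp, mkate2, motion, valid
    (frame 0-based and contiguous per animal).  Positions are multiplied by
    ``unit_scale`` (micrometers per table unit).  Missing cells render the
    frame invalid.  An optional ``speed`` column is carried through.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".bed") else ","
    # round_trip parsing so written float64 values are recovered bit-for-bit
    df = pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")
    missing = [c for c in ("animal_id", "frame") if c not in df.columns]
    if missing:
        raise ValueError(f"trace table missing columns {missing}")
    traces = []
    for animal_id, grp in df.groupby("animal_id", sort=True):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy()
        if not np.array_equal(frames, np.arange(len(frames))):
            raise ValueError(f"non-contiguous frames for animal {animal_id!r}")
        n = len(frames)

        def col(name, scale=1.0):
            if name not in grp.columns:
                return None
            vals = pd.to_numeric(grp[name], errors="coerce").to_numpy(dtype=float)
            if np.isnan(vals).all():    # channel not recorded for this animal
                return None
            return vals * scale

        x = col("x", unit_scale)
        y = col("y", unit_scale)
        gcamp, mkate2, motion = col("gcamp"), col("mkate2"), col("motion")
        speed, rim = col("speed"), col("rim")
        for name, arr in (("gcamp", gcamp), ("mkate2", mkate2), ("motion", motion)):
            if arr is not None and np.any(arr[np.isfinite(arr)] < 0):
                raise ValueError(f"negative intensities in column {name!r} for animal {animal_id!r}")

        valid = np.ones(n, dtype=bool)
        if "valid" in grp.columns:
            vraw = grp["valid"]
            valid &= vraw.map(lambda v: str(v).strip().lower() in ("1", "true", "yes")).to_numpy()
        for arr in (x, y, gcamp, mkate2, motion):
            if arr is not None:
                valid &= np.isfinite(arr)

        strain = str(grp["strain"].iloc[0]) if "strain" in grp.columns else ""
        if strain_map and str(animal_id) in strain_map:
            strain = strain_map[str(animal_id)]
        traces.append(Trace(animal_id=str(animal_id), strain=strain, dt=dt,
                            t=np.arange(n) * dt, x=x, y=y, gcamp=gcamp,
                            mkate2=mkate2, motion=motion, speed=speed, rim=rim,
                            valid=valid))
    return traces


def write_trace_table(traces: Iterable[Trace], path: str | Path) -> None:
    """Write traces to a CSV readable by :func:`read_trace_table`."""
    rows = []
    for tr in traces:
        n = tr.n_frames
        def ch(arr):
            return arr if arr is not None else np.full(n, np.nan)
        rows.append(pd.DataFrame({
            "animal_id": tr.animal_id,
            "strain": tr.strain,
            "frame": np.arange(n),
            "x": ch(tr.x), "y": ch(tr.y),
            "gcamp": ch(tr.gcamp), "mkate2": ch(tr.mkate2),
            "motion": ch(tr.motion), "speed": ch(tr.speed), "rim": ch(tr.rim),
            "valid": tr.valid.astype(int),
        }))
    # %.17g guarantees float64 values survive the text round trip bit-for-bit
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Bout table I/O (BED-like TSV; times in seconds, not genomic coordinates)
# ---------------------------------------------------------------------------

_BOUT_HEADER = "# wormq bouts: half-open intervals [start_time_s, end_time_s); times in seconds"


def write_bouts(boutset: BoutSet, path: str | Path, append: bool = False) -> None:
    """Write a BoutSet as a BED-like tab-separated interval table."""
    # BoutSet.__post_init__ already refuses overlapping bouts
    path = Path(path)
    mode = "a" if append and path.exists() else "w"
    with open(path, mode) as fh:
        if mode == "w":
            fh.write(_BOUT_HEADER + "\n")
            fh.write("animal_id\tstart_time_s\tend_time_s\tlabel\tduration_s\n")
        for b in boutset.bouts:
            fh.write(f"{boutset.animal_id}\t{b.start_time:.6f}\t{b.end_time:.6f}"
                     f"\t{b.label}\t{b.duration:.6f}\n")


def read_bouts(path: str | Path, dt: float, trace_duration: float,
               animal_id: str | None = None) -> list[BoutSet]:
    """Read a bout table back into BoutSets (one per animal x label)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.empty:
        return []
    out = []
    for (aid, label), grp in df.groupby(["animal_id", "label"], sort=True):
        if animal_id is not None and str(aid) != animal_id:
            continue
        bouts = [Bout(start_index=int(round(r.start_time_s / dt)),
                      end_index=int(round(r.end_time_s / dt)),
                      dt=dt, label=label)
                 for r in grp.itertuples()]
        out.append(BoutSet(animal_id=str(aid), label=label, bouts=bouts,
                           trace_duration=trace_duration))
    return out


# ---------------------------------------------------------------------------
# Survival table I/O
# ---------------------------------------------------------------------------

def read_survival_table(path: str | Path) -> SurvivalTable:
    """Read a survival CSV (strain, day, n_alive, n_scored, endpoint)."""
    df = pd.read_csv(path, comment="#")
    if "endpoint" not in df.columns:
        df["endpoint"] = "survival"
    return SurvivalTable(df)


def write_survival_table(table: SurvivalTable, path: str | Path) -> None:
    cols = [c for c in table.data.columns if c != "fraction"]
    table.data[cols].to_csv(path, index=False)
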