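"""Table IO, run configuration, and the synthetic fixture generator.

Abundance tables travel as UTF-8 tab-separated files with a header line and
columns ``time  population  type  count``; shift curves as
``delay  mean  sd  n``.  Run configurations are flat YAML mappings whose keys
mirror the Params fields (plus schedule and seed); unknown keys are errors so
sweep typos fail loudly.

The fixture generator emulates the statistical shape of experiment-derived
count tables — approximately exponential clone-size distributions, partial
type overlap between the bacterial and phage populations, and gradual type
turnover — so the whole analysis layer can run without any external data.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .analysis import AbundanceSeries, ShiftCurve
from .params import CrossReactivity, Params
from .simulate import RecordingSchedule, make_schedule, run_length_rule

__all__ = [
    "FixtureSpec",
    "generate_fixture",
    "read_series",
    "write_series",
    "write_shift_curve",
    "load_config",
    "save_config",
    "write_manifest",
    "run_length_rule",
]

PathLike = Union[str, Path]

_SERIES_COLUMNS = ["time", "population", "type", "count"]


# ----------------------------------------------------------------------
# abundance-series IO
# ----------------------------------------------------------------------

def write_series(path: PathLike, *series: AbundanceSeries) -> None:
    """Write one or more series (long format, tab-separated, with header)."""
    rows = []
    for s in series:
        for i, t in enumerate(s.times):
            for k, ty in enumerate(s.types):
                c = s.counts[i, k]
                if c > 0:
                    rows.append((t, s.population, ty, c))
    df = pd.DataFrame(rows, columns=_SERIES_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_series(path: PathLike, population: Optional[str] = None,
                units: str = "generations") -> AbundanceSeries:
    """Read one population's series back; validates header and uniqueness.

    Malformed rows raise with a line number; duplicate (time, type) cells are
    a validation error.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header != _SERIES_COLUMNS:
        raise ValueError(f"{path}: expected header {_SERIES_COLUMNS}, got {header}")
    try:
        df = pd.read_csv(path, sep="\t", dtype={"type": str})
    except Exception as err:  # pragma: no cover - pandas error text varies
        raise ValueError(f"{path}: parse error: {err}") from err
    for ln, row in enumerate(df.itertuples(index=False), start=2):
        if pd.isna(row.time) or pd.isna(row.count):
            raise ValueError(f"{path}:{ln}: malformed row {tuple(row)}")
        if row.count < 0:
            raise ValueError(f"{path}:{ln}: negative count")
    pops = sorted(df["population"].unique())
    if population is None:
        if len(pops) != 1:
            raise ValueError(f"{path}: contains populations {pops}; pick one")
        population = pops[0]
    sub = df[df["population"] == population]
    if sub.duplicated(subset=["time", "type"]).any():
        dup = sub[sub.duplicated(subset=["time", "type"])].iloc[0]
        raise ValueError(f"{path}: duplicate (time, type) cell "
                         f"({dup['time']}, {dup['type']})")
    times = np.sort(sub["time"].unique())
    types = sorted(sub["type"].unique())
    counts = np.zeros((len(times), len(types)))
    ti = {t: i for i, t in enumerate(times)}
    ki = {t: k for k, t in enumerate(types)}
    for row in sub.itertuples(index=False):
        counts[ti[row.time], ki[row.type]] = row.count
    return AbundanceSeries(times, types, counts, population, units)


def write_shift_curve(path: PathLike, curve: ShiftCurve) -> None:
    curve.to_frame().to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------

_PARAM_KEYS = {f.name for f in dataclasses.fields(Params)}
_SCHEDULE_KEYS = {"t_end", "snapshot_times", "n_snapshots", "totals_every",
                  "steady_state_start"}
_OTHER_KEYS = {"seed", "engine", "tau", "leap_eps", "adaptive", "m_init", "nV0",
               "xr_mode", "theta"}


def load_config(path: PathLike) -> Dict[str, object]:
    """Load a flat YAML run configuration; unknown keys are errors.

    Returns a dict with ``params`` (Params), ``schedule`` (RecordingSchedule
    or None) and the remaining run options.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a flat key-value mapping")
    unknown = set(raw) - _PARAM_KEYS - _SCHEDULE_KEYS - _OTHER_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    pkw = {k: v for k, v in raw.items() if k in _PARAM_KEYS and k != "xr"}
    if "xr_mode" in raw or "theta" in raw:
        pkw["xr"] = CrossReactivity(mode=raw.get("xr_mode", "none"),
                                    theta=float(raw.get("theta", 0.0)))
    params = Params(**pkw)
    schedule = None
    if _SCHEDULE_KEYS & set(raw):
        t_end = raw.get("t_end")
        if t_end is None:
            t_end, _ = run_length_rule(params.C0)
        snaps = raw.get("snapshot_times")
        if snaps is None:
            n = int(raw.get("n_snapshots", 15))
            ss = raw.get("steady_state_start", t_end / 5.0)
            snaps = list(np.linspace(ss, t_end, n))
        schedule = make_schedule(
            t_end, snaps, totals_every=float(raw.get("totals_every", 10.0)),
            steady_state_start=raw.get("steady_state_start"))
    opts = {k: raw[k] for k in _OTHER_KEYS & set(raw) if k not in ("xr_mode", "theta")}
    return {"params": params, "schedule": schedule, **opts}


def save_config(path: PathLike, params: Params, seed: int = 0,
                **extra: object) -> None:
    d = dataclasses.asdict(params)
    xr = d.pop("xr")
    d["xr_mode"] = str(xr["mode"].value if hasattr(xr["mode"], "value") else xr["mode"])
    d["theta"] = xr["theta"]
    d["seed"] = seed
    d.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def write_manifest(path: PathLike, params: Params, seed: int,
                   wall_seconds: Optional[float] = None, **extra: object) -> None:
    """Run manifest written beside outputs (params, seed, version, wall time)."""
    from . import __version__
    d = dataclasses.asdict(params)
    d["xr"] = {"mode": str(params.xr.mode.value), "theta": params.xr.theta}
    manifest = {"params": d, "seed": seed, "version": __version__,
                "wall_seconds": wall_seconds,
                "written": time.strftime("%Y-%m-%dT%H:%M:%S")}
    manifest.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, default=str)


# ----------------------------------------------------------------------
# synthetic fixtures
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureSpec:
    """Shape parameters for a synthetic paired bacteria/phage count table.

    ``overlap`` is the fraction of each population's types shared with the
    other at any time; ``turnover`` is the per-step probability that a type
    dies and is replaced by a fresh label; clone sizes are exponential with
    mean ``size_mean``.
    """

    n_times: int = 20
    dt: float = 1.0
    n_bacteria_types: int = 40
    n_phage_types: int = 40
    size_mean: float = 50.0
    overlap: float = 0.5
    turnover: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_times < 2 or self.n_bacteria_types < 1 or self.n_phage_types < 1:
            raise ValueError("degenerate fixture specification")
        if not 0 <= self.overlap <= 1 or not 0 <= self.turnover <= 1:
            raise ValueError("overlap and turnover must lie in [0, 1]")
        if self.size_mean <= 0:
            raise ValueError("size_mean must be positive")


def generate_fixture(spec: FixtureSpec) -> Tuple[AbundanceSeries, AbundanceSeries]:
    """Reproducible paired (bacteria, phage) abundance series.

    Shared types carry labels ``S####``; private types ``B####``/``V####``.
    Sizes are redrawn from the exponential law at birth and jittered
    multiplicatively between steps; a dying type's replacement is shared with
    probability ``overlap`` so the overlap fraction is maintained on average.
    """
    rng = np.random.default_rng(spec.seed)
    label_counter = [0]

    def fresh(prefix: str) -> str:
        label_counter[0] += 1
        return f"{prefix}{label_counter[0]:05d}"

    def size() -> float:
        return max(1.0, round(rng.exponential(spec.size_mean)))

    n_shared_b = int(round(spec.overlap * spec.n_bacteria_types))
    n_shared_v = int(round(spec.overlap * spec.n_phage_types))
    n_shared = min(n_shared_b, n_shared_v)
    shared = [fresh("S") for _ in range(n_shared)]
    bact = {lab: size() for lab in shared}
    bact.update({fresh("B"): size() for _ in range(spec.n_bacteria_types - n_shared)})
    phage = {lab: size() for lab in shared}
    phage.update({fresh("V"): size() for _ in range(spec.n_phage_types - n_shared)})

    tables_b, tables_v = [dict(bact)], [dict(phage)]
    for _ in range(spec.n_times - 1):
        for tab, other, prefix in ((bact, phage, "B"), (phage, bact, "V")):
            for lab in list(tab):
                if rng.random() < spec.turnover:
                    del tab[lab]
                    if rng.random() < spec.overlap:
                        new = fresh("S")
                        tab[new] = size()
                        other[new] = size()
                    else:
                        tab[fresh(prefix)] = size()
                else:
                    tab[lab] = max(1.0, round(tab[lab] * rng.lognormal(0.0, 0.2)))
        tables_b.append(dict(bact))
        tables_v.append(dict(phage))

    times = np.arange(spec.n_times) * spec.dt

    def to_series(tables, population) -> AbundanceSeries:
        types = sorted(set().union(*[set(t) for t in tables]))
        counts = np.zeros((len(tables), len(types)))
        idx = {t: k for k, t in enumerate(types)}
        for i, tab in enumerate(tables):
            for lab, c in tab.items():
                counts[i, idx[lab]] = c
        return AbundanceSeries(times, types, counts, population, "generations")

    return to_series(tables_b, "bacteria"), to_series(tables_v, "phage")
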