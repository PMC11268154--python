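"""Synthetic camera-trap detection logs with the structure the analysis assumes.

The generator emulates a decade-scale array of cameras in an urban-adjacent
reserve network: per-camera daily human-disturbance counts are
negative-binomial (visitation is clustered, so heavier-tailed than Poisson)
with a rising multi-year trend and an annual seasonal cycle; each taxon is
detected on a camera-day with probability given by its response curve
evaluated at that day's human count; scheduled "wilderness access day"
pulse events multiply the day's expected human count (10-fold by default)
and suppress detection on the day before and the day of the event, with
recovery the day after.

Defaults mirror the study system: 50 cameras over nine years from
2007-06-01, with the seven focal species' fitted Arps-curve parameters.
Every draw flows from a single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date, datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .decay_models import CurveParams, ModelForm, eval_curve
from .response_curves import HUMAN, DetectionEvent, ResponseCurve, events_to_frame

__all__ = [
    "TaxonSpec",
    "HumanProcess",
    "PulseSpec",
    "SimConfig",
    "SimResult",
    "DEFAULT_TAXA",
    "simulate_humans",
    "simulate_detections",
    "simulate_dataset",
    "simulate_response_data",
    "write_fixture",
    "load_config",
]

#: Most deduplicated human records that fit in one day under the 1-h merge
#: rule with the margins used by the event-burst writer.
MAX_EVENTS_PER_DAY = 22


@dataclass(frozen=True)
class TaxonSpec:
    """Generating response-curve parameters for one taxon."""

    name: str
    y0: float
    sensitivity: float
    discount: float = 0.0
    form: str = "arps"

    def params(self) -> CurveParams:
        return CurveParams(self.y0, self.sensitivity, self.discount)


#: The seven focal species with their fitted Arps parameters
#: (prevalence at zero disturbance, sensitivity, discount).
DEFAULT_TAXA: tuple[TaxonSpec, ...] = (
    TaxonSpec("bobcat", 0.594, 3.50, 0.859),
    TaxonSpec("puma", 0.720, 4.57, 0.780),
    TaxonSpec("grey_fox", 0.711, 3.88, 0.706),
    TaxonSpec("coyote", 0.505, 2.03, 0.764),
    TaxonSpec("striped_skunk", 0.616, 2.49, 0.639),
    TaxonSpec("raccoon", 0.847, 12.48, 0.823),
    TaxonSpec("mule_deer", 0.798, 6.24, 0.733),
)


@dataclass(frozen=True)
class HumanProcess:
    """Daily human-record process per camera.

    mean_daily : baseline expected deduplicated human records per camera-day.
    dispersion : negative-binomial size parameter (np.inf -> Poisson).
    trend_per_year : proportional increase in the mean per year.
    seasonal_amplitude : relative amplitude of the annual cycle (seen as
        quarterly seasonality at the study's quarterly sampling).
    """

    mean_daily: float = 2.0
    dispersion: float = 1.5
    trend_per_year: float = 0.15
    seasonal_amplitude: float = 0.3

    def __post_init__(self) -> None:
        if self.mean_daily <= 0:
            raise ValueError("mean_daily must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass(frozen=True)
class PulseSpec:
    """Wilderness-access-day pulse events.

    fold multiplies the day's expected human count (>= 1); suppression maps
    day offsets to multipliers in (0, 1] on detection probability — default
    is activity depressed from the day before through the event day, with
    recovery the day after.
    """

    dates: tuple[date, ...] = ()
    fold: float = 10.0
    suppression: dict[int, float] = field(default_factory=lambda: {-1: 0.3, 0: 0.3})

    def __post_init__(self) -> None:
        if self.fold < 1:
            raise ValueError("fold must be >= 1")
        for j, m in self.suppression.items():
            if not 0 < m <= 1:
                raise ValueError(f"suppression multiplier at offset {j} must be in (0, 1]")


@dataclass(frozen=True)
class SimConfig:
    n_cameras: int = 50
    n_days: int = 3287  # nine years
    start_date: date = date(2007, 6, 1)
    human: HumanProcess = field(default_factory=HumanProcess)
    taxa: tuple[TaxonSpec, ...] = DEFAULT_TAXA
    pulse: PulseSpec | None = None
    dedup_emulation: bool = False
    seed: int = 0

    def dates(self) -> list[date]:
        return [self.start_date + timedelta(days=i) for i in range(self.n_days)]


@dataclass
class SimResult:
    config: SimConfig
    day_table: pd.DataFrame  # camera_id, date, human_count, one column per taxon
    events: list[DetectionEvent]


# ---------------------------------------------------------------------------

def _daily_mean(cfg: SimConfig) -> np.ndarray:
    h = cfg.human
    t_years = np.arange(cfg.n_days) / 365.25
    mean = h.mean_daily * (1.0 + h.trend_per_year * t_years)
    mean = mean * (1.0 + h.seasonal_amplitude * np.sin(2.0 * np.pi * t_years))
    mean = np.clip(mean, 1e-9, None)
    if cfg.pulse is not None:
        dates = cfg.dates()
        idx = {d: i for i, d in enumerate(dates)}
        for d in cfg.pulse.dates:
            if d in idx:
                mean[idx[d]] *= cfg.pulse.fold
    return mean


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float, size) -> np.ndarray:
    if np.isinf(dispersion):
        return rng.poisson(mean, size=size)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_humans(cfg: SimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-camera, per-day deduplicated human counts, shape (n_cameras, n_days)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    mean = _daily_mean(cfg)
    return _nb_draw(rng, mean[None, :], cfg.human.dispersion, (cfg.n_cameras, cfg.n_days))


def _suppression_by_day(cfg: SimConfig) -> np.ndarray:
    mult = np.ones(cfg.n_days)
    if cfg.pulse is None:
        return mult
    idx = {d: i for i, d in enumerate(cfg.dates())}
    for d in cfg.pulse.dates:
        for j, m in cfg.pulse.suppression.items():
            day = d + timedelta(days=j)
            if day in idx:
                mult[idx[day]] = min(mult[idx[day]], m)
    return mult


def simulate_detections(
    human_counts: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Bernoulli detection per camera-day and taxon at the curve's probability,
    times the pulse suppression multiplier where one applies."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    n_cam, n_days = human_counts.shape
    dates = cfg.dates()
    mult = _suppression_by_day(cfg)

    cols = {
        "camera_id": np.repeat([f"cam{i:03d}" for i in range(n_cam)], n_days),
        "date": np.tile([d.isoformat() for d in dates], n_cam),
        "human_count": human_counts.reshape(-1),
    }
    x = human_counts.astype(float)
    for spec in cfg.taxa:
        p = eval_curve(spec.form, x, spec.params()) * mult[None, :]
        cols[spec.name] = (rng.random((n_cam, n_days)) < p).astype(int).reshape(-1)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Timestamped event emission

def _human_event_times(count: int, rng: np.random.Generator) -> list[float]:
    """Start minutes for `count` human records, spaced so the 1-h merge
    keeps them distinct (hence the cap at MAX_EVENTS_PER_DAY)."""
    if count == 0:
        return []
    spacing = 1440.0 / count
    jitter_max = max(0.0, spacing - 65.0)
    return [i * spacing + rng.uniform(0.0, jitter_max) for i in range(count)]


def _emit_day_events(
    camera: str,
    day: date,
    human_count: int,
    detected: dict[str, int],
    burst: bool,
    rng: np.random.Generator,
) -> list[DetectionEvent]:
    events: list[DetectionEvent] = []
    base = datetime.combine(day, datetime.min.time())
    for t0 in _human_event_times(human_count, rng):
        n_frames = int(rng.integers(1, 4)) if burst else 1
        t = t0
        for _ in range(n_frames):
            events.append(DetectionEvent(camera, base + timedelta(minutes=t), HUMAN, 1))
            t += rng.uniform(1.0, 2.0)
    for taxon, hit in detected.items():
        if not hit:
            continue
        t = rng.uniform(0.0, 1380.0)
        n_frames = int(rng.integers(1, 4)) if burst else 1
        for _ in range(n_frames):
            events.append(DetectionEvent(camera, base + timedelta(minutes=t), taxon, 1))
            t += rng.uniform(1.0, 2.0)
    return events


def simulate_dataset(cfg: SimConfig) -> SimResult:
    """Full generator: human counts, detections and (always) timestamped events.

    With ``dedup_emulation=True`` each record is expanded into a short burst
    of raw frames that the deduplication stage must collapse; otherwise one
    event row per deduplicated record is emitted.  Either way the emitted
    events round-trip through dedup + camera-day binning to the returned
    day table (human counts above MAX_EVENTS_PER_DAY are capped — more
    records cannot coexist in a day under the 1-h merge rule).
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_h, rng_d, rng_e = [np.random.default_rng(s) for s in ss.spawn(3)]
    humans = simulate_humans(cfg, rng_h)
    humans = np.minimum(humans, MAX_EVENTS_PER_DAY)
    table = simulate_detections(humans, cfg, rng_d)

    taxa = [t.name for t in cfg.taxa]
    events: list[DetectionEvent] = []
    dates = cfg.dates()
    n_days = cfg.n_days
    for row_block in range(cfg.n_cameras):
        cam = f"cam{row_block:03d}"
        sl = slice(row_block * n_days, (row_block + 1) * n_days)
        h = table["human_count"].to_numpy()[sl]
        det = {t: table[t].to_numpy()[sl] for t in taxa}
        for i, day in enumerate(dates):
            if h[i] == 0 and not any(det[t][i] for t in taxa):
                continue
            events.extend(
                _emit_day_events(
                    cam, day, int(h[i]), {t: int(det[t][i]) for t in taxa},
                    cfg.dedup_emulation, rng_e,
                )
            )
    return SimResult(cfg, table, events)


# ---------------------------------------------------------------------------
# Direct response-curve data (recovery experiments)

def simulate_response_data(
    params: CurveParams,
    form: ModelForm | str = "arps",
    x_levels=range(16),
    days_per_level: int = 2000,
    rng: np.random.Generator | int | None = None,
    taxon: str = "synthetic",
) -> ResponseCurve:
    """Bernoulli detections at fixed disturbance levels, summarised to a curve.

    The workhorse of parameter-recovery experiments: at each level x the
    detection proportion over ``days_per_level`` camera-days estimates the
    generating curve with binomial noise sqrt(y(1-y)/n).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    xs = np.array(list(x_levels), dtype=float)
    probs = eval_curve(form, xs, params)
    hits = rng.binomial(days_per_level, probs)
    return ResponseCurve(
        taxon, xs, hits / days_per_level, np.full(len(xs), days_per_level)
    )


# ---------------------------------------------------------------------------
# Fixture files

def write_fixture(cfg: SimConfig, out_dir) -> dict[str, Path]:
    """Emit events.csv, true_params.json and pulse_dates.txt; deterministic
    under the config seed."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        res = simulate_dataset(cfg)
        paths = {
            "events": out / "events.csv",
            "true_params": out / "true_params.json",
            "pulse_dates": out / "pulse_dates.txt",
        }
        events_to_frame(res.events).to_csv(paths["events"], index=False)
        truth = {
            "n_cameras": cfg.n_cameras,
            "n_days": cfg.n_days,
            "start_date": cfg.start_date.isoformat(),
            "seed": cfg.seed,
            "human": asdict(cfg.human),
            "taxa": [asdict(t) for t in cfg.taxa],
            "pulse": None
            if cfg.pulse is None
            else {
                "dates": [d.isoformat() for d in cfg.pulse.dates],
                "fold": cfg.pulse.fold,
                "suppression": {str(k): v for k, v in cfg.pulse.suppression.items()},
            },
        }
        paths["true_params"].write_text(json.dumps(truth, indent=2))
        pulse_dates = [] if cfg.pulse is None else [d.isoformat() for d in cfg.pulse.dates]
        paths["pulse_dates"].write_text("\n".join(pulse_dates) + ("\n" if pulse_dates else ""))
    except OSError as exc:
        raise OSError(f"cannot write fixture under {out}: {exc}") from exc
    return paths


def load_config(path) -> SimConfig:
    """Build a SimConfig from a YAML file (schema mirrors the dataclasses)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    human = HumanProcess(**raw.get("human", {}))
    taxa = tuple(TaxonSpec(**t) for t in raw.get("taxa", [])) or DEFAULT_TAXA
    pulse = None
    if "pulse" in raw and raw["pulse"]:
        p = dict(raw["pulse"])
        p["dates"] = tuple(date.fromisoformat(str(d)) for d in p.get("dates", ()))
        if "suppression" in p:
            p["suppression"] = {int(k): float(v) for k, v in p["suppression"].items()}
        pulse = PulseSpec(**p)
    return SimConfig(
        n_cameras=int(raw.get("n_cameras", 50)),
        n_days=int(raw.get("n_days", 3287)),
        start_date=date.fromisoformat(str(raw.get("start_date", "2007-06-01"))),
        human=human,
        taxa=taxa,
        pulse=pulse,
        dedup_emulation=bool(raw.get("dedup_emulation", False)),
        seed=int(raw.get("seed", 0)),
    )
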