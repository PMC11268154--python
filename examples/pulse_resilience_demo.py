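"""Activity around high-disturbance pulse events.

Simulates a year of monthly "wilderness access days" at a seven-camera
canyon — each event brings a 10-fold spike in human disturbance and
suppresses mammal activity from the day before through the event day —
then fits the negative-binomial activity model per day offset.
"""

from datetime import date, timedelta

from fearcurve import extract_pulse_windows, fit_pulse_activity, pool_window_counts
from fearcurve.response_curves import deduplicate_events
from fearcurve.synthetic_data import HumanProcess, PulseSpec, SimConfig, simulate_dataset

event_dates = tuple(date(2010, 1, 15) + timedelta(days=30 * k) for k in range(12))
cfg = SimConfig(
    n_cameras=7,
    n_days=400,
    start_date=date(2010, 1, 1),
    human=HumanProcess(mean_daily=1.0, dispersion=2.0, trend_per_year=0.0,
                       seasonal_amplitude=0.0),
    pulse=PulseSpec(dates=event_dates, fold=10.0, suppression={-1: 0.3, 0: 0.3}),
    dedup_emulation=True,
    seed=2010,
)
events = deduplicate_events(simulate_dataset(cfg).events)
cameras = [f"cam{i:03d}" for i in range(7)]

windows = extract_pulse_windows(events, list(event_dates), cameras)
activity = fit_pulse_activity(pool_window_counts(windows), seed=7, n_draws=2000)

print("day offset j   posterior activity A_j   95% HDI")
for j in activity.offsets:
    s = activity.summary[j]["A"]
    print(f"{j:>+10d}   {s['mean']:22.2f}   [{s['hdi_low']:.2f}, {s['hdi_high']:.2f}]")
print("\nActivity dips the day before the event (anticipating the build-up),")
print("bottoms out on the access day itself, and is back at baseline one")
print("day later — pulse disturbance, so far, not press.")
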