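"""Virtual Y-junction droplet sorter with verification accounting.

Droplets default to the waste outlet (the keep channel has higher
fluidic resistance).  A keep decision fires a dielectrophoretic pulse
train — 20 square pulses at 500 Hz, 40 ms total, 1.32 kV — that
deflects the droplet into the keep channel.  The model captures the two
failure mechanisms of the physical junction:

* **actuation failure** — with probability ``failure_probability`` the
  field fails to steer the target (timing/field-strength errors) and it
  goes to waste;
* **collision co-sorting** — any trailing droplet whose detection falls
  inside the 40 ms active-field window is deflected together with the
  target, which is why the actuation duration caps throughput at 25 Hz.

A second camera watches the outlets: every keep-channel arrival within
the 200 ms verification window of an actuation is matched FIFO
one-to-one to that actuation and recorded as a successful sorting
event; keep arrivals with no matching actuation are false positives.
Junction-to-outlet travel time is constant plus Gaussian jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import ConfusionCounts


@dataclass
class ActuationConfig:
    pulse_count: int = 20
    pulse_frequency_hz: float = 500.0
    pulse_duration_total_ms: float = 40.0
    amplitude_kv: float = 1.32
    failure_probability: float = 0.0
    verification_window_ms: float = 200.0
    travel_time_ms: float = 50.0
    travel_jitter_ms: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.failure_probability <= 1.0:
            raise ValueError("failure_probability must lie in [0, 1]")
        expected = 1e3 * self.pulse_count / self.pulse_frequency_hz
        if abs(expected - self.pulse_duration_total_ms) > 0.5:
            raise ValueError(
                "pulse_count / pulse_frequency must match the total pulse "
                f"duration ({expected:.1f} != {self.pulse_duration_total_ms} ms)")


@dataclass
class SortEvent:
    """Per-droplet outcome in the event log."""

    droplet_id: int
    decision: str              # keep | waste (requested)
    actuated: bool             # a pulse was fired for this droplet
    actuation_success: bool
    co_sorted: bool            # dragged along by another droplet's field
    outlet: str                # keep | waste (where it really went)
    t_detect_s: float
    t_actuate_s: float | None
    t_arrive_s: float | None   # keep-outlet arrival time (None for waste)
    verified: bool = False
    false_positive: bool = False


def run_sorter(timestamps, decisions, cfg: ActuationConfig | None = None,
               seed: int = 0, droplet_ids=None) -> list[SortEvent]:
    """Route a droplet train through the junction.

    Parameters
    ----------
    timestamps : sequence of float
        Detection times (s), non-decreasing.
    decisions : sequence of str
        Per-droplet 'keep'/'waste', aligned with ``timestamps``.
    """
    cfg = cfg or ActuationConfig()
    t = np.asarray(timestamps, dtype=float)
    decisions = list(decisions)
    if len(decisions) != t.size:
        raise ValueError("decisions must align with the droplet stream")
    if droplet_ids is None:
        droplet_ids = list(range(t.size))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))

    pulse_s = cfg.pulse_duration_total_ms * 1e-3
    events: list[SortEvent] = []
    field_until = -np.inf  # end of the currently active DEP field
    for i in range(t.size):
        dec = decisions[i]
        if dec not in ("keep", "waste"):
            raise ValueError(f"decision must be keep/waste, got {dec!r}")
        actuated = dec == "keep"
        success = False
        t_act = None
        co_sorted = False
        if actuated:
            t_act = float(t[i])
            success = rng.random() >= cfg.failure_probability
            if success:
                field_until = t[i] + pulse_s
        elif t[i] < field_until:
            # trailing droplet caught by an earlier droplet's field
            co_sorted = True
        deflected = (actuated and success) or co_sorted
        outlet = "keep" if deflected else "waste"
        t_arr = None
        if deflected:
            travel = (cfg.travel_time_ms +
                      rng.normal(0.0, cfg.travel_jitter_ms)) * 1e-3
            t_arr = float(t[i] + max(travel, 0.0))
        events.append(SortEvent(
            droplet_id=droplet_ids[i], decision=dec, actuated=actuated,
            actuation_success=success, co_sorted=co_sorted, outlet=outlet,
            t_detect_s=float(t[i]), t_actuate_s=t_act, t_arrive_s=t_arr))
    return verify(events, cfg)


def verify(events: list[SortEvent],
           cfg: ActuationConfig | None = None) -> list[SortEvent]:
    """FIFO one-to-one matching of keep-outlet arrivals to actuations.

    Marks each actuated droplet ``verified`` when a keep arrival lands
    within the verification window of its pulse; keep arrivals that no
    actuation claims are flagged ``false_positive``.
    """
    cfg = cfg or ActuationConfig()
    window_s = cfg.verification_window_ms * 1e-3
    actuations = sorted((e for e in events if e.actuated and e.t_actuate_s
                         is not None), key=lambda e: e.t_actuate_s)
    arrivals = sorted((e for e in events if e.outlet == "keep" and
                       e.t_arrive_s is not None), key=lambda e: e.t_arrive_s)
    matched: set[int] = set()
    for act in actuations:
        act.verified = False
        for j, arr in enumerate(arrivals):
            if j in matched:
                continue
            dt = arr.t_arrive_s - act.t_actuate_s
            if dt < 0:
                continue
            if dt <= window_s:
                act.verified = True
                matched.add(j)
            break  # FIFO: only the earliest unmatched arrival is eligible
    claimed_ids = {arrivals[j].droplet_id for j in matched}
    for e in events:
        e.false_positive = (e.outlet == "keep" and
                            e.droplet_id not in claimed_ids)
    return events


def confusion_from_log(events: list[SortEvent], target_flags,
                       detected_flags=None) -> ConfusionCounts:
    """Tally confusion counts from an event log plus ground-truth targets.

    ``target_flags[i]`` says whether droplet i truly is a target;
    ``detected_flags`` (default: the keep decisions) says whether the
    imaging algorithm flagged it.
    """
    targets = {e.droplet_id: bool(f)
               for e, f in zip(events, target_flags, strict=True)}
    if detected_flags is None:
        detected = {e.droplet_id: e.decision == "keep" for e in events}
    else:
        detected = {e.droplet_id: bool(f)
                    for e, f in zip(events, detected_flags, strict=True)}
    tk = wk = tw = ww = 0
    for e in events:
        is_t = targets[e.droplet_id]
        kept = e.outlet == "keep"
        if is_t and kept:
            tk += 1
        elif is_t:
            tw += 1
        elif kept:
            wk += 1
        else:
            ww += 1
    return ConfusionCounts(
        targets_in=sum(targets.values()),
        others_in=len(targets) - sum(targets.values()),
        targets_detected=sum(detected[e.droplet_id] and targets[e.droplet_id]
                             for e in events),
        targets_keep=tk, targets_waste=tw,
        others_keep=wk, others_waste=ww)


def log_to_frame(events: list[SortEvent]) -> pd.DataFrame:
    """Event log as a CSV-ready DataFrame mirroring the real-time log."""
    return pd.DataFrame({
        "droplet_id": [e.droplet_id for e in events],
        "decision": [e.decision for e in events],
        "actuated": [e.actuated for e in events],
        "outlet": [e.outlet for e in events],
        "verified": [e.verified for e in events],
        "false_positive": [e.false_positive for e in events],
        "t_detect_s": [e.t_detect_s for e in events],
        "t_actuate_s": [e.t_actuate_s for e in events],
        "t_arrive_s": [e.t_arrive_s for e in events],
    })
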