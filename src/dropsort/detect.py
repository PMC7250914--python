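"""Droplet presence detection.

Two independent detectors emulate the rig's two trigger paths:

* **ROI detector** (camera path): the mean intensity of a fixed region
  of interest is tracked as an exponential moving average Im_bar; a
  droplet transit is declared when the instantaneous ROI mean drops
  below T = 0.98 * Im_bar (the dark rim entering the ROI pulls the mean
  down).  Because T is proportional to the running mean, detection is
  invariant to global illumination rescaling.  Hysteresis: after a
  trigger the detector re-arms only once the mean has been back above T
  for two consecutive frames, so one transit yields one event.

* **Backscatter trigger** (laser path): a pure 1-D signal-processing
  emulation of the laser/photodiode/microcontroller chain — trigger when
  the signal departs from a trailing-window baseline by more than a
  configurable delta, with a refractory hold until it returns to the
  baseline band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .micrograph import Micrograph


@dataclass
class DetectionEvent:
    index: int            # frame (or sample) index of the crossing
    roi_mean: float
    threshold: float
    source: str = "roi"


@dataclass
class ROIDetector:
    """Adaptive ROI mean-intensity droplet detector.

    ``roi`` is (row_start, row_stop, col_start, col_stop) in pixels.
    """

    roi: tuple[int, int, int, int]
    threshold_multiplier: float = 0.98
    ema_decay: float = 0.99
    rearm_frames: int = 2

    running_mean: float | None = field(default=None, repr=False)
    state: str = field(default="armed", repr=False)
    _above: int = field(default=0, repr=False)

    def _roi_mean(self, frame: Micrograph) -> float:
        r0, r1, c0, c1 = self.roi
        rows, cols = frame.shape
        if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
            raise ValueError(f"ROI {self.roi} outside frame bounds {frame.shape}")
        return float(frame.pixels[r0:r1, c0:c1].mean())

    def step(self, frame: Micrograph, index: int) -> DetectionEvent | None:
        m = self._roi_mean(frame)
        if self.running_mean is None:
            self.running_mean = m
            return None
        threshold = self.threshold_multiplier * self.running_mean
        event = None
        if self.state == "armed":
            if m < threshold:
                event = DetectionEvent(index, m, threshold)
                self.state = "triggered"
                self._above = 0
        else:
            if m >= threshold:
                self._above += 1
                if self._above >= self.rearm_frames:
                    self.state = "armed"
            else:
                self._above = 0
        if m >= threshold:
            # only un-triggered frames update the baseline
            self.running_mean = (self.ema_decay * self.running_mean +
                                 (1.0 - self.ema_decay) * m)
        return event


def roi_detect(frames, det: ROIDetector) -> list[DetectionEvent]:
    """Run the ROI detector over a frame sequence; one event per transit."""
    events = []
    for i, frame in enumerate(frames):
        ev = det.step(frame, i)
        if ev is not None:
            events.append(ev)
    return events


def backscatter_trigger(trace, window: int, delta: float) -> list[int]:
    """Trigger indices where a 1-D trace departs from its trailing baseline.

    The baseline is the mean of the last ``window`` in-band samples.
    After a trigger the detector holds (refractory) until the signal is
    back within +/- delta of the baseline.
    """
    x = np.asarray(trace, dtype=float)
    if x.size == 0:
        raise ValueError("empty trace")
    if window < 2:
        raise ValueError("window must be >= 2")
    if delta <= 0:
        raise ValueError("delta must be positive")
    triggers: list[int] = []
    recent: list[float] = [x[0]]
    armed = True
    for i in range(1, x.size):
        baseline = float(np.mean(recent[-window:]))
        inside = abs(x[i] - baseline) <= delta
        if armed:
            if not inside:
                triggers.append(i)
                armed = False
            else:
                recent.append(x[i])
        else:
            if inside:
                armed = True
                recent.append(x[i])
    return triggers


def events_to_frame(events: list[DetectionEvent], frame_rate_hz: float = 1.0):
    """Detection events as a CSV-ready DataFrame."""
    import pandas as pd

    return pd.DataFrame({
        "event_id": range(len(events)),
        "time_s": [e.index / frame_rate_hz for e in events],
        "source": [e.source for e in events],
        "roi_mean": [e.roi_mean for e in events],
        "threshold": [e.threshold for e in events],
    })
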