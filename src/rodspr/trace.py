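"""Photocurrent response traces.

A :class:`ResponseTrace` stores the suppression of the circulating (dark)
current following a flash at ``t = 0``: ``r(t) = J_dark - J(t)`` in pA,
positive for the normal light response.  Samples before ``t = 0`` (present
in synthetic recordings) represent pre-flash baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class ResponseTrace:
    t: np.ndarray                    # ms, uniform grid
    r: np.ndarray                    # pA, dark-current suppression
    j_dark: float | None = None      # pA, reference circulating current
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.t.shape != self.r.shape:
            raise ValueError("time and current arrays must have equal shape")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else 0.0

    def baseline_corrected(self, window: float = 500.0) -> "ResponseTrace":
        """Subtract the mean over the pre-flash window (last ``window`` ms
        before t=0); a no-op when the trace has no pre-flash samples."""
        pre = (self.t < 0) & (self.t >= -window)
        if not pre.any():
            return self
        return ResponseTrace(
            self.t, self.r - float(self.r[pre].mean()), self.j_dark, dict(self.meta)
        )

    def post_flash(self) -> "ResponseTrace":
        m = self.t >= 0
        return ResponseTrace(self.t[m], self.r[m], self.j_dark, dict(self.meta))

    def resampled(self, t_new: np.ndarray) -> "ResponseTrace":
        return ResponseTrace(
            np.asarray(t_new, dtype=float),
            np.interp(t_new, self.t, self.r),
            self.j_dark,
            dict(self.meta),
        )

    def normalized(self) -> "ResponseTrace":
        peak = float(np.max(self.r))
        if peak <= 0:
            raise ValueError("cannot normalize a non-positive trace")
        return ResponseTrace(self.t, self.r / peak, self.j_dark, dict(self.meta))

    # -- I/O ------------------------------------------------------------
    def write(self, path: str | Path) -> None:
        """Two-column text (time_ms, current_pA) with a JSON sidecar."""
        path = Path(path)
        np.savetxt(
            path,
            np.column_stack([self.t, self.r]),
            header="time_ms current_pA",
            fmt="%.6g",
        )
        sidecar = {"j_dark": self.j_dark, **self.meta}
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1, default=str)
        )

    @classmethod
    def read(cls, path: str | Path) -> "ResponseTrace":
        path = Path(path)
        data = np.loadtxt(path)
        meta_path = path.with_suffix(path.suffix + ".json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        j_dark = meta.pop("j_dark", None)
        return cls(data[:, 0], data[:, 1], j_dark, meta)


def mean_trace(traces: list[ResponseTrace]) -> ResponseTrace:
    """Pointwise mean of traces sharing a time grid."""
    t0 = traces[0].t
    for tr in traces[1:]:
        if len(tr.t) != len(t0) or not np.allclose(tr.t, t0):
            raise ValueError("traces must share a common time grid")
    r = np.mean([tr.r for tr in traces], axis=0)
    return ResponseTrace(t0, r, traces[0].j_dark, {"n_averaged": len(traces)})
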