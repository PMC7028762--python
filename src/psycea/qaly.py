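"""Quality-adjusted life-years from utility trajectories.

The post period QALY is the area under the utility-versus-time curve over
the 12 study months, with linear interpolation between survey dates
(trapezoid rule at nominal visit times 0, 3, 6, 12 months). The pre period
QALY assumes the baseline utility was stable over the year before first
contact, so it equals the baseline utility × 1 year. No discounting is
applied over the 12-month horizon.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .periods import VISIT_TIMES_YEARS


def _check_times(visit_times) -> np.ndarray:
    t = np.asarray(visit_times, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise ValueError("visit_times must be a 1-D sequence of at least two times")
    if not np.all(np.diff(t) > 0):
        raise ValueError(f"visit_times must be strictly increasing, got {t.tolist()}")
    if not np.isclose(t[-1] - t[0], 1.0):
        raise ValueError(f"visit_times must span one year, got {t.tolist()}")
    return t


def qaly_post(utilities, visit_times=VISIT_TIMES_YEARS) -> float:
    """Trapezoid-rule QALY of one client's utility trajectory over one year."""
    t = _check_times(visit_times)
    u = np.asarray(utilities, dtype=float)
    if u.shape != t.shape:
        raise ValueError(f"{len(u)} utilities for {len(t)} visit times")
    if np.isnan(u).any():
        raise ValueError("incomplete trajectory: impute missing visits first (LOCF)")
    return float(np.trapezoid(u, t))


def qaly_pre(baseline_utility: float) -> float:
    """Pre-period QALY: baseline utility assumed stable over the prior year."""
    u = float(baseline_utility)
    if not 0.0 < u <= 1.0:
        raise ValueError(f"baseline utility must be in (0, 1], got {u}")
    return u


def qaly_deltas(
    trajectories: pd.DataFrame, visit_times=VISIT_TIMES_YEARS
) -> pd.DataFrame:
    """Per-client QALY pairs and differences.

    ``trajectories`` is the LOCF-completed long table (client_id, visit,
    utility). Returns one row per client with ``qaly_pre``, ``qaly_post``
    and ``delta`` = post − pre.
    """
    t = _check_times(visit_times)
    wide = (
        trajectories.pivot_table(index="client_id", columns="visit", values="utility")
        .reindex(columns=range(len(t)))
        .sort_index()
    )
    if wide.isna().any().any():
        offenders = wide.index[wide.isna().any(axis=1)].tolist()
        raise ValueError(f"incomplete trajectories for clients: {offenders}")
    post = np.trapezoid(wide.to_numpy(), t, axis=1)
    pre = wide[0].to_numpy(dtype=float)
    if np.any((pre <= 0) | (pre > 1)):
        raise ValueError("baseline utilities must be in (0, 1]")
    out = pd.DataFrame(
        {"client_id": wide.index, "qaly_pre": pre, "qaly_post": post}
    ).reset_index(drop=True)
    out["delta"] = out["qaly_post"] - out["qaly_pre"]
    return out
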