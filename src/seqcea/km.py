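"""Kaplan-Meier curve I/O and individual-patient-data reconstruction.

Digitized published survival curves arrive as (time, survival) tables,
optionally with a numbers-at-risk table. This module validates them,
reconstructs approximate individual patient data (IPD) with the Guyot
interval-allocation algorithm, and re-estimates product-limit curves so
that reconstructions can be round-trip checked.

Time is in months everywhere. Input files may declare a different unit in
a ``# time_unit:`` header comment and are converted on read.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = [
    "KMCurve",
    "IPDRecord",
    "KMValidationError",
    "ReconstructionError",
    "read_km_table",
    "guyot_reconstruct",
    "km_estimate",
]


class KMValidationError(ValueError):
    """A survival table violates the Kaplan-Meier curve invariants."""


class ReconstructionError(ValueError):
    """A risk table cannot be reconciled with its survival curve."""


_TIME_UNIT_FACTORS = {"months": 1.0, "month": 1.0, "years": 12.0, "year": 12.0,
                      "weeks": 12.0 / 52.1775, "week": 12.0 / 52.1775,
                      "days": 12.0 / 365.25, "day": 12.0 / 365.25}


@dataclass
class KMCurve:
    """A survival step function S(t) with an optional numbers-at-risk table.

    Parameters
    ----------
    label:
        Free-text identifier (trial, treatment, health state, endpoint).
    times:
        Months from state entry; nondecreasing, starting at 0.
    survival:
        Survival probability at each time; nonincreasing, in [0, 1],
        with S(0) = 1.
    risk_table:
        Optional ``(k, 2)`` array of (time in months, number at risk).
    """

    label: str
    times: np.ndarray
    survival: np.ndarray
    risk_table: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.times.shape != self.survival.shape or self.times.ndim != 1:
            raise KMValidationError("times and survival must be 1-D and equal length")
        order = np.argsort(self.times, kind="stable")
        self.times = self.times[order]
        self.survival = self.survival[order]
        if self.times.size == 0 or self.times[0] > 0:
            self.times = np.concatenate([[0.0], self.times])
            self.survival = np.concatenate([[1.0], self.survival])
        if self.times[0] < 0:
            raise KMValidationError("negative time in survival table")
        if abs(self.survival[0] - 1.0) > 1e-9:
            raise KMValidationError(
                f"survival at time 0 is {self.survival[0]!r}, expected 1.0")
        bad = np.where((self.survival < -1e-12) | (self.survival > 1 + 1e-12))[0]
        if bad.size:
            raise KMValidationError(
                f"survival outside [0, 1] at row {bad[0]} "
                f"(t={self.times[bad[0]]}, S={self.survival[bad[0]]})")
        drops = np.diff(self.survival)
        bad = np.where(drops > 1e-9)[0]
        if bad.size:
            i = bad[0] + 1
            raise KMValidationError(
                f"survival increases at row {i} (t={self.times[i]}, "
                f"S={self.survival[i]} > {self.survival[i - 1]})")
        if self.risk_table is not None:
            rt = np.asarray(self.risk_table, dtype=float)
            if rt.ndim != 2 or rt.shape[1] != 2:
                raise KMValidationError("risk_table must have columns (time, n_at_risk)")
            rt = rt[np.argsort(rt[:, 0], kind="stable")]
            if np.any(rt[:, 1] < 0):
                raise KMValidationError("negative number at risk")
            if np.any(np.diff(rt[:, 1]) > 0):
                raise KMValidationError("numbers at risk must be nonincreasing in time")
            self.risk_table = rt

    @property
    def max_time(self) -> float:
        return float(self.times[-1])

    def evaluate(self, t) -> np.ndarray:
        """Step-function (last observation carried forward) evaluation of S(t)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        return self.survival[np.clip(idx, 0, len(self.times) - 1)]

    def monthly(self, horizon: int | None = None) -> np.ndarray:
        """S evaluated on the integer-month grid 0..horizon (LOCF resampling)."""
        if horizon is None:
            horizon = int(np.floor(self.max_time))
        return self.evaluate(np.arange(horizon + 1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival})


@dataclass(frozen=True)
class IPDRecord:
    """One reconstructed patient: follow-up time in months and event flag."""

    time: float
    event: int

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("IPD time must be nonnegative")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 (censored) or 1 (event)")


def _read_table(path, columns) -> pd.DataFrame:
    """Read a delimited table, honouring an optional '# key: value' header."""
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.lstrip().startswith("#"):
            stripped = line.lstrip().lstrip("#").strip()
            if ":" in stripped:
                key, _, value = stripped.partition(":")
                meta[key.strip().lower()] = value.strip()
        else:
            body.append(line)
    df = pd.read_csv(io.StringIO("".join(body)), sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise KMValidationError(f"{path}: missing column(s) {missing}")
    df.attrs["meta"] = meta
    return df


def read_km_table(path, risk_path=None, label: str | None = None) -> KMCurve:
    """Read a digitized KM curve from a CSV with columns ``time, survival``.

    An optional companion file with columns ``time, n_at_risk`` supplies the
    numbers-at-risk table. A ``# time_unit: years`` (or weeks/days) header
    comment converts times to months on read. A (0, 1) point is prepended if
    absent; non-monotone or out-of-range survival raises
    :class:`KMValidationError` naming the offending row.
    """
    df = _read_table(path, ["time", "survival"])
    unit = df.attrs["meta"].get("time_unit", "months").lower()
    if unit not in _TIME_UNIT_FACTORS:
        raise KMValidationError(f"unknown time unit {unit!r}")
    factor = _TIME_UNIT_FACTORS[unit]
    risk = None
    if risk_path is not None:
        rdf = _read_table(risk_path, ["time", "n_at_risk"])
        runit = rdf.attrs["meta"].get("time_unit", unit).lower()
        risk = np.column_stack([
            rdf["time"].to_numpy(float) * _TIME_UNIT_FACTORS[runit],
            rdf["n_at_risk"].to_numpy(float),
        ])
    meta = dict(df.attrs["meta"])
    return KMCurve(
        label=label or df.attrs["meta"].get("label", str(path)),
        times=df["time"].to_numpy(float) * factor,
        survival=df["survival"].to_numpy(float),
        risk_table=risk,
        meta=meta,
    )


def _interval_ipd(times, surv, s_enter, n_enter, t_lo, t_hi, n_exit, interval_index):
    """Allocate events and censorings within one risk-table interval.

    Follows the published interval scheme: guess the number censored in the
    interval, spread the censoring times uniformly, derive event counts at
    each curve step from the product-limit relation, and adjust the censoring
    guess until the implied number at risk at the interval end matches the
    risk table.

    Returns (event_times, censor_times, n_at_exit, s_at_exit).
    """
    n_enter = int(round(n_enter))
    best = None
    max_cens = n_enter if n_exit is None else n_enter - int(round(n_exit))
    for n_cens in range(0, max(max_cens, 0) + 1):
        if n_cens > 0:
            cens_times = t_lo + (np.arange(1, n_cens + 1) - 0.5) / n_cens * (t_hi - t_lo)
        else:
            cens_times = np.empty(0)
        n = n_enter
        s_km = s_enter
        s_prev_target = s_enter
        events, censors = [], []
        used_cens = 0
        ok = True
        for t_k, s_k in zip(times, surv):
            take = np.searchsorted(cens_times, t_k, side="left") - used_cens
            if take > 0:
                censors.extend(cens_times[used_cens:used_cens + take])
                n -= take
                used_cens += take
            if n <= 0:
                ok = s_k >= s_prev_target - 1e-9
                if not ok:
                    break
                continue
            if s_prev_target <= 0:
                d_k = 0
            else:
                d_k = int(round(n * (1.0 - s_k / s_prev_target)))
            if d_k < 0:
                ok = False
                break
            d_k = min(d_k, n)
            events.extend([t_k] * d_k)
            if d_k > 0:
                s_km *= 1.0 - d_k / n
            n -= d_k
            s_prev_target = s_km if s_km > 0 else s_k
        if not ok:
            continue
        if used_cens < n_cens:
            censors.extend(cens_times[used_cens:])
            n -= n_cens - used_cens
        target = n if n_exit is None else int(round(n_exit))
        err = abs(n - target)
        if best is None or err < best[0]:
            best = (err, events, censors, n, s_km)
        if err == 0:
            break
    if best is None or (n_exit is not None and best[0] != 0):
        raise ReconstructionError(
            f"risk table inconsistent with curve in interval {interval_index} "
            f"[{t_lo}, {t_hi}]: cannot match number at risk")
    _, events, censors, n, s_km = best
    return np.asarray(events), np.asarray(censors), n, s_km


def guyot_reconstruct(curve: KMCurve) -> list[IPDRecord]:
    """Reconstruct individual patient data from a digitized KM curve.

    Requires a risk table whose first entry gives the initial sample size.
    Within each risk-table interval, event and censoring counts are chosen so
    the product-limit estimate of the output reproduces the input survival at
    the curve's time points and the numbers at risk at interval boundaries.
    After the last risk-table time (or when the table has a single entry,
    i.e. no interior censoring information), no censoring is assumed except
    administratively at the last follow-up time.
    """
    if curve.risk_table is None or len(curve.risk_table) < 1:
        raise ReconstructionError(
            "guyot_reconstruct requires a risk table with at least one entry")
    rt = curve.risk_table
    boundaries = list(rt[:, 0])
    counts = list(rt[:, 1])
    t_end = curve.max_time
    if boundaries[-1] < t_end:
        boundaries.append(t_end)
        counts.append(None)  # unknown: last interval assumes no dropout
    events_all, censors_all = [], []
    n_cur = int(round(counts[0]))
    s_cur = 1.0
    mask_t = curve.times > 0
    step_t, step_s = curve.times[mask_t], curve.survival[mask_t]
    # intervals are half-open [lo, hi): a step exactly at a boundary belongs
    # to the interval starting there, matching the convention that patients
    # with an event at t are still counted at risk at t
    segments = [(boundaries[i], boundaries[i + 1], counts[i + 1],
                 (step_t >= boundaries[i]) & (step_t < boundaries[i + 1]))
                for i in range(len(boundaries) - 1)]
    # trailing steps at exactly the end of follow-up: events only, after the
    # last boundary count
    segments.append((t_end, t_end, None, step_t >= boundaries[-1]))
    for i, (t_lo, t_hi, n_exit, sel) in enumerate(segments):
        ev, ce, n_cur, s_cur = _interval_ipd(
            step_t[sel], step_s[sel], s_cur, n_cur, t_lo, t_hi, n_exit, i)
        events_all.append(ev)
        censors_all.append(ce)
    ipd = [IPDRecord(float(t), 1) for t in np.concatenate(events_all)] if events_all else []
    for ce in censors_all:
        ipd.extend(IPDRecord(float(t), 0) for t in ce)
    # survivors are censored administratively at the end of follow-up
    ipd.extend(IPDRecord(float(t_end), 0) for _ in range(n_cur))
    ipd.sort(key=lambda r: (r.time, -r.event))
    return ipd


def km_estimate(ipd: list[IPDRecord], label: str = "km") -> KMCurve:
    """Product-limit estimate of a reconstructed (or simulated) IPD set."""
    if not ipd:
        raise ValueError("km_estimate requires a nonempty IPD list")
    times = np.array([r.time for r in ipd], dtype=float)
    events = np.array([r.event for r in ipd], dtype=int)
    if np.all((times == 0) & (events == 0)):
        raise ValueError("all records censored at time 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return KMCurve(label=label,
                   times=sf.index.to_numpy(float),
                   survival=sf.iloc[:, 0].to_numpy(float))


def risk_table_from_ipd(ipd: list[IPDRecord], at_times) -> np.ndarray:
    """Numbers at risk (follow-up >= t) at the requested times."""
    times = np.sort(np.array([r.time for r in ipd], dtype=float))
    at_times = np.asarray(at_times, dtype=float)
    n = len(times) - np.searchsorted(times, at_times, side="left")
    return np.column_stack([at_times, n.astype(float)])
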