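"""Rescale MSMC output to years / N_e and locate rCCR split times.

MSMC reports per-time-segment coalescence rates lambda in units scaled by
the mutation rate.  With a per-generation mutation rate mu and generation
time g (years), a scaled time t converts to t/mu generations and (t/mu)*g
years, and the within-population rate lambda_00 converts to an effective
population size N_e = 1/(2*lambda_00*mu).  For cross-population runs the
relative cross-coalescence rate rCCR = 2*lambda_01/(lambda_00+lambda_11)
falls from ~1 (single population) towards 0 after a split; the time at which
it crosses 0.5 is the conventional split-time proxy.

Defaults are the buffalo-panel constants mu = 1.26e-8 and g = 6 years.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_MU = 1.26e-8
DEFAULT_GEN_YEARS = 6.0

_COLS1 = ["time_index", "left_time_boundary", "right_time_boundary", "lambda_00"]
_COLS3 = _COLS1 + ["lambda_01", "lambda_11"]


def read_msmc(path: str) -> pd.DataFrame:
    """Parse an MSMC final output table (1 or 3 lambda columns).

    Whitespace-separated, header-tolerant, gzip accepted.  Boundaries must be
    non-decreasing and rates non-negative; violations name the row.
    """
    df = pd.read_csv(path, sep=r"\s+", compression="infer")
    if not set(df.columns) >= {"time_index"}:
        # headerless dialect: infer from column count
        df = pd.read_csv(path, sep=r"\s+", header=None, compression="infer")
        if df.shape[1] == 4:
            df.columns = _COLS1
        elif df.shape[1] == 6:
            df.columns = _COLS3
        else:
            raise ValueError(f"{path}: expected 4 or 6 columns, got {df.shape[1]}")
    # normalise MSMC's lambda_00/lambda_01/lambda_11 header variants
    rename = {c: c.replace("lambda00", "lambda_00").replace("lambda01", "lambda_01")
              .replace("lambda11", "lambda_11") for c in df.columns}
    df = df.rename(columns=rename)
    needed = _COLS3 if "lambda_01" in df.columns else _COLS1
    missing = set(needed) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df[needed].astype(float)
    lam_cols = [c for c in df.columns if c.startswith("lambda")]
    for row in range(len(df)):
        if df.loc[row, "right_time_boundary"] < df.loc[row, "left_time_boundary"]:
            raise ValueError(f"{path}: row {row}: boundaries decrease")
        if row and df.loc[row, "left_time_boundary"] < df.loc[row - 1, "left_time_boundary"]:
            raise ValueError(f"{path}: row {row}: boundaries not sorted")
        if (df.loc[row, lam_cols] < 0).any():
            raise ValueError(f"{path}: row {row}: negative coalescence rate")
    return df


def scale_track(track: pd.DataFrame, mu: float = DEFAULT_MU,
                g: float = DEFAULT_GEN_YEARS) -> pd.DataFrame:
    """Convert a scaled track to years and N_e (left-boundary time anchor)."""
    if mu <= 0 or g <= 0:
        raise ValueError("mu and g must be positive")
    out = pd.DataFrame({
        "years": track["left_time_boundary"] / mu * g,
        "years_right": track["right_time_boundary"] / mu * g,
    })
    with np.errstate(divide="ignore"):
        out["Ne"] = 1.0 / (2.0 * track["lambda_00"] * mu)
    if "lambda_01" in track.columns:
        out["rCCR"] = cross_coalescence(track)
    return out


def cross_coalescence(track: pd.DataFrame) -> np.ndarray:
    """Relative cross-coalescence rate 2*lam01/(lam00+lam11) per segment."""
    if "lambda_01" not in track.columns or "lambda_11" not in track.columns:
        raise ValueError("cross-coalescence needs all three lambda columns")
    lam00 = track["lambda_00"].to_numpy(dtype=float)
    lam01 = track["lambda_01"].to_numpy(dtype=float)
    lam11 = track["lambda_11"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return 2.0 * lam01 / (lam00 + lam11)


def find_crossing(times: np.ndarray, rccr: np.ndarray,
                  level: float = 0.5) -> list[float]:
    """Times where the rCCR series crosses ``level``, most recent first.

    Scanning from recent to ancient, a crossing is linearly interpolated
    between the last point at or above the level and the first below it; an
    exact hit at a point returns that point's time.  Empty when the series
    never crosses.
    """
    times = np.asarray(times, dtype=float)
    rccr = np.asarray(rccr, dtype=float)
    if times.shape != rccr.shape:
        raise ValueError("times and rccr must align")
    crossings: list[float] = []
    for a in range(len(times) - 1):
        ya, yb = rccr[a], rccr[a + 1]
        if np.isnan(ya) or np.isnan(yb):
            continue
        if ya == level:
            crossings.append(float(times[a]))
        elif (ya - level) * (yb - level) < 0:
            frac = (ya - level) / (ya - yb)
            crossings.append(float(times[a] + frac * (times[a + 1] - times[a])))
    if len(rccr) and rccr[-1] == level:
        crossings.append(float(times[-1]))
    # drop duplicates from exact boundary hits
    out: list[float] = []
    for c in crossings:
        if not out or abs(c - out[-1]) > 1e-12:
            out.append(c)
    return out


def split_time(track: pd.DataFrame, mu: float = DEFAULT_MU,
               g: float = DEFAULT_GEN_YEARS, level: float = 0.5) -> float | None:
    """Most recent rCCR crossing of ``level``, in years; None if no crossing."""
    scaled = scale_track(track, mu=mu, g=g)
    crossings = find_crossing(scaled["years"].to_numpy(), scaled["rCCR"].to_numpy(),
                              level=level)
    return crossings[0] if crossings else None
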