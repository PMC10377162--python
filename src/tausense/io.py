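"""Containers and plain-text readers/writers for TCSPC decay histograms and
titration tables.

Decay histograms are stored as 2-column delimited text (time_ps, counts)
with ``#``-prefixed header lines carrying instrument metadata. Titration
tables are delimited text with columns ``concentration_M``, ``replicate``,
``response`` and ``response_units``. Concentrations are handled internally in
molar units; lifetimes are reported in ns while the time axis is kept in ps.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DecayHistogram",
    "TitrationSeries",
    "FormatError",
    "read_decay",
    "write_decay",
    "read_titration",
    "write_titration",
    "parse_concentration",
]

#: minimum number of distinct concentrations required by the isotherm fitters
MIN_CONCENTRATIONS_FOR_FIT = 4

_UNIT_SCALE = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
    "fM": 1e-15,
    "aM": 1e-18,
}


class FormatError(ValueError):
    """Raised when an input file does not conform to the expected dialect."""


def parse_concentration(text: str | float) -> float:
    """Convert a concentration with an optional unit suffix to molar.

    Accepts bare numbers (taken as molar) or strings such as ``"18 pM"``,
    ``"1.5nM"`` or ``"150 nM"``. Case of the metric prefix matters
    (``m`` = milli, ``M`` = molar).
    """
    if isinstance(text, (int, float)):
        return float(text)
    m = re.fullmatch(r"\s*([0-9.eE+-]+)\s*([a-zA-Zµ]*M)?\s*", str(text))
    if m is None:
        raise ValueError(f"cannot parse concentration {text!r}")
    value = float(m.group(1))
    unit = m.group(2) or "M"
    if unit not in _UNIT_SCALE:
        raise ValueError(f"unknown concentration unit {unit!r} in {text!r}")
    return value * _UNIT_SCALE[unit]


@dataclass
class DecayHistogram:
    """Binned photon counts versus time, for a sample decay or a prompt (IRF).

    Parameters
    ----------
    times
        Channel-center times in ps, uniformly spaced, increasing.
    counts
        Nonnegative integer photon counts per channel.
    channel_width
        Time per channel in ps. Derived from ``times`` if not given.
    role
        ``"decay"`` for a sample measurement, ``"prompt"`` for the
        instrument response function.
    label
        Free-text sample identity (e.g. analyte concentration).
    """

    times: np.ndarray
    counts: np.ndarray
    channel_width: float | None = None
    role: str = "decay"
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.times.ndim != 1 or self.counts.ndim != 1:
            raise ValueError("times and counts must be 1-D")
        if len(self.times) != len(self.counts):
            raise ValueError("times and counts must have equal length")
        if len(self.times) < 2:
            raise ValueError("a decay histogram needs at least 2 channels")
        diffs = np.diff(self.times)
        if np.any(diffs <= 0):
            raise FormatError("times must be strictly increasing")
        w = diffs.mean()
        if np.max(np.abs(diffs - w)) > 1e-9 * max(abs(w), 1.0):
            raise FormatError("non-uniform channel spacing")
        if self.channel_width is None:
            self.channel_width = float(w)
        elif abs(self.channel_width - w) > 1e-6 * w:
            raise FormatError(
                f"header channel_width {self.channel_width} disagrees with "
                f"time column spacing {w}"
            )
        if np.any(np.asarray(self.counts, dtype=float) < 0):
            raise ValueError("counts must be nonnegative")
        # measured data are integer counts; float counts are tolerated so the
        # container can also hold noiseless model expectations
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_float = np.asarray(self.counts, dtype=float)
            as_int = np.rint(as_float).astype(np.int64)
            if np.max(np.abs(as_int - as_float)) <= 1e-9:
                self.counts = as_int
            else:
                self.counts = as_float
        if self.counts.sum() <= 0:
            raise ValueError("histogram has zero total counts")
        if self.role not in ("decay", "prompt"):
            raise ValueError(f"role must be 'decay' or 'prompt', got {self.role!r}")

    @property
    def n_channels(self) -> int:
        return len(self.times)

    @property
    def total_counts(self) -> int:
        return int(self.counts.sum())

    @property
    def peak_channel(self) -> int:
        return int(np.argmax(self.counts))

    def normalized(self) -> np.ndarray:
        """Counts normalized to unit sum (the convolution kernel weights)."""
        total = float(self.counts.sum())
        return np.asarray(self.counts, dtype=float) / total

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DecayHistogram):
            return NotImplemented
        return (
            np.allclose(self.times, other.times, rtol=0, atol=1e-9)
            and np.array_equal(self.counts, other.counts)
            and self.role == other.role
            and self.label == other.label
        )


def write_decay(hist: DecayHistogram, path: str | Path) -> None:
    """Write a decay histogram as 2-column text with a metadata header.

    Byte-deterministic: fixed float formatting and fixed header key order.
    """
    path = Path(path)
    lines = [
        f"# channel_width_ps={hist.channel_width:.6f}",
        f"# n_channels={hist.n_channels}",
        f"# role={hist.role}",
        f"# label={hist.label}",
        "# columns=time_ps\tcounts",
    ]
    for t, c in zip(hist.times, hist.counts):
        lines.append(f"{t:.6f}\t{int(c)}")
    path.write_text("\n".join(lines) + "\n")


def read_decay(path: str | Path) -> DecayHistogram:
    """Read a decay histogram written by :func:`write_decay`.

    The channel width is derived from the time column when the header omits
    it; header and column disagree → :class:`FormatError`.
    """
    path = Path(path)
    header: dict[str, str] = {}
    times: list[float] = []
    counts: list[int] = []
    n_rows = 0
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                header[key.strip()] = val.strip()
            continue
        n_rows += 1
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"{path}: expected 2 columns, got {len(parts)}")
        times.append(float(parts[0]))
        c = float(parts[1])
        if c < 0:
            raise ValueError(f"{path}: negative count {c}")
        counts.append(int(round(c)))
    if n_rows == 0:
        raise FormatError(f"{path}: no data rows")
    width = float(header["channel_width_ps"]) if "channel_width_ps" in header else None
    if "n_channels" in header and int(header["n_channels"]) != n_rows:
        raise FormatError(
            f"{path}: header n_channels={header['n_channels']} but {n_rows} rows"
        )
    return DecayHistogram(
        times=np.array(times),
        counts=np.array(counts, dtype=np.int64),
        channel_width=width,
        role=header.get("role", "decay"),
        label=header.get("label", ""),
    )


@dataclass
class TitrationSeries:
    """Analyte concentrations with replicate responses (τ₂ in ns or rfu).

    ``dispersions`` holds the per-concentration sample standard deviation,
    NaN ("unavailable") where a group has a single replicate — deliberately
    distinct from 0 so that blank statistics are never silently taken from a
    single measurement.
    """

    concentrations: np.ndarray
    responses: list[np.ndarray]
    response_kind: str = "lifetime_tau2"
    label: str = ""
    dispersions: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if len(self.responses) != len(self.concentrations):
            raise ValueError("one replicate group per concentration required")
        self.responses = [np.asarray(r, dtype=float) for r in self.responses]
        if any(len(r) == 0 for r in self.responses):
            raise ValueError("empty replicate group")
        if self.response_kind not in ("lifetime_tau2", "intensity"):
            raise ValueError(f"unknown response_kind {self.response_kind!r}")
        self.dispersions = np.array(
            [r.std(ddof=1) if len(r) > 1 else np.nan for r in self.responses]
        )
        if len(self.concentrations) < MIN_CONCENTRATIONS_FOR_FIT:
            warnings.warn(
                f"only {len(self.concentrations)} distinct concentrations; "
                f"isotherm fitting requires ≥{MIN_CONCENTRATIONS_FOR_FIT}",
                stacklevel=2,
            )

    @property
    def n_points(self) -> int:
        return len(self.concentrations)

    @property
    def means(self) -> np.ndarray:
        return np.array([r.mean() for r in self.responses])

    @property
    def units(self) -> str:
        return "ns" if self.response_kind == "lifetime_tau2" else "rfu"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c, reps in zip(self.concentrations, self.responses):
            for i, r in enumerate(reps):
                rows.append(
                    {
                        "concentration_M": c,
                        "replicate": i,
                        "response": r,
                        "response_units": self.units,
                    }
                )
        return pd.DataFrame(rows)


def write_titration(series: TitrationSeries, path: str | Path) -> None:
    """Write a titration table as tab-separated text (deterministic output)."""
    df = series.to_frame()
    with open(path, "w") as fh:
        fh.write(f"# response_kind={series.response_kind}\n")
        fh.write(f"# label={series.label}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_titration(path: str | Path) -> TitrationSeries:
    """Read a titration table; groups replicates and sorts concentrations.

    Rejects duplicate (concentration, replicate) pairs. Never silently drops
    rows: every input row either becomes a record or raises.
    """
    path = Path(path)
    header: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        for line in iter(fh.readline, ""):
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, _, v = body.partition("=")
                    header[k.strip()] = v.strip()
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        df = pd.read_csv(fh, sep=None, engine="python")
    required = {"concentration_M", "replicate", "response"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df.duplicated(subset=["concentration_M", "replicate"]).any():
        raise FormatError(f"{path}: duplicate (concentration, replicate) pairs")
    kind = header.get("response_kind")
    if kind is None:
        units = set(df.get("response_units", pd.Series(["ns"])).unique())
        kind = "intensity" if units == {"rfu"} else "lifetime_tau2"
    grouped = df.sort_values("concentration_M").groupby("concentration_M", sort=True)
    concentrations = np.array(sorted(df["concentration_M"].unique()))
    responses = [grouped.get_group(c)["response"].to_numpy() for c in concentrations]
    return TitrationSeries(
        concentrations=concentrations,
        responses=responses,
        response_kind=kind,
        label=header.get("label", ""),
    )
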