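"""Dose-response viability mapping and release-profile safety classification.

MSC viability after bupivacaine exposure was tabulated as mean +/- SEM over a
concentration grid (0, 0.01, 0.1, 0.5, 1 mM) at two exposure durations (24 h,
48 h), normalised to the basal-medium control. This module represents that
table, interpolates viability at arbitrary dose (log-dose linear between
knots, per pharmacological convention), derives the largest tabulated dose
meeting a viability floor, classifies simulated release profiles against a
concentration ceiling, and reimplements the one-way ANOVA + Fisher LSD
post-hoc procedure used on group viability measurements.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ExtrapolationError, ParseError, ValidationError
from .release_model import ReleaseCurve

logger = logging.getLogger("depotsim")

ALPHA_DEFAULT = 0.05
VIABILITY_FLOOR_DEFAULT = 90.0  # %
SAFE_CONCENTRATION_DEFAULT = 0.1  # mM

_CELL_RE = re.compile(
    r"^\s*(\d+(?:\.\d+)?)\s*(?:±|\+/-|\+-)\s*(\d+(?:\.\d+)?)\s*(%?)\s*$")


@dataclass(frozen=True)
class ViabilityTable:
    """Viability dose-response grid: mean % of control with SEM.

    ``mean_viability`` and ``sem`` are (n_times, n_concentrations) matrices.
    If a 0 mM control column is present its mean must be 100% at every
    exposure (the table is normalised to control).
    """

    concentrations: np.ndarray  # mM, strictly increasing
    exposure_times: np.ndarray  # h, strictly increasing
    mean_viability: np.ndarray  # %
    sem: np.ndarray             # %
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        c = np.asarray(self.concentrations, float)
        t = np.asarray(self.exposure_times, float)
        m = np.asarray(self.mean_viability, float)
        s = np.asarray(self.sem, float)
        if not (np.all(np.diff(c) > 0) and np.all(np.diff(t) > 0)):
            raise ValidationError("concentration and exposure grids must be strictly increasing")
        if m.shape != (t.size, c.size) or s.shape != m.shape:
            raise ValidationError(
                f"matrix shape {m.shape} does not match grids ({t.size}, {c.size})")
        if np.any(m < 0) or np.any(s < 0):
            raise ValidationError("viability means and SEMs must be non-negative")
        if c[0] == 0.0 and not np.allclose(m[:, 0], 100.0):
            raise ValidationError("control column (0 mM) must be 100% at all exposures")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "exposure_times", t)
        object.__setattr__(self, "mean_viability", m)
        object.__setattr__(self, "sem", s)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_csv(cls, path) -> "ViabilityTable":
        """Read a table whose rows are exposure times and columns doses.

        Header: ``exposure_h,<c1> mM,<c2> mM,...``; cells are
        ``mean ± sem`` (SEM in %, a missing % sign marks the SEM suspect and
        is recorded in metadata, not repaired).
        """
        with open(path, encoding="utf-8") as fh:
            lines = [ln.rstrip("\n") for ln in fh]
        if not lines:
            raise ParseError("empty viability table", line=1)
        header = [h.strip() for h in lines[0].split(",")]
        if header[0] != "exposure_h":
            raise ParseError(f"first column must be 'exposure_h', got {header[0]!r}", line=1)
        try:
            concs = [float(h.replace("mM", "").strip()) for h in header[1:]]
        except ValueError as exc:
            raise ParseError(f"bad concentration header: {exc}", line=1) from exc

        times, means, sems = [], [], []
        verbatim: dict[tuple[float, float], str] = {}
        suspect: list[tuple[float, float]] = []
        for i, ln in enumerate(lines[1:], start=2):
            if not ln.strip():
                continue
            cells = [c.strip() for c in ln.split(",")]
            if len(cells) != len(header):
                raise ParseError(f"expected {len(header)} columns, got {len(cells)}", line=i)
            try:
                t = float(cells[0])
            except ValueError as exc:
                raise ParseError(f"bad exposure time {cells[0]!r}", line=i) from exc
            row_m, row_s = [], []
            for conc, cell in zip(concs, cells[1:]):
                match = _CELL_RE.match(cell)
                if match is None:
                    raise ParseError(f"cell {cell!r} is not 'mean ± sem'", line=i)
                row_m.append(float(match.group(1)))
                row_s.append(float(match.group(2)))
                verbatim[(t, conc)] = cell
                if match.group(3) != "%":
                    suspect.append((t, conc))
            times.append(t)
            means.append(row_m)
            sems.append(row_s)
        meta = {"verbatim": verbatim, "suspect_sem_cells": suspect, "source": str(path)}
        if suspect:
            logger.warning("viability table has %d cell(s) with suspect SEM "
                           "(missing %% sign): %s", len(suspect), suspect)
        return cls(np.array(concs), np.array(times), np.array(means),
                   np.array(sems), metadata=meta)

    @classmethod
    def packaged(cls) -> "ViabilityTable":
        """The packaged bupivacaine/MSC dose-response fixture."""
        ref = resources.files("depotsim.data") / "table1_viability.csv"
        with resources.as_file(ref) as path:
            return cls.from_csv(path)

    # -- helpers ------------------------------------------------------------

    def _time_row(self, exposure: float) -> int:
        t = self.exposure_times
        if exposure < t[0] - 1e-9 or exposure > t[-1] + 1e-9:
            raise ValidationError(
                f"exposure {exposure} h outside tabulated range [{t[0]}, {t[-1]}] h")
        exact = np.isclose(t, exposure)
        if exact.any():
            return int(np.argmax(exact))
        idx = int(np.argmin(np.abs(t - exposure)))
        warnings.warn(
            f"exposure {exposure} h not tabulated; using nearest grid time {t[idx]} h",
            UserWarning, stacklevel=3)
        return idx


@dataclass(frozen=True)
class SafetyReport:
    """Outcome of screening a release profile against a concentration ceiling."""

    threshold_concentration: float  # mM
    max_observed_concentration: float  # mM
    first_exceedance_time: float | None  # h
    safe: bool

    def __post_init__(self):
        if self.safe != (self.first_exceedance_time is None):
            raise ValidationError("safe flag inconsistent with first_exceedance_time")


def interpolate_viability(table: ViabilityTable, concentration: float,
                          exposure: float) -> float:
    """Viability (%) at an arbitrary dose and a tabulated exposure time.

    Exact at grid knots. Between positive doses the interpolation is linear
    in log10(concentration); between 0 mM and the smallest positive dose it
    is linear in concentration. Doses above the grid maximum raise
    :class:`ExtrapolationError` (no extrapolation).
    """
    if concentration < 0:
        raise ValidationError("concentration must be >= 0")
    row = table.mean_viability[table._time_row(exposure)]
    c = table.concentrations
    if concentration > c[-1] * (1 + 1e-12):
        raise ExtrapolationError(
            f"concentration {concentration} mM above tabulated maximum {c[-1]} mM")
    exact = np.isclose(c, concentration, rtol=1e-12, atol=1e-15)
    if exact.any():
        return float(row[np.argmax(exact)])
    j = int(np.searchsorted(c, concentration))  # c[j-1] < conc < c[j]
    if j == 0:
        # below the smallest tabulated dose and no 0 mM knot: treat control as 100%
        c_lo, v_lo = 0.0, 100.0
    else:
        c_lo, v_lo = c[j - 1], row[j - 1]
    c_hi, v_hi = c[j], row[j]
    if c_lo == 0.0:
        w = (concentration - c_lo) / (c_hi - c_lo)
    else:
        w = (np.log10(concentration) - np.log10(c_lo)) / (np.log10(c_hi) - np.log10(c_lo))
    return float(v_lo + w * (v_hi - v_lo))


def max_safe_concentration(table: ViabilityTable, viability_floor: float = VIABILITY_FLOOR_DEFAULT,
                           exposure: float = 48.0) -> float | None:
    """Largest tabulated dose whose mean viability meets the floor.

    Returns ``None`` when no tabulated dose (including the control, if
    present) satisfies the floor.
    """
    if not (0 < viability_floor <= 100):
        raise ValidationError("viability_floor must be in (0, 100]")
    row = table.mean_viability[table._time_row(exposure)]
    ok = np.nonzero(row >= viability_floor)[0]
    if ok.size == 0:
        return None
    return float(table.concentrations[ok.max()])


def classify_release_safety(curve: ReleaseCurve | tuple[np.ndarray, np.ndarray],
                            threshold: float = SAFE_CONCENTRATION_DEFAULT) -> SafetyReport:
    """Screen a concentration time series against a ceiling.

    Accepts a :class:`ReleaseCurve` (its well concentration is screened) or a
    ``(times_h, concentrations_mM)`` pair, e.g. a cell-apparent series. The
    profile is safe when it never exceeds the threshold.
    """
    if isinstance(curve, ReleaseCurve):
        times, conc = curve.times, curve.well_concentration
    else:
        times = np.asarray(curve[0], float)
        conc = np.asarray(curve[1], float)
    if times.size == 0:
        raise ValidationError("cannot classify an empty series")
    if np.any(conc < 0):
        raise ValidationError("negative concentrations in release profile")
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    over = np.nonzero(conc > threshold)[0]
    first = float(times[over[0]]) if over.size else None
    return SafetyReport(threshold_concentration=float(threshold),
                        max_observed_concentration=float(conc.max()),
                        first_exceedance_time=first,
                        safe=first is None)


# ---------------------------------------------------------------------------
# Group comparison: one-way ANOVA + Fisher LSD
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA with Fisher LSD pairwise post-hoc results.

    The ANOVA is computed from sums of squares; LSD pairwise t statistics use
    the pooled within-group mean square (no multiplicity adjustment, per the
    LSD procedure).
    """

    groups: tuple[str, ...]
    n_per_group: tuple[int, ...]
    f_stat: float
    p_value: float
    df_between: int
    df_within: int
    mse: float
    lsd: pd.DataFrame  # columns: group_a, group_b, mean_diff, t_stat, p_value, significant
    alpha: float


def compare_groups(measurements: dict[str, np.ndarray] | pd.DataFrame,
                   alpha: float = ALPHA_DEFAULT) -> GroupComparison:
    """One-way ANOVA followed by Fisher's LSD post-hoc comparisons.

    ``measurements`` is either a mapping from group name to replicate values
    or a DataFrame with ``group`` and ``value`` columns. Requires at least two
    groups with at least two replicates each and nonzero pooled within-group
    variance.
    """
    if isinstance(measurements, pd.DataFrame):
        if not {"group", "value"} <= set(measurements.columns):
            raise ValidationError("DataFrame must have 'group' and 'value' columns")
        data = {str(g): sub["value"].to_numpy(float)
                for g, sub in measurements.groupby("group", sort=False)}
    else:
        data = {str(g): np.asarray(v, float) for g, v in measurements.items()}

    names = tuple(data)
    if len(names) < 2:
        raise ValidationError("need at least two groups")
    for g, v in data.items():
        if v.size < 2:
            raise ValidationError(f"group {g!r} needs at least two replicates")
        if not np.all(np.isfinite(v)):
            raise ValidationError(f"group {g!r} contains non-finite values")

    ns = np.array([data[g].size for g in names])
    means = np.array([data[g].mean() for g in names])
    n_total = int(ns.sum())
    grand = float(np.concatenate([data[g] for g in names]).mean())

    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((data[g] - data[g].mean()) ** 2) for g in names))
    df_between = len(names) - 1
    df_within = n_total - len(names)
    if ss_within <= 0:
        raise ValidationError("zero within-group variance in every group; "
                              "ANOVA mean square error is degenerate")
    ms_between = ss_between / df_between
    mse = ss_within / df_within
    f_stat = ms_between / mse
    p_value = float(stats.f.sf(f_stat, df_between, df_within))

    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            diff = means[i] - means[j]
            se = np.sqrt(mse * (1 / ns[i] + 1 / ns[j]))
            t = diff / se
            p = float(2 * stats.t.sf(abs(t), df_within))
            rows.append({"group_a": names[i], "group_b": names[j],
                         "mean_diff": diff, "t_stat": t, "p_value": p,
                         "significant": p <= alpha})
    lsd = pd.DataFrame(rows, columns=["group_a", "group_b", "mean_diff",
                                      "t_stat", "p_value", "significant"])
    return GroupComparison(groups=names, n_per_group=tuple(int(n) for n in ns),
                           f_stat=float(f_stat), p_value=p_value,
                           df_between=df_between, df_within=df_within,
                           mse=float(mse), lsd=lsd, alpha=alpha)


__all__ = [
    "ViabilityTable", "SafetyReport", "GroupComparison",
    "interpolate_viability", "max_safe_concentration",
    "classify_release_safety", "compare_groups",
    "VIABILITY_FLOOR_DEFAULT", "SAFE_CONCENTRATION_DEFAULT", "ALPHA_DEFAULT",
]
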