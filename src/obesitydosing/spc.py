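"""Statistical process control for proportions.

Implements the Shewhart p-chart used to monitor monthly order
appropriateness: per phase the centerline is the *pooled* proportion
``p̄ = Σ successes / Σ n`` (weighted, not a mean of monthly proportions —
required for the binomial limit formula to be coherent) and each subgroup
``i`` gets three-sigma limits ``p̄ ± 3·sqrt(p̄(1-p̄)/n_i)`` clipped to
[0, 1]. Two special-cause rules are active by default: a point beyond the
three-sigma limits, and a run of eight consecutive points strictly on one
side of the centerline (points exactly on the centerline break the run).
Confirmed shifts are folded into the chart by re-phasing: the centerline
is recomputed independently before and after the shift point.

A funnel chart plots unit-level proportions against the pooled overall
proportion with limits that narrow as ``sqrt(1/n)``; units strictly
outside their limits are flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import DataIntegrityError, EmptyChartError

DEFAULT_RUN_LENGTH = 8
DEFAULT_SIGMA = 3.0

RULE_BEYOND_LIMITS = "beyond_limits"
RULE_RUN_SHIFT = "run_shift"
DEFAULT_RULES = (RULE_BEYOND_LIMITS, RULE_RUN_SHIFT)


@dataclass(frozen=True)
class SubgroupProportion:
    """One subgroup (a month, or a unit): n trials, `successes` successes."""

    label: str
    n: int
    successes: int

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise DataIntegrityError(f"subgroup {self.label!r}: n must be positive")
        if not (0 <= self.successes <= self.n):
            raise DataIntegrityError(
                f"subgroup {self.label!r}: successes {self.successes} "
                f"outside [0, {self.n}]"
            )

    @property
    def proportion(self) -> float:
        return self.successes / self.n


@dataclass(frozen=True)
class Signal:
    """A special-cause signal: which rule fired at which point, which side."""

    index: int
    rule: str
    side: str  # "above" | "below"


@dataclass
class PChartResult:
    """A built p-chart: per-point statistics, phase centerlines, signals."""

    subgroups: list[SubgroupProportion]
    phases: list[tuple[int, float]]       # (start index, centerline p̄)
    proportions: list[float]
    centerline: list[float]               # per-point (phase-resolved)
    ucl: list[float]
    lcl: list[float]
    signals: list[Signal] = field(default_factory=list)

    def phase_of(self, index: int) -> int:
        """0-based phase number containing point ``index``."""
        k = 0
        for j, (start, _) in enumerate(self.phases):
            if index >= start:
                k = j
        return k


@dataclass
class FunnelResult:
    """Unit-level funnel chart: pooled proportion and per-unit limits."""

    overall_p: float
    sigma: float
    units: list[tuple[str, int, float, float, float, bool]]
    # (label, n, proportion, lower limit, upper limit, flagged)


# ---------------------------------------------------------------------------
# p-chart construction
# ---------------------------------------------------------------------------


def _pooled(series: Sequence[SubgroupProportion]) -> float:
    return sum(s.successes for s in series) / sum(s.n for s in series)


def build_pchart(
    series: Sequence[SubgroupProportion],
    phase_breaks: Sequence[int] = (),
    *,
    rules: Sequence[str] = DEFAULT_RULES,
    run_length: int = DEFAULT_RUN_LENGTH,
    sigma: float = DEFAULT_SIGMA,
) -> PChartResult:
    """Build a (possibly multi-phase) p-chart over an ordered series.

    ``phase_breaks`` are indices at which a new phase (new centerline)
    starts; they must be strictly increasing and lie strictly inside the
    series. Signals are evaluated per phase for the rules requested.
    """
    series = list(series)
    if not series:
        raise EmptyChartError("cannot build a p-chart from an empty series")
    breaks = list(phase_breaks)
    if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
        raise DataIntegrityError("phase breaks must be strictly increasing")
    if any(not (0 < b < len(series)) for b in breaks):
        raise DataIntegrityError(
            f"phase breaks {breaks} must lie strictly inside (0, {len(series)})"
        )

    starts = [0] + breaks
    ends = breaks + [len(series)]
    phases: list[tuple[int, float]] = []
    centerline: list[float] = []
    ucl: list[float] = []
    lcl: list[float] = []
    for start, end in zip(starts, ends):
        pbar = _pooled(series[start:end])
        phases.append((start, pbar))
        for sub in series[start:end]:
            half = sigma * math.sqrt(pbar * (1.0 - pbar) / sub.n)
            centerline.append(pbar)
            ucl.append(min(1.0, pbar + half))
            lcl.append(max(0.0, pbar - half))

    chart = PChartResult(
        subgroups=series,
        phases=phases,
        proportions=[s.proportion for s in series],
        centerline=centerline,
        ucl=ucl,
        lcl=lcl,
    )
    if RULE_BEYOND_LIMITS in rules:
        for i, p in enumerate(chart.proportions):
            if p > chart.ucl[i]:
                chart.signals.append(Signal(i, RULE_BEYOND_LIMITS, "above"))
            elif p < chart.lcl[i]:
                chart.signals.append(Signal(i, RULE_BEYOND_LIMITS, "below"))
    if RULE_RUN_SHIFT in rules:
        chart.signals.extend(detect_shift(chart, run_length))
    chart.signals.sort(key=lambda s: (s.index, s.rule))
    return chart


def detect_shift(chart: PChartResult, run_length: int = DEFAULT_RUN_LENGTH) -> list[Signal]:
    """Find sustained runs on one side of the phase centerline.

    A signal is emitted at the point where ``run_length`` consecutive
    subgroups have fallen strictly on the same side of the current phase's
    centerline; points exactly on the centerline break the run, and a run
    longer than ``run_length`` yields a single signal at its
    ``run_length``-th point.
    """
    signals: list[Signal] = []
    starts = [s for s, _ in chart.phases]
    ends = starts[1:] + [len(chart.proportions)]
    for (start, pbar), end in zip(chart.phases, ends):
        side = 0  # +1 above, -1 below, 0 on centerline
        run = 0
        fired = False
        for i in range(start, end):
            p = chart.proportions[i]
            this = 1 if p > pbar else (-1 if p < pbar else 0)
            if this != 0 and this == side:
                run += 1
            else:
                side, run, fired = this, (1 if this != 0 else 0), False
            if run >= run_length and not fired:
                signals.append(
                    Signal(i, RULE_RUN_SHIFT, "above" if side > 0 else "below")
                )
                fired = True
    return signals


def rephase(
    series: Sequence[SubgroupProportion],
    at: int,
    *,
    rules: Sequence[str] = DEFAULT_RULES,
    run_length: int = DEFAULT_RUN_LENGTH,
    sigma: float = DEFAULT_SIGMA,
) -> PChartResult:
    """Rebuild the chart with independent centerlines before/after ``at``.

    Applying this at each confirmed shift reproduces the stepped
    multi-phase chart structure used in QI reporting.
    """
    return build_pchart(
        series, [at], rules=rules, run_length=run_length, sigma=sigma
    )


# ---------------------------------------------------------------------------
# Funnel chart
# ---------------------------------------------------------------------------


def build_funnel(
    units: Iterable[SubgroupProportion],
    sigma: float = DEFAULT_SIGMA,
) -> FunnelResult:
    """Funnel chart of unit-level proportions around the pooled proportion.

    Limits are ``overall_p ± sigma·sqrt(overall_p(1-overall_p)/n_i)``
    clipped to [0, 1]; a unit is flagged only when strictly outside its
    limits (a point exactly on a limit is in control).
    """
    units = list(units)
    if not units or sum(u.n for u in units) <= 0:
        raise EmptyChartError("funnel chart requires at least one non-empty unit")
    overall = _pooled(units)
    rows: list[tuple[str, int, float, float, float, bool]] = []
    for u in units:
        half = sigma * math.sqrt(overall * (1.0 - overall) / u.n)
        lower = max(0.0, overall - half)
        upper = min(1.0, overall + half)
        p = u.proportion
        flagged = p < lower or p > upper
        rows.append((u.label, u.n, p, lower, upper, flagged))
    return FunnelResult(overall_p=overall, sigma=sigma, units=rows)


# ---------------------------------------------------------------------------
# Rendering (optional figures)
# ---------------------------------------------------------------------------


def plot_pchart(chart: PChartResult, path: str, title: str = "p-chart") -> None:
    """Render the chart to an image file (matplotlib, headless-safe)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    x = range(len(chart.proportions))
    fig, ax = plt.subplots(figsize=(9, 4))
    ax.plot(x, chart.proportions, "o-", label="proportion")
    ax.step(x, chart.centerline, where="mid", color="green", label="centerline")
    ax.step(x, chart.ucl, where="mid", color="red", ls="--", label="UCL/LCL")
    ax.step(x, chart.lcl, where="mid", color="red", ls="--")
    for sig in chart.signals:
        ax.plot(sig.index, chart.proportions[sig.index], "rx", ms=12)
    ax.set_xticks(list(x))
    ax.set_xticklabels([s.label for s in chart.subgroups], rotation=90, fontsize=7)
    ax.set_ylabel("proportion appropriate")
    ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_funnel(result: FunnelResult, path: str, title: str = "funnel chart") -> None:
    """Render a funnel chart to an image file."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    ns = sorted(n for _, n, *_ in result.units)
    grid = range(max(1, ns[0]), ns[-1] + 1)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    p = result.overall_p
    ax.plot(
        list(grid),
        [min(1.0, p + result.sigma * math.sqrt(p * (1 - p) / n)) for n in grid],
        "r--", lw=1,
    )
    ax.plot(
        list(grid),
        [max(0.0, p - result.sigma * math.sqrt(p * (1 - p) / n)) for n in grid],
        "r--", lw=1,
    )
    ax.axhline(p, color="green", lw=1)
    for label, n, prop, _lo, _hi, flagged in result.units:
        ax.plot(n, prop, "rs" if flagged else "bo")
        ax.annotate(label, (n, prop), fontsize=7, xytext=(3, 3),
                    textcoords="offset points")
    ax.set_xlabel("orders (n)")
    ax.set_ylabel("proportion")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
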