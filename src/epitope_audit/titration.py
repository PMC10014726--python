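"""Three-point antibody titration scoring and concentration selection.

Each antibody is stained at 0.5x, 1x and 2x the vendor-recommended
concentration.  Two percent-positive readouts are taken per point:

* ``pct_signal_plus_noise`` — gated on the unstained control (a high
  quantile of the unstained distribution), which counts specific staining
  plus nonspecific background;
* ``pct_signal`` — gated by peak separation on the stained sample itself
  (KDE valley); if no separated positive peak exists the point has no
  signal.

The optimal concentration is the one that keeps a positive peak (signal at
least ``min_signal_pct`` and within ``signal_retention_delta`` of the series
maximum) while minimizing signal-plus-noise; ties go to the lower
concentration, which also minimizes antibody cost.  The signal-to-
signal-plus-noise ratio is reported as a diagnostic only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .flow_model import (
    ConfigError,
    DataError,
    EventTable,
    FixtureError,
    NoSignalError,
    PaperFixtures,
    ValidationError,
)
from .gating import GateMethod, GatingConfig, fit_gate, percent_positive

__all__ = [
    "TitrationPoint",
    "TitrationSeries",
    "TitrationConfig",
    "score_titration_point",
    "score_titration_series",
    "select_concentration",
    "titration_table_report",
]


@dataclass(frozen=True)
class TitrationPoint:
    """Scored readouts at one staining concentration (µg per 100 µL per
    10^6 cells)."""

    concentration: float
    pct_signal_plus_noise: float
    pct_signal: float

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValidationError("concentration must be positive")
        for name in ("pct_signal_plus_noise", "pct_signal"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValidationError(f"{name}={v} outside [0, 100]")

    @property
    def noise_excess(self) -> float:
        return self.pct_signal_plus_noise - self.pct_signal

    @property
    def signal_to_signal_plus_noise(self) -> float | None:
        """Diagnostic ratio; None when there is no signal-plus-noise."""
        if self.pct_signal_plus_noise <= 0:
            return None
        return self.pct_signal / self.pct_signal_plus_noise


@dataclass(frozen=True)
class TitrationSeries:
    """Three scored points at 0.5x/1x/2x the recommended concentration plus
    the selected (1-based) point index."""

    antibody: str
    stimulation: str
    points: tuple[TitrationPoint, TitrationPoint, TitrationPoint]
    chosen_index: int
    recommended_concentration: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        if len(self.points) != 3:
            raise ValidationError("a titration series has exactly 3 points")
        c = [p.concentration for p in self.points]
        if not (c[0] < c[1] < c[2]):
            raise ValidationError("concentrations must be strictly increasing")
        if abs(c[1] - self.recommended_concentration) > 1e-6 * c[1]:
            raise ValidationError(
                "the middle point must sit at the recommended concentration")
        if self.chosen_index not in (1, 2, 3):
            raise ValidationError("chosen_index must be 1, 2 or 3")


@dataclass(frozen=True)
class TitrationConfig:
    """Mechanization of "keeps a positive peak".

    A point retains signal when its percent-positive signal is at least
    ``min_signal_pct`` (absolute floor, for dim markers) and within
    ``signal_retention_delta`` (fractional) of the series maximum.
    """

    signal_retention_delta: float = 0.10
    min_signal_pct: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.signal_retention_delta < 1.0):
            raise ConfigError("signal_retention_delta must be in [0, 1)")
        if self.min_signal_pct < 0:
            raise ConfigError("min_signal_pct must be non-negative")


def score_titration_point(
    stained: EventTable,
    unstained: EventTable,
    channel: str | None = None,
    config: GatingConfig | None = None,
) -> TitrationPoint:
    """Score one stained sample against the unstained control.

    The signal-plus-noise gate is a quantile of the unstained control; the
    signal gate is a KDE valley fit on the stained sample itself.  When the
    valley engine falls back (no separated positive peak), the point's
    signal is 0.
    """
    if stained.meta.concentration is None:
        raise DataError(
            f"sample {stained.sample_id!r} has no staining concentration")
    channel = channel or stained.channels[0]
    noise_gate = fit_gate(unstained, channel,
                          method=GateMethod.CONTROL_QUANTILE, params=config)
    psn = percent_positive(stained, noise_gate, params=config).pct_positive
    signal_gate = fit_gate(stained, channel, method=GateMethod.KDE_VALLEY,
                           params=config)
    if signal_gate.method is GateMethod.KDE_VALLEY:
        ps = percent_positive(stained, signal_gate, params=config).pct_positive
    else:
        ps = 0.0
    return TitrationPoint(concentration=stained.meta.concentration,
                          pct_signal_plus_noise=psn, pct_signal=ps)


def select_concentration(
    points: Sequence[TitrationPoint],
    config: TitrationConfig | None = None,
) -> int:
    """Pick the optimal of three scored points; returns a 1-based index.

    Eligible points keep a positive peak (see :class:`TitrationConfig`);
    among them the lowest signal-plus-noise wins, ties broken toward the
    lower concentration.  Depends only on the ordering of concentrations,
    not their absolute values.
    """
    config = config or TitrationConfig()
    points = list(points)
    if len(points) != 3:
        raise ValidationError("select_concentration needs exactly 3 points")
    concs = [p.concentration for p in points]
    if not (concs[0] < concs[1] < concs[2]):
        raise ValidationError("points must be ordered by concentration")

    max_signal = max(p.pct_signal for p in points)
    floor = (1.0 - config.signal_retention_delta) * max_signal
    eligible = [
        i for i, p in enumerate(points)
        if p.pct_signal >= config.min_signal_pct and p.pct_signal >= floor
    ]
    if not eligible:
        raise NoSignalError("no titration point shows a positive peak")
    best = min(eligible,
               key=lambda i: (points[i].pct_signal_plus_noise, concs[i]))
    return best + 1


def score_titration_series(
    antibody: str,
    stained: Sequence[EventTable],
    unstained: EventTable,
    stimulation: str = "none",
    gating_config: GatingConfig | None = None,
    config: TitrationConfig | None = None,
) -> TitrationSeries:
    """Score three stained samples and select the optimal concentration."""
    pts = sorted(
        (score_titration_point(s, unstained, config=gating_config)
         for s in stained),
        key=lambda p: p.concentration,
    )
    if len(pts) != 3:
        raise ValidationError("a titration series has exactly 3 stained samples")
    chosen = select_concentration(pts, config=config)
    return TitrationSeries(
        antibody=antibody, stimulation=stimulation, points=tuple(pts),
        chosen_index=chosen, recommended_concentration=pts[1].concentration)


def titration_table_report(fixtures: PaperFixtures) -> dict[int, int]:
    """Count antibodies in the bundled titration table by chosen point.

    Returns ``{1: n_lowest, 2: n_middle, 3: n_highest}``.
    """
    counts = {1: 0, 2: 0, 3: 0}
    for row in fixtures.table3:
        if row.chosen_index not in counts:
            raise FixtureError(
                f"antibody {row.antibody}: chosen value matches no tested "
                "concentration")
        counts[row.chosen_index] += 1
    return counts
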