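"""Synthetic flow-cytometry and ADT data with known ground truth.

Generates the statistical structure the analysis pipeline assumes so every
downstream rule can be tested against a recoverable truth:

* per-sample fluorescence events drawn from a two-component mixture on the
  log10-intensity scale (negative and positive population, each
  log10-normal);
* enzymatic digestion modeled as full epitope loss with probability ``c``
  (the cleavage fraction: the event is resampled from the negative
  component) plus a multiplicative intensity retention ``r`` on surviving
  positive cells — the simplest two-parameter model producing both
  population loss and an MFI shift;
* donor variability as a shared additive log10 shift of both population
  means, which leaves the ground-truth relative change donor-invariant;
* concentration-dependent staining for titration series, with positive
  median intensity following saturation binding conc/(conc + kd) and
  nonspecific background entering as a location-scale inflation of the
  negative component, linear in concentration;
* overdispersed (negative-binomial) ADT counts with an optional planted
  fraction of antibody-aggregate cells.

All generators are pure functions of (spec, seed): a single user seed is
combined with a stable per-sample key hash into independent substreams, so
outputs do not depend on generation order.

With the gate fixed on the undigested sample and ``r = 1``, digestion thins
the positive population binomially, so the expected percent positive of the
digested sample is ``(1 - c)`` times the undigested one and the expected
relative change approaches ``100 * c``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm

from .adt_qc import AdtMatrix
from .flow_model import (
    Activation,
    Condition,
    EventTable,
    Lineage,
    SampleMeta,
    ValidationError,
)

__all__ = [
    "MarkerSimSpec",
    "CohortSimSpec",
    "TruthTable",
    "AdtTruth",
    "simulate_sample",
    "simulate_digestion_pair",
    "simulate_cohort",
    "simulate_titration_series",
    "simulate_adt_counts",
]


def _substream(seed: int, *key_parts: object) -> np.random.Generator:
    """Independent generator for (seed, sample key); order-insensitive."""
    key = "|".join(str(p) for p in key_parts)
    digest = zlib.crc32(key.encode("utf-8")) & 0xFFFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF,
                                                         digest]))


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerSimSpec:
    """Generative parameters for one marker/clone.

    Locations and scales are on the log10-intensity scale.  The defaults
    describe a well-resolved marker: 30% positive cells with an 8-sd mode
    separation (2 log10 units at sd 0.25).
    """

    marker: str
    clone: str
    parent_lineage: Lineage = Lineage.LYMPHOID
    pos_fraction: float = 0.3
    neg_log_mean: float = 1.0
    neg_log_sd: float = 0.25
    pos_log_mean: float = 3.0
    pos_log_sd: float = 0.25
    cleavage_fraction: float = 0.0
    mfi_retention: float = 1.0
    requires_activation: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "parent_lineage",
                           Lineage.parse(self.parent_lineage))
        if not self.pos_log_mean > self.neg_log_mean:
            raise ValidationError("pos_log_mean must exceed neg_log_mean")
        if not (0.0 <= self.cleavage_fraction <= 1.0):
            raise ValidationError("cleavage_fraction must be in [0, 1]")
        if not (0.0 < self.mfi_retention <= 1.0):
            raise ValidationError("mfi_retention must be in (0, 1]")
        if not (0.0 <= self.pos_fraction <= 1.0):
            raise ValidationError("pos_fraction must be in [0, 1]")
        if min(self.neg_log_sd, self.pos_log_sd) <= 0:
            raise ValidationError("log sds must be positive")


@dataclass(frozen=True)
class CohortSimSpec:
    """A donors x replicates x markers digestion cohort.

    Defaults (3 donors x 3 replicates, 2e4 events per sample) sit inside
    the published design range of 2-4 donors and 2-18 replicates per clone.
    """

    markers: tuple[MarkerSimSpec, ...]
    n_donors: int = 3
    replicates_per_donor: int = 3
    n_events: int = 20_000
    donor_shift_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple(self.markers))
        if self.n_donors < 1 or self.n_events < 1:
            raise ValidationError("n_donors and n_events must be >= 1")
        if self.replicates_per_donor < 1:
            raise ValidationError("replicates_per_donor must be >= 1")


@dataclass(frozen=True)
class TruthTable:
    """Ground truth behind a simulated cohort.

    ``clone_truth`` has one row per (marker, clone) with the true cleavage
    fraction, the retention, and the expected relative change
    ``100 * (1 - (1 - c) * d(r))`` where ``d(r)`` is the fraction of
    retained positive cells still above a mid-separation gate.
    ``sample_labels`` maps sample_id to the per-event pre-digestion
    positive/negative labels.
    """

    clone_truth: pd.DataFrame
    sample_labels: dict[str, np.ndarray]


def expected_relative_change(spec: MarkerSimSpec) -> float:
    """Expected RC under the thinning-plus-retention digestion model."""
    gate = 0.5 * (spec.neg_log_mean + spec.pos_log_mean)
    p_above = norm.sf(gate, loc=spec.pos_log_mean, scale=spec.pos_log_sd)
    p_above_retained = norm.sf(
        gate, loc=spec.pos_log_mean + np.log10(spec.mfi_retention),
        scale=spec.pos_log_sd)
    d = p_above_retained / p_above if p_above > 0 else 0.0
    rc = 100.0 * (1.0 - (1.0 - spec.cleavage_fraction) * d)
    return float(min(rc, 100.0))


# ---------------------------------------------------------------------------
# Event-level generators
# ---------------------------------------------------------------------------

def _draw_events(
    spec: MarkerSimSpec,
    condition: Condition,
    n_events: int,
    donor_shift: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Log10 intensities and pre-digestion positive labels for one sample."""
    if condition is Condition.UNSTAINED:
        labels = np.zeros(n_events, dtype=bool)
    else:
        labels = rng.random(n_events) < spec.pos_fraction
    log_int = np.empty(n_events)
    neg = ~labels
    log_int[neg] = rng.normal(spec.neg_log_mean + donor_shift,
                              spec.neg_log_sd, size=int(neg.sum()))
    log_int[labels] = rng.normal(spec.pos_log_mean + donor_shift,
                                 spec.pos_log_sd, size=int(labels.sum()))
    if condition is Condition.DIGESTED:
        cleaved = labels & (rng.random(n_events) < spec.cleavage_fraction)
        log_int[cleaved] = rng.normal(spec.neg_log_mean + donor_shift,
                                      spec.neg_log_sd, size=int(cleaved.sum()))
        survivors = labels & ~cleaved
        log_int[survivors] += np.log10(spec.mfi_retention)
    return log_int, labels


def simulate_sample(
    spec: MarkerSimSpec,
    condition: Condition | str = Condition.UNDIGESTED,
    n_events: int = 20_000,
    donor_shift: float = 0.0,
    seed: int = 0,
    donor_id: str = "d1",
    replicate: int = 0,
    experiment_day: str = "day1",
    concentration: float | None = None,
) -> EventTable:
    """One simulated event table; deterministic given (spec, seed, keys)."""
    condition = Condition.parse(condition)
    rng = _substream(seed, spec.marker, spec.clone, donor_id, replicate,
                     condition.value)
    log_int, _ = _draw_events(spec, condition, n_events, donor_shift, rng)
    sample_id = (f"{spec.marker}_{spec.clone}_{donor_id}_r{replicate}_"
                 f"{condition.value}")
    meta = SampleMeta(
        donor_id=donor_id, marker=spec.marker, clone=spec.clone,
        condition=condition, parent_lineage=spec.parent_lineage,
        activation=(Activation.POLYCLONAL_48H if spec.requires_activation
                    else Activation.NONE),
        concentration=concentration, experiment_day=experiment_day,
    )
    return EventTable(sample_id=sample_id, channels=[spec.marker],
                      events=(10.0 ** log_int)[:, None], meta=meta)


def simulate_digestion_pair(
    spec: MarkerSimSpec,
    n_events: int = 20_000,
    donor_shift: float = 0.0,
    seed: int = 0,
    donor_id: str = "d1",
    replicate: int = 0,
    experiment_day: str = "day1",
) -> tuple[EventTable, EventTable]:
    """Matched undigested/digested tables sharing donor shift and metadata."""
    common = dict(n_events=n_events, donor_shift=donor_shift, seed=seed,
                  donor_id=donor_id, replicate=replicate,
                  experiment_day=experiment_day)
    undigested = simulate_sample(spec, Condition.UNDIGESTED, **common)
    digested = simulate_sample(spec, Condition.DIGESTED, **common)
    return undigested, digested


def simulate_cohort(
    spec: CohortSimSpec,
) -> tuple[list[EventTable], TruthTable]:
    """One undigested/digested pair per donor x replicate x marker."""
    tables: list[EventTable] = []
    sample_labels: dict[str, np.ndarray] = {}
    for d in range(spec.n_donors):
        donor_id = f"donor{d + 1}"
        donor_shift = float(
            _substream(spec.seed, "donor_shift", donor_id).normal(
                0.0, spec.donor_shift_sd))
        for rep in range(spec.replicates_per_donor):
            for mk in spec.markers:
                for condition in (Condition.UNDIGESTED, Condition.DIGESTED):
                    rng = _substream(spec.seed, mk.marker, mk.clone, donor_id,
                                     rep, condition.value)
                    log_int, labels = _draw_events(
                        mk, condition, spec.n_events, donor_shift, rng)
                    sample_id = (f"{mk.marker}_{mk.clone}_{donor_id}_r{rep}_"
                                 f"{condition.value}")
                    meta = SampleMeta(
                        donor_id=donor_id, marker=mk.marker, clone=mk.clone,
                        condition=condition, parent_lineage=mk.parent_lineage,
                        activation=(Activation.POLYCLONAL_48H
                                    if mk.requires_activation
                                    else Activation.NONE),
                        experiment_day=f"day{rep + 1}",
                    )
                    tables.append(EventTable(
                        sample_id=sample_id, channels=[mk.marker],
                        events=(10.0 ** log_int)[:, None], meta=meta))
                    sample_labels[sample_id] = labels
    clone_truth = pd.DataFrame([
        {
            "marker": mk.marker,
            "clone": mk.clone,
            "cleavage_fraction": mk.cleavage_fraction,
            "mfi_retention": mk.mfi_retention,
            "expected_rc": expected_relative_change(mk),
        }
        for mk in spec.markers
    ])
    return tables, TruthTable(clone_truth=clone_truth,
                              sample_labels=sample_labels)


# ---------------------------------------------------------------------------
# Titration series
# ---------------------------------------------------------------------------

def simulate_titration_series(
    spec: MarkerSimSpec,
    concentrations: Sequence[float],
    kd: float,
    background_slope: float = 0.0,
    n_events: int = 10_000,
    seed: int = 0,
    donor_id: str = "d1",
) -> tuple[list[EventTable], EventTable]:
    """Stained samples at three concentrations plus an unstained control.

    The positive-population median intensity follows saturation binding:
    its log10 location is shifted by log10(conc / (conc + kd)), floored at
    the negative mean (an unstained epitope is indistinguishable from
    background).  Nonspecific background raises the negative component's
    location and scale linearly in concentration.  The three stained
    samples share one set of base event draws (common random numbers), so
    concentration changes act as deterministic transforms — mirroring
    titration of aliquots of one cell preparation.
    """
    concentrations = [float(c) for c in concentrations]
    if len(concentrations) != 3:
        raise ValidationError("a titration series has exactly 3 concentrations")
    if not (concentrations[0] < concentrations[1] < concentrations[2]):
        raise ValidationError("concentrations must be strictly increasing")
    if kd <= 0 or background_slope < 0:
        raise ValidationError("kd must be positive, background_slope >= 0")

    rng = _substream(seed, spec.marker, spec.clone, donor_id, "titration")
    labels = rng.random(n_events) < spec.pos_fraction
    z_pos = rng.standard_normal(n_events)
    z_neg = rng.standard_normal(n_events)
    rng_unstained = _substream(seed, spec.marker, spec.clone, donor_id,
                               "unstained")

    stained: list[EventTable] = []
    for i, conc in enumerate(concentrations):
        occupancy = conc / (conc + kd)
        pos_mean = max(spec.neg_log_mean,
                       spec.pos_log_mean + np.log10(occupancy))
        inflation = background_slope * conc
        neg_mean = spec.neg_log_mean + 0.5 * inflation
        neg_sd = spec.neg_log_sd * (1.0 + inflation)
        log_int = np.where(labels,
                           pos_mean + spec.pos_log_sd * z_pos,
                           neg_mean + neg_sd * z_neg)
        meta = SampleMeta(
            donor_id=donor_id, marker=spec.marker, clone=spec.clone,
            condition=Condition.UNDIGESTED, parent_lineage=spec.parent_lineage,
            activation=(Activation.PMA_IONO_6H if spec.requires_activation
                        else Activation.NONE),
            concentration=conc,
        )
        stained.append(EventTable(
            sample_id=f"{spec.marker}_{donor_id}_titration{i + 1}",
            channels=[spec.marker], events=(10.0 ** log_int)[:, None],
            meta=meta))

    log_unstained = rng_unstained.normal(spec.neg_log_mean, spec.neg_log_sd,
                                         size=n_events)
    unstained = EventTable(
        sample_id=f"{spec.marker}_{donor_id}_unstained",
        channels=[spec.marker], events=(10.0 ** log_unstained)[:, None],
        meta=SampleMeta(
            donor_id=donor_id, marker=spec.marker, clone=spec.clone,
            condition=Condition.UNSTAINED,
            parent_lineage=spec.parent_lineage),
    )
    return stained, unstained


# ---------------------------------------------------------------------------
# ADT counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdtTruth:
    """Planted truth for a simulated ADT matrix: per-cell/antibody signal
    labels and the per-cell aggregate flags."""

    signal: np.ndarray          # bool, cells x antibodies
    aggregate: np.ndarray       # bool, cells


def _nb_counts(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Negative-binomial counts with variance mean + mean^2 / dispersion."""
    mean = np.asarray(mean, dtype=float)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate_adt_counts(
    n_cells: int,
    antibodies: Sequence[str],
    signal_cells_fraction: float = 0.3,
    background_mean: float = 2.0,
    signal_mean: float = 200.0,
    dispersion: float = 2.0,
    aggregate_fraction: float = 0.0,
    aggregate_inflation: float = 20.0,
    seed: int = 0,
) -> tuple[AdtMatrix, AdtTruth]:
    """Overdispersed ADT counts with planted signal cells and aggregates.

    Per antibody, a ``signal_cells_fraction`` of cells draw counts around
    ``signal_mean`` and the rest around ``background_mean``.  A fraction of
    cells are antibody aggregates whose count means are inflated
    ``aggregate_inflation``-fold across every antibody.
    """
    if min(background_mean, signal_mean) <= 0:
        raise ValidationError("count means must be positive")
    if not (0.0 <= aggregate_fraction < 1.0):
        raise ValidationError("aggregate_fraction must be in [0, 1)")
    antibodies = list(antibodies)
    rng = _substream(seed, "adt", n_cells, len(antibodies))

    aggregate = rng.random(n_cells) < aggregate_fraction
    signal = np.empty((n_cells, len(antibodies)), dtype=bool)
    counts = np.empty((n_cells, len(antibodies)), dtype=np.int64)
    for j, _ in enumerate(antibodies):
        is_signal = rng.random(n_cells) < signal_cells_fraction
        mean = np.where(is_signal, signal_mean, background_mean)
        mean = np.where(aggregate, mean * aggregate_inflation, mean)
        counts[:, j] = _nb_counts(rng, mean, dispersion)
        signal[:, j] = is_signal

    matrix = AdtMatrix(
        cells=[f"cell{i:05d}" for i in range(n_cells)],
        antibodies=antibodies,
        counts=sp.csr_matrix(counts),
    )
    return matrix, AdtTruth(signal=signal, aggregate=aggregate)
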