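"""Digestion-sensitivity scoring of antibody clones.

Implements the relative-change (RC) statistic for paired percent-positive
measurements,

    RC = 100 * (pct_undigested - pct_digested) / pct_undigested,

together with the replicate inclusion criteria, the replicate categorization
bands (RC >= 50 sensitive, 25 <= RC < 50 partially sensitive, otherwise
insensitive, with a special rule for rare populations at <= 5% undigested
positivity), the clone-level majority/tie classification, and cohort
summarization.  RC is at most 100 (complete loss of positive staining) and
unbounded below (staining can increase after digestion).

Boundary conventions: an RC of exactly 50 counts as sensitive, so the bands
are [50, 100] and [25, 50).  A clone category requires a strict majority
(> 50%) of included replicates; any split with no strict majority —
including the published 50/50 full/partial and partial/insensitive ties —
is called partially sensitive.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .flow_model import (
    ClassificationError,
    ConfigError,
    DataError,
    FixtureError,
    Lineage,
    PaperFixtures,
    Table2Row,
    UndefinedRCError,
    ValidationError,
)

__all__ = [
    "Category",
    "ExclusionReason",
    "ReplicateMeasurement",
    "ReplicateCall",
    "CloneCall",
    "SensitivityConfig",
    "CohortReport",
    "relative_change",
    "average_technical_repeats",
    "apply_inclusion_criteria",
    "classify_replicate",
    "classify_clone",
    "classify_fixture_clones",
    "summarize_cohort",
]


class Category(Enum):
    SENSITIVE = "sensitive"
    PARTIALLY_SENSITIVE = "partially_sensitive"
    INSENSITIVE = "insensitive"
    EXCLUDED = "excluded"


class ExclusionReason(Enum):
    TOO_FEW_DONORS = "too_few_donors"
    NO_POSITIVE_IN_UNDIGESTED = "no_positive_in_undigested"
    INSUFFICIENT_ACTIVATION = "insufficient_activation"
    NONE = "none"


@dataclass(frozen=True)
class ReplicateMeasurement:
    """Paired percent-positive values for one clone/donor/replicate.

    ``cd69_pct_activated`` carries the activation control for markers that
    require stimulation; ``mfi_*`` optionally carry mean channel intensities
    for the MFI-based RC variant.
    """

    marker: str
    clone: str
    donor_id: str
    experiment_day: str
    parent_lineage: Lineage
    pct_pos_undigested: float
    pct_pos_digested: float
    positive_detected_digested: bool = True
    activation_required: bool = False
    cd69_pct_activated: float | None = None
    is_totalseqc: bool = False
    mfi_undigested: float | None = None
    mfi_digested: float | None = None

    def __post_init__(self) -> None:
        for name in ("pct_pos_undigested", "pct_pos_digested"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValidationError(f"{name}={v} outside [0, 100]")


@dataclass(frozen=True)
class ReplicateCall:
    measurement: ReplicateMeasurement
    rc: float | None
    category: Category
    exclusion_reason: ExclusionReason = ExclusionReason.NONE
    rare_population_rule_applied: bool = False

    def __post_init__(self) -> None:
        excluded = self.category is Category.EXCLUDED
        if excluded != (self.exclusion_reason is not ExclusionReason.NONE):
            raise ValidationError(
                "category is excluded iff an exclusion reason is given"
            )
        if self.rc is not None and self.rc > 100.0 + 1e-9:
            raise ValidationError("relative change cannot exceed 100")


@dataclass(frozen=True)
class CloneCall:
    marker: str
    clone: str
    is_totalseqc: bool
    n_donors: int
    n_replicates_included: int
    prop_sensitive: float
    prop_partial: float
    prop_insensitive: float
    category: Category

    def __post_init__(self) -> None:
        if self.n_replicates_included < 1:
            raise ValidationError("a clone call needs >= 1 included replicate")
        total = self.prop_sensitive + self.prop_partial + self.prop_insensitive
        if abs(total - 100.0) > 1.0:
            raise ValidationError(f"category proportions sum to {total}")


@dataclass(frozen=True)
class SensitivityConfig:
    """Thresholds of the replicate/clone classification rules.

    ``cd69_min_pct`` mechanizes "sufficient activation signal" for
    activation-dependent markers; the published criterion is visual, so the
    cut-off is exposed here rather than fixed.  ``use_mfi`` switches RC to
    the mean-fluorescence-intensity variant; the percent-positive definition
    is normative and remains the default.
    """

    rc_sensitive_min: float = 50.0
    rc_partial_min: float = 25.0
    rare_population_pct: float = 5.0
    min_donors: int = 2
    cd69_min_pct: float = 20.0
    use_mfi: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.rc_partial_min < self.rc_sensitive_min <= 100.0):
            raise ConfigError(
                "require 0 < rc_partial_min < rc_sensitive_min <= 100"
            )
        if self.min_donors < 1:
            raise ConfigError("min_donors must be >= 1")


# ---------------------------------------------------------------------------
# Replicate-level operations
# ---------------------------------------------------------------------------

def relative_change(pct_undig: float, pct_dig: float) -> float:
    """Relative change of positive staining, as a percentage.

    Defined only for a non-zero undigested percentage; callers must have
    excluded zero-positivity replicates beforehand.
    """
    if pct_undig <= 0.0:
        raise UndefinedRCError(
            "relative change undefined for zero undigested positivity"
        )
    # Formulated so the upper bound is exact: pct_dig = 0 gives exactly 100.
    return 100.0 * (1.0 - pct_dig / pct_undig)


def average_technical_repeats(
    measurements: Sequence[ReplicateMeasurement],
) -> list[ReplicateMeasurement]:
    """Collapse same-day repeats of one clone/marker/donor to mean values.

    Measurements sharing (clone, marker, donor, experiment day) — e.g.
    repeat readings from different staining panels run on the same day —
    are averaged into a single replicate; detectability is the logical OR of
    the group.  All other measurements pass through unchanged, preserving
    first-occurrence order.
    """
    groups: dict[tuple, list[ReplicateMeasurement]] = {}
    for m in measurements:
        key = (m.clone, m.marker, m.donor_id, m.experiment_day)
        groups.setdefault(key, []).append(m)

    out: list[ReplicateMeasurement] = []
    for group in groups.values():
        if len(group) == 1:
            out.append(group[0])
            continue
        first = group[0]
        cd69 = [m.cd69_pct_activated for m in group
                if m.cd69_pct_activated is not None]
        mfi_u = [m.mfi_undigested for m in group if m.mfi_undigested is not None]
        mfi_d = [m.mfi_digested for m in group if m.mfi_digested is not None]
        out.append(replace(
            first,
            pct_pos_undigested=float(np.mean(
                [m.pct_pos_undigested for m in group])),
            pct_pos_digested=float(np.mean(
                [m.pct_pos_digested for m in group])),
            positive_detected_digested=any(
                m.positive_detected_digested for m in group),
            activation_required=any(m.activation_required for m in group),
            cd69_pct_activated=float(np.mean(cd69)) if cd69 else None,
            mfi_undigested=float(np.mean(mfi_u)) if mfi_u else None,
            mfi_digested=float(np.mean(mfi_d)) if mfi_d else None,
        ))
    return out


def classify_replicate(
    measurement: ReplicateMeasurement,
    config: SensitivityConfig | None = None,
) -> ReplicateCall:
    """Categorize one included replicate by its relative change.

    Replicates with at most ``rare_population_pct`` undigested positivity
    are scored by visibility of the digested positive population instead of
    by RC (the RC formula inflates for rare populations): visible positive
    population -> insensitive, none -> sensitive.  RC is still recorded.
    """
    config = config or SensitivityConfig()
    m = measurement
    if config.use_mfi:
        if m.mfi_undigested is None or m.mfi_digested is None:
            raise DataError(
                f"{m.clone}/{m.donor_id}: MFI variant requested but MFI absent"
            )
        rc = relative_change(m.mfi_undigested, m.mfi_digested)
    else:
        rc = relative_change(m.pct_pos_undigested, m.pct_pos_digested)

    if m.pct_pos_undigested <= config.rare_population_pct:
        category = (Category.INSENSITIVE if m.positive_detected_digested
                    else Category.SENSITIVE)
        return ReplicateCall(measurement=m, rc=rc, category=category,
                             rare_population_rule_applied=True)
    if rc >= config.rc_sensitive_min:
        category = Category.SENSITIVE
    elif rc >= config.rc_partial_min:
        category = Category.PARTIALLY_SENSITIVE
    else:
        category = Category.INSENSITIVE
    return ReplicateCall(measurement=m, rc=rc, category=category)


def apply_inclusion_criteria(
    measurements: Sequence[ReplicateMeasurement],
    config: SensitivityConfig | None = None,
) -> list[ReplicateCall]:
    """Apply the a-priori inclusion criteria and classify survivors.

    A clone is excluded entirely when it was measured in fewer than
    ``min_donors`` distinct donors; a replicate is excluded when the
    undigested sample shows no positive cells, or (for activation-dependent
    markers) when the CD69 activation control falls below ``cd69_min_pct``.
    """
    config = config or SensitivityConfig()
    donors_per_clone: dict[tuple[str, str], set[str]] = {}
    for m in measurements:
        donors_per_clone.setdefault((m.marker, m.clone), set()).add(m.donor_id)

    calls: list[ReplicateCall] = []
    for m in measurements:
        if len(donors_per_clone[(m.marker, m.clone)]) < config.min_donors:
            calls.append(ReplicateCall(
                measurement=m, rc=None, category=Category.EXCLUDED,
                exclusion_reason=ExclusionReason.TOO_FEW_DONORS))
            continue
        if m.activation_required:
            if m.cd69_pct_activated is None:
                raise DataError(
                    f"{m.clone}/{m.donor_id}: activation-dependent marker "
                    "without a CD69 activation measurement"
                )
            if m.cd69_pct_activated < config.cd69_min_pct:
                calls.append(ReplicateCall(
                    measurement=m, rc=None, category=Category.EXCLUDED,
                    exclusion_reason=ExclusionReason.INSUFFICIENT_ACTIVATION))
                continue
        if m.pct_pos_undigested <= 0.0:
            calls.append(ReplicateCall(
                measurement=m, rc=None, category=Category.EXCLUDED,
                exclusion_reason=ExclusionReason.NO_POSITIVE_IN_UNDIGESTED))
            continue
        calls.append(classify_replicate(m, config))
    return calls


# ---------------------------------------------------------------------------
# Clone-level classification
# ---------------------------------------------------------------------------

def _category_from_counts(n_sens: int, n_part: int, n_insens: int) -> Category:
    """Majority/tie rule over replicate category counts.

    Strict majority (> 50% of included replicates) wins; any split without
    a strict majority is partially sensitive.
    """
    total = n_sens + n_part + n_insens
    if total < 1:
        raise ClassificationError("no included replicates to classify")
    if 2 * n_sens > total:
        return Category.SENSITIVE
    if 2 * n_insens > total:
        return Category.INSENSITIVE
    if 2 * n_part > total:
        return Category.PARTIALLY_SENSITIVE
    return Category.PARTIALLY_SENSITIVE


def classify_clone(
    calls: Sequence[ReplicateCall],
    config: SensitivityConfig | None = None,
) -> CloneCall:
    """Aggregate replicate calls for one clone into a clone-level category.

    Excluded replicates never enter the proportions.  The order of
    ``calls`` is irrelevant.
    """
    included = [c for c in calls if c.category is not Category.EXCLUDED]
    if not included:
        raise ClassificationError("no included replicates for this clone")
    markers = {(c.measurement.marker, c.measurement.clone) for c in calls}
    if len(markers) != 1:
        raise ClassificationError(
            f"classify_clone received calls for multiple clones: {markers}"
        )
    counts = Counter(c.category for c in included)
    n = len(included)
    n_sens = counts.get(Category.SENSITIVE, 0)
    n_part = counts.get(Category.PARTIALLY_SENSITIVE, 0)
    n_insens = counts.get(Category.INSENSITIVE, 0)
    marker, clone = next(iter(markers))
    return CloneCall(
        marker=marker,
        clone=clone,
        is_totalseqc=any(c.measurement.is_totalseqc for c in included),
        n_donors=len({c.measurement.donor_id for c in included}),
        n_replicates_included=n,
        prop_sensitive=100.0 * n_sens / n,
        prop_partial=100.0 * n_part / n,
        prop_insensitive=100.0 * n_insens / n,
        category=_category_from_counts(n_sens, n_part, n_insens),
    )


def classify_fixture_clones(
    table2: Sequence[Table2Row],
    config: SensitivityConfig | None = None,
) -> list[CloneCall]:
    """Run the clone-level classifier on the bundled sensitivity table.

    The published table reports integer category percentages and the number
    of included replicates; the per-replicate category counts are recovered
    as round(pct * n / 100) and fed through the same majority/tie rule used
    for raw data.
    """
    out: list[CloneCall] = []
    for row in table2:
        n = row.n_replicates
        k_sens = round(row.pct_sensitive * n / 100.0)
        k_part = round(row.pct_partial * n / 100.0)
        k_insens = round(row.pct_not * n / 100.0)
        if k_sens + k_part + k_insens != n:
            raise FixtureError(
                f"clone {row.clone}: percentages do not resolve to "
                f"{n} replicate counts"
            )
        out.append(CloneCall(
            marker=row.marker,
            clone=row.clone,
            is_totalseqc=row.is_totalseqc,
            n_donors=row.n_donors,
            n_replicates_included=n,
            prop_sensitive=100.0 * k_sens / n,
            prop_partial=100.0 * k_part / n,
            prop_insensitive=100.0 * k_insens / n,
            category=_category_from_counts(k_sens, k_part, k_insens),
        ))
    return out


# ---------------------------------------------------------------------------
# Cohort summarization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortReport:
    """Cohort-level outputs: per-clone table, replicate aggregates, clone
    category counts (overall and TotalSeq-C-restricted), and optional
    lineage-grouping counts."""

    clone_table: pd.DataFrame
    replicate_summary: dict
    clone_counts: dict
    clone_counts_totalseqc: dict
    lineage_counts: pd.DataFrame


def summarize_cohort(
    clone_calls: Sequence[CloneCall],
    replicate_calls: Sequence[ReplicateCall] = (),
    marker_lineages: Mapping[str, frozenset[str]] | None = None,
) -> CohortReport:
    """Aggregate clone and replicate calls into the standard report.

    ``marker_lineages`` optionally maps each marker to the set of immune
    lineages expressing it (e.g. {"T", "NK/ILC", "monocyte"}); when given,
    clone counts per exclusive lineage intersection are tabulated.
    """
    clone_table = pd.DataFrame([
        {
            "marker": c.marker,
            "clone": c.clone,
            "is_totalseqc": c.is_totalseqc,
            "n_donors": c.n_donors,
            "n_replicates": c.n_replicates_included,
            "pct_sensitive": round(c.prop_sensitive),
            "pct_partial": round(c.prop_partial),
            "pct_not": round(c.prop_insensitive),
            "category": c.category.value,
        }
        for c in clone_calls
    ])

    included = [c for c in replicate_calls if c.category is not Category.EXCLUDED]
    rcs = np.array([c.rc for c in included if c.rc is not None], dtype=float)
    cat_counts = Counter(c.category.value for c in included)
    replicate_summary = {
        "n_total": len(replicate_calls),
        "n_included": len(included),
        "n_excluded": len(replicate_calls) - len(included),
        "category_counts": dict(cat_counts),
        "category_proportions": {
            k: v / len(included) for k, v in cat_counts.items()
        } if included else {},
        "median_rc": float(np.median(rcs)) if rcs.size else None,
        "iqr_rc": (
            (float(np.percentile(rcs, 25)), float(np.percentile(rcs, 75)))
            if rcs.size else None),
        "min_rc": float(rcs.min()) if rcs.size else None,
        "max_rc": float(rcs.max()) if rcs.size else None,
    }

    clone_counts = dict(Counter(c.category.value for c in clone_calls))
    clone_counts_totalseqc = dict(Counter(
        c.category.value for c in clone_calls if c.is_totalseqc))

    if marker_lineages:
        rows = []
        groupings: dict[frozenset, list[CloneCall]] = {}
        for c in clone_calls:
            group = frozenset(marker_lineages.get(c.marker, frozenset()))
            groupings.setdefault(group, []).append(c)
        for group, members in sorted(
                groupings.items(), key=lambda kv: sorted(kv[0])):
            by_cat = Counter(m.category.value for m in members)
            rows.append({
                "lineages": "+".join(sorted(group)) if group else "unassigned",
                "n_clones": len(members),
                **{f"n_{cat.value}": by_cat.get(cat.value, 0)
                   for cat in (Category.SENSITIVE,
                               Category.PARTIALLY_SENSITIVE,
                               Category.INSENSITIVE)},
            })
        lineage_counts = pd.DataFrame(rows)
    else:
        lineage_counts = pd.DataFrame(
            columns=["lineages", "n_clones", "n_sensitive",
                     "n_partially_sensitive", "n_insensitive"])

    return CohortReport(
        clone_table=clone_table,
        replicate_summary=replicate_summary,
        clone_counts=clone_counts,
        clone_counts_totalseqc=clone_counts_totalseqc,
        lineage_counts=lineage_counts,
    )
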