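"""Interaction scoring, bootstrap confidence intervals and sign consistency.

The deviation of a measured cocktail from Bliss independence is scored as

    I = ln(1 + g_observed - prod(g_singles))

in natural-log units: I < 0 means synergy (more killing than independent
action), I > 0 antagonism.  Significance comes from a percentile bootstrap
over biological repeats: per-repeat scores are resampled with replacement,
and the 5th/95th percentiles of the resample means form the confidence
interval.  A cocktail is called antagonistic when I > 0 and the 5th
percentile is > 0, synergistic when I < 0 and the 95th percentile is < 0,
and additive otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .datamodel import Cocktail, CombinationDataset, ViabilityRecord
from .exceptions import DomainError, ValidationError

ANTAGONISTIC = "antagonistic"
SYNERGISTIC = "synergistic"
ADDITIVE = "additive"

DEFAULT_N_BOOT = 10_000
MIN_N_BOOT = 1_000


def interaction_score(g_combo: float, singles: Mapping[str, float] | Sequence[float]) -> float:
    """``I = ln(1 + g_combo - prod(singles))``; negative = synergy.

    Raises :class:`DomainError` when the log argument is non-positive (an
    extreme synergy beyond what the score can represent).
    """
    values = list(singles.values()) if isinstance(singles, Mapping) else list(singles)
    bliss = math.prod(float(v) for v in values)
    arg = 1.0 + float(g_combo) - bliss
    if arg <= 0:
        raise DomainError(
            f"interaction score undefined: 1 + g - Bliss = {arg:.6g} <= 0 "
            f"(g={g_combo}, Bliss product={bliss:.6g})"
        )
    return math.log(arg)


def classify(I: float, ci_low: float, ci_high: float) -> str:
    """Three-way synergy call from the point estimate and its 5%/95% bounds."""
    if ci_low > ci_high:
        raise ValidationError(f"ci_low {ci_low} > ci_high {ci_high}")
    if I > 0 and ci_low > 0:
        return ANTAGONISTIC
    if I < 0 and ci_high < 0:
        return SYNERGISTIC
    return ADDITIVE


@dataclass(frozen=True)
class InteractionResult:
    """Interaction score with percentile-bootstrap CI and synergy call."""

    cell_line: str
    cocktail: Cocktail
    I: float
    ci_low: float
    ci_high: float
    label: str
    n_repeats: int
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValidationError("ci_low > ci_high")


def bootstrap_interaction(
    combo_repeats: Sequence[float],
    single_means: Mapping[str, float],
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    cocktail: Cocktail | None = None,
    cell_line: str = "",
) -> InteractionResult:
    """Percentile bootstrap of the interaction score over biological repeats.

    Per-repeat scores ``I_r = ln(1 + g_r - prod(single_means))`` are resampled
    with replacement ``n_boot`` times; the reported I is the mean of the
    resample means and the CI their 5th/95th percentiles.  Singles enter as
    fixed means (they are not jointly resampled).  Any repeat with a
    non-positive log argument makes the score undefined and raises before
    resampling — repeats are never dropped silently.
    """
    repeats = [float(g) for g in combo_repeats]
    if len(repeats) < 2:
        raise ValidationError(f"bootstrap requires >= 2 repeats, got {len(repeats)}")
    if n_boot < MIN_N_BOOT:
        raise ValidationError(f"n_boot must be >= {MIN_N_BOOT}, got {n_boot}")
    scores = np.array([interaction_score(g, single_means) for g in repeats])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(scores), size=(n_boot, len(scores)))
    boot_means = scores[idx].mean(axis=1)
    I = float(boot_means.mean())
    ci_low, ci_high = (float(q) for q in np.percentile(boot_means, [5.0, 95.0]))
    if cocktail is None:
        cocktail = Cocktail(tuple(single_means))
    return InteractionResult(
        cell_line=cell_line,
        cocktail=cocktail,
        I=I,
        ci_low=ci_low,
        ci_high=ci_high,
        label=classify(I, ci_low, ci_high),
        n_repeats=len(repeats),
        n_boot=n_boot,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Pair consistency (does a cocktail's synergy sign match any of its pairs?)
# ---------------------------------------------------------------------------


@dataclass
class ConsistencySummary:
    """Counts of significant cocktails (order >= 3) whose sign is echoed by a pair.

    ``exceptions`` lists the significant cocktails containing no
    significantly same-signed pair — candidates for true third-or-higher-order
    interactions.
    """

    cell_line: str
    n_antagonistic: int = 0
    n_antagonistic_with_antagonistic_pair: int = 0
    n_synergistic: int = 0
    n_synergistic_with_synergistic_pair: int = 0
    exceptions: list[str] = field(default_factory=list)


def label_record(
    record: ViabilityRecord,
    singles: Mapping[str, float],
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> str:
    """Synergy call for one record.

    Prefers the record's stored interaction score and CI bounds (as carried
    from a published table); falls back to bootstrapping its repeats when
    those are absent.  Records with neither are called additive by default
    (no evidence of interaction).
    """
    if record.interaction is not None and record.ci_low is not None:
        return classify(record.interaction, record.ci_low, record.ci_high)
    if record.repeats is not None and len(record.repeats) >= 2:
        result = bootstrap_interaction(
            record.repeats,
            {d: singles[d] for d in record.cocktail.drugs},
            n_boot=n_boot,
            seed=seed,
            cocktail=record.cocktail,
            cell_line=record.cell_line,
        )
        return result.label
    return ADDITIVE


def pair_consistency_summary(
    dataset: CombinationDataset,
    cell_line: str,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> ConsistencySummary:
    """Compare each significant cocktail's sign with its constituent pairs.

    Every cocktail of order >= 3 and every pair is classified via
    :func:`classify` (from stored CI columns, or bootstrapped repeats when
    available).  For each significantly antagonistic (synergistic) cocktail,
    counts whether at least one constituent pair is significantly
    antagonistic (synergistic); cocktails matching none of their measured
    pairs are listed as exceptions.
    """
    if cell_line not in dataset.cell_lines():
        raise ValidationError(f"unknown cell line {cell_line!r}")
    singles = dataset.singles_map(cell_line)
    pair_labels: dict[str, str] = {}
    for r in dataset:
        if r.cell_line == cell_line and r.order == 2:
            pair_labels[r.cocktail.name] = label_record(r, singles, n_boot, seed)

    summary = ConsistencySummary(cell_line=cell_line)
    for r in sorted(dataset, key=lambda r: (r.order, r.cocktail.name)):
        if r.cell_line != cell_line or r.order < 3:
            continue
        label = label_record(r, singles, n_boot, seed)
        if label == ADDITIVE:
            continue
        pair_signs = [
            pair_labels.get(p.name, ADDITIVE) for p in r.cocktail.pairs()
        ]
        has_match = label in pair_signs
        if label == ANTAGONISTIC:
            summary.n_antagonistic += 1
            summary.n_antagonistic_with_antagonistic_pair += has_match
        else:
            summary.n_synergistic += 1
            summary.n_synergistic_with_synergistic_pair += has_match
        if not has_match:
            summary.exceptions.append(r.cocktail.name)
    return summary
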