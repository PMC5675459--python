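"""Cocktail-effect prediction formulas.

All formulas predict the viability of an M-drug cocktail from single-drug
and/or pair viabilities measured at the same fixed doses:

* **Bliss independence** — ``g = prod(g_i)``: drugs act independently.
* **Pairs model** — ``g = prod(g_ij) ** (1/(M-1))``: the product of all
  M(M-1)/2 pair viabilities raised to 1/(M-1); uses pair data only.
* **Regression** — ``g = prod(g_ij) / prod(g_i) ** (M-2)``: the log-linear
  machine-learning estimate; for triplets ``g12*g23*g13/(g1*g2*g3)``.
* **Isserlis** — maximum-entropy pairing formula, defined for M = 3 and 4
  only (triplet: ``g1*g23 + g2*g13 + g3*g12 - 2*g1*g2*g3``).
* **Log-linear family** — ``g = prod(g_ij)**alpha * prod(g_i)**beta`` with
  ``beta = 1 - (M-1)*alpha``, which interpolates Bliss (alpha=0), the pairs
  model (alpha=1/(M-1), beta=0) and regression (alpha=1).

The beta constraint makes every family member *Bliss-conserving*: if every
pair is itself Bliss-consistent (``g_ij = g_i*g_j``), the prediction reduces
to the plain product of singles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .datamodel import Cocktail, CombinationDataset
from .exceptions import (
    DegenerateInputError,
    MissingInputError,
    UnsupportedOrderError,
    ValidationError,
)

#: Families accepted by :class:`ModelSpec`.
FAMILIES = ("bliss", "pairs", "regression", "isserlis", "loglinear")

#: Single-drug viabilities at or below this floor make formulas with negative
#: exponents blow up; such inputs raise rather than being silently clamped.
EPSILON = 1e-9


@dataclass(frozen=True)
class ModelSpec:
    """Which prediction formula to use.

    ``alpha`` is meaningful only for the ``loglinear`` family; the named
    families fix it implicitly (Bliss: 0, regression: 1, pairs: 1/(M-1)).
    ``beta`` is always derived as ``1 - (M-1)*alpha`` at prediction time.
    """

    family: str
    alpha: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown model family {self.family!r}; expected one of {FAMILIES}")
        if self.family == "loglinear" and self.alpha is None:
            raise ValidationError("loglinear family requires an explicit alpha")
        if self.family != "loglinear" and self.alpha is not None:
            raise ValidationError(f"alpha is only meaningful for loglinear, not {self.family!r}")

    def alpha_for_order(self, order: int) -> float:
        """The effective pair exponent alpha for an M-drug cocktail."""
        if self.family == "bliss":
            return 0.0
        if self.family == "regression":
            return 1.0
        if self.family == "pairs":
            if order < 2:
                raise UnsupportedOrderError("pairs model requires M >= 2")
            return 1.0 / (order - 1)
        if self.family == "loglinear":
            return float(self.alpha)  # type: ignore[arg-type]
        raise UnsupportedOrderError("isserlis is not a log-linear family member")

    def beta_for_order(self, order: int) -> float:
        """The single-drug exponent beta = 1 - (M-1)*alpha."""
        return 1.0 - (order - 1) * self.alpha_for_order(order)

    @property
    def label(self) -> str:
        if self.family == "loglinear":
            return f"loglinear(alpha={self.alpha:g})"
        return self.family


@dataclass(frozen=True)
class Prediction:
    """A predicted cocktail viability and the measurements it consumed."""

    cell_line: str
    cocktail: Cocktail
    value: float
    model: ModelSpec
    inputs_used: tuple[str, ...] = ()
    clamped: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.value) or self.value < 0:
            raise ValidationError(
                f"{self.cocktail}: predicted viability must be finite and >= 0, got {self.value!r}"
            )


def _lookup_singles(singles: Mapping[str, float], cocktail: Cocktail) -> list[float]:
    missing = [d for d in cocktail.drugs if d not in singles]
    if missing:
        raise MissingInputError(
            f"{cocktail}: missing single-drug viability for {', '.join(missing)}",
            missing=tuple(missing),
        )
    return [float(singles[d]) for d in cocktail.drugs]


def _lookup_pairs(pairs: Mapping, cocktail: Cocktail) -> list[float]:
    # accept Cocktail keys or "A+B" string keys
    table = {
        (k.name if isinstance(k, Cocktail) else Cocktail.parse(k).name): float(v)
        for k, v in pairs.items()
    }
    wanted = cocktail.pairs()
    missing = [p.name for p in wanted if p.name not in table]
    if missing:
        raise MissingInputError(
            f"{cocktail}: missing pair viability for {', '.join(missing)}",
            missing=tuple(missing),
        )
    values = [table[p.name] for p in wanted]
    if any(v < 0 for v in values):
        raise ValidationError(f"{cocktail}: pair viabilities must be >= 0")
    return values


def predict_bliss(
    singles: Mapping[str, float], cocktail: Cocktail, cell_line: str = ""
) -> Prediction:
    """Bliss independence: the product of the M single-drug viabilities."""
    values = _lookup_singles(singles, cocktail)
    return Prediction(
        cell_line=cell_line,
        cocktail=cocktail,
        value=math.prod(values),
        model=ModelSpec("bliss"),
        inputs_used=tuple(cocktail.drugs),
    )


def predict_pairs(
    pairs: Mapping, cocktail: Cocktail, cell_line: str = ""
) -> Prediction:
    """Pairs model: ``(prod of all pair viabilities) ** (1/(M-1))``.

    For M=2 this returns the measured pair itself.
    """
    if cocktail.order < 2:
        raise UnsupportedOrderError(f"pairs model requires M >= 2, got M={cocktail.order}")
    values = _lookup_pairs(pairs, cocktail)
    value = math.prod(values) ** (1.0 / (cocktail.order - 1))
    return Prediction(
        cell_line=cell_line,
        cocktail=cocktail,
        value=value,
        model=ModelSpec("pairs"),
        inputs_used=tuple(p.name for p in cocktail.pairs()),
    )


def _check_singles_positive(values: Sequence[float], cocktail: Cocktail) -> None:
    if any(v <= EPSILON for v in values):
        bad = [d for d, v in zip(cocktail.drugs, values) if v <= EPSILON]
        raise DegenerateInputError(
            f"{cocktail}: single-drug viability <= {EPSILON} for {', '.join(bad)}; "
            "a negative exponent would blow up"
        )


def predict_regression(
    singles: Mapping[str, float], pairs: Mapping, cocktail: Cocktail, cell_line: str = ""
) -> Prediction:
    """Regression formula: ``prod(pairs) / prod(singles) ** (M-2)`` (M >= 3)."""
    if cocktail.order < 3:
        raise UnsupportedOrderError(f"regression formula requires M >= 3, got M={cocktail.order}")
    s = _lookup_singles(singles, cocktail)
    _check_singles_positive(s, cocktail)
    p = _lookup_pairs(pairs, cocktail)
    value = math.prod(p) * math.prod(s) ** (-(cocktail.order - 2))
    return Prediction(
        cell_line=cell_line,
        cocktail=cocktail,
        value=value,
        model=ModelSpec("regression"),
        inputs_used=tuple(cocktail.drugs) + tuple(q.name for q in cocktail.pairs()),
    )


def predict_isserlis(
    singles: Mapping[str, float], pairs: Mapping, cocktail: Cocktail, cell_line: str = ""
) -> Prediction:
    """Maximum-entropy (Isserlis) formula for M in {3, 4}.

    Triplet: ``g1*g23 + g2*g13 + g3*g12 - 2*g1*g2*g3``.
    Quadruplet: ``g12*g34 + g13*g24 + g14*g23 - 2*g1*g2*g3*g4`` (the sum over
    the three perfect pairings).  The formula is not positivity-preserving;
    negative outputs are clamped to 0 with ``clamped=True`` recorded.
    """
    M = cocktail.order
    if M not in (3, 4):
        raise UnsupportedOrderError(f"isserlis formula is defined for M in {{3, 4}}, got M={M}")
    s = _lookup_singles(singles, cocktail)
    ptable = {
        p.name: v for p, v in zip(cocktail.pairs(), _lookup_pairs(pairs, cocktail))
    }
    d = cocktail.drugs

    def g(i: int, j: int) -> float:
        return ptable[Cocktail((d[i], d[j])).name]

    if M == 3:
        raw = s[0] * g(1, 2) + s[1] * g(0, 2) + s[2] * g(0, 1) - 2 * math.prod(s)
    else:
        raw = g(0, 1) * g(2, 3) + g(0, 2) * g(1, 3) + g(0, 3) * g(1, 2) - 2 * math.prod(s)
    clamped = raw < 0
    return Prediction(
        cell_line=cell_line,
        cocktail=cocktail,
        value=max(raw, 0.0),
        model=ModelSpec("isserlis"),
        inputs_used=tuple(cocktail.drugs) + tuple(q.name for q in cocktail.pairs()),
        clamped=clamped,
    )


def predict_loglinear(
    singles: Mapping[str, float],
    pairs: Mapping,
    cocktail: Cocktail,
    alpha: float,
    cell_line: str = "",
) -> Prediction:
    """Log-linear family: ``prod(pairs)**alpha * prod(singles)**beta``.

    ``beta = 1 - (M-1)*alpha`` preserves Bliss conservation.  Singles are only
    consumed (and required positive) when beta != 0, so the pairs-model member
    alpha = 1/(M-1) tolerates missing or zero singles.
    """
    M = cocktail.order
    if M < 2:
        raise UnsupportedOrderError(f"loglinear family requires M >= 2, got M={M}")
    beta = 1.0 - (M - 1) * alpha
    p = _lookup_pairs(pairs, cocktail)
    if alpha < 0 and any(v == 0 for v in p):
        raise DegenerateInputError(f"{cocktail}: zero pair viability with negative alpha")
    pair_part = math.prod(v**alpha for v in p) if alpha != 0 else 1.0
    inputs = tuple(q.name for q in cocktail.pairs())
    if beta != 0:
        s = _lookup_singles(singles, cocktail)
        if beta < 0:
            _check_singles_positive(s, cocktail)
        single_part = math.prod(v**beta for v in s)
        inputs = tuple(cocktail.drugs) + inputs
    else:
        single_part = 1.0
    return Prediction(
        cell_line=cell_line,
        cocktail=cocktail,
        value=pair_part * single_part,
        model=ModelSpec("loglinear", alpha=alpha),
        inputs_used=inputs,
    )


def predict(
    model: ModelSpec,
    singles: Mapping[str, float],
    pairs: Mapping,
    cocktail: Cocktail,
    cell_line: str = "",
) -> Prediction:
    """Dispatch to the family-specific prediction function."""
    if model.family == "bliss":
        return predict_bliss(singles, cocktail, cell_line)
    if model.family == "pairs":
        return predict_pairs(pairs, cocktail, cell_line)
    if model.family == "regression":
        return predict_regression(singles, pairs, cocktail, cell_line)
    if model.family == "isserlis":
        return predict_isserlis(singles, pairs, cocktail, cell_line)
    return predict_loglinear(singles, pairs, cocktail, float(model.alpha), cell_line)


@dataclass
class SkippedCocktail:
    """A cocktail left unpredicted, with the reason (missing inputs, order...)."""

    cell_line: str
    cocktail: Cocktail
    reason: str


@dataclass
class DatasetPredictions:
    """Predictions for one cell line of a dataset, plus the skip list."""

    predictions: list[Prediction] = field(default_factory=list)
    skipped: list[SkippedCocktail] = field(default_factory=list)

    def __iter__(self):
        return iter(self.predictions)

    def __len__(self) -> int:
        return len(self.predictions)


def predict_dataset(
    dataset: CombinationDataset,
    cell_line: str,
    model: ModelSpec,
    min_order: int = 3,
    max_order: int | None = None,
) -> DatasetPredictions:
    """Predict every cocktail of order >= ``min_order`` appearing in the dataset.

    Cocktails are taken from the union over cell lines (so a cocktail excluded
    from one cell line's measurements is still predicted for it when its
    inputs exist); those whose required inputs are missing for ``cell_line``
    — or outside a formula's order range — land in the skip list with a
    reason.  The default ``min_order=3`` excludes the pairs themselves, which
    are model *inputs*: evaluating them would trivially inflate any fit.
    """
    if len(dataset) and cell_line not in dataset.cell_lines():
        raise ValidationError(
            f"unknown cell line {cell_line!r}; dataset has {dataset.cell_lines()}"
        )
    singles = dataset.singles_map(cell_line)
    pairs = dataset.pairs_map(cell_line)
    out = DatasetPredictions()
    for cocktail in dataset.cocktails():
        if cocktail.order < min_order:
            continue
        if max_order is not None and cocktail.order > max_order:
            continue
        try:
            out.predictions.append(predict(model, singles, pairs, cocktail, cell_line))
        except (MissingInputError, UnsupportedOrderError, DegenerateInputError) as err:
            out.skipped.append(SkippedCocktail(cell_line, cocktail, str(err)))
    return out
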