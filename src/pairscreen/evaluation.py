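"""Model-fit metrics, the alpha scan, ranking accuracy and noise amplification.

Model quality is measured by the coefficient of determination

    R^2 = 1 - sum((y_i - f_i)^2) / sum((y_i - mean(y))^2)

over observed cocktail viabilities y and predictions f; R^2 is not clipped
at 0, so badly mis-scaled models show meaningfully negative values.

The *alpha scan* evaluates the log-linear family over a grid of the pair
exponent alpha (with beta = 1 - (M-1)*alpha) and reports the argmax — a
screen with only pairwise structure peaks near alpha = 1/(M-1), the pairs
model.

The *noise amplification factor* of a model is the standard deviation of its
log prediction in multiples of the per-measurement log-scale noise sigma,
under independent multiplicative errors on every input measurement.  Closed
forms for the log-linear family follow from summing independent Gaussian
exponents; a Monte-Carlo estimator cross-checks them by actually perturbing
the inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .datamodel import CombinationDataset
from .exceptions import UnsupportedOrderError, ValidationError
from .models import ModelSpec, SkippedCocktail, predict_dataset


# ---------------------------------------------------------------------------
# R^2 and dataset-level model evaluation
# ---------------------------------------------------------------------------


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination 1 - SSres/SStot (may be negative)."""
    y = np.asarray(observed, dtype=float)
    f = np.asarray(predicted, dtype=float)
    if y.shape != f.shape or y.ndim != 1 or y.size == 0:
        raise ValidationError(
            f"observed and predicted must be equal-length non-empty vectors, "
            f"got {y.shape} and {f.shape}"
        )
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValidationError("R^2 undefined: observed values have zero variance")
    ss_res = float(np.sum((y - f) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class EvaluationReport:
    """Fit of one model over a pooled set of measured cocktails."""

    model: ModelSpec
    cell_lines: list[str]
    n_points: int
    r2: float
    per_order: dict[int, tuple[int, float | None]]
    skipped: list[SkippedCocktail] = field(default_factory=list)


def evaluate_models(
    dataset: CombinationDataset,
    models: Sequence[ModelSpec],
    cell_lines: Sequence[str] | None = None,
    min_order: int = 3,
    max_order: int | None = None,
) -> list[EvaluationReport]:
    """Pooled R^2 of each model against the measured cocktails.

    For every cell line, cocktails of order in [min_order, max_order] that
    are both measured and predictable (all required inputs present, order in
    the formula's range) contribute one (observed, predicted) point; points
    are pooled across cell lines before computing R^2.  Cocktails a model
    cannot predict are recorded in its skip list, so point sets are identical
    across models except for missing inputs or order restrictions (e.g. the
    Isserlis formula stops at quadruplets).
    """
    if cell_lines is None:
        cell_lines = dataset.cell_lines()
    reports = []
    for model in models:
        obs: list[float] = []
        pred: list[float] = []
        orders: list[int] = []
        skipped: list[SkippedCocktail] = []
        for cl in cell_lines:
            result = predict_dataset(dataset, cl, model, min_order=min_order, max_order=max_order)
            skipped.extend(result.skipped)
            for p in result.predictions:
                record = dataset.get(cl, p.cocktail)
                if record is None:
                    continue  # predicted but never measured: nothing to score
                obs.append(record.viability)
                pred.append(p.value)
                orders.append(p.cocktail.order)
        r2 = r_squared(obs, pred) if obs else float("nan")
        per_order: dict[int, tuple[int, float | None]] = {}
        for m in sorted(set(orders)):
            sel = [i for i, o in enumerate(orders) if o == m]
            sub_obs = [obs[i] for i in sel]
            sub_pred = [pred[i] for i in sel]
            try:
                sub_r2: float | None = r_squared(sub_obs, sub_pred)
            except ValidationError:
                sub_r2 = None
            per_order[m] = (len(sel), sub_r2)
        reports.append(
            EvaluationReport(
                model=model,
                cell_lines=list(cell_lines),
                n_points=len(obs),
                r2=r2,
                per_order=per_order,
                skipped=skipped,
            )
        )
    return reports


# ---------------------------------------------------------------------------
# Alpha scan over the log-linear family
# ---------------------------------------------------------------------------


def default_alpha_grid(step: float = 0.05) -> np.ndarray:
    """The standard scan grid alpha = 0, step, ..., 1."""
    n = round(1.0 / step)
    return np.linspace(0.0, 1.0, n + 1)


@dataclass
class AlphaScanResult:
    """R^2 of the log-linear family over a grid of the pair exponent alpha."""

    alphas: np.ndarray
    r2_values: np.ndarray
    best_alpha: float
    order_restriction: int | str = "pooled"


def alpha_scan(
    dataset: CombinationDataset,
    cell_lines: Sequence[str] | None = None,
    alpha_grid: Iterable[float] | None = None,
    order_restriction: int | None = None,
) -> AlphaScanResult:
    """Scan the log-linear family and locate the best-fitting alpha.

    ``order_restriction`` limits the evaluation to cocktails of one order M
    (how the 1/(M-1) optimum is cleanly exposed); ``None`` pools all orders
    >= 3.  Ties resolve to the smallest alpha — the lower-variance model.
    """
    alphas = np.asarray(
        list(alpha_grid) if alpha_grid is not None else default_alpha_grid(), dtype=float
    )
    if alphas.size == 0:
        raise ValidationError("alpha grid must be non-empty")
    if order_restriction is None:
        min_order, max_order = 3, None
    else:
        min_order = max_order = int(order_restriction)
    r2_values = np.empty_like(alphas)
    for i, a in enumerate(alphas):
        report = evaluate_models(
            dataset,
            [ModelSpec("loglinear", alpha=float(a))],
            cell_lines=cell_lines,
            min_order=min_order,
            max_order=max_order,
        )[0]
        r2_values[i] = report.r2
    # argmax with ties to the smallest alpha (np.argmax takes the first max)
    order = np.argsort(alphas, kind="stable")
    alphas, r2_values = alphas[order], r2_values[order]
    best_alpha = float(alphas[int(np.argmax(r2_values))])
    return AlphaScanResult(
        alphas=alphas,
        r2_values=r2_values,
        best_alpha=best_alpha,
        order_restriction="pooled" if order_restriction is None else int(order_restriction),
    )


# ---------------------------------------------------------------------------
# Top-k ranking accuracy
# ---------------------------------------------------------------------------


def ranking_accuracy(
    observed: Sequence[float],
    predicted: Sequence[float],
    top_fraction: float = 0.1,
    names: Sequence[str] | None = None,
) -> float:
    """Overlap of the top-k most effective cocktails by observation vs prediction.

    "Most effective" means *lowest* viability.  ``k = floor(top_fraction * n)``;
    ties are broken by canonical cocktail name (or index when names are
    absent) so the ranking is deterministic.
    """
    y = np.asarray(observed, dtype=float)
    f = np.asarray(predicted, dtype=float)
    if y.shape != f.shape or y.ndim != 1:
        raise ValidationError("observed and predicted must be equal-length vectors")
    n = y.size
    if n < 10:
        raise ValidationError(f"ranking accuracy requires >= 10 points, got {n}")
    if not 0 < top_fraction <= 1:
        raise ValidationError("top_fraction must be in (0, 1]")
    k = math.floor(top_fraction * n)
    if k == 0:
        raise ValidationError(f"top_fraction {top_fraction} selects zero of {n} cocktails")
    tie_break = np.asarray(names) if names is not None else np.arange(n)
    if tie_break.shape != y.shape:
        raise ValidationError("names must match the data length")
    top_obs = set(np.lexsort((tie_break, y))[:k])
    top_pred = set(np.lexsort((tie_break, f))[:k])
    return len(top_obs & top_pred) / k


# ---------------------------------------------------------------------------
# Noise amplification under independent multiplicative measurement noise
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseFactor:
    """Std of a model's log prediction in multiples of per-measurement sigma."""

    family: str
    order: int
    factor: float
    alpha: float | None = None


def noise_amplification_analytic(
    family: str, order: int, alpha: float | None = None
) -> NoiseFactor:
    """Closed-form noise amplification for the log-linear family.

    With independent log-scale noise sigma on every input, a model
    ``prod(pairs)**a * prod(singles)**b`` has log-prediction standard
    deviation ``sigma * sqrt(a^2 * M(M-1)/2 + b^2 * M)``.  Hence:

    * bliss:       sqrt(M)
    * regression:  sqrt(M(M-1)/2 + M(M-2)^2)
    * pairs:       sqrt(M / (2(M-1)))
    """
    M = int(order)
    if family == "bliss":
        if M < 1:
            raise UnsupportedOrderError("bliss noise factor requires M >= 1")
        return NoiseFactor("bliss", M, math.sqrt(M))
    if M < 2:
        raise UnsupportedOrderError(f"{family} noise factor requires M >= 2")
    if family == "pairs":
        return NoiseFactor("pairs", M, math.sqrt(M / (2.0 * (M - 1))))
    if family == "regression":
        if M < 3:
            raise UnsupportedOrderError("regression noise factor requires M >= 3")
        return NoiseFactor("regression", M, math.sqrt(M * (M - 1) / 2.0 + M * (M - 2) ** 2))
    if family == "loglinear":
        if alpha is None:
            raise ValidationError("loglinear noise factor requires alpha")
        a = float(alpha)
        b = 1.0 - (M - 1) * a
        return NoiseFactor(
            "loglinear", M, math.sqrt(a * a * M * (M - 1) / 2.0 + b * b * M), alpha=a
        )
    raise UnsupportedOrderError(f"no analytic noise factor for family {family!r}")


def noise_amplification_mc(
    family: str,
    order: int,
    sigma: float = 0.05,
    n_sims: int = 100_000,
    seed: int = 0,
    alpha: float | None = None,
    truth_single: float = 0.8,
) -> float:
    """Monte-Carlo noise amplification: perturb inputs, measure the log spread.

    Builds a Bliss-consistent ground truth (every single at ``truth_single``,
    every pair their product), multiplies each input measurement by
    ``exp(sigma * Z)`` with independent standard-normal Z, evaluates the model
    on the perturbed inputs, and returns ``std(log prediction) / sigma``.
    """
    if not 0 < sigma <= 0.2:
        raise ValidationError("sigma must be in (0, 0.2]")
    if n_sims < 10_000:
        raise ValidationError("n_sims must be >= 10^4 for a stable estimate")
    M = int(order)
    if family == "loglinear":
        if alpha is None:
            raise ValidationError("loglinear requires alpha")
        a = float(alpha)
    elif family == "bliss":
        a = 0.0
    elif family == "pairs":
        a = 1.0 / (M - 1)
    elif family == "regression":
        a = 1.0
        if M < 3:
            raise UnsupportedOrderError("regression requires M >= 3")
    else:
        raise UnsupportedOrderError(f"no Monte-Carlo noise factor for family {family!r}")
    b = 1.0 - (M - 1) * a

    rng = np.random.default_rng(seed)
    n_pairs = M * (M - 1) // 2
    g_single = np.full(M, truth_single)
    g_pair = np.full(n_pairs, truth_single**2)
    singles = g_single * np.exp(sigma * rng.standard_normal((n_sims, M)))
    pairs = g_pair * np.exp(sigma * rng.standard_normal((n_sims, n_pairs)))
    # evaluate the formula in linear space, exactly as a caller would
    pred = pairs.prod(axis=1) ** a * singles.prod(axis=1) ** b
    return float(np.log(pred).std(ddof=1) / sigma)
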