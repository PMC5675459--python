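"""Synthetic fully factorial screens with known pairwise ground truth.

The generator emulates a single-dose combination screen:

1. true single-drug viabilities are drawn uniformly from ``single_range``
   (default (0.6, 0.9), mirroring a high-survival LD20-style design);
2. true pair viabilities deviate multiplicatively from Bliss,
   ``g_ij = g_i * g_j * exp(delta_ij)`` with
   ``delta_ij ~ Normal(0, pair_interaction_sd)``;
3. true higher-order cocktails follow the log-linear family at a known
   exponent ``true_alpha`` (optionally plus an independent per-cocktail
   log deviation ``high_order_sd``, emulating genuine third-order effects);
4. each observed repeat multiplies the truth by ``exp(noise_sigma * Z)``
   with independent standard-normal Z — independent multiplicative
   measurement noise.

Because the generative exponent is known, the alpha scan has a well-defined
recovery target (:func:`recover_alpha`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .datamodel import Cocktail, CombinationDataset, ViabilityRecord
from .evaluation import alpha_scan
from .exceptions import ValidationError


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a simulated fully factorial screen.

    Defaults describe a realistic six-drug, single-dose cytotoxicity screen:
    high-survival doses, pair interactions of about +/-10% (log scale),
    5% multiplicative measurement noise, six biological repeats.
    """

    n_drugs: int = 6
    max_order: int = 6
    true_alpha: float = 0.5
    single_range: tuple[float, float] = (0.6, 0.9)
    pair_interaction_sd: float = 0.1
    noise_sigma: float = 0.05
    high_order_sd: float = 0.0
    n_repeats: int = 6
    seed: int = 0
    cell_line: str = "SIM"

    def __post_init__(self) -> None:
        if self.n_drugs < 3:
            raise ValidationError("n_drugs must be >= 3")
        if not 2 <= self.max_order <= self.n_drugs:
            raise ValidationError("max_order must be in [2, n_drugs]")
        lo, hi = self.single_range
        if not (0 < lo <= hi <= 1):
            raise ValidationError("single_range must lie within (0, 1]")
        for name in ("pair_interaction_sd", "noise_sigma", "high_order_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_repeats < 2:
            raise ValidationError("n_repeats must be >= 2")


def _drug_names(n: int) -> list[str]:
    return [f"D{i + 1:02d}" for i in range(n)]


def generate_screen(config: SyntheticConfig) -> CombinationDataset:
    """Simulate one screen; bit-reproducible for a fixed config (incl. seed).

    Every subset of the drug panel up to ``max_order`` yields one record with
    per-repeat observations, their mean, and the standard error of the mean.
    """
    rng = np.random.default_rng(config.seed)
    drugs = _drug_names(config.n_drugs)

    true_single = {
        d: float(rng.uniform(*config.single_range)) for d in drugs
    }
    true_pair: dict[str, float] = {}
    for a, b in combinations(drugs, 2):
        delta = rng.normal(0.0, config.pair_interaction_sd) if config.pair_interaction_sd else 0.0
        true_pair["+".join((a, b))] = true_single[a] * true_single[b] * math.exp(delta)

    def truth(cocktail: Cocktail) -> float:
        M = cocktail.order
        if M == 1:
            return true_single[cocktail.drugs[0]]
        if M == 2:
            return true_pair[cocktail.name]
        alpha = config.true_alpha
        beta = 1.0 - (M - 1) * alpha
        log_g = alpha * sum(math.log(true_pair[p.name]) for p in cocktail.pairs())
        log_g += beta * sum(math.log(true_single[d]) for d in cocktail.drugs)
        if config.high_order_sd:
            log_g += rng.normal(0.0, config.high_order_sd)
        return math.exp(log_g)

    dataset = CombinationDataset(name=f"synthetic(seed={config.seed})")
    for order in range(1, config.max_order + 1):
        for combo in combinations(drugs, order):
            cocktail = Cocktail(combo)
            g = truth(cocktail)
            if config.noise_sigma:
                reps = g * np.exp(config.noise_sigma * rng.standard_normal(config.n_repeats))
            else:
                reps = np.full(config.n_repeats, g)
            reps = np.minimum(reps, 2.0)  # keep pathological noise draws in range
            mean = float(reps.mean())
            ste = float(reps.std(ddof=1) / math.sqrt(config.n_repeats))
            dataset.add(
                ViabilityRecord(
                    cell_line=config.cell_line,
                    cocktail=cocktail,
                    viability=mean,
                    ste=ste,
                    repeats=tuple(float(r) for r in reps),
                )
            )
    dataset.validate()
    return dataset


def recover_alpha(
    dataset: CombinationDataset,
    alpha_grid: Iterable[float] | None = None,
    cell_lines: Sequence[str] | None = None,
) -> float:
    """Best-fitting log-linear exponent for a screen of one cocktail order.

    The dataset's cocktails of order >= 3 must all share one order M (the
    optimum 1/(M-1) is order-specific); mixed orders raise.  Returns the
    alpha-scan argmax over ``alpha_grid``.
    """
    orders = {c.order for c in dataset.cocktails() if c.order >= 3}
    if not orders:
        raise ValidationError("dataset contains no cocktails of order >= 3")
    if len(orders) > 1:
        raise ValidationError(
            f"mixed cocktail orders {sorted(orders)}; restrict to a single order"
        )
    result = alpha_scan(
        dataset,
        cell_lines=cell_lines,
        alpha_grid=alpha_grid,
        order_restriction=orders.pop(),
    )
    return result.best_alpha
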