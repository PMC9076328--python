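"""Laterality indices: classical LI per quantity and the weighted ELI.

The classical laterality index contrasts a nonnegative quantity Q measured
over the left (C3) and right (C4) hemispheres:

    LI = (Q_LH - Q_RH) / (Q_LH + Q_RH)  in [-1, 1],

with +1 pure left dominance and -1 pure right dominance.  The enhanced
laterality index fuses N quantities with convex weights summing to 1:

    ELI = sum_i lambda_i * (Q_LH^i - Q_RH^i) / (Q_LH^i + Q_RH^i).

With the two quantities used here (fuzzy entropy and energy) and a single
weight lambda, ELI(lambda) = lambda * LI_FE + (1 - lambda) * LI_E, linear in
lambda with endpoints LI_E at 0 and LI_FE at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

WEIGHT_SUM_TOL = 1e-12

DEFAULT_LAMBDA_GRID: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(11))


@dataclass(frozen=True)
class QuantityPair:
    """One quantity measured on both hemispheres (left C3, right C4)."""

    q_lh: float
    q_rh: float
    quantity_name: str = "other"

    def __post_init__(self) -> None:
        if self.q_lh < 0 or self.q_rh < 0:
            raise ValueError("invalid quantity: negative value")
        if self.q_lh + self.q_rh == 0:
            raise ValueError("undefined laterality: Q_LH + Q_RH = 0")


def laterality_index(pair: QuantityPair, scale: float = 1.0) -> float:
    """Classical LI = scale * (Q_LH - Q_RH) / (Q_LH + Q_RH).

    Antisymmetric under hemisphere swap and invariant to a common positive
    rescaling of both quantities.  Both quantities zero is an error rather
    than 0 — symmetry is never fabricated from empty signals.
    """
    if scale <= 0:
        raise ValueError("invalid quantity: scale must be positive")
    return scale * (pair.q_lh - pair.q_rh) / (pair.q_lh + pair.q_rh)


def _validate_weights(weights: Sequence[float]) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if np.any((w < 0) | (w > 1)):
        raise ValueError("invalid weight: weights must lie in [0, 1]")
    if abs(float(w.sum()) - 1.0) > WEIGHT_SUM_TOL:
        raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")
    return w


def enhanced_laterality_index(
    pairs: Sequence[QuantityPair], weights: Sequence[float]
) -> float:
    """Convex combination of per-quantity laterality indices.

    With a single pair and weight 1 the result is bit-identical to
    `laterality_index` of that pair.
    """
    if len(pairs) == 0:
        raise ValueError("arity mismatch: need at least one quantity pair")
    if len(pairs) != len(weights):
        raise ValueError(
            f"arity mismatch: {len(pairs)} pairs vs {len(weights)} weights"
        )
    w = _validate_weights(weights)
    return float(sum(wi * laterality_index(p) for wi, p in zip(w, pairs)))


def eli_lambda_sweep(
    li_fe: float, li_e: float, grid: Sequence[float] = DEFAULT_LAMBDA_GRID
) -> dict[float, float]:
    """ELI(lambda) = lambda*LI_FE + (1-lambda)*LI_E over a weight grid.

    lambda weights the complexity index LI_FE; 1-lambda weights the strength
    index LI_E.  Exactly linear in lambda.
    """
    for name, v in (("li_fe", li_fe), ("li_e", li_e)):
        if not -1.0 <= v <= 1.0:
            raise ValueError(f"invalid quantity: {name}={v} outside [-1, 1]")
    out: dict[float, float] = {}
    for lam in grid:
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"invalid weight: lambda={lam} outside [0, 1]")
        out[float(lam)] = lam * li_fe + (1.0 - lam) * li_e
    return out


def build_laterality_table(
    aggregate: pd.DataFrame, grid: Sequence[float] = DEFAULT_LAMBDA_GRID
) -> pd.DataFrame:
    """Per (subject, band, condition) LI_FE, LI_E and the ELI lambda-sweep.

    ``aggregate`` is the output of `features.aggregate_features` with one row
    per (subject, channel, band, condition) and columns FE_mean, E_mean.
    """
    wide = aggregate.pivot_table(
        index=["subject", "band", "condition"],
        columns="channel",
        values=["FE_mean", "E_mean"],
        sort=False,
    )
    rows = []
    for (subject, band, condition), row in wide.iterrows():
        li_fe = laterality_index(
            QuantityPair(row[("FE_mean", "C3")], row[("FE_mean", "C4")], "FE")
        )
        li_e = laterality_index(
            QuantityPair(row[("E_mean", "C3")], row[("E_mean", "C4")], "E")
        )
        sweep = eli_lambda_sweep(li_fe, li_e, grid)
        rows.append(
            {
                "subject": subject,
                "band": band,
                "condition": condition,
                "li_fe": li_fe,
                "li_e": li_e,
                **{f"eli_{lam:g}": v for lam, v in sweep.items()},
            }
        )
    return pd.DataFrame(rows)
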