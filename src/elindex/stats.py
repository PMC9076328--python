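"""Reporting layer: mean±SD summaries and paired-samples t tests.

Comparisons are paired by subject on the per-subject averaged features
(the 20-epoch means), n = number of subjects, which avoids the
pseudo-replication of treating epochs as independent observations.  Tests
are two-sided at alpha = 0.05; no multiple-testing correction is applied by
default (per-cell annotation), with Holm correction available via a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sct

from .preprocess import BAND_ORDER, CHANNELS, CONDITIONS

ALPHA_DEFAULT = 0.05


@dataclass
class PairedComparison:
    """One paired contrast with its t statistic and two-sided p value."""

    label: str
    n: int
    t_stat: float
    p_value: float  # NaN when undefined (all differences exactly zero)
    significant: bool
    note: str = ""


def summarize(values) -> tuple[float, float]:
    """Mean and sample standard deviation (ddof=1) of a feature vector."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("insufficient data: need at least 2 values")
    return float(arr.mean()), float(arr.std(ddof=1))


def paired_t(
    sample_a, sample_b, label: str = "", alpha: float = ALPHA_DEFAULT
) -> PairedComparison:
    """Paired-samples t test: t = mean(d) / (sd(d)/sqrt(n)) on d = a - b.

    Degenerate cases: identical samples give an undefined p (NaN, not
    significant, with a warning); zero-variance nonzero differences give
    t = ±inf, p = 0.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("insufficient data: samples must be equal-length vectors")
    if a.size < 2:
        raise ValueError("insufficient data: need at least 2 pairs")
    d = a - b
    n = d.size
    sd = float(d.std(ddof=1))
    md = float(d.mean())
    if sd == 0.0:
        if md == 0.0:
            warnings.warn(
                f"paired_t[{label}]: all differences zero, p undefined", stacklevel=2
            )
            return PairedComparison(label, n, np.nan, np.nan, False, "all-zero differences")
        t = np.inf if md > 0 else -np.inf
        return PairedComparison(label, n, t, 0.0, True, "zero-variance differences")
    t = md / (sd / np.sqrt(n))
    p = float(2.0 * sct.t.sf(abs(t), df=n - 1))
    return PairedComparison(label, n, float(t), p, p < alpha)


def holm_correct(comparisons: list[PairedComparison], alpha: float = ALPHA_DEFAULT) -> None:
    """Re-flag significance with Holm's step-down correction, in place."""
    from statsmodels.stats.multitest import multipletests

    defined = [c for c in comparisons if np.isfinite(c.p_value) or c.p_value == 0.0]
    if not defined:
        return
    reject, _, _, _ = multipletests(
        [c.p_value for c in defined], alpha=alpha, method="holm"
    )
    for c, r in zip(defined, reject):
        c.significant = bool(r)


def _pivot(table: pd.DataFrame, value_col: str) -> pd.DataFrame:
    wide = table.pivot_table(
        index="subject", columns=["channel", "band", "condition"], values=value_col,
        sort=False,
    )
    if wide.isna().any().any():
        raise ValueError("unbalanced design: missing cell for some subject")
    return wide


def comparison_matrix(
    table: pd.DataFrame,
    axis: str,
    value_col: str = "FE_mean",
    alpha: float = ALPHA_DEFAULT,
    holm: bool = False,
) -> list[PairedComparison]:
    """Subject-paired t tests along one design axis of the feature table.

    axis="bands": the 6 unordered band pairs per (channel, condition);
    axis="hemispheres": C3 vs C4 per (band, condition);
    axis="conditions": normal vs OSA per (band, channel).
    Every subject must have both members of every pair ("unbalanced design"
    otherwise).
    """
    wide = _pivot(table, value_col)
    cells = set(wide.columns)
    bands = [b for b in BAND_ORDER if any(c[1] == b for c in cells)]
    out: list[PairedComparison] = []
    if axis == "bands":
        for ch in CHANNELS:
            for cond in CONDITIONS:
                for b1, b2 in combinations(bands, 2):
                    out.append(
                        paired_t(
                            wide[(ch, b1, cond)],
                            wide[(ch, b2, cond)],
                            label=f"{b1}-{b2}|{ch}|{cond}",
                            alpha=alpha,
                        )
                    )
    elif axis == "hemispheres":
        for band in bands:
            for cond in CONDITIONS:
                out.append(
                    paired_t(
                        wide[("C3", band, cond)],
                        wide[("C4", band, cond)],
                        label=f"C3-C4|{band}|{cond}",
                        alpha=alpha,
                    )
                )
    elif axis == "conditions":
        for band in bands:
            for ch in CHANNELS:
                out.append(
                    paired_t(
                        wide[(ch, band, "normal")],
                        wide[(ch, band, "OSA")],
                        label=f"normal-OSA|{band}|{ch}",
                        alpha=alpha,
                    )
                )
    else:
        raise ValueError(f"unbalanced design: unknown axis {axis!r}")
    if holm:
        holm_correct(out, alpha=alpha)
    return out


def build_report(
    table: pd.DataFrame, alpha: float = ALPHA_DEFAULT, holm: bool = False
) -> pd.DataFrame:
    """Long-format report mirroring the summary and t-test table layout.

    One block of mean±SD rows per feature (FE_mean, E_mean, and E_norm when
    present) followed by the three comparison axes for FE_mean and E_mean,
    with an asterisk column marking p < alpha.  E_norm is summarized but not
    tested: per-(subject, condition) min-max pins the extreme bands at 0/1
    for every subject, which degenerates paired contrasts.
    """
    rows = []
    value_cols = [c for c in ("FE_mean", "E_mean", "E_norm") if c in table.columns]
    for value_col in value_cols:
        for (band, cond, ch), grp in table.groupby(
            ["band", "condition", "channel"], sort=False
        ):
            mean, sd = summarize(grp[value_col])
            rows.append(
                {
                    "table": "summary",
                    "feature": value_col,
                    "label": f"{band}|{ch}|{cond}",
                    "n": len(grp),
                    "mean": mean,
                    "sd": sd,
                    "t_stat": np.nan,
                    "p_value": np.nan,
                    "significant": "",
                }
            )
        if value_col == "E_norm":
            continue
        for axis in ("bands", "hemispheres", "conditions"):
            for comp in comparison_matrix(
                table, axis, value_col=value_col, alpha=alpha, holm=holm
            ):
                rows.append(
                    {
                        "table": axis,
                        "feature": value_col,
                        "label": comp.label,
                        "n": comp.n,
                        "mean": np.nan,
                        "sd": np.nan,
                        "t_stat": comp.t_stat,
                        "p_value": comp.p_value,
                        "significant": "*" if comp.significant else "",
                    }
                )
    return pd.DataFrame(rows)
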