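"""Per-epoch fuzzy entropy and energy, and their per-segment averages.

Fuzzy entropy (FuzzyEn) measures signal complexity as

    FE(m, n, r) = ln phi^m - ln phi^(m+1),

where phi^m averages the pairwise similarities exp(-(d_st)^n / r) of
baseline-removed m-length template vectors under the Chebyshev distance,
with tolerance r tied to the epoch standard deviation (r = r_factor * SD).
Signal strength is the epoch energy, the plain sum of squared samples.

Two indexing conventions are supported.  The default, ``chen``, follows the
FuzzyEn literature: N - m template vectors for both phi^m and phi^(m+1)
(so the two are comparable) with each vector's own mean removed.  The
``paper_literal`` convention uses N - m + 1 vectors for phi^m and N - m for
phi^(m+1), removing the whole-epoch mean instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import cdist

from .preprocess import (
    BAND_ORDER,
    CONDITIONS,
    Epoch,
    Recording,
    decompose_bands,
    epoch_split,
    lowpass_filter,
    segment_record,
)

__all__ = [
    "FuzzyEnParams",
    "fuzzy_entropy",
    "epoch_energy",
    "average_over_epochs",
    "normalize_strength",
    "extract_features",
    "aggregate_features",
]


@dataclass(frozen=True)
class FuzzyEnParams:
    """Fuzzy-entropy parameters.

    m : embedding dimension (template length).
    n : fuzzy power of the similarity kernel exp(-(d)^n / r).
    r_factor : tolerance as a multiple of the signal SD (population SD,
        divide by N, so the brute-force oracle matches bit-for-bit).
    convention : "chen" or "paper_literal" (see module docstring).
    baseline : "vector_mean" (each template vector's own mean removed) or
        "epoch_mean"; None ties it to the convention.
    sd_scope : "epoch" (r from each epoch's SD, keeps epoch-wise scale
        invariance) or "segment" (r from the whole band signal's SD).
    """

    m: int = 2
    n: float = 2.0
    r_factor: float = 0.2
    convention: str = "chen"
    baseline: str | None = None
    sd_scope: str = "epoch"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("invalid params: m must be >= 1")
        if self.n <= 0 or self.r_factor <= 0:
            raise ValueError("invalid params: n and r_factor must be positive")
        if self.convention not in ("chen", "paper_literal"):
            raise ValueError(f"invalid params: convention {self.convention!r}")
        if self.baseline not in (None, "vector_mean", "epoch_mean"):
            raise ValueError(f"invalid params: baseline {self.baseline!r}")
        if self.sd_scope not in ("epoch", "segment"):
            raise ValueError(f"invalid params: sd_scope {self.sd_scope!r}")

    @property
    def effective_baseline(self) -> str:
        if self.baseline is not None:
            return self.baseline
        return "vector_mean" if self.convention == "chen" else "epoch_mean"


def _phi(x: np.ndarray, length: int, count: int, n: float, r: float, baseline: str) -> float:
    """Mean pairwise similarity of `count` template vectors of `length`."""
    templates = sliding_window_view(x, length)[:count]
    if baseline == "vector_mean":
        templates = templates - templates.mean(axis=1, keepdims=True)
    else:  # epoch mean; inert under Chebyshev but applied for fidelity
        templates = templates - x.mean()
    d = cdist(templates, templates, "chebyshev")
    sim = np.exp(-(d**n) / r)
    np.fill_diagonal(sim, 0.0)
    return sim.sum() / (count * (count - 1))


def fuzzy_entropy(
    epoch: Epoch | np.ndarray,
    params: FuzzyEnParams = FuzzyEnParams(),
    scale: float | None = None,
) -> float:
    """Fuzzy entropy ln phi^m - ln phi^(m+1) of one epoch.

    The tolerance r = r_factor * SD enters through the SD-normalized epoch:
    the similarity kernel exp(-(d)^n / r) is evaluated on x / SD with
    r = r_factor, which is the printed definition for unit-SD signals and
    makes FE exactly invariant to a positive rescaling of the epoch for any
    fuzzy power n.  ``scale`` overrides the normalizing SD (used when
    sd_scope="segment").  A constant epoch returns 0 by continuity: all
    template distances are 0, every similarity is 1, so phi^m = phi^(m+1)
    without ever dividing by the SD.
    """
    x = epoch.samples if isinstance(epoch, Epoch) else np.asarray(epoch, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("invalid signal: non-finite samples")
    n_samp, m = len(x), params.m
    if n_samp <= m + 1:
        raise ValueError(f"epoch too short: N={n_samp} <= m+1={m + 1}")
    if scale is None:
        scale = float(x.std())  # population SD
    if scale == 0.0:
        if np.ptp(x) == 0.0:
            return 0.0
        raise ValueError("invalid params: zero scale for a non-constant epoch")
    x = x / scale
    r = params.r_factor
    baseline = params.effective_baseline
    if params.convention == "chen":
        counts = (n_samp - m, n_samp - m)
    else:  # paper_literal: all available vectors at each length
        counts = (n_samp - m + 1, n_samp - m)
    phi_m = _phi(x, m, counts[0], params.n, r, baseline)
    phi_m1 = _phi(x, m + 1, counts[1], params.n, r, baseline)
    return float(np.log(phi_m) - np.log(phi_m1))


def epoch_energy(epoch: Epoch | np.ndarray) -> float:
    """Signal strength of one epoch: the sum of squared samples (uV^2)."""
    x = epoch.samples if isinstance(epoch, Epoch) else np.asarray(epoch, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("invalid signal: non-finite samples")
    return float(np.sum(x * x))


def average_over_epochs(values) -> float:
    """Arithmetic mean of per-epoch feature values (20 under defaults)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no epochs")
    return float(arr.mean())


def extract_features(
    recordings,
    fuzzyen: FuzzyEnParams = FuzzyEnParams(),
    conditions=CONDITIONS,
    segment_s: float = 20.0,
    epoch_s: float = 1.0,
    filter_cutoff_hz: float = 50.0,
    filter_order: int = 8,
    band_edges=None,
    wavelet_backend: str = "wpt",
    wavelet_family: str = "dmey",
    compute_fe: bool = True,
) -> pd.DataFrame:
    """Run the preprocessing chain and per-epoch feature extraction.

    Returns a tidy epoch-level table with one row per
    (subject, channel, band, condition, epoch_index) and columns FE and E.
    ``compute_fe=False`` skips the entropy (FE is NaN), useful when only
    energy-based indices are needed.
    """
    rows = []
    for rec in recordings:
        for condition in conditions:
            for seg in segment_record(rec, condition, window_s=segment_s):
                seg_f = lowpass_filter(seg, cutoff_hz=filter_cutoff_hz, order=filter_order)
                bandset = decompose_bands(
                    seg_f, band_edges=band_edges, backend=wavelet_backend, wavelet=wavelet_family
                )
                for band, sig in bandset.bands.items():
                    seg_sd = (
                        float(np.asarray(sig).std())
                        if fuzzyen.sd_scope == "segment"
                        else None
                    )
                    for ep in epoch_split(sig, seg.fs, epoch_s=epoch_s):
                        fe = (
                            fuzzy_entropy(ep, fuzzyen, scale=seg_sd)
                            if compute_fe
                            else np.nan
                        )
                        rows.append(
                            (
                                rec.subject_id,
                                seg.channel,
                                band,
                                condition,
                                ep.index,
                                fe,
                                epoch_energy(ep),
                            )
                        )
    return pd.DataFrame(
        rows, columns=["subject", "channel", "band", "condition", "epoch_index", "FE", "E"]
    )


def aggregate_features(epoch_table: pd.DataFrame) -> pd.DataFrame:
    """Average epoch-level FE and E per (subject, channel, band, condition)."""
    agg = (
        epoch_table.groupby(["subject", "channel", "band", "condition"], sort=False)
        .agg(FE_mean=("FE", "mean"), E_mean=("E", "mean"), n_epochs=("E", "size"))
        .reset_index()
    )
    order = {b: i for i, b in enumerate(BAND_ORDER)}
    return agg.sort_values(
        ["subject", "condition", "channel", "band"],
        key=lambda col: col.map(order) if col.name == "band" else col,
        kind="stable",
    ).reset_index(drop=True)


def normalize_strength(table: pd.DataFrame) -> pd.DataFrame:
    """Add a min-max normalized strength column E_norm in [0, 1].

    Normalization is within each (subject, condition) group across channels
    and bands.  E_norm is for reporting/plotting only; laterality indices are
    always computed from raw E_mean, because min-max shifting would break the
    scale invariance of LI_E.  A degenerate all-equal group maps to 0.5 with
    a warning.
    """
    out = table.copy()

    def _minmax(group: pd.Series) -> pd.Series:
        lo, hi = group.min(), group.max()
        if hi == lo:
            warnings.warn(
                "normalize_strength: all-equal group mapped to 0.5", stacklevel=2
            )
            return pd.Series(0.5, index=group.index)
        return (group - lo) / (hi - lo)

    out["E_norm"] = out.groupby(["subject", "condition"], sort=False)["E_mean"].transform(
        _minmax
    )
    return out
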