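"""Retention-time-local intensity normalization.

Systematic intensity biases in LC-MS runs (electrospray instability,
gradient effects) vary smoothly with retention time. For each sample, the
log10 intensity deviations from a reference sample are computed on the
peptide-charges quantified in both, ordered by the sample's retention
times, smoothed with a cubic spline, and the smoothed curve is subtracted
as a correction — including for peptide-charges absent from the reference,
whose correction is the curve evaluated (constant-extrapolated) at their
retention time.

The default smoother is a least-squares cubic B-spline with interior
knots placed at retention-time quantiles. Because the knots depend only
on the RT support, the smoother is a linear projection, which makes
normalization exactly idempotent: re-normalizing an already-normalized
table refits a curve of zero. A penalized smoothing spline with
GCV-selected penalty (``smoothing="gcv"``) and a fixed-penalty variant
(``smoothing=<float>``) are also available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.interpolate import LSQUnivariateSpline, make_smoothing_spline

__all__ = ["DeviationCurve", "choose_reference", "compute_deviation_curve", "normalize_table"]

KEY = ["peptide", "charge"]


@dataclass
class DeviationCurve:
    """Smoothed log10-intensity deviation of one sample vs the reference."""

    sample_id: str
    reference_id: str
    support: np.ndarray  # ordered RT values the curve was fitted on
    n_shared: int
    kind: str  # "spline" or "constant"
    _predict: Callable[[np.ndarray], np.ndarray]

    def __call__(self, rt) -> np.ndarray:
        rt = np.asarray(rt, dtype=float)
        if self.kind == "constant" or len(self.support) == 0:
            return self._predict(rt)
        # constant extrapolation beyond the fitted RT support
        clipped = np.clip(rt, self.support[0], self.support[-1])
        return self._predict(clipped)


def choose_reference(table: pd.DataFrame) -> str:
    """The sample with the most quantified peptide-charges; ties broken by
    lexicographically smallest sample_id."""
    if len(table) == 0:
        raise ValueError("cannot choose a reference from an empty table")
    counts = (
        table.groupby("sample_id", sort=True)
        .size()
        .sort_values(ascending=False, kind="stable")
    )
    top = counts[counts == counts.iloc[0]]
    return sorted(top.index)[0]


def _fit_spline(rt: np.ndarray, dev: np.ndarray, smoothing) -> Callable:
    if smoothing in (None, "auto"):
        n = len(rt)
        # chromatographic drift varies on the scale of many minutes: one
        # interior knot per ~15 min of RT span tracks it without chasing
        # per-peptide noise
        span = rt[-1] - rt[0]
        n_interior = int(np.clip(round(span / 900.0), 4, 20))
        n_interior = min(n_interior, max(n // 10, 1), max(n - 5, 1))
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        knots = np.unique(np.quantile(rt, qs))
        knots = knots[(knots > rt[0]) & (knots < rt[-1])]
        return _robust_spline(rt, dev, knots)
    lam = None if smoothing == "gcv" else float(smoothing)
    return make_smoothing_spline(rt, dev, lam=lam)


def _robust_spline(rt, dev, knots, max_iter=50, tol=1e-10):
    """Bisquare-reweighted least-squares spline.

    Deviation curves must track the systematic drift of the *unchanged*
    majority of peptides; genuinely differential peptides are large-
    residual outliers that would otherwise leak biology into the
    correction. Iterating the weighted fit to a fixed point keeps the
    smoother a (weighted) projection, so normalization stays idempotent.
    """
    w = np.ones_like(dev)
    fit = LSQUnivariateSpline(rt, dev, t=knots, k=3, w=w)
    for _ in range(max_iter):
        resid = dev - fit(rt)
        scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        if scale <= 0:
            break
        u = resid / (4.685 * scale)
        w_new = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        # keep a floor so the banded solver stays well posed
        w_new = np.maximum(w_new, 1e-6)
        new_fit = LSQUnivariateSpline(rt, dev, t=knots, k=3, w=w_new)
        delta = float(np.max(np.abs(new_fit(rt) - fit(rt))))
        fit, w = new_fit, w_new
        if delta < tol:
            break
    return fit


def compute_deviation_curve(
    sample: str,
    reference: str,
    table: pd.DataFrame,
    smoothing="auto",
    min_shared: int = 50,
) -> DeviationCurve:
    """Fit the smoothed deviation curve of ``sample`` against ``reference``.

    Deviations ``d = log10 I_sample - log10 I_reference`` are computed on
    shared peptide-charges and ordered by the *sample's* retention times;
    duplicate RTs are aggregated by mean deviation before fitting. With
    fewer than ``min_shared`` shared peptide-charges (or fewer than 4
    usable points) the curve degrades to a constant median correction,
    with a warning.
    """
    s = table[table["sample_id"] == sample]
    r = table[table["sample_id"] == reference]
    merged = s.merge(r[KEY + ["log10_intensity"]], on=KEY, suffixes=("", "_ref"))
    n_shared = len(merged)
    dev = (merged["log10_intensity"] - merged["log10_intensity_ref"]).to_numpy()

    if n_shared < max(min_shared, 4):
        const = float(np.median(dev)) if n_shared else 0.0
        warnings.warn(
            f"sample {sample}: only {n_shared} peptide-charges shared with "
            f"reference {reference}; falling back to a constant median "
            f"correction ({const:+.4f})",
            stacklevel=2,
        )
        return DeviationCurve(
            sample, reference, np.array([]), n_shared, "constant",
            lambda rt, c=const: np.full_like(np.asarray(rt, float), c),
        )

    order = np.lexsort((merged["peptide"].to_numpy(), merged["rt_seconds"].to_numpy()))
    rt = merged["rt_seconds"].to_numpy()[order]
    dev = dev[order]
    # aggregate duplicate RT values by mean deviation
    uniq_rt, inverse = np.unique(rt, return_inverse=True)
    if len(uniq_rt) < len(rt):
        sums = np.bincount(inverse, weights=dev)
        cnts = np.bincount(inverse)
        dev = sums / cnts
        rt = uniq_rt
    if len(rt) < 4:
        const = float(np.median(dev))
        warnings.warn(
            f"sample {sample}: fewer than 4 distinct RT points; constant "
            f"median correction", stacklevel=2,
        )
        return DeviationCurve(
            sample, reference, np.array([]), n_shared, "constant",
            lambda x, c=const: np.full_like(np.asarray(x, float), c),
        )
    spline = _fit_spline(rt, dev, smoothing)
    return DeviationCurve(sample, reference, rt, n_shared, "spline", spline)


def normalize_table(
    table: pd.DataFrame,
    reference: str | None = None,
    smoothing="auto",
    min_shared: int = 50,
) -> tuple[pd.DataFrame, dict[str, DeviationCurve]]:
    """Apply RT-local normalization to every non-reference sample.

    Each sample's deviation curve (vs the reference) is evaluated at every
    one of its peptide-charges' retention times — including those absent
    from the reference — and subtracted from the log10 intensity. The
    reference sample is returned unchanged. Row count and order are
    preserved.
    """
    if reference is None:
        reference = choose_reference(table)
    if reference not in set(table["sample_id"]):
        raise ValueError(f"reference sample {reference!r} not present in table")
    out = table.copy()
    curves: dict[str, DeviationCurve] = {}
    for sample in sorted(out["sample_id"].unique()):
        if sample == reference:
            continue
        curve = compute_deviation_curve(
            sample, reference, table, smoothing=smoothing, min_shared=min_shared
        )
        curves[sample] = curve
        mask = out["sample_id"] == sample
        rt = out.loc[mask, "rt_seconds"].to_numpy()
        out.loc[mask, "log10_intensity"] = (
            out.loc[mask, "log10_intensity"].to_numpy() - curve(rt)
        )
    return out, curves


def deviation_diagnostics(curve: DeviationCurve, table: pd.DataFrame) -> pd.DataFrame:
    """Per-shared-peptide diagnostic table (RT, raw and smoothed deviation)."""
    s = table[table["sample_id"] == curve.sample_id]
    r = table[table["sample_id"] == curve.reference_id]
    merged = s.merge(r[KEY + ["log10_intensity"]], on=KEY, suffixes=("", "_ref"))
    merged = merged.sort_values("rt_seconds")
    rt = merged["rt_seconds"].to_numpy()
    return pd.DataFrame(
        {
            "sample_id": curve.sample_id,
            "rt_seconds": rt,
            "raw_deviation": (
                merged["log10_intensity"] - merged["log10_intensity_ref"]
            ).to_numpy(),
            "smoothed_deviation": curve(rt),
        }
    )
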