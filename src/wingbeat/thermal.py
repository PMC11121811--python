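"""Temperature dependence of wingbeat frequency and its correction.

For each cluster, events are binned into 0.5 degC temperature intervals
(observations below 10 degC are omitted: insects rarely fly that cold and
the sparse bins are statistically unstable), the mean frequency per bin is
computed, and an ordinary least-squares line through the bin means gives the
cluster's thermal slope in Hz/degC.

The per-cluster slopes grow with the cluster's frequency. Fitting
``slope = a * f**2 + b * f`` (no constant: a hypothetical 0 Hz flapper has
no thermal response) across clusters yields a general correction

    f_corrected = f_initial + (a * f_initial**2 + b * f_initial) * (T_ref - T)

which shifts any measured frequency to its expected value at the reference
temperature ``T_ref`` (20 degC by default). Both fits are unweighted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClusterThermalFit",
    "CorrectionModel",
    "InsufficientDataError",
    "bin_and_fit",
    "fit_slope_polynomial",
    "slope_at",
    "correct_frequency",
    "corrected_distribution",
    "fit_clusters",
]


class InsufficientDataError(ValueError):
    """Too few qualifying temperature bins (or data pairs) to fit."""


@dataclass
class ClusterThermalFit:
    """Binned means and linear thermal fit for one cluster."""

    cluster_id: int
    bin_centers: np.ndarray  # degC
    bin_means: np.ndarray  # Hz
    bin_counts: np.ndarray
    slope: float  # Hz/degC
    slope_se: float
    intercept: float  # Hz at 0 degC
    mean_freq_at_ref: float  # Hz, fit evaluated at t_ref
    t_ref: float = 20.0

    def as_dict(self) -> dict:
        return {
            "cluster_id": int(self.cluster_id),
            "bin_centers": [float(v) for v in self.bin_centers],
            "bin_means": [float(v) for v in self.bin_means],
            "bin_counts": [int(v) for v in self.bin_counts],
            "slope": float(self.slope),
            "slope_se": float(self.slope_se),
            "intercept": float(self.intercept),
            "mean_freq_at_ref": float(self.mean_freq_at_ref),
            "t_ref": float(self.t_ref),
        }


@dataclass(frozen=True)
class CorrectionModel:
    """Frequency-dependent thermal slope ``s(f) = a f^2 + b f + c``.

    ``c`` is fixed at 0 so that ``s(0) = 0``; the correction at
    ``T = t_ref`` is identically zero for every frequency.
    """

    a: float
    b: float
    c: float = 0.0
    t_ref: float = 20.0

    def slope_at(self, f):
        f = np.asarray(f, dtype=float)
        out = self.a * f**2 + self.b * f + self.c
        return float(out) if out.ndim == 0 else out

    def correct(self, f, t):
        f = np.asarray(f, dtype=float)
        t = np.asarray(t, dtype=float)
        out = f + self.slope_at(f) * (self.t_ref - t)
        return float(out) if out.ndim == 0 else out

    def as_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "c": self.c, "t_ref": self.t_ref}

    @classmethod
    def from_dict(cls, d: Mapping) -> "CorrectionModel":
        return cls(a=d["a"], b=d["b"], c=d.get("c", 0.0), t_ref=d.get("t_ref", 20.0))


def bin_and_fit(
    temperatures: np.ndarray,
    frequencies: np.ndarray,
    cluster_id: int = 0,
    bin_width: float = 0.5,
    t_min: float = 10.0,
    t_max: float | None = None,
    min_bin_count: int = 20,
    t_ref: float = 20.0,
) -> ClusterThermalFit:
    """Bin a cluster's events by temperature and fit a line to bin means.

    Bin edges are half-open intervals ``[t, t + bin_width)`` anchored at the
    integer degC grid. Events below ``t_min`` (and above ``t_max`` if given)
    are omitted; bins holding fewer than ``min_bin_count`` events are
    dropped. The slope and its standard error come from unweighted OLS of
    the bin means on the bin centers.
    """
    t = np.asarray(temperatures, dtype=float)
    f = np.asarray(frequencies, dtype=float)
    if t.shape != f.shape:
        raise ValueError("temperatures and frequencies must align")
    keep = t >= t_min
    if t_max is not None:
        keep &= t < t_max
    t, f = t[keep], f[keep]
    if t.size == 0:
        raise InsufficientDataError("no events at or above t_min")

    start = np.floor(t_min)
    edges = np.arange(start, np.max(t) + bin_width, bin_width)
    idx = np.digitize(t, edges) - 1
    centers, means, counts = [], [], []
    for b in range(edges.size - 1):
        in_bin = idx == b
        n_b = int(in_bin.sum())
        if n_b >= min_bin_count and edges[b] >= t_min:
            centers.append(edges[b] + bin_width / 2.0)
            means.append(float(f[in_bin].mean()))
            counts.append(n_b)
    if len(centers) < 3:
        raise InsufficientDataError(
            f"cluster {cluster_id}: only {len(centers)} qualifying bins"
        )
    res = stats.linregress(centers, means)
    return ClusterThermalFit(
        cluster_id=cluster_id,
        bin_centers=np.asarray(centers),
        bin_means=np.asarray(means),
        bin_counts=np.asarray(counts),
        slope=float(res.slope),
        slope_se=float(res.stderr),
        intercept=float(res.intercept),
        mean_freq_at_ref=float(res.intercept + res.slope * t_ref),
        t_ref=t_ref,
    )


def fit_slope_polynomial(
    mean_freqs: Sequence[float], slopes: Sequence[float], t_ref: float = 20.0
) -> CorrectionModel:
    """Fit ``slope = a f^2 + b f`` (no constant) across clusters.

    Unweighted least squares on the (mean frequency, thermal slope) pairs of
    the individual clusters. At least three pairs are required and the
    design must not be degenerate.
    """
    f = np.asarray(mean_freqs, dtype=float)
    s = np.asarray(slopes, dtype=float)
    if f.shape != s.shape or f.size < 3:
        raise InsufficientDataError("need at least 3 (frequency, slope) pairs")
    X = np.column_stack([f**2, f])
    coef, _, rank, _ = np.linalg.lstsq(X, s, rcond=None)
    if rank < 2:
        raise ValueError("degenerate design: frequencies are collinear")
    return CorrectionModel(a=float(coef[0]), b=float(coef[1]), c=0.0, t_ref=t_ref)


def slope_at(model: CorrectionModel, f):
    """Thermal slope s(f) in Hz/degC predicted by the quadratic model."""
    return model.slope_at(f)


def correct_frequency(f_initial, t, model: CorrectionModel):
    """Shift measured frequencies to the model's reference temperature.

    ``f_corrected = f_initial + s(f_initial) * (t_ref - t)``. At
    ``t = t_ref`` this is the identity. A negative result signals
    out-of-domain extrapolation; values are returned as computed so the
    caller can flag them.
    """
    return model.correct(f_initial, t)


def corrected_distribution(
    frequencies: np.ndarray,
    temperatures: np.ndarray,
    model: CorrectionModel,
    n_bins: int = 100,
    freq_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw and temperature-corrected frequency histograms on a shared grid.

    Returns ``(hist_raw, hist_corrected, bin_edges)``; both histograms count
    every event (the shared grid is widened to cover raw and corrected
    values), so total counts are conserved.
    """
    f = np.asarray(frequencies, dtype=float)
    t = np.asarray(temperatures, dtype=float)
    fc = model.correct(f, t)
    if freq_range is None:
        lo = min(f.min(), fc.min())
        hi = max(f.max(), fc.max())
        freq_range = (lo, hi + 1e-9)
    edges = np.linspace(freq_range[0], freq_range[1], n_bins + 1)
    hist_raw, _ = np.histogram(np.clip(f, *freq_range), bins=edges)
    hist_cor, _ = np.histogram(np.clip(fc, *freq_range), bins=edges)
    return hist_raw, hist_cor, edges


def fit_clusters(
    events: pd.DataFrame,
    label_col: str = "cluster",
    bin_width: float = 0.5,
    t_min: float = 10.0,
    t_max: float | None = None,
    min_bin_count: int = 20,
    t_ref: float = 20.0,
) -> tuple[dict[int, ClusterThermalFit], CorrectionModel]:
    """Per-cluster thermal fits plus the pooled quadratic correction model.

    Clusters with insufficient data are skipped; the quadratic fit uses the
    (mean frequency at t_ref, slope) pairs of the clusters that did fit.
    """
    fits: dict[int, ClusterThermalFit] = {}
    for cid, grp in events.groupby(label_col):
        try:
            fits[int(cid)] = bin_and_fit(
                grp["temperature_C"].to_numpy(),
                grp["wingbeat_hz"].to_numpy(),
                cluster_id=int(cid),
                bin_width=bin_width,
                t_min=t_min,
                t_max=t_max,
                min_bin_count=min_bin_count,
                t_ref=t_ref,
            )
        except InsufficientDataError:
            continue
    if len(fits) < 3:
        raise InsufficientDataError("fewer than 3 clusters could be fitted")
    model = fit_slope_polynomial(
        [ft.mean_freq_at_ref for ft in fits.values()],
        [ft.slope for ft in fits.values()],
        t_ref=t_ref,
    )
    return fits, model


def save_fits(
    path, fits: Mapping[int, ClusterThermalFit], model: CorrectionModel
) -> None:
    payload = {
        "model": model.as_dict(),
        "clusters": {str(k): v.as_dict() for k, v in fits.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_model(path) -> CorrectionModel:
    with open(path) as fh:
        payload = json.load(fh)
    return CorrectionModel.from_dict(payload["model"])
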