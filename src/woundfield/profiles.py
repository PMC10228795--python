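"""Reporter-profile processing: track aggregation, LOESS smoothing, masking.

Raw inputs are bundles of fluorescence line traces drawn from the wound
centre outwards; they are averaged, rescaled to a maximum of one and
smoothed into the 1D reference curves consumed by the observed-bistable
classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["TrackSet", "ReporterProfile", "aggregate_tracks", "loess_smooth", "apply_mask"]

CHANNELS = ("JNK", "JAK", "EdU", "UPD", "")


@dataclass
class TrackSet:
    """k >= 1 intensity traces along a shared centre-to-periphery axis.

    ``distances`` and ``intensities`` are (k, m) arrays; rows are tracks.
    Distances are monotone within each track but tracks may differ in pixel
    pitch — aggregation resamples them onto a common grid.
    """

    distances: np.ndarray
    intensities: np.ndarray
    channel: str = ""

    def __post_init__(self) -> None:
        self.distances = np.atleast_2d(np.asarray(self.distances, dtype=float))
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.distances.shape != self.intensities.shape:
            raise ValueError("distances and intensities must have the same (k, m) shape")
        if self.distances.shape[1] < 2:
            raise ValueError("tracks need at least 2 samples")
        if np.any(np.diff(self.distances, axis=1) <= 0):
            raise ValueError("distances must increase monotonically along each track")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be >= 0")

    @property
    def n_tracks(self) -> int:
        return self.distances.shape[0]


@dataclass
class ReporterProfile:
    """A 1D intensity curve on [0, 1]; the ``mask`` flags excluded positions."""

    positions: np.ndarray
    values: np.ndarray
    sem: np.ndarray | None = None
    channel: str = ""
    scaled: bool = False
    mask: np.ndarray | None = None
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape or self.positions.ndim != 1:
            raise ValueError("positions and values must be matching 1D arrays")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
            if self.sem.shape != self.values.shape:
                raise ValueError("sem must match values")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask must match values")
        if self.scaled:
            vmax = self.values[~self.mask].max() if self.mask is not None else self.values.max()
            if not np.isclose(vmax, 1.0):
                raise ValueError("scaled profile must peak at 1 over unmasked positions")

    @property
    def unmasked(self) -> np.ndarray:
        if self.mask is None:
            return np.ones_like(self.values, dtype=bool)
        return ~self.mask

    def rescale(self) -> "ReporterProfile":
        """Divide by the maximum over unmasked positions so the peak is 1."""
        vmax = float(self.values[self.unmasked].max())
        if vmax <= 0:
            raise ValueError("cannot rescale: no positive intensity outside the mask")
        return replace(
            self,
            values=self.values / vmax,
            sem=None if self.sem is None else self.sem / vmax,
            ci_low=None if self.ci_low is None else self.ci_low / vmax,
            ci_high=None if self.ci_high is None else self.ci_high / vmax,
            scaled=True,
        )


def aggregate_tracks(ts: TrackSet, n_grid: int = 100) -> ReporterProfile:
    """Average tracks pointwise and rescale the mean so it peaks at 1.

    Each track's axis is normalised to [0, 1] and linearly resampled onto a
    common ``n_grid``-point grid before averaging; the per-position standard
    error of the mean is carried along (scaled by the same factor).
    """
    grid = np.linspace(0.0, 1.0, n_grid)
    resampled = np.empty((ts.n_tracks, n_grid))
    for i in range(ts.n_tracks):
        x = ts.distances[i]
        span = x[-1] - x[0]
        resampled[i] = np.interp(grid, (x - x[0]) / span, ts.intensities[i])
    mean = resampled.mean(axis=0)
    vmax = float(mean.max())
    if vmax <= 0:
        raise ValueError("all-zero tracks: scaling undefined")
    if ts.n_tracks > 1:
        sem = resampled.std(axis=0, ddof=1) / np.sqrt(ts.n_tracks)
    else:
        sem = np.zeros(n_grid)
    return ReporterProfile(
        positions=grid,
        values=mean / vmax,
        sem=sem / vmax,
        channel=ts.channel,
        scaled=True,
    )


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None)
    return w**3


def loess_smooth(p: ReporterProfile, span: float = 0.8, degree: int = 1,
                 z: float = 1.96) -> ReporterProfile:
    """Locally weighted polynomial regression with tricube weights.

    For each position the neighbourhood holds ``ceil(span * n)`` points; a
    degree-``degree`` weighted fit is evaluated there.  Returns the fitted
    curve with a pointwise ~95% confidence band built from the equivalent-
    kernel norm and a residual variance estimate.  Masked positions take no
    part in the fit and are returned untouched.
    """
    if not (0.0 < span <= 1.0):
        raise ValueError(f"span must be in (0, 1], got {span}")
    keep = p.unmasked
    x = p.positions[keep]
    y = p.values[keep]
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 unmasked points to smooth")
    k = max(int(np.ceil(span * n)), degree + 2)

    fitted = np.empty(n)
    l_norm2 = np.empty(n)  # squared norm of the equivalent kernel row
    trace_l = 0.0
    for i in range(n):
        dist = np.abs(x - x[i])
        bw = np.partition(dist, k - 1)[k - 1]
        if bw <= 0:
            bw = max(x[-1] - x[0], 1.0) * 1e-12
        w = _tricube(dist / bw)
        idx = w > 0
        xi, wi, yi = x[idx] - x[i], w[idx], y[idx]
        X = np.vander(xi, degree + 1, increasing=True)
        XtW = X.T * wi
        try:
            beta_map = np.linalg.solve(XtW @ X, XtW)  # (degree+1, m)
            li = np.zeros(n)
            li[idx] = beta_map[0]
        except np.linalg.LinAlgError:
            li = np.zeros(n)
            li[idx] = wi / wi.sum()
        fitted[i] = li @ y
        l_norm2[i] = float(li @ li)
        trace_l += li[i]

    resid = y - fitted
    dof = max(n - trace_l, 1.0)
    sigma2 = float(resid @ resid) / dof
    half = z * np.sqrt(sigma2 * l_norm2)

    values = p.values.copy()
    values[keep] = fitted
    ci_low = p.values.copy()
    ci_high = p.values.copy()
    ci_low[keep] = fitted - half
    ci_high[keep] = fitted + half
    return replace(p, values=values, sem=p.sem, ci_low=ci_low, ci_high=ci_high, scaled=False)


def apply_mask(p: ReporterProfile, region: tuple[float, float]) -> ReporterProfile:
    """Exclude a sub-interval of [0, 1] from scaling, smoothing and correlation.

    Values at surviving positions are untouched; if the profile was scaled,
    it is rescaled to the unmasked maximum.
    """
    lo, hi = region
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("mask region must be a sub-interval of [0, 1]")
    new_mask = (p.positions >= lo) & (p.positions <= hi)
    if p.mask is not None:
        new_mask |= p.mask
    if new_mask.all():
        raise ValueError("mask cannot cover the whole profile")
    was_scaled = p.scaled
    out = replace(p, mask=new_mask, scaled=False)
    if was_scaled:
        out = out.rescale()
    return out
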