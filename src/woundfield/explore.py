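"""Parameter-space exploration: sampling, pattern classification, scan analyses.

A steady state counts as a *simple* bistable pattern when JNK falls and JAK
rises from wound centre to periphery, each by more than 10% relative
difference; it counts as an *observed* bistable pattern when both curves
correlate (Pearson r > 0.7, strict) with reference reporter profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    HILL_NAMES,
    PARAM_NAMES,
    DimensionlessParameters,
    ModelConfiguration,
)
from .simulate import SteadyStateField, integrate_to_steady_state

__all__ = [
    "DEFAULT_RANGES",
    "SamplingConfig",
    "ClassificationRecord",
    "sample_parameters",
    "classify_simple",
    "classify_observed",
    "pearson",
    "half_max_position",
    "intersection_position",
    "run_scan",
    "compare_models",
    "parameter_density",
    "ConstantInputError",
    "FlatCurveError",
]


class ConstantInputError(ValueError):
    """Pearson correlation is undefined for a constant sequence."""


class FlatCurveError(ValueError):
    """Half-max position is undefined for a flat curve."""


# tabulated scanned ranges (log-uniform draws); Hill coefficients uniform [1, 4]
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "gamma": (0.01, 1e4),
    "k_deg_JNK": (0.01, 1e4),
    "k_deg_JAK": (0.01, 1e4),
    "k_deg_UPD": (0.01, 1e4),
    "k_act_EIG": (1e-5, 10.0),
    "k_act_JNK": (0.01, 1e4),
    "k_act_JAK": (0.01, 1e4),
    "k_act_UPD": (0.01, 1e4),
    "K_m_EIG": (1e-5, 10.0),
    "K_m_JNK": (0.01, 1e4),
    "K_m_JAK": (0.01, 1e4),
    "K_m_UPD": (0.01, 1e4),
    "k_inh_JAK_by_JNK": (0.01, 1e4),
    "k_inh_JNK_by_JAK": (0.01, 1e4),
    "d": (1.5, 4.0),
    "n1": (1.0, 4.0),
    "n2": (1.0, 4.0),
    "n3": (1.0, 4.0),
    "n4": (1.0, 4.0),
    "ni1": (1.0, 4.0),
    "ni2": (1.0, 4.0),
}

#: named diffusion regimes: UPD faster, slower or equal to EIG
DIFFUSION_REGIMES = {
    "faster": (1.5, 4.0),
    "slower": (0.25, 0.67),
    "equal": (1.0, 1.0),
}

#: one shared interval for every non-Hill parameter (legacy global mode)
GLOBAL_INTERVAL = (1e-3, 1e2)


@dataclass(frozen=True)
class SamplingConfig:
    """How to draw an ensemble of dimensionless parameter sets."""

    n_sets: int = 1000
    seed: int = 0
    #: per-parameter overrides of the tabulated ranges
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    hill_scheme: str = "continuous"  # or "integer"
    diffusion: str = "faster"  # key of DIFFUSION_REGIMES
    global_interval: bool = False
    share_inhibition_hill: bool = False  # tie ni1 = n2, ni2 = n3 (19-parameter scan)

    def __post_init__(self) -> None:
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")
        if self.hill_scheme not in ("continuous", "integer"):
            raise ValueError(f"unknown hill_scheme {self.hill_scheme!r}")
        if self.diffusion not in DIFFUSION_REGIMES:
            raise ValueError(f"diffusion must be one of {sorted(DIFFUSION_REGIMES)}")
        unknown = set(self.ranges) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameters in ranges: {sorted(unknown)}")
        for name, (lo, hi) in self.ranges.items():
            if not (0 < lo <= hi):
                raise ValueError(f"range for {name} must satisfy 0 < low <= high, got {(lo, hi)}")

    def resolved_ranges(self) -> dict[str, tuple[float, float]]:
        """Effective per-parameter ranges: defaults, then regime, then overrides."""
        r = dict(DEFAULT_RANGES)
        if self.global_interval:
            for name in PARAM_NAMES:
                if name not in HILL_NAMES and name != "d":
                    r[name] = GLOBAL_INTERVAL
        r["d"] = DIFFUSION_REGIMES[self.diffusion]
        r.update(self.ranges)
        return r


def sample_parameters(cfg: SamplingConfig) -> pd.DataFrame:
    """Draw ``cfg.n_sets`` parameter sets, log-uniform per tabulated range.

    Hill coefficients are drawn uniformly on [1, 4] (continuous by default,
    integer-valued under ``hill_scheme='integer'``).  Column order is
    PARAM_NAMES; the index is the set id.  Deterministic per seed.
    """
    rng = np.random.default_rng(cfg.seed)
    ranges = cfg.resolved_ranges()
    cols: dict[str, np.ndarray] = {}
    for name in PARAM_NAMES:
        lo, hi = ranges[name]
        if name in HILL_NAMES:
            if cfg.hill_scheme == "integer":
                cols[name] = rng.integers(int(lo), int(hi), endpoint=True, size=cfg.n_sets).astype(float)
            else:
                cols[name] = rng.uniform(lo, hi, size=cfg.n_sets)
        elif lo == hi:
            cols[name] = np.full(cfg.n_sets, lo)
        else:
            cols[name] = np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.n_sets))
    if cfg.share_inhibition_hill:
        cols["ni1"] = cols["n2"].copy()
        cols["ni2"] = cols["n3"].copy()
    df = pd.DataFrame(cols, columns=list(PARAM_NAMES))
    df.index.name = "set_id"
    return df


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


@dataclass
class SimpleClassification:
    simple: bool
    jak_rises: bool
    jnk_falls: bool
    rel_diff_jak: float
    rel_diff_jnk: float
    note: str = ""


@dataclass
class ObservedClassification:
    observed: bool
    r_jnk: float
    r_jak: float
    note: str = ""


def _relative_difference(u0: float, u1: float) -> float:
    """|u(1) - u(0)| / max(u(0), u(1)); nan when both endpoints are 0."""
    denom = max(u0, u1)
    if denom <= 0:
        return math.nan
    return abs(u1 - u0) / denom


def _endpoint_curves(field: SteadyStateField | tuple[np.ndarray, np.ndarray]):
    if isinstance(field, SteadyStateField):
        return field.state.JNK, field.state.JAK
    jnk, jak = field
    return np.asarray(jnk, dtype=float), np.asarray(jak, dtype=float)


def classify_simple(field, min_rel_change: float = 0.10) -> SimpleClassification:
    """Endpoint-based bistability test; all four criteria strict."""
    jnk, jak = _endpoint_curves(field)
    if isinstance(field, SteadyStateField) and not field.converged:
        return SimpleClassification(False, False, False, math.nan, math.nan, "not converged")
    jak_rises = bool(jak[0] < jak[-1])
    jnk_falls = bool(jnk[0] > jnk[-1])
    rd_jak = _relative_difference(float(jak[0]), float(jak[-1]))
    rd_jnk = _relative_difference(float(jnk[0]), float(jnk[-1]))
    note = ""
    if math.isnan(rd_jak) or math.isnan(rd_jnk):
        note = "relative difference undefined on a zero curve"
        simple = False
    else:
        simple = jak_rises and jnk_falls and rd_jak > min_rel_change and rd_jnk > min_rel_change
    return SimpleClassification(simple, jak_rises, jnk_falls, rd_jak, rd_jnk, note)


def pearson(a, b) -> float:
    """Product-moment correlation; raises ConstantInputError on flat input."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("sequences must be 1D with equal length")
    if a.size < 3:
        raise ValueError("need at least 3 points")
    da = a - a.mean()
    db = b - b.mean()
    na = math.sqrt(float(da @ da))
    nb = math.sqrt(float(db @ db))
    if na == 0.0 or nb == 0.0:
        raise ConstantInputError("correlation undefined for constant input")
    r = float(da @ db) / (na * nb)
    return min(1.0, max(-1.0, r))


def _resample_reference(ref, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reference values on the model grid plus a keep-mask (True = use)."""
    x = np.asarray(ref.positions, dtype=float)
    v = np.asarray(ref.values, dtype=float)
    keep = np.ones(grid.shape, dtype=bool)
    m = getattr(ref, "mask", None)
    if m is not None and np.any(m):
        m = np.asarray(m, dtype=bool)
        keep = np.interp(grid, x, m.astype(float)) < 0.5
        x, v = x[~m], v[~m]
    return np.interp(grid, x, v), keep


def classify_observed(field, references, grid: np.ndarray | None = None,
                      threshold: float = 0.7) -> ObservedClassification:
    """Correlate JNK and JAK steady-state curves with reference profiles.

    ``references`` is a (jnk_profile, jak_profile) pair; both are linearly
    resampled to the model grid, honouring any excluded region.  The flag
    requires r > threshold (strict) for both curves.
    """
    jnk, jak = _endpoint_curves(field)
    if isinstance(field, SteadyStateField) and not field.converged:
        return ObservedClassification(False, math.nan, math.nan, "not converged")
    if grid is None:
        grid = (np.arange(jnk.size) + 0.5) / jnk.size
    ref_jnk, ref_jak = references
    r = {}
    note = ""
    for name, curve, ref in (("jnk", jnk, ref_jnk), ("jak", jak, ref_jak)):
        v, keep = _resample_reference(ref, grid)
        try:
            r[name] = pearson(curve[keep], v[keep])
        except ConstantInputError:
            r[name] = math.nan
            note = f"constant {name} curve: correlation undefined"
    observed = (not note) and r["jnk"] > threshold and r["jak"] > threshold
    return ObservedClassification(bool(observed), r["jnk"], r["jak"], note)


# ---------------------------------------------------------------------------
# gradient geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HalfMax:
    position: float
    crossed: bool  #: False when the curve never falls below half max


def half_max_position(positions, values) -> HalfMax:
    """Where the linearly interpolated curve first falls to half its maximum.

    Scans away from the maximum (rightward when the peak sits in the left
    half of the domain, leftward otherwise).  A curve that never falls below
    half max reports the domain end it scanned to, with ``crossed=False``.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need matching 1D position/value arrays with >= 2 points")
    ymax = float(y.max())
    if ymax <= 0 or y.max() == y.min():
        raise FlatCurveError("half-max position undefined for a flat curve")
    half = ymax / 2.0
    i0 = int(np.argmax(y))
    rightward = x[i0] <= (x[0] + x[-1]) / 2.0
    idx = range(i0, x.size - 1) if rightward else range(i0, 0, -1)
    step = 1 if rightward else -1
    for i in idx:
        y0, y1 = y[i], y[i + step]
        if (y0 >= half) and (y1 < half):
            frac = (y0 - half) / (y0 - y1)
            return HalfMax(float(x[i] + frac * (x[i + step] - x[i])), True)
    return HalfMax(float(x[-1] if rightward else x[0]), False)


def intersection_position(positions, jnk, jak) -> float | None:
    """Leftmost x where max-rescaled JAK meets or exceeds max-rescaled JNK.

    Linear interpolation between the bracketing compartments; ``None`` when
    the curves never cross (a valid outcome, preserved as missing).
    """
    x = np.asarray(positions, dtype=float)
    a = np.asarray(jnk, dtype=float)
    b = np.asarray(jak, dtype=float)
    if not (x.shape == a.shape == b.shape):
        raise ValueError("curves must share the grid")
    if a.max() <= 0 or b.max() <= 0:
        return None
    g = b / b.max() - a / a.max()
    if g[0] > 0:
        return float(x[0])
    below = g < 0
    # a genuine crossing needs JAK strictly below JNK first; two rescaled
    # flat curves coincide everywhere and count as no crossing
    for i in range(x.size - 1):
        if below[i] and not below[i + 1]:
            frac = -g[i] / (g[i + 1] - g[i])
            return float(x[i] + frac * (x[i + 1] - x[i]))
    return None


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------

RECORD_COLUMNS = [
    "set_id", "topology", "converged", "residual", "final_time",
    "simple", "observed", "r_jnk", "r_jak",
    "jak_rises", "jnk_falls", "rel_diff_jak", "rel_diff_jnk",
    "jnk_half_max", "eig_half_max", "intersection", "min_value", "message",
]


@dataclass
class ClassificationRecord:
    """One steady state's labels, diagnostics and gradient geometry."""

    set_id: int
    topology: str
    converged: bool
    residual: float
    final_time: float
    simple: bool
    observed: bool
    r_jnk: float
    r_jak: float
    jak_rises: bool
    jnk_falls: bool
    rel_diff_jak: float
    rel_diff_jnk: float
    jnk_half_max: float
    eig_half_max: float
    intersection: float | None
    min_value: float
    message: str = ""


def _safe_half_max(x, y) -> float:
    try:
        return half_max_position(x, y).position
    except FlatCurveError:
        return math.nan


def classify_field(field: SteadyStateField, references, cfg: ModelConfiguration,
                   set_id: int = 0) -> ClassificationRecord:
    """Full ClassificationRecord for one integrated steady state."""
    grid = cfg.centers
    simple = classify_simple(field)
    observed = classify_observed(field, references, grid)
    st = field.state
    inter = intersection_position(grid, st.JNK, st.JAK) if field.converged else None
    return ClassificationRecord(
        set_id=set_id,
        topology=cfg.topology,
        converged=field.converged,
        residual=field.residual,
        final_time=field.final_time,
        simple=bool(simple.simple and field.converged),
        observed=bool(observed.observed and field.converged),
        r_jnk=observed.r_jnk,
        r_jak=observed.r_jak,
        jak_rises=simple.jak_rises,
        jnk_falls=simple.jnk_falls,
        rel_diff_jak=simple.rel_diff_jak,
        rel_diff_jnk=simple.rel_diff_jnk,
        jnk_half_max=_safe_half_max(grid, st.JNK) if field.converged else math.nan,
        eig_half_max=_safe_half_max(grid, st.EIG) if field.converged else math.nan,
        intersection=inter,
        min_value=field.min_value,
        message=field.message or (simple.note or observed.note),
    )


def _records_to_frame(records: list[ClassificationRecord], params: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for r in records:
        d = {c: getattr(r, c) for c in RECORD_COLUMNS}
        d["intersection"] = math.nan if r.intersection is None else r.intersection
        rows.append(d)
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    merged = df.merge(params.reset_index(), on="set_id", how="left", validate="many_to_one")
    return merged


def run_scan(
    sampling: SamplingConfig,
    cfg: ModelConfiguration | None = None,
    references=None,
    topologies: tuple[str, ...] = ("unidirectional", "mutual"),
    progress: bool = False,
    checkpoint_path=None,
    checkpoint_every: int = 1000,
) -> pd.DataFrame:
    """Integrate every sampled set under each topology and classify it.

    The same parameter draw feeds both topologies, so model comparison is
    paired.  Per-set failures are recorded (``converged=False``), never
    raised.  With ``checkpoint_path`` the record table is appended to disk
    every ``checkpoint_every`` sets, making long scans resumable.
    """
    if cfg is None:
        cfg = ModelConfiguration()
    if references is None:
        from .synthetic_data import generate_reference_pair

        references = generate_reference_pair(n_points=cfg.n_compartments)
    params = sample_parameters(sampling)
    cfgs = {t: cfg.with_topology(t) for t in topologies}

    records: list[ClassificationRecord] = []
    done_rows = 0
    for set_id, row in zip(params.index, params.to_numpy()):
        q = DimensionlessParameters(**dict(zip(PARAM_NAMES, map(float, row))))
        for topo in topologies:
            tc = cfgs[topo]
            try:
                fld = integrate_to_steady_state(q, tc)
                rec = classify_field(fld, references, tc, set_id=int(set_id))
            except Exception as exc:  # defensive: a scan must never abort
                rec = ClassificationRecord(
                    int(set_id), topo, False, math.nan, math.nan, False, False,
                    math.nan, math.nan, False, False, math.nan, math.nan,
                    math.nan, math.nan, None, math.nan, f"error: {exc}",
                )
            records.append(rec)
        if progress and (set_id + 1) % 1000 == 0:
            print(f"  scanned {set_id + 1}/{sampling.n_sets} parameter sets", flush=True)
        if checkpoint_path is not None and (set_id + 1) % checkpoint_every == 0:
            frame = _records_to_frame(records, params)
            frame.iloc[done_rows:].to_csv(
                checkpoint_path, mode="a", header=done_rows == 0, index=False,
            )
            done_rows = len(frame)
    frame = _records_to_frame(records, params)
    if checkpoint_path is not None and done_rows < len(frame):
        frame.iloc[done_rows:].to_csv(checkpoint_path, mode="a", header=done_rows == 0, index=False)
    return frame


def compare_models(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-topology bistable counts plus paired same-set contingencies.

    Returns ``(summary, paired)``: summary has counts/percentages of simple,
    observed and both-criteria bistable solutions per topology; paired
    cross-tabulates the two topologies set by set for each criterion.
    """
    if len(records) == 0:
        raise ValueError("empty record table")
    topologies = sorted(records["topology"].unique())
    if len(topologies) != 2:
        raise ValueError(f"need records for exactly two topologies, got {topologies}")
    by_topo = {t: records[records["topology"] == t].set_index("set_id") for t in topologies}
    ids0, ids1 = (set(by_topo[t].index) for t in topologies)
    if ids0 != ids1:
        raise ValueError("topologies cover different parameter-set ids")

    rows = []
    for t in topologies:
        df = by_topo[t]
        n = len(df)
        n_simple = int(df["simple"].sum())
        n_observed = int(df["observed"].sum())
        n_both = int((df["simple"] & df["observed"]).sum())
        rows.append({
            "topology": t,
            "n_sets": n,
            "n_converged": int(df["converged"].sum()),
            "n_simple": n_simple,
            "n_observed": n_observed,
            "n_both": n_both,
            "pct_simple": 100.0 * n_simple / n,
            "pct_observed": 100.0 * n_observed / n,
            "pct_both": 100.0 * n_both / n,
        })
    summary = pd.DataFrame(rows).set_index("topology")

    t0, t1 = topologies
    a, b = by_topo[t0].sort_index(), by_topo[t1].sort_index()
    paired_rows = []
    for crit in ("simple", "observed"):
        fa = a[crit].to_numpy(dtype=bool)
        fb = b[crit].to_numpy(dtype=bool)
        paired_rows.append({
            "criterion": crit,
            "both": int((fa & fb).sum()),
            f"{t0}_only": int((fa & ~fb).sum()),
            f"{t1}_only": int((~fa & fb).sum()),
            "neither": int((~fa & ~fb).sum()),
        })
    paired = pd.DataFrame(paired_rows).set_index("criterion")
    return summary, paired


def parameter_density(records: pd.DataFrame, parameter: str, bins: int = 20,
                      value_range: tuple[float, float] | None = None) -> pd.DataFrame:
    """Per-bin fraction of simple-bistable classifications for one parameter.

    Bins are log-spaced over the scanned range (or over the observed data
    range when no range is given).  Counts over all bins sum to the number
    of classified records.
    """
    if parameter not in PARAM_NAMES:
        raise ValueError(f"unknown parameter {parameter!r}")
    if parameter not in records.columns:
        raise ValueError(f"record table lacks a {parameter!r} column")
    v = records[parameter].to_numpy(dtype=float)
    flag = records["simple"].to_numpy(dtype=bool)
    if value_range is None:
        lo, hi = DEFAULT_RANGES[parameter]
        lo = min(lo, v.min())
        hi = max(hi, v.max())
    else:
        lo, hi = value_range
    edges = np.geomspace(lo, hi, bins + 1)
    idx = np.clip(np.searchsorted(edges, v, side="right") - 1, 0, bins - 1)
    n_total = np.bincount(idx, minlength=bins)
    n_simple = np.bincount(idx[flag], minlength=bins)
    with np.errstate(invalid="ignore"):
        freq = np.where(n_total > 0, n_simple / np.maximum(n_total, 1), 0.0)
    return pd.DataFrame({
        "bin_low": edges[:-1],
        "bin_high": edges[1:],
        "n_total": n_total,
        "n_simple": n_simple,
        "frequency": freq,
    })
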