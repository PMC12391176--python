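"""Bootstrap time-frequency masking and region-of-interest extraction.

The mask discovers event-related (de)synchronization regions without fixing
their time-frequency bounds a priori:

1. Stack every participant's dB time-frequency map (all groups, all
   pinpricks pooled, which guards against circularity in later group
   comparisons) and form the grand average.
2. At every bin in the 0-1.6 s analysis window, one-sample t-test across
   participants of the dB value minus that participant's mean baseline dB at
   the same frequency.
3. Build a null by circularly shifting the maps over time and frequency: per
   iteration each participant's map is rotated by its own uniformly drawn
   (df, dt) pair — destroying the event alignment across participants while
   preserving every map's marginal structure — and the t-map recomputed;
   2000 iterations give 2000 null t-values per bin.
4. A bin enters the mask when its observed |t| reaches the 95th percentile
   of its own bin's null |t| values (a config switch restores the literal
   one-sided rule on signed t).

``shift_mode="shared"`` instead applies one common shift to all
participants. That variant is kept because it admits exhaustive enumeration
of all F x T distinct shifts on small grids, but it is degenerate as a
discovery tool: the t-statistic commutes with a common relabeling of bins,
so the shifted t-map is exactly the observed t-map rotated, every bin's null
is the map's own t-value distribution, and the mask reduces to "the top
(100 - percentile)% of |t| bins" no matter how strong or extended the real
effects are. Independent per-participant shifts are therefore the default.

Connected mask components (4-neighbor) are labeled as ROIs. Components are
first split by the sign of the underlying t-map (synchronizations and
desynchronizations are distinct phenomena even when their bins touch), a
grand-average effect-size floor excludes leakage halos, and a component
whose row-marginal |t| profile dips between two band peaks is cut at the
trough — frequency-adjacent phenomena otherwise fuse into one blob purely
through wavelet smearing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as cc_label

from .core import ParameterError, PipelineError
from .timefreq import EpochWindowTF, TFRMatrix


@dataclass
class MaskConfig:
    n_iterations: int = 2000
    percentile: float = 95.0
    two_sided: bool = True
    shift_mode: str = "independent"  # "independent" | "shared" (see module docstring)
    min_roi_bins: int = 10
    min_effect_db: float = 0.25  # grand-average |dB| floor for ROI membership
    split_trough_ratio: float = 0.7  # row-profile trough depth triggering a band split

    def __post_init__(self) -> None:
        if not 0 < self.percentile < 100:
            raise ParameterError("percentile must be in (0, 100)")
        if self.n_iterations < 100:
            raise ParameterError("need at least 100 null iterations")


@dataclass
class ROI:
    label: str
    sign: int  # +1 synchronization, -1 desynchronization, 0 unknown
    f_lo: float
    f_hi: float
    t_lo: float
    t_hi: float
    bins: np.ndarray  # (n, 2) array of (freq_index, time_index)

    @property
    def n_bins(self) -> int:
        return len(self.bins)


def grand_average_stack(tfrs: list[TFRMatrix]) -> tuple[np.ndarray, TFRMatrix]:
    """Stack per-participant dB maps and form their grand average.

    All inputs must share axes; the per-participant maps are retained as the
    sample for the t-tests.
    """
    if len(tfrs) < 2:
        raise PipelineError("need at least 2 participants")
    ref = tfrs[0]
    for t in tfrs[1:]:
        if (t.values.shape != ref.values.shape
                or not np.allclose(t.freqs, ref.freqs)
                or not np.allclose(t.times, ref.times)):
            raise PipelineError("time-frequency axes differ across participants")
    stack = np.stack([t.values for t in tfrs])
    grand = TFRMatrix(stack.mean(axis=0), ref.freqs.copy(), ref.times.copy(),
                      units=ref.units, labels={"kind": "grand_average", "n": len(tfrs)})
    return stack, grand


def baseline_corrected_stack(stack: np.ndarray, times: np.ndarray,
                             window: EpochWindowTF | None = None
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Per participant: analysis-window dB minus mean baseline dB per frequency.

    Returns ``(X, analysis_times)`` with X of shape (n, n_freqs, n_analysis).
    """
    window = window or EpochWindowTF()
    b0, b1 = window.db_baseline
    a0, a1 = window.analysis
    bmask = (times >= b0) & (times < b1)
    amask = (times >= a0) & (times < a1)
    if not bmask.any() or not amask.any():
        raise PipelineError("baseline or analysis window outside the epoch")
    base = stack[:, :, bmask].mean(axis=2, keepdims=True)
    return stack[:, :, amask] - base, times[amask]


def pointwise_tstats(X: np.ndarray) -> np.ndarray:
    """One-sample t across participants at every bin (df = n - 1).

    Zero-variance bins give +-inf with the numpy warning suppressed (they are
    flagged by being non-finite downstream).
    """
    n = X.shape[0]
    if n < 3:
        raise PipelineError("need at least 3 participants for the t-map")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return t


def _tstats_shifted(X: np.ndarray, df: int, dt: int) -> np.ndarray:
    """Direct-recompute reference: shift every participant's map, re-test."""
    return pointwise_tstats(np.roll(X, (df, dt), axis=(1, 2)))


def circular_shift_null(X: np.ndarray, config: MaskConfig | None = None,
                        seed: int | np.random.Generator = 0,
                        shifts: list[tuple[int, int]] | None = None) -> np.ndarray:
    """Null t-distribution per bin from circular time-frequency shifts.

    Default (``shift_mode="independent"``): per iteration, each participant's
    matrix is rolled by its own uniformly drawn (df, dt) and the t-map of the
    misaligned stack computed. ``"shared"``: one (df, dt) per iteration
    applied to every matrix, in which case the shifted t-map equals the
    observed t-map rolled by that amount (used for speed; the direct
    recompute is exercised by ``_tstats_shifted``); pass ``shifts`` to
    enumerate, e.g. all F x T distinct shared shifts on a toy grid.

    Returns an array (n_iterations, n_freqs, n_times); the all-zero shift
    reproduces the observed t-map in either mode.
    """
    config = config or MaskConfig()
    t_obs = pointwise_tstats(X)
    n, F, T = X.shape
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if shifts is not None or config.shift_mode == "shared":
        if shifts is None:
            dfs = rng.integers(0, F, size=config.n_iterations)
            dts = rng.integers(0, T, size=config.n_iterations)
            shifts = list(zip(dfs.tolist(), dts.tolist()))
        null = np.empty((len(shifts), F, T), dtype=np.float32)
        for i, (df, dt) in enumerate(shifts):
            null[i] = np.roll(t_obs, (df, dt), axis=(0, 1))
        return null

    if config.shift_mode != "independent":
        raise ParameterError(f"unknown shift_mode {config.shift_mode!r}")
    null = np.empty((config.n_iterations, F, T), dtype=np.float32)
    shifted = np.empty_like(X)
    for i in range(config.n_iterations):
        dfs = rng.integers(0, F, size=n)
        dts = rng.integers(0, T, size=n)
        for p in range(n):
            shifted[p] = np.roll(X[p], (dfs[p], dts[p]), axis=(0, 1))
        null[i] = pointwise_tstats(shifted)
    return null


def build_mask(t_obs: np.ndarray, null: np.ndarray,
               config: MaskConfig | None = None) -> np.ndarray:
    """Per-bin percentile thresholding of the observed t-map.

    Two-sided (default): |t| >= the configured percentile of that bin's null
    |t| values. One-sided: signed t against the signed-null percentile.
    """
    config = config or MaskConfig()
    q = config.percentile / 100.0
    if config.two_sided:
        thr = np.quantile(np.abs(null), q, axis=0)
        return np.abs(t_obs) >= thr
    thr = np.quantile(null, q, axis=0)
    return t_obs >= thr


_BAND_EDGES = [(0.0, 4.0, "delta"), (4.0, 7.0, "theta"), (7.0, 13.0, "alpha"),
               (13.0, 100.0, "beta")]


def _band_name(freq: float, sign: int) -> str:
    for lo, hi, name in _BAND_EDGES:
        if lo <= freq < hi:
            if name == "beta":
                return "beta2_resync" if sign > 0 else "beta1_desync"
            suffix = "sync" if sign >= 0 else "desync"
            return f"{name}_{suffix}"
    return "unknown"


def _split_component(comp_mask: np.ndarray, tmag: np.ndarray,
                     config: MaskConfig) -> np.ndarray:
    """Split one component at frequency rows where its |t| profile dips.

    Frequency-adjacent phenomena of the same sign (e.g. two neighboring
    band-limited desynchronizations) fuse into a single connected component
    through spectral smearing. The component's row-marginal mean |t| profile
    then shows a trough between the band peaks; whenever an interior row
    falls below ``split_trough_ratio`` times the smaller flanking peak, the
    component is cut at that row (recursively). Deterministic and 1-D, which
    keeps the rule robust and easy to reason about. Returns an integer label
    image over the component (0 outside).
    """
    rows = np.flatnonzero(comp_mask.any(axis=1))
    profile = np.array([tmag[r, comp_mask[r]].mean() for r in rows])

    def find_cut(lo: int, hi: int) -> int | None:
        # deepest admissible trough strictly inside rows[lo:hi+1]
        best, best_depth = None, 1.0
        for i in range(lo + 1, hi):
            left = profile[lo:i].max()
            right = profile[i + 1:hi + 1].max()
            depth = profile[i] / max(min(left, right), 1e-12)
            if depth < config.split_trough_ratio and depth < best_depth:
                best, best_depth = i, depth
        return best

    pieces: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        cut = find_cut(lo, hi)
        if cut is None:
            pieces.append((lo, hi))
        else:
            recurse(lo, cut)
            recurse(cut + 1, hi)

    recurse(0, len(rows) - 1)
    out = np.zeros(comp_mask.shape, dtype=int)
    for k, (lo, hi) in enumerate(pieces, start=1):
        sub = np.zeros_like(comp_mask)
        sub[rows[lo]:rows[hi] + 1] = comp_mask[rows[lo]:rows[hi] + 1]
        out[sub] = k
    return out


def label_rois(mask: np.ndarray, config: MaskConfig | None = None,
               freqs: np.ndarray | None = None, times: np.ndarray | None = None,
               tmap: np.ndarray | None = None,
               grand_db: np.ndarray | None = None) -> list[ROI]:
    """Connected mask components as labeled ROIs.

    Components use 4-neighbor connectivity; components smaller than
    ``min_roi_bins`` are discarded. When the t-map is supplied, bins are first
    stratified by t sign, and components containing several well-separated
    |t| peaks are watershed-split between them (see module docstring). When
    the grand-average dB map is supplied, ROI membership additionally
    requires |grand dB| >= ``min_effect_db``: with trial-averaged maps the
    pointwise t-test resolves offsets of a fraction of a dB, so a bare mask
    also captures physiologically meaningless spectral-leakage halos around
    real effects; the floor restricts ROIs to bins with a non-trivial effect
    size. Each ROI reports its frequency/time bounds and a band label from
    its |t|-weighted centroid frequency. An empty mask gives an empty list.
    """
    config = config or MaskConfig()
    if grand_db is not None:
        mask = mask & (np.abs(grand_db) >= config.min_effect_db)
    F, T = mask.shape
    freqs = np.arange(F, dtype=float) if freqs is None else np.asarray(freqs)
    times = np.arange(T, dtype=float) if times is None else np.asarray(times)

    pieces: list[tuple[np.ndarray, int]] = []  # (bool image, sign)
    if tmap is None:
        lab = cc_label(mask, connectivity=1)
        for v in range(1, lab.max() + 1):
            pieces.append((lab == v, 0))
    else:
        for sign in (+1, -1):
            strat = mask & ((tmap > 0) if sign > 0 else (tmap < 0))
            lab = cc_label(strat, connectivity=1)
            for v in range(1, lab.max() + 1):
                comp = lab == v
                if comp.sum() < config.min_roi_bins:
                    pieces.append((comp, sign))
                    continue
                sub = _split_component(comp, np.abs(tmap), config)
                for w in range(1, sub.max() + 1):
                    relab = cc_label(sub == w, connectivity=1)  # cuts may disconnect
                    for v2 in range(1, relab.max() + 1):
                        pieces.append((relab == v2, sign))

    rois: list[ROI] = []
    for img, sign in pieces:
        rr, cc = np.nonzero(img)
        if len(rr) < config.min_roi_bins:
            continue
        if tmap is not None:
            weights = np.abs(tmap[rr, cc])
            centroid_f = float(np.average(freqs[rr], weights=weights))
        else:
            centroid_f = float(np.mean(freqs[rr]))
        name = _band_name(centroid_f, sign)
        rois.append(ROI(label=name, sign=sign,
                        f_lo=float(freqs[rr].min()), f_hi=float(freqs[rr].max()),
                        t_lo=float(times[cc].min()), t_hi=float(times[cc].max()),
                        bins=np.column_stack([rr, cc])))
    rois.sort(key=lambda r: (r.f_lo, r.t_lo))
    seen: dict[str, int] = {}
    for r in rois:
        seen[r.label] = seen.get(r.label, 0) + 1
        if seen[r.label] > 1:
            r.label = f"{r.label}-{seen[r.label]}"
    return rois


def extract_roi_power(tfr: TFRMatrix, rois: list[ROI],
                      window: EpochWindowTF | None = None) -> dict[str, float]:
    """Mean dB over each ROI's member bins for one participant/condition.

    ROI bin indices refer to the analysis-window grid; the participant's dB
    map is windowed the same way and averaged directly (a constant +3 dB map
    gives 3 dB for every ROI).
    """
    window = window or EpochWindowTF()
    a0, a1 = window.analysis
    amask = (tfr.times >= a0) & (tfr.times < a1)
    vals = tfr.values[:, amask]
    F, T = vals.shape
    out = {}
    for roi in rois:
        if roi.bins[:, 0].max() >= F or roi.bins[:, 1].max() >= T:
            raise PipelineError(f"ROI {roi.label} exceeds the TFR grid")
        out[roi.label] = float(vals[roi.bins[:, 0], roi.bins[:, 1]].mean())
    return out


def discover_rois(tfrs: list[TFRMatrix], config: MaskConfig | None = None,
                  seed: int = 0, window: EpochWindowTF | None = None) -> dict:
    """The full four-step masking procedure on a cohort of dB maps.

    Returns a dict with the stack, grand average, observed t-map, mask, ROIs,
    and the analysis-window axes.
    """
    config = config or MaskConfig()
    window = window or EpochWindowTF()
    stack, grand = grand_average_stack(tfrs)
    X, atimes = baseline_corrected_stack(stack, grand.times, window)
    t_obs = pointwise_tstats(X)
    null = circular_shift_null(X, config, seed)
    mask = build_mask(t_obs, null, config)
    grand_corr = X.mean(axis=0)  # grand-average baseline-corrected dB
    rois = label_rois(mask, config, grand.freqs, atimes, tmap=t_obs,
                      grand_db=grand_corr)
    return {"stack": stack, "grand": grand, "tmap": t_obs, "mask": mask,
            "rois": rois, "freqs": grand.freqs, "times": atimes,
            "n_null": null.shape[0]}


def roi_jaccard(roi: ROI, window: tuple[float, float, float, float],
                freqs: np.ndarray, times: np.ndarray) -> float:
    """Jaccard overlap between an ROI's bins and a rectangular target window.

    ``window`` is (f_lo, f_hi, t_lo, t_hi) in Hz/s on the analysis grid.
    """
    f_lo, f_hi, t_lo, t_hi = window
    rect = np.zeros((len(freqs), len(times)), dtype=bool)
    rect[np.ix_((freqs >= f_lo) & (freqs <= f_hi),
                (times >= t_lo) & (times <= t_hi))] = True
    mask = np.zeros_like(rect)
    mask[roi.bins[:, 0], roi.bins[:, 1]] = True
    union = (rect | mask).sum()
    return float((rect & mask).sum() / union) if union else 0.0
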