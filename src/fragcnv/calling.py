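"""Query scoring, score combination, segmentation and event calling.

A query sample is scored *within itself*: each usable bin's observation is
compared to the weighted mean and standard deviation of the observations in
its reference bins (on other chromosomes) of the same sample, per datatype.
The read-count and fragment-size Z tracks are combined (Fisher by default),
segmented with circular binary segmentation, and thresholded into events.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import ndtri_exp

from .binning import BinGrid, BinnedSample, fs_region_filter
from .refbuild import (
    FRAGMENT_SIZE,
    READ_COUNT,
    ReferenceSet,
    apply_bias_correction,
    normalize_counts,
)

TRACKS = (READ_COUNT, FRAGMENT_SIZE, "combined")

DEFAULT_ALPHA = 0.01
DEFAULT_N_PERM = 1000
DEFAULT_MIN_BINS = 2
MIN_VALID_NEIGHBORS = 10

MODE_I_MIN_SPAN = 10_000_000
MODE_II_MIN_SPAN = 1_000_000
Z_THRESHOLD = 5.0


@dataclass
class ZTrack:
    """Per-bin Z-scores for the three signals; NaN where invalid."""

    grid: BinGrid
    z_rc: np.ndarray
    z_fs: np.ndarray  # oriented: gains push positive
    z_comb: np.ndarray

    def z(self, track: str) -> np.ndarray:
        if track == READ_COUNT:
            return self.z_rc
        if track == FRAGMENT_SIZE:
            return self.z_fs
        if track == "combined":
            return self.z_comb
        raise ValueError(f"unknown track {track!r}")

    def valid(self, track: str) -> np.ndarray:
        return np.isfinite(self.z(track))

    def to_bedgraph(self, track: str, path: str | Path) -> None:
        z = self.z(track)
        g = self.grid
        with open(path, "w") as fh:
            for i in np.flatnonzero(np.isfinite(z)):
                fh.write(
                    f"{g.chrom_order[g.bin_chrom[i]]}\t{g.bin_start[i]}\t"
                    f"{g.bin_end[i]}\t{z[i]:.4f}\n"
                )


@dataclass
class Segment:
    chrom: str
    start_bp: int
    end_bp: int
    bin_indices: np.ndarray  # full-bin indices of the valid bins covered


@dataclass
class Event:
    chrom: str
    start_bp: int
    end_bp: int
    n_bins: int
    z_segment: float
    direction: str  # "gain" | "loss"

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp


# ---------------------------------------------------------------------------
# per-bin Z


def within_sample_z(
    sample: BinnedSample,
    ref: ReferenceSet,
    datatype: str,
    min_valid_neighbors: int = MIN_VALID_NEIGHBORS,
) -> np.ndarray:
    """Per-bin within-sample Z for one datatype; NaN where undefined.

    The observation vector (normalized counts or per-bin mean fragment
    sizes) is bias-corrected with the reference's model, then each query
    bin's value is standardized against the weighted mean/SD of its
    reference bins *in this same sample*.  Query bins whose own observation
    is unusable, whose usable-neighbor count falls below
    ``min_valid_neighbors``, or whose neighbor SD is 0 are invalidated.
    """
    if sample.grid.grid_hash != ref.grid.grid_hash:
        raise ValueError(
            "sample grid does not match reference grid "
            f"({sample.grid.grid_hash} vs {ref.grid.grid_hash}); "
            "re-bin the sample at the reference bin size"
        )
    dref = ref.references[datatype]
    model = dref.model
    support = model.support
    n_bins = ref.grid.n_bins

    if datatype == READ_COUNT:
        vec = normalize_counts(sample, ref.mask)[support]
        obs_ok_sup = np.ones(vec.shape, dtype=bool)
    else:
        fsm = sample.fs_mean
        sample_ok = sample.fs_mask & (sample.fs_n > 0) & np.isfinite(fsm)
        vec = fsm[support].copy()
        obs_ok_sup = sample_ok[support]
        # missing observations are mean-imputed so the projection is defined;
        # the affected bins stay invalid as queries and as neighbors
        vec[~obs_ok_sup] = model.mean_vector[~obs_ok_sup]
    corrected = apply_bias_correction(vec, model)

    val_full = np.full(n_bins, np.nan)
    val_full[dref.query_bins] = corrected
    ok_full = np.zeros(n_bins, dtype=bool)
    ok_full[dref.query_bins] = obs_ok_sup

    nb = dref.neighbors
    safe_nb = np.clip(nb, 0, n_bins - 1)
    nb_ok = (nb >= 0) & ok_full[safe_nb]
    V = np.where(nb_ok, val_full[safe_nb], 0.0)
    W = np.where(nb_ok, dref.weights, 0.0)
    wsum = W.sum(axis=1)
    n_ok = nb_ok.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        Wn = W / wsum[:, None]
        mu = (Wn * V).sum(axis=1)
        var = (Wn * (V - mu[:, None]) ** 2 * nb_ok).sum(axis=1)
        sd = np.sqrt(var)
        z_sup = (corrected - mu) / sd
    valid = obs_ok_sup & (wsum > 0) & (n_ok >= min_valid_neighbors) & (sd > 0)
    z_full = np.full(n_bins, np.nan)
    z_full[dref.query_bins[valid]] = z_sup[valid]
    return z_full


def orient_fs(z_fs_raw: np.ndarray) -> np.ndarray:
    """Flip the fragment-size Z so copy-number gains push it positive.

    Elevated fetal content shortens fragments, so a raw Z of "longer than
    expected" is evidence *against* a gain; negating makes the track
    concordant with the read-count Z.
    """
    return -np.asarray(z_fs_raw, dtype=np.float64)


# ---------------------------------------------------------------------------
# combination


def _fisher_one_sided(logp_a: np.ndarray, logp_b: np.ndarray) -> np.ndarray:
    """Fisher-combine two one-sided log p-values into a Z, in log space."""
    X = -2.0 * (logp_a + logp_b)
    return -ndtri_exp(sps.chi2.logsf(X, df=4))


def combine_z(
    z_rc: np.ndarray,
    z_fs: np.ndarray,
    method: str = "fisher",
) -> np.ndarray:
    """Combine the two oriented Z tracks into one.

    ``fisher``: both one-sided Fisher combinations (gain side from the
    upper-tail p-values, loss side from the lower-tail ones) are evaluated
    through the chi-square(4) tail; the combined Z takes the stronger side,
    negated for the loss side so sign encodes direction.  ``stouffer``:
    (z_rc + z_fs)/sqrt(2).  Bins where only one track is valid inherit that
    track's Z; bins where neither is valid stay NaN.
    """
    z_rc = np.asarray(z_rc, dtype=np.float64)
    z_fs = np.asarray(z_fs, dtype=np.float64)
    ok_rc = np.isfinite(z_rc)
    ok_fs = np.isfinite(z_fs)
    both = ok_rc & ok_fs
    out = np.full(z_rc.shape, np.nan)
    out[ok_rc & ~ok_fs] = z_rc[ok_rc & ~ok_fs]
    out[ok_fs & ~ok_rc] = z_fs[ok_fs & ~ok_rc]
    if not both.any():
        return out
    a, b = z_rc[both], z_fs[both]
    if method == "stouffer":
        out[both] = (a + b) / math.sqrt(2.0)
    elif method == "fisher":
        z_gain = _fisher_one_sided(sps.norm.logsf(a), sps.norm.logsf(b))
        z_loss = _fisher_one_sided(sps.norm.logcdf(a), sps.norm.logcdf(b))
        out[both] = np.where(z_gain >= z_loss, z_gain, -z_loss)
    else:
        raise ValueError(f"unknown combination method {method!r}")
    return out


# ---------------------------------------------------------------------------
# circular binary segmentation


def _max_arc_stat(x: np.ndarray, min_bins: int) -> tuple[float, int, int] | None:
    """Max standardized arc-vs-rest mean-difference statistic over all arcs
    [i, j) with both the arc and its complement >= min_bins long.

    Returns (|t|, i, j) or None when no admissible arc exists or the segment
    is constant.  Ties resolve to the first (i, j) in row-major order.
    """
    n = len(x)
    if n < 2 * min_bins:
        return None
    s = float(np.std(x))
    if s == 0.0:
        return None
    S = np.concatenate([[0.0], np.cumsum(x)])
    tot = S[-1]
    iidx, jidx = np.meshgrid(
        np.arange(n + 1), np.arange(n + 1), indexing="ij"
    )
    nin = jidx - iidx
    ok = (nin >= min_bins) & (n - nin >= min_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        sum_in = S[jidx] - S[iidx]
        m_in = sum_in / nin
        m_out = (tot - sum_in) / (n - nin)
        t = np.abs(m_in - m_out) / (s * np.sqrt(1.0 / nin + 1.0 / (n - nin)))
    t[~ok] = -np.inf
    flat = int(np.argmax(t))  # first maximum in row-major (i, then j) order
    i, j = divmod(flat, n + 1)
    return float(t[i, j]), int(i), int(j)


def _arc_split_significant(
    x: np.ndarray,
    t_obs: float,
    min_bins: int,
    alpha: float,
    n_perm: int,
    rng: np.random.Generator,
) -> bool:
    """Permutation test: is the observed max arc statistic significant?

    p = (1 + #{perm >= obs}) / (1 + n_perm); permutations abort early once
    the exceedance count already forces p >= alpha (the decision cannot
    change, and the per-segment RNG stream is independent of later calls).
    """
    fail_at = alpha * (1 + n_perm) - 1.0
    count = 0
    for _ in range(n_perm):
        xp = rng.permutation(x)
        res = _max_arc_stat(xp, min_bins)
        if res is not None and res[0] >= t_obs - 1e-12:
            count += 1
            if count >= fail_at:
                return False
    return count < fail_at


def cbs_segment(
    values: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    min_bins: int = DEFAULT_MIN_BINS,
    seed: int = 0,
    _offset: int = 0,
) -> list[tuple[int, int]]:
    """Recursive circular binary segmentation of a 1-D score array.

    Finds the arc maximizing the standardized mean-difference statistic,
    accepts the split when its permutation p-value is below ``alpha``
    (``n_perm`` seeded permutations), and recurses.  Returns half-open
    (start, end) index pairs partitioning [0, n).

    Each (sub)segment's permutation RNG is seeded from
    (seed, segment start in the original array, segment length), making the
    output deterministic and reproducible piecewise.
    """
    x = np.asarray(values, dtype=np.float64)
    n = len(x)
    if n == 0:
        return []
    if not np.all(np.isfinite(x)):
        raise ValueError("cbs_segment requires finite values")
    res = _max_arc_stat(x, min_bins)
    if res is None:
        return [(0, n)]
    t_obs, i, j = res
    rng = np.random.default_rng([seed, _offset, n])
    if not _arc_split_significant(x, t_obs, min_bins, alpha, n_perm, rng):
        return [(0, n)]
    pieces = [(0, i), (i, j), (j, n)]
    out: list[tuple[int, int]] = []
    for a, b in pieces:
        if b <= a:
            continue
        for sa, sb in cbs_segment(
            x[a:b], alpha, n_perm, min_bins, seed, _offset + a
        ):
            out.append((a + sa, a + sb))
    return out


# ---------------------------------------------------------------------------
# segment scoring and event calling


def score_segment(segment: Segment, z: np.ndarray) -> float:
    """Stouffer aggregation of the segment's valid bin Z-scores:
    sum(z_i)/sqrt(m)."""
    vals = z[segment.bin_indices]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("segment has no valid bins")
    return float(vals.sum() / math.sqrt(len(vals)))


def segment_track(
    ztrack: ZTrack,
    track: str = "combined",
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    min_bins: int = DEFAULT_MIN_BINS,
    seed: int = 0,
) -> list[Segment]:
    """Segment each chromosome's valid bins of the chosen track with CBS.

    Segment spans run from the start of their first valid bin to the end of
    their last one; together the segments tile each chromosome's valid bins.
    """
    z = ztrack.z(track)
    g = ztrack.grid
    segments: list[Segment] = []
    for ci, chrom in enumerate(g.chrom_order):
        on_chrom = np.flatnonzero((g.bin_chrom == ci) & np.isfinite(z))
        if len(on_chrom) == 0:
            continue
        for a, b in cbs_segment(
            z[on_chrom], alpha, n_perm, min_bins, seed, _offset=int(on_chrom[0])
        ):
            bins = on_chrom[a:b]
            segments.append(
                Segment(
                    chrom=chrom,
                    start_bp=int(g.bin_start[bins[0]]),
                    end_bp=int(g.bin_end[bins[-1]]),
                    bin_indices=bins,
                )
            )
    return segments


def call_events(
    segments: Sequence[Segment],
    z: np.ndarray,
    mode: str = "I",
) -> list[Event]:
    """Threshold scored segments into events.

    Mode I: span > 10 Mb and Z >= 5 (gains only).
    Mode II: span > 1 Mb and |Z| >= 5 (gains and losses).
    """
    if mode not in ("I", "II"):
        raise ValueError(f"unknown mode {mode!r}")
    events = []
    for seg in segments:
        zs = score_segment(seg, z)
        span = seg.end_bp - seg.start_bp
        if mode == "I":
            keep = span > MODE_I_MIN_SPAN and zs >= Z_THRESHOLD
        else:
            keep = span > MODE_II_MIN_SPAN and abs(zs) >= Z_THRESHOLD
        if keep:
            events.append(
                Event(
                    chrom=seg.chrom,
                    start_bp=seg.start_bp,
                    end_bp=seg.end_bp,
                    n_bins=len(seg.bin_indices),
                    z_segment=zs,
                    direction="gain" if zs >= 0 else "loss",
                )
            )
    return events


# ---------------------------------------------------------------------------
# orchestration


def score_sample(
    sample: BinnedSample,
    ref: ReferenceSet,
    combine: str = "fisher",
    fs_min_frags: int = 10,
    fs_max_cov_z: float = 3.0,
    min_valid_neighbors: int = MIN_VALID_NEIGHBORS,
) -> ZTrack:
    """Full per-bin scoring of a query sample against a reference set."""
    filtered = fs_region_filter(sample, fs_min_frags, fs_max_cov_z)
    z_rc = within_sample_z(filtered, ref, READ_COUNT, min_valid_neighbors)
    z_fs = orient_fs(within_sample_z(filtered, ref, FRAGMENT_SIZE, min_valid_neighbors))
    z_comb = combine_z(z_rc, z_fs, method=combine)
    return ZTrack(sample.grid, z_rc, z_fs, z_comb)


def segment_and_call(
    ztrack: ZTrack,
    track: str = "combined",
    mode: str = "I",
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    min_bins: int = DEFAULT_MIN_BINS,
    seed: int = 0,
) -> tuple[list[Segment], list[Event]]:
    """Segment the chosen track and call events at the mode's thresholds;
    whichever track drives the run is also the one thresholded."""
    segments = segment_track(ztrack, track, alpha, n_perm, min_bins, seed)
    events = call_events(segments, ztrack.z(track), mode=mode)
    return segments, events


def events_to_table(events: Sequence[Event]):
    import pandas as pd

    return pd.DataFrame(
        {
            "chrom": [e.chrom for e in events],
            "start": [e.start_bp for e in events],
            "end": [e.end_bp for e in events],
            "direction": [e.direction for e in events],
            "z_segment": [e.z_segment for e in events],
            "n_bins": [e.n_bins for e in events],
        }
    )
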