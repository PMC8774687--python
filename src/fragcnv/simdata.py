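"""Bin-level synthetic cohorts with the statistical structure the caller
assumes: Poisson read counts with shared multiplicative bin biases, fragment
sizes drawn from a maternal/fetal two-component mixture, a fetal-fraction
parameter, and copy-number events that perturb both signals.

The size mixture is calibrated numerically so that at the cohort-default
fetal fraction (7.5%) the overall truncated-at-zero mixture has mean 173 bp
and SD 56 bp.  The maternal/fetal component gap defaults to 45 bp, which at
that fetal fraction yields a ~1.5 bp chromosome-wide shift on a trisomic
chromosome (shift = (ff' - ff) * gap with ff' = 3ff/(2+ff)).

Simulation happens at bin level so 400-control cohorts run in seconds; a
small read-level SAM emitter exists only for alignment-filter fixtures.
"""
from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .binning import BinGrid, BinnedSample

COHORT_FF = 0.075
TARGET_SIZE_MEAN = 173.0
TARGET_SIZE_SD = 56.0
DEFAULT_SIZE_GAP = 45.0  # maternal minus fetal component mean, bp

#: fragments per 750 kb bin at 0.25x coverage with 2x36 bp read pairs
COVERAGE_025X_750KB = 0.25 * 750_000 / 72


def miniature_grid(
    n_chroms: int = 22,
    chrom_length: int = 60_000_000,
    bin_size: int = 750_000,
    special: dict[int, int] | None = None,
) -> BinGrid:
    """A pseudo-genome grid: ``n_chroms`` chromosomes named chr1..chrN.

    ``special`` overrides individual chromosome lengths by 1-based number,
    e.g. ``{21: 45_000_000}``.
    """
    lengths = [chrom_length] * n_chroms
    for num, ln in (special or {}).items():
        lengths[num - 1] = ln
    return BinGrid(
        tuple(f"chr{i}" for i in range(1, n_chroms + 1)),
        tuple(lengths),
        bin_size,
    )


@functools.lru_cache(maxsize=None)
def calibrate_mixture(
    gap: float = DEFAULT_SIZE_GAP,
    ff: float = COHORT_FF,
    target_mean: float = TARGET_SIZE_MEAN,
    target_sd: float = TARGET_SIZE_SD,
) -> tuple[float, float]:
    """Solve for (maternal mean, component SD) so the truncated-at-zero
    two-normal mixture at fetal fraction ``ff`` has the target moments.

    The truncation correction is small (~0.2 bp on the mean) but larger than
    the acceptance band at n = 1e6 draws, so it is solved for exactly using
    truncated-normal component moments.
    """

    def mixture_moments(mu_m: float, sigma: float) -> tuple[float, float]:
        mean = var_plus_sq = 0.0
        for w, mu in ((1.0 - ff, mu_m), (ff, mu_m - gap)):
            a = (0.0 - mu) / sigma
            m, v = sps.truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
            mean += w * float(m)
            var_plus_sq += w * (float(v) + float(m) ** 2)
        return mean, np.sqrt(var_plus_sq - mean**2)

    def residual(p):
        m, s = mixture_moments(p[0], p[1])
        return [m - target_mean, s - target_sd]

    guess = [target_mean + ff * gap, np.sqrt(target_sd**2 - ff * (1 - ff) * gap**2)]
    sol = optimize.fsolve(residual, guess, xtol=1e-12)
    check = residual(sol)
    if max(abs(c) for c in check) > 1e-6:
        raise RuntimeError(f"mixture calibration failed to converge: {check}")
    return float(sol[0]), float(sol[1])


@dataclass(frozen=True)
class CNVSpec:
    """A planted event: whole span [start_bp, end_bp) on one chromosome."""

    chrom: str
    start_bp: int
    end_bp: int
    kind: str = "gain"  # "gain" (3 fetal copies) | "loss" (1 fetal copy)

    @property
    def fetal_copy_factor(self) -> float:
        return 1.5 if self.kind == "gain" else 0.5


@dataclass(frozen=True)
class SimParams:
    grid: BinGrid
    n_controls: int = 50
    n_cases: int = 1
    coverage: float = COVERAGE_025X_750KB  # mean fragments per full-width bin
    ff: float | tuple[float, float] = COHORT_FF  # scalar or Uniform(lo, hi)
    size_gap: float = DEFAULT_SIZE_GAP
    mu_maternal: float | None = None  # None -> calibrated
    sigma_fs: float | None = None  # None -> calibrated
    n_bias: int = 2
    bias_magnitude: float = 0.05
    fs_bias_magnitude: float = 1.0  # bp
    cnv: CNVSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        ffs = self.ff if isinstance(self.ff, tuple) else (self.ff, self.ff)
        if not all(0 < f < 1 for f in ffs):
            raise ValueError("fetal fraction must lie in (0, 1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.size_gap < 0:
            raise ValueError("size_gap must be non-negative")
        if self.sigma_fs is not None and self.sigma_fs <= 0:
            raise ValueError("sigma_fs must be positive")

    @property
    def components(self) -> tuple[float, float, float]:
        """(maternal mean, fetal mean, component SD), calibrated if needed."""
        if self.mu_maternal is None or self.sigma_fs is None:
            mu_m, sigma = calibrate_mixture(self.size_gap)
            mu_m = self.mu_maternal if self.mu_maternal is not None else mu_m
            sigma = self.sigma_fs if self.sigma_fs is not None else sigma
        else:
            mu_m, sigma = self.mu_maternal, self.sigma_fs
        return mu_m, mu_m - self.size_gap, sigma


def expected_count_ratio(ff: float, kind: str = "gain") -> float:
    """Affected/unaffected expected read-count ratio: 1 + ff/2 for a gain."""
    g = 1.5 if kind == "gain" else 0.5
    return 1.0 + ff * (g - 1.0)


def affected_fetal_fraction(ff: float, kind: str = "gain") -> float:
    """Fetal read fraction on the affected region: 3ff/(2+ff) for a gain."""
    g = 1.5 if kind == "gain" else 0.5
    return g * ff / ((1.0 - ff) + g * ff)


def expected_fs_shift(ff: float, size_gap: float, kind: str = "gain") -> float:
    """Expected mean fragment-size change on the affected region (bp,
    negative for a gain): -(ff' - ff) * gap."""
    return -(affected_fetal_fraction(ff, kind) - ff) * size_gap


def _bias_profiles(params: SimParams) -> tuple[np.ndarray, np.ndarray]:
    """Cohort-shared bias profiles, deterministic in params.seed."""
    rng = np.random.default_rng([params.seed, 0xB1A5])
    n = params.grid.n_bins
    count_profiles = rng.standard_normal((params.n_bias, n))
    fs_profiles = rng.standard_normal((params.n_bias, n))
    return count_profiles, fs_profiles


def draw_fragment_sizes(
    n: int,
    ff: float,
    params: SimParams,
    seed: int,
) -> np.ndarray:
    """Draw ``n`` fragment sizes from the maternal/fetal mixture (bp,
    truncated at 0), without bin bias.  Used for calibration checks."""
    mu_m, mu_f, sigma = params.components
    rng = np.random.default_rng([seed, 0x512E])
    n_fetal = rng.binomial(n, ff)
    sizes = np.concatenate(
        [
            _truncated_normal(rng, mu_m, sigma, n - n_fetal),
            _truncated_normal(rng, mu_f, sigma, n_fetal),
        ]
    )
    return rng.permutation(sizes)


def _truncated_normal(
    rng: np.random.Generator, mu: float, sigma: float, n: int
) -> np.ndarray:
    """Normal(mu, sigma) truncated at 0 via rejection resampling.

    Equivalent in distribution to scipy's truncnorm but much faster at the
    ~1e-3 rejection rates these parameters imply.
    """
    x = rng.normal(mu, sigma, n)
    bad = np.flatnonzero(x < 0)
    while bad.size:
        x[bad] = rng.normal(mu, sigma, bad.size)
        bad = bad[x[bad] < 0]
    return x


def _grouped_sums(values: np.ndarray, group_sizes: np.ndarray) -> np.ndarray:
    """Sum consecutive runs of ``values`` with lengths ``group_sizes``."""
    offsets = np.concatenate([[0], np.cumsum(group_sizes)[:-1]])
    if values.size == 0:
        return np.zeros(len(group_sizes))
    # reduceat misbehaves for empty trailing/repeated groups; clip and zero
    out = np.add.reduceat(values, np.minimum(offsets, values.size - 1))
    out[group_sizes == 0] = 0.0
    return out


def simulate_sample(
    params: SimParams,
    is_case: bool,
    seed: int,
    ff: float | None = None,
    sample_id: str | None = None,
) -> BinnedSample:
    """Generate one bin-level sample; deterministic under (params.seed, seed).

    Per bin: rate = coverage * width_fraction * exp(sum_k profile_k * s_k)
    * copy_factor, counts ~ Poisson(rate); each fragment is fetal with the
    bin's fetal fraction (elevated to ff' on gained regions) and its size is
    drawn from the corresponding truncated-normal component; a per-sample
    fragment-size bias offset is added per bin.
    """
    grid = params.grid
    if ff is None:
        ff = params.ff if not isinstance(params.ff, tuple) else sum(params.ff) / 2
    mu_m, mu_f, sigma = params.components
    rng = np.random.default_rng([params.seed, seed])

    count_profiles, fs_profiles = _bias_profiles(params)
    s = rng.normal(0.0, params.bias_magnitude, size=params.n_bias)
    u = rng.normal(0.0, params.fs_bias_magnitude, size=params.n_bias)
    bias = np.exp(count_profiles.T @ s) if params.n_bias else np.ones(grid.n_bins)
    fs_offset = fs_profiles.T @ u if params.n_bias else np.zeros(grid.n_bins)

    width_frac = (grid.bin_end - grid.bin_start) / grid.bin_size
    cn = np.ones(grid.n_bins)
    ff_bin = np.full(grid.n_bins, ff)
    if is_case and params.cnv is not None:
        c = params.cnv
        ci = grid.chrom_index[c.chrom]
        in_cnv = (
            (grid.bin_chrom == ci)
            & (grid.bin_start < c.end_bp)
            & (grid.bin_end > c.start_bp)
        )
        g = c.fetal_copy_factor
        cn[in_cnv] = 1.0 + ff * (g - 1.0)
        ff_bin[in_cnv] = affected_fetal_fraction(ff, c.kind)

    lam = params.coverage * width_frac * bias * cn
    counts = rng.poisson(lam)

    n_fetal = rng.binomial(counts, ff_bin)
    n_maternal = counts - n_fetal
    fs_sum = np.zeros(grid.n_bins)
    for n_by_bin, mu in ((n_maternal, mu_m), (n_fetal, mu_f)):
        draws = _truncated_normal(rng, mu, sigma, int(n_by_bin.sum()))
        fs_sum += _grouped_sums(draws, n_by_bin)
    fs_sum += counts * fs_offset  # shared per-bin size bias
    fs_sum[counts == 0] = 0.0

    if sample_id is None:
        sample_id = f"{'case' if is_case else 'ctrl'}_{seed}"
    return BinnedSample(sample_id, grid, counts, fs_sum, counts.copy())


@dataclass
class SimTruth:
    """Per-sample ground truth emitted alongside a simulated cohort."""

    sample_id: str
    is_case: bool
    ff: float
    chrom: str | None
    start_bp: int | None
    end_bp: int | None
    kind: str | None
    expected_count_ratio: float | None
    expected_fs_shift: float | None


def simulate_cohort(
    params: SimParams,
) -> tuple[list[BinnedSample], list[BinnedSample], list[SimTruth]]:
    """Generate ``n_controls`` controls plus ``n_cases`` cases and a truth
    table.  Case fetal fractions are drawn from Uniform(lo, hi) when
    ``params.ff`` is a (lo, hi) tuple.  Byte-identical under a fixed seed."""
    rng = np.random.default_rng([params.seed, 0xC0407])
    controls, cases, truth = [], [], []
    for i in range(params.n_controls):
        s = simulate_sample(params, False, seed=1000 + i)
        controls.append(s)
        truth.append(
            SimTruth(s.sample_id, False, _scalar_ff(params, rng=None), None, None, None, None, None, None)
        )
    for j in range(params.n_cases):
        ff = _scalar_ff(params, rng)
        s = simulate_sample(params, True, seed=2000 + j, ff=ff)
        cases.append(s)
        c = params.cnv
        truth.append(
            SimTruth(
                s.sample_id,
                True,
                ff,
                c.chrom if c else None,
                c.start_bp if c else None,
                c.end_bp if c else None,
                c.kind if c else None,
                expected_count_ratio(ff, c.kind) if c else None,
                expected_fs_shift(ff, params.size_gap, c.kind) if c else None,
            )
        )
    return controls, cases, truth


def _scalar_ff(params: SimParams, rng: np.random.Generator | None) -> float:
    if isinstance(params.ff, tuple):
        lo, hi = params.ff
        if rng is None:
            return (lo + hi) / 2
        return float(rng.uniform(lo, hi))
    return float(params.ff)


def truth_to_frame(truth: Sequence[SimTruth]) -> pd.DataFrame:
    return pd.DataFrame([t.__dict__ for t in truth])


# ---------------------------------------------------------------------------
# read-level toy SAM emitter (for alignment-filter fixtures only)


def write_toy_sam(
    path: str | Path,
    pairs: Sequence[dict],
    chrom_lengths: dict[str, int] | None = None,
) -> None:
    """Write a minimal SAM file from pair descriptions.

    Each pair dict takes: chrom, start1, start2 (0-based), and optionally
    mapq1/mapq2 (default 30), proper (default True), secondary (default
    False), name.  Reads are 36 bp, forward/reverse oriented.
    """
    chrom_lengths = chrom_lengths or {"chr1": 10_000_000}
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for c, ln in chrom_lengths.items():
        lines.append(f"@SQ\tSN:{c}\tLN:{ln}")
    read_len = 36
    seq = "A" * read_len
    qual = "I" * read_len
    for k, p in enumerate(pairs):
        name = p.get("name", f"pair{k}")
        chrom = p.get("chrom", "chr1")
        s1, s2 = p["start1"], p["start2"]
        q1, q2 = p.get("mapq1", 30), p.get("mapq2", 30)
        proper = p.get("proper", True)
        secondary = p.get("secondary", False)
        flag1 = 0x1 | 0x40 | 0x20  # paired, first, mate reverse
        flag2 = 0x1 | 0x80 | 0x10  # paired, second, reverse
        if proper:
            flag1 |= 0x2
            flag2 |= 0x2
        if secondary:
            flag1 |= 0x100
            flag2 |= 0x100
        tlen = s2 + read_len - s1
        for flag, start, mapq, t in ((flag1, s1, q1, tlen), (flag2, s2, q2, -tlen)):
            mate_start = s2 if start == s1 else s1
            lines.append(
                "\t".join(
                    [
                        name,
                        str(flag),
                        chrom,
                        str(start + 1),  # SAM is 1-based
                        str(mapq),
                        f"{read_len}M",
                        "=",
                        str(mate_start + 1),
                        str(t),
                        seq,
                        qual,
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")
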