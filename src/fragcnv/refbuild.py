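"""Reference construction from a panel of negative controls.

From control samples on a shared grid this module: normalizes read counts,
derives the global usability mask, trains one PCA bias model per datatype
(read count and fragment size, in parallel), and for every usable bin finds
its K most similar bins on *other* chromosomes — similarity being the
Euclidean distance between the two bins' across-control vectors.  The result
is a :class:`ReferenceSet` that any query sample on the same grid can be
scored against.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .binning import BinGrid, BinnedSample

logger = logging.getLogger(__name__)

READ_COUNT = "read_count"
FRAGMENT_SIZE = "fragment_size"
DATATYPES = (READ_COUNT, FRAGMENT_SIZE)

DEFAULT_K = 300
DEFAULT_N_COMP = 5
DEFAULT_MASK_MIN_FRAC = 0.1
DEFAULT_MASK_ZERO_FRAC = 0.1
WEIGHT_EPS = 1e-9


@dataclass
class ControlPanel:
    """Negative-control samples sharing one grid."""

    samples: list[BinnedSample]

    def __post_init__(self) -> None:
        if len(self.samples) < 2:
            raise ValueError("a control panel needs at least 2 samples")
        h = self.samples[0].grid.grid_hash
        if any(s.grid.grid_hash != h for s in self.samples):
            raise ValueError("all panel samples must share one grid")

    @property
    def n_controls(self) -> int:
        return len(self.samples)

    @property
    def grid(self) -> BinGrid:
        return self.samples[0].grid

    def count_matrix(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Samples x bins matrix of normalized counts (full bin length)."""
        return np.stack([normalize_counts(s, mask) for s in self.samples])

    def fs_matrix(self) -> np.ndarray:
        """Samples x bins matrix of per-bin mean fragment sizes.

        NaN where a sample has no fragments in a bin or its fs_mask is
        cleared there.
        """
        rows = []
        for s in self.samples:
            m = s.fs_mean
            rows.append(np.where(s.fs_mask, m, np.nan))
        return np.stack(rows)


def normalize_counts(
    binned: BinnedSample | np.ndarray,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Counts divided by the total over unmasked bins (sums to 1 there).

    Masked bins are set to 0.  Scale-invariant: doubling all counts leaves
    the output unchanged.
    """
    counts = binned.counts if isinstance(binned, BinnedSample) else np.asarray(binned)
    counts = counts.astype(np.float64)
    if mask is None:
        mask = np.ones(counts.shape, dtype=bool)
    total = counts[mask].sum()
    if total <= 0:
        raise ValueError("cannot normalize: zero total count over unmasked bins")
    out = np.zeros_like(counts)
    out[mask] = counts[mask] / total
    return out


def build_global_mask(
    panel: ControlPanel,
    mask_min_frac: float = DEFAULT_MASK_MIN_FRAC,
    mask_zero_frac: float = DEFAULT_MASK_ZERO_FRAC,
) -> np.ndarray:
    """Per-bin usability mask (True = usable) derived from the panel.

    A bin is masked out when its median normalized coverage across controls
    falls below ``mask_min_frac`` times the genome-wide median, or when it is
    zero in more than ``mask_zero_frac`` of the controls.  Deterministic
    given the panel.  Such bins typically sit at centromeres or repeats.
    """
    raw = np.stack(
        [s.counts / max(s.counts.sum(), 1) for s in panel.samples]
    )
    med = np.median(raw, axis=0)
    genome_med = np.median(med)
    zero_frac = (raw == 0).mean(axis=0)
    usable = (med >= mask_min_frac * genome_med) & (zero_frac <= mask_zero_frac)
    logger.info("global mask: %d/%d bins usable", int(usable.sum()), usable.size)
    return usable


@dataclass
class BiasModel:
    """Mean + principal-component bias subspace for one datatype.

    Trained on the control panel over the bins in ``support``; applies only
    to samples on the same grid/support.
    """

    datatype: str
    support: np.ndarray  # full-length bool; bins the model covers
    mean_vector: np.ndarray  # length support.sum()
    components: np.ndarray  # (n_comp, support.sum()), orthonormal rows

    @property
    def n_comp(self) -> int:
        return self.components.shape[0]


def fit_bias_model(
    panel: ControlPanel,
    datatype: str,
    n_comp: int = DEFAULT_N_COMP,
    mask: np.ndarray | None = None,
) -> BiasModel:
    """Train the PCA bias model for one datatype on the panel.

    For ``read_count`` the training matrix holds normalized counts over the
    masked-in bins; for ``fragment_size`` it holds per-bin mean fragment
    sizes, excluding any bin where some control has no usable fragment-size
    signal.  Components are the top right-singular vectors of the
    column-centered matrix, with a deterministic sign convention.
    """
    if datatype not in DATATYPES:
        raise ValueError(f"unknown datatype {datatype!r}")
    if n_comp < 0:
        raise ValueError("n_comp must be >= 0")
    if n_comp >= panel.n_controls:
        raise ValueError(
            f"n_comp={n_comp} requires more than {panel.n_controls} controls"
        )
    if mask is None:
        mask = np.ones(panel.grid.n_bins, dtype=bool)
    if datatype == READ_COUNT:
        X_full = panel.count_matrix(mask)
        support = mask.copy()
    else:
        X_full = panel.fs_matrix()
        support = mask & np.all(np.isfinite(X_full), axis=0)
    X = X_full[:, support]
    mean = X.mean(axis=0)
    comps = np.empty((0, X.shape[1]))
    if n_comp > 0:
        Xc = X - mean
        _, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
        k = min(n_comp, Vt.shape[0])
        comps = Vt[:k].copy()
        for row in comps:  # sign convention: largest-|.| element positive
            if row[np.argmax(np.abs(row))] < 0:
                row *= -1
    return BiasModel(datatype, support, mean, comps)


def apply_bias_correction(sample_vector: np.ndarray, model: BiasModel) -> np.ndarray:
    """Remove the model's bias subspace from a sample vector.

    ``sample_vector`` is either full bin length (subset by the model's
    support) or already in support space.  Returns the support-space vector
    with its projection onto the component subspace removed and the mean
    restored: signal outside the bias subspace is preserved.
    """
    v = np.asarray(sample_vector, dtype=np.float64)
    nsup = int(model.support.sum())
    if v.shape == model.support.shape:
        v = v[model.support]
    elif v.shape != (nsup,):
        raise ValueError(
            f"vector length {v.shape} matches neither grid ({model.support.size}) "
            f"nor support ({nsup})"
        )
    r = v - model.mean_vector
    if model.n_comp:
        r = r - model.components.T @ (model.components @ r)
    return model.mean_vector + r


@dataclass
class DatatypeReference:
    """Neighbor table for one datatype: per usable query bin, the K nearest
    bins on other chromosomes plus inverse-distance weights."""

    model: BiasModel
    query_bins: np.ndarray  # full-bin indices, one row per entry below
    neighbors: np.ndarray  # (n_query, K) full-bin indices, -1 padded
    weights: np.ndarray  # (n_query, K), rows sum to 1 over valid entries

    def row_of(self, bin_index: int) -> int:
        pos = np.searchsorted(self.query_bins, bin_index)
        if pos == len(self.query_bins) or self.query_bins[pos] != bin_index:
            raise KeyError(f"bin {bin_index} has no reference entry")
        return int(pos)


def build_reference(
    panel: ControlPanel,
    datatype: str,
    K: int = DEFAULT_K,
    model: BiasModel | None = None,
    mask: np.ndarray | None = None,
    n_comp: int = DEFAULT_N_COMP,
) -> DatatypeReference:
    """Rank, per usable query bin, all usable bins on other chromosomes by
    Euclidean distance between their across-control vectors; keep the K
    nearest with weights proportional to 1/(d+eps), normalized.

    Distances are computed on bias-corrected control values.  Ties are broken
    by lower bin index; if fewer than K candidates exist, all are kept (with
    a warning).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    grid = panel.grid
    if mask is None:
        mask = build_global_mask(panel)
    if model is None:
        model = fit_bias_model(panel, datatype, n_comp=n_comp, mask=mask)
    if datatype == READ_COUNT:
        X_full = panel.count_matrix(mask)
    else:
        X_full = panel.fs_matrix()
    X = np.stack(
        [apply_bias_correction(row[model.support], model) for row in X_full]
    )  # controls x support bins

    sup_idx = np.flatnonzero(model.support)
    cols = X.T  # support bins x controls
    D = cdist(cols, cols)
    chrom = grid.bin_chrom[sup_idx]
    same_chrom = chrom[:, None] == chrom[None, :]
    D[same_chrom] = np.inf

    if len(sup_idx):
        min_candidates = int((~same_chrom).sum(axis=1).min())
        if min_candidates < K:
            logger.warning(
                "fewer than K=%d candidates available (min %d); keeping all",
                K,
                min_candidates,
            )

    order = np.argsort(D, axis=1, kind="stable")  # stable -> ties by bin index
    n_q = len(sup_idx)
    neighbors = np.full((n_q, K), -1, dtype=np.int64)
    weights = np.zeros((n_q, K), dtype=np.float64)
    for i in range(n_q):
        sel = order[i]
        sel = sel[np.isfinite(D[i, sel])][:K]
        d = D[i, sel]
        w = 1.0 / (d + WEIGHT_EPS)
        w /= w.sum()
        neighbors[i, : len(sel)] = sup_idx[sel]
        weights[i, : len(sel)] = w
    return DatatypeReference(model, sup_idx, neighbors, weights)


@dataclass
class ReferenceSet:
    """The full two-datatype reference: grid, global mask, per-datatype bias
    models and neighbor tables, and the parameters used to build them."""

    grid: BinGrid
    mask: np.ndarray
    K: int
    references: dict[str, DatatypeReference]
    params: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        payload: dict[str, np.ndarray | int | str] = {
            "format_version": 1,
            "grid_hash": self.grid.grid_hash,
            "chrom_order": np.asarray(self.grid.chrom_order),
            "chrom_lengths": np.asarray(self.grid.chrom_lengths, dtype=np.int64),
            "bin_size": self.grid.bin_size,
            "mask": self.mask,
            "K": self.K,
            "param_keys": np.asarray(sorted(self.params)),
            "param_vals": np.asarray(
                [str(self.params[k]) for k in sorted(self.params)]
            ),
        }
        for dt, ref in self.references.items():
            payload[f"{dt}_support"] = ref.model.support
            payload[f"{dt}_mean"] = ref.model.mean_vector
            payload[f"{dt}_components"] = ref.model.components
            payload[f"{dt}_query_bins"] = ref.query_bins
            payload[f"{dt}_neighbors"] = ref.neighbors
            payload[f"{dt}_weights"] = ref.weights
        np.savez_compressed(path, **payload)

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceSet":
        with np.load(path, allow_pickle=False) as z:
            grid = BinGrid(
                tuple(str(c) for c in z["chrom_order"]),
                tuple(int(l) for l in z["chrom_lengths"]),
                int(z["bin_size"]),
            )
            if str(z["grid_hash"]) != grid.grid_hash:
                raise ValueError(f"grid hash mismatch in {path}")
            refs = {}
            for dt in DATATYPES:
                if f"{dt}_support" not in z:
                    continue
                model = BiasModel(
                    dt,
                    z[f"{dt}_support"],
                    z[f"{dt}_mean"],
                    z[f"{dt}_components"],
                )
                refs[dt] = DatatypeReference(
                    model,
                    z[f"{dt}_query_bins"],
                    z[f"{dt}_neighbors"],
                    z[f"{dt}_weights"],
                )
            params = {
                str(k): str(v) for k, v in zip(z["param_keys"], z["param_vals"])
            }
            return cls(grid, z["mask"], int(z["K"]), refs, params)


def build_reference_set(
    panel: ControlPanel,
    K: int = DEFAULT_K,
    n_comp: int = DEFAULT_N_COMP,
    mask_min_frac: float = DEFAULT_MASK_MIN_FRAC,
    mask_zero_frac: float = DEFAULT_MASK_ZERO_FRAC,
) -> ReferenceSet:
    """End-to-end reference construction: mask, both bias models, both
    neighbor tables.  The two datatypes are processed independently and may
    select different neighbors."""
    mask = build_global_mask(panel, mask_min_frac, mask_zero_frac)
    refs = {}
    for dt in DATATYPES:
        model = fit_bias_model(panel, dt, n_comp=n_comp, mask=mask)
        refs[dt] = build_reference(panel, dt, K=K, model=model, mask=mask)
    params = {
        "K": K,
        "n_comp": n_comp,
        "mask_min_frac": mask_min_frac,
        "mask_zero_frac": mask_zero_frac,
        "n_controls": panel.n_controls,
    }
    return ReferenceSet(panel.grid, mask, K, refs, params)
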