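"""Adaptive band-pair selection and thresholded functional-brain-network construction.

For every ROI pair the dependence measure (|CCC| or MI) is evaluated over
all unordered frequency-band combinations (k <= l, the first ROI taking
band k) and the maximising combination is retained -- the band-adaptive
edge weight.  CCC edges carry Monte Carlo permutation p-values; MI edge
matrices are min-max normalised per subject (NMI).  Thresholding first
zeroes non-significant CCC edges (p >= alpha) and then keeps only edges at
or above the t-quantile of the surviving nonzero weights (Heaviside
gating, with a weight equal to the quantile surviving).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import (
    MiEstimatorConfig,
    MiMatrix,
    _linear_binning,
    _mi_from_joint,
    _permutation_indices,
    mutual_information,
    normalize_mi_matrix,
    view_signal,
)
from .errors import DegenerateInputError, InvalidArgumentError
from .wavelet import WaveletDecomposition

__all__ = [
    "EdgeEstimate",
    "Fbn",
    "RawFbn",
    "PermutationConfig",
    "best_band_pair",
    "build_raw_fbn",
    "apply_threshold",
    "band_response_histogram",
    "DEFAULT_THRESHOLD_GRID",
]

DEFAULT_THRESHOLD_GRID = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 0.99)


@dataclass
class EdgeEstimate:
    """Best band combination and measure value for one ROI pair (i < j).

    band_k / band_l are 1-based band indices; band_k is the band assigned
    to roi_i, band_l the band assigned to roi_j.
    """

    roi_i: int
    roi_j: int
    band_k: int
    band_l: int
    value: float
    p_value: float | None = None


@dataclass
class PermutationConfig:
    """Monte Carlo significance settings for CCC edges."""

    n_iter: int = 1000
    alpha: float = 0.05
    scheme: str = "permute"
    seed: int = 0


@dataclass
class RawFbn:
    """Un-thresholded adaptive network: weights, p-values and selected bands."""

    weights: np.ndarray
    band_k: np.ndarray
    band_l: np.ndarray
    p_values: np.ndarray | None
    method: str
    roi_labels: list[str] = field(default_factory=list)
    subject_id: str = ""


@dataclass
class Fbn:
    """Thresholded symmetric n x n network with zero diagonal."""

    weights: np.ndarray
    method: str
    threshold_t: float
    alpha: float | None = None
    roi_labels: list[str] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise InvalidArgumentError("FBN weights must be square")
        if not np.allclose(w, w.T):
            raise InvalidArgumentError("FBN weights must be symmetric")
        self.weights = w

    @property
    def n_edges(self) -> int:
        """Number of surviving (nonzero) upper-triangle edges."""
        iu = np.triu_indices(self.weights.shape[0], k=1)
        return int(np.count_nonzero(self.weights[iu]))


def _band_pair_mask(a: int, include_same_band: bool) -> np.ndarray:
    """Boolean (a, a) mask of admissible (k, l) combinations, k <= l."""
    mask = np.triu(np.ones((a, a), dtype=bool), k=0 if include_same_band else 1)
    if not mask.any():
        raise InvalidArgumentError("band-pair search space is empty")
    return mask


def _argmax_band_pair(values: np.ndarray, mask: np.ndarray) -> tuple[int, int, float]:
    """First (row-major) maximiser over masked entries: ties -> smallest k then l."""
    masked = np.where(mask, values, -np.inf)
    flat = int(np.argmax(masked))  # row-major => smallest k, then smallest l
    k, l = divmod(flat, values.shape[1])
    return k, l, float(values[k, l])


def _normalized_complex_rows(coeffs: np.ndarray) -> np.ndarray:
    """Centre and L2-normalise each (roi, band) coefficient row."""
    centred = coeffs - coeffs.mean(axis=-1, keepdims=True)
    norms = np.sqrt(np.sum(np.abs(centred) ** 2, axis=-1, keepdims=True))
    if np.any(norms == 0):
        raise DegenerateInputError("constant wavelet coefficient row")
    return centred / norms


class _MiScanCache:
    """Per-(roi, band) KDE ingredients reused across all band-pair scans."""

    def __init__(self, dec: WaveletDecomposition, cfg: MiEstimatorConfig):
        self.cfg = cfg
        self.sig = view_signal(dec.coeffs, cfg)  # (n, a, m)
        n_sig = self.sig.shape[-1]
        if cfg.bandwidth_rule == "silverman":
            self.h = 1.06 * np.std(self.sig, axis=-1, ddof=1) * n_sig ** (-1 / 5)
        else:
            self.h = np.full(self.sig.shape[:2], float(cfg.bandwidth_h))
        if np.any(self.h <= 0):
            raise DegenerateInputError("constant coefficient signal in MI scan")
        G = cfg.grid_points
        lo = self.sig.min(axis=-1) - 3 * self.h
        hi = self.sig.max(axis=-1) + 3 * self.h
        steps = (hi - lo) / (G - 1)
        self.grids = lo[..., None] + steps[..., None] * np.arange(G)

    def mi(self, i: int, k: int, j: int, l: int) -> float:
        from scipy.signal import fftconvolve

        cfg = self.cfg
        x, y = self.sig[i, k], self.sig[j, l]
        hx, hy = self.h[i, k], self.h[j, l]
        gx, gy = self.grids[i, k], self.grids[j, l]
        if cfg.kernel_cov == "matched" and cfg.bandwidth_rule == "silverman":
            r = float(np.clip(np.corrcoef(x, y)[0, 1], -0.999, 0.999))
        else:
            r = 0.0
        dx = gx[1] - gx[0]
        dy = gy[1] - gy[0]
        u = (np.arange(-int(np.ceil(4 * hx / dx)), int(np.ceil(4 * hx / dx)) + 1) * dx)[:, None]
        v = (np.arange(-int(np.ceil(4 * hy / dy)), int(np.ceil(4 * hy / dy)) + 1) * dy)[None, :]
        quad = (u**2 / hx**2 - 2 * r * u * v / (hx * hy) + v**2 / hy**2) / (1 - r**2)
        kernel = np.exp(-0.5 * quad) / (2 * np.pi * hx * hy * np.sqrt(1 - r**2))
        counts = _linear_binning(x, y, gx, gy)
        joint = np.clip(fftconvolve(counts, kernel, mode="same") / x.size, 0.0, None)
        return _mi_from_joint(joint, gx, gy)


def best_band_pair(
    dec: WaveletDecomposition,
    roi_i: int,
    roi_j: int,
    measure: str = "ccc",
    mi_cfg: MiEstimatorConfig | None = None,
    include_same_band: bool = True,
) -> EdgeEstimate:
    """Exhaustive search for the band combination maximising the measure.

    Scans unordered band pairs (k <= l), band k on roi_i and band l on
    roi_j, including k = l unless ``include_same_band`` is False; ties are
    broken by the smallest k, then the smallest l.  Band indices in the
    returned estimate are 1-based.
    """
    n, a = dec.n_rois, dec.n_bands
    for roi in (roi_i, roi_j):
        if not 0 <= roi < n:
            raise InvalidArgumentError(f"ROI index {roi} out of range [0, {n})")
    if roi_i == roi_j:
        raise InvalidArgumentError("roi_i and roi_j must differ")
    if measure not in ("ccc", "nmi"):
        raise InvalidArgumentError(f"unknown measure {measure!r}")
    mask = _band_pair_mask(a, include_same_band)

    if measure == "ccc":
        zi = _normalized_complex_rows(dec.coeffs[roi_i])
        zj = _normalized_complex_rows(dec.coeffs[roi_j])
        values = np.abs(zi @ zj.conj().T)
    else:
        mi_cfg = mi_cfg or MiEstimatorConfig()
        sig = view_signal(dec.coeffs, mi_cfg)
        values = np.full((a, a), -np.inf)
        ks, ls = np.nonzero(mask)
        for k, l in zip(ks, ls):
            values[k, l] = mutual_information(sig[roi_i, k], sig[roi_j, l], mi_cfg)
    k, l, value = _argmax_band_pair(values, mask)
    return EdgeEstimate(roi_i=roi_i, roi_j=roi_j, band_k=k + 1, band_l=l + 1, value=value)


def build_raw_fbn(
    dec: WaveletDecomposition,
    measure: str = "ccc",
    mi_cfg: MiEstimatorConfig | None = None,
    perm_cfg: PermutationConfig | None = None,
    include_same_band: bool = True,
) -> RawFbn:
    """Band-adaptive dependence matrix over all ROI pairs of one subject.

    Every upper-triangle ROI pair gets its best band combination; the
    matrix is mirrored to the lower triangle.  With ``measure="ccc"`` and a
    :class:`PermutationConfig`, permutation p-values are computed at each
    pair's selected band combination (one shared set of surrogate
    permutations per subject).  With ``measure="nmi"`` the resulting MI
    matrix is min-max normalised over this subject's off-diagonal entries.
    """
    if measure not in ("ccc", "nmi"):
        raise InvalidArgumentError(f"unknown measure {measure!r}")
    n, a, m = dec.coeffs.shape
    mask = _band_pair_mask(a, include_same_band)
    weights = np.zeros((n, n))
    band_k = np.zeros((n, n), dtype=int)
    band_l = np.zeros((n, n), dtype=int)
    p_values: np.ndarray | None = None

    if measure == "ccc":
        z = _normalized_complex_rows(dec.coeffs.reshape(n * a, m)).reshape(n, a, m)
        gram = np.abs(np.einsum("ikm,jlm->ijkl", z, z.conj()))
        if perm_cfg is not None:
            p_values = np.zeros((n, n))
            rng = np.random.default_rng(perm_cfg.seed)
            idx = _permutation_indices(m, perm_cfg.n_iter, perm_cfg.scheme, rng)
        for i in range(n):
            for j in range(i + 1, n):
                k, l, value = _argmax_band_pair(gram[i, j], mask)
                weights[i, j] = weights[j, i] = value
                band_k[i, j] = band_k[j, i] = k + 1
                band_l[i, j] = band_l[j, i] = l + 1
                if perm_cfg is not None:
                    null = np.abs(z[j, l][idx] @ z[i, k].conj())
                    p = (1 + np.count_nonzero(null >= value)) / (1 + perm_cfg.n_iter)
                    p_values[i, j] = p_values[j, i] = p
    else:
        cache = _MiScanCache(dec, mi_cfg or MiEstimatorConfig())
        ks, ls = np.nonzero(mask)
        for i in range(n):
            for j in range(i + 1, n):
                values = np.full((a, a), -np.inf)
                for k, l in zip(ks, ls):
                    values[k, l] = cache.mi(i, k, j, l)
                k, l, value = _argmax_band_pair(values, mask)
                weights[i, j] = weights[j, i] = value
                band_k[i, j] = band_k[j, i] = k + 1
                band_l[i, j] = band_l[j, i] = l + 1
        weights = normalize_mi_matrix(MiMatrix(weights)).values

    return RawFbn(
        weights=weights,
        band_k=band_k,
        band_l=band_l,
        p_values=p_values,
        method="CCCf" if measure == "ccc" else "NMIf",
        roi_labels=list(dec.roi_labels),
        subject_id=dec.subject_id,
    )


def apply_threshold(
    raw: RawFbn | np.ndarray,
    t: float,
    alpha: float = 0.05,
    p_values: np.ndarray | None = None,
) -> Fbn:
    """Significance gating followed by percentile (Heaviside) thresholding.

    Step 1: where p-values are available, edges with p >= alpha are zeroed.
    Step 2: v_t is the t-quantile (linear interpolation) of the surviving
    nonzero upper-triangle weights; edges below v_t are removed, edges at
    or above v_t keep their weight.  t = 0 retains every surviving edge.
    """
    if not 0.0 <= t <= 1.0:
        raise InvalidArgumentError(f"threshold fraction t must be in [0, 1], got {t}")
    if isinstance(raw, RawFbn):
        weights = raw.weights
        p_values = raw.p_values if p_values is None else p_values
        method, labels, subject = raw.method, raw.roi_labels, raw.subject_id
    else:
        weights = np.asarray(raw, dtype=float)
        method, labels, subject = "unknown", [], ""
    w = np.array(weights, dtype=float)
    if p_values is not None:
        w[np.asarray(p_values) >= alpha] = 0.0
    np.fill_diagonal(w, 0.0)
    iu = np.triu_indices(w.shape[0], k=1)
    surviving = w[iu]
    nonzero = surviving[surviving > 0]
    if nonzero.size:
        vt = np.quantile(nonzero, t)
        w[w < vt] = 0.0
    return Fbn(
        weights=w,
        method=method,
        threshold_t=float(t),
        alpha=alpha if p_values is not None else None,
        roi_labels=labels,
        subject_id=subject,
    )


def band_response_histogram(raws: list[RawFbn], n_bands: int | None = None) -> np.ndarray:
    """How often each band index was selected across all edges and subjects.

    Both ends of every selected combination are counted once, so a
    same-band pair (k, k) contributes 2 to band k and the counts sum to
    2 x (edges x subjects).  Returns counts for bands 1..a.
    """
    if not raws:
        raise InvalidArgumentError("empty cohort")
    a = n_bands or max(int(r.band_l.max()) for r in raws)
    counts = np.zeros(a, dtype=int)
    for raw in raws:
        iu = np.triu_indices(raw.weights.shape[0], k=1)
        for bands in (raw.band_k[iu], raw.band_l[iu]):
            counts += np.bincount(bands - 1, minlength=a)[:a]
    return counts
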