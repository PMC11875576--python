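"""Synthetic multi-subject ROI cohorts with known band-limited couplings.

Each ROI signal is background noise (white or 1/f^beta) plus planted
components.  A *linear* edge adds the same narrowband source (band-pass
filtered Gaussian noise centred on a band frequency) to both ROIs, giving
a linear correlation visible to CCC.  A *nonlinear* edge couples two ROIs
so that the linear correlation vanishes but mutual information does not:
"quadratic" adds the standardised square of the source's band component to
the target (zero linear correlation by the symmetry of the square),
"envelope" amplitude-modulates a carrier at a different frequency with the
source's envelope.  Group-difference edges exist only in group 1, giving
the two classes distinguishable networks.  Everything is deterministic
given the seed, and the planted structure is returned as ground truth.

Coupling ``strength`` is the standard deviation of the planted component
relative to the unit-variance background, so strength s corresponds to a
broadband SNR (planted/background variance ratio) of s^2.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import InvalidArgumentError
from .timeseries import RoiTimeSeries
from .wavelet import WaveletConfig, band_frequencies

__all__ = [
    "LinearEdge",
    "NonlinearEdge",
    "SyntheticConfig",
    "GroundTruth",
    "Cohort",
    "generate_cohort",
    "write_cohort",
    "fast_preset",
    "study_preset",
]

# Spectral width (cycles/sample) of a planted narrowband source: about one
# fifth of the default inter-band spacing, so a coupling stays band-resolved.
NARROWBAND_SIGMA = 0.005


@dataclass(frozen=True)
class LinearEdge:
    roi_i: int
    roi_j: int
    band: int  # 1-based band index
    strength: float


@dataclass(frozen=True)
class NonlinearEdge:
    roi_i: int  # source ROI (must have the lower index for band scans k <= l)
    roi_j: int  # target ROI
    band: int  # 1-based source band index
    kind: str  # "quadratic" or "envelope"
    strength: float
    carrier_band: int | None = None  # envelope only; defaults to band + 3 (clipped)


@dataclass
class SyntheticConfig:
    """Shape, background and planted couplings of a synthetic cohort."""

    n_per_group: int = 20
    n_rois: int = 20
    n_timepoints: int = 80
    tr: float = 3.0
    background: str = "white"  # or "one_over_f"
    background_exponent: float = 1.0
    band_freqs: np.ndarray | None = None  # cycles/sample; default = analysis grid
    narrowband_sigma: float = NARROWBAND_SIGMA
    nonlinear_sigma: float = 2 * NARROWBAND_SIGMA
    linear_edges: list[LinearEdge] = field(default_factory=list)
    nonlinear_edges: list[NonlinearEdge] = field(default_factory=list)
    group_diff_edges: list[LinearEdge | NonlinearEdge] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1 or self.n_rois < 2 or self.n_timepoints < 8:
            raise InvalidArgumentError("cohort dimensions too small")
        if self.background not in ("white", "one_over_f"):
            raise InvalidArgumentError(f"unknown background {self.background!r}")
        if self.band_freqs is None:
            self.band_freqs = band_frequencies(WaveletConfig())
        self.band_freqs = np.asarray(self.band_freqs, dtype=float)
        if np.any(self.band_freqs >= 0.5):
            raise InvalidArgumentError("planted band frequency at or above Nyquist (0.5 cycles/sample)")
        for e in self.all_edges():
            if not (0 <= e.roi_i < self.n_rois and 0 <= e.roi_j < self.n_rois):
                raise InvalidArgumentError(f"edge {e} references an invalid ROI")
            if e.roi_i == e.roi_j:
                raise InvalidArgumentError(f"edge {e} is a self-loop")
            if not (1 <= e.band <= len(self.band_freqs)):
                raise InvalidArgumentError(f"edge {e} references an invalid band")
            if not (0.0 <= e.strength <= 1.0):
                raise InvalidArgumentError(f"edge {e} strength outside [0, 1]")
            if isinstance(e, NonlinearEdge):
                if e.kind not in ("quadratic", "envelope"):
                    raise InvalidArgumentError(f"unknown nonlinear kind {e.kind!r}")
                if e.kind == "quadratic" and 2 * self.band_freqs[e.band - 1] >= 0.5:
                    raise InvalidArgumentError(
                        f"quadratic edge {e}: harmonic 2f at or above Nyquist"
                    )

    def all_edges(self):
        return [*self.linear_edges, *self.nonlinear_edges, *self.group_diff_edges]


@dataclass
class GroundTruth:
    """Planted structure, for evaluating recovery by the pipeline."""

    edges: list[dict]
    seed: int

    def to_json(self) -> str:
        return json.dumps({"seed": self.seed, "edges": self.edges}, indent=2)


@dataclass
class Cohort:
    subjects: list[RoiTimeSeries]
    labels: np.ndarray  # 0 = group 0 (control-like), 1 = group 1
    ground_truth: GroundTruth


def _narrowband(m: int, freq: float, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance real noise with a Gaussian spectral window around freq.

    Linear couplings use a narrow window (band-resolved); nonlinear
    couplings use a wider one so the envelope, which carries the
    dependence, varies within the record.
    """
    fr = np.fft.rfftfreq(m, d=1.0)
    spec = (rng.standard_normal(fr.size) + 1j * rng.standard_normal(fr.size)) * np.exp(
        -0.5 * ((fr - freq) / sigma) ** 2
    )
    s = np.fft.irfft(spec, m)
    return _standardized(s)


def _bandpass(x: np.ndarray, freq: float, sigma: float) -> np.ndarray:
    """Gaussian band-pass of a real signal around freq (cycles/sample)."""
    fr = np.fft.rfftfreq(x.size, d=1.0)
    window = np.exp(-0.5 * ((fr - freq) / sigma) ** 2)
    return np.fft.irfft(np.fft.rfft(x) * window, x.size)


def _standardized(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise InvalidArgumentError("degenerate planted component")
    return (x - x.mean()) / sd


def _background(m: int, n: int, cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal((m, n))
    if cfg.background == "white":
        return noise
    fr = np.fft.rfftfreq(m, d=1.0)
    shape = np.ones_like(fr)
    shape[1:] = fr[1:] ** (-cfg.background_exponent / 2.0)
    shape[0] = 0.0
    shaped = np.fft.irfft(np.fft.rfft(noise, axis=0) * shape[:, None], m, axis=0)
    return (shaped - shaped.mean(axis=0)) / shaped.std(axis=0)


def _apply_edge(
    data: np.ndarray, edge, cfg: SyntheticConfig, rng: np.random.Generator
) -> None:
    from scipy.signal import hilbert

    m = data.shape[0]
    f = cfg.band_freqs[edge.band - 1]
    sigma = cfg.narrowband_sigma if isinstance(edge, LinearEdge) else cfg.nonlinear_sigma
    s = _narrowband(m, f, sigma, rng)
    if isinstance(edge, LinearEdge):
        data[:, edge.roi_i] += edge.strength * s
        data[:, edge.roi_j] += edge.strength * s
        return
    data[:, edge.roi_i] += edge.strength * s
    if edge.kind == "quadratic":
        # keep only the 2f harmonic of the square (A^2 cos 2phi): the slow
        # envelope-squared baseband would otherwise bleed into low analysis
        # bands; the harmonic alone is still linearly uncorrelated with s
        # but shares its envelope, so MI sees it and CCC does not
        harmonic = _bandpass(s**2, 2 * f, 2 * cfg.nonlinear_sigma)
        data[:, edge.roi_j] += edge.strength * _standardized(harmonic)
    else:  # envelope
        a = len(cfg.band_freqs)
        carrier_band = edge.carrier_band or min(edge.band + 3, a)
        fc = cfg.band_freqs[carrier_band - 1]
        envelope = np.abs(hilbert(s))
        phase = rng.uniform(0, 2 * np.pi)
        carrier = np.cos(2 * np.pi * fc * np.arange(m) + phase)
        data[:, edge.roi_j] += edge.strength * _standardized(envelope * carrier)


def generate_cohort(cfg: SyntheticConfig) -> Cohort:
    """Draw the full two-group cohort described by ``cfg``.

    Group 0 subjects carry the shared linear and nonlinear edges; group 1
    subjects additionally carry ``group_diff_edges``.  Subjects are
    independent realisations; the planted edge list, not the noise, is
    what the groups share.
    """
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(2 * cfg.n_per_group)
    subjects: list[RoiTimeSeries] = []
    labels = np.repeat([0, 1], cfg.n_per_group)
    for idx, (child, label) in enumerate(zip(children, labels)):
        rng = np.random.default_rng(child)
        data = _background(cfg.n_timepoints, cfg.n_rois, cfg, rng)
        for edge in [*cfg.linear_edges, *cfg.nonlinear_edges]:
            _apply_edge(data, edge, cfg, rng)
        for edge in cfg.group_diff_edges:
            # draw the source even for group 0 so both groups consume the
            # same random stream, then discard it for group 0
            snapshot = data.copy()
            _apply_edge(data, edge, cfg, rng)
            if label == 0:
                data = snapshot
        group = "g1" if label else "g0"
        subjects.append(
            RoiTimeSeries(subject_id=f"{group}_{idx:03d}", data=data, tr=cfg.tr)
        )
    records = []
    for edge in cfg.all_edges():
        rec = asdict(edge)
        rec["coupling"] = "linear" if isinstance(edge, LinearEdge) else edge.kind
        rec["group_specific"] = edge in cfg.group_diff_edges
        records.append(rec)
    return Cohort(subjects=subjects, labels=labels, ground_truth=GroundTruth(records, cfg.seed))


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write per-subject CSVs, a manifest CSV and the ground-truth JSON.

    Values are written with 10 significant digits; reading the files back
    through :func:`wavefbn.cohort_io.read_cohort` reproduces the matrices
    to that precision.  Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = ["subject_id,path,label,tr_seconds"]
    for ts, label in zip(cohort.subjects, cohort.labels):
        fname = f"{ts.subject_id}.csv"
        header = ",".join(ts.roi_labels)
        np.savetxt(out / fname, ts.data, fmt="%.10g", delimiter=",", header=header, comments="")
        rows.append(f"{ts.subject_id},{fname},{int(label)},{ts.tr:g}")
    manifest = out / "manifest.csv"
    manifest.write_text("\n".join(rows) + "\n")
    (out / "ground_truth.json").write_text(cohort.ground_truth.to_json() + "\n")
    return manifest


def fast_preset(effect: str = "strong", seed: int = 0) -> SyntheticConfig:
    """Small cohort (20 ROIs, 20 + 20 subjects, 80 points at TR = 3 s).

    "strong" plants clearly separable group differences (six linear and two
    quadratic group-specific edges at strength 0.8 on top of four shared
    edges); "null" plants no edges at all.
    """
    if effect == "null":
        return SyntheticConfig(seed=seed)
    if effect != "strong":
        raise InvalidArgumentError(f"unknown effect preset {effect!r}")
    shared = [
        LinearEdge(0, 1, 2, 0.8),
        LinearEdge(2, 3, 5, 0.8),
        LinearEdge(4, 5, 8, 0.8),
        NonlinearEdge(6, 7, 3, "quadratic", 0.8),
    ]
    group = [
        LinearEdge(8, 9, 2, 0.8),
        LinearEdge(10, 11, 4, 0.8),
        LinearEdge(12, 13, 6, 0.8),
        LinearEdge(14, 15, 8, 0.8),
        LinearEdge(16, 17, 3, 0.8),
        LinearEdge(18, 19, 5, 0.8),
        NonlinearEdge(8, 11, 2, "quadratic", 0.8),
        NonlinearEdge(12, 15, 4, "quadratic", 0.8),
    ]
    return SyntheticConfig(
        linear_edges=[e for e in shared if isinstance(e, LinearEdge)],
        nonlinear_edges=[e for e in shared if isinstance(e, NonlinearEdge)],
        group_diff_edges=list(group),
        seed=seed,
    )


def study_preset(seed: int = 0) -> SyntheticConfig:
    """Cohort at the scale of the motivating study: 90 ROIs, 45 + 46-like groups.

    Uses 45 subjects per group (balanced), 80 time points at TR = 3 s, ten
    planted linear edges and four nonlinear ones, a third of them
    group-specific.
    """
    rng = np.random.default_rng(seed)
    rois = rng.choice(90, size=28, replace=False)
    linear = [
        LinearEdge(int(min(a, b)), int(max(a, b)), int(band), 0.8)
        for (a, b), band in zip(rois[:20].reshape(10, 2), rng.integers(1, 11, 10))
    ]
    nonlinear = [
        NonlinearEdge(int(min(a, b)), int(max(a, b)), int(band), "quadratic", 0.8)
        for (a, b), band in zip(rois[20:].reshape(4, 2), rng.integers(1, 6, 4))
    ]
    return SyntheticConfig(
        n_per_group=45,
        n_rois=90,
        linear_edges=linear[:7],
        nonlinear_edges=nonlinear[:3],
        group_diff_edges=[*linear[7:], *nonlinear[3:]],
        seed=seed,
    )
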