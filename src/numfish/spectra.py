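"""Spatial-frequency content of stimulus images: radial spectra and total power.

A stimulus image can be summarised by how much energy it carries at each
spatial frequency.  The procedure: 2-D FFT of the grayscale image, modulus
(amplitude) centred on the zero-frequency component, radial average over
annuli of equal width, then summation of the per-bin values into a scalar
"total power".  Two comparison arrays yield a normalised *total power index*

    TPI = (TP_large - TP_small) / (TP_large + TP_small)  in [-1, 1],

which can be correlated with behavioural accuracy per control condition.

Options are explicit because the summary is convention-sensitive: the DC
bin (mean luminance, not pattern) is excluded by default, and the radially
averaged quantity is the amplitude |F| by default with |F|^2 available via
``use_power_not_amplitude``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SpectrumSummary",
    "PowerIndex",
    "SpectrumOptions",
    "amplitude_spectrum",
    "radial_average",
    "total_power",
    "image_total_power",
    "total_power_index",
    "accuracy_spectrum_correlation",
]


@dataclass(frozen=True)
class SpectrumOptions:
    """Conventions used to reduce a 2-D spectrum to a scalar."""

    dc_included: bool = False
    use_power_not_amplitude: bool = False
    n_bins: int | None = None  # None: one bin per integer radius


@dataclass(frozen=True)
class SpectrumSummary:
    """Radially averaged spectrum: bin centres, per-bin means, and options."""

    radial_freq_bins: np.ndarray  # bin-centre radius in frequency samples
    mean_amplitude_per_bin: np.ndarray
    options: SpectrumOptions

    @property
    def n_bins(self) -> int:
        return len(self.radial_freq_bins)


@dataclass(frozen=True)
class PowerIndex:
    """Normalised total-power difference between the two arrays of a pair."""

    tp_large: float
    tp_small: float
    index: float


def amplitude_spectrum(image: np.ndarray) -> np.ndarray:
    """Modulus of the 2-D discrete Fourier transform, DC centred.

    Requires a square image (rescaling is outside this function's contract).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError(f"expected a square 2-D image, got shape {img.shape}")
    if img.shape[0] < 2:
        raise ValueError("image side must be >= 2")
    return np.abs(np.fft.fftshift(np.fft.fft2(img)))


def radial_average(
    amplitude: np.ndarray, n_bins: int | None = None
) -> SpectrumSummary:
    """Average a centred 2-D spectrum over annuli of equal radial width.

    Each coefficient is assigned to an annulus by its integer-rounded radius
    from the DC position; with ``n_bins=None`` every integer radius gets its
    own bin (bin width = 1 frequency sample, the default convention).
    """
    amp = np.asarray(amplitude, dtype=float)
    side = amp.shape[0]
    cy, cx = side // 2, side // 2  # fftshift puts DC here
    yy, xx = np.indices(amp.shape)
    r = np.rint(np.hypot(yy - cy, xx - cx)).astype(int)
    r_max = int(r.max())
    if n_bins is None:
        n_bins = r_max + 1
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    width = (r_max + 1) / n_bins
    idx = np.minimum((r / width).astype(int), n_bins - 1)
    sums = np.bincount(idx.ravel(), weights=amp.ravel(), minlength=n_bins)
    counts = np.bincount(idx.ravel(), minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    # for unit-width bins the "centre" is the integer radius itself
    centers = np.arange(n_bins) * width
    return SpectrumSummary(
        radial_freq_bins=centers,
        mean_amplitude_per_bin=means,
        options=SpectrumOptions(n_bins=n_bins),
    )


def total_power(
    summary: SpectrumSummary, options: SpectrumOptions | None = None
) -> float:
    """Sum the radial profile into a scalar total power.

    The DC bin (lowest-frequency annulus, which contains the zero-frequency
    coefficient) is excluded unless ``options.dc_included``.
    """
    options = options or SpectrumOptions()
    values = summary.mean_amplitude_per_bin
    if not options.dc_included:
        values = values[1:]
    return float(np.sum(values))


def image_total_power(
    image: np.ndarray, options: SpectrumOptions | None = None
) -> float:
    """Total power of an image under the given options (one-stop pipeline)."""
    options = options or SpectrumOptions()
    amp = amplitude_spectrum(image)
    if options.use_power_not_amplitude:
        amp = amp**2
    summary = radial_average(amp, options.n_bins)
    return total_power(summary, options)


def total_power_index(tp_large: float, tp_small: float) -> PowerIndex:
    """Normalised difference (TP_large - TP_small)/(TP_large + TP_small)."""
    total = tp_large + tp_small
    if total == 0:
        raise ValueError("total power index undefined when both powers are zero")
    return PowerIndex(
        tp_large=tp_large,
        tp_small=tp_small,
        index=(tp_large - tp_small) / total,
    )


def accuracy_spectrum_correlation(
    accuracy_by_condition: np.ndarray, index_by_condition: np.ndarray
) -> tuple[float, int, float]:
    """Pearson correlation between per-condition accuracy and power index.

    Returns ``(r, df, p)`` with ``df = n - 2`` and the two-sided p-value
    from the t-transform of r.
    """
    x = np.asarray(accuracy_by_condition, dtype=float)
    y = np.asarray(index_by_condition, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), len(x) - 2, float(res.pvalue)
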