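"""Canonical double-gamma hemodynamic response function.

The kernel is the difference of two gamma densities — a positive response
lobe and a delayed undershoot — parameterized directly by the quantities the
analyses care about: time of the response peak, its dispersion (the gamma
SD), and the undershoot ratio. The dispersion relates to the peak full width
at half maximum through the Gaussian factor 2*sqrt(2*ln 2).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

#: FWHM of a unit-SD Gaussian.
FWHM_PER_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))

DEFAULT_PEAK_S = 5.0
DEFAULT_DISP_S = 1.0
DEFAULT_UNDER_PEAK_S = 15.0
DEFAULT_UNDER_RATIO = 1.0 / 6.0


def _gamma_from_mode_sd(mode: float, sd: float) -> tuple[float, float]:
    """Shape/scale of a gamma density with the given mode and SD.

    mode = (k-1)*theta and SD = sqrt(k)*theta give
    theta**2 + mode*theta - sd**2 = 0.
    """
    if mode <= 0 or sd <= 0:
        raise ValueError("mode and sd must be positive")
    theta = (-mode + np.sqrt(mode**2 + 4.0 * sd**2)) / 2.0
    k = mode / theta + 1.0
    return k, theta


def double_gamma(
    t: np.ndarray,
    time_to_peak: float = DEFAULT_PEAK_S,
    peak_disp: float = DEFAULT_DISP_S,
    undershoot_ratio: float = DEFAULT_UNDER_RATIO,
    undershoot_peak: float = DEFAULT_UNDER_PEAK_S,
    undershoot_disp: float | None = None,
) -> np.ndarray:
    """Double-gamma HRF evaluated at times ``t`` (s), normalized to peak 1.

    Negative times map to 0. ``undershoot_disp`` defaults to twice the
    response dispersion, giving the broad late undershoot of the canonical
    shape.
    """
    t = np.asarray(t, dtype=float)
    if undershoot_disp is None:
        undershoot_disp = 2.0 * peak_disp
    k1, th1 = _gamma_from_mode_sd(time_to_peak, peak_disp)
    k2, th2 = _gamma_from_mode_sd(undershoot_peak, undershoot_disp)
    pos = stats.gamma.pdf(t, k1, scale=th1)
    und = stats.gamma.pdf(t, k2, scale=th2)
    # scale undershoot so its peak is undershoot_ratio times the main peak
    peak1 = stats.gamma.pdf(time_to_peak, k1, scale=th1)
    peak2 = stats.gamma.pdf(undershoot_peak, k2, scale=th2)
    h = pos / peak1 - undershoot_ratio * und / peak2
    h = np.where(t < 0, 0.0, h)
    return h


def hrf_peak_time(
    time_to_peak: float,
    peak_disp: float,
    undershoot_ratio: float = DEFAULT_UNDER_RATIO,
) -> float:
    """Actual argmax of the double-gamma shape (the undershoot shifts the
    peak slightly earlier than the positive lobe's mode)."""
    t = np.linspace(max(0.0, time_to_peak - 3 * peak_disp),
                    time_to_peak + 3 * peak_disp, 2001)
    h = double_gamma(t, time_to_peak, peak_disp, undershoot_ratio)
    return float(t[np.argmax(h)])


def disp_to_fwhm(peak_disp: float) -> float:
    """Convert a gamma-dispersion (SD, seconds) to the FWHM of the
    equivalent Gaussian peak: fwhm = 2*sqrt(2*ln 2) * peak_disp."""
    if not peak_disp > 0:
        raise ValueError("peak_disp must be positive")
    return FWHM_PER_SD * float(peak_disp)
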