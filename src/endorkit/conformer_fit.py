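"""Spectrum processing and the two-conformer superposition fit.

An experimental 19F ENDOR dataset is a set of spectra acquired at several
observer positions and tau values.  Two candidate conformers (a "stacked"
and a "flipped" arrangement of the fluorotyrosine relative to the radical)
are each simulated under every acquisition setting; the single mixing
fraction f of the flipped conformer is then scanned on a grid and the
root-mean-square deviation between mixture and data, summed over all
spectra (one global parameter set), locates the best ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .endor_sim import (
    AcquisitionSettings,
    Spectrum,
    _require_common_axis,
    normalize,
    simulate_mims_endor,
)
from .spin_models import SpinSystem

__all__ = [
    "ConformerEnsemble",
    "FitResult",
    "subtract_reference",
    "smooth_savitzky_golay",
    "mix_spectra",
    "rmsd",
    "fit_fraction",
    "fit_fraction_precomputed",
]


@dataclass(frozen=True)
class ConformerEnsemble:
    """Named conformers with a mixing fraction for the second (flipped) one."""

    conformers: tuple[tuple[str, SpinSystem], ...]
    fraction_flipped: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "conformers", tuple(self.conformers))
        if not 0.0 <= self.fraction_flipped <= 1.0:
            raise ValueError(f"fraction must be in [0, 1], got {self.fraction_flipped}")

    @property
    def labels(self):
        return [lab for lab, _ in self.conformers]

    @property
    def systems(self):
        return [sys for _, sys in self.conformers]

    def require_pair(self):
        if len(self.conformers) < 2:
            raise ValueError("a conformer-ratio fit needs at least 2 conformers")
        return self.conformers[0][1], self.conformers[1][1]


@dataclass
class FitResult:
    """Outcome of the global one-parameter ratio fit."""

    fraction: float
    rmsd_min: float
    fractions: np.ndarray
    rmsd_curve: np.ndarray
    uncertainty: float
    normalization: str = "max"

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fitted fraction outside [0, 1]")

    def uncertainty_interval(self, factor: float = 1.05):
        """Fraction interval where the rmsd curve stays below factor x minimum."""
        ok = self.rmsd_curve <= factor * self.rmsd_curve.min()
        return float(self.fractions[ok].min()), float(self.fractions[ok].max())


def subtract_reference(spectrum: Spectrum, reference: Spectrum, mask=None) -> Spectrum:
    """Remove a scaled contaminant/background reference spectrum.

    The scale c is fitted by least squares over ``mask`` (boolean array on
    the common axis; default all points); the result records c in its
    metadata.
    """
    _require_common_axis(spectrum, reference, "subtract_reference")
    r = reference.intensity
    if not np.any(r != 0):
        raise ValueError("reference spectrum is identically zero")
    m = np.ones_like(r, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    denom = float(r[m] @ r[m])
    if denom == 0:
        raise ValueError("reference spectrum is zero on the fit mask")
    c = float(spectrum.intensity[m] @ r[m]) / denom
    return spectrum.copy_with(
        intensity=spectrum.intensity - c * r, metadata={"reference_scale": c}
    )


def smooth_savitzky_golay(spectrum: Spectrum, window: int, order: int) -> Spectrum:
    """Savitzky-Golay smoothing; polynomials up to ``order`` pass unchanged."""
    if window % 2 == 0 or window <= order or order < 0:
        raise ValueError(f"need odd window > order >= 0, got window={window} order={order}")
    y = savgol_filter(spectrum.intensity, window, order)
    return spectrum.copy_with(intensity=y, metadata={"smoothing": f"savgol({window},{order})"})


def mix_spectra(
    stacked: Spectrum, flipped: Spectrum, f: float, normalization: str = "max"
) -> Spectrum:
    """(1-f) x stacked + f x flipped, each normalized before mixing."""
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"mixing fraction must be in [0, 1], got {f}")
    _require_common_axis(stacked, flipped, "mix_spectra")
    s = normalize(stacked, normalization)
    fl = normalize(flipped, normalization)
    y = (1.0 - f) * s.intensity + f * fl.intensity
    return stacked.copy_with(
        intensity=y,
        metadata={"mixing_fraction": f, "normalization": normalization, "composed": "mixture"},
    )


def rmsd(sim: Spectrum, exp: Spectrum, window=None) -> float:
    """Root-mean-square pointwise deviation over the analysis window."""
    _require_common_axis(sim, exp, "rmsd")
    if window is None:
        m = np.ones_like(sim.intensity, dtype=bool)
    else:
        lo, hi = window
        m = (sim.axis_mhz >= lo) & (sim.axis_mhz <= hi)
    if not np.any(m):
        raise ValueError("empty analysis window")
    return float(np.sqrt(np.mean((sim.intensity[m] - exp.intensity[m]) ** 2)))


def _parabolic_refine(f_grid: np.ndarray, curve: np.ndarray, i: int) -> float:
    if 0 < i < len(f_grid) - 1:
        y0, y1, y2 = curve[i - 1], curve[i], curve[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom > 0:
            delta = 0.5 * (y0 - y2) / denom
            return float(np.clip(f_grid[i] + delta * (f_grid[1] - f_grid[0]), 0.0, 1.0))
    return float(f_grid[i])


def fit_fraction_precomputed(
    pairs: list[tuple[Spectrum, Spectrum, Spectrum]],
    grid_step: float = 0.01,
    normalization: str = "max",
    window=None,
) -> FitResult:
    """Global ratio fit from precomputed (stacked, flipped, experimental) triples.

    All spectra are normalized; the summed rmsd over every triple is scanned
    on a fraction grid and the minimum refined parabolically.  Deterministic.
    """
    if grid_step > 0.01:
        raise ValueError(f"grid step must be <= 0.01, got {grid_step}")
    if not pairs:
        raise ValueError("no spectra to fit")
    f_grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    curve = np.zeros_like(f_grid)
    for stacked, flipped, exp in pairs:
        exp_n = normalize(exp, normalization)
        for j, f in enumerate(f_grid):
            mix = mix_spectra(stacked, flipped, f, normalization)
            curve[j] += rmsd(normalize(mix, normalization), exp_n, window=window)
    i = int(np.argmin(curve))
    f_star = _parabolic_refine(f_grid, curve, i)
    ok = curve <= 1.05 * curve[i]
    width = float(f_grid[ok].max() - f_grid[ok].min())
    return FitResult(
        fraction=f_star,
        rmsd_min=float(curve[i] / len(pairs)),
        fractions=f_grid,
        rmsd_curve=curve / len(pairs),
        uncertainty=width / 2.0,
        normalization=normalization,
    )


def fit_fraction(
    exp_spectra: list[Spectrum],
    ensemble: ConformerEnsemble,
    settings_list: list[AcquisitionSettings] | None = None,
    grid_step: float = 0.01,
    normalization: str = "max",
    window=None,
) -> FitResult:
    """Fit the flipped-conformer fraction to a multi-setting ENDOR dataset.

    Each conformer is simulated under the acquisition settings of every
    experimental spectrum (taken from spectrum metadata when
    ``settings_list`` is omitted); a single fraction is fitted globally
    across all spectra.  Invariant to rescaling the experimental spectra.
    """
    stacked_sys, flipped_sys = ensemble.require_pair()
    if settings_list is None:
        settings_list = []
        for s in exp_spectra:
            try:
                settings_list.append(AcquisitionSettings.from_dict(s.metadata["settings"]))
            except KeyError:
                raise ValueError(
                    "experimental spectrum carries no acquisition settings; "
                    "pass settings_list explicitly"
                ) from None
    if len(settings_list) != len(exp_spectra):
        raise ValueError("need one settings entry per experimental spectrum")
    pairs = []
    for exp, st in zip(exp_spectra, settings_list):
        stacked = simulate_mims_endor(stacked_sys, st)
        flipped = simulate_mims_endor(flipped_sys, st)
        _require_common_axis(stacked, exp, "fit_fraction")
        pairs.append((stacked, flipped, exp))
    return fit_fraction_precomputed(
        pairs, grid_step=grid_step, normalization=normalization, window=window
    )
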