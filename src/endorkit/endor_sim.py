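"""Orientation-selective Mims ENDOR powder simulation.

First-order (high-field) treatment: at W band the 19F Larmor frequency
(~134 MHz) exceeds the couplings of interest (<= 2 MHz) by two orders of
magnitude, so the two ENDOR branches are

    nu(m_S = +-1/2) = | nu_n * l  -+  (1/2) A l |

with l the field direction in the g frame and A the hyperfine matrix.
Orientation selection enters through the anisotropic electron Zeeman
interaction (and strongly coupled nuclei, e.g. the beta proton of a tyrosyl
radical): each powder orientation is weighted by a Gaussian excitation
window around the observer field.  Mims ENDOR efficiency is
(1/2) sin^2(pi a tau) with a the orientation-dependent splitting, giving
blind spots at a * tau integer (including the center of the spectrum).

Everything is deterministic: a Fibonacci hemisphere grid, no RNG.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .spin_models import GTensor, SpinSystem, larmor_frequency, resonance_field

__all__ = [
    "AcquisitionSettings",
    "Spectrum",
    "orientation_grid",
    "effective_g",
    "selection_weight",
    "endor_frequencies",
    "mims_response",
    "simulate_mims_endor",
    "compose_observer_sum",
    "compose_tau_sum",
    "epr_envelope_weights",
    "observer_field",
    "normalize",
    "LINEWIDTH_SMALL_KHZ",
    "LINEWIDTH_LARGE_KHZ",
    "LINEWIDTH_THRESHOLD_KHZ",
]

#: ENDOR line width rule: 25 kHz FWHM below 0.5 MHz couplings, 250 kHz above
LINEWIDTH_SMALL_KHZ = 25.0
LINEWIDTH_LARGE_KHZ = 250.0
LINEWIDTH_THRESHOLD_KHZ = 500.0


@dataclass(frozen=True)
class AcquisitionSettings:
    """Mims ENDOR acquisition parameters.

    ``observer`` is either a named canonical position ("gx" | "gy" | "gz")
    translated to a field via the spin system's g value at the configured
    microwave frequency, or an explicit field in tesla.
    ``rf_half_span_mhz``/``rf_step_mhz`` define the RF offset axis relative
    to the Larmor frequency of ``reference_isotope``.
    """

    mw_frequency_ghz: float = 94.0
    observer: str | float = "gy"
    tau_ns: float = 236.0
    rf_half_span_mhz: float = 4.0
    rf_step_mhz: float = 0.008
    sigma_b_mt: float = 0.3
    n_orientations: int = 4000
    orientation_selection: bool = True
    reference_isotope: str = "19F"

    def __post_init__(self):
        if self.tau_ns <= 0:
            raise ValueError(f"tau must be > 0 ns, got {self.tau_ns}")
        if self.rf_step_mhz <= 0 or self.rf_half_span_mhz <= 0:
            raise ValueError("RF axis span and step must be > 0")
        if self.rf_step_mhz > LINEWIDTH_SMALL_KHZ / 1e3 / 3.0:
            raise ValueError(
                f"axis step {self.rf_step_mhz} MHz exceeds a third of the smallest "
                f"line width ({LINEWIDTH_SMALL_KHZ} kHz)"
            )

    def axis_mhz(self) -> np.ndarray:
        n = int(round(self.rf_half_span_mhz / self.rf_step_mhz))
        return np.arange(-n, n + 1) * self.rf_step_mhz

    def to_dict(self) -> dict:
        return {
            "mw_frequency_ghz": self.mw_frequency_ghz,
            "observer": self.observer,
            "tau_ns": self.tau_ns,
            "rf_half_span_mhz": self.rf_half_span_mhz,
            "rf_step_mhz": self.rf_step_mhz,
            "sigma_b_mt": self.sigma_b_mt,
            "n_orientations": self.n_orientations,
            "orientation_selection": self.orientation_selection,
            "reference_isotope": self.reference_isotope,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionSettings":
        return cls(**d)


@dataclass
class Spectrum:
    """A 1-D ENDOR spectrum on an RF-offset axis (MHz from nu_n)."""

    axis_mhz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.axis_mhz = np.asarray(self.axis_mhz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis_mhz.shape != self.intensity.shape:
            raise ValueError("axis and intensity must have the same shape")
        if np.any(np.diff(self.axis_mhz) <= 0):
            raise ValueError("spectrum axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("spectrum intensities must be finite")

    def copy_with(self, intensity=None, metadata=None) -> "Spectrum":
        md = dict(self.metadata)
        if metadata:
            md.update(metadata)
        return Spectrum(
            axis_mhz=self.axis_mhz.copy(),
            intensity=self.intensity.copy() if intensity is None else np.asarray(intensity, float),
            metadata=md,
        )


def _require_common_axis(a: Spectrum, b: Spectrum, what: str) -> None:
    if a.axis_mhz.shape != b.axis_mhz.shape or not np.allclose(
        a.axis_mhz, b.axis_mhz, rtol=0, atol=1e-9
    ):
        raise ValueError(f"{what}: spectra do not share a common axis")


def normalize(spectrum: Spectrum, mode: str = "max") -> Spectrum:
    """Return a max- or area-normalized copy (no-op for an all-zero spectrum)."""
    y = spectrum.intensity
    if mode == "max":
        scale = np.max(np.abs(y))
    elif mode == "area":
        scale = np.trapezoid(np.abs(y), spectrum.axis_mhz)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if scale == 0:
        return spectrum.copy_with(metadata={"normalization": mode})
    return spectrum.copy_with(intensity=y / scale, metadata={"normalization": mode})


def orientation_grid(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic ~equal-area hemisphere grid (Fibonacci lattice).

    Returns (n x 3 unit vectors, weights summing to 1).  A hemisphere
    suffices because both g and A enter quadratically.
    """
    if n < 100:
        raise ValueError(f"orientation grid needs n >= 100, got {n}")
    i = np.arange(n)
    z = (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    s = np.sqrt(1.0 - z**2)
    vecs = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    return vecs, np.full(n, 1.0 / n)


def effective_g(orientation: np.ndarray, g: GTensor) -> np.ndarray:
    """Effective g value(s) sqrt(sum (l_i g_i)^2) in the g principal frame."""
    l = np.atleast_2d(np.asarray(orientation, dtype=float))
    ge = np.sqrt((l**2 @ g.principal_values**2))
    return ge if ge.size > 1 else float(ge[0])


def observer_field(system: SpinSystem, settings: AcquisitionSettings) -> float:
    """Observer field in tesla for named (gx/gy/gz) or explicit positions."""
    obs = settings.observer
    if isinstance(obs, str):
        try:
            g_val = {"gx": system.g.gx, "gy": system.g.gy, "gz": system.g.gz}[obs]
        except KeyError:
            raise ValueError(f"unknown observer position {obs!r}; use gx, gy, gz or a field") from None
        return resonance_field(g_val, settings.mw_frequency_ghz)
    return float(obs)


def _resonance_fields_t(
    orientations: np.ndarray, system: SpinSystem, mw_ghz: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-orientation EPR resonance fields including strong-nucleus splittings.

    Returns (n_orient x n_branches fields in tesla, branch weights).  Each
    strongly coupled nucleus of spin I contributes 2I+1 equally weighted
    m_I branches shifting the resonance by m_I * A_eff / (g_eff mu_B / h).
    """
    from .constants import H_PLANCK, MU_B

    l = np.atleast_2d(orientations)
    ge = np.sqrt(l**2 @ system.g.principal_values**2)
    b_center = (
        H_PLANCK * mw_ghz * 1e9 / (MU_B * ge)
    )  # tesla, per orientation

    branch_shifts = [np.zeros((len(l), 1))]
    for nc in system.selection_nuclei():
        A = nc.tensor.matrix_khz() / 1e3  # MHz
        a_eff = np.linalg.norm(l @ A.T, axis=1)  # MHz, per orientation
        m_i = np.arange(-nc.nucleus.spin, nc.nucleus.spin + 1)
        shift_t = (
            a_eff[:, None] * m_i[None, :] * 1e6 * H_PLANCK / (MU_B * ge[:, None])
        )
        branch_shifts.append(shift_t)

    # combine branches across nuclei (outer sum)
    combo = branch_shifts[0]
    for s in branch_shifts[1:]:
        combo = (combo[:, :, None] + s[:, None, :]).reshape(len(l), -1)
    fields = b_center[:, None] + combo
    weights = np.full(combo.shape[1], 1.0 / combo.shape[1])
    return fields, weights


def selection_weight(
    orientations: np.ndarray,
    system: SpinSystem,
    b_obs_t: float,
    mw_ghz: float,
    sigma_b_mt: float,
) -> np.ndarray:
    """Gaussian excitation weight in [0, 1] for each orientation.

    Average over the m_I branches of the strongly coupled (selection-only)
    nuclei of exp(-(B_res - B_obs)^2 / (2 sigma_B^2)).
    """
    if sigma_b_mt <= 0:
        raise ValueError(f"sigma_B must be > 0 mT, got {sigma_b_mt}")
    fields, branch_w = _resonance_fields_t(orientations, system, mw_ghz)
    sigma_t = sigma_b_mt * 1e-3
    w = np.exp(-((fields - b_obs_t) ** 2) / (2.0 * sigma_t**2))
    return w @ branch_w


def endor_frequencies(
    orientations: np.ndarray, hyperfine_matrix_mhz: np.ndarray, nu_n_mhz: float
) -> tuple[np.ndarray, np.ndarray]:
    """First-order ENDOR branch frequencies (MHz) per orientation.

    nu(m_S = +-1/2) = |nu_n l -+ (1/2) A l| evaluated as a vector norm, so
    the pseudo-secular contribution to the nuclear effective field is kept.
    """
    if nu_n_mhz <= 0:
        raise ValueError(f"Larmor frequency must be > 0 MHz, got {nu_n_mhz}")
    l = np.atleast_2d(orientations)
    Al = l @ np.asarray(hyperfine_matrix_mhz).T
    nu_alpha = np.linalg.norm(nu_n_mhz * l - 0.5 * Al, axis=1)
    nu_beta = np.linalg.norm(nu_n_mhz * l + 0.5 * Al, axis=1)
    return nu_alpha, nu_beta


def mims_response(splitting_mhz, tau_ns):
    """Mims ENDOR efficiency (1/2) sin^2(pi a tau); blind at a*tau integer."""
    tau_ns = np.asarray(tau_ns, dtype=float)
    if np.any(tau_ns <= 0):
        raise ValueError("tau must be > 0 ns")
    a_tau = np.asarray(splitting_mhz, dtype=float) * tau_ns * 1e-3
    return 0.5 * np.sin(np.pi * a_tau) ** 2


def _deposit(axis: np.ndarray, values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    out = np.zeros_like(axis)
    step = axis[1] - axis[0]
    pos = (values - axis[0]) / step
    i0 = np.floor(pos).astype(int)
    frac = pos - i0
    ok = (i0 >= 0) & (i0 < len(axis) - 1)
    np.add.at(out, i0[ok], weights[ok] * (1.0 - frac[ok]))
    np.add.at(out, i0[ok] + 1, weights[ok] * frac[ok])
    return out


def linewidth_for(tensor) -> float:
    """Line width rule (kHz FWHM) based on the largest principal coupling."""
    return (
        LINEWIDTH_SMALL_KHZ
        if tensor.max_abs_khz < LINEWIDTH_THRESHOLD_KHZ
        else LINEWIDTH_LARGE_KHZ
    )


def simulate_mims_endor(system: SpinSystem, settings: AcquisitionSettings) -> Spectrum:
    """Powder Mims ENDOR spectrum of a spin system.

    For every orientation on a deterministic hemisphere grid, each
    ENDOR-active nucleus contributes two Gaussian-broadened sticks at its
    branch frequencies, weighted by solid angle, by the Gaussian orientation
    -selection window at the observer field, and by the Mims efficiency at
    the orientation-dependent splitting.  Peaks are placed on the offset
    axis relative to the Larmor frequency of the reference isotope, so
    nuclei of other isotopes (e.g. ring protons at long tau) appear at
    their true offsets in that window.  Selection-only nuclei shape the
    EPR envelope but contribute no peaks.
    """
    from .spin_models import NucleusSpec

    axis = settings.axis_mhz()
    b_obs = observer_field(system, settings)
    ref = NucleusSpec.from_isotope(settings.reference_isotope)
    nu_ref = larmor_frequency(ref, b_obs)

    orientations, solid_w = orientation_grid(settings.n_orientations)
    if settings.orientation_selection:
        sel = selection_weight(
            orientations, system, b_obs, settings.mw_frequency_ghz, settings.sigma_b_mt
        )
    else:
        sel = np.ones(len(orientations))
    base_w = solid_w * sel

    step = axis[1] - axis[0]
    total = np.zeros_like(axis)
    truncated = []
    for nc in system.endor_nuclei(settings.tau_ns):
        A_mhz = nc.tensor.matrix_khz() / 1e3
        nu_n = larmor_frequency(nc.nucleus, b_obs)
        nu_a, nu_b = endor_frequencies(orientations, A_mhz, nu_n)
        eff = mims_response(np.abs(nu_a - nu_b), settings.tau_ns)
        w = base_w * eff
        hist = np.zeros_like(axis)
        for nu in (nu_a, nu_b):
            offs = nu - nu_ref
            if np.any((offs < axis[0]) | (offs > axis[-1])):
                truncated.append(nc.label or nc.nucleus.isotope)
            hist += _deposit(axis, offs, w)
        lw = linewidth_for(nc.tensor)
        sigma_pts = lw / 1e3 / 2.354820045 / step
        total += gaussian_filter1d(hist, sigma_pts, mode="constant")

    if truncated:
        warnings.warn(
            f"peaks of nuclei {sorted(set(truncated))} fall outside the RF axis and were truncated",
            stacklevel=2,
        )
    return Spectrum(
        axis_mhz=axis,
        intensity=total,
        metadata={
            "settings": settings.to_dict(),
            "observer_field_t": b_obs,
            "species": system.label,
            "normalization": "none",
        },
    )


def compose_observer_sum(spectra: list[Spectrum], epr_weights) -> Spectrum:
    """Weighted sum of observer-position spectra.

    Weights reflect the EPR signal strength at each observer position; the
    result is divided by the weight sum and records the weights used.
    """
    w = np.asarray(epr_weights, dtype=float)
    if len(spectra) != len(w):
        raise ValueError("need one weight per spectrum")
    if np.any(w < 0) or np.all(w == 0):
        raise ValueError("weights must be >= 0 and not all zero")
    for s in spectra[1:]:
        _require_common_axis(spectra[0], s, "compose_observer_sum")
    y = sum(wi * s.intensity for wi, s in zip(w, spectra)) / w.sum()
    return spectra[0].copy_with(
        intensity=y,
        metadata={"observer_weights": [float(x) for x in w], "composed": "observer_sum"},
    )


def compose_tau_sum(spec_a: Spectrum, spec_b: Spectrum) -> Spectrum:
    """Scan-normalized average of two tau acquisitions.

    Blind spots of one tau are filled by the other; summing acquisitions at
    two nearby tau values attenuates coherent background features tuned to
    a single tau.
    """
    _require_common_axis(spec_a, spec_b, "compose_tau_sum")
    tau_a = spec_a.metadata.get("settings", {}).get("tau_ns")
    tau_b = spec_b.metadata.get("settings", {}).get("tau_ns")
    if tau_a is not None and tau_a == tau_b:
        warnings.warn(f"both spectra were acquired at tau = {tau_a} ns", stacklevel=2)
    y = 0.5 * (spec_a.intensity + spec_b.intensity)
    return spec_a.copy_with(
        intensity=y, metadata={"composed": "tau_sum", "tau_values_ns": [tau_a, tau_b]}
    )


def epr_envelope_weights(
    system: SpinSystem, settings_list: list[AcquisitionSettings]
) -> np.ndarray:
    """Relative EPR signal strength at each acquisition's observer field.

    Powder echo-detected EPR amplitude approximated by the same Gaussian
    excitation model as the orientation selection; used to weight
    observer-position spectra in :func:`compose_observer_sum`.
    """
    weights = []
    for st in settings_list:
        orientations, solid_w = orientation_grid(st.n_orientations)
        b_obs = observer_field(system, st)
        sel = selection_weight(
            orientations, system, b_obs, st.mw_frequency_ghz, st.sigma_b_mt
        )
        weights.append(float(np.sum(solid_w * sel)))
    return np.asarray(weights)
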