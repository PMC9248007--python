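"""Spin-Hamiltonian parameter containers.

The electron Zeeman interaction is described by a diagonal g tensor in its
own principal frame (the "g frame"); for a tyrosyl radical the convention is
x along the C-O(radical) bond, y in-plane perpendicular to it, z normal to
the ring.  Every hyperfine tensor is specified by its principal values (kHz)
plus z-y-z Euler angles (degrees, active rotation) that carry the A principal
frame into the g frame: the columns of ``Rz(alpha) @ Ry(beta) @ Rz(gamma)``
are the A principal axes expressed in g-frame coordinates.

Units: hyperfine couplings kHz, Larmor/axis frequencies MHz, fields tesla.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import (
    H_PLANCK,
    KNOWN_ISOTOPES,
    MU_B,
    MU_N,
    NUCLEAR_G,
    NUCLEAR_SPIN,
)

__all__ = [
    "GTensor",
    "NucleusSpec",
    "HyperfineTensor",
    "NucleusCoupling",
    "SpinSystem",
    "larmor_frequency",
    "resonance_field",
    "build_axial_hyperfine",
    "euler_rotation_matrix",
    "TYROSYL_G",
]


def euler_rotation_matrix(alpha_deg: float, beta_deg: float, gamma_deg: float) -> np.ndarray:
    """Active z-y-z rotation matrix Rz(alpha) @ Ry(beta) @ Rz(gamma)."""
    a, b, c = np.deg2rad([alpha_deg, beta_deg, gamma_deg])

    def rz(t):
        return np.array(
            [[np.cos(t), -np.sin(t), 0.0], [np.sin(t), np.cos(t), 0.0], [0.0, 0.0, 1.0]]
        )

    def ry(t):
        return np.array(
            [[np.cos(t), 0.0, np.sin(t)], [0.0, 1.0, 0.0], [-np.sin(t), 0.0, np.cos(t)]]
        )

    return rz(a) @ ry(b) @ rz(c)


@dataclass(frozen=True)
class GTensor:
    """Principal g values, ordered gx >= gy >= gz for tyrosyl radicals."""

    gx: float
    gy: float
    gz: float

    def __post_init__(self):
        if not (self.gx >= self.gy >= self.gz > 0):
            raise ValueError(
                f"expected gx >= gy >= gz > 0, got ({self.gx}, {self.gy}, {self.gz})"
            )

    @property
    def principal_values(self) -> np.ndarray:
        return np.array([self.gx, self.gy, self.gz])

    @property
    def isotropic(self) -> float:
        return (self.gx + self.gy + self.gz) / 3.0

    def to_dict(self) -> dict:
        return {"gx": self.gx, "gy": self.gy, "gz": self.gz}


#: g tensor of the Y356 tyrosyl radical (W-band characterization)
TYROSYL_G = GTensor(2.0062, 2.0044, 2.0022)


@dataclass(frozen=True)
class NucleusSpec:
    """An NMR-active nucleus: isotope label, g factor, spin quantum number."""

    isotope: str
    g_n: float
    spin: float

    @classmethod
    def from_isotope(cls, isotope: str) -> "NucleusSpec":
        if isotope not in NUCLEAR_G:
            raise KeyError(
                f"unknown isotope {isotope!r}; known isotopes: {', '.join(KNOWN_ISOTOPES)}"
            )
        return cls(isotope=isotope, g_n=NUCLEAR_G[isotope], spin=NUCLEAR_SPIN[isotope])

    @property
    def gamma_mhz_per_t(self) -> float:
        """Gyromagnetic ratio gamma/2pi in MHz/T (magnitude)."""
        return abs(self.g_n) * MU_N / H_PLANCK / 1e6

    def to_dict(self) -> dict:
        return {"isotope": self.isotope}


def larmor_frequency(nucleus: NucleusSpec, field_t: float) -> float:
    """Nuclear Larmor frequency nu_n = (gamma/2pi) * B0 in MHz.

    Linear in the field; ``field_t`` must be >= 0.
    """
    if field_t < 0:
        raise ValueError(f"field must be >= 0 T, got {field_t}")
    return nucleus.gamma_mhz_per_t * field_t


def resonance_field(g_eff: float, mw_frequency_ghz: float) -> float:
    """Electron resonance field B0 = h nu / (mu_B g_eff) in tesla."""
    if g_eff <= 0:
        raise ValueError(f"g_eff must be > 0, got {g_eff}")
    if mw_frequency_ghz <= 0:
        raise ValueError(f"mw_frequency must be > 0 GHz, got {mw_frequency_ghz}")
    return H_PLANCK * mw_frequency_ghz * 1e9 / (MU_B * g_eff)


@dataclass(frozen=True)
class HyperfineTensor:
    """Hyperfine tensor: principal values (kHz) + z-y-z Euler angles (deg).

    ``principal_khz`` are (Ax, Ay, Az); the isotropic part is the mean and
    the remainder is the traceless (dipolar) part.  For a purely dipolar
    axial tensor the principal values are (-T, -T, +2T) with the unique
    axis third.
    """

    principal_khz: tuple[float, float, float]
    euler_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def a_iso_khz(self) -> float:
        return float(np.mean(self.principal_khz))

    @property
    def dipolar_part_khz(self) -> np.ndarray:
        return np.asarray(self.principal_khz, dtype=float) - self.a_iso_khz

    @property
    def max_abs_khz(self) -> float:
        return float(np.max(np.abs(self.principal_khz)))

    def axial_decomposition(self, rtol: float = 1e-6) -> tuple[float, float]:
        """Return (T, a_iso) in kHz for an axial tensor (a-T, a-T, a+2T).

        Raises ValueError if the dipolar part is not axial about the third
        principal axis.
        """
        dip = self.dipolar_part_khz
        T = dip[2] / 2.0
        ref = np.array([-T, -T, 2.0 * T])
        tol = rtol * max(1.0, abs(T))
        if not np.allclose(dip, ref, atol=tol):
            raise ValueError(f"tensor is not axial about its third axis: dipolar part {dip}")
        return float(T), self.a_iso_khz

    def rotation(self) -> np.ndarray:
        return euler_rotation_matrix(*self.euler_deg)

    def matrix_khz(self) -> np.ndarray:
        """Full 3x3 tensor in the g frame (kHz)."""
        r = self.rotation()
        return r @ np.diag(self.principal_khz) @ r.T

    def to_dict(self) -> dict:
        return {
            "principal_khz": [float(v) for v in self.principal_khz],
            "euler_deg": [float(v) for v in self.euler_deg],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HyperfineTensor":
        return cls(
            principal_khz=tuple(float(v) for v in d["principal_khz"]),
            euler_deg=tuple(float(v) for v in d.get("euler_deg", (0.0, 0.0, 0.0))),
        )


def build_axial_hyperfine(
    T_khz: float,
    a_iso_khz: float = 0.0,
    unique_axis_angles_deg: tuple[float, float] = (0.0, 0.0),
) -> HyperfineTensor:
    """Axial hyperfine tensor (a-T, a-T, a+2T) kHz.

    ``unique_axis_angles_deg = (alpha, beta)`` are the azimuth/polar angles
    of the unique axis in the g frame (the axis is Rz(alpha) Ry(beta) z).
    """
    alpha, beta = unique_axis_angles_deg
    return HyperfineTensor(
        principal_khz=(a_iso_khz - T_khz, a_iso_khz - T_khz, a_iso_khz + 2.0 * T_khz),
        euler_deg=(float(alpha), float(beta), 0.0),
    )


@dataclass(frozen=True)
class NucleusCoupling:
    """One nucleus attached to the electron spin.

    ``endor_active``: the nucleus contributes ENDOR peaks.
    ``selection_only``: the nucleus only shapes the EPR envelope used for
    orientation selection (e.g. the strongly coupled beta proton).
    ``min_tau_ns``: ENDOR peaks are simulated only for tau >= this value
    (ring protons are conventionally included only in long-tau acquisitions).
    """

    nucleus: NucleusSpec
    tensor: HyperfineTensor
    label: str = ""
    endor_active: bool = True
    selection_only: bool = False
    min_tau_ns: float = 0.0

    def to_dict(self) -> dict:
        return {
            "isotope": self.nucleus.isotope,
            "label": self.label,
            "endor_active": self.endor_active,
            "selection_only": self.selection_only,
            "min_tau_ns": self.min_tau_ns,
            **self.tensor.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NucleusCoupling":
        return cls(
            nucleus=NucleusSpec.from_isotope(d["isotope"]),
            tensor=HyperfineTensor.from_dict(d),
            label=d.get("label", ""),
            endor_active=d.get("endor_active", True),
            selection_only=d.get("selection_only", False),
            min_tau_ns=d.get("min_tau_ns", 0.0),
        )


@dataclass(frozen=True)
class SpinSystem:
    """An electron spin (g tensor) plus its coupled nuclei."""

    g: GTensor
    nuclei: tuple[NucleusCoupling, ...] = field(default_factory=tuple)
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "nuclei", tuple(self.nuclei))

    def endor_nuclei(self, tau_ns: float | None = None):
        """Nuclei that contribute ENDOR peaks (optionally at a given tau)."""
        out = []
        for nc in self.nuclei:
            if not nc.endor_active or nc.selection_only:
                continue
            if tau_ns is not None and tau_ns < nc.min_tau_ns:
                continue
            out.append(nc)
        return out

    def selection_nuclei(self):
        """Strongly coupled nuclei that shape the EPR envelope."""
        return [nc for nc in self.nuclei if nc.selection_only]

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "g": self.g.to_dict(),
            "nuclei": [nc.to_dict() for nc in self.nuclei],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpinSystem":
        g = d["g"]
        return cls(
            g=GTensor(g["gx"], g["gy"], g["gz"]),
            nuclei=tuple(NucleusCoupling.from_dict(n) for n in d.get("nuclei", [])),
            label=d.get("label", ""),
        )
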