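"""Ground-truth synthetic inputs for the whole pipeline.

Real samples of the radical-transfer intermediate are not deposited as
spectra, so every analysis here runs on synthetic data with known truth:
idealized fluorotyrosine ring geometries, a stacked/flipped conformer pair
parameterized the way a quantum-chemistry-fed workflow would supply it,
multi-setting noisy 19F Mims ENDOR datasets, and PELDOR traces.

Defaults encode the study conditions: a two-conformer ensemble whose
flipped member represents 25% of the population, 19F couplings
(T_a ~ 1 MHz rhombic with a_iso ~ -1 MHz; T_b = 246, T_c = 159,
T_d = 83 kHz), three observer positions x two tau regimes, 5% additive
Gaussian noise, and a 3.03 nm / 0.12 nm FWHM interspin distance for the
DEER channel.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .conformer_fit import ConformerEnsemble, mix_spectra
from .dipolar_geometry import RingGeometry, dipolar_tensor_from_vector
from .endor_sim import (
    AcquisitionSettings,
    Spectrum,
    normalize,
    simulate_mims_endor,
)
from .peldor import DeerTrace, DistanceDistribution, default_r_grid, simulate_trace
from .spin_models import (
    TYROSYL_G,
    HyperfineTensor,
    NucleusCoupling,
    NucleusSpec,
    SpinSystem,
    build_axial_hyperfine,
)

__all__ = [
    "SyntheticTruth",
    "tyrosine_ring_coords",
    "build_conformer_pair",
    "default_settings_list",
    "generate_endor_dataset",
    "generate_deer_dataset",
    "beta_proton_coupling",
    "ring_proton_couplings",
]

# ring construction constants (A)
_CC = 1.39
_CO_RADICAL = 1.26
_CO_PHENOL = 1.38
_CF = 1.35
_CH = 1.08
_C_CB = 1.51


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters recorded alongside every generated dataset."""

    fraction_flipped: float = 0.25
    stacked_distances_a: tuple[float, float] = (8.4, 10.0)
    flipped_distances_a: tuple[float, float] = (4.6, 7.3)
    deer_mean_nm: float = 3.03
    deer_fwhm_nm: float = 0.12
    noise_sigma: float = 0.05
    contaminant_scale: float = 0.3
    seed: int = 2024

    def manifest(self, **extra) -> dict:
        d = asdict(self)
        d.update(extra)
        return d


def tyrosine_ring_coords(
    include_fluorines: bool = True, radical: bool = True
) -> RingGeometry:
    """Idealized planar (fluoro)tyrosine side chain in the g frame.

    The ring lies in the xy plane with the C4-O bond along +x (the g_x
    convention for a tyrosyl radical); C-C 1.39 A hexagon, C4-O 1.26 A for
    the radical (1.38 A otherwise), C-F 1.35 A at C3/C5 when fluorinated.
    """
    atoms: dict[str, np.ndarray] = {}
    angles = {"C1": 180.0, "C2": 120.0, "C3": 60.0, "C4": 0.0, "C5": -60.0, "C6": -120.0}
    for name, ang in angles.items():
        a = np.deg2rad(ang)
        atoms[name] = _CC * np.array([np.cos(a), np.sin(a), 0.0])

    def radial(name, bond):
        u = atoms[name] / np.linalg.norm(atoms[name])
        return atoms[name] + bond * u

    atoms["O"] = radial("C4", _CO_RADICAL if radical else _CO_PHENOL)
    atoms["CB"] = radial("C1", _C_CB)
    for pos in ("2", "6"):
        atoms[f"H{pos}"] = radial(f"C{pos}", _CH)
    for pos in ("3", "5"):
        if include_fluorines:
            atoms[f"F{pos}"] = radial(f"C{pos}", _CF)
        else:
            atoms[f"H{pos}"] = radial(f"C{pos}", _CH)
    geom = RingGeometry(atoms=atoms, label="fluorotyrosine" if include_fluorines else "tyrosine")
    geom.validate()
    return geom


def beta_proton_coupling() -> NucleusCoupling:
    """Strongly coupled beta-methylene proton of the tyrosyl radical.

    Shapes the EPR envelope (hence orientation selection) but lies far
    outside the 19F RF window; representative ~55 MHz isotropic coupling
    with mild axial anisotropy.
    """
    return NucleusCoupling(
        nucleus=NucleusSpec.from_isotope("1H"),
        tensor=HyperfineTensor(principal_khz=(53000.0, 53000.0, 59000.0)),
        label="beta-H",
        selection_only=True,
    )


def ring_proton_couplings() -> list[NucleusCoupling]:
    """C3/C5 ring protons of the radical, included only at long tau.

    Representative alpha-proton tensors (~-27, -8, -19 MHz); their branch
    frequencies sit around the 1H Larmor frequency and leak into the 19F
    window as a broad background at long-tau acquisitions.
    """
    out = []
    for label, euler in (("H3", (60.0, 90.0, 0.0)), ("H5", (-60.0, 90.0, 0.0))):
        out.append(
            NucleusCoupling(
                nucleus=NucleusSpec.from_isotope("1H"),
                tensor=HyperfineTensor(
                    principal_khz=(-26500.0, -7900.0, -19400.0), euler_deg=euler
                ),
                label=label,
                min_tau_ns=500.0,
            )
        )
    return out


# fixed unique-axis orientations (alpha, beta) of the 19F dipolar tensors in
# the g frame; F_b is nearly parallel to g_x, the others are representative
_F_AXIS_DEG = {
    "F_a": (0.0, 30.0),
    "F_b": (0.0, 90.0),
    "F_c": (30.0, 60.0),
    "F_d": (60.0, 110.0),
}

#: DFT-style dipolar coupling constants (kHz) for the purely dipolar nuclei
_TABLE_T_KHZ = {"F_b": 246.0, "F_c": 159.0, "F_d": 83.0}

#: rhombic tensor of the proximal flipped-conformer fluorine (kHz)
_F_A_PRINCIPAL_KHZ = (580.0, -1668.0, -1952.0)


def _fluorine(label: str, tensor: HyperfineTensor) -> NucleusCoupling:
    return NucleusCoupling(
        nucleus=NucleusSpec.from_isotope("19F"), tensor=tensor, label=label
    )


def build_conformer_pair(
    stacked_distances_a: tuple[float, float] = (8.4, 10.0),
    flipped_distances_a: tuple[float, float] = (4.6, 7.3),
    flipped_aiso_khz: float = -1013.0,
    tensor_source: str = "table",
    fraction_flipped: float = 0.25,
    include_ring_protons: bool = True,
) -> ConformerEnsemble:
    """Stacked/flipped conformer pair sharing the tyrosyl g tensor.

    ``tensor_source="table"`` (default) uses the explicit coupling
    constants a quantum-chemistry analysis supplies (T_b/T_c/T_d and the
    rhombic proximal tensor with ``flipped_aiso_khz``), mirroring the fact
    that the proximal fluorine sits below the point-dipole validity limit.
    ``tensor_source="geometry"`` instead derives every distal tensor from
    the point-dipole relation at the stated distances (the proximal
    fluorine keeps its explicit tensor, scaled to the requested a_iso).
    """
    if any(d <= 0 for d in (*stacked_distances_a, *flipped_distances_a)):
        raise ValueError("all fluorine-centroid distances must be > 0")
    if tensor_source not in ("table", "geometry"):
        raise ValueError(f"unknown tensor_source {tensor_source!r}")

    def axial(label: str, distance_a: float) -> HyperfineTensor:
        angles = _F_AXIS_DEG[label]
        if tensor_source == "table":
            return build_axial_hyperfine(_TABLE_T_KHZ[label], 0.0, angles)
        a, b = np.deg2rad(angles)
        axis = np.array([np.cos(a) * np.sin(b), np.sin(a) * np.sin(b), np.cos(b)])
        return dipolar_tensor_from_vector(
            distance_a * axis, NucleusSpec.from_isotope("19F")
        )

    f_a_principal = tuple(
        v - (-1013.0) + flipped_aiso_khz for v in _F_A_PRINCIPAL_KHZ
    )
    f_a = HyperfineTensor(
        principal_khz=f_a_principal, euler_deg=(*_F_AXIS_DEG["F_a"], 0.0)
    )

    common = [beta_proton_coupling()]
    if include_ring_protons:
        common += ring_proton_couplings()

    stacked = SpinSystem(
        g=TYROSYL_G,
        nuclei=tuple(
            [
                _fluorine("F_c", axial("F_c", stacked_distances_a[0])),
                _fluorine("F_d", axial("F_d", stacked_distances_a[1])),
            ]
            + common
        ),
        label="stacked",
    )
    flipped = SpinSystem(
        g=TYROSYL_G,
        nuclei=tuple(
            [
                _fluorine("F_a", f_a),
                _fluorine("F_b", axial("F_b", flipped_distances_a[1])),
            ]
            + common
        ),
        label="flipped",
    )
    return ConformerEnsemble(
        conformers=(("stacked", stacked), ("flipped", flipped)),
        fraction_flipped=fraction_flipped,
    )


def default_settings_list(n_orientations: int = 3000) -> list[AcquisitionSettings]:
    """Three observer positions x two tau regimes.

    Short tau (236 ns) on a +-4 MHz axis for the ~1.6 MHz coupling; long
    tau (620 ns) on a +-0.6 MHz axis for the <= 250 kHz couplings.
    """
    out = []
    for obs in ("gx", "gy", "gz"):
        out.append(
            AcquisitionSettings(
                observer=obs,
                tau_ns=236.0,
                rf_half_span_mhz=4.0,
                rf_step_mhz=0.008,
                n_orientations=n_orientations,
            )
        )
        out.append(
            AcquisitionSettings(
                observer=obs,
                tau_ns=620.0,
                rf_half_span_mhz=0.6,
                rf_step_mhz=0.004,
                n_orientations=n_orientations,
            )
        )
    return out


def _contaminant_spectrum(axis_mhz: np.ndarray) -> np.ndarray:
    """Synthetic contaminant-radical 19F background: smooth broad humps.

    Emulates the residual fluorinated-radical signal as a structureless
    baseline (not a simulation of the contaminant species itself).  The
    shape is fixed in physical frequency units - its features are several
    MHz wide, so a narrow small-coupling window sees only a slowly varying
    baseline, as for a real contaminant with large couplings.
    """
    y = 0.6 * np.exp(-(axis_mhz**2) / (2 * 2.2**2))
    y += 0.4 * np.exp(-((axis_mhz - 1.4) ** 2) / (2 * 0.8**2))
    y += 0.4 * np.exp(-((axis_mhz + 1.4) ** 2) / (2 * 0.8**2))
    return y


def generate_endor_dataset(
    ensemble: ConformerEnsemble,
    truth: SyntheticTruth,
    settings_list: list[AcquisitionSettings] | None = None,
    outdir: str | Path | None = None,
    include_contaminant: bool = True,
):
    """Noisy two-conformer ENDOR dataset with a truth manifest.

    For every acquisition setting the two conformers are simulated, mixed
    at the truth fraction (max-normalized components), max-normalized, and
    degraded with i.i.d. Gaussian noise (sigma as a fraction of the
    maximum).  Optionally a scaled synthetic contaminant background is
    added; the clean contaminant reference is returned so the background
    subtraction step can be exercised.  Fully reproducible from the seed.

    Returns ``(spectra, references, manifest)``; files are written when
    ``outdir`` is given.
    """
    if settings_list is None:
        settings_list = default_settings_list()
    stacked_sys, flipped_sys = ensemble.require_pair()
    f = truth.fraction_flipped
    seeds = np.random.SeedSequence(truth.seed).spawn(len(settings_list))

    spectra, references = [], []
    for st, ss in zip(settings_list, seeds):
        with warnings.catch_warnings():
            # ring-proton background intentionally extends beyond the window
            warnings.simplefilter("ignore")
            stacked = simulate_mims_endor(stacked_sys, st)
            flipped = simulate_mims_endor(flipped_sys, st)
        clean = normalize(mix_spectra(stacked, flipped, f), "max")
        y = clean.intensity.copy()
        ref = None
        if include_contaminant:
            ref_y = _contaminant_spectrum(clean.axis_mhz)
            y = y + truth.contaminant_scale * ref_y
            ref = clean.copy_with(
                intensity=ref_y,
                metadata={"species": "contaminant-reference", "synthetic": True},
            )
        rng = np.random.default_rng(ss)
        y = y + rng.normal(0.0, truth.noise_sigma, size=y.shape)
        spec = clean.copy_with(
            intensity=y,
            metadata={
                "species": "synthetic-mixture",
                "fraction_flipped": f,
                "noise_sigma": truth.noise_sigma,
                "contaminant_scale": truth.contaminant_scale if include_contaminant else 0.0,
            },
        )
        spectra.append(spec)
        references.append(ref)

    manifest = truth.manifest(
        n_settings=len(settings_list),
        settings=[st.to_dict() for st in settings_list],
        kind="endor",
    )
    if outdir is not None:
        from .cli_io import write_spectrum

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for i, (spec, ref) in enumerate(zip(spectra, references)):
            write_spectrum(spec, outdir / f"spectrum_{i:02d}.dat")
            if ref is not None:
                write_spectrum(ref, outdir / f"reference_{i:02d}.dat")
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return spectra, references, manifest


def gaussian_distribution(
    mean_nm: float, fwhm_nm: float, r_nm: np.ndarray | None = None
) -> DistanceDistribution:
    """Unit-area Gaussian distance distribution on the default r grid."""
    if r_nm is None:
        r_nm = default_r_grid()
    sigma = fwhm_nm / 2.354820045
    p = np.exp(-((r_nm - mean_nm) ** 2) / (2 * sigma**2))
    return DistanceDistribution(
        r_nm=r_nm, density=p, metadata={"mean_nm": mean_nm, "fwhm_nm": fwhm_nm}
    )


def generate_deer_dataset(
    truth: SyntheticTruth,
    lam: float = 0.3,
    bg_k_per_us: float = 0.2,
    t_us: np.ndarray | None = None,
    noise_sigma: float | None = None,
    outdir: str | Path | None = None,
) -> tuple[DeerTrace, DistanceDistribution, dict]:
    """PELDOR trace from a Gaussian ground-truth distance distribution."""
    if t_us is None:
        t_us = np.linspace(0.0, 2.5, 251)
    if noise_sigma is None:
        noise_sigma = 0.0
    p_true = gaussian_distribution(truth.deer_mean_nm, truth.deer_fwhm_nm)
    trace = simulate_trace(
        p_true, lam, bg_k_per_us, t_us, noise_sigma=noise_sigma, seed=truth.seed
    )
    manifest = truth.manifest(
        kind="deer", **{"lambda": lam, "bg_k_per_us": bg_k_per_us, "deer_noise_sigma": noise_sigma}
    )
    if outdir is not None:
        from .cli_io import write_trace

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_trace(trace, outdir / "deer_trace.dat")
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return trace, p_true, manifest
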