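#!/usr/bin/env python
"""Invert a synthetic PELDOR trace to the radical-pair distance distribution.

A 4-pulse dipolar evolution trace is generated from a Gaussian ground
truth (mean 3.03 nm, FWHM 0.12 nm, modulation depth 0.3, exponential
intermolecular background), background-corrected, and inverted by
nonnegative Tikhonov regularization with the regularization weight chosen
on the L-curve.  The recovered distribution and a JSON report are written
to results/.
"""

import json
from pathlib import Path

import numpy as np

from endorkit.cli_io import write_trace
from endorkit.peldor import (
    background_correct,
    default_r_grid,
    distribution_peak_fwhm,
    lcurve_select,
    tikhonov_invert,
)
from endorkit.synthetic_data import SyntheticTruth, generate_deer_dataset

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    OUT.mkdir(exist_ok=True)
    truth = SyntheticTruth(deer_mean_nm=3.03, deer_fwhm_nm=0.12, seed=2024)
    trace, p_true, manifest = generate_deer_dataset(
        truth, lam=0.3, bg_k_per_us=0.2, t_us=np.linspace(0, 2.5, 251)
    )
    write_trace(trace, OUT / "deer_trace.dat")

    form_factor, lam_hat = background_correct(trace, fit_start_us=1.25)
    r = default_r_grid()
    alpha = lcurve_select(form_factor, r)
    dist = tikhonov_invert(form_factor, r, alpha)
    peak, fwhm, multimodal = distribution_peak_fwhm(dist)

    print(
        f"truth: 3.03 nm / 0.12 nm FWHM -> recovered peak {peak:.3f} nm, "
        f"FWHM {fwhm:.3f} nm (alpha* = {alpha:.3g}, lambda_hat = {lam_hat:.3f}, "
        f"multimodal = {multimodal})"
    )
    np.savetxt(
        OUT / "deer_distribution.dat",
        np.column_stack([dist.r_nm, dist.density]),
        header="r_nm P(r)",
    )
    report = {
        "peak_nm": peak,
        "fwhm_nm": fwhm,
        "alpha": alpha,
        "lambda_hat": lam_hat,
        "multimodal": multimodal,
        "manifest": manifest,
    }
    (OUT / "deer_report.json").write_text(json.dumps(report, indent=2))
    print(f"wrote {OUT / 'deer_report.json'} and the distribution table")


if __name__ == "__main__":
    main()
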