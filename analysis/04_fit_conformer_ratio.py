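#!/usr/bin/env python
"""Recover the flipped-conformer population from a synthetic ENDOR dataset.

A two-conformer dataset (three observer positions x two tau regimes) is
generated at a known flipped fraction of 25% with 5% additive noise plus a
contaminant background, the background is removed with the reference
spectrum, and the single-parameter global rmsd fit is scanned over the
mixing fraction.  The residual curve and the fit summary are written to
results/.
"""

import csv
import json
import warnings
from pathlib import Path

import numpy as np

from endorkit.conformer_fit import fit_fraction_precomputed, subtract_reference
from endorkit.endor_sim import simulate_mims_endor
from endorkit.synthetic_data import (
    SyntheticTruth,
    build_conformer_pair,
    default_settings_list,
    generate_endor_dataset,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    OUT.mkdir(exist_ok=True)
    ensemble = build_conformer_pair()
    settings = default_settings_list(n_orientations=3000)
    truth = SyntheticTruth(fraction_flipped=0.25, noise_sigma=0.05, seed=2024)

    spectra, references, manifest = generate_endor_dataset(
        ensemble, truth, settings, include_contaminant=True
    )

    # background removal: the contaminant scale is fitted on the wide
    # short-tau window, whose outer region is background-only (ring protons
    # enter only at long tau), and the same scale removes the contaminant
    # from the co-acquired narrow window at the same observer position
    cleaned = []
    for i in range(0, len(spectra), 2):  # settings come as (short, long) pairs
        sp_short, sp_long = spectra[i], spectra[i + 1]
        ref_short, ref_long = references[i], references[i + 1]
        mask = np.abs(sp_short.axis_mhz) > 0.6 * sp_short.axis_mhz.max()
        sub_short = subtract_reference(sp_short, ref_short, mask=mask)
        c = sub_short.metadata["reference_scale"]
        sub_long = sp_long.copy_with(
            intensity=sp_long.intensity - c * ref_long.intensity,
            metadata={"reference_scale": c},
        )
        cleaned.extend([sub_short, sub_long])

    stacked_sys, flipped_sys = ensemble.require_pair()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pairs = [
            (simulate_mims_endor(stacked_sys, st), simulate_mims_endor(flipped_sys, st), sp)
            for st, sp in zip(settings, cleaned)
        ]
    result = fit_fraction_precomputed(pairs)
    lo, hi = result.uncertainty_interval()

    print(
        f"true flipped fraction 25% -> fitted {100 * result.fraction:.1f}% "
        f"(rmsd {result.rmsd_min:.3f}, 5%-rmsd interval {100 * lo:.0f}-{100 * hi:.0f}%)"
    )
    summary = {
        "true_fraction": truth.fraction_flipped,
        "fitted_fraction": result.fraction,
        "rmsd_min": result.rmsd_min,
        "uncertainty_interval": [lo, hi],
        "contaminant_scales_fitted": [
            sp.metadata["reference_scale"] for sp in cleaned
        ],
        "manifest": manifest,
    }
    (OUT / "conformer_fit.json").write_text(json.dumps(summary, indent=2))
    with (OUT / "conformer_fit_curve.csv").open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["fraction", "rmsd"])
        w.writerows(zip(result.fractions.round(3), result.rmsd_curve.round(6)))
    print(f"wrote {OUT / 'conformer_fit.json'} and the residual curve")


if __name__ == "__main__":
    main()
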