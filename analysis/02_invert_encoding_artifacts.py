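#!/usr/bin/env python
"""Demonstrate the phase-contrast artifact corrections on encoded phantoms.

Encodes a velocity phantom (degree-4 eddy-current background polynomial,
one velocity plateau at 1.5×VENC that aliases, optional phase noise), then
inverts: decode, detect static tissue, fit and subtract the background,
temporally unwrap.  Reports recovery error with and without noise to
results/preprocess_recovery.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import lvflow as lf
from lvflow import preprocess as pp

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def run_case(noise_sd: float, rng: np.random.Generator) -> dict:
    field = lf.make_aliasing_phantom(shape=(24, 24, 24), venc=1.2,
                                     peak_over_venc=1.5)
    enc = lf.EncodingSpec(venc=1.2, poly_coeffs=rng.normal(0, 0.05, (3, 35)),
                          noise_sd=noise_sd)
    imgs = lf.encode_phase_contrast(field, enc, seed=SEED)
    # velocity noise per sample is VENC/pi times the phase noise; keep the
    # static-tissue gate comfortably above it
    sd_gate = max(0.03, 2.5 * enc.venc / np.pi * noise_sd)
    recovered, model, static = pp.decode_and_correct(imgs, sd_threshold=sd_gate)
    err = np.abs(recovered.values - field.values)
    return {
        "noise_sd_rad": noise_sd,
        "static_voxels": static.n_voxels,
        "bg_fit_rms_m_s": float(model.residual_rms.max()),
        "max_err_m_s": float(err.max()),
        "rms_err_m_s": float(np.sqrt(np.mean(err**2))),
    }


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    rows = [run_case(sd, rng) for sd in (0.0, 0.05, 0.1)]
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "preprocess_recovery.csv", index=False)
    print(df.to_string(index=False, float_format=lambda x: f"{x:.3g}"))
    print(
        "\nnoise-free encoding is inverted to machine precision; with phase "
        "noise the residual error tracks the injected noise level "
        "(sigma_v = VENC/pi * sigma_phase), as expected for an unbiased decode."
    )


if __name__ == "__main__":
    main()
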