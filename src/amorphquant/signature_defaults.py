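"""Default component signatures for the synthetic spectrum generator.

Provenance: only the band POSITIONS are anchored to reported itraconazole /
hydroxypropyl-cellulose spectroscopy — the crystalline C-H first-overtone
double peak at 5800/5900 cm^-1, its amorphous counterpart shifted to
5775 cm^-1, the moisture combination band near 5000 cm^-1, and the nu(C=C)
Raman band at 1614-1618 cm^-1.  Every height, width, shape mix, background
amplitude and noise level below is an INVENTED fixture default, chosen to
give qualitatively realistic FT-NIR / dispersive-Raman traces, and tunable
here without code edits.

Peak tuples are ``(center_cm1, fwhm_cm1, height, shape_mix)`` with
``shape_mix`` blending Gaussian (0) to Lorentzian (1) pseudo-Voigt profiles.

Design notes on the invented values:

* NIR polymer bands are strong and moderately sharp: at 77% w/w the polymer
  dominates the per-spectrum variance of the derivative spectra, so the
  standard-normal-variate scale factor stays nearly constant across the
  calibration design and the response stays close to linear in composition —
  the regime a linear PLS calibration presumes.
* Raman amorphous bands keep the crystalline centers with 2.0x the width and
  0.50x the height.  The integrated band area is thus conserved on amorphous
  conversion, which keeps the 1614 cm^-1 peak-area normalisation denominator
  stable across the design (again protecting linearity) while the peak
  HEIGHT at 1618 cm^-1 still drops sharply with amorphous content.
* The NIR moisture band has two sources: the hygroscopic amorphous drug
  (amplitude scaling with amorphous fraction) and the cellulose polymer,
  which at 77% w/w contributes a large composition-independent share.  The
  whole band is jittered per spectrum by the noise model (log-sd 0.7, about
  a factor-two ambient-humidity swing), so the 4800-5200 cm^-1 region is
  mostly moisture noise rather than signal — which is exactly why excluding
  it improves a calibration model.
"""

from __future__ import annotations

#: Raman fluorescence background decay constant (cm^-1): A * exp(-shift/tau).
FLUORESCENCE_TAU = 600.0

#: NIR moisture (water combination) band: Gaussian center / FWHM (cm^-1) and
#: the hard support outside which the rendered band is exactly zero.
WATER_BAND_CENTER = 5000.0
WATER_BAND_FWHM = 200.0
WATER_BAND_SUPPORT = (4600.0, 5400.0)

# -- NIR (FT reflectance, 3600-12500 cm^-1) ---------------------------------

NIR_PEAKS = {
    "crystalline_drug": [
        (5800.0, 60.0, 1.00, 0.3),   # C-H first overtone, resolved doublet
        (5900.0, 60.0, 0.80, 0.3),
        (4400.0, 80.0, 0.45, 0.3),   # C-H combination region
        (6100.0, 70.0, 0.30, 0.3),
    ],
    "amorphous_drug": [
        (5775.0, 90.0, 1.00, 0.3),   # single broadened, shifted overtone band
        (4400.0, 120.0, 0.40, 0.3),
        (6100.0, 110.0, 0.25, 0.3),
    ],
    "polymer": [
        (4350.0, 120.0, 0.50, 0.2),  # cellulose C-H / O-H combination bands
        (4750.0, 120.0, 0.40, 0.2),
        (5800.0, 150.0, 0.35, 0.2),
        (6900.0, 200.0, 0.60, 0.2),  # O-H first overtone
        (8300.0, 300.0, 0.25, 0.2),
    ],
    "colourant": [
        (8000.0, 30000.0, 0.10, 0.0),  # near-flat reflectance offset
    ],
}

#: Moisture band amplitude per component (NIR only).  The amorphous drug is
#: the hygroscopic solid-state form; the cellulose polymer carries ambient
#: moisture regardless of drug form.
NIR_WATER_AMPLITUDE = {
    "crystalline_drug": 0.0,
    "amorphous_drug": 0.35,
    "polymer": 0.25,
    "colourant": 0.0,
}

# -- Raman (dispersive, 100-2000 cm^-1) -------------------------------------

_RAMAN_CRYSTALLINE = [
    (1618.0, 12.0, 1.00, 0.5),  # nu(C=C) — the quantification anchor band
    (1450.0, 14.0, 0.55, 0.5),
    (1350.0, 12.0, 0.40, 0.5),
    (1230.0, 14.0, 0.45, 0.5),
    (1040.0, 12.0, 0.35, 0.5),
    (740.0, 12.0, 0.30, 0.5),
    (680.0, 12.0, 0.25, 0.5),
    (520.0, 14.0, 0.20, 0.5),
    (320.0, 16.0, 0.22, 0.5),
]

#: Amorphous bands share crystalline centers: broadened and shrunk with the
#: integrated band area conserved.
AMORPHOUS_FWHM_FACTOR = 2.0
AMORPHOUS_HEIGHT_FACTOR = 0.50

RAMAN_PEAKS = {
    "crystalline_drug": _RAMAN_CRYSTALLINE,
    "amorphous_drug": [
        (c, w * AMORPHOUS_FWHM_FACTOR, h * AMORPHOUS_HEIGHT_FACTOR, m)
        for (c, w, h, m) in _RAMAN_CRYSTALLINE
    ],
    "polymer": [
        (1460.0, 60.0, 0.16, 0.3),
        (1370.0, 60.0, 0.14, 0.3),
        (1120.0, 70.0, 0.20, 0.3),
        (890.0, 60.0, 0.12, 0.3),
    ],
    "colourant": [
        (1000.0, 20000.0, 0.02, 0.0),  # near-flat scattering offset
    ],
}

#: Fluorescence amplitude per component (Raman only; the amorphous form is
#: the coloured, fluorescent one).
RAMAN_FLUORESCENCE_AMPLITUDE = {
    "crystalline_drug": 0.0,
    "amorphous_drug": 0.80,
    "polymer": 0.0,
    "colourant": 0.0,
}

# -- Noise defaults (all invented; intensity units match the signatures) ----

DEFAULT_NOISE = dict(
    additive_sd=0.002,
    multiplicative_sd=0.05,
    baseline_offset_sd=0.01,
    baseline_slope_sd=0.005,
    disc_extra_scatter=2.0,
    water_band_jitter_sd=0.7,
)
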