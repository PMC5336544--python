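"""Published summary data used as worked-example inputs.

Mean total econazole nitrate amounts (ug/cm^2) recovered from porcine SC
(n = 14 skin replicates per product and phase) after a 6-h uptake and a
subsequent 17-h clearance period, for three commercial 1% w/v creams, with
the reported 90% confidence bounds.  These published summary statistics serve
as inputs to the combined [uptake + clearance] bioequivalence worked example;
the replicate-level data behind them were never deposited, so only
mean-arithmetic checks are possible against them.
"""

#: per-product, per-phase mean SC amounts and 90% CI bounds (ug/cm^2)
EN_SC_SUMMARY: dict[str, dict[str, dict[str, float]]] = {
    "Perrigo": {
        "uptake": {"mean": 2.19, "ci_low": 1.61, "ci_high": 4.18},
        "clearance": {"mean": 1.96, "ci_low": 1.48, "ci_high": 3.23},
    },
    "Fougera": {
        "uptake": {"mean": 1.81, "ci_low": 1.17, "ci_high": 3.70},
        "clearance": {"mean": 2.28, "ci_low": 1.42, "ci_high": 4.24},
    },
    "Taro": {
        "uptake": {"mean": 1.77, "ci_low": 1.44, "ci_high": 2.22},
        "clearance": {"mean": 2.80, "ci_low": 1.44, "ci_high": 4.88},
    },
}

#: the reference listed product in that comparison
EN_REFERENCE_PRODUCT = "Fougera"

#: per-phase replicate count behind each summary mean
EN_N_PER_PHASE = 14
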