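"""Bench validation formulas: chlorophyll fluorescence and qPCR.

Two small, exactly specified computations used to sanity-check plant
stress physiology and expression measurements alongside the sequencing
analysis.
"""

from __future__ import annotations

import math

from .errors import ValidationError


def fv_fm(fo: float, fm: float) -> float:
    """Maximum photochemical quantum yield of PS II: (Fm - Fo) / Fm.

    Fo is the minimal and Fm the maximal chlorophyll fluorescence of a
    dark-adapted leaf; the yield lies in [0, 1].
    """
    if not (math.isfinite(fo) and math.isfinite(fm)):
        raise ValidationError("fluorescence readings must be finite")
    if fm <= 0:
        raise ValidationError(f"Fm must be > 0, got {fm}")
    if fo < 0 or fo > fm:
        raise ValidationError(f"Fo must satisfy 0 <= Fo <= Fm, got Fo={fo}, Fm={fm}")
    return (fm - fo) / fm


def ddct_fold_change(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression fold change by the 2^-ddCt method.

    dCt = Ct_target - Ct_reference within each sample;
    ddCt = dCt_treated - dCt_control; the fold change is 2^-ddCt.
    Assumes ~100% amplification efficiency for both assays.
    """
    cts = (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control)
    if not all(math.isfinite(c) and c > 0 for c in cts):
        raise ValidationError("all Ct values must be finite and > 0")
    dct_treated = ct_target_treated - ct_ref_treated
    dct_control = ct_target_control - ct_ref_control
    ddct = dct_treated - dct_control
    return 2.0 ** (-ddct)
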