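"""Doppler-based pressure estimation used in clinical PH screening.

The systolic pulmonary artery pressure follows from the simplified Bernoulli
relation applied to the tricuspid regurgitation jet,

    sPAP = 4 · TRV² + RAP          (TRV in m/s, pressures in mmHg)

and the mean pressure from its strong linear relationship with sPAP,

    mPAP = 0.61 · sPAP + 2 mmHg.

PH is defined as mPAP > 20 mmHg at rest. Outputs are real-valued mmHg.
"""

from __future__ import annotations

from .types import ClinicalMeasures, ValidationError

__all__ = ["estimate_spap", "estimate_mpap", "screen_measures"]


def estimate_spap(trv: float, rap: float) -> float:
    """Systolic pulmonary artery pressure (mmHg) from TRV (m/s) and RAP
    (mmHg)."""
    if trv < 0:
        raise ValidationError(f"TRV must be >= 0 m/s, got {trv}")
    if rap < 0:
        raise ValidationError(f"RAP must be >= 0 mmHg, got {rap}")
    return 4.0 * trv**2 + rap


def estimate_mpap(spap: float) -> float:
    """Mean pulmonary artery pressure (mmHg) from the systolic pressure."""
    if spap < 0:
        raise ValidationError(f"sPAP must be >= 0 mmHg, got {spap}")
    return 0.61 * spap + 2.0


def screen_measures(trv: float, rap: float) -> ClinicalMeasures:
    """Convenience: populate a ClinicalMeasures record from TRV and RAP."""
    spap = estimate_spap(trv, rap)
    return ClinicalMeasures(trv=trv, rap=rap, spap=spap, mpap=estimate_mpap(spap))
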