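"""Shared phospho-readout bookkeeping.

The protein endpoints are ratios of an annotated set of active
(phosphorylated) species to the total moiety pool summed over every form
and complex, mirroring ppERK/total-ERK and pAKT/total-AKT quantifications.
"""

from __future__ import annotations

from typing import Mapping

from .network import NetworkModel, moiety_totals


def phospho_fraction(model: NetworkModel, state: Mapping[str, float], moiety: str) -> float:
    """Active-form fraction of a moiety at the given state.

    ``state`` maps species id -> concentration.  The active species set
    comes from ``model.annotations["readouts"][moiety]["active"]``; the
    denominator is the moiety total (all forms and complexes, counting
    multiplicity).
    """
    readouts = model.annotations.get("readouts", {})
    if moiety not in readouts or "active" not in readouts[moiety]:
        raise KeyError(f"moiety {moiety!r} has no readout annotation on this model")
    active = readouts[moiety]["active"]
    numerator = sum(float(state.get(sid, 0.0)) for sid in active)
    total = moiety_totals(model, state).get(moiety, 0.0)
    if total <= 0:
        raise ZeroDivisionError(f"moiety {moiety!r} has zero total concentration")
    return numerator / total
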