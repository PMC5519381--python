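"""Sample-preparation arithmetic for micellar folding stocks."""

from __future__ import annotations

__all__ = ["detergent_protein_ratio", "FOLDING_STOCK_DPC_M",
           "FOLDING_STOCK_PROTEIN_M"]

#: micellar folding-stock composition: 100 mM DPC detergent ...
FOLDING_STOCK_DPC_M: float = 100e-3
#: ... containing ~30 uM protein
FOLDING_STOCK_PROTEIN_M: float = 30e-6


def detergent_protein_ratio(detergent_M: float | None = None,
                            protein_M: float | None = None) -> float:
    """Detergent-to-protein molar ratio (DPR) of a folding stock.

    Defaults to the standard stock composition (30 uM protein in 100 mM
    DPC), for which the DPR is ~3300:1.
    """
    if detergent_M is None:
        detergent_M = FOLDING_STOCK_DPC_M
    if protein_M is None:
        protein_M = FOLDING_STOCK_PROTEIN_M
    if protein_M <= 0 or detergent_M <= 0:
        raise ValueError("concentrations must be positive")
    return detergent_M / protein_M
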