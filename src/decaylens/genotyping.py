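"""Genotyping-PCR arithmetic for an indel allele.

The mutant allele analyzed here carries a deletion together with a small
insertion at the cut site; genotyping distinguishes wild-type and mutant
fish by the resulting size difference of a PCR amplicon spanning the
lesion.
"""

from __future__ import annotations

__all__ = ["net_deletion", "mutant_amplicon_length"]


def net_deletion(deleted_nt: int, inserted_nt: int) -> int:
    """Net nucleotides lost by a combined deletion/insertion lesion."""
    if deleted_nt < 0 or inserted_nt < 0:
        raise ValueError("lengths must be non-negative")
    return deleted_nt - inserted_nt


def mutant_amplicon_length(wt_amplicon_nt: int, deleted_nt: int, inserted_nt: int = 0) -> int:
    """Expected mutant PCR product size given the wild-type amplicon size
    and the lesion."""
    out = wt_amplicon_nt - net_deletion(deleted_nt, inserted_nt)
    if out < 0:
        raise ValueError("lesion larger than the amplicon")
    return out
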