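"""Default amplicon panel.

The panel covers the three murine age-associated regions Prima1, Hsf4
and Kcns1 with 4, 12 and 21 neighboring CpGs respectively. The reference
sequences shipped here are synthetic stand-ins: they reproduce the CpG
counts and an amplicon-like layout (the only CG dinucleotides are the
indexed CpGs, with non-CpG cytosines present so conversion QC is
exercised), not the genomic sequences. Supply your own panel file for
real data.
"""

from __future__ import annotations

from .amplicon import AmpliconSpec

__all__ = ["build_reference", "default_panel", "DEFAULT_CPG_COUNTS"]

DEFAULT_CPG_COUNTS = {"Prima1": 4, "Hsf4": 12, "Kcns1": 21}

# Spacers contain C but no G, so concatenation can never create a CG
# outside the intended CpG sites.
_SPACERS = {
    "Prima1": "TACTTCATTACATT",
    "Hsf4": "ATTCCATACTTCAA",
    "Kcns1": "TTCATACCATTCTA",
}


def build_reference(n_cpgs: int, spacer: str) -> tuple[str, tuple[int, ...]]:
    """Synthetic amplicon reference: spacer + (CG + spacer) * n_cpgs.

    Returns the sequence and the 0-based offsets of each CpG cytosine.
    """
    if "G" in spacer:
        raise ValueError("spacer must not contain G (would risk spurious CpGs)")
    if n_cpgs < 1:
        raise ValueError("n_cpgs must be >= 1")
    parts = [spacer]
    positions = []
    pos = len(spacer)
    for _ in range(n_cpgs):
        positions.append(pos)
        parts.append("CG")
        parts.append(spacer)
        pos += 2 + len(spacer)
    return "".join(parts), tuple(positions)


def default_panel(
    max_mismatch_frac: float = 0.1, min_conversion: float = 0.9
) -> list[AmpliconSpec]:
    """The three-amplicon synthetic stand-in panel (4/12/21 CpGs)."""
    specs = []
    for name, n in DEFAULT_CPG_COUNTS.items():
        seq, pos = build_reference(n, _SPACERS[name])
        specs.append(
            AmpliconSpec(
                name=name,
                reference_seq=seq,
                cpg_positions=pos,
                max_mismatch_frac=max_mismatch_frac,
                min_conversion=min_conversion,
            )
        )
    return specs
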