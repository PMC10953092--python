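"""Canonical SBS96 category layout (COSMIC column order).

Categories are pyrimidine-centered: substitution blocks C>A, C>G, C>T,
T>A, T>C, T>G; within each block the 5' flank varies first, then the 3'
flank, each in A, C, G, T order. Labels look like ``"A[C>T]G"``.
"""

from __future__ import annotations

BASES = "ACGT"
PYRIMIDINES = "CT"
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

SBS96_CONTEXTS: tuple[str, ...] = tuple(
    f"{f5}[{sub}]{f3}" for sub in SUBSTITUTIONS for f5 in BASES for f3 in BASES
)

_INDEX = {label: i for i, label in enumerate(SBS96_CONTEXTS)}


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def category(ref: str, alt: str, flank5: str, flank3: str) -> str:
    """Pyrimidine-collapsed SBS96 label for a single-base substitution.

    Purine-centered substitutions are reverse-complemented so that the
    reference base is always C or T.
    """
    ref, alt = ref.upper(), alt.upper()
    flank5, flank3 = flank5.upper(), flank3.upper()
    for b in (ref, alt, flank5, flank3):
        if b not in BASES:
            raise ValueError(f"non-ACGT base in substitution context: {b!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ for an SNV")
    if ref not in PYRIMIDINES:
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        flank5, flank3 = COMPLEMENT[flank3], COMPLEMENT[flank5]
    return f"{flank5}[{ref}>{alt}]{flank3}"


def category_index(label: str) -> int:
    try:
        return _INDEX[label]
    except KeyError:
        raise ValueError(f"unknown SBS96 category: {label!r}") from None
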