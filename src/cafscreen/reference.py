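"""Built-in reference gene sets.

Only the CRC CAFGs named with SE values in the source study's main text are
shipped; the full 115-gene catalogue is a user-supplied input
(:meth:`cafscreen.compare.ReferenceGeneSet.from_tsv`).
"""

from __future__ import annotations

from .compare import ReferenceGeneSet

# CRC stromal SE ratios of the named CAFGs (Agilent microdissection cohort).
CRC_CAFG_SE: dict[str, float] = {
    "FAP": 20.2,
    "ACTA2": 20.2,
    "VIM": 17.8,
    "SPARC": 17.2,
    "COL12A1": 18.3,
    "DKK3": 13.9,
    "INHBA": 20.9,
    "ANTXR1": 24.3,
    "PDGFRB": 14.8,
    "SLC24A3": 23.6,
    "ITGA11": 16.4,
    "MMP2": 18.4,
    "CCL2": 18.0,
    "POSTN": 15.4,
    "PDPN": 11.2,
    "LRRC15": 10.5,
}


def crc_cafg_reference() -> ReferenceGeneSet:
    """The named CRC CAFGs (SE >= 10 in colorectal stroma) with their SE values."""
    return ReferenceGeneSet(
        name="CRC_CAFG",
        genes=frozenset(CRC_CAFG_SE),
        source_values=dict(CRC_CAFG_SE),
    )
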