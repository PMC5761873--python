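"""Accessors for the packaged known-piRNA reference.

The shipped FASTA contains synthetic stand-in sequences, constructed to
match the documented descriptors of the named piRNAs (length, GC
content, 1U/10A composition); they are not database sequences.  Use a
real reference FASTA via :func:`pirome.read_processing.read_reference_fasta`
for production annotation.
"""

from __future__ import annotations

from importlib import resources

from .seq_utils import gc_fraction, to_rna


def load_known_pirnas() -> dict[str, str]:
    """Packaged reference piRNAs as {id: RNA sequence}."""
    from Bio import SeqIO

    path = resources.files("pirome.data").joinpath("known_pirnas_synthetic.fa")
    with path.open() as fh:
        return {rec.id: to_rna(str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")}


def get_reference_pirna(pirna_id: str) -> str:
    """Look up one reference piRNA sequence (RNA alphabet) by identifier."""
    ref = load_known_pirnas()
    try:
        return ref[pirna_id]
    except KeyError:
        raise KeyError(f"unknown reference piRNA {pirna_id!r}") from None


def gc_percent(pirna_id: str) -> float:
    """GC content of a reference piRNA, in percent."""
    return 100.0 * gc_fraction(get_reference_pirna(pirna_id))
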