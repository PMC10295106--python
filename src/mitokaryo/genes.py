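"""The canonical 37-gene bilaterian mitochondrial gene namespace.

Bilaterian mitochondrial genomes carry 13 protein-coding genes, two rRNA
genes and 22 tRNA genes.  tRNAs are named by the one-letter code of the
amino acid they carry, with the two leucine and two serine isoacceptors
distinguished as L1/L2 and S1/S2.  This module owns symbol validation and
the ``trnX``-style aliases used in GenBank-flavoured notation.
"""

from __future__ import annotations

PROTEIN_CODING: tuple[str, ...] = (
    "atp6", "atp8", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
)

RRNA: tuple[str, ...] = ("rrnS", "rrnL")

TRNA: tuple[str, ...] = (
    "A", "C", "D", "E", "F", "G", "H", "I", "K", "L1", "L2",
    "M", "N", "P", "Q", "R", "S1", "S2", "T", "V", "W", "Y",
)

#: The full 37-gene complement, in a stable reporting order.
GENE_NAMESPACE: tuple[str, ...] = PROTEIN_CODING + RRNA + TRNA

_GENE_SET = frozenset(GENE_NAMESPACE)

# "trnA" etc. are accepted on input and used in GRIMM export, where bare
# one-letter tokens would be ambiguous with chromosome labels.
_ALIASES: dict[str, str] = {f"trn{t}": t for t in TRNA}
_REVERSE_ALIASES: dict[str, str] = {t: f"trn{t}" for t in TRNA}


class UnknownGeneError(ValueError):
    """Raised when a token is not in the 37-gene namespace."""


def is_trna(symbol: str) -> bool:
    return symbol in TRNA


def normalize_symbol(token: str) -> str:
    """Resolve a gene token (canonical symbol or ``trnX`` alias) to its
    canonical symbol.  Symbols are case-sensitive.

    >>> normalize_symbol("trnL1")
    'L1'
    >>> normalize_symbol("cox1")
    'cox1'
    """
    if token in _GENE_SET:
        return token
    if token in _ALIASES:
        return _ALIASES[token]
    raise UnknownGeneError(f"unknown mitochondrial gene symbol: {token!r}")


def grimm_token(symbol: str) -> str:
    """Symbol as written in GRIMM export (tRNAs become trn-prefixed)."""
    return _REVERSE_ALIASES.get(symbol, symbol)
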