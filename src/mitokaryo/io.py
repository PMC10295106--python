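"""Reading and writing karyotype descriptions.

Two text formats are supported:

* the ``.karyo`` dialect — ``#`` comments, optional ``species:`` / ``host:``
  header lines, then one chromosome per line::

      M1 (9499 bp): atp6 atp8 NCR:49 nad2 nad5 I
      M2: P K S1 NCR:141 -Q

  A token is a gene symbol (``trnX`` aliases accepted), ``-``-prefixed when
  transcribed in the reverse orientation, or ``NCR:<length>`` for a
  non-coding region.  The parenthesized size after the label is optional
  assembly metadata (total chromosome size in bp).

* GRIMM-style export — one genome per ``>species`` block, one line of signed
  gene tokens per chromosome, tRNAs written trn-prefixed, no NCRs.
"""

from __future__ import annotations

import re

from .genes import UnknownGeneError, grimm_token, normalize_symbol
from .karyotype import (
    Karyotype,
    KaryotypeError,
    Minichromosome,
    NonCodingRegion,
    OrientedGene,
)


class KaryoParseError(ValueError):
    """Malformed .karyo document; message carries the line number and token."""


_CHROM_RE = re.compile(
    r"^(?P<label>[^:()]+?)\s*(?:\(\s*(?P<size>\d+)\s*bp\s*\))?\s*:\s*(?P<body>.*)$"
)
_NCR_RE = re.compile(r"^NCR:(?P<len>\d+)(?::(?P<label>\S+))?$")


def parse_karyotype(text: str, species_id: str | None = None) -> Karyotype:
    """Parse a ``.karyo`` document into a validated :class:`Karyotype`.

    The written left-to-right token order is preserved as the circular order
    of each chromosome.  Unknown gene symbols and duplicated genes raise
    errors naming the offending token/gene and line.
    """
    species = species_id
    host: str | None = None
    chromosomes: list[Minichromosome] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower().startswith("species:"):
            species = line.split(":", 1)[1].strip()
            continue
        if line.lower().startswith("host:"):
            host = line.split(":", 1)[1].strip()
            continue
        m = _CHROM_RE.match(line)
        if not m or not m.group("body").strip():
            raise KaryoParseError(f"line {lineno}: expected 'LABEL: tok tok ...', got {raw!r}")
        elements: list[OrientedGene | NonCodingRegion] = []
        for tok in m.group("body").split():
            ncr = _NCR_RE.match(tok)
            if ncr:
                elements.append(
                    NonCodingRegion(int(ncr.group("len")), ncr.group("label"))
                )
                continue
            orientation = 1
            gene_tok = tok
            if tok.startswith("-"):
                orientation = -1
                gene_tok = tok[1:]
            try:
                symbol = normalize_symbol(gene_tok)
            except UnknownGeneError as exc:
                raise KaryoParseError(f"line {lineno}: {exc} (token {tok!r})") from exc
            elements.append(OrientedGene(symbol, orientation))
        size = int(m.group("size")) if m.group("size") else None
        try:
            chromosomes.append(Minichromosome(m.group("label").strip(), elements, size))
        except KaryotypeError as exc:
            raise KaryoParseError(f"line {lineno}: {exc}") from exc
    if species is None:
        raise KaryoParseError("document has no 'species:' header and no species_id given")
    return Karyotype(species, chromosomes, host=host)


def read_karyotype(path) -> Karyotype:
    with open(path, encoding="utf-8") as fh:
        return parse_karyotype(fh.read())


def write_karyotype(k: Karyotype) -> str:
    """Serialize to the ``.karyo`` dialect (inverse of :func:`parse_karyotype`
    up to comments)."""
    lines = [f"species: {k.species_id}"]
    if k.host:
        lines.append(f"host: {k.host}")
    for chrom in k.chromosomes:
        toks = []
        for e in chrom.elements:
            if isinstance(e, NonCodingRegion):
                toks.append(f"NCR:{e.length}" + (f":{e.label}" if e.label else ""))
            else:
                toks.append(e.token)
        size = f" ({chrom.total_size_bp} bp)" if chrom.total_size_bp else ""
        lines.append(f"{chrom.label}{size}: {' '.join(toks)}")
    return "\n".join(lines) + "\n"


def write_grimm(karyotypes: list[Karyotype]) -> str:
    """GRIMM-style export: signed gene orders, one chromosome per line."""
    blocks = []
    for k in karyotypes:
        lines = [f">{k.species_id}"]
        for chrom in k.chromosomes:
            toks = [
                ("-" if s < 0 else "") + grimm_token(g)
                for g, s in chrom.signed_genes()
            ]
            lines.append(" ".join(toks) + " $")
        blocks.append("\n".join(lines))
    return "\n".join(blocks) + "\n"
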