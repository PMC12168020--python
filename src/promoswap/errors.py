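"""Exception hierarchy shared across the toolkit."""


class PromoswapError(ValueError):
    """Base class for all toolkit errors."""


class ParseError(PromoswapError):
    """A file could not be parsed (FASTA/GFF3/FASTQ/table)."""


class DesignError(PromoswapError):
    """A guide or construct cannot be designed under the stated constraints."""


class AssemblyError(PromoswapError):
    """A digestion/ligation step is inconsistent (wrong overhangs, stray sites)."""


class QCError(PromoswapError):
    """Library QC input is inconsistent (empty pool, duplicate constructs, bad reads)."""
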