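"""Small file-format helpers shared across the pipeline."""

from __future__ import annotations

from pyfaidx import Fasta


def load_fasta(path) -> dict[str, str]:
    """Read a FASTA into an upper-case contig-name -> sequence mapping."""
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}
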