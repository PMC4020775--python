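"""Bundled reference annotations."""

from __future__ import annotations

import tempfile
from importlib import resources
from pathlib import Path

from .annotation_io import MitogenomeRecord, parse_feature_table


def atta_laevigata_path() -> Path:
    """Filesystem path of the bundled *Atta laevigata* feature table."""
    source = resources.files("mitoarch.data").joinpath("atta_laevigata_kc346251.tsv")
    with resources.as_file(source) as p:
        if p.exists():
            return Path(p)
    # resources may hand back an ephemeral extraction; fall back to a copy
    tmp = Path(tempfile.mkdtemp()) / "atta_laevigata_kc346251.tsv"
    tmp.write_text(source.read_text())
    return tmp


def atta_laevigata() -> MitogenomeRecord:
    """The published *A. laevigata* mitogenome annotation (18,729 bp, 37 genes).

    Coordinates, strands and PCG start/stop codons as deposited for
    GenBank accession KC346251; the record carries no sequence.
    """
    return parse_feature_table(atta_laevigata_path())
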