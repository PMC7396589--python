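"""Small shared I/O helpers: transparent gzip handling for text formats."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Union

PathLike = Union[str, Path]

_GZIP_MAGIC = b"\x1f\x8b"


def open_text(path: PathLike, mode: str = "rt") -> IO[str]:
    """Open a possibly gzip-compressed text file.

    Writing: compression is chosen by the ``.gz`` suffix.
    Reading: the gzip magic bytes are sniffed, so a mislabelled file still opens.
    """
    path = Path(path)
    if "r" in mode:
        with open(path, "rb") as probe:
            magic = probe.read(2)
        if magic == _GZIP_MAGIC:
            return gzip.open(path, mode)
        return open(path, mode)
    if path.suffix == ".gz":
        # level 1: these are scratch/intermediate artifacts, speed over ratio
        return gzip.open(path, mode, compresslevel=1)
    return open(path, mode)
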