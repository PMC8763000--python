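"""Reading and writing of GMT gene-set files.

GMT is the tab-separated convention used by MSigDB and GSEA: one set per
line, ``name<TAB>description<TAB>gene1<TAB>gene2...``.
"""

from __future__ import annotations

import os
from typing import Sequence


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read a GMT file into an ordered ``{set name: gene list}`` mapping."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{ln}: GMT line needs name, description and >=1 gene"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{ln}: duplicate gene-set name {name!r}")
            sets[name] = [g for g in fields[2:] if g]
    return sets


def write_gmt(
    sets: dict[str, Sequence[str]], path: str | os.PathLike, description: str = "na"
) -> None:
    """Write ``{set name: gene list}`` to a GMT file."""
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *map(str, genes)]) + "\n")
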