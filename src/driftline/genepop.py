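"""GENEPOP file reader/writer.

Supports the classic layout: a title line, one locus name per line (or
a single comma-separated line), ``Pop`` markers, and individual lines
``name , 010012 030030 ...`` with alleles as fixed-width 2- or 3-digit
codes; 00/000 marks a missing allele. Population labels are taken from
the name of each Pop block's last individual, per convention, unless
explicit ``pop_labels`` are given at write time.
"""

from __future__ import annotations

import numpy as np

from .popgen import GenotypeTable


def read_genepop(path) -> GenotypeTable:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if len(lines) < 3:
        raise ValueError("not a GENEPOP file: too short")
    title = lines[0]
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        loci.extend(x.strip() for x in lines[i].split(",") if x.strip())
        i += 1
    if i == len(lines):
        raise ValueError("no 'Pop' marker found")
    blocks: list[list[tuple[str, list[str]]]] = []
    current: list[tuple[str, list[str]]] = []
    for ln in lines[i:]:
        if ln.strip().lower() == "pop":
            if current:
                blocks.append(current)
            current = []
            continue
        if "," not in ln:
            raise ValueError(f"malformed individual line: {ln!r}")
        name, rest = ln.split(",", 1)
        toks = rest.split()
        if len(toks) != len(loci):
            raise ValueError(f"{name.strip()}: expected {len(loci)} loci, got {len(toks)}")
        current.append((name.strip(), toks))
    if current:
        blocks.append(current)

    ids, pops, rows = [], [], []
    for b, block in enumerate(blocks):
        label = block[-1][0] or f"pop_{b}"
        for name, toks in block:
            ids.append(name)
            pops.append(label)
            row = []
            for t in toks:
                if len(t) not in (4, 6):
                    raise ValueError(f"bad allele token {t!r} (need 4 or 6 digits)")
                w = len(t) // 2
                row.append((int(t[:w]), int(t[w:])))
            rows.append(row)
    return GenotypeTable(alleles=np.array(rows, dtype=np.int16),
                         pops=np.array(pops), ids=ids, loci=loci)


def write_genepop(table: GenotypeTable, path, title: str = "driftline export",
                  digits: int = 3) -> None:
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    if int(table.alleles.max()) >= 10 ** digits:
        raise ValueError("allele codes too large for the chosen digit width")
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for loc in table.loci:
            fh.write(str(loc) + "\n")
        for p in table.pop_names:
            fh.write("Pop\n")
            idx = np.flatnonzero(table.pops == p)
            for k, i in enumerate(idx):
                # convention: the block's label is its last individual's name
                name = str(p) if k == len(idx) - 1 else str(table.ids[i])
                geno = " ".join(f"{a:0{digits}d}{b:0{digits}d}"
                                for a, b in table.alleles[i])
                fh.write(f"{name} , {geno}\n")
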