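"""File formats: matrix TSV, BED-like annotation TSV, GMT term sets, band
TSV, Newick trees and JSON reports.

All files are UTF-8, tab-separated with '.' decimal.  Floats are written with
``repr`` (shortest round-tripping form) and missing values as ``NA``, so
write(read(x)) is byte-identical for files produced by these writers.
Annotation coordinates are 1-based closed by default, declared in a header
comment; ``bed_strict`` switches to 0-based half-open BED on disk.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cgh import ANNOTATION_COLUMNS, validate_annotation
from .enrichment import Term, TermCollection
from .karyotype import BandPattern

__all__ = [
    "FormatError",
    "read_matrix_tsv", "write_matrix_tsv",
    "read_annotation_tsv", "write_annotation_tsv",
    "read_gmt", "write_gmt",
    "read_bands_tsv", "write_bands_tsv",
    "read_json", "write_json",
    "NewickNode", "parse_newick", "write_newick_node",
]

_COORD_COMMENT = "# coordinates: 1-based, closed"


class FormatError(ValueError):
    """Input file violates its format; message carries file and line."""


def _fmt(value: float) -> str:
    if isinstance(value, float) and math.isnan(value):
        return "NA"
    return repr(float(value))


def _parse_float(token: str, path, lineno: int, what: str) -> float:
    if token == "NA":
        return math.nan
    try:
        return float(token)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: non-numeric {what}: {token!r}") from None


def _read_rows(path) -> list[tuple[int, list[str]]]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rows.append((lineno, line.split("\t")))
    if not rows:
        raise FormatError(f"{path}: empty file")
    return rows


# -- log2-ratio matrix ------------------------------------------------------

def read_matrix_tsv(path) -> pd.DataFrame:
    rows = _read_rows(path)
    lineno, header = rows[0]
    if header[0] != "gene_id" or len(header) < 2:
        raise FormatError(
            f"{path}:{lineno}: matrix header must start with 'gene_id' "
            "followed by strain ids"
        )
    strains = header[1:]
    if len(set(strains)) != len(strains):
        raise FormatError(f"{path}:{lineno}: duplicate strain ids in header")
    genes, data = [], []
    for lineno, fields in rows[1:]:
        if len(fields) != len(header):
            raise FormatError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        genes.append(fields[0])
        data.append(
            [_parse_float(t, path, lineno, "log2 ratio") for t in fields[1:]]
        )
    if len(set(genes)) != len(genes):
        raise FormatError(f"{path}: duplicate gene ids")
    return pd.DataFrame(
        np.array(data, dtype=float) if data else np.empty((0, len(strains))),
        index=pd.Index(genes, name="gene_id"),
        columns=strains,
    )


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(str(c) for c in matrix.columns) + "\n")
        for gene, row in zip(matrix.index, matrix.to_numpy(dtype=float)):
            fh.write(str(gene) + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


# -- genome annotation ------------------------------------------------------

def read_annotation_tsv(path, bed_strict: bool = False) -> pd.DataFrame:
    rows = _read_rows(path)
    lineno, header = rows[0]
    expected = ["chromosome", "start", "end", "gene_id", "subtelomeric"]
    if header != expected:
        raise FormatError(f"{path}:{lineno}: annotation header must be {expected}")
    out = []
    for lineno, fields in rows[1:]:
        if len(fields) != 5:
            raise FormatError(f"{path}:{lineno}: expected 5 fields, got {len(fields)}")
        try:
            chrom, start, end = int(fields[0]), int(fields[1]), int(fields[2])
            subtel = int(fields[4])
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: chromosome/start/end/subtelomeric must be integers"
            ) from None
        if subtel not in (0, 1):
            raise FormatError(f"{path}:{lineno}: subtelomeric flag must be 0 or 1")
        if bed_strict:
            start = start + 1  # 0-based half-open on disk -> 1-based closed
        out.append((fields[3], chrom, start, end, subtel))
    ann = pd.DataFrame(out, columns=list(ANNOTATION_COLUMNS))
    return validate_annotation(ann)


def write_annotation_tsv(annotation: pd.DataFrame, path, bed_strict: bool = False) -> None:
    validate_annotation(annotation)
    with open(path, "w", encoding="utf-8") as fh:
        if not bed_strict:
            fh.write(_COORD_COMMENT + "\n")
        fh.write("chromosome\tstart\tend\tgene_id\tsubtelomeric\n")
        for row in annotation.itertuples(index=False):
            start = row.start - 1 if bed_strict else row.start
            fh.write(
                f"{row.chromosome}\t{start}\t{row.end}\t{row.gene_id}\t"
                f"{int(row.subtelomeric)}\n"
            )


# -- GMT term sets ----------------------------------------------------------

def read_gmt(path) -> TermCollection:
    terms = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs id, description and >= 1 gene"
                )
            terms.append(
                Term(term_id=fields[0], name=fields[1],
                     members=frozenset(fields[2:]))
            )
    try:
        return TermCollection(terms)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_gmt(terms: TermCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in terms:
            fh.write(
                term.term_id + "\t" + term.name + "\t"
                + "\t".join(sorted(term.members)) + "\n"
            )


# -- band patterns ----------------------------------------------------------

def read_bands_tsv(path) -> list[BandPattern]:
    rows = _read_rows(path)
    lineno, header = rows[0]
    if header != ["strain_id", "band_sizes_kb"]:
        raise FormatError(
            f"{path}:{lineno}: bands header must be ['strain_id', 'band_sizes_kb']"
        )
    patterns = []
    seen = set()
    for lineno, fields in rows[1:]:
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
        strain = fields[0]
        if strain in seen:
            raise FormatError(f"{path}:{lineno}: duplicate strain id {strain!r}")
        seen.add(strain)
        sizes = tuple(
            _parse_float(tok, path, lineno, "band size")
            for tok in fields[1].split(",")
            if tok != ""
        )
        try:
            patterns.append(BandPattern(strain_id=strain, band_sizes_kb=sizes))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    return patterns


def write_bands_tsv(patterns, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("strain_id\tband_sizes_kb\n")
        for p in patterns:
            fh.write(
                p.strain_id + "\t" + ",".join(_fmt(s) for s in p.band_sizes_kb) + "\n"
            )


# -- JSON -------------------------------------------------------------------

def read_json(path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


# -- Newick -----------------------------------------------------------------

@dataclass
class NewickNode:
    """Generic parsed Newick tree node (children empty for leaves)."""

    label: str = ""
    length: float | None = None
    children: list["NewickNode"] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.children is None:
            self.children = []

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.label]
        out = []
        for child in self.children:
            out.extend(child.leaves())
        return out


def parse_newick(text: str) -> NewickNode:
    s = text.strip()
    if not s.endswith(";"):
        raise FormatError("Newick string must end with ';'")
    s = s[:-1]
    pos = 0

    def parse_node() -> NewickNode:
        nonlocal pos
        node = NewickNode()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if pos >= len(s):
                    raise FormatError("unbalanced parentheses in Newick string")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise FormatError(f"unexpected character {s[pos]!r} in Newick string")
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        node.label = s[start:pos]
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            try:
                node.length = float(s[start:pos])
            except ValueError:
                raise FormatError(
                    f"bad branch length {s[start:pos]!r} in Newick string"
                ) from None
        return node

    root = parse_node()
    if pos != len(s):
        raise FormatError("trailing characters in Newick string")
    return root


def write_newick_node(node: NewickNode) -> str:
    def render(n: NewickNode) -> str:
        if n.children:
            body = "(" + ",".join(render(c) for c in n.children) + ")" + n.label
        else:
            body = n.label
        if n.length is not None:
            body += ":" + format(n.length, ".12g")
        return body

    return render(node) + ";"
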