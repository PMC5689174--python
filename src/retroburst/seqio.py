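"""Readers/writers for the plain-text formats shared by all pipeline stages.

FASTA is read with Biopython; GFF3 writing/parsing is handled here because
the pipeline uses a single, small feature schema (``LTR_retrotransposon``
records with ``long_terminal_repeat`` children) rather than arbitrary GFF.

Coordinates are 0-based half-open everywhere in memory and converted to
1-based inclusive on the way to/from GFF3.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio import SeqIO

NUCLEOTIDES = set("ACGTN")

GFF_SOURCE = "retroburst"
ELEMENT_TYPE = "LTR_retrotransposon"
LTR_TYPE = "long_terminal_repeat"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> List[Tuple[str, str]]:
    """Read a FASTA file into ``[(sequence_id, sequence), ...]``.

    Sequences are uppercased; ids must be unique and sequences non-empty.
    """
    records: List[Tuple[str, str]] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for {rec.id!r} in {path}")
        records.append((rec.id, seq))
    return records


def write_fasta(path, records: Iterable[Tuple[str, str]], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 element annotations


@dataclass
class ElementAnnotation:
    """Neutral element record used as the GFF3 interchange unit.

    ``start``/``end`` and the LTR intervals are 0-based half-open on the
    genome sequence named by ``seq_id``.  ``attributes`` carries stage
    outputs (Family, Age, TSD, Superfamily, ...) as strings.
    """

    element_id: str
    seq_id: str
    start: int
    end: int
    ltr5: Optional[Tuple[int, int]] = None
    ltr3: Optional[Tuple[int, int]] = None
    attributes: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad element interval [{self.start}, {self.end})")
        for name, iv in (("ltr5", self.ltr5), ("ltr3", self.ltr3)):
            if iv is not None and not (self.start <= iv[0] < iv[1] <= self.end):
                raise ValueError(f"{name} interval {iv} outside element")


def _fmt_attrs(attrs: Dict[str, str]) -> str:
    def esc(v: str) -> str:
        return str(v).replace(";", "%3B").replace("=", "%3D")

    return ";".join(f"{k}={esc(v)}" for k, v in attrs.items())


def _parse_attrs(text: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            raise FormatError(f"malformed GFF3 attribute {part!r}")
        k, v = part.split("=", 1)
        out[k] = v.replace("%3B", ";").replace("%3D", "=")
    return out


def write_elements_gff(path, elements: Sequence[ElementAnnotation]) -> None:
    """Write elements and their LTR children as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for el in elements:
            attrs = {"ID": el.element_id, **el.attributes}
            fh.write(
                "\t".join(
                    [
                        el.seq_id,
                        GFF_SOURCE,
                        ELEMENT_TYPE,
                        str(el.start + 1),
                        str(el.end),
                        ".",
                        "+",
                        ".",
                        _fmt_attrs(attrs),
                    ]
                )
                + "\n"
            )
            for tag, iv in (("five_prime", el.ltr5), ("three_prime", el.ltr3)):
                if iv is None:
                    continue
                child = {"ID": f"{el.element_id}.ltr_{tag}", "Parent": el.element_id}
                fh.write(
                    "\t".join(
                        [
                            el.seq_id,
                            GFF_SOURCE,
                            LTR_TYPE,
                            str(iv[0] + 1),
                            str(iv[1]),
                            ".",
                            "+",
                            ".",
                            _fmt_attrs(child),
                        ]
                    )
                    + "\n"
                )


def read_elements_gff(path) -> List[ElementAnnotation]:
    """Parse a GFF3 file written by :func:`write_elements_gff`."""
    elements: Dict[str, ElementAnnotation] = {}
    ltrs: List[Tuple[str, str, int, int]] = []  # (parent, which, start, end)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns")
            seq_id, _src, ftype, start, end, _score, _strand, _phase, attr_s = cols
            start_i, end_i = int(start) - 1, int(end)
            if end_i <= start_i:
                raise FormatError(f"{path}:{lineno}: end < start")
            attrs = _parse_attrs(attr_s)
            if ftype == ELEMENT_TYPE:
                eid = attrs.pop("ID")
                elements[eid] = ElementAnnotation(
                    element_id=eid, seq_id=seq_id, start=start_i, end=end_i, attributes=attrs
                )
            elif ftype == LTR_TYPE:
                parent = attrs.get("Parent")
                if parent is None:
                    raise FormatError(f"{path}:{lineno}: LTR feature without Parent")
                which = "five" if "five" in attrs.get("ID", "") else "three"
                ltrs.append((parent, which, start_i, end_i))
    for parent, which, s, e in ltrs:
        if parent not in elements:
            raise FormatError(f"LTR child references unknown element {parent!r}")
        el = elements[parent]
        if which == "five":
            el.ltr5 = (s, e)
        else:
            el.ltr3 = (s, e)
    out = list(elements.values())
    out.sort(key=lambda el: (el.seq_id, el.start, el.end, el.element_id))
    return out


# ---------------------------------------------------------------------------
# TSV


def write_tsv(path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        for row in rows:
            w.writerow(row)


def read_tsv(path, expect_header: bool = True) -> Tuple[List[str], List[List[str]]]:
    with open(path, newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        rows = [row for row in r if row]
    if not rows:
        return [], []
    if expect_header:
        return rows[0], rows[1:]
    return [], rows


# ---------------------------------------------------------------------------
# Structural validation (pipeline `validate` subcommand)

_NEWICK_LEAF = re.compile(r"[(,]\s*([^(),:;]+)")


def validate_formats(path, format_name: str) -> List[str]:
    """Structurally validate a file; returns diagnostics (empty = clean)."""
    diags: List[str] = []
    if format_name == "FASTA":
        seen = set()
        name = None
        nbases = 0
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if line.startswith(">"):
                    if name is not None and nbases == 0:
                        diags.append(f"line {lineno}: empty sequence for {name!r}")
                    name = line[1:].split()[0] if len(line) > 1 else ""
                    if not name:
                        diags.append(f"line {lineno}: empty FASTA header")
                    elif name in seen:
                        diags.append(f"line {lineno}: duplicate id {name!r}")
                    seen.add(name)
                    nbases = 0
                elif line:
                    if name is None:
                        diags.append(f"line {lineno}: sequence before header")
                        name = ""
                    bad = set(line.upper()) - NUCLEOTIDES
                    if bad:
                        diags.append(f"line {lineno}: illegal characters {sorted(bad)}")
                    nbases += len(line)
            if name is not None and nbases == 0:
                diags.append(f"end of file: empty sequence for {name!r}")
    elif format_name == "GFF3":
        ids = set()
        parents: List[Tuple[int, str]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) != 9:
                    diags.append(f"line {lineno}: expected 9 columns, got {len(cols)}")
                    continue
                try:
                    start, end = int(cols[3]), int(cols[4])
                except ValueError:
                    diags.append(f"line {lineno}: non-integer coordinates")
                    continue
                if start < 1:
                    diags.append(f"line {lineno}: start < 1 (GFF3 is 1-based)")
                if end < start:
                    diags.append(f"line {lineno}: end < start")
                try:
                    attrs = _parse_attrs(cols[8])
                except FormatError as exc:
                    diags.append(f"line {lineno}: {exc}")
                    continue
                if "ID" in attrs:
                    ids.add(attrs["ID"])
                if "Parent" in attrs:
                    parents.append((lineno, attrs["Parent"]))
        for lineno, parent in parents:
            if parent not in ids:
                diags.append(f"line {lineno}: Parent={parent!r} references unknown ID")
    elif format_name == "newick":
        text = open(path).read().strip()
        depth = 0
        for ch in text:
            depth += ch == "("
            depth -= ch == ")"
            if depth < 0:
                diags.append("unbalanced parentheses (extra ')')")
                break
        if depth > 0:
            diags.append("unbalanced parentheses (unclosed '(')")
        if not text.endswith(";"):
            diags.append("missing terminating ';'")
        leaves = [m.group(1).strip() for m in _NEWICK_LEAF.finditer(text)]
        if not any(leaves):
            diags.append("no labeled leaves found")
    elif format_name == "TSV":
        widths = set()
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    widths.add(len(line.rstrip("\n").split("\t")))
        if len(widths) > 1:
            diags.append(f"inconsistent column counts: {sorted(widths)}")
    else:
        raise ValueError(f"unknown format {format_name!r}")
    return diags
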