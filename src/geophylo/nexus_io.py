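"""Reading and writing the NEXUS dialect used for geophylogenies.

The input is a NEXUS file carrying (a) a TAXA block or implicit taxa, (b) a
TREES block with one or more Newick trees and an optional TRANSLATE table,
(c) a CHARACTERS block of ``DATATYPE=GEOGRAPHIC`` (the Mesquite Cartographer
convention) giving a latitude/longitude pair per OTU, and (d) optionally a
NOTES block whose ALTTAXNAMES commands group OTUs into taxa (e.g. several
barcode sequences belonging to one species).

Dialect notes
-------------
* Keywords are case-insensitive; ``[...]`` comments are stripped before
  tokenisation except the rooting hints ``[&R]``/``[&U]`` inside TREE
  commands, which are captured.
* Quoted labels are preserved verbatim (``''`` escapes a quote); unquoted
  underscores read as spaces, per standard NEXUS practice.
* The GEOGRAPHIC matrix accepts plain ``lat lon`` pairs or parenthesised
  ``(lat lon)`` tuples; ``?`` in either column means the OTU has no
  locality.  CHARSTATELABELS may swap the column-to-axis assignment; the
  default is column 1 = latitude, column 2 = longitude.  An OTU may appear
  on several rows, one occurrence per row; NTAX counts distinct OTUs.
* Mesquite's exact ALTTAXNAMES syntax varies; this module emits a simple
  documented form (``ALTTAXNAMES TAXON = <name> OTUS = <otu> ...;``) and
  parses NOTES tolerantly — an ALTTAXNAMES command it cannot understand is
  skipped with a warning, never fatal.
"""

from __future__ import annotations

import re
from typing import Dict, List, Optional, Sequence, Tuple

from .model import GeoCoordinate, NexusDocument, OccurrenceSet, PhyloTree


class NexusError(ValueError):
    """Malformed or unconvertible NEXUS input."""


# ---------------------------------------------------------------------------
# low-level text handling


def strip_comments(text: str) -> str:
    """Remove [bracketed] comments (nesting allowed), outside quoted labels.

    The rooting hints ``[&R]`` and ``[&U]`` are kept so the tree parser can
    see them.
    """
    out: List[str] = []
    i, n = 0, len(text)
    in_quote = False
    while i < n:
        ch = text[i]
        if in_quote:
            out.append(ch)
            if ch == "'":
                if i + 1 < n and text[i + 1] == "'":
                    out.append("'")
                    i += 1
                else:
                    in_quote = False
            i += 1
        elif ch == "'":
            in_quote = True
            out.append(ch)
            i += 1
        elif ch == "[":
            m = re.match(r"\[&[RU]\]", text[i:], re.IGNORECASE)
            if m:
                out.append(m.group(0))
                i += m.end()
                continue
            depth = 1
            i += 1
            while i < n and depth:
                if text[i] == "[":
                    depth += 1
                elif text[i] == "]":
                    depth -= 1
                i += 1
            if depth:
                raise NexusError("unterminated [comment]")
        else:
            out.append(ch)
            i += 1
    return "".join(out)


def _split_commands(block: str) -> List[str]:
    """Split block content into ;-terminated commands, respecting quotes."""
    cmds: List[str] = []
    buf: List[str] = []
    in_quote = False
    i, n = 0, len(block)
    while i < n:
        ch = block[i]
        if in_quote:
            buf.append(ch)
            if ch == "'":
                if i + 1 < n and block[i + 1] == "'":
                    buf.append("'")
                    i += 1
                else:
                    in_quote = False
        elif ch == "'":
            in_quote = True
            buf.append(ch)
        elif ch == ";":
            cmd = "".join(buf).strip()
            if cmd:
                cmds.append(cmd)
            buf = []
        else:
            buf.append(ch)
        i += 1
    tail = "".join(buf).strip()
    if tail:
        cmds.append(tail)
    return cmds


_BARE_LABEL = re.compile(r"[A-Za-z0-9.\-]+\Z")
_UNDERSCORABLE = re.compile(r"[A-Za-z0-9.\- ]+\Z")


def quote_label(label: str) -> str:
    """Write a label the shortest way that reads back identically."""
    if label and _BARE_LABEL.match(label) and label.upper() not in ("AND",):
        return label
    if label and "_" not in label and _UNDERSCORABLE.match(label):
        return label.replace(" ", "_")
    return "'" + label.replace("'", "''") + "'"


def _tokenize(text: str) -> List[str]:
    """Tokens: quoted labels (unquoted, verbatim), punctuation, bare words.

    Bare-word underscores are converted to spaces here; callers treating a
    token as a keyword or number are unaffected (those contain none).
    """
    tokens: List[str] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch == "'":
            j = i + 1
            buf: List[str] = []
            while j < n:
                if text[j] == "'":
                    if j + 1 < n and text[j + 1] == "'":
                        buf.append("'")
                        j += 2
                    else:
                        j += 1
                        break
                else:
                    buf.append(text[j])
                    j += 1
            else:
                raise NexusError("unterminated quoted label")
            tokens.append("".join(buf))
            i = j
        elif ch in "(),=;":
            tokens.append(ch)
            i += 1
        else:
            j = i
            while j < n and not text[j].isspace() and text[j] not in "(),=;'":
                j += 1
            tokens.append(text[i:j].replace("_", " "))
            i = j
    return tokens


# ---------------------------------------------------------------------------
# Newick


def parse_newick(newick: str, translate: Optional[Dict[str, str]] = None) -> PhyloTree:
    """Parse a Newick string (optionally with a TRANSLATE table) into a tree.

    Accepts quoted labels, branch lengths, internal-node labels, and a
    leading ``[&R]``/``[&U]`` rooting annotation.  Errors report the
    character offset at fault.
    """
    translate = translate or {}
    tree = PhyloTree()
    s = newick.strip()
    m = re.match(r"\[&([RU])\]\s*", s, re.IGNORECASE)
    if m:
        tree.rooted = m.group(1).upper() == "R"
        s = s[m.end():]
    pos = 0
    n = len(s)

    def err(msg: str) -> NexusError:
        return NexusError(f"Newick parse error at offset {pos}: {msg}")

    def skip_ws() -> None:
        nonlocal pos
        while pos < n and s[pos].isspace():
            pos += 1

    def read_label() -> Optional[str]:
        nonlocal pos
        skip_ws()
        if pos >= n:
            return None
        if s[pos] == "'":
            j = pos + 1
            buf: List[str] = []
            while j < n:
                if s[j] == "'":
                    if j + 1 < n and s[j + 1] == "'":
                        buf.append("'")
                        j += 2
                    else:
                        j += 1
                        pos = j
                        return "".join(buf)
                else:
                    buf.append(s[j])
                    j += 1
            raise err("unterminated quoted label")
        j = pos
        while j < n and s[j] not in "(),:;[" and not s[j].isspace():
            j += 1
        if j == pos:
            return None
        token = s[pos:j]
        pos = j
        return token.replace("_", " ")

    def read_length() -> Optional[float]:
        nonlocal pos
        skip_ws()
        if pos < n and s[pos] == ":":
            pos += 1
            skip_ws()
            j = pos
            while j < n and (s[j] in "+-.eE" or s[j].isdigit()):
                j += 1
            try:
                val = float(s[pos:j])
            except ValueError:
                raise err(f"bad branch length {s[pos:j]!r}")
            pos = j
            return val
        return None

    def resolve(label: str) -> str:
        if translate:
            if label in translate:
                return translate[label]
            raise err(f"unknown TRANSLATE token {label!r}")
        return label

    def parse_clade(parent: Optional[int]) -> int:
        nonlocal pos
        skip_ws()
        if pos < n and s[pos] == "(":
            pos += 1
            nid = tree.add_node(parent=parent)
            while True:
                parse_clade(nid)
                skip_ws()
                if pos < n and s[pos] == ",":
                    pos += 1
                    continue
                if pos < n and s[pos] == ")":
                    pos += 1
                    break
                raise err("expected ',' or ')'")
            label = read_label()  # internal label, not translated
            if label:
                tree.node(nid).label = label
            tree.node(nid).length = read_length()
            return nid
        label = read_label()
        if label is None:
            raise err("expected a leaf label or '('")
        nid = tree.add_node(parent=parent, label=resolve(label))
        tree.node(nid).length = read_length()
        return nid

    parse_clade(None)
    skip_ws()
    if pos >= n or s[pos] != ";":
        raise err("expected terminating ';'")
    pos += 1
    skip_ws()
    if pos != n:
        raise err("trailing characters after ';'")
    labels = tree.leaf_labels()
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise NexusError(f"duplicate leaf labels: {dupes}")
    return tree


# ---------------------------------------------------------------------------
# blocks


_BLOCK_RE = re.compile(r"\bBEGIN\s+(\w+)\s*;(.*?)\bEND\s*;", re.IGNORECASE | re.DOTALL)


def _find_blocks(text: str) -> List[Tuple[str, str]]:
    return [(m.group(1).upper(), m.group(2)) for m in _BLOCK_RE.finditer(text)]


def _parse_taxa_block(content: str) -> List[str]:
    for cmd in _split_commands(content):
        tokens = _tokenize(cmd)
        if tokens and tokens[0].upper() == "TAXLABELS":
            return tokens[1:]
    return []


def _parse_trees_block(content: str) -> List[Tuple[str, PhyloTree]]:
    translate: Dict[str, str] = {}
    trees: List[Tuple[str, PhyloTree]] = []
    for cmd in _split_commands(content):
        head = cmd.split(None, 1)[0].upper() if cmd.split() else ""
        if head == "TRANSLATE":
            body = cmd.split(None, 1)[1] if len(cmd.split(None, 1)) > 1 else ""
            tokens = _tokenize(body)
            entries: List[List[str]] = [[]]
            for tok in tokens:
                if tok == ",":
                    entries.append([])
                else:
                    entries[-1].append(tok)
            for entry in entries:
                if len(entry) == 2:
                    translate[entry[0]] = entry[1]
                elif entry:
                    raise NexusError(f"bad TRANSLATE entry: {entry!r}")
        elif head == "TREE":
            m = re.match(r"TREE\s+('[^']*'|\S+)\s*=\s*(.*)", cmd, re.IGNORECASE | re.DOTALL)
            if not m:
                raise NexusError(f"malformed TREE command: {cmd[:60]!r}")
            name = m.group(1).strip("'")
            payload = m.group(2).strip()
            if not payload.endswith(";"):
                payload += ";"
            trees.append((name, parse_newick(payload, translate or None)))
    return trees


def _to_float(token: str) -> float:
    # tolerate the unicode minus sign that typeset tables sometimes carry
    return float(token.replace("−", "-"))


def parse_geographic_matrix(content: str) -> Tuple[OccurrenceSet, List[str]]:
    """Parse a CHARACTERS block of DATATYPE=GEOGRAPHIC.

    Returns the occurrence set plus warnings (OTUs with missing
    coordinates).  Raises if the datatype is not geographic, a cell is
    non-numeric, or the distinct-OTU count disagrees with NTAX.
    """
    ntax: Optional[int] = None
    lat_col = 0  # default: column 1 = latitude
    is_geo = False
    matrix_tokens: Optional[List[str]] = None
    for cmd in _split_commands(content):
        parts = cmd.split(None, 1)
        head = parts[0].upper() if parts else ""
        rest = parts[1] if len(parts) > 1 else ""
        if head == "DIMENSIONS":
            m = re.search(r"NTAX\s*=\s*(\d+)", rest, re.IGNORECASE)
            if m:
                ntax = int(m.group(1))
            m = re.search(r"NCHAR\s*=\s*(\d+)", rest, re.IGNORECASE)
            if m and int(m.group(1)) != 2:
                raise NexusError(f"geographic matrix must have NCHAR=2, got {m.group(1)}")
        elif head == "FORMAT":
            m = re.search(r"DATATYPE\s*=\s*(\w+)", rest, re.IGNORECASE)
            if m and m.group(1).upper() == "GEOGRAPHIC":
                is_geo = True
        elif head == "CHARSTATELABELS":
            tokens = _tokenize(rest)
            entries: List[List[str]] = [[]]
            for tok in tokens:
                if tok == ",":
                    entries.append([])
                else:
                    entries[-1].append(tok)
            for entry in entries:
                if len(entry) >= 2 and entry[0] == "1":
                    if entry[1].lower().startswith("lon"):
                        lat_col = 1
                    elif entry[1].lower().startswith("lat"):
                        lat_col = 0
        elif head == "MATRIX":
            matrix_tokens = _tokenize(rest)
    if not is_geo:
        raise NexusError("CHARACTERS block is not DATATYPE=GEOGRAPHIC")
    if matrix_tokens is None:
        raise NexusError("CHARACTERS block has no MATRIX command")

    occ = OccurrenceSet()
    warnings: List[str] = []
    seen_otus: Dict[str, None] = {}
    i, n = 0, len(matrix_tokens)
    while i < n:
        label = matrix_tokens[i]
        i += 1
        vals: List[str] = []
        while len(vals) < 2 and i < n:
            tok = matrix_tokens[i]
            if tok == "(":
                i += 1
                continue
            if tok == ")":
                i += 1
                continue
            vals.append(tok)
            i += 1
        if len(vals) != 2:
            raise NexusError(f"matrix row for {label!r} does not have 2 values")
        # swallow a trailing ')'
        if i < n and matrix_tokens[i] == ")":
            i += 1
        seen_otus.setdefault(label)
        if "?" in vals:
            warnings.append(f"OTU {label!r} has missing coordinates; no point will be drawn")
            continue
        try:
            a, b = _to_float(vals[0]), _to_float(vals[1])
        except ValueError:
            raise NexusError(f"non-numeric coordinate in row for {label!r}: {vals!r}")
        lat, lon = (a, b) if lat_col == 0 else (b, a)
        try:
            occ.records.append((label, GeoCoordinate(lon=lon, lat=lat)))
        except ValueError as exc:
            raise NexusError(f"row for {label!r}: {exc}")
    if ntax is not None and len(seen_otus) != ntax:
        raise NexusError(
            f"matrix names {len(seen_otus)} distinct OTUs but DIMENSIONS declares NTAX={ntax}"
        )
    return occ, warnings


def parse_alt_taxa(content: str) -> Tuple[Dict[str, str], List[str]]:
    """Parse ALTTAXNAMES commands from a NOTES block (tolerantly).

    Understands the dialect this package writes —
    ``ALTTAXNAMES TAXON = <name> OTUS = <otu> <otu> ...;`` — and skips, with
    a warning, any ALTTAXNAMES command it cannot interpret.  An OTU assigned
    to two different taxa is an error; repeated identical assignments are
    deduplicated.
    """
    mapping: Dict[str, str] = {}
    warnings: List[str] = []
    for cmd in _split_commands(content):
        parts = cmd.split(None, 1)
        if not parts or parts[0].upper() != "ALTTAXNAMES":
            continue
        tokens = _tokenize(parts[1] if len(parts) > 1 else "")
        taxon: Optional[str] = None
        otus: List[str] = []
        ok = True
        i = 0
        mode = None
        while i < len(tokens):
            tok = tokens[i]
            up = tok.upper()
            if up == "TAXON" and i + 1 < len(tokens) and tokens[i + 1] == "=":
                mode = "taxon"
                i += 2
                continue
            if up == "OTUS" and i + 1 < len(tokens) and tokens[i + 1] == "=":
                mode = "otus"
                i += 2
                continue
            if tok in ("(", ")", ","):
                i += 1
                continue
            if mode == "taxon" and taxon is None:
                taxon = tok
            elif mode == "otus":
                otus.append(tok)
            else:
                ok = False
            i += 1
        if not ok or taxon is None or not otus:
            warnings.append(f"could not interpret ALTTAXNAMES command: {cmd[:60]!r}")
            continue
        for otu in otus:
            if otu in mapping and mapping[otu] != taxon:
                raise NexusError(
                    f"OTU {otu!r} assigned to two taxa: {mapping[otu]!r} and {taxon!r}"
                )
            mapping[otu] = taxon
    return mapping, warnings


# ---------------------------------------------------------------------------
# whole documents


def parse_nexus(text: str) -> NexusDocument:
    """Parse a NEXUS document string into a :class:`NexusDocument`.

    Requires a ``#NEXUS`` header, a TREES block, and a CHARACTERS block of
    DATATYPE=GEOGRAPHIC; TAXA and NOTES blocks are optional (taxa are
    inferred from trees and the matrix when absent).
    """
    stripped_head = text.lstrip()
    if not stripped_head[:6].upper() == "#NEXUS":
        raise NexusError("not a NEXUS file: missing #NEXUS header")
    body = strip_comments(stripped_head[6:])
    blocks = _find_blocks(body)
    names = [name for name, _ in blocks]

    doc = NexusDocument()
    taxa: List[str] = []
    for name, content in blocks:
        if name == "TAXA":
            taxa = _parse_taxa_block(content)
        elif name == "TREES":
            doc.trees.extend(_parse_trees_block(content))
        elif name == "CHARACTERS":
            occ, warns = parse_geographic_matrix(content)
            doc.geo = occ
            doc.warnings.extend(warns)
        elif name == "NOTES":
            mapping, warns = parse_alt_taxa(content)
            doc.alt_names = mapping
            doc.warnings.extend(warns)

    if not doc.trees:
        raise NexusError(f"no tree: NEXUS file has no TREES block (blocks found: {names or 'none'})")
    if not doc.geo.records and "CHARACTERS" not in names:
        raise NexusError(
            f"no geographic data: no CHARACTERS block of DATATYPE=GEOGRAPHIC (blocks found: {names})"
        )

    if taxa:
        doc.taxa = taxa
    else:
        seen: Dict[str, None] = {}
        for _, tree in doc.trees:
            for lbl in tree.leaf_labels():
                seen.setdefault(lbl)
        for otu, _ in doc.geo.records:
            seen.setdefault(otu)
        doc.taxa = list(seen)

    # taxon grouping: invert alt_names (taxon -> member OTUs)
    for otu, taxon in doc.alt_names.items():
        doc.geo.grouping.setdefault(taxon, []).append(otu)

    located = set(doc.geo.located_otus())
    for _, tree in doc.trees:
        for lbl in tree.leaf_labels():
            if lbl not in located:
                msg = f"OTU {lbl!r} has no occurrence; it will be drawn without a connector"
                if msg not in doc.warnings and not any(lbl in w for w in doc.warnings):
                    doc.warnings.append(msg)

    doc.validate()
    return doc


def write_nexus(doc: NexusDocument) -> str:
    """Serialise a document to the dialect :func:`parse_nexus` reads.

    The output round-trips: ``parse_nexus(write_nexus(doc)) == doc``.
    """
    lines: List[str] = ["#NEXUS", ""]
    lines.append("BEGIN TAXA;")
    lines.append(f"\tDIMENSIONS NTAX={len(doc.taxa)};")
    lines.append("\tTAXLABELS " + " ".join(quote_label(t) for t in doc.taxa) + ";")
    lines.append("END;")
    lines.append("")
    lines.append("BEGIN TREES;")
    for name, tree in doc.trees:
        rooting = ""
        if tree.rooted is not None:
            rooting = "[&R] " if tree.rooted else "[&U] "
        lines.append(f"\tTREE {quote_label(name)} = {rooting}{tree.to_newick()}")
    lines.append("END;")
    lines.append("")
    distinct = {o: None for o, _ in doc.geo.records}
    lines.append("BEGIN CHARACTERS;")
    lines.append(f"\tDIMENSIONS NTAX={len(distinct)} NCHAR=2;")
    lines.append("\tFORMAT DATATYPE=GEOGRAPHIC MISSING=?;")
    lines.append("\tCHARSTATELABELS 1 latitude, 2 longitude;")
    lines.append("\tMATRIX")
    for otu, coord in doc.geo.records:
        lines.append(f"\t\t{quote_label(otu)} {coord.lat:.6f} {coord.lon:.6f}")
    lines.append("\t;")
    lines.append("END;")
    if doc.alt_names:
        groups: Dict[str, List[str]] = {}
        for otu, taxon in doc.alt_names.items():
            groups.setdefault(taxon, []).append(otu)
        lines.append("")
        lines.append("BEGIN NOTES;")
        for taxon, otus in groups.items():
            lines.append(
                f"\tALTTAXNAMES TAXON = {quote_label(taxon)} OTUS = "
                + " ".join(quote_label(o) for o in otus)
                + ";"
            )
        lines.append("END;")
    lines.append("")
    return "\n".join(lines)
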